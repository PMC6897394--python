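"""Grade-specific domain classification across a multi-sample panel.

Domains from a panel of cell lines labelled High-Grade or Low-Grade are
merged into union regions; a binary membership matrix (region x sample)
records which samples carry each region; regions are then classified as
common (present in all samples), High-Grade-unique (HGU), Low-Grade-unique
(LGU) or other.  The two broad domain types (super-enhancers and broad
H3K4me3) can then be overlapped within each class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet, SignalTrack, concat, merge_within, overlaps, region_signal

logger = logging.getLogger(__name__)

__all__ = [
    "SamplePanel",
    "MembershipMatrix",
    "CATEGORIES",
    "build_membership",
    "classify_regions",
    "overlap_domain_types",
    "signal_matrix",
]

HIGH = "High"
LOW = "Low"
CATEGORIES = ("common", "HGU", "LGU", "other")


@dataclass
class SamplePanel:
    """Per-sample domain sets with a High/Low group label per sample."""

    sample_ids: list[str]
    group_of: dict[str, str]
    domain_sets: dict[str, IntervalSet]

    def __post_init__(self) -> None:
        for sid in self.sample_ids:
            if sid not in self.group_of:
                raise ValueError(f"sample {sid!r} has no group label")
            if self.group_of[sid] not in (HIGH, LOW):
                raise ValueError(
                    f"group of {sid!r} must be {HIGH!r} or {LOW!r}"
                )
            if sid not in self.domain_sets:
                raise ValueError(f"sample {sid!r} has no domain set")
        groups = {self.group_of[s] for s in self.sample_ids}
        if groups != {HIGH, LOW}:
            raise ValueError("panel needs >= 1 sample in each group")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]


@dataclass
class MembershipMatrix:
    """Union regions x samples binary occupancy."""

    union_regions: IntervalSet
    occupancy: np.ndarray  # (n_regions, n_samples) of 0/1
    sample_ids: list[str]
    group_of: dict[str, str]

    def to_dataframe(self) -> pd.DataFrame:
        idx = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.union_regions]
        return pd.DataFrame(self.occupancy, index=idx, columns=self.sample_ids)


def build_membership(panel: SamplePanel, merge_gap: int = 0) -> MembershipMatrix:
    """Union regions (merged across all samples) x binary sample occupancy.

    ``occupancy[r, s] = 1`` iff sample s's domain set overlaps union region r
    by >= 1 bp.  Every row has at least one 1 by construction.
    """
    if not panel.sample_ids:
        raise ValueError("empty panel")
    union = merge_within(
        concat(panel.domain_sets[s] for s in panel.sample_ids), gap=merge_gap
    )
    occ = np.zeros((len(union), len(panel.sample_ids)), dtype=np.int8)
    for j, sid in enumerate(panel.sample_ids):
        hit, _ = overlaps(union, panel.domain_sets[sid])
        occ[:, j] = hit
    return MembershipMatrix(
        union_regions=union,
        occupancy=occ,
        sample_ids=list(panel.sample_ids),
        group_of=dict(panel.group_of),
    )


def classify_regions(
    m: MembershipMatrix,
    min_in_group: int | str = "all",
    max_in_other: int = 0,
) -> np.ndarray:
    """Label each union region common / HGU / LGU / other.

    common: present in every sample.  HGU: present in >= ``min_in_group``
    High samples ("all" = every High sample) and <= ``max_in_other`` Low
    samples; LGU symmetric.  Everything else is other.  The labels partition
    the regions, and relabelling High<->Low swaps HGU<->LGU exactly.
    """
    high_idx = [i for i, s in enumerate(m.sample_ids) if m.group_of[s] == HIGH]
    low_idx = [i for i, s in enumerate(m.sample_ids) if m.group_of[s] == LOW]
    if not high_idx or not low_idx:
        raise ValueError("both groups must be non-empty")
    n_high, n_low = len(high_idx), len(low_idx)
    k_high = n_high if min_in_group == "all" else int(min_in_group)
    k_low = n_low if min_in_group == "all" else int(min_in_group)
    if not (1 <= k_high <= n_high and 1 <= k_low <= n_low):
        raise ValueError("min_in_group out of range for a group")
    occ = m.occupancy.astype(bool)
    in_high = occ[:, high_idx].sum(axis=1)
    in_low = occ[:, low_idx].sum(axis=1)
    hgu = (in_high >= k_high) & (in_low <= max_in_other)
    lgu = (in_low >= k_low) & (in_high <= max_in_other)
    labels = np.full(len(occ), "other", dtype=object)
    # a row satisfying both rules (possible when max_in_other >= min_in_group)
    # stays "other" so High<->Low relabelling swaps HGU<->LGU exactly
    labels[hgu & ~lgu] = "HGU"
    labels[lgu & ~hgu] = "LGU"
    labels[(in_high == n_high) & (in_low == n_low)] = "common"
    return labels


def category_counts(labels: np.ndarray) -> dict[str, int]:
    return {c: int(np.sum(labels == c)) for c in CATEGORIES}


def overlap_domain_types(
    se_regions: IntervalSet,
    se_labels: np.ndarray,
    broad_regions: IntervalSet,
    broad_labels: np.ndarray,
    categories: tuple[str, ...] = CATEGORIES,
) -> pd.DataFrame:
    """Overlap SE and broad domains within each grade category.

    For each category, counts of broad-only (B), SE-only (S) and overlapping
    (B^S, >= 1 bp) regions; B^S is counted on the SE side (SE regions of the
    category overlapping >= 1 broad region of the same category).
    """
    rows = []
    for cat in categories:
        se_sub = IntervalSet(
            intervals=[iv for iv, l in zip(se_regions, se_labels) if l == cat]
        )
        br_sub = IntervalSet(
            intervals=[iv for iv, l in zip(broad_regions, broad_labels) if l == cat]
        )
        if len(se_sub) and len(br_sub):
            se_hit, _ = overlaps(se_sub, br_sub)
            br_hit, _ = overlaps(br_sub, se_sub)
        else:
            se_hit = np.zeros(len(se_sub), dtype=bool)
            br_hit = np.zeros(len(br_sub), dtype=bool)
        rows.append(
            {
                "category": cat,
                "B_only": int(np.sum(~br_hit)),
                "S_only": int(np.sum(~se_hit)),
                "B_and_S": int(np.sum(se_hit)),
            }
        )
    return pd.DataFrame(rows)


def signal_matrix(
    regions: IntervalSet,
    tracks: dict[str, SignalTrack],
    mode: str = "mean",
) -> pd.DataFrame:
    """Region x sample signal matrix; regions sorted, samples as given."""
    ivs = regions.sorted_intervals()
    data = {
        sid: [region_signal(tr, iv, mode) for iv in ivs]
        for sid, tr in tracks.items()
    }
    idx = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in ivs]
    return pd.DataFrame(data, index=idx, columns=list(tracks))
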