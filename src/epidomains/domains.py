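"""Super-enhancer and broad-H3K4me3 domain calling.

Super-enhancers are called ROSE-style: H3K27ac peaks are stitched within a
distance window (default 12.5 kb; 5 kb is a common alternative), each
stitched region is scored by input-corrected signal area, regions are ranked
by ascending score, and the cutoff is the score at the point where the
rank-normalized curve's slope first exceeds 1 ("tangent" cutoff).  Regions
scoring strictly above the cutoff are super-enhancers.

Broad H3K4me3 domains are simply the widest peaks: the top fraction
(default 5%) of peaks ranked by width.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    merge_within,
    region_signal,
    write_bed,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RankedRegionSet",
    "BroadDomainSet",
    "stitch",
    "score_regions",
    "tangent_cutoff",
    "call_super_enhancers",
    "call_broad_domains",
]

DEFAULT_STITCH_GAP = 12_500
ALT_STITCH_GAP = 5_000  # the tighter window some protocols use
DEFAULT_TOP_FRACTION = 0.05


@dataclass
class RankedRegionSet:
    """Stitched regions with scores, ascending ranks, cutoff and SE flags."""

    regions: IntervalSet
    scores: np.ndarray
    ranks: np.ndarray  # 1..n by ascending score
    cutoff_score: float = math.nan
    is_super: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def n_super(self) -> int:
        return int(np.sum(self.is_super))

    def super_regions(self) -> IntervalSet:
        ivs = [iv for iv, s in zip(self.regions, self.is_super) if s]
        return IntervalSet(
            intervals=ivs, sample_id=self.regions.sample_id, mark=self.regions.mark
        )

    def typical_regions(self) -> IntervalSet:
        ivs = [iv for iv, s in zip(self.regions, self.is_super) if not s]
        return IntervalSet(
            intervals=ivs, sample_id=self.regions.sample_id, mark=self.regions.mark
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.regions],
                "start": [iv.start for iv in self.regions],
                "end": [iv.end for iv in self.regions],
                "score": self.scores,
                "rank": self.ranks,
                "is_super": self.is_super,
            }
        )

    def write(self, prefix: str) -> None:
        """Write ranked TSV plus separate super/typical BED files."""
        self.to_dataframe().to_csv(f"{prefix}_ranked.tsv", sep="\t", index=False)
        write_bed(self.super_regions(), f"{prefix}_super.bed")
        write_bed(self.typical_regions(), f"{prefix}_typical.bed")


@dataclass
class BroadDomainSet:
    """The widest peaks: top ``top_fraction`` of peaks by width."""

    domains: IntervalSet
    widths: np.ndarray
    width_threshold: int
    top_fraction: float = DEFAULT_TOP_FRACTION

    def __len__(self) -> int:
        return len(self.domains)


def stitch(
    peaks: IntervalSet,
    stitch_gap: int = DEFAULT_STITCH_GAP,
    tss_exclude: pd.DataFrame | None = None,
    tss_flank: int = 2_500,
) -> IntervalSet:
    """Stitch peaks within ``stitch_gap`` bp into candidate enhancer regions.

    ``tss_exclude`` is an optional gene model (as produced by
    :func:`epidomains.differential.read_gene_model`); peaks lying fully inside
    any TSS +/- ``tss_flank`` window are removed before stitching.
    """
    ivs = list(peaks)
    if tss_exclude is not None and len(tss_exclude):
        windows: dict[str, list[tuple[int, int]]] = {}
        for row in tss_exclude.itertuples():
            windows.setdefault(row.chrom, []).append(
                (max(0, row.tss - tss_flank), row.tss + tss_flank + 1)
            )
        kept = []
        for iv in ivs:
            inside = any(
                s <= iv.start and iv.end <= e for s, e in windows.get(iv.chrom, ())
            )
            if not inside:
                kept.append(iv)
        ivs = kept
    if not ivs:
        logger.warning("stitch: all peaks excluded; result is empty")
        return IntervalSet(
            intervals=[], sample_id=peaks.sample_id, mark=peaks.mark, merged=True
        )
    out = merge_within(
        IntervalSet(intervals=ivs, sample_id=peaks.sample_id, mark=peaks.mark),
        gap=stitch_gap,
    )
    return out


def score_regions(
    stitched: IntervalSet,
    treat: SignalTrack,
    ctrl: SignalTrack | None = None,
) -> RankedRegionSet:
    """Score stitched regions by input-corrected signal area, clipped at 0.

    score = area(treat) - area(ctrl); ranks 1..n ascend with score (ties
    broken by genomic coordinate for determinism).  No cutoff is set yet.
    """
    scores = np.empty(len(stitched), dtype=float)
    for i, iv in enumerate(stitched):
        s = region_signal(treat, iv, "area")
        if ctrl is not None:
            s -= region_signal(ctrl, iv, "area")
        scores[i] = max(s, 0.0)
    order = sorted(
        range(len(stitched)), key=lambda i: (scores[i], stitched[i].sort_key())
    )
    ranks = np.empty(len(stitched), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return RankedRegionSet(
        regions=stitched,
        scores=scores,
        ranks=ranks,
        is_super=np.zeros(len(stitched), dtype=bool),
    )


def tangent_cutoff(scores: np.ndarray) -> float:
    """Cutoff score of the ranked (hockey-stick) curve.

    ``scores`` must be sorted ascending.  Both axes are scaled to [0, 1]
    (x = rank/n, y = score/max); the cutoff is the unscaled score at the
    first rank where the discrete slope between consecutive scaled points
    exceeds 1.  Regions scoring strictly above the cutoff are
    super-enhancers.  A flat curve yields cutoff = the common score (zero
    super-enhancers).  The result is invariant under positive rescaling of
    all scores.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or len(scores) < 2:
        raise ValueError("need >= 2 scores")
    if np.any(np.diff(scores) < 0):
        raise ValueError("scores must be sorted ascending")
    smax = scores[-1]
    if smax <= 0 or scores[0] == smax:
        logger.warning("tangent_cutoff: flat score curve; no super-enhancers")
        return float(smax)
    n = len(scores)
    y = scores / smax
    # slope between ranks i and i+1 of the scaled curve: dy / (1/n)
    dy = np.diff(y) * n
    crossing = np.nonzero(dy > 1.0)[0]
    if len(crossing) == 0:
        logger.warning("tangent_cutoff: slope never exceeds 1; no super-enhancers")
        return float(smax)
    return float(scores[crossing[0]])


def call_super_enhancers(
    peaks: IntervalSet,
    treat: SignalTrack,
    ctrl: SignalTrack | None = None,
    stitch_gap: int = DEFAULT_STITCH_GAP,
    tss_exclude: pd.DataFrame | None = None,
    tss_flank: int = 2_500,
) -> RankedRegionSet:
    """stitch -> score -> tangent cutoff; the full ROSE-style composition."""
    stitched = stitch(peaks, stitch_gap, tss_exclude, tss_flank)
    if len(stitched) == 0:
        logger.warning("call_super_enhancers: empty stitched set")
        return RankedRegionSet(
            regions=stitched,
            scores=np.array([]),
            ranks=np.array([], dtype=int),
            cutoff_score=math.nan,
            is_super=np.array([], dtype=bool),
        )
    rrs = score_regions(stitched, treat, ctrl)
    if len(rrs) == 1:
        rrs.cutoff_score = float(rrs.scores[0])
        rrs.is_super = np.zeros(1, dtype=bool)
        return rrs
    ascending = rrs.scores[np.argsort(rrs.ranks)]
    rrs.cutoff_score = tangent_cutoff(ascending)
    rrs.is_super = rrs.scores > rrs.cutoff_score
    return rrs


def call_broad_domains(
    peaks: IntervalSet, top_fraction: float = DEFAULT_TOP_FRACTION
) -> BroadDomainSet:
    """Keep the top ``top_fraction`` of peaks by width (broad domains).

    Exactly ``ceil(top_fraction * n)`` peaks are kept; ties in width are
    broken by (chrom, start) ascending so output is deterministic.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    if len(peaks) == 0:
        raise ValueError("peaks must be non-empty")
    n_keep = math.ceil(top_fraction * len(peaks))
    if n_keep < 1:  # pragma: no cover - ceil(>0) >= 1
        logger.warning("call_broad_domains: keeping a single peak")
        n_keep = 1
    ranked = sorted(peaks, key=lambda iv: (-iv.width, iv.chrom, iv.start, iv.end))
    kept = ranked[:n_keep]
    widths = np.array([iv.width for iv in kept], dtype=int)
    return BroadDomainSet(
        domains=IntervalSet(
            intervals=sorted(kept, key=GenomicInterval.sort_key),
            sample_id=peaks.sample_id,
            mark=peaks.mark,
        ),
        widths=widths,
        width_threshold=int(widths.min()),
        top_fraction=top_fraction,
    )
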