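"""Seeded synthetic data with planted structure for every pipeline stage.

The panel generator emulates a seven-cell-line study design: a High-Grade
group and a Low-Grade group of samples, each carrying super-enhancer-like
and broad-H3K4me3-like domains that are either common to all samples,
unique to one group, or sample-specific background.  Planted regions are
separated by at least twice the stitch gap so stitching can never merge two
distinct truths, signal noise is multiplicative log-normal (ChIP enrichment
is ratio-scaled), and every generator is bit-reproducible given its seed.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .differential import RegionCounts, CONTROL, TREATED
from .intervals import (
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    write_bed,
    write_bedgraph,
)
from .tads import ContactMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PanelConfig",
    "PlantedRegion",
    "PanelSim",
    "simulate_panel",
    "simulate_enhancer_landscape",
    "simulate_contact_matrix",
    "simulate_treatment",
    "simulate_expression",
]

DOMAIN_TYPES = ("SE", "broadK4")
MARK_OF = {"SE": "H3K27ac", "broadK4": "H3K4me3"}
BASE_SIGNAL = 1.0


@dataclass
class PanelConfig:
    """Study-design parameters of the synthetic cell-line panel."""

    n_samples_high: int = 3
    n_samples_low: int = 4
    n_common: int = 38
    n_hgu: int = 61
    n_lgu: int = 224
    n_background: int = 50  # per sample, per domain type; sample-specific
    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("chr1", 40_000_000),
            ("chr2", 40_000_000),
            ("chr3", 40_000_000),
            ("chr4", 40_000_000),
        ]
    )
    signal_contrast: float = 20.0  # planted vs typical fold difference
    noise_sd: float = 0.2  # log-normal sigma on signal
    se_width: int = 20_000
    broad_width: int = 10_000
    background_width: int = 1_000
    separation: int = 25_000  # >= 2 x stitch gap, so truths never merge
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_high < 1 or self.n_samples_low < 1:
            raise ValueError("need >= 1 sample per group")
        if min(self.n_common, self.n_hgu, self.n_lgu, self.n_background) < 0:
            raise ValueError("region counts must be >= 0")
        if any(l <= 0 for _, l in self.genome):
            raise ValueError("chromosome lengths must be > 0")
        if self.signal_contrast <= 1:
            raise ValueError("signal_contrast must exceed 1")

    @property
    def sample_ids(self) -> list[str]:
        return [f"High{i+1}" for i in range(self.n_samples_high)] + [
            f"Low{i+1}" for i in range(self.n_samples_low)
        ]

    @property
    def group_of(self) -> dict[str, str]:
        out = {f"High{i+1}": "High" for i in range(self.n_samples_high)}
        out.update({f"Low{i+1}": "Low" for i in range(self.n_samples_low)})
        return out


@dataclass(frozen=True)
class PlantedRegion:
    interval: GenomicInterval
    category: str  # common / HGU / LGU / background
    domain_type: str  # SE / broadK4
    sample_id: str | None = None  # set for background regions


@dataclass
class PanelSim:
    """Everything the panel generator plants, in memory."""

    config: PanelConfig
    truth: list[PlantedRegion]
    domains: dict[str, dict[str, IntervalSet]]  # domain_type -> sample -> set
    peaks: dict[str, dict[str, IntervalSet]]
    signal: dict[str, dict[str, SignalTrack]]

    def truth_counts(self, domain_type: str) -> dict[str, int]:
        out = {"common": 0, "HGU": 0, "LGU": 0}
        for t in self.truth:
            if t.domain_type == domain_type and t.category in out:
                out[t.category] += 1
        return out

    def write(self, outdir: str | Path) -> None:
        """Write per-sample BED and bedGraph files plus the truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for dt in DOMAIN_TYPES:
            for sid in self.config.sample_ids:
                write_bed(self.domains[dt][sid], outdir / f"{sid}_{dt}_domains.bed")
                write_bed(self.peaks[dt][sid], outdir / f"{sid}_{dt}_peaks.bed")
                write_bedgraph(
                    self.signal[dt][sid], outdir / f"{sid}_{MARK_OF[dt]}.bedGraph"
                )
        rows = [
            {
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "category": t.category,
                "domain_type": t.domain_type,
                "sample_id": t.sample_id or ".",
            }
            for t in self.truth
        ]
        pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _place_regions(
    rng: np.random.Generator,
    genome: list[tuple[str, int]],
    widths: list[int],
    separation: int,
    max_tries: int = 2_000,
) -> list[GenomicInterval]:
    """Place regions by rejection sampling, edges >= ``separation`` apart."""
    lengths = np.array([l for _, l in genome], dtype=float)
    probs = lengths / lengths.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in genome}
    out: list[GenomicInterval] = []
    for w in widths:
        for _ in range(max_tries):
            ci = int(rng.choice(len(genome), p=probs))
            chrom, clen = genome[ci]
            if clen < w + 2:
                continue
            s = int(rng.integers(0, clen - w))
            e = s + w
            ivs = occupied[chrom]
            k = bisect.bisect_left(ivs, (s, e))
            ok = True
            if k > 0 and s - ivs[k - 1][1] < separation:
                ok = False
            if ok and k < len(ivs) and ivs[k][0] - e < separation:
                ok = False
            if ok:
                bisect.insort(ivs, (s, e))
                out.append(GenomicInterval(chrom, s, e))
                break
        else:
            raise ValueError(
                "genome too small to place regions with the required separation"
            )
    return out


def simulate_panel(cfg: PanelConfig) -> PanelSim:
    """Generate the synthetic cell-line panel.

    Common regions appear (as peaks, domains and elevated signal) in every
    sample; HGU regions only in High samples; LGU only in Low samples;
    background regions each in exactly one sample at baseline signal.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = cfg.sample_ids
    group_of = cfg.group_of

    truth: list[PlantedRegion] = []
    plan: list[tuple[int, str, str, str | None]] = []  # width, cat, dtype, sample
    for dt in DOMAIN_TYPES:
        w = cfg.se_width if dt == "SE" else cfg.broad_width
        for cat, n in (("common", cfg.n_common), ("HGU", cfg.n_hgu), ("LGU", cfg.n_lgu)):
            plan.extend((w, cat, dt, None) for _ in range(n))
        for sid in samples:
            plan.extend(
                (cfg.background_width, "background", dt, sid)
                for _ in range(cfg.n_background)
            )
    placed = _place_regions(
        rng, cfg.genome, [p[0] for p in plan], cfg.separation
    )
    for iv, (_, cat, dt, sid) in zip(placed, plan):
        truth.append(PlantedRegion(iv, cat, dt, sid))

    def present_in(t: PlantedRegion, sid: str) -> bool:
        if t.category == "common":
            return True
        if t.category == "HGU":
            return group_of[sid] == "High"
        if t.category == "LGU":
            return group_of[sid] == "Low"
        return t.sample_id == sid

    domains: dict[str, dict[str, IntervalSet]] = {dt: {} for dt in DOMAIN_TYPES}
    peaks: dict[str, dict[str, IntervalSet]] = {dt: {} for dt in DOMAIN_TYPES}
    signal: dict[str, dict[str, SignalTrack]] = {dt: {} for dt in DOMAIN_TYPES}
    for dt in DOMAIN_TYPES:
        for sid in samples:
            present = [
                t for t in truth if t.domain_type == dt and present_in(t, sid)
            ]
            present.sort(key=lambda t: t.interval.sort_key())
            dom_ivs = []
            pk_ivs = []
            sig_ivs = []
            sig_vals = []
            for t in present:
                iv = t.interval
                planted = t.category != "background"
                dom_ivs.append(iv)
                if dt == "SE" and planted:
                    # a super-enhancer is a cluster of constituent peaks
                    third = iv.width // 5
                    for k in range(3):
                        s = iv.start + k * 2 * third
                        pk_ivs.append(GenomicInterval(iv.chrom, s, s + third))
                else:
                    pk_ivs.append(iv)
                level = BASE_SIGNAL * (cfg.signal_contrast if planted else 1.0)
                if cfg.noise_sd > 0:
                    level *= float(rng.lognormal(0.0, cfg.noise_sd))
                sig_ivs.append(iv)
                sig_vals.append(level)
            mark = MARK_OF[dt]
            domains[dt][sid] = IntervalSet(
                intervals=dom_ivs, sample_id=sid, mark=mark
            )
            peaks[dt][sid] = IntervalSet(intervals=pk_ivs, sample_id=sid, mark=mark)
            signal[dt][sid] = SignalTrack.from_intervals(
                sig_ivs, sig_vals, sample_id=sid
            )
    return PanelSim(config=cfg, truth=truth, domains=domains, peaks=peaks, signal=signal)


def simulate_shared_domain_panel(
    n_shared: dict[str, int] | None = None,
    n_se_only: dict[str, int] | None = None,
    n_broad_only: dict[str, int] | None = None,
    n_samples_high: int = 3,
    n_samples_low: int = 4,
    genome: list[tuple[str, int]] | None = None,
    region_width: int = 10_000,
    separation: int = 25_000,
    seed: int = 0,
) -> tuple[dict[str, dict[str, IntervalSet]], dict[str, str], list[str]]:
    """Paired SE/broad panels with a controlled number of shared regions.

    ``n_shared[cat]`` regions appear (at the same coordinates) in both the
    SE and the broad domain sets of every sample the category prescribes;
    ``n_se_only`` / ``n_broad_only`` regions appear in only one domain type.
    Returns (domain sets per type per sample, group_of, sample_ids); feed
    each type through build_membership/classify_regions and overlap the two
    labelled sets.
    """
    n_shared = n_shared or {"common": 0, "HGU": 34, "LGU": 87}
    n_se_only = n_se_only or {"common": 10, "HGU": 10, "LGU": 10}
    n_broad_only = n_broad_only or {"common": 10, "HGU": 10, "LGU": 10}
    genome = genome or [("chr1", 60_000_000), ("chr2", 60_000_000)]
    rng = np.random.default_rng(seed)
    plan: list[tuple[str, tuple[str, ...]]] = []  # category, domain types
    for cat in ("common", "HGU", "LGU"):
        plan.extend((cat, ("SE", "broadK4")) for _ in range(n_shared.get(cat, 0)))
        plan.extend((cat, ("SE",)) for _ in range(n_se_only.get(cat, 0)))
        plan.extend((cat, ("broadK4",)) for _ in range(n_broad_only.get(cat, 0)))
    placed = _place_regions(rng, genome, [region_width] * len(plan), separation)
    sample_ids = [f"High{i+1}" for i in range(n_samples_high)] + [
        f"Low{i+1}" for i in range(n_samples_low)
    ]
    group_of = {s: ("High" if s.startswith("High") else "Low") for s in sample_ids}
    sets: dict[str, dict[str, list[GenomicInterval]]] = {
        dt: {s: [] for s in sample_ids} for dt in DOMAIN_TYPES
    }
    group_for_cat = {"HGU": "High", "LGU": "Low"}
    for iv, (cat, dts) in zip(placed, plan):
        for sid in sample_ids:
            if cat == "common" or group_of[sid] == group_for_cat[cat]:
                for dt in dts:
                    sets[dt][sid].append(iv)
    out = {
        dt: {
            sid: IntervalSet(
                intervals=sorted(ivs, key=GenomicInterval.sort_key),
                sample_id=sid,
                mark=MARK_OF[dt],
            )
            for sid, ivs in sets[dt].items()
        }
        for dt in DOMAIN_TYPES
    }
    return out, group_of, sample_ids


def simulate_enhancer_landscape(
    n_super: int = 10,
    n_typical: int = 500,
    contrast: float = 20.0,
    noise_sd: float = 0.1,
    peak_width: int = 1_000,
    cluster_span: int = 9_000,
    chrom_length: int = 40_000_000,
    seed: int = 0,
) -> tuple[IntervalSet, SignalTrack, SignalTrack, IntervalSet]:
    """One sample's enhancer landscape for super-enhancer-caller testing.

    Plants ``n_super`` clusters of three high-signal peaks (within
    ``cluster_span``, so a 12.5 kb stitch joins each cluster into one
    region) among ``n_typical`` single baseline peaks.  Returns
    (peaks, treatment track, input-control track, true super regions).
    """
    rng = np.random.default_rng(seed)
    genome = [("chr1", chrom_length)]
    widths = [cluster_span] * n_super + [peak_width] * n_typical
    placed = _place_regions(rng, genome, widths, separation=30_000)
    pk_ivs: list[GenomicInterval] = []
    sig_ivs: list[GenomicInterval] = []
    sig_vals: list[float] = []
    true_supers: list[GenomicInterval] = []
    for iv, w in zip(placed, widths):
        if w == cluster_span:
            true_supers.append(iv)
            step = (cluster_span - peak_width) // 2
            for k in range(3):
                s = iv.start + k * step
                pk = GenomicInterval(iv.chrom, s, s + peak_width)
                pk_ivs.append(pk)
                sig_ivs.append(pk)
                sig_vals.append(
                    BASE_SIGNAL * contrast * float(rng.lognormal(0.0, noise_sd))
                )
        else:
            pk_ivs.append(iv)
            sig_ivs.append(iv)
            sig_vals.append(BASE_SIGNAL * float(rng.lognormal(0.0, noise_sd)))
    peaks = IntervalSet(
        intervals=sorted(pk_ivs, key=GenomicInterval.sort_key),
        sample_id="sim",
        mark="H3K27ac",
    )
    treat = SignalTrack.from_intervals(sig_ivs, sig_vals, sample_id="sim")
    # flat low input coverage under every peak
    ctrl = SignalTrack.from_intervals(
        sorted(sig_ivs, key=GenomicInterval.sort_key),
        [0.2 * BASE_SIGNAL] * len(sig_ivs),
        sample_id="input",
    )
    return peaks, treat, ctrl, IntervalSet(
        intervals=sorted(true_supers, key=GenomicInterval.sort_key)
    )


def simulate_contact_matrix(
    n_bins: int,
    tad_sizes: list[int],
    contrast: float = 10.0,
    noise_sd: float = 0.0,
    bin_size: int = 40_000,
    chrom: str = "chr1",
    seed: int = 0,
) -> tuple[ContactMatrix, list[int]]:
    """Blocky contact matrix with planted TADs.

    Within-block mean is ``contrast`` x the between-block mean; multiplicative
    log-normal noise; symmetrized.  Returns the matrix and the true internal
    boundary bins (first bin of each non-initial block).
    """
    if sum(tad_sizes) != n_bins:
        raise ValueError("tad_sizes must sum to n_bins")
    if any(s <= 0 for s in tad_sizes):
        raise ValueError("tad_sizes must be positive")
    rng = np.random.default_rng(seed)
    m = np.full((n_bins, n_bins), 1.0)
    edges = np.cumsum([0] + list(tad_sizes))
    for a, b in zip(edges[:-1], edges[1:]):
        m[a:b, a:b] = contrast
    if noise_sd > 0:
        noise = rng.lognormal(0.0, noise_sd, size=m.shape)
        m = m * noise
        m = (m + m.T) / 2.0
    true_boundaries = [int(e) for e in edges[1:-1]]
    return ContactMatrix(chrom=chrom, bin_size=bin_size, matrix=m), true_boundaries


def simulate_treatment(
    regions: IntervalSet,
    frac_increased: float = 0.1,
    frac_decreased: float = 0.0,
    effect_fold: float = 4.0,
    poisson_mean: float = 20.0,
    n_reps: int = 2,
    seed: int = 0,
) -> tuple[RegionCounts, np.ndarray]:
    """Poisson counts per region per replicate with planted fold-changes.

    The first ``frac_increased`` (resp. next ``frac_decreased``) of a random
    region permutation are scaled by ``effect_fold`` (resp. 1/effect_fold)
    in treated samples.  Returns (RegionCounts, truth labels in
    {increased, decreased, null}).
    """
    if frac_increased + frac_decreased > 1:
        raise ValueError("fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    n = len(regions)
    perm = rng.permutation(n)
    n_up = int(round(frac_increased * n))
    n_dn = int(round(frac_decreased * n))
    labels = np.full(n, "null", dtype=object)
    labels[perm[:n_up]] = "increased"
    labels[perm[n_up : n_up + n_dn]] = "decreased"
    mult = np.ones(n)
    mult[labels == "increased"] = effect_fold
    mult[labels == "decreased"] = 1.0 / effect_fold
    cols = {}
    condition_of = {}
    for r in range(n_reps):
        sid = f"ctrl{r+1}"
        cols[sid] = rng.poisson(poisson_mean, size=n)
        condition_of[sid] = CONTROL
    for r in range(n_reps):
        sid = f"treat{r+1}"
        cols[sid] = rng.poisson(poisson_mean * mult)
        condition_of[sid] = TREATED
    counts = pd.DataFrame(cols, index=range(n))
    return (
        RegionCounts(regions=regions, counts=counts, condition_of=condition_of),
        labels,
    )


def simulate_expression(
    genes: pd.DataFrame,
    category_of_gene: dict[str, str],
    affected_categories: tuple[str, ...] = ("increased",),
    group_effect: float = 1.0,
    noise_sd: float = 0.1,
    n_reps: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-gene expression log2 fold-changes with planted group effects.

    Genes whose category is in ``affected_categories`` get mean log2fc =
    ``group_effect``; all others 0; Gaussian noise averaged over ``n_reps``
    replicate draws.  Returns (TSV-ready DataFrame, gene -> log2fc map).
    """
    rng = np.random.default_rng(seed)
    rows = []
    fc_map: dict[str, float] = {}
    for g in genes["gene_id"]:
        cat = category_of_gene.get(g, "null")
        mu = group_effect if cat in affected_categories else 0.0
        val = mu + float(rng.normal(0.0, noise_sd, size=n_reps).mean())
        fc_map[g] = val
        rows.append({"gene_id": g, "category": cat, "log2fc": val})
    return pd.DataFrame(rows), fc_map
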