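"""Differential enrichment under drug treatment, location annotation,
gene assignment and expression comparison.

The differential test is deliberately simple plumbing: replicates are pooled
per condition and each region's treated count is tested against the
library-size expectation with an exact two-sided binomial test; FDR is
controlled by Benjamini-Hochberg and regions are called
increased / decreased / unchanged at FDR < 0.1 by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IntervalSet, SignalTrack, region_signal

logger = logging.getLogger(__name__)

__all__ = [
    "RegionCounts",
    "read_gene_model",
    "count_in_regions",
    "differential_regions",
    "annotate_location",
    "assign_genes",
    "expression_change_by_category",
]

TREATED = "treated"
CONTROL = "control"
DEFAULT_FDR = 0.1
DEFAULT_GENE_WINDOW = 100_000
DEFAULT_PROMOTER_WINDOW = (-2_000, 500)


@dataclass
class RegionCounts:
    """Integer read/fragment counts per region per sample."""

    regions: IntervalSet
    counts: pd.DataFrame  # region x sample, integer
    condition_of: dict[str, str]
    library_size: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        if len(self.counts) != len(self.regions):
            raise ValueError("counts rows must match regions")
        for s in self.counts.columns:
            if self.condition_of.get(s) not in (TREATED, CONTROL):
                raise ValueError(f"sample {s!r} needs condition treated/control")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)
        if (self.library_size <= 0).any():
            raise ValueError("zero library size")

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of[s] == condition]


def read_gene_model(path: str | Path) -> pd.DataFrame:
    """Load a gene model from minimal TSV or BED12.

    TSV columns: gene_id, chrom, strand, tss, start, end (header optional,
    detected).  BED12: chrom, start, end, name, score, strand, ... with the
    TSS inferred from strand.  Returns a DataFrame with columns
    gene_id, chrom, strand, tss, start, end.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if f[0] == "gene_id":  # header
                continue
            if len(f) >= 12 or (len(f) >= 6 and f[1].isdigit() and f[2].isdigit()):
                chrom, start, end = f[0], int(f[1]), int(f[2])
                gene_id, strand = f[3], f[5]
            elif len(f) >= 6:
                gene_id, chrom, strand = f[0], f[1], f[2]
                start, end = int(f[4]), int(f[5])
            else:
                raise ValueError(f"{path} line {lineno}: unrecognized gene row")
            if strand not in ("+", "-"):
                raise ValueError(f"{path} line {lineno}: strand must be +/-")
            tss = start if strand == "+" else end - 1
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "strand": strand,
                    "tss": tss,
                    "start": start,
                    "end": end,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "start", "end"])


def gene_model_from_records(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records)
    if "tss" not in df.columns:
        df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df[["gene_id", "chrom", "strand", "tss", "start", "end"]]


def count_in_regions(
    regions: IntervalSet,
    sample_data: dict[str, IntervalSet | SignalTrack],
    condition_of: dict[str, str],
) -> RegionCounts:
    """Counts per region per sample.

    Fragment sets are counted by midpoint containment (midpoint =
    (start+end)//2; half-open, so a midpoint at the region end is outside).
    Signal tracks are converted to integer counts by rounding the region's
    signal area.
    """
    cols = {}
    for sid, data in sample_data.items():
        if isinstance(data, SignalTrack):
            cols[sid] = [
                int(round(region_signal(data, iv, "area"))) for iv in regions
            ]
        else:
            mids: dict[str, np.ndarray] = {}
            for chrom in {f.chrom for f in data}:
                m = sorted(
                    (f.start + f.end) // 2 for f in data if f.chrom == chrom
                )
                mids[chrom] = np.asarray(m, dtype=np.int64)
            vals = []
            for iv in regions:
                m = mids.get(iv.chrom)
                if m is None:
                    vals.append(0)
                else:
                    vals.append(
                        int(
                            np.searchsorted(m, iv.end, side="left")
                            - np.searchsorted(m, iv.start, side="left")
                        )
                    )
            cols[sid] = vals
    counts = pd.DataFrame(cols, index=range(len(regions)))
    return RegionCounts(regions=regions, counts=counts, condition_of=dict(condition_of))


def differential_regions(
    rc: RegionCounts, fdr_threshold: float = DEFAULT_FDR
) -> pd.DataFrame:
    """Pooled binomial test of treated vs control counts per region.

    Replicates are pooled within condition.  For region i with pooled counts
    (t_i, c_i) and pooled library sizes (T, C), the null treated proportion
    is p0 = T/(T+C) and the p-value is the exact two-sided binomial test of
    t_i successes in t_i + c_i trials.  log2fc uses pseudocount 1 on the
    counts only (log2(((t+1)/T) / ((c+1)/C))); the test itself does not.
    FDR is Benjamini-Hochberg across all regions.

    Returns a DataFrame with chrom/start/end, t, c, log2fc, p_value, fdr,
    direction in {increased, decreased, unchanged}.
    """
    t_samples = rc.samples_in(TREATED)
    c_samples = rc.samples_in(CONTROL)
    if not t_samples or not c_samples:
        raise ValueError("need >= 1 treated and >= 1 control sample")
    t = rc.counts[t_samples].sum(axis=1).to_numpy()
    c = rc.counts[c_samples].sum(axis=1).to_numpy()
    T = float(rc.library_size[t_samples].sum())
    C = float(rc.library_size[c_samples].sum())
    p0 = T / (T + C)
    pvals = np.ones(len(t))
    for i, (ti, ci) in enumerate(zip(t, c)):
        n = int(ti + ci)
        if n == 0:
            continue
        pvals[i] = stats.binomtest(int(ti), n, p0, alternative="two-sided").pvalue
    log2fc = np.where(
        (t + c) == 0, 0.0, np.log2(((t + 1) / T) / ((c + 1) / C))
    )
    fdr = multipletests(pvals, method="fdr_bh")[1]
    direction = np.full(len(t), "unchanged", dtype=object)
    sig = fdr < fdr_threshold
    direction[sig & (log2fc > 0)] = "increased"
    direction[sig & (log2fc < 0)] = "decreased"
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in rc.regions],
            "start": [iv.start for iv in rc.regions],
            "end": [iv.end for iv in rc.regions],
            "t": t,
            "c": c,
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
        }
    )


def _promoter_window(tss: int, strand: str, window: tuple[int, int]) -> tuple[int, int]:
    """Half-open promoter interval, offsets in transcription direction."""
    a, b = window
    if strand == "+":
        return (max(0, tss + a), tss + b)
    return (max(0, tss - b + 1), tss - a + 1)


def annotate_location(
    regions: IntervalSet,
    genes: pd.DataFrame,
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> np.ndarray:
    """Label each region promoter / intragenic / distal intergenic.

    Precedence: promoter (overlaps a strand-aware TSS window) > intragenic
    (overlaps a gene body) > distal intergenic.  The labels partition the
    regions.
    """
    if genes.empty:
        raise ValueError("gene model is empty")
    prom: dict[str, list[tuple[int, int]]] = {}
    body: dict[str, list[tuple[int, int]]] = {}
    for row in genes.itertuples():
        prom.setdefault(row.chrom, []).append(
            _promoter_window(row.tss, row.strand, promoter_window)
        )
        body.setdefault(row.chrom, []).append((row.start, row.end))
    labels = np.full(len(regions), "distal intergenic", dtype=object)
    for i, iv in enumerate(regions):
        if any(s < iv.end and iv.start < e for s, e in prom.get(iv.chrom, ())):
            labels[i] = "promoter"
        elif any(s < iv.end and iv.start < e for s, e in body.get(iv.chrom, ())):
            labels[i] = "intragenic"
    return labels


def assign_genes(
    regions: IntervalSet,
    genes: pd.DataFrame,
    window: int = DEFAULT_GENE_WINDOW,
) -> pd.DataFrame:
    """Link each region to every gene whose TSS lies within ``window`` bp.

    Distance is from the TSS to the nearest base of the region (0 if the TSS
    is inside).  A region may link many genes and vice versa.  Returns a
    DataFrame with region_index, chrom, start, end, gene_id, distance.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    rows = []
    for i, iv in enumerate(regions):
        sub = genes[genes["chrom"] == iv.chrom]
        for g in sub.itertuples():
            if iv.start <= g.tss < iv.end:
                d = 0
            elif g.tss < iv.start:
                d = iv.start - g.tss
            else:
                d = g.tss - (iv.end - 1)
            if d <= window:
                rows.append(
                    {
                        "region_index": i,
                        "chrom": iv.chrom,
                        "start": iv.start,
                        "end": iv.end,
                        "gene_id": g.gene_id,
                        "distance": d,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["region_index", "chrom", "start", "end", "gene_id", "distance"],
    )


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test; degenerate cases -> p=1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        return (0.0, 1.0) if x.mean() == y.mean() else (math.inf, 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def expression_change_by_category(
    genes_by_category: dict[str, list[str]],
    expr_log2fc: dict[str, float],
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Distributions of gene expression log2 fold-change per domain category,
    with pairwise Welch t-tests between categories.

    Categories with fewer than 2 genes having expression values are excluded
    with a warning.  Returns (per-category log2fc vectors, pairwise table
    with columns category_a, category_b, t, p_value).
    """
    dists: dict[str, np.ndarray] = {}
    for cat, gene_ids in genes_by_category.items():
        vals = np.array(
            [expr_log2fc[g] for g in dict.fromkeys(gene_ids) if g in expr_log2fc]
        )
        if len(vals) < 2:
            logger.warning(
                "category %r has < 2 genes with expression; excluded", cat
            )
            continue
        dists[cat] = vals
    cats = list(dists)
    rows = []
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            t, p = welch_t_test(dists[a], dists[b])
            rows.append({"category_a": a, "category_b": b, "t": t, "p_value": p})
    return dists, pd.DataFrame(rows, columns=["category_a", "category_b", "t", "p_value"])
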