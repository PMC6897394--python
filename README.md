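# epidomains

Analysis of **broad epigenomic domains** — super-enhancers and broad
H3K4me3 domains — across a panel of tumour cell lines, with differential
enrichment under drug treatment and enrichment of domains at topologically
associated domain (TAD) boundaries.

The package is aimed at computational epigenomics work of the kind done on
pancreatic ductal adenocarcinoma (PDAC) cell-line panels: a group of
poorly differentiated ("High-Grade", mesenchymal) lines and a group of
well-differentiated ("Low-Grade", epithelial) lines, each with H3K27ac and
H3K4me3 ChIP-seq peak calls and signal tracks, optionally a chromatin
contact matrix, and expression data under histone-acetyltransferase (HAT)
inhibitor treatment. It consumes standard text formats (BED/narrowPeak/
broadPeak peaks, bedGraph signal, dense or triplet contact matrices, TSV
gene models and expression tables) and is fully testable offline through a
seeded synthetic-data generator with planted structure.

## What it computes

- **Super-enhancers** (ROSE-style ranked ordering): H3K27ac peaks stitched
  within 12.5 kb, scored by input-corrected signal area
  s = max(0, area_treat − area_input), ranked ascending, and thresholded at
  the first rank where the slope of the rank- and score-normalised curve
  exceeds 1. Regions above the cutoff are super-enhancers.
- **Broad H3K4me3 domains**: the widest ⌈0.05·n⌉ of n H3K4me3 peaks.
- **Grade classification**: union regions across the panel with a binary
  region × sample membership matrix; regions present in all samples are
  *common*, present only in the High-Grade group *HGU*, only in the
  Low-Grade group *LGU*; the two domain types are then overlapped per
  category.
- **Differential enrichment** under treatment: pooled exact binomial test
  of treated vs control counts per region against the library-size null,
  Benjamini–Hochberg FDR, direction called at FDR < 0.1; location
  annotation (promoter / intragenic / distal intergenic), gene assignment
  within 100 kb, and Welch's t-test comparison of expression changes
  between domain categories.
- **TADs and boundary enrichment**: simplified TopDom (diamond binSignal,
  strict local minima, rank-sum filter) at 40 kb resolution, and a
  permutation test of feature counts at boundary bins ± 20 kb against
  randomly drawn bin sets, with an add-one empirical p-value.

See `docs/methods.md` for the full model description and the design
decisions.

## Worked example

```python
from epidomains import (PanelConfig, simulate_panel, SamplePanel,
                        build_membership, classify_regions,
                        call_super_enhancers, simulate_enhancer_landscape)
from epidomains.grades import category_counts

# a noise-free 7-line panel planting 38 common, 61 HGU, 224 LGU domains
cfg = PanelConfig(noise_sd=0.0, seed=1)
sim = simulate_panel(cfg)
panel = SamplePanel(cfg.sample_ids, cfg.group_of, sim.domains["SE"])
labels = classify_regions(build_membership(panel))
print("SE categories:", category_counts(labels))

# super-enhancer calling on one simulated enhancer landscape
peaks, treat, ctrl, truth = simulate_enhancer_landscape(seed=1)
rrs = call_super_enhancers(peaks, treat, ctrl)
print(f"{rrs.n_super} super-enhancers of {len(rrs)} stitched regions "
      f"(cutoff score {rrs.cutoff_score:.1f})")
```

prints

```
SE categories: {'common': 38, 'HGU': 61, 'LGU': 224, 'other': 350}
10 super-enhancers of 510 stitched regions (cutoff score 1175.2)
```

The 38/61/224 are the planted grade-specific category counts recovered
exactly from the membership classification (the 350 *other* regions are
the sample-specific background enhancers); the second line shows the
ranked-ordering cutoff isolating exactly the ten planted high-signal
clusters from 500 typical enhancers.

## Command line

```bash
epidomains all --outdir out --seed 7          # full pipeline on a synthetic fixture
epidomains call-se --peaks peaks.bed --treat chip.bedGraph --ctrl input.bedGraph --outdir out
epidomains call-broad --peaks k4me3_peaks.bed --outdir out
epidomains classify --panel panel_table.tsv --outdir out
epidomains tads --matrix contacts.tsv --outdir out
epidomains enrich --matrix contacts.tsv --features ctcf.bed --outdir out
```

All parameters live in one YAML config (`--config`, unknown keys
rejected); the resolved config is written next to the outputs, and
identical config + seed reproduce every output byte for byte.

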