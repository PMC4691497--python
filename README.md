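# h2azdyn

Analysis toolkit for histone-variant ChIP-seq occupancy dynamics across a
cell-state time course (e.g. fibroblasts reprogramming to induced
pluripotent stem cells, with an intermediate sample). Given aligned tag
positions per sample, a gene annotation, and chromosome sizes, it
produces the genome-scale summaries such a study rests on:

- **Peak calling** — a transparent Poisson sliding-window scan: windows of
  width 2·*b* (default *b* = 300 bp) step by *b*/2 against the genome-wide
  background rate λ = library size / genome length; a window with *k* tags
  is significant when the Poisson upper tail P(X ≥ k; λ·2b) < 10⁻⁴;
  significant windows within *b* of each other merge into one peak whose
  summit is the maximum of the 150 bp-extended fragment pileup.
- **Feature partition & enrichment** — every genomic base is labeled with
  one of seven classes (promoter = 2 kb upstream of the TSS, 5′UTR, CDS,
  intron, 3′UTR, downstream = 2 kb past the TES, intergenic). Each peak is
  assigned the class under its summit, and per-class relative enrichment
  is (peaks in class / total peaks) / (bases in class / total bases).
- **Composite profiles** — mean reads-per-million (RPM) coverage in 200 bp
  windows over ±5 kb around the TSS or TES, strand-oriented and averaged
  over a gene cohort, optionally stratified into four expression classes
  (high / middle / low / lowest).
- **Occupancy dynamics** — a gene is *occupied* when a peak overlaps its
  promoter or gene body; three samples' occupied sets are decomposed into
  the seven Venn regions.
- **Auxiliary statistics** — hypergeometric over-representation of a gene
  list against gene sets with Benjamini–Hochberg adjustment, term rank
  percentiles normalized to 100, and ChIP-qPCR fold over the IgG control
  2^(Ct_IgG − Ct_ChIP).
- **Synthetic data** — a seeded generator that plants the signal structure
  the analysis assumes (uniform background, bimodal TSS-flanking
  enrichment with a dip over the TSS, amplitudes scaling with expression
  class, per-sample intensity and occupied-gene fraction) together with
  an exact planted-truth record, so the whole pipeline is testable with
  no external data.

## Worked example

```python
from h2azdyn import (SimulationConfig, simulate_all, call_peaks,
                     composite_profile, occupied_genes)

world = simulate_all(SimulationConfig(seed=7))
genes, sizes = world["genes"], world["sizes"]
tags = world["samples"]["MEF"]["tags"]

peaks = call_peaks(tags, sizes)
tss = composite_profile(tags, genes, sizes, "TSS")
print(len(peaks), len(occupied_genes(peaks, genes)))
print(round(tss.anchor_window_value(), 1), round(float(tss.values.max()), 1))
```

prints

```
67 67
144.8 646.3
```

67 peaks were called on the simulated fibroblast sample and every one of
the 67 genes carrying planted signal is recovered as occupied. The TSS
composite reads 144.8 RPM in the window over the TSS itself against a
646.3 RPM flanking maximum — the bimodal profile with a central dip that
marks nucleosomes flanking a nucleosome-free region. The scripts in
`examples/` walk through each capability (peak calling, feature
enrichment, profiles, occupancy Venn, over-representation) the same way.

A thin CLI mirrors the library: `h2azdyn simulate`, `h2azdyn callpeaks`,
and `h2azdyn run --config run.yaml` for the full pipeline with a
JSON run report.

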