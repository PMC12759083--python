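# mitosense

Quantitative pipelines for PINK1–Parkin mitophagy reporter experiments.

Studies of the PINK1–Parkin pathway increasingly read pathway activity out
of single-cell reporters — whole-cell MFN2-Halo fluorescence (Parkin's
degradation of Mitofusin-2), membrane-potential dyes (MitoLite NIR, TMRE),
PINK1-YFP stabilisation, and the pH-sensitive mt-Keima excitation-ratio
shift — measured by FACS-bin pooled CRISPRi screens, flow cytometry, and
confocal microscopy, with label-free proteomics downstream. `mitosense`
implements the analysis layer of that experimental program as a tested,
reusable Python library:

* **screen_scoring** — guide count tables from high/low reporter bins →
  guide log2FC and p values (median-of-ratios normalisation, pooled-variance
  test), Bonferroni correction, gene scores
  *score = (−log₁₀ p_adj) · log₂FC*, and the six-screen rule set that calls
  **Parkin activators** (significant, log₂FC < −1 in untreated HeLa+Parkin,
  and > 1.25 below the Parkin-free comparison), **Parkin facilitators**
  (significant, log₂FC > 1 under oligomycin/antimycin, and > 1 above both
  comparators) and Parkin-independent **MFN2 down-/up-regulators**, with
  gene-symbol harmonisation and MitoCarta-style annotation.
* **flow_stats** — MFN2 degradation % =
  `100·(normint⁺ − normint⁻)/normint⁺` on CTRL-normalised population means;
  CTRL-normalised reporter intensities; the two-step MitoLite normalisation
  (BFP⁺/BFP⁻ within sample, then vs CTRL); mt-Keima gating with a 10 %
  spillover compensation and a triangular mitophagy gate; and the
  PINK1 × MMP quadrant analysis with its guide-negative normalisation
  factor.
* **image_quant** — the fixed-threshold (80–255 on 8-bit) mask workflow:
  mitochondrial mask = MTS ∪ dye mask, partitioned by dye positivity;
  per-connected-component channel intensities; and the colocalisation
  statistic *R over background* = r_obs − mean r over 20 pixel-randomised
  controls.
* **proteomics** — two-sided t tests with Benjamini–Hochberg FDR and the
  significance flag (FDR < 0.05, |log₂FC| > 1 or 0.5 by experiment),
  normalisation to the non-mitochondrial median, and the strong-presequence
  rule (mitochondrial, not OMM, MTS score ≥ 2, start < 20 residues).
* **synthetic_data** — planted-truth generators for all three modalities:
  negative-binomial screen counts driven by a reporter-quantile sorting
  model, lognormal flow events with guide-positive subpopulations, and
  images of curvilinear mitochondria-like objects with per-object
  membrane-potential classes. Every downstream stage is testable against
  known ground truth without instrument data.

The library API is the primary surface (see `examples/`); a thin CLI
(`mitosense sim|screen|flow|image|prot …`) wraps it for shell use.

## Worked example

`examples/screen_hit_calling.py` simulates the six-screen design with 30
planted Parkin activators among 300 genes (reporter shift −3 in the
Parkin-expressing screens only), scores every screen and classifies hits:

```
planted activators: 30
called activators:  31 (30 true, 1 false)
annotated mitochondrial among calls: 15

top 5 gene scores (untreated HeLa + Parkin):
          log2fc  p_adj    score
gene
GENE0017  -9.607    0.0 -396.118
GENE0021  -9.503    0.0 -337.896
GENE0023  -9.694    0.0 -324.870
GENE0015  -8.328    0.0 -236.461
GENE0020  -8.327    0.0 -232.395
```

A gene whose knockdown activates the pathway degrades the MFN2 reporter,
so its guides deplete from the high-fluorescence bin: strongly negative
log₂FC, hence a large negative gene score. All 30 planted genes are
recovered with one false call. The other examples print a degradation
estimate within half a point of the planted 50 %, a quadrant table whose
normalisation factor absorbs a planted 2× staining artifact, a mt-Keima
gate recovering a planted 30 % mitophagy fraction, and an image partition
that reproduces a planted 3× PINK1 contrast between depolarised and
polarised mitochondria.

Real data drop in at the same interfaces: guide count TSVs
(`guide_id  gene  rep1 …`, e.g. derived from the deposited sequencing data,
GEO GSE298056), flow event CSVs exported per sample, and multi-page TIFFs
with polygon ROIs.

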