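# mintcoloc

Quantification of locus-specific histone-modification signals in single
nuclei, for live-cell imaging experiments that pair a genetically encoded
modification probe (a fluorescent "mintbody", YFP channel) with a
LacO/LacI-tagged locus (CFP channel). An artificial chromosome carrying a
target sequence plus LacO repeats appears as a single CFP focus; if the
target sequence recruits the histone modification, the YFP probe
co-enriches at that focus. `mintcoloc` turns such two-channel nucleus
images into per-nucleus statistics and cohort-level significance tests —
and ships a fully parameterized synthetic image generator with ground
truth, so the entire pipeline is testable without a microscope.

## What it computes

For each nucleus (one 2D two-channel image):

1. **Segmentation** — the diffuse nuclear distribution of the probe is
   used as the signal for finding the nucleus edge: Otsu auto-thresholding
   (between-class-variance maximization over 256 histogram-edge
   candidates, evaluated on exact pixel values), binarization, largest
   8-connected component, hole filling.
2. **Pearson correlation coefficient (PCC)** over the in-mask pixels,

   r = Σᵢ(Yᵢ−Ȳ)(Cᵢ−C̄) / √(Σᵢ(Yᵢ−Ȳ)² Σᵢ(Cᵢ−C̄)²),

   i ranging over nucleus pixels only. Positive r indicates
   co-localization; r ≈ 0 no association.
3. **Binary co-localization call** — multi-scale Laplacian-of-Gaussian
   spot detection in both channels (sub-pixel centroids), then greedy
   nearest-neighbor matching; the nucleus is called co-localized when a
   CFP (locus) spot has a YFP spot within 2 px (configurable).

Across a cohort, two groups are compared on both readouts: frequency of
co-localization (two-sided Fisher's exact test on the 2×2 table) and mean
PCC (equal-variance two-sample Student's t-test), with significance
flagged at α = 0.01. Time-lapse series (default 11 frames, 30-min
intervals, 0–300 min) are analyzed frame by frame, reporting the fraction
of frames co-localized and the PCC trajectory.

## Worked example

Simulate two cohorts — an enriched condition (a locus that recruits the
modification, YFP co-enrichment 4× the diffuse nuclear level) and an
operator-only control (no enrichment) — then analyze and compare:

```bash
mintcoloc simulate --preset her1 --preset laco-only --n 30 --seed 1 --out-dir imgs
mintcoloc analyze imgs --out-dir out
mintcoloc compare out/results.csv her1 laco-only
```

prints

```
                 n  coloc    freq  mean PCC
her1            30     30    1.00     0.519
laco-only       30      0    0.00     0.008
Fisher exact p = 1.69e-17 (significant at alpha=0.01)
Student t = 21.941, p = 9.03e-30 (significant at alpha=0.01)
```

All 30 enriched nuclei are called co-localized and none of the controls;
the enriched cohort's mean PCC is strongly positive (0.52) while the
control sits at zero (0.008), and both the frequency contrast (Fisher)
and the mean-PCC contrast (t-test) are significant far below α = 0.01.
A time-lapse run over the default acquisition

```bash
mintcoloc timelapse --preset rex1 --seed 1 --out-dir tl
# 11 frames over 300 min; mean PCC 0.578; co-localized in 100% of frames
```

shows a stably maintained association across the series. `analyze` writes
a per-nucleus CSV (threshold, mask area, PCC, spot counts, call, status —
one row per input nucleus, failures flagged, nothing dropped), and the
simulator writes 16-bit two-channel TIFFs with sidecar JSON ground truth
plus a manifest, so `analyze` on the written directory reproduces the
in-memory analysis exactly. `mintcoloc run config.yaml` drives the whole
pipeline from a YAML config with a master seed; identical config + seed
gives bit-identical outputs.

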