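# Methods

## The measurement model

The pipeline quantifies, per nucleus, whether a fluorescently tagged
locus (CFP: LacI bound to LacO repeats on an artificial chromosome) is
co-enriched for a histone modification visualized by a live-cell probe
(YFP: a modification-specific mintbody). Two operationalizations are
computed side by side, because they fail differently:

* the **in-mask Pearson correlation** uses every nucleus pixel and is
  therefore sensitive to diffuse partial enrichment, but it conflates
  locus-specific signal with any other shared spatial structure;
* the **spot-distance call** asks the narrower question "is there a YFP
  focus where the CFP focus is?", mirroring visual judgment of "same
  morphologies and locations". It is robust to broad nuclear structure
  but blind to sub-threshold enrichment.

Both restrict to the segmented nucleus. That restriction is essential for
the PCC: over the whole frame, both channels are brighter inside the
nucleus than outside, so the shared nucleus footprint alone produces a
positive correlation with no in-nucleus association at all (the package
tests assert this failure mode explicitly).

## Segmentation

The YFP probe's diffuse nuclear distribution serves as the signal for
the nucleus boundary. The threshold maximizes Otsu's between-class
variance w₀w₁(μ₀−μ₁)² over 256 histogram-edge candidates, with class
statistics computed from the exact pixel values rather than binned
approximations, so the result is reproducible by exhaustive search; ties
break toward the lower threshold and the reported value is a bin edge
(candidates exclude the minimum, so a perfectly bimodal image yields a
threshold strictly between the modes). The auto-threshold family has
several near-equivalent variants (isodata/Ridler–Calvard, etc.); the
method name is recorded in the output so alternates can be added behind
the same contract, and masks from noise-free images are invariant under
positive affine intensity transforms (asserted as a property test).

Binarization keeps the largest 8-connected component (one nucleus per
image, by acquisition design) and fills holes afterwards, so locally dark
pixels — the LacI focus itself can exclude the probe — cannot punch holes
in the correlation domain. Components below `min_area_px` (default 50 px)
are a segmentation failure, recorded per nucleus, never raised through
the cohort run.

## PCC and its undefined cases

`pearson_cc` is the direct Σ-formula over mask pixels, clipped to [−1, 1]
against float error; it requires ≥ 3 mask pixels and nonzero variance in
both channels. Zero in-mask variance makes the PCC undefined: such nuclei
are excluded from mean-PCC statistics but retained in frequency counts
(the call is still computable). Raw intensities are used — the PCC is
invariant under per-channel positive affine transforms, so uniform
background subtraction cannot change it.

## Spot detection and the co-localization call

Spots are detected on a scale-normalized Laplacian-of-Gaussian stack
(−σ²·LoG, σ on a geometric grid over 1–4 px, matching the diffraction-
limited focus size at the default geometry), as 3D local maxima with
response ≥ 0.3 × the maximum in-mask response, refined to sub-pixel
centroids by a per-axis quadratic fit and de-duplicated by suppression
within the stronger spot's scale. The image is centered by its in-mask
mean before filtering: the LoG of a constant is zero analytically, but
truncated kernels leave a residue proportional to the constant level that
would otherwise masquerade as response on flat images. A flat in-mask
image returns no spots.

The call is greedy nearest-neighbor matching of CFP spots (strongest
first) to unmatched YFP spots at centroid distance ≤ `d_max_px`
(default 2 px, closed boundary), positive iff at least one CFP spot is
matched. The distance threshold stands in for the visual criterion; an
optional scale-agreement factor ("same morphologies") exists but is off
by default to keep the call purely positional. Matching is monotone in
`d_max_px`: widening the radius never revokes a call.

## Cohort statistics

Frequencies are compared with the two-sided Fisher's exact test (standard
convention: sum of hypergeometric probabilities of all tables, fixed
margins, at most as probable as observed — delegated to
`scipy.stats.fisher_exact` and verified against exhaustive enumeration
for every table with group sizes ≤ 30). Mean PCCs are compared with the
classic equal-variance Student's t-test (df = n_a + n_b − 2), two-sided,
as named. Significance is flagged at α = 0.01. Both sidedness choices are
the conservative default. No multiple-testing correction is applied:
comparisons are single pairwise contrasts, and raw p-values are reported.
Nuclei are treated as independent observations; worm-level clustering is
out of scope.

## The synthetic generator

Each simulated nucleus is a filled disk (default radius 40 px in a
128×128 raster; the 640×640 still and 512×256 time-lapse acquisition
geometries are available presets). Noise-free expectations:

* YFP: `bg_out` outside the nucleus; inside, `f · (yfp_nuc + Σ territory
  Gaussians + enrichment · yfp_nuc · G(spot))` where f is a per-nucleus
  lognormal expression factor (σ_log = 0.3 by default — the probe is
  expressed at different levels in different cells and animals);
* CFP: `bg_out` plus a single Gaussian locus focus (amplitude 300 a.u.,
  σ = 2 px) everywhere.

The YFP enrichment at the locus is expressed **relative to the diffuse
nuclear level**, so the expression factor multiplies signal and
enrichment alike and cancels in the correlation expectation — PCC values
are comparable across differently expressing cells, which is the implicit
assumption behind averaging them. Two broad "chromosome territory" blobs
(amplitude 80 a.u., σ = radius/3) emulate the X-chromosome-like enriched
pattern; their centers are uniform over the whole nucleus disk. That
choice is deliberate: drawing territories preferentially near the center
makes both channels centrally concentrated and induces a spurious
positive PCC (≈ +0.02) with zero enrichment, whereas the uniform draw
keeps the null mean within sampling error of zero (asserted at n = 200).

Noise is Poisson shot noise (gain 5 photons/a.u.; `inf` disables it) plus
Gaussian read noise (σ = 5 a.u.), clipped at zero — the standard
fluorescence image-formation model, and the simplest that supports SNR
sweeps (SNR here = (in-nucleus level − background)/noise σ; defaults give
SNR ≈ 13). Images are quantized to the uint16 grid at generation time so
the TIFF round-trip (simulate → write → read → analyze) is bit-exact;
oracle tests that compare against closed-form expectation rasters disable
quantization via `quantize=False`.

Condition presets map to enrichment levels: strong recruiting sequences
(`her1`, `rex1`) → 4.0, a weakly modified promoter (`abts1b`) → 0.5, the
operator-only control (`laco-only`) and the male condition (no
modification at the locus) → 0.0. These reproduce the qualitative
ordering and sign structure of the motivating contrasts (null ≈ 0 <
weak < strong, with the strong condition's mean PCC near +0.5 under
default noise); absolute values are simulator properties, not predictions
for any real acquisition — real intensity statistics were never available
to calibrate against, so noise levels are chosen only to make
segmentation and correlation behave plausibly.

Time-lapse series fix the nucleus, territories and expression factor,
re-draw noise per frame, and move the locus by a Gaussian random walk
(step σ = 1 px/frame by default) reflected radially at the boundary of
the admissible region (nucleus radius minus 3 spot σ, so the focus stays
fully nuclear); reflection rather than rejection keeps the walk
deterministic in the number of random draws. Default acquisition: 11
frames at 30-min intervals, timestamps 0–300 min.

Reproducibility: a master seed is split into per-nucleus seeds via
`numpy.random.SeedSequence(master, spawn_key=(group, nucleus))` — a
splittable counter scheme with no collision risk; identical parameters
and seed give bit-identical images.

## Numerical and design choices

* 0-based (row, col) pixel coordinates and 8-connectivity throughout.
* Otsu ties break toward the lower threshold; foreground is strictly
  above the threshold.
* Sub-pixel offsets are clipped to ±0.5 px and applied only along axes
  where the response is locally concave.
* Undefined-PCC and segmentation-failure handling is decided once
  (exclude from mean-PCC only / exclude from both readouts, respectively)
  and honored by the cohort statistics and the CSV output.
* Fisher p-value comparison uses a 1 + 1e−7 relative tolerance when
  summing "at most as probable" tables, matching the standard
  implementation's tie handling.
* Channel order in TIFFs is YFP-then-CFP by manifest convention, with an
  override because microscope exports vary.

## Verification scales

The cohort-scale checks run at: 1,000 random masked pairs (PCC oracle),
100 random images (threshold oracle), all 245,025 tables with both group
sizes ≤ 30 (Fisher oracle), 20 seeds at SNR 5 (segmentation), 200 nuclei
and 200 two-cohort repeats at 25 nuclei/group (null calibration and
type-I), 50 nuclei per enrichment level over {0, 0.5, 1, 2, 4}
(monotonicity), 100 repeats at 25 nuclei/group (power; the motivating
cohorts used more than 24 animals per condition), and 50 nuclei with a
60% enriched fraction (frequency recovery). These sizes give the
binomial/sampling margins the assertions rely on while keeping the full
suite in single-digit minutes on one CPU.

## Limitations

The generator emulates single, roughly circular, well-separated nuclei
in 2D with Gaussian foci and spatially uniform noise. It does not model
z-structure, photobleaching, chromatic shift or registration error
between channels, multiple nuclei per frame, irregular nuclear shapes,
autofluorescence gradients, or movement during acquisition. Passing
tests therefore demonstrate the correctness and calibration of the
analysis on images satisfying those assumptions — not performance on any
particular microscope's data, for which the segmentation SNR sweep and
the configurable noise model are the entry points for revalidation.
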