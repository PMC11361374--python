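# Methods

This note documents the models, defaults and numerical choices behind
`nepheno`, what the synthetic-data generators do and do not emulate, and
the known limitations of each stage.

## Synthetic data: what is emulated

The generators exist so that every pipeline stage can be scored against a
known ground truth. They emulate the *geometry and statistics* that the
downstream operations are sensitive to, not optical realism.

**Nucleus images.** Nuclei are rasterized ellipses (semi-major axis drawn
from `radius_range`, default 18–28 px; eccentricity from
`eccentricity_range`, default 0–0.6; uniform orientation) placed without
overlap by rejection sampling with a bounded retry budget (default 1000
attempts per nucleus; exceeding it raises a placement error rather than
silently under-filling the field). The DAPI channel is the union of the
ellipse interiors and any planted bleb disks; the lamin-B1 channel is the
elliptical boundary ring only (default width 3 px). A bleb is a disk
centered on the ellipse boundary; its recorded truth mask is the
protruding part (disk minus ellipse), which is lamin-negative by
construction — exactly the DAPI-positive/lamin-negative definition the
bleb caller tests. Intensities are background (default 100) plus object
signal (default 1000), Gaussian-blurred (σ = 1 px) with additive Gaussian
noise (SD 10) clipped at zero. With blur and noise set to 0, thresholding
the DAPI channel at the background level reproduces the true object masks
pixel-for-pixel; this "geometric soundness" property is what makes exact
recall/precision statements about the detectors meaningful.

**Foci images.** Marker puncta are isotropic Gaussian spots (σ = 1.5 px,
diffraction-limited scale) at uniform positions strictly inside each
nucleus, with peak amplitude over background giving a defined peak SNR of
`focus_amplitude / noise_sd`. Planted foci are pairwise separated by at
least `min_focus_separation` (default 6σ): two spots closer than the
detector's resolution necessarily merge into one connected component
(that merge is documented detector behavior), so the default ground truth
plants individually resolvable spots and detection F1 measures detector
accuracy, not the resolution limit.

**FRAP traces.** The acquisition protocol is 3 pre-bleach frames plus 90
recovery frames at 1-s intervals (93 frames). The pre-bleach plateau is
normalized to 1.0 and the bleach is instantaneous between frames 3 and 4.
Post-bleach ROI intensity follows `y0 + (a − y0)(1 − exp(−b x))`; both ROI
and the unbleached reference decay as `exp(−reference_decay_rate · t)`
(default 0.002 s⁻¹) to emulate acquisition photobleaching, and additive
Gaussian noise (default SD 0.02 of the normalized scale) is applied to
the ROI. The reference-ratio correction cancels the decay exactly, so a
noiseless corrected trace equals the model to machine precision.

**Count matrices.** Per-gene means are log-normal (`exp(N(5, 1.5²))`,
median ≈ 150 counts); counts are negative-binomial with variance
`μ + φμ²` and a single shared dispersion φ (default 0.1, a typical bulk
RNA-seq scale). A fraction of genes has its group-2 mean multiplied by
`2^planted_log2fc`; per-sample size factors multiply all means of that
sample. Dispersion below ~1e-12 degrades gracefully to Poisson.

**What is not emulated:** 3-D structure, realistic point-spread functions,
cell-to-cell intensity heterogeneity, spatially correlated noise,
chromatin texture, uneven illumination, gene-specific dispersions and
count outliers. Tests passing on these synthetics therefore demonstrate
the correctness of the computations and their behavior under the stated
noise models — not performance on real micrographs or real RNA-seq, where
segmentation and testing error modes are richer.

All generators are deterministic: the same spec and seed give bit-identical
output.

## Segmentation

Identify-primary-objects style: Gaussian smoothing (σ = 1 px), global
threshold (Otsu by default — the common default of this kind of workflow;
a fixed threshold is available), hole filling, 8-connected components,
area gate (defaults 200–50 000 px²), and exclusion of any object with a
pixel in the first/last row or column. Labels are renumbered in
raster-scan order of each component's first pixel so output is stable and
comparable across runs. Hole filling precedes area filtering so a
ring-like lamin stain segments as a full nucleus — required for the
mask-subtraction bleb caller. An all-constant image yields zero objects.
Touching nuclei are *not* declumped by default (a documented limitation);
an optional distance-transform watershed sits behind
`SegmentationParams(declump_watershed=True)`. Marker-positive gating
(`gate_positive_nuclei`) retains objects whose mean marker intensity meets
a threshold, preserving label numbers.

## Morphometry and bleb calling

Area is the pixel count; perimeter is the Crofton multi-direction
estimator. A naive pixel-edge perimeter overestimates a disk's perimeter
by ~13%, which biases 4πA/P² low by >20% and would break the exact
"circle → 1" anchor; the Crofton estimate stays within ~1% for radii
≥ 20 px, and measured form factors of rasterized disks are asserted to
within ±5%. Rasterized form factors can marginally exceed 1.

Bleb calling matches DAPI and lamin objects one-to-one by maximal pixel
overlap (greedy on descending overlap, ties to the smaller label pair).
The lamin object is hole-filled before subtraction, because lamin B1
stains the envelope rim and subtracting an unfilled ring would mark the
entire nucleoplasm as bleb. Candidates are 8-connected components of
`DAPI \ filled(lamin)`; components below `min_bleb_area` (default 50 px²,
a declared parameter — the appropriate value depends on magnification)
or lying entirely within `edge_margin` (default 1 px) of the filled lamin
object are discarded as registration slivers. DAPI nuclei with no lamin
match are flagged and excluded from bleb statistics (count reported as
missing, not 0). A nucleus is "blebbed" if it has ≥ 1 bleb; the
percentage of blebbing is over nuclei with a defined count. Raising
`min_bleb_area` can only decrease counts (monotone by construction).

## Foci detection

Enhancement is a white top-hat with a disk of radius `feature_size`
(default 5 px), which zeroes flat backgrounds and removes constant
offsets and slow gradients — counts are invariant to adding a constant to
the raw image. Detection then thresholds within each nucleus at
background + k·spread (default k = 5) of the enhanced, lightly smoothed
signal (σ = 1 px, acting as a matched filter at the spot scale). The
background moments are estimated robustly — median and 1.4826·MAD — rather
than by the plain mean and SD: bright foci contribute most of the naive
within-nucleus variance, so a mean+SD threshold scales with spot
brightness and bright foci suppress their own detection; the robust
estimate targets the background distribution as long as foci occupy a
minority of nucleus pixels. When the MAD is zero up to float residue
(noiseless backgrounds) the plain SD is used as a fallback. Components
within 2–200 px² count as foci; nuclei under 10 px report a missing (not
zero) count. Raising k never increases any count. Spots closer than about
twice the above-threshold blob radius merge into one component and count
as one focus.

## FRAP

Correction is a double normalization: ROI divided frame-by-frame by the
unbleached reference (cancelling acquisition photobleaching), then scaled
so the pre-bleach mean is 1. The pre-bleach scaling is what makes the
plateau `a` interpretable on [0, 1] and the immobile-fraction percentage
a percentage. Fitting is bounded nonlinear least squares (trf) over
y0, a ∈ [0, 1.5], b ∈ (0, ∞), initialized from the first post-bleach
value, the mean of the last five values, and a log-linear fit of
`(a − y)/(a − y0)`; tolerances are tight enough that noiseless traces
recover parameters to better than 1e-6. The model value at x = 0 is
fitted (y0) rather than pinned to the first measured frame, for
robustness to acquisition jitter. Non-convergence returns
`converged=False` with derived fields withheld; summaries exclude such
fits but report their count.

Two immobile-fraction conventions are provided. The default (`plateau`)
reports IF% = a·100 — the definition printed alongside this fitting model
in the analysis this package reproduces. With a 0→1 double-normalized
trace, however, the plateau a is conventionally the *mobile* fraction and
the immobile fraction is (1 − a)·100; that is available as
`immobile_convention="complement"`. The package does not guess intent:
it implements the printed formula as the default and surfaces the switch.
t½ = ln 2 / b holds identically for every converged fit, by construction.

## Differential expression

Size factors are median-of-ratios: per sample, the median over usable
genes (no zero count in any sample) of the ratio to the gene's
across-sample geometric mean. Factors are defined up to a common scale;
equivariance statements are about factor ratios. The built-in per-gene
test is a pooled-variance t test on log2(normalized + 0.5) with the fold
change computed from normalized group means (pseudocount 0.5 for
zero-count genes); it is a pluggable stand-in with approximately uniform
null p-values at moderate dispersion, not a negative-binomial Wald test —
externally computed (gene, log2fc, pvalue) tables are accepted anywhere
downstream. BH adjustment is the standard step-up procedure (delegated to
statsmodels and verified against a literal brute-force implementation of
the definition). DE subsetting uses *strict* inequalities — padj < 0.001
and |log2FC| > 2 — so boundary values are excluded, and no gene-level
pre-filter is applied by default.

## Statistics and aggregation

The unpaired t test is Student's pooled-variance test (the named test in
the readouts this package reproduces); Welch is behind a flag. Zero
variance in both groups returns p = 1 for equal means and p = 0
otherwise, by convention, instead of NaN. ANOVA uses the one-way F test
with Tukey HSD adjusted pairwise p-values from the studentized-range
distribution; all-constant input returns an invalid-result flag rather
than raising. For large family-wise-error simulations a vectorized
max-studentized-range path is provided
(`max_studentized_range`/`tukey_critical_q`); for balanced designs
`q > q_crit` is exactly equivalent to the smallest Tukey-adjusted p being
below α, and the equivalence is asserted against `anova_tukey` in the
test suite.

Replicate-first aggregation is the default reporting pattern: a statistic
(mean form factor, % blebbing, % foci-positive) is computed per
biological replicate, and condition-level tests run on the replicate
values (typically n = 3), not on pooled cells — pooling would treat every
cell as independent and pseudo-replicate. Significance stars: ns > 0.05,
\* < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001.

## Problem sizes used in the validation suite

The simulation scales were chosen to make each statistical check
well-powered while keeping the whole suite quick on a laptop: 200
noiseless nuclei for bleb recall/precision; 12 nuclei × 5 foci per SNR
level for focus F1; 25 noisy traces per FRAP condition and a 27-point
kinetic parameter grid; 2000 genes (100 planted DE) for the DE chain and
5000 genes for null-uniformity; 10⁴ null replicates for the type-I-error
and family-wise-error checks; and a 2-condition × 3-replicate × 300-nucleus
imaging experiment (planted blebbing 10% vs 40%) for the end-to-end test.

## Known limitations

- No declumping by default: merged adjacent nuclei are filtered out by the
  area gate rather than split.
- Bleb calling depends on cross-channel registration; real misalignment
  larger than `edge_margin` produces rim artifacts.
- The built-in per-gene test is underpowered relative to NB-based engines
  at small n and is meant as a default for synthetic data, not a
  replacement for a dedicated DE package.
- All geometry is 2-D and in pixel units; no physical calibration is
  applied anywhere.
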