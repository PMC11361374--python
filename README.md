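# nepheno

Quantitative phenotyping of nuclear-envelope (NE) integrity from two-channel
fluorescence microscopy, plus the two companion analyses that usually travel
with it: FRAP recovery kinetics of NE proteins and differential-expression
filtering of gene-level count matrices. The package is aimed at cell
biologists who score NE deformation, blebbing and rupture across conditions
and want the whole measurement chain — segmentation, morphometry, foci
counting, curve fitting, multiple-testing correction and replicate-level
statistics — as tested, scriptable code instead of a point-and-click
pipeline. Every stage can be exercised end-to-end on synthetic images,
traces and count matrices with known ground truth.

## What it computes

**Nuclear morphometry.** Nuclei are segmented from the DAPI channel
(Gaussian smoothing, Otsu threshold, hole filling, area gates,
border-object exclusion). For each nucleus the *form factor*

    FF = 4πA / P²

is computed from the pixel area A and a Crofton multi-direction perimeter
estimate P. FF = 1 for a perfect circle and decreases with deformation.

**Bleb calling.** A nuclear bleb is chromatin protruding through a gap in
the lamina: DAPI-positive, lamin-B1-negative. Blebs are called per nucleus
as the connected components of `DAPI object \ filled(lamin object)` after
matching objects across channels by maximal overlap, filtered by a minimum
pixel area. The headline readout is the percentage of blebbed nuclei.

**Foci counting.** Puncta (e.g. the dsDNA sensor cGAS at rupture sites, or
proximity-ligation spots) are enhanced with a white top-hat transform and
detected per nucleus at a robust adaptive threshold; reported as counts per
nucleus and the percentage of foci-positive nuclei.

**FRAP kinetics.** Bleached-ROI traces are reference-corrected and
normalized, then fitted with

    y = y0 + (a − y0)(1 − e^(−bx)),

giving the half-time of recovery t½ = ln 2 / b and an immobile-fraction
percentage (two reporting conventions available, see `docs/methods.md`).

**Differential expression filtering.** Median-of-ratios size factors,
Benjamini–Hochberg adjustment, and strict thresholding
(padj < 0.001, |log2FC| > 2 by default) into up/down gene lists. The
per-gene test is pluggable; a simple t test on log-normalized counts is the
built-in default.

**Statistics.** Two-tailed paired/unpaired t tests (Student pooled-variance
by default), one-way ANOVA with Tukey's HSD, and replicate-first
aggregation: per-replicate summaries are computed first and condition-level
tests run on those, never on pooled single cells.

## Worked example

```python
import nepheno as ne

spec = ne.NucleusImageSpec(image_size=(512, 512), n_nuclei=8,
                           blebs_per_nucleus=("bernoulli", 0.5), seed=1)
dapi, lamin, truth = ne.make_nucleus_image(spec)

dm = ne.segment_nuclei(dapi)
lm = ne.segment_nuclei(lamin)
records = ne.measure_nuclei(dm, {"dapi": dapi})
blebs, unmatched = ne.detect_blebs(dm, lm)
records = records.merge(ne.bleb_counts_per_nucleus(dm, blebs, unmatched), on="label")
print(records[["label", "area_px", "form_factor", "n_blebs"]].round(3).to_string(index=False))
print(f"percent blebbing: {ne.percent_blebbing(records['n_blebs']):.1f}%")

fit = ne.fit_trace(ne.simulate_frap(
    ne.FrapSimSpec(y0=0.2, a=0.7, b=0.1, noise_sd=0.02, seed=1)))
print(f"FRAP: a={fit.a:.3f} b={fit.b:.4f} "
      f"IF%={fit.immobile_fraction_pct:.1f} t1/2={fit.t_half:.2f}s")
```

prints

```
 label  area_px  form_factor  n_blebs
     1   1015.0        0.995      0.0
     2   1422.0        0.942      1.0
     3   1775.0        1.004      0.0
     4   1731.0        0.997      0.0
     5   1494.0        0.889      1.0
     6   1035.0        0.995      0.0
     7   1304.0        0.956      0.0
     8   1485.0        0.907      1.0
percent blebbing: 37.5%
FRAP: a=0.691 b=0.0998 IF%=69.1 t1/2=6.95s
```

Eight nuclei were planted, four of them with one bleb each; three of the
four are recovered at the default minimum-bleb-area filter (37.5%
blebbed), and blebbed nuclei have visibly lower form factors. The FRAP fit
recovers the planted kinetics (a = 0.7, b = 0.1 s⁻¹, t½ = 6.93 s) from a
noisy 93-frame trace. Rasterized form factors can slightly exceed 1
(perimeter-estimator bias, a few tenths of a percent for round nuclei).

A command-line interface mirrors the library:

```sh
ne-pheno simulate nuclei --seed 1 --out sim/
ne-pheno measure --dapi sim/dapi.tif --lamin sim/laminB1.tif --out out/
ne-pheno frap --input trace.csv --out fits/
ne-pheno de --counts counts.tsv --groups groups.csv --out de/
ne-pheno run --config experiment.yaml --out run/   # full pipeline + manifest
```

## Layout

- `src/nepheno/synthetic_data.py` — ground-truthed generators (images, FRAP traces, count matrices)
- `src/nepheno/io_formats.py` — TIFF/CSV/JSON/YAML I/O and the raster/table data model
- `src/nepheno/segmentation.py` — nucleus identification and marker-positive gating
- `src/nepheno/morphometry.py` — form factor, bleb calling, condition summaries
- `src/nepheno/foci.py` — speckle enhancement and per-nucleus focus counting
- `src/nepheno/frap.py` — bleach correction, recovery fitting, kinetic summaries
- `src/nepheno/transcript_stats.py` — size factors, BH adjustment, DE subsetting
- `src/nepheno/stats_reporting.py` — t tests, ANOVA/Tukey, replicate aggregation
- `src/nepheno/cli.py` — `ne-pheno` command-line orchestration
- `docs/methods.md` — models, parameter choices, numerical details, limitations
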