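# Methods

## Measurement model

DAPI fluorescence is assumed linear in DNA amount over the measured range
(roughly 0.5–20 pg here).  A nucleus's background-corrected integrated
optical density (IOD, arbitrary units) therefore relates to its DNA content
through a single unknown gain, eliminated by ratioing against co-stained
erythrocyte nuclei of constant content:

    pg = standard_pg · IOD / mean IOD(standards),    standard_pg = 2.4 pg.

The calibration is single-ratio by construction — no multi-point curve is
fitted, and `to_picograms` is exactly linear and homogeneous (`pg(a·x) =
a·pg(x)`).  The standard population is summarised by a 10% two-sided
trimmed mean to damp occasional mis-segmented standards; with a single
standard nucleus the plain value is used and a warning logged.  Standards
and samples are assumed to share one slide and exposure; calibrating one
image against standards in another is allowed only behind an explicit
`allow_cross_image` acknowledgment, because fluorometric comparability
across exposures is an assumption, not a given.

## Synthetic scenes

The generator is the package's substitute for the micrographs this kind of
study is performed on; it emulates the statistical structure the analysis
assumes and provides exact per-nucleus ground truth.

**DNA content.**  Each stage is a mixture of components; a component draws
per-nucleus true pg from a lognormal with the component's arithmetic mean
and coefficient of variation.  The lognormal was chosen because
fluorometric dispersion is scale-proportional and the values are positive
by construction.  The component cv is realised as nucleus-to-nucleus
variation in ground-truth pg (with a separate `measurement_cv`, default 0,
for pure intensity noise): this makes per-nucleus recovery errors
well-defined — the pipeline recovers each nucleus's true pg to a median
error well under 5% at default noise — while the zero-cv case still yields
exactly `gain · mean_pg` intensities.

**Stage presets.**  The seven presets carry the published per-stage means,
SDs and nucleus counts (released zoospores 0.76 ± 0.07 pg, n = 387;
unreleased zoospores 0.79 ± 0.05, n = 64; male gametophytes 2.01 ± 0.22,
n = 1464; female gametophytes 2.27 ± 0.56, n = 946; embryonic sporophytes
1.64 ± 0.21, n = 408; meristoderm 1.51 ± 0.16, n = 905; cortex/medulla
2.40 ± 0.41, n = 629).  Stages in which minor higher-ploidy subpopulations
were observed gain extra components at 2×/4×/8× the main mean with default
fractions 2% (`+`) and 10% (`++`); the true abundances behind those flags
are not published, so the fractions are explicit configuration, not
inferred fact.  The cortex/medulla preset spreads its abundant high-C flag
over 4C/8C/16C components (10% / 6% / 4%).

**Nucleus size.**  Area couples to DNA content as
`area = area_per_pg · size_scale · pg^(2/3)` (volume-proportional DNA under
a spherical nucleus; exponent 1.0 available).  `size_scale` is a per-stage
factor set from the published relative-nucleus-size column, because
nucleus size across tissues tracks cell size and vacuolation, not DNA
alone — without it the generator would order female gametophytes above
meristoderm in size, contradicting the observed ladder.  Components listed
as decoupled (the male-gametophyte preset by default) draw their size from
the 1C-sized distribution regardless of pg, reproducing the observed
anomaly: male mean nucleus size within a few percent of zoospores at ~2.6×
the DNA.  A 5% lognormal area jitter is applied throughout.

**Rendering.**  Nuclei are smooth elliptical blobs (raised-cosine radial
profile, zero at the rim) scaled so the integrated signal above background
equals the ground-truth intensity exactly; placement is rejection sampling
with pairwise bounding-circle separation (default 4 px) and a border
margin, bounded at 10,000 retries per nucleus before a `PlacementError`
advising a larger image.  `suggest_shape` sizes a square image for ~12%
packing.  Background is `level + linear gradient + N(0, noise_sd)` with
defaults 100 / (0.005, 0.005) per px / 2.0 — a visibly tilted, realistically
noisy field at the default gain of 5000 a.u./pg (zoospore nuclei then
average ≈19 counts/px over background, a routine exposure).  Identical spec
and seed give bit-identical tables and images.

**What the generator does not emulate** — and hence what passing tests do
not certify about real micrographs: optically blurred nucleus boundaries
and halos, chloroplast autofluorescence, touching or overlapping nuclei in
tissue context (the renderer places nuclei disjointly unless positions are
forced), saturation, vignetting or other non-linear shading, and staining
heterogeneity beyond the lognormal dispersions.

## Image quantification

Background is estimated by block-median reduction (8× by default), median
filtering at the user radius (which must exceed the largest nucleus
radius), Gaussian smoothing and bilinear upsampling; the estimator is
unbiased under symmetric noise and follows linear gradients, and recovers
the generating background under nucleus centroids to well under 1% on
synthetic scenes.  skimage's rolling-ball is available as an alternative.

Segmentation thresholds the background-subtracted image with Otsu's
method, guarded from below by 3 robust sigmas (1.4826·MAD) so nucleus-free
images yield an empty mask rather than a noise-driven threshold; a fixed
threshold and a plain 3-sigma method are configurable.  Connected regions
are filtered to `[min_area, max_area]`; an optional distance-transform
watershed (off by default) splits touching nuclei.  Labels are grown by
2 px, and IOD is integrated over regions expanded by a further 4 px (never
across a neighbouring label): the rendered nuclei have smooth rims whose
sub-threshold tails would otherwise be lost in proportions that differ
between dim samples and bright standards, biasing the calibrated ratio.
Regions touching the image border are excluded from measurement by default
(their signal is truncated); coordinates are 0-based (row, col).

Relative nucleus size is the segmented area divided by a reference area,
by default the mean area of the run's standard nuclei — making NRS
unitless and comparable across runs, though only up to a constant factor
relative to any other normalisation.  Standards in images are identified
by a standards mask (the generator emits one; for real images a curated
erythrocyte mask), a separate standards image, or an IOD gate.

## Frequency classes and the peak-class estimator

Classes are half-open `[e_i, e_i+1)` of equal width, anchored at
`floor(min/width)·width` so edges sit on multiples of the width.  The
default width is 0.1 pg, matching the two-decimal granularity of reported
values; Freedman–Diaconis is available as `"auto"`.  The peak region is
the set of tied maximum-count classes plus anything between them; it grows
contiguously while the neighbouring count strictly exceeds half the peak
count ("above 50%" is exclusive).  The estimate is the mean ± sample SD of
the raw values in the included classes (a count-weighted midpoint mode
exists for comparison).  The all-nuclei mean ± SD is always reported
alongside, since both summaries are in common use and they differ exactly
when minor high-C subpopulations are present.

A property worth knowing: the estimator is quantised.  Which neighbour
classes cross the 50% line flips between finite samples, and each flip
moves the included-class mean by a few hundredths of a pg; with edges
anchored at multiples of 0.1 pg, a stage whose mode sits near a class edge
(e.g. mean 0.76, SD 0.07) alternates between a one-class and a two-class
estimate (≈0.75 vs ≈0.78).  For broad stages the lognormal skew also
biases the trimmed mean slightly low (≈−0.03 pg at cv ≈ 0.11).  The
estimator therefore reproduces generating means to ~0.02–0.03 pg — ample
for C-class assignment, which operates on log₂ ratios — but it is not a
√n-consistent mean estimator, and tests asserting recovery beyond that
granularity will flicker.  The implementation is cross-checked against a
brute-force interval-enumeration oracle on random histograms.

## C-class ladder and flags

`assign_c_class` places `pg / reference_1C` on {1, 2, 4, 8, 16} by nearest
log₂ distance; boundaries sit at geometric midpoints (√2·1C, 2√2·1C, …)
and exact midpoints resolve upward.  `in_tolerance` flags deviations
beyond 0.25 log₂ units from the called class.  The reference defaults to
the released-zoospore peak-class mean of the same run.  Note that stages
whose content sits between ladder points — male gametophytes at 2.6× 1C,
cortex/medulla at ~3.1× — are numerically nearest 2C and 4C respectively
and are reported as such with `in_tolerance=False`; whether such values
reflect polyteny at a nominal lower ploidy is a biological relabeling the
caller deliberately does not make.  Flags for classes above the main one
are `+` for fractions in (0, 0.05] and `++` above; 0.05 is configurable.

`stage_ratio` rounds half away from zero to one decimal (2.01/0.76 → 2.6);
`pg_to_mb` multiplies by 980.

## Pipeline, determinism and problem sizes

`run_pipeline` resolves a YAML/JSON/dict configuration against explicit
defaults, logs every design-decision parameter in effect, and writes
measurements, calibrations, per-stage histograms, a Table-style summary
(pg rounded to 2 decimals, ratios to 1), a correlation report and figures.
Per-stage seeds derive from the run seed via `SeedSequence`, so reruns are
byte-identical.  The size–content report computes per-nucleus Pearson and
Spearman coefficients (undefined, not zero, under zero variance) plus
per-stage mean residuals from the pooled least-squares fit; with the
decoupled male group in the pool the Pearson coefficient stays positive
while the Spearman can go negative — the rank structure genuinely breaks,
consistent with the non-linear relation the correlation is meant to
expose.

The test suite and acceptance script run stage simulations at the
published nucleus counts; recovery replicate counts (60 table-route plus a
handful of full image-route replicates per stage) and scene sizes are the
package's choice of desk-scale problem sizes.

## Known limitations

- The peak-class estimator's quantisation (above) bounds recovery accuracy
  at ~0.02–0.03 pg regardless of n.
- Segmentation is 2-D, single-channel, and tuned for well-separated
  nuclei; dense tissue fields need the watershed option and realistic
  expectations.
- NRS matches any published absolute scale only up to a constant, because
  the reference area is the run's own standard population.
- The synthetic generator's fidelity limits are listed above; none of the
  tests certify performance on real micrographs with optics-induced blur
  or autofluorescence.
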