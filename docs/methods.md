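# Methods

This note records the models, conventions and numerical choices behind each
filotip module, what the synthetic generators do and do not emulate, and the
known limitations.

## Profile mapping

**Normalization.** `normalize_image` linearly rescales an image so the
brightest pixel inside a supplied cell mask maps to 65535 and the modal
pixel value outside the mask (the background floor) maps to 0, clipping to
the 16-bit range. The mode is used rather than the mean because dim cellular
signal outside the mask would otherwise inflate the floor. Normalization
happens **before** profile extraction, so the absolute tip-positivity
threshold (5000 ADU) refers to the adjusted 16-bit scale; a constant image
has no defined scale and raises.

**Extraction.** Profiles are sampled along tip-first polylines at ~1-pixel
arc spacing by bilinear interpolation; sample 0 is the tip vertex.
`width > 1` averages parallel samples offset perpendicular to the local
tangent in 1-pixel steps. Filopodium length is the polyline arc length
times the pixel size (µm); no length normalization is applied anywhere.

**Binning.** Each profile is reduced to exactly 40 bins: sample *i* of *n*
goes to bin `floor(i·40/n)` (equal-width partition of the sample index) and
each bin takes the **median** of its samples. Profiles with fewer than 40
samples are nearest-neighbour upsampled to 40 and flagged rather than
rejected — short filopodia are real and should stay in the analysis. Maps
are per-bin arithmetic means across profiles, with the contributing *n*
recorded.

**Enrichment and positivity.** The tip is bins 1–6 and the shaft bins 7–40;
the enrichment ratio is tip mean over shaft mean (undefined and raised when
the shaft mean is zero; callers exclude and log such profiles). A
filopodium is tip-positive when its tip-bin average is **at least** 5000 —
the boundary is inclusive. Both the tip-bin window and the threshold are
parameters; the defaults are the conventional choices above.

## Spot counting (screen)

Maxima follow prominence ("noise tolerance") semantics: a maximum counts
when the descent to the saddle separating it from any higher region is at
least the prominence. This is computed by greyscale morphological
reconstruction of `image − h` under `image` (h-maxima); on integer images
`h = prominence − 0.5` makes the ≥-rule exact. Two peaks joined by a ridge
whose dip is smaller than the prominence merge into one count. Before
counting, an optional rolling-ball background subtraction (default radius
50 px) is applied. The cell mask comes from the F-actin channel: Otsu
threshold (overridable), hole filling, largest connected component; only
maxima **outside** the mask are counted, separating filopodial puncta from
intracellular pools. An empty mask is an error distinct from a zero count.
The prominence has no canonical value and is a required analysis parameter;
the fixtures use 2000 ADU.

## Tracking

Detection is scale-normalized Laplacian-of-Gaussian filtering at
`σ = diameter/(2√2)` (default diameter 0.8 µm), local maxima above a quality
threshold on the detector's arbitrary response scale, and per-axis quadratic
subpixel refinement clipped to ±0.5 px. Linking is the gap-free special
case of LAP tracking: per consecutive frame pair, an exact minimum-cost
bipartite assignment (Hungarian algorithm) over candidate pairs within the
1 µm gate; unmatched detections start or end tracks, and no gap closing,
splitting or merging is performed. Lifetime is `(frames − 1) × interval`
(default 5 s); tracks touching the first or last movie frame are censored
and excluded from summaries by default, since their true span is unknown.
The quality threshold cannot be mapped onto any external software's units
and is exposed as a free parameter.

## Immunogold distributions

Density curves use a Gaussian KDE; "auto" bandwidth is Silverman's rule, or
a fixed kernel SD in nm may be given (required for zero-variance input).
The default grid extends four bandwidths beyond the data so the trapezoidal
integral of the returned curve is 1 within ±0.01. The two-sample KS
statistic is the exact sup-difference of the ECDFs. The bootstrap test
resamples **both** groups, at their original sizes, with replacement from
the pooled data (the natural null of a common distribution) and reports
`p = (1 + #{D* ≥ D}) / (n_boot + 1)` — never exactly zero; the default is
1000 resamples. Distances stay on their input nm scale throughout.

## Binding model

The bound-complex concentration solves the single-site mass-action
quadratic exactly, in the cancellation-free form
`[AL] = 2A₀L₀ / (b + √(b² − 4A₀L₀))` with `b = A₀+L₀+K_d`, so ligand
depletion of the fixed 20 nM fluorescent partner is modeled rather than
approximated. The fit estimates three parameters (K_d, F_free, F_bound):
amplitudes are left free because fixing them requires plateau knowledge the
data may not contain. For fixed K_d the model is linear in the amplitudes,
so "auto" initialization profiles the SSE over a 61-point log grid of K_d
in [10⁻¹², 1] M by linear least squares and refines the best seed with a
bounded trust-region solver on log₁₀K_d. A fitted signal swing (|ΔF| times
the realized bound-fraction range) below three residual standard deviations
raises a no-binding error instead of reporting a meaningless K_d; automatic
initialization also requires the ligand series to span at least two decades.
Replicates are pooled by concatenating raw points, not by averaging per
concentration. An optional case-resampling bootstrap gives a percentile
95% CI for K_d.

## Flow, qPCR and resampling statistics

The two activity indices are plain ratios of per-condition population
summaries (means by default, medians flagged); both are invariant under a
common detector gain. Fold change is `2^−ΔΔCt` against a reference gene and
control condition, invariant to constant Ct shifts. The randomization test
permutes group labels preserving sizes, uses the difference of means by
default (medians optional), and reports the two-sided
`(1 + #{|s*| ≥ |s|}) / (R + 1)` Monte-Carlo p (default R = 1000), or the
exact enumeration proportion when requested. Effect sizes are differences
of group statistics with independent within-group percentile-bootstrap CIs.
Tukey summaries use linear-interpolation (type-7) quartiles — the rule must
be declared because the 1.5×IQR fences depend on it — with whiskers at the
most extreme observations inside the fences. Gating is upstream of this
module; only a rectangular gate for synthetic tables is provided.

## Synthetic generators

Scenes place a circular cell body at the image centre and straight,
1-px-wide anti-aliased filopodia radiating from its boundary; polylines are
stored tip-first with the base on the cell-boundary circle. Channel laws:
`tip_exponential` (amplitude × exp(−d/decay) in arc distance from the tip,
present on each filopodium with probability `tip_positive_fraction`, the
stored ground truth), `uniform` (body + filopodia), `shaft_uniform`
(filopodia only), `body_only`. Noise is `Poisson(I/g)·g + N(0, σ_read)`
then clipped and rounded to uint16 — a generic camera model, declared not
inferred. Defaults (0.08 µm pixels, 8 µm cell radius, 30 filopodia of
2–8 µm, gain 2, read SD 100 ADU) give a super-resolution-scale fixture on
which absolute ADU thresholds are meaningful. Gold particles draw from a
truncated exponential (tip-concentrated) or uniform law; titrations follow
the depletion quadratic with Gaussian noise; flow populations are
log-normal per stain; time lapses give each spot an Exp(mean) lifetime
rounded **up** to whole frames (≥ 1), a uniform birth frame, and uniform
steps of at most `max_step` µm per frame clipped to the arena.

What the generators do **not** emulate: curved or branching filopodia, a
realistic PSF or structured-illumination reconstruction artifacts,
photobleaching, spatially varying background, spot-intensity fluctuation,
antibody labeling efficiency, or gating artifacts in flow data. Passing
recovery tests therefore demonstrates correctness of the measurement code
under the stated laws, not robustness to every property of real data.

## Numerical choices and degenerate inputs

Seeds: every stochastic routine takes an explicit seed; the pipeline
derives per-stage seeds by stable SHA-256 hashing of (global seed, stage
name), keeping stages independently reproducible. Ties in the assignment
step are resolved by the LAP solver deterministically; forbidden links use
a large finite cost so maximizing the number of in-gate links dominates.
Quadratic-root evaluation is exact to ~1e−10 relative residual. Degenerate
cases raise typed errors rather than returning sentinels: empty masks,
constant images, zero shaft means, flat titrations, F_free = F_bound,
missing Ct cells, sub-pixel spot diameters, non-positive intervals.

## Problem sizes

The test suite exercises the stochastic properties at deliberate desk
scale: 500 null simulations × 199 resamples for randomization-test
calibration, 400 simulations × 99 bootstrap replicates for KS-p uniformity,
8 scenes × 50 filopodia (400 total) for positivity recovery, 2000 spots ×
150 frames for lifetime recovery, and 200 noisy titrations for the K_d bias
study. These sizes give 3-SE binomial bands of a few percentage points
while keeping the full suite under a minute on one CPU.

## Known limitations

Filopodium tracing is out of scope — profiles come from annotations or the
generator, mirroring manual tracing practice. TIFF calibration relies on
the YAML sidecar, not OME metadata. The LoG quality scale is
detector-specific, so thresholds must be calibrated per dataset. The
bootstrap-KS null is the pooled-resampling construction; other bootstrap
variants exist and give slightly different small-sample behaviour.
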