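# Methods

`mapkit` implements the analysis layer of a navigated-TMS (nTMS) motor-
mapping study — from raw stimulation-session tables and EMG sweeps to
group-level nonparametric statistics — together with a synthetic-data
generator that produces whole cohorts with the statistical structure the
analysis assumes. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
emulate.

## Coordinate and protocol conventions

Coordinates are right-handed RAS millimetres; `x < 0` is the left
hemisphere, `y` runs posterior→anterior, `z` inferior→superior.
Protocol constants live in `mapkit.config.Defaults` (preset
`table1_table2_defaults`): 5 mm stimulation-grid line spacing, mapping at
110 % of the APB resting motor threshold (rMT), rest/active blocks at
120 % rMT, 11 rest MEPs (first discarded), 7 silent-period trials
(minimum and maximum trimmed), MEP acceptance at ≥ 50 µV peak-to-peak,
90 % confidence ellipsoids, 10 mm FWHM smoothing, 4×4×2-voxel box ROIs
at 1.5 mm voxels, and an uncorrected voxel-wise alpha of 0.001.

## Synthetic cortex generator

Each muscle (APB, ADM, FDI hand; ECR, FCR, BB arm) has a latent cortical
field: a 2D Gaussian amplitude profile with spread σ (4.5–6 mm), peak
amplitude `a_max` (400–1200 µV) and a site threshold `t_rel`·rMT. A
stimulus at in-plane distance `d` and intensity `I` yields

    amplitude = a_max · exp(−d²/(2σ²)) · logistic((I − t_rel·rMT)/(0.05·rMT)) · ε

with multiplicative log-normal noise ε (σ_log = 0.5, the scale of
well-documented trial-to-trial MEP variability). Amplitudes below a
20 µV noise floor are zeroed so the ≥ 50 µV criterion does real work.
Hand-muscle field centres cluster in a hand-knob-like patch at
(±35, −22, 68) mm; arm centres sit ~8–10 mm medial. Stimulation grids
lie on the plane tangent to a spherical head model at the field
centroid; curvature is ignored at grid scale.

Group presets encode two cohorts. The control preset is left/right
symmetric up to noise. The lateralized ("AS-like") preset toggles five
effects, each switchable by a flag: left-hemisphere arm footprint area
×1.4 (σ scaled by √1.4), arm fields shifted 4 mm toward the hand cluster
in the left hemisphere (raising hand/arm overlap), a shorter
right-hemisphere silent period (97 vs 124 ms preset means), a longer
left-hemisphere active MEP latency, and left-hemisphere CoG scatter with
3× the cluster volume (per-axis jitter scaled by 3^(1/3)). Scalar
measures (rMT, silent period, MEP amplitude/latency, box-and-block
scores, daily activity) are drawn from group mean/SD presets truncated
to physiological ranges.

EMG sweeps are built constructively: tonic Gaussian background (60 µV
RMS for active trials, 4 µV at rest), a biphasic Hann-windowed sine MEP
scaled to the target peak-to-peak, a near-silent segment (2 % residual)
of the target silent-period duration after the MEP end, then resumed
background. Tissue-probability volumes are a uniform background (0.55)
with box patches at per-ROI true densities plus voxel noise, clipped to
[0, 1]; a canonical 40×48×40 grid at 1.5 mm carries twelve ROIs
(face/hand/leg × motor/sensory × L/R).

Everything derives from named substreams of one master seed, so
identical seeds give byte-identical serialized cohorts, and every
artifact retains the latent parameters that produced it for
parameter-recovery testing.

What the generator does **not** emulate: biophysical E-field spread,
coil orientation, scalp–cortex distance, cortical folding (fields are
planar Gaussians), non-stationary EMG background, or realistic anatomy
in the volumes. Passing tests therefore demonstrate correctness of the
measurement and statistics layers under the stated model, not
performance on vendor data.

## EMG features

MEP amplitude is the peak-to-peak of the 10–60 ms post-stimulus window;
onset latency is the first crossing of |signal| above the pre-stimulus
mean + 3·SD. Amplitude is measured on rest trials; with tonic
contraction the background (±2.5 SD excursions of a 60 µV RMS signal)
contaminates peak-to-peak readings by several percent, which is why the
protocol takes amplitudes at rest. The rest-block summary discards the
first trial (systematically facilitated) and averages the remaining ten.

Silent-period duration is measured on the 5 ms moving-average rectified
trace. "Absolute EMG silence" cannot be literal zero in noise, so: MEP
end = last sample above (pre-stimulus mean + 2·SD of the smoothed trace)
within the MEP window; background return = first subsequent sample at or
above 50 % of the pre-stimulus smoothed level sustained for 5 ms. A
mean-plus-2·SD *return* criterion was rejected on calibration grounds:
the smoothed tonic background sits at its own mean, so a sustained
excursion above mean + 2·SD essentially never occurs and the return
would be missed; the half-of-baseline sustained criterion is standard
silent-period practice. Trials without tonic background (rectified
pre-stimulus mean below 10 µV) are flagged invalid. The block summary
trims exactly one minimum and one maximum before averaging. All
thresholds are config-exposed.

## Threshold hunting

rMT is estimated by sequential maximum likelihood (ML-PEST): response
probability Φ((I − t)/s) with relative spread s = 0.07·t (the published
assumption of adaptive motor-threshold tools), candidate grid 20–100
%MSO in 0.1 steps, each stimulus delivered at the current ML estimate
rounded to 1 %MSO (start 45, ties to the lower intensity). The
likelihood carries two virtual anchor trials — a non-response at 20 and
a response at 100 %MSO — keeping it proper before both response types
have been observed; their influence vanishes as data accumulate. With 20
stimuli the estimate recovers a 56 %MSO threshold to within ±2 %MSO in
≈ 89–90 % of runs; this is essentially the information bound — even 20
stimuli placed exactly at the (unknown) true threshold reach only ≈ 92 %.

## Motor-map metrics

The centre of gravity (CoG) is the amplitude-weighted mean of
accepted-site coordinates Σaᵢxᵢ/Σaᵢ (an unweighted accepted-site
centroid is available via `weighted=False`; weighted is the default).

Representation areas: sites are projected onto the two leading principal
axes of the site cloud (the out-of-plane residual is reported; for
tangent-plane grids it is bounded by head-model curvature), amplitudes —
zeros at no-response sites anchor the map borders — are interpolated by
a thin-plate spline (`scipy.interpolate.RBFInterpolator`) onto a 0.5 mm
lattice over the mapped region padded by one grid spacing (5 mm),
clamped at ≥ 0, and the area is the count of cells ≥ 50 µV times the
cell area, in cm². With fewer than four accepted sites the spline is
unreliable and the area falls back to accepted-site count × (5 mm)²,
flagged. Composite hand/arm maps take the per-site **maximum** across
member muscles, preserving the "any member responded" semantics the
overlap definition requires. Hand and arm areas for one hemisphere are
computed on a shared plane and lattice; relative overlap is
100·|intersection|/|union| of the two super-threshold masks. Ratio
metrics (hand/arm per hemisphere, left/right per muscle set) propagate
zero denominators as flagged NaNs.

The spline-area estimator was calibrated against an analytic oracle: a
Gaussian field whose ≥ 50 µV contour encloses exactly 4.0 cm² is
recovered to ≈ 0.3 % at 5 mm sampling (tolerances in the tests are the
looser 10 %/3 % the sampling theory supports in general position).

## CoG geometry

CoGs are affinely normalized per subject (identity default; nonlinear
warps are out of scope — the pipeline consumes an affine). The
confidence ellipsoid of a CoG cluster has centre at the sample mean and
semi-axis i = √(q·λᵢ) along eigenvector i of the sample covariance
(n−1 divisor), q the chi-square quantile at the confidence level with
3 df (q ≈ 6.2514 at 90 %). The covariance is **not** divided by n: the
ellipsoid describes cluster dispersion, not mean uncertainty. Volume is
(4/3)π·∏(semi-axes), reported in cm³. Principal orientation is labelled
by the coordinate axis with the largest |cosine| to the leading
eigenvector (x lateral–medial, y anterior–posterior, z
superior–inferior; ties → "oblique").

## ROI morphometry

Smoothing is separable Gaussian convolution, σ = FWHM/(2√(2 ln 2))
scaled per axis by voxel size, reflect padding, re-clipped to [0, 1] for
probability maps. ROI density is the arithmetic mean of the 4×4×2-voxel
box (span [c − e//2, c − e//2 + e) per axis); out-of-bounds boxes are
rejected rather than cropped, and densities are extracted from
*unsmoothed* subject maps by default (flag to smooth first). The
voxel-wise group comparison is a pooled-variance two-sample t per voxel,
two-tailed threshold at alpha = 0.001 uncorrected (tailedness is a
design choice; no multiple-comparison correction, matching the
exploratory design), zero-variance voxels masked as NaN, suprathreshold
voxels labelled with 26-connectivity.

## Group statistics

Mann–Whitney U (between groups), Wilcoxon signed rank (between
hemispheres) and Spearman correlations are exact at study scale:
p values come from full enumeration of rank-label assignments (U),
sign patterns via the generating-polynomial convolution (W⁺), or all n!
permutations (rho, n ≤ 8) whenever the combined n ≤ 16; ties are
handled with average ranks inside the permutation distribution, and
two-sided p values are tail-doubled and capped at 1. Above the
switchover the scipy asymptotic approximations are used and tagged.
Null distributions are cached on the rank multiset, which makes the
2,000-run size simulations cheap. Empirical size at n = 8+8 and nominal
0.05 is ≈ 0.052 (U) and ≈ 0.035 (W; exact signed-rank tests are
conservative at small n because of the discrete support). Summary
tables report group mean (SD) per measure per hemisphere with
between-group and within-group p values and significance stars at
p ≤ 0.05; correlations use the mean of left- and right-hand
box-and-block scores. Holm adjustment is available but off by default.

## Pipeline and problem sizes

`run_all` wires the stages together deterministically and writes
per-subject metrics, the three summary tables, ellipsoid records and a
manifest (config + SHA-256) sufficient to reproduce every number. The
default simulated study is 8 + 8 subjects, a 7×7 grid per hemisphere at
5 mm spacing, 11 + 7 EMG trials per hemisphere and one 40×48×40 volume
per subject; a full run completes in a few seconds on one CPU. Test and
calibration problem sizes (e.g. 10,000-point coverage clouds, 500-trace
detector sweeps, 20-cohort direction checks) were chosen so the whole
suite runs in well under a minute while keeping Monte-Carlo error small
against each stated tolerance.

## Known limitations

- Areas are measured on a PCA plane, not the cortical surface; for
  strongly curved patches the planar projection underestimates geodesic
  extent.
- The silent-period MEP-end criterion is an operationalization (the
  measurement literature does not fix one); it is recorded in the result
  metadata and config.
- The exact tests enumerate up to combined n = 16; far beyond that the
  asymptotic branch inherits scipy's tie corrections.
- The generator's per-muscle stimulus count (one per grid square over a
  fixed extent) approximates an adaptive "extend until no responses"
  border rule.
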