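# Methods

## System and measurement model

The package analyses TIRF/epifluorescence images of supported lipid
bilayers carrying a fluorescent membrane-anchored receptor, plus the
kinetic traces and calibration standards that accompany such experiments.
Cluster formation on the bilayer is treated as a two-dimensional phase
transition: below a critical solution concentration of the crosslinking
partner the membrane is homogeneous; above it, bright protein-rich domains
coexist with a dilute surround. Two order parameters track the transition —
the fraction of total image fluorescence inside thresholded clusters, and
the pixel-intensity variance. Both are computed on corrected images
(background-subtracted, divided by a max-normalized flat-field).

## Image model and corrections

A recorded image is modelled as
`I = V · S + offset + ε`, with `S` the fluorescence signal, `V` a smooth
vignetting field in (0, 1], `offset` the camera baseline and `ε` additive
Gaussian read noise. Corrections invert this model in order: per-pixel
background subtraction, then division by flat-field factors derived from a
homogeneous reference bilayer (median-filtered, radius 3 px, so single hot
pixels cannot set the normalizing maximum). Factors below 0.01 are not
divided; those pixels are flagged invalid instead, since dividing by a
near-zero factor amplifies noise without bound. Rolling-ball flattening is
implemented as grayscale opening with a flat disk (default radius 50 px):
the opening estimates the local background, which is subtracted and the
result clipped at zero. The paraboloid ("ball") structuring element is not
implemented.

## Thresholding and segmentation

Triangle and maximum-entropy thresholds operate on a 256-bin histogram
over [min, max] (the ImageJ convention). The triangle chord runs from the
tallest bin to the farthest non-empty bin on the longer tail side, with
distance ties broken toward higher intensity because clusters are bright.
The iterative rule `t ← mean(I<t) + 3·sd(I<t)` starts from the whole-image
mean + 3 sd and stops at a relative change below 0.1% (at most 100
rounds); when the background is noiseless the returned threshold is nudged
one float upward so background pixels stay strictly below it. Components
are labelled at 8-connectivity; components under 4 px are discarded as
shot noise; components touching the image border are flagged and excluded
from size statistics.

A global histogram threshold always exists, even for cluster-free images,
so the titration pipeline validates each detection: images whose
thresholded mask covers more than half the image, or whose mask mean
exceeds the surround mean by less than 3 background standard deviations,
are recorded as cluster-free (fractional intensity 0). Without this guard
a unimodal noise histogram split near its median would masquerade as a
giant cluster.

## Clustering-concentration estimators

"Begins increasing" is operationalized two ways. The primary estimator
fits a flat baseline joined continuously to a rising line, scanning the
breakpoint over interior grid concentrations and keeping the least-squares
optimum. Because titration curves saturate, points beyond half-saturation
(relative to the median of the first three points) are dropped before the
scan — the linear rise approximates the curve only near the onset, and the
plateau otherwise dominates the fit and drags the breakpoint left. A
detection requires the rising slope to be significantly positive (one-sided
t-test within the segmented model) *and* the segmented model to beat the
flat model by the nested F-test, both at α = 0.05. The secondary estimator
reports the first concentration whose statistic exceeds the mean + 3 sd of
the first three points. Variance is reported both raw (counts², camera-
dependent) and as the dimensionless CV² = Var/mean².

## Size and spatial statistics

Non-edge cluster areas are binned linearly (Freedman–Diaconis width by
default, floored at one pixel area; the grid is anchored at the largest
bin-width multiple at or below the smallest area so the first bin is fully
populated). Law discrimination regresses ln N on s and on ln s over
occupied bins and prefers the law with the higher r², requiring a margin
of 0.02. The regressions are count-weighted (Var(ln N) ≈ 1/N for Poisson
counts); unweighted log-space fits let one-count tail bins randomize the
comparison at realistic sample sizes. The reported mean cluster size s̄
comes from the direct nonlinear fit N(s) = N₀·e^(−s/s̄), which is unbiased
where the log-space slope is systematically shallow.

Quadrat analysis divides the image into 5 × 5 boxes (remainder pixels join
the last row/column). Per box, clusters are counted including (any pixel in
the box) and excluding (all pixels in the box) boundary-crossing clusters;
a cluster spanning k boxes is counted in each of the k boxes of the
including count. Half the mean per-box excess is subtracted from each
including count, removing the overcounting on average; the conservation
identity `Σ corrected = Σ including − n_boxes · avg_edge/2` holds exactly.
The corrected counts of a spatially random pattern are summarized by a
least-squares Gaussian on the relative-frequency histogram (unit-width bins
centred on integers), with a Shapiro–Wilk p-value as a cross-check.

## Kinetics

FRAP normalization computes `(I − bg)/(ref − bg)` per frame — `ref` being
an imaging-only acquisition-bleaching control, taken as 1 when absent —
and divides by the pre-bleach mean of that quotient. Recovery fits use
post-bleach frames only, rebased to the bleach instant, with the model
`f(t) = plateau − Σ Aᵢ e^(−t/τᵢ)`. Bi-exponential least squares is
initialization-sensitive, so fits multistart over τ ∈ {T/100, T/10, T/3}
(T = recording span; ordered pairs for two components) crossed with
amplitude splits {0.25, 0.5, 0.75}, keeping the lowest sum of squares.
Time constants pinned at the search bounds are flagged rather than
silently returned. Asymptotic 95% confidence half-widths come from the
Jacobian at the optimum; the fast-fraction CI uses the delta method.
Model choice follows the classical nested F-test; a perfect
two-component fit returns "double" with p = 0. When a trace carries no
explicit pre-bleach count, the bleach frame is the first frame more than
3 sd below the pre-bleach mean. Dissociation decays are fit to
`A·e^(−t/τ) + C` with the same multistart policy.

Actin half-times are computed per cluster within a 27-minute analysis
window: after subtracting the mean of the first two frames, t_1/2 is the
linearly interpolated crossing of half the (windowed) maximum. When the
trace jumps from baseline straight past half-maximum between two frames,
t_1/2 is assigned to the frame where signal first appears — interpolating
into the pre-assembly lag would invent a crossing time in a period with no
signal. Traces never exceeding twice their baseline are flagged as
"no assembly" rather than given a half-time. Rank (Spearman) correlations
of t_1/2 against cluster area and receptor intensity quantify whether
assembly onset depends on cluster properties.

Drift correction of image stacks is out of scope; the kinetics module
accepts pre-extracted ROI traces. (For image-mode inputs, integer-pixel
translational registration by cross-correlation of consecutive frames
would be the natural preprocessing step; feature-based alignment is not
provided.)

## Density calibration

The correction factor `F = slope(protein standard)/slope(dye standard)` is
the relative per-molecule brightness of the labeled protein vs the
reference lipid on the instrument; it is invariant to common rescaling of
both curves. Mole fraction converts to surface density as
`fraction × leaflets × 10⁸ Å²µm⁻² / headgroup area`, with 69 Å² and two
leaflets by default (a single-leaflet convention would halve the result;
the parameter is exposed). A measured intensity is divided by F, inverted
through the bilayer standard curve (intercept retained; forcing through
the origin is a configuration choice), and divided by the labeled fraction
to report total molecules. The inversion refuses densities below zero
(mis-subtracted background) or beyond 1.5× the largest standard
(fluorescence is linear in density only up to roughly 60% labeling, so
extrapolation is unsafe); labeled fractions above 0.6 trigger a warning.

## Synthetic data: what it emulates, and what it does not

The generator renders 512 × 512 px scenes at 0.16 µm/px by default (a
~56 µm field then spans ~350 px), as
`V · B · (1 + (E−1)·mask) + offset + ε` with background level B,
enrichment E (default 4), quadratic radial vignette V and Gaussian read
noise ε. Nucleated morphology seeds a homogeneous Poisson process of
puncta whose areas follow an exponential law; each punctum is a
star-shaped domain (low-order Fourier perturbation of a disk, normalized
so the enclosed area equals the drawn area regardless of irregularity, and
never smaller than one pixel). Spinodal morphology thresholds a smoothed
Gaussian random field at the quantile matching the requested area
fraction. Titration series switch on clusters above a 200 nM onset with
clustered area fraction `φ_max·(1 − e^(−(c−c*)/w))`, w = 150 nM,
φ_max = 0.25. FRAP traces follow
`(1−d) + d·m·Σ fᵢ(1−e^(−t/τᵢ))` (bleach depth d = 0.8, mobile fraction
m = 1 by default), times a mono-exponential acquisition-bleaching factor
referenced to the start of acquisition, plus 1% Gaussian noise; five
pre-bleach frames precede the bleach at t = 0. Actin traces rise as
`1 − e^(−(t−lag)/τ_rise)` after lags uniform on 6–15 min, sampled every
3 min.

Deliberate simplifications: noise is additive Gaussian only (no Poisson
shot noise, no EM-CCD excess noise); photophysics beyond mono-exponential
acquisition bleaching is absent; clusters do not move, coalesce, ripen or
deplete their surroundings (protein conservation is not enforced — the
mean field density is unchanged during a titration, matching the
homogeneous-reservoir regime); there is no physical model of the
multivalent bond network. Passing tests therefore certify the measurement
pipeline — segmentation, statistics, fitting — under a faithful noise and
geometry model, not the biology of cluster formation.

## Problem sizes and numerical choices

Tests and the benchmark script scale the study designs to what the
statistics require rather than to raw image throughput: titration checks
use 128 × 128 px scenes over 12 log-spaced concentrations (25–1000 nM) and
100 seeds; spatial statistics use the 93-region × 25-box design at
256 × 256 px; size-law discrimination uses 500 clusters × 50 seeds;
F-test calibration uses 200 traces. Calibration round-trips use 24 points
per standard, because the conversion chains three fitted slopes and the
per-slope sampling error must stay well below the 2% acceptance bound.
Breakpoint scans report grid concentrations (no sub-grid interpolation);
exponential fits bound τ within [10⁻⁵, 10³] × the recording span; all
random draws flow from explicit integer seeds through NumPy generators,
making every result bit-reproducible.

## Known limitations

- The triangle/maximum-entropy thresholds operate on the raw-intensity
  histogram; 8-bit requantization of 16-bit data (as some ImageJ workflows
  do) can shift thresholds by up to one bin.
- The hockey-stick breakpoint is reported on the concentration grid, so
  its resolution is the local grid spacing; log-spaced titrations resolve
  the onset only to ~±40% in concentration at 12 points per decade-and-a-
  half.
- Asymptotic confidence intervals undercover slightly for strongly
  correlated amplitude pairs in bi-exponential fits; bootstrap intervals
  are not provided.
- Watershed splitting of merged clusters and cross-frame cluster tracking
  are not implemented; coalescence shows up only as changed size
  distributions.
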