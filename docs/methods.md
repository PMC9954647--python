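# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, what the synthetic generators do and do not emulate,
and the known limitations.

## Bright-field morphometry

**Segmentation model.** Spheroids appear as dark, roughly circular objects on
a bright background. The pipeline is fixed as: invert → Otsu threshold →
fill interior holes → remove speckles → keep the largest component.
Inversion is against the dtype's representable maximum for integer images
(so an 8-bit pixel 0 maps to 255) and against the image maximum for float
images; either way double inversion restores the input. Hole filling is done
before speckle removal because bright spheroid cores would otherwise puncture
the mask, and the area entering the volume and circularity formulas must be
the full object area.

**Otsu threshold.** Computed on a 256-bin histogram over the representable
intensity range (float images are min–max scaled first). The threshold is
the bin index t maximizing the between-class variance ω₀ω₁(μ₀−μ₁)² of the
split {bins ≤ t} vs {bins > t}; ties resolve to the lowest maximizing index,
making output deterministic. Foreground is strictly above the upper edge of
bin t on the inverted image. A histogram with fewer than two populated bins
has no threshold and raises.

**Speckle filter.** A component is debris when its equivalent-circle
diameter 2·√(area/π) is strictly below 10 px. The equivalent-circle metric
is a deliberate disambiguation: "diameter" of an irregular blob is otherwise
undefined.

**Minimum Feret diameter.** A binary mask is treated as a union of unit
squares; its exact convex hull is the hull of the 4 corner points of each
boundary pixel. The minimum caliper width of a convex polygon is attained
flush with one of its edges, so rotating calipers over hull-edge normals is
exact for this geometry (an axis-aligned 100×40 px rectangle measures
exactly 40 px; a rasterized disk of diameter d measures d to within the
rasterization). The maximum Feret diameter is the largest pairwise distance
between hull vertices. Tests compare against an independent 0.1°-grid
projection scan over the same point cloud.

**Derived quantities.** d and A convert to physical units via the
user-supplied μm/px scale (d·scale, A·scale²); the microscope scale is a
required input because it is acquisition-specific. V = (4/3)π(d/2)³ models
the spheroid as a sphere of radius d/2; C = π(d/2)²/A compares the circle of
that radius to the measured area. C is reported unclamped — concave or noisy
masks can push it slightly above 1 — and a QC warning applies above 1.1.
Both are pure functions of (d, A), reproducible from the output table to
1e−9 relative.

**ROUT outlier screen (constant model).** Used to catch failed
segmentations, not biological variation. Location is the sample median;
residual scale (RSDR) is the 68.27th percentile of |residuals| scaled by
N/(N−1) — a robust SD analogue insensitive to the outliers being hunted.
Points are ranked by |residual| descending and tested sequentially with
two-tailed t P-values (df = N−1) against the step-down thresholds
αᵢ = Q(N−i+1)/N, stopping at the first non-rejection; Q defaults to 0.01.
When RSDR is exactly 0 (duplicated values), any nonzero residual is flagged.
Samples below min_n = 10 are not screened. This is a stated variant:
value-level equivalence with commercial implementations is not claimed; the
procedure is validated by simulation (≤2 % flagged on clean Gaussian data,
≥95 % joint recovery of five planted 8σ outliers at n = 100).

**Pairing.** Growth is assessed per well position (batch_id, well_id) by
inner join across the two timepoints; wells flagged as outlier or
multi-object at either timepoint are excluded from the paired tests but kept
in the output CSV with their flags as a reviewable QC artifact.

## MEA activity

**Filtering.** 4th-order Butterworth band-pass, 200 Hz – 3 kHz, applied
forward–backward (zero phase) so spike times are not biased by filter delay.
Corners must stay below Nyquist; the default sampling rate in the synthetic
generator is 12.5 kHz, comfortably above twice the 3 kHz corner.

**Noise estimate.** σ = MAD/0.6745. The raw SD is inflated by the spikes
themselves; the MAD estimator is consistent for Gaussian noise and stays
within ~2 % when 10σ events occupy <5 % of samples.

**Spike detection.** Threshold k·σ with k = 6. Local extrema of |V| (default
polarity "both"; symmetric thresholds are the common vendor convention when
only "peak voltage" is specified) at or above threshold become spikes, timed
at the extremum sample. A 1 ms dead time suppresses secondary extrema of the
same biphasic waveform, keeping the larger-amplitude event in any conflict.

**Bursts.** Maximal runs of consecutive inter-spike intervals ≤ 100 ms with
≥ 5 spikes. The boundary is inclusive ("no more than 100 ms"); numerically
the comparison carries a 1 ns guard so that an ISI of exactly 100 ms built
by floating-point summation stays inside a burst. Bursts are disjoint and
maximal by construction. Network-level burst metrics are deliberately absent:
with one spheroid per electrode there is no network to aggregate.

**Summaries.** Mean firing rate = spikes/duration exactly; the TTX/vehicle
endpoint reports 1 − MFR_dosed/MFR_baseline, with NaN when the baseline is
silent. Electrodes whose spheroid was not centered are excluded from
longitudinal tables with a count.

## qPCR quantification

**Model.** Ct = intercept + slope·log₁₀(ng), slope = −1/log₁₀(1+E). The
calibration mix is a 4-fold series from 50 ng down to 50/4⁷ ≈ 0.003052 ng
(8 levels). The fit is ordinary least squares over all standard wells; a
non-negative slope is rejected outright, and quality flags (not errors)
raise when E leaves [0.8, 1.1] or r² < 0.98. Quantities are curve-relative
(ng-equivalents of the standard mix), sufficient for ratios; no copy-number
conversion is attempted.

**Normalization.** Technical replicates are averaged at the Ct level before
quantification (replicate handling is a convention choice; averaging Cts is
the common one). The endogenous control is the arithmetic mean of the ACTB
and GAPDH quantities — the literal reading of "mean between" the two
controls; the geometric mean is available as an option. A non-detect target
is reported as ratio 0 with detected = false; a non-detect control makes the
sample unusable and raises. Normalization is scale-invariant by
construction.

**Stage testing.** Per gene, one-way ANOVA across stages then Dunnett's
two-sided comparisons against a reference stage. Pluripotency markers
(NANOG, OCT4) naturally reference the iPSC stage, others the MN-progenitor
stage; the mapping is configurable per gene. Genes never detected anywhere
(e.g. GFAP) are skipped rather than tested against all-zero groups.

## Statistics

Paired and unpaired t tests use the closed-form statistics (Welch by default
for unpaired, since equal variances are rarely defensible; pooled-variance
available by flag). Identical pairs return t = 0, p = 1; a zero-variance
difference vector with nonzero mean has no defined statistic and raises.

Dunnett adjusted p-values come from seeded Monte Carlo over the joint null:
group means ~ N(0, 1/nᵢ), pooled scale ~ √(χ²_df/df) with df = N−k, and the
k−1 statistics share the reference mean and the scale, reproducing the
equicorrelated multivariate-t dependence for arbitrary group sizes. The
adjusted p of comparison j is the fraction of null draws whose max |T|
reaches |t_j|; accuracy is bounded by the draw count (default 100,000,
Monte-Carlo SE ≤ ~0.0016 near p = 0.5) rather than a quadrature rule, and
the null sample can be precomputed and reused across calls with the same
design. With k = 2 the procedure collapses exactly to the single
equal-variance t test, which the tests verify, along with agreement with an
independent library implementation.

## Synthetic data: what it emulates, and what it does not

*Images* have a bright background (0.85 of full scale) and a dark elliptical
spheroid whose interior runs a mild radial gradient (0.25 at the center to
0.45 at the rim) — dark enough to threshold cleanly after inversion, graded
enough that Otsu is not handed a two-valued toy problem. The planted
diameter is the minor axis, i.e. the true minimum Feret diameter;
eccentricity stretches the major axis. Speckles are 2–8 px dark blobs kept
clear of the spheroid; satellites for the split-spheroid failure mode are
0.35× the main diameter, placed toward the image diagonals where a centered
object leaves room. Noise is additive Gaussian, parameterized as a fraction
of full scale. Not emulated: uneven illumination, out-of-focus blur,
touching debris, meniscus shadows — so passing recovery tests demonstrate
correctness of the measurement chain, not robustness to every real-world
artifact.

*Traces* are white Gaussian noise plus a biphasic difference-of-Gaussians
waveform (~1 ms support, dominant negative phase, negative peak on the
planted sample) scaled to a stated multiple of the noise SD. Defaults pin
the recording conditions the analysis assumes: 300 s duration, 12.5 kHz
sampling. Tonic trains are homogeneous Poisson; bursty trains draw Poisson
burst onsets with ≥5 spikes at 5–95 ms ISIs and inter-burst gaps well above
100 ms so planted bursts never merge; TTX is noise only. Not emulated:
1/f and line noise, electrode drift, overlapping units, waveform variability
— detection scores on these fixtures are upper bounds on real-data
performance.

*Plates* draw standard and unknown Cts from the same log-linear curve
(default intercept 22 cycles at 1 ng) with i.i.d. Gaussian Ct noise; a zero
planted quantity yields non-detect wells (empty Ct field in CSV).
Inhibition, primer-efficiency differences between genes, and Monte-Carlo
plate effects are not modeled.

## Demo study and problem sizes

`make_demo_dataset` plants: per line, 30 wells with day-14 diameters
~N(300, 12) px (line A) / ~N(260, 12) px (line B) and paired growth factor
~N(1.08, 0.02); one undersized day-28 well (0.4× the line mean) mimicking a
failed segmentation; one split-spheroid day-28 well; electrode firing rates
rising 0.4 → 1.6 Hz over days 7–28 with bursty regimes from day 21; a
TTX/vehicle endpoint pair; and the stage-specific expression profile
(controls flat, pluripotency iPSC-only, MN markers ≥10× up at spheroid
stages, GFAP absent). Demo traces run 60 s (the package's demo problem
size; the trace generator itself defaults to 300 s recordings), and demo
images are 512×512 px at 0.02 full-scale noise. The acceptance script
scales simulation counts similarly (e.g. 500 histograms/trains, 15 recovery
images, 3 × 300 s traces, 5,000 paired-t and 500 Dunnett replicates).

## Known limitations

- ROUT and the spike detector are stated variants of proprietary
  implementations (Prism, AxIS); equivalence is claimed at the level of
  simulated error control and planted-truth recovery, not value-for-value.
- Circularity and minimum Feret on very small objects (tens of pixels)
  carry rasterization error of order 1 px; the pipeline targets spheroids
  ≥100 px across.
- The qPCR model assumes one shared efficiency per gene across its dynamic
  range; strong inhibition at high input violates this and would bend the
  standard curve.
- 3D reconstruction of cleared immunostained spheroids and marker-intensity
  quantification in image stacks are out of scope.
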