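# Methods

This note documents the models, rules and numerical choices behind
`rsdelta`, what the synthetic data do and do not emulate, and the known
limitations.

## Recording model and preprocessing

A `Recording` is a channels × samples array in µV at 128–512 Hz with the
19 canonical 10–20 electrodes (plus an optional EOG channel). All
analysis runs at the native sampling rate; nothing above 40 Hz is used
downstream, so recordings at 128 Hz are fully adequate and no resampling
is performed.

Epochs are consecutive, non-overlapping 2-s windows
(`[start, start + 2·fs)`, 0-based half-open) taken from the first 3 min
of a recording by default; a trailing remainder is discarded. The
artifact rules replace visual review with fixed, config-exposed
thresholds (`ArtifactConfig`):

- *ocular*: |correlation| between the EOG channel and a frontal channel
  above 0.7 **and** a low-passed (7 Hz) frontal peak-to-peak deflection
  above 80 µV;
- *movement*: a < 2 Hz deflection above 100 µV peak-to-peak on ≥ 90% of
  channels simultaneously;
- *muscle*: mean power in 30–min(100, Nyquist) Hz above 0.5 µV²/Hz with
  a non-declining log-power trend from 25 Hz upward (slope ≥ 0), i.e. the
  plateau that distinguishes EMG from the normal high-frequency roll-off;
- *sleep*: a K-complex-like matched-filter response above 0.8 with a
  concurrent amplitude above 75 µV.

Precedence when several rules fire is movement > muscle > ocular >
sleep. The thresholds were calibrated on the synthetic cohorts to reach
≥ 0.9 recall at ≤ 0.1 false-positive rate at the default artifact
amplitudes; they are surrogates for expert judgment, not clinically
validated values. Retention below 80% artifact-free epochs triggers a
warning; zero clean epochs is an error.

## Spectra and individual frequency landmarks

Power spectra are Welch averages of Hann-windowed periodograms where
each Welch segment is one 2-s epoch (no sub-windowing, no overlap),
giving exactly 0.5 Hz resolution with density scaling (integrating the
PSD of white noise recovers its variance; checked to 5%).

The transition frequency TF is the minimum of the channel-averaged PSD
on [3, 8] Hz (ties to the lowest frequency; a boundary minimum is
flagged as a fallback). The alpha peak IAF is the highest interior local
maximum on [6, 14] Hz (flat or monotone spectra fall back to the global
maximum with a flag). Landmark detection averages all 19 channels
unweighted; a posterior-only average is a trivial variant the caller can
compute. Band membership uses bin centers in half-open ranges, so
adjacent bands are disjoint at shared edges; the deliberate gap between
the individual alpha top (IAF + 2, clipped at 14 Hz) and the fixed beta
onset at 14 Hz is left unassigned.

## The epileptiform-activity rubric

Detection runs on the full longitudinal ("double banana") bipolar
montage. A candidate apex must (a) exceed `k_mad = 4` robust standard
deviations (1.4826 × rolling MAD, 10-s blocks) of a zero-phase 2.5–40 Hz
band-limited copy of the derivation, (b) exceed an absolute visibility
floor of 30 µV, and (c) have a normalized second difference above 0.5.
Candidates within 100 ms are merged per derivation and across
derivations (largest amplitude wins). Durations, rise and decay times
are measured between baseline crossings of the slow-detrended raw
signal.

The six criteria are scored as: (1) 2–3 major lobes (≥ 45% of the apex,
lightly smoothed, within −100 ms…+350 ms around the transient) plus a
sharp apex; (2) duration outside 0.5–2× the dominant background period
(spectral peak of the surrounding ±1 s, 1–20 Hz); (3) rise/decay ratio
≥ 1.5 between crossings, or ≥ 2.0 on the apex slopes (the slope route is
noisier at clinical sampling rates, hence the higher bar); (4) a 0.5–4 Hz
deflection of ≥ 30% of the apex amplitude within 500 ms after it;
(5) near-event RMS (±500 ms, transient core excluded) differing ≥ 30%
from the outer context; (6) a focal scalp field — the top-3 monopolar
channels at the apex instant carry ≥ 60% of the squared field and the
dominant channel stands ≥ 4× above the scalp median. An event is
epileptiform when ≥ 4 of 6 criteria hold. The spike / sharp-wave duration
boundary is resolved at 80 ms (the published ranges overlap at
70–80 ms). Benign rhythmic delta runs — ≥ 3 quasi-periodic 0.5–4 Hz
waves of 50–100 µV with amplitude and interval CV < 0.3 and no embedded
fast component — are labeled TIRDA (temporal) or FIRDA (frontal), and
events on the affected derivations inside a run are removed from the
epileptiform set; a run containing a sharp transient is not benign.

All thresholds were tuned once against the synthetic ground truth to
reach ≥ 0.9 event-level sensitivity at ≤ 1 false alarm/min; they encode
one defensible reading of criteria that are stated only verbally in the
clinical literature. A patient is EEA-positive with ≥ 1 confirmed event
(`min_events` exposed). **Limitation:** at a residual false-alarm rate
of ~0.5/min, the one-event rule has limited patient-level specificity on
long recordings; cohort-level statistics in the tests therefore group
patients by generator ground truth, and the detector is validated at the
event level. A count- or rate-based patient rule would trade sensitivity
for specificity; none is prescribed here.

## Head model, source space and inverse

The forward model is a dipole in three concentric spheres (brain, skull,
scalp; radii 87/92/100 mm; conductivities 0.33/0.0042/0.33 S/m) solved
per spherical-harmonic degree from the interface conditions and summed
as a Legendre series (60 terms; the equal-conductivity limit matches the
closed-form homogeneous-sphere solution to < 10⁻⁶). Electrode positions
follow the 10–20 construction: the outer ring at 90° inclination at the
standard azimuths, midline and intermediate sites as spherical arc
midpoints. Gains are average-referenced; data entering the inverse are
average-referenced implicitly through the operator.

The source space is a cubic lattice (default 8 mm) restricted to a
cortical shell at 78 mm radius, excluding the bottom cap. Each voxel is
labeled with the Brodmann area of the nearest seed direction from a
packaged synthetic atlas (`data/ba_seeds.csv`, bilateral by mirror
symmetry) — a desk-scale stand-in for a voxelwise cytoarchitectonic
atlas — and BAs map to the five lobar ROIs by the fixed table in
`sources.BA_TO_ROI`; cingulate seeds (BA 23/24/31/32) map to no ROI and
exercise the "none" rule.

The inverse is eLORETA: symmetric 3×3 voxel weights refined by
fixed-point iteration until the relative change is < 10⁻⁶ (error after
200 iterations), with Tikhonov regularization α scaled by trace(C)/E
(default α = 10⁻²; α = 0 gives the exact zero-error single-dipole
localization property, verified for random voxels). Scalp input per
0.5 Hz bin is the per-electrode power vector by default (propagated as an
amplitude pattern, which keeps voxel power linear in scalp power); a
Hermitian cross-spectral matrix is also accepted and is exact for
coherent point sources — the localization tests use that route, since a
squared-magnitude-only pattern discards the potential's sign structure.
Voxel powers over all bins up to 40 Hz are normalized by their grand
mean (relative power; scale-invariant, mean exactly 1), summed into the
subject's individual bands and averaged per ROI.

## Group statistics

Regional activities are log10-transformed (the generative model is
multiplicative, so log values are near-Gaussian); normality per
band × ROI cell is tested with the Lilliefors-corrected
Kolmogorov–Smirnov statistic, since cell means and SDs are estimated.

The mixed ANOVA uses the classical sums-of-squares decomposition with
subjects nested in groups: Group is tested against subjects-within-
groups; Band, ROI and their interactions with Group against their own
within strata; Band × ROI and the triple interaction against the
Band × ROI × subjects stratum. Unequal group sizes enter through the
per-group subject counts (weighted-means solution; the generator is
balanced within subjects by design). Each within stratum carries a
Greenhouse–Geisser epsilon and a Mauchly test computed from the pooled
within-group covariance of the stratum's contrast space (the interaction
stratum uses the Kronecker contrast); the GG-corrected p replaces the
raw p when Mauchly rejects at 0.05. Against pingouin's mixed ANOVA on a
one-within-factor design, F and p agree to machine precision; epsilon
conventions differ slightly (pooled within-group vs. pooled-total
covariance).

Duncan's multiple range test ranks the group means and refers a pair
spanning r steps to the studentized range with protection level
1−(1−α)^(r−1); the reported pairwise p inverts that level
(p = 1−(1−p_range)^(1/(r−1)); for r = 2 it equals the studentized-range
tail, i.e. the two-sided t probability with q = √2·|t|). Cell-level
contrasts use the pooled within-group variance of that cell; the family
threshold is 0.05/25 = 0.002 for 5 bands × 5 ROIs. Grubbs screening uses
the two-sided t-based critical value, applied iteratively at α = 0.001.
Exact 2×2 and 2×3 contingency tests are full enumerations under fixed
margins, two-sided by the point-probability method (the 2×2 case matches
`scipy.stats.fisher_exact`). ROC analysis reports the trapezoidal AUROC
(equal to the Mann–Whitney pairwise probability) with the operating
point at Youden's J; weighted accuracy is
(sens·n_cases + spec·n_controls)/N.

## The synthetic cohorts

Each subject's background is a sum of stationary Gaussian processes
shaped in the frequency domain: 1/f noise (20 µV²/Hz at 1 Hz), an alpha
bump at the subject's IAF (σ = 1.2 Hz) with a posterior gradient
(occipital > parietal > temporal > central > frontal; `posterior_gain`
scales the gradient and 0 removes it), and small delta (2.2 Hz) and
theta (4.8 Hz) bumps. IAF is drawn from N(9.5, 0.8²) Hz; the delta bump
power varies between subjects with SD 0.15 in log10 units.

The EEA group's pathology is a gain on the temporal-channel delta
component. One unit of `delta_effect_size` applies a log10 power gain of
0.38 to that component — calibrated once so that, at the default
desk-scale conditions, d = 1 shifts the measured temporal-ROI log10
source activity by roughly 1–1.5 of its between-subject SDs. The
injected gain must exceed the target shift because the delta bump rides
on the 1/f background, and band individualization plus relative-power
normalization absorb part of it. Injected discharges are asymmetric
triangular transients (rise 30% of the duration) with a 30% undershoot
and a slow same-polarity after-wave of 80% amplitude — the morphology of
a spike-wave complex — at 130 µV nominal amplitude with a steep spatial
falloff centered on anterior temporal / frontal electrodes, the typical
scalp topography of temporal-lobe interictal discharges. Benign delta
runs are integer numbers of full sine cycles (uniform morphology,
55–95 µV) on one temporal or frontal side; artifacts are blinks with an
EOG mirror, EMG-like bursts with gently rising high-band spectra, and
large synchronous slow deflections.

What the generator does **not** emulate: volume-conducted correlation
structure between channels (channels are independent processes with a
deterministic power topography, so bipolar derivations are noisier than
in real EEG); non-stationarity of vigilance; sleep architecture; realistic
discharge propagation; the gender imbalance of the motivating cohort
(available via `emulate_gender_skew` but off by default, gender being a
covariate control rather than a mechanism). Passing tests therefore show
that the pipeline recovers what it assumes — not that the detector or the
effect-size calibration transfer to clinical recordings.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give bit-identical cohorts
and reports. The test suite and the acceptance checks run on reduced
problem sizes chosen as the package's own desk-scale defaults: 60–120 s
recordings at 128 Hz, a source grid of ~400–900 voxels at 8–10 mm
spacing (compared with the 6,239-voxel 5-mm MNI152 grid of the standard
eLORETA freeware), 9–20
replicate cohorts for power-style properties and 100–200 replicates for
type-I calibration. The statistical conclusions these checks support are
qualitative (effect present and ordered, error rates at their nominal
levels), not numerical reproductions of any clinical result.

## Known limitations

- The spherical head model and the synthetic BA atlas are geometric
  idealizations; ROI averages are meaningful relative to each other, not
  anatomically precise.
- The per-bin power-vector inverse input is a pragmatic default; exact
  source power requires the cross-spectral route.
- Patient-level EEA specificity at `min_events=1` is limited (see the
  rubric section).
- The Duncan test's cell-level error term ignores covariance with other
  cells; this matches common practice for planned cell contrasts but is
  not the only defensible choice.
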