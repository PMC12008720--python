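# Methods

`taugraph` implements a complete analysis chain linking regional tau PET
burden to resting-state EEG functional-network organisation, together with
a synthetic cohort generator that makes every stage testable without
access to patient data. This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic validation does
and does not establish.

## EEG conditioning

A recording (channels × samples, µV, 10-5 montage labels) passes through a
fixed chain:

1. **Down-sampling** to 256 Hz (polyphase, anti-aliased). Upsampling is
   refused.
2. **Average re-reference**: the instantaneous mean over channels is
   subtracted.
3. **Broadband band-pass** 0.5–40 Hz, zero-phase Butterworth applied
   forward–backward. The default order is 6: a 4th-order design leaves
   ≈1.4% steady-state leakage for a 60 Hz tone at fs = 256, while order 6
   brings it to ≈0.16%, comfortably inside the 40 dB/octave stop-band
   contract the pipeline promises. Zero-phase filtering is mandatory
   because phase metrics follow. The order and an FIR alternative are
   configurable.
4. **Epoching**: the first 60 s are discarded (initial accommodation),
   then non-overlapping 20 s epochs are cut; trailing remainder samples
   are dropped. A five-minute recording therefore yields exactly 12 epochs
   (240 s retained).

Re-referencing and filtering are both linear, so their order is
immaterial; the test suite asserts this as a regression check.

Power spectra use Welch's method with a 500 ms Hamming taper and 50%
overlap (overlap is a package default, exposed in config), giving a 2 Hz
frequency resolution. Relative band power is a df-weighted bin sum over
the band divided by the same sum over 0.5–40 Hz; full-width bin sums
(rather than trapezoids) are used so a spectral peak on a band-edge bin
counts fully toward its band.

Bad-channel detection and ICA artifact removal are a deliberate no-op
hook: the package starts from cleaned recordings, and the synthetic data
contain no artifacts.

## Connectivity: weighted Phase Lag Index

For channels i, j and frequency f the wPLI is

    wPLI_ij(f) = | Σ_k Im X_ij,k(f) | / Σ_k | Im X_ij,k(f) |

with X_ij,k the cross-spectrum of Welch segment k (500 ms Hamming, 50%
overlap → 79 segments per 20 s epoch) and the convention 0/0 → 0
(identical signals are "not lag-coupled"). Weighting the lag signs by
|Im X| makes the estimator insensitive to instantaneous mixing — the
volume-conduction confound that contaminates sensor-space amplitude and
coherence measures. The plain estimator is used (the debiased squared
variant is available behind a flag, matching the convention of taking
absolute values as edge weights).

Band values are unweighted means over the bins whose centers lie in the
closed band interval (alpha 8–13 Hz → bins {8, 10, 12} at 2 Hz
resolution). The expectation runs over segments *within* an epoch; the 12
per-epoch matrices are then averaged element-wise into the subject
adjacency. Both conventions are config-exposed. The adjacency is
symmetric, non-negative, zero-diagonal and bounded by 1 — asserted, not
assumed.

Implementation detail: per-segment channel spectra are stored and the
pairwise cross-spectra are materialized on demand; storing X_ij densely
for 128 channels would take gigabytes per subject.

## Graph outcomes

Two weighted global measures on the dense sensor-space graph (no
thresholding by default; wPLI graphs are fully dense in practice):

* **Global clustering coefficient C** (segregation): the Onnela
  geometric-mean triangle variant with weights scaled by the global
  maximum,

      c_i = Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i (k_i − 1)),

  averaged over nodes with at least two neighbours (nodes with fewer
  carry no triangle information and get c_i = 0). This is the Brain
  Connectivity Toolbox convention; the Barrat variant sits behind a flag.
* **Characteristic path length L** (integration): edge length 1/w
  (strong coupling = short distance; 1 − w is a config alternative),
  all-pairs Dijkstra, mean over ordered reachable pairs; unreachable
  pairs are excluded and counted (they cannot occur on dense wPLI
  graphs, but the rule is needed for degenerate inputs).

Exact invariances, both asserted in tests: multiplying all weights by
λ > 0 leaves C unchanged and divides L by λ; relabeling channels changes
nothing. Because of the max normalization, C measures the *shape* of the
weight distribution: a uniformly strongly coupled network has C near 1,
and heterogeneous weakening lowers it.

Electrode subsets (64/32/24, nested 10-10/extended-10-20 reductions of
the 128-channel montage) restrict the adjacency rows/columns — a pure
sensor-space restriction, no re-estimation. The label lists are editable
text files; the shipped sets are standard reductions, since clinical cap
layouts vary by site.

## PET quantification

Amyloid SUVR converts to Centiloid through tracer-specific linear maps:

    PiB:          CL = 132.53 × SUVR − 147.64
    NAV4694:      CL = 107.78 × SUVR − 114.71
    florbetaben:  CL = 147    × SUVR − 166.5

Positivity is CL > 23.5 (ties negative; the measure is continuous, so the
boundary rule is documented rather than consequential). Tau composite
VOIs are voxel-count-weighted means of member-region DVR; the early
metaVOI covers the medial-temporal territory affected first (entorhinal,
perirhinal, hippocampus, parahippocampus, fusiform), a neocortical VOI
covers temporo-parietal spread. The tau-positivity threshold is mean +
1 sample SD (n − 1 denominator) over an amyloid-negative cognitively
unimpaired reference sample; the reference n is recorded in the output
metadata. Printed thresholds in the source literature cannot be exactly
reproduced from printed summary statistics (rounding and a reference-
sample ambiguity), so they are treated as approximate anchors: the
package reproduces 0.92 from a (0.86, 0.06) reference summary, within
rounding of the published 0.921.

## Statistical battery

* **Primary model**: OLS of C (and of L) on tau DVR in the early metaVOI
  plus age, sex (F = 0/M = 1) and APOEε4 carriership (noncarrier = 0).
  Per-coefficient t tests, overall F test. Rank-deficient designs are
  refused with the offending columns named.
* **Subgroup associations**: Spearman ρ with asymptotic p and Fisher-z
  95% CI (n − 3); partial variant ranks all variables, residualizes the
  ranks on the covariates and correlates residuals (t on n − k − 2 df,
  Fisher-z CI on n − k − 3). Verified to machine precision against an
  independent residualization oracle and against pingouin.
* **Group contrasts**: tie-corrected Kruskal–Wallis with Dunn's post hoc
  z tests; Holm adjustment for post hoc pairs, Benjamini–Hochberg for the
  per-region family (both configurable).
* **Two-group contrasts** (tau-positive vs -negative): Shapiro–Wilk at
  α = 0.05 on each group picks Welch's t (both normal) or the rank-sum
  test; constant groups fall back to rank-sum with a warning; the choice
  is logged.
* **Gatekeeping**: per-region analyses run only when the primary
  regression's tau term is significant for that outcome — enforced
  structurally (the tables are absent otherwise), not by annotation.
* **Factor analysis** of the 10-test neuropsychological battery: minres
  extraction of 2 factors from the correlation matrix, varimax rotation
  with Kaiser normalization, factors ordered by explained variance with
  dominant loadings oriented positive. Sampling-adequacy gates (Bartlett
  sphericity p < 0.05, KMO ≥ 0.6) refuse unsuitable data with
  diagnostics. Fit indices use the ML discrepancy with Bartlett's
  correction (CFI against the independence model, RMSEA); they are
  standard approximations, adequate for gating, not for model
  comparison. Thurstone regression scores use weights W = R⁻¹Λ on
  standardized scores, with a ridge-regularized inverse (logged ε) for
  near-singular R.

Whole-group versus subset sample selection is an explicit per-stage
config field, since mixed designs vary between analyses. Raw (not
null-model-normalized) weighted graph measures enter all models.

## Synthetic cohort generator

The generator encodes the study design through one latent severity
s ∈ [0, 1] per subject, drawn uniformly from a group-specific range
(CU− 0–0.25, CU+ 0.10–0.60, prodromal 0.50–1.0; three groups of 37/14/15
by default):

* **EEG** (300 s, 128 channels, 256 Hz by default): all channels share
  one alpha source (carrier drawn 9–11 Hz, slow phase drift, amplitude
  modulation), delayed per channel by a lag drawn continuously in 1–4
  samples (applied as an FFT phase ramp, so pairwise lags are nonzero
  almost surely — integer lags would leave equal-lag pairs invisible to
  the wPLI) and scaled by g·(1 + coupling_slope·s) times a per-channel
  gain jitter. Independent 1/f noise (spectral shaping, 1 Hz knee) and a
  stochastic theta oscillation (Gaussian spectral bump at 6 Hz) whose
  amplitude grows with s are added per channel; the declining alpha and
  growing theta produce the classic spectral "slowing". Eyes-open halves
  the alpha source amplitude (a simple stand-in for alpha blocking; the
  eyes-open generative regime is otherwise unconstrained). A zero-lag
  confound switch mixes one instantaneous source into all channels with
  random positive gains, for testing that the wPLI — unlike amplitude
  measures — does not inflate under volume-conduction-like mixing.
* **Calibration.** Defaults (alpha 30 µV, 1/f noise 10 µV, theta 2.5 µV
  growing by factor 1 + 1.2 s, coupling slope −0.6) place severity 0 in
  the strongly coupled, near-homogeneous regime of the wPLI and severity
  1 near the noise floor. On this branch attenuation makes the weight
  distribution more heterogeneous relative to its maximum, so C falls
  and L rises with s — the degradation pattern the pipeline is designed
  to detect — and the pooled tau–C Spearman correlation lands near −0.4
  at n = 66. Note the opposite branch exists: starting from a
  noise-dominated network, further attenuation drives the graph toward
  the *uniform* null and max-normalized clustering rises; the defaults
  deliberately avoid it.
* **Tau**: DVR_r = base_r + slope_r·s + N(0, 0.06), floored at 0.05;
  slopes are steepest in perirhinal cortex (the earliest-affected
  region), and bases/slopes are chosen so the three groups reproduce a
  plausible CU− < CU+ < prodromal ordering with realistic means. The
  early-metaVOI value is the voxel-weighted aggregate of its member
  regions.
* **Amyloid**: group-consistent Centiloid draws (CU− strictly below
  23.5, the other groups above), mapped back to tracer SUVR through the
  inverse calibration, with tracers assigned 35/55/10% (PiB / NAV4694 /
  florbetaben).
* **Neuropsych**: ten test scores from a fixed 10×2 loading matrix
  (episodic-memory and language/executive factors); the memory factor
  declines with s. Scores are shifted/scaled to plausible raw ranges.
* **Covariates** (age, sex, APOEε4, education) follow group-level
  regimes but are independent of s by default, so the tau effect is
  identifiable in the regression; a confounding switch couples age to s
  for sensitivity analyses.

Ground truth (severities, per-channel lags and gains, noiseless tau,
true factor scores) is stored separately and consumed only by recovery
tests. Everything is deterministic given (config, seed); recordings are
regenerated on demand from per-subject seeds rather than held in memory
(a full cohort of five-minute 128-channel recordings is ~5 GB).

### What the generator does *not* emulate

No scalp geometry, no 3-D electrode positions, no blinks/ECG/muscle
artifacts, no non-stationarities beyond slow amplitude modulation, no
spatial correlation structure in the noise, and no relationship between
electrode adjacency and coupling strength. Passing tests therefore show
that the *estimators and statistics* behave correctly under the assumed
generative structure — not that the pipeline is robust to real-world
artifact regimes, which require the usual upstream cleaning.

## Problem sizes in the validation suites

Monte-Carlo suites run at sizes chosen as a package default so the whole
validation completes in minutes on one CPU, while the statistical
property under test is preserved:

* direction recovery (sign of the tau coefficients at n = 66): 20
  cohorts at 16 channels / 100 s recordings / fs = 128;
* type-I error of the primary regression's tau term under a null
  generator (coupling and tau slopes zeroed): 500 cohorts of n = 30 at 8
  channels / 80 s / fs = 128;
* electrode-subset agreement (Spearman of subject-level C between 128
  and 64 electrodes): one full-scale default cohort (n = 66, 128
  channels, 300 s);
* factor recovery: n = 500 simulated batteries.

## Known limitations

* Sensor-space only; volume conduction limits spatial interpretation
  even with a lag-based estimator (the 64-electrode agreement check
  probes robustness, not localization).
* Fit indices for the factor model are asymptotic approximations.
* The EDF/BrainVision readers require the optional `mne` dependency;
  the package's native recording format is a plain TSV sample matrix
  with a YAML sidecar header.
* The eyes-open generative regime is a minimal placeholder (halved alpha
  amplitude), flagged as such.
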