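"""Synthetic cohort generator.

Emulates the data structure of a three-group tau-PET / high-density-EEG
study (amyloid-negative and amyloid-positive cognitively unimpaired
groups plus a prodromal dementia group) through a single latent
disease-severity parameter s in [0, 1]:

* every EEG channel receives a common alpha-band source with a
  channel-specific **nonzero** time lag, mixed at a coupling weight that
  declines linearly in s — the substrate the wPLI is designed to detect,
  imposed with lags only because wPLI is blind to zero-lag mixing;
* a stochastic theta-band component grows with s and the coupled alpha
  component shrinks, producing the classic spectral "slowing";
* regional tau DVR rises linearly in s, earliest/steepest in perirhinal
  cortex; amyloid Centiloid separates the three groups at the 23.5
  cut-off;
* ten neuropsychological scores follow a two-factor structure whose first
  (episodic-memory) factor declines with s.

Ground truth (severities, coupling parameters, noiseless tau, true factor
scores) is retained for recovery tests and never consumed by the analysis
stages.  Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .montage import load_montage
from .pet import (EARLY_METAVOI, RegionTau, aggregate_voi,
                  suvr_to_centiloid, classify_amyloid, TRACER_CALIBRATIONS)
from .preprocess import Recording, bandpass_array

__all__ = [
    "CohortConfig",
    "Cohort",
    "GroundTruth",
    "TEST_NAMES",
    "DEFAULT_LOADINGS",
    "simulate_subject_eeg",
    "simulate_tau_profile",
    "simulate_neuropsych",
    "simulate_cohort",
    "write_cohort",
]

GROUPS = ("CU-", "CU+", "prodromal")

#: regional tau model: DVR_r(s) = base_r + slope_r * s + noise.
#: Bases anchor the amyloid-negative end; slopes encode the spread with
#: disease severity, steepest in perirhinal cortex (earliest region).
TAU_BASES = {
    "entorhinal": 0.67, "perirhinal": 0.77, "hippocampus": 0.80,
    "parahippocampus": 0.82, "fusiform": 0.85, "neocortical": 0.88,
}
TAU_SLOPES = {
    "entorhinal": 0.48, "perirhinal": 0.98, "hippocampus": 0.55,
    "parahippocampus": 0.60, "fusiform": 0.70, "neocortical": 0.35,
}
#: plausible relative region sizes used as voxel-count weights
VOXEL_COUNTS = {
    "entorhinal": 800, "perirhinal": 700, "hippocampus": 1700,
    "parahippocampus": 1200, "fusiform": 2600, "neocortical": 20000,
}

#: group-level demographic regimes (age mean/sd, male fraction,
#: APOEe4 carrier fraction) mirroring a genetically enriched elderly cohort
DEMOGRAPHICS = {
    "CU-": {"age": (66.8, 7.0), "male_frac": 15 / 37, "apoe4_frac": 0.46},
    "CU+": {"age": (74.2, 7.0), "male_frac": 7 / 14, "apoe4_frac": 0.79},
    "prodromal": {"age": (71.4, 6.5), "male_frac": 10 / 15, "apoe4_frac": 0.53},
}

#: amyloid Centiloid regimes per group (uniform ranges; CU- strictly below
#: the 23.5 positivity cut-off, the other groups strictly above)
CL_RANGES = {"CU-": (-12.0, 20.0), "CU+": (28.0, 95.0), "prodromal": (35.0, 110.0)}

TEST_NAMES = (
    "avlt_tl", "avlt_dr", "bsrt_tr", "bsrt_dr", "bnt",
    "animal_fluency", "letter_fluency", "palpa49", "tmt_ba", "raven",
)

#: 10 x 2 population loading matrix: factor 1 = episodic memory,
#: factor 2 = language / executive function
DEFAULT_LOADINGS = np.array([
    [0.80, 0.10],   # avlt_tl
    [0.85, 0.05],   # avlt_dr
    [0.88, 0.10],   # bsrt_tr
    [0.82, 0.05],   # bsrt_dr
    [0.10, 0.68],   # bnt
    [0.15, 0.60],   # animal_fluency
    [0.05, 0.62],   # letter_fluency
    [0.10, 0.55],   # palpa49
    [0.05, 0.50],   # tmt_ba
    [0.15, 0.58],   # raven
])

#: plausible raw-score scales (mean, sd) per test
TEST_SCALES = {
    "avlt_tl": (45.0, 9.0), "avlt_dr": (9.0, 3.0), "bsrt_tr": (60.0, 8.0),
    "bsrt_dr": (10.0, 2.5), "bnt": (54.0, 4.0), "animal_fluency": (22.0, 5.0),
    "letter_fluency": (38.0, 10.0), "palpa49": (28.0, 2.0),
    "tmt_ba": (2.4, 0.8), "raven": (46.0, 8.0),
}


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults encode the reference study conditions: 37/14/15 subjects per
    group, five-minute 128-channel recordings at 256 Hz, graded coupling
    loss and spectral slowing, graded regional tau, and amyloid separation
    at the Centiloid cut-off.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"CU-": 37, "CU+": 14, "prodromal": 15})
    duration_s: float = 300.0
    fs: float = 256.0
    n_channels: int = 128
    severity_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "CU-": (0.0, 0.25), "CU+": (0.10, 0.60), "prodromal": (0.50, 1.0)})
    # EEG generative model
    coupling_base: float = 1.0
    coupling_slope: float = -0.6      # per unit severity; negative
    alpha_amp: float = 30.0           # uV, coupled alpha source
    theta_amp: float = 2.5            # uV at severity 0
    theta_slope: float = 1.2          # relative theta growth per unit severity
    noise_sd: float = 10.0            # uV, 1/f background per channel
    zero_lag_amp: float = 0.0         # shared instantaneous confound (off)
    include_eyes_open: bool = False
    # tau model
    tau_bases: Mapping[str, float] = field(default_factory=lambda: dict(TAU_BASES))
    tau_slopes: Mapping[str, float] = field(default_factory=lambda: dict(TAU_SLOPES))
    tau_noise_sd: float = 0.06
    # neuropsych model
    neuropsych_noise_sd: float = 0.6
    # covariates independent of severity unless the confound switch is on
    confound_covariates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
            if n < 1:
                raise ValueError(f"group {g!r} must have at least 1 subject")
        if self.duration_s < 80:
            raise ValueError(
                "duration_s must be >= 80 s (60 s discard + one 20 s epoch)")
        if self.fs < 128:
            raise ValueError("fs must be >= 128 Hz")
        for g, (lo, hi) in self.severity_ranges.items():
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"severity range for {g!r} must lie in [0, 1]")
        if any(b <= 0 for b in self.tau_bases.values()):
            raise ValueError("tau base DVR values must be positive")

    @property
    def channel_labels(self) -> list[str]:
        full = load_montage(128).labels
        if self.n_channels <= 128:
            return list(full[: self.n_channels])
        return list(full) + [f"EXT{i}" for i in range(self.n_channels - 128)]

    @property
    def regions(self) -> list[str]:
        return list(self.tau_bases)


@dataclass
class GroundTruth:
    """Latent quantities retained for recovery tests only."""

    severity: pd.Series                       # per subject
    coupling_weight: pd.Series                # per subject, mean channel gain
    channel_lags: Mapping[str, np.ndarray]    # per subject, samples
    channel_gains: Mapping[str, np.ndarray]   # per subject
    tau_noiseless: pd.DataFrame               # per subject x region
    true_factors: pd.DataFrame                # per subject x 2


def _draw_eeg_params(rng: np.random.Generator, config: CohortConfig,
                     severity: float) -> dict:
    """Structural draws for one recording; consumed in a fixed order so the
    cohort generator can reproduce them without synthesizing signals."""
    f0 = rng.uniform(9.0, 11.0)
    lags = rng.uniform(1.0, 4.0, config.n_channels)        # samples, nonzero
    gain_jitter = rng.uniform(0.8, 1.2, config.n_channels)
    g = config.coupling_base * (1.0 + config.coupling_slope * severity)
    gains = g * gain_jitter
    return {"f0": f0, "lags": lags, "gains": gains}


def _unit_rms_shape(s: np.ndarray, n: int) -> np.ndarray:
    """Scale a spectral amplitude shape so that shaping unit-variance white
    noise with it yields (expected) unit-RMS output."""
    c = np.full(s.size, 2.0)
    c[0] = 1.0
    if n % 2 == 0:
        c[-1] = 1.0
    norm = np.sqrt((c * s ** 2).sum() / n)
    return s / max(norm, 1e-300)


def _pink_shape(freqs: np.ndarray, n: int) -> np.ndarray:
    """1/f spectral amplitude shape (power ~ 1/f above a 1 Hz knee)."""
    s = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    s[0] = 0.0
    return _unit_rms_shape(s, n)


def _theta_shape(freqs: np.ndarray, n: int) -> np.ndarray:
    """Band-limited stochastic theta oscillation: Gaussian bump at 6 Hz."""
    s = np.exp(-0.5 * ((freqs - 6.0) / 1.0) ** 2)
    s[0] = 0.0
    return _unit_rms_shape(s, n)


def simulate_subject_eeg(config: CohortConfig, severity: float, seed: int,
                         condition: str = "eyes_closed",
                         subject_id: str = "sim") -> Recording:
    """One multichannel recording at the given disease severity.

    All channels share one alpha source (carrier in 9-11 Hz with slow phase
    drift and amplitude modulation), delayed per channel by 1-4 samples
    (applied as an FFT phase ramp, so pairwise lags are nonzero) and scaled
    by the severity-dependent coupling weight.  Independent 1/f noise and a
    severity-growing stochastic theta oscillation are added per channel.
    Eyes-open halves the alpha source amplitude.
    """
    if not 0 <= severity <= 1:
        raise ValueError(f"severity must lie in [0, 1], got {severity}")
    if condition not in ("eyes_closed", "eyes_open"):
        raise ValueError(f"unknown condition {condition!r}")
    fs, n_ch = config.fs, config.n_channels
    n = int(round(config.duration_s * fs))
    if config.duration_s < 80:
        raise ValueError("duration too short for the 60 s discard + 20 s epoch contract")

    rng = np.random.default_rng(seed)
    p = _draw_eeg_params(rng, config, severity)

    # --- common alpha source: drifting-phase, amplitude-modulated sinusoid
    t = np.arange(n) / fs
    drift = np.cumsum(rng.normal(0.0, 0.01, n))            # slow phase drift
    envelope = 1.0 + 0.3 * bandpass_array(
        rng.standard_normal(n), 0.05, 0.5, fs, order=2)
    amp = config.alpha_amp * (0.5 if condition == "eyes_open" else 1.0)
    source = amp * envelope * np.sin(2 * np.pi * p["f0"] * t + drift)

    # --- per-channel fractional delays via frequency-domain phase ramp;
    # the source is band-limited to 5-16 Hz (carrier 9-11 Hz plus drift and
    # envelope sidebands), so the ramp only needs those bins
    spec = np.fft.rfft(source)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    keep = (freqs >= 5.0) & (freqs <= 16.0)
    shifted = np.zeros((n_ch, freqs.size), dtype=complex)
    shifted[:, keep] = spec[keep][None, :] * np.exp(
        -2j * np.pi * np.outer(p["lags"] / fs, freqs[keep]))
    x = p["gains"][:, None] * np.fft.irfft(shifted, n=n, axis=1)

    # --- per-channel background: independent 1/f noise plus a stochastic
    # theta oscillation growing with severity, both by spectral shaping of
    # one white-noise stream per channel
    theta_amp = config.theta_amp * (1.0 + config.theta_slope * severity)
    if config.noise_sd > 0 or theta_amp > 0:
        Z = np.fft.rfft(rng.standard_normal((n_ch, n)), axis=1)
        shape = (config.noise_sd * _pink_shape(freqs, n)
                 + theta_amp * _theta_shape(freqs, n))
        x += np.fft.irfft(Z * shape, n=n, axis=1)

    # --- optional shared zero-lag (volume-conduction-like) confound:
    # one instantaneous source mixed into every channel with a random
    # positive gain (so the average reference cannot cancel it exactly)
    if config.zero_lag_amp > 0:
        shared = bandpass_array(rng.standard_normal(n), 2.0, 30.0, fs)
        shared /= max(shared.std(), 1e-12)
        mix = rng.uniform(0.5, 1.5, n_ch)
        x += config.zero_lag_amp * mix[:, None] * shared[None, :]

    return Recording(samples=x, fs=fs, channel_labels=config.channel_labels,
                     condition=condition, subject_id=subject_id)


def simulate_tau_profile(severity: float, config: CohortConfig, seed: int,
                         ) -> dict[str, float]:
    """Regional tau DVR at the given severity: base + slope * s + noise."""
    if not 0 <= severity <= 1:
        raise ValueError(f"severity must lie in [0, 1], got {severity}")
    slopes = dict(config.tau_slopes)
    peri = slopes.get("perirhinal")
    if peri is not None and any(v > peri for v in slopes.values()):
        raise ValueError("perirhinal must carry the steepest tau slope")
    rng = np.random.default_rng(seed)
    out = {}
    for region, base in config.tau_bases.items():
        if base <= 0:
            raise ValueError(f"non-positive base DVR for {region!r}")
        dvr = base + slopes.get(region, 0.0) * severity
        if config.tau_noise_sd > 0:
            dvr += rng.normal(0.0, config.tau_noise_sd)
        out[region] = max(dvr, 0.05)  # DVR is a positive ratio
    return out


def simulate_neuropsych(true_factors: np.ndarray, loadings: np.ndarray,
                        noise_sd: float, seed: int) -> np.ndarray:
    """Ten raw test scores from a 2-factor model.

    scores_z = loadings @ factors + noise, then shifted/scaled to each
    test's plausible raw range.
    """
    true_factors = np.asarray(true_factors, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    if true_factors.shape != (2,):
        raise ValueError("true_factors must be a 2-vector")
    if loadings.shape != (10, 2):
        raise ValueError("loadings must be 10 x 2")
    if np.abs(loadings).max() > 1:
        raise ValueError("loadings must be bounded by 1 in magnitude")
    rng = np.random.default_rng(seed)
    z = loadings @ true_factors
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, 10)
    scales = np.array([TEST_SCALES[t] for t in TEST_NAMES])
    return scales[:, 0] + scales[:, 1] * z


@dataclass
class Cohort:
    """A simulated cohort.

    Recordings are regenerated deterministically on demand from per-subject
    seeds (``recording``/``iter_recordings``) rather than held in memory: a
    full 128-channel five-minute cohort would occupy gigabytes.
    """

    config: CohortConfig
    subjects: pd.DataFrame
    ground_truth: GroundTruth
    eeg_seeds: Mapping[str, int]

    @property
    def conditions(self) -> tuple[str, ...]:
        return (("eyes_closed", "eyes_open") if self.config.include_eyes_open
                else ("eyes_closed",))

    def recording(self, subject_id: str, condition: str = "eyes_closed",
                  ) -> Recording:
        if subject_id not in self.eeg_seeds:
            raise KeyError(f"unknown subject {subject_id!r}")
        if condition not in self.conditions:
            raise KeyError(f"condition {condition!r} not simulated")
        severity = float(self.ground_truth.severity[subject_id])
        seed = self.eeg_seeds[subject_id]
        if condition == "eyes_open":
            seed = seed + 1_000_003  # disjoint stream, still reproducible
        return simulate_subject_eeg(self.config, severity, seed,
                                    condition=condition, subject_id=subject_id)

    def iter_recordings(self, condition: str = "eyes_closed",
                        ) -> Iterator[Recording]:
        for sid in self.subjects["subject_id"]:
            yield self.recording(sid, condition)


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort table plus ground truth (no EEG synthesis;
    recordings come lazily from :meth:`Cohort.recording`)."""
    rng = np.random.default_rng(config.seed)
    rows, sev, cw, lags_map, gains_map, tau_clean, factors = (
        [], {}, {}, {}, {}, {}, {})
    eeg_seeds: dict[str, int] = {}
    idx = 0
    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        if n == 0:
            continue
        lo, hi = config.severity_ranges[group]
        demo = DEMOGRAPHICS[group]
        for _ in range(n):
            sid = f"sub-{idx:03d}"
            idx += 1
            severity = float(rng.uniform(lo, hi))
            if config.confound_covariates:
                age = float(np.clip(60 + 20 * severity + rng.normal(0, 4), 50, 90))
            else:
                age = float(np.clip(rng.normal(*demo["age"]), 50, 90))
            sex = "M" if rng.random() < demo["male_frac"] else "F"
            apoe4 = int(rng.random() < demo["apoe4_frac"])
            education = float(np.clip(rng.normal(16.8, 4.0), 8, 32))

            # amyloid: CL consistent with group, mapped back to SUVR
            cl = float(rng.uniform(*CL_RANGES[group]))
            tracer = str(rng.choice(list(TRACER_CALIBRATIONS),
                                    p=[0.35, 0.55, 0.10]))
            a, b = TRACER_CALIBRATIONS[tracer]
            suvr = (cl - b) / a

            # tau: noiseless profile retained as ground truth
            tau_seed = int(rng.integers(2**31))
            noiseless = {r: config.tau_bases[r]
                         + config.tau_slopes.get(r, 0.0) * severity
                         for r in config.regions}
            tau = simulate_tau_profile(severity, config, tau_seed)
            region_taus = [RegionTau(r, tau[r], VOXEL_COUNTS.get(r, 1000))
                           for r in config.regions]
            tau_early = aggregate_voi(region_taus, EARLY_METAVOI)
            tau_neo = tau.get("neocortical", np.nan)

            # neuropsych: memory factor declines with severity
            f1 = -1.5 * severity + float(rng.normal(0, 0.7))
            f2 = float(rng.normal(0, 1.0))
            np_seed = int(rng.integers(2**31))
            scores = simulate_neuropsych(np.array([f1, f2]), DEFAULT_LOADINGS,
                                         config.neuropsych_noise_sd, np_seed)

            eeg_seed = int(rng.integers(2**31))
            p = _draw_eeg_params(np.random.default_rng(eeg_seed), config, severity)

            row = {
                "subject_id": sid, "group": group, "age": age, "sex": sex,
                "apoe4": apoe4, "education": education, "tracer": tracer,
                "suvr": suvr, "cl_amyloid": suvr_to_centiloid(suvr, tracer),
                "amyloid_status": classify_amyloid(cl),
                "tau_early_metavoi": tau_early, "tau_neocortical": tau_neo,
            }
            row.update({f"tau_{r}": v for r, v in tau.items()})
            row.update(dict(zip(TEST_NAMES, scores)))
            rows.append(row)

            sev[sid] = severity
            cw[sid] = float(p["gains"].mean())
            lags_map[sid] = p["lags"]
            gains_map[sid] = p["gains"]
            tau_clean[sid] = noiseless
            factors[sid] = (f1, f2)
            eeg_seeds[sid] = eeg_seed

    if not rows:
        raise ValueError("cohort is empty: every group has n = 0")
    subjects = pd.DataFrame(rows)
    gt = GroundTruth(
        severity=pd.Series(sev, name="severity"),
        coupling_weight=pd.Series(cw, name="coupling_weight"),
        channel_lags=lags_map, channel_gains=gains_map,
        tau_noiseless=pd.DataFrame(tau_clean).T,
        true_factors=pd.DataFrame(factors, index=["factor1", "factor2"]).T,
    )
    return Cohort(config=config, subjects=subjects, ground_truth=gt,
                  eeg_seeds=eeg_seeds)


def write_cohort(cohort: Cohort, out_dir, include_recordings: bool = False,
                 ) -> None:
    """Serialize the cohort: subjects TSV, withheld ground-truth TSV, YAML
    config (explicit seed), and optionally per-subject recording files."""
    from pathlib import Path
    from . import io as tio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(out / "cohort.tsv", sep="\t", index=False)
    gt = cohort.ground_truth
    gt_table = pd.concat(
        [gt.severity, gt.coupling_weight, gt.true_factors,
         gt.tau_noiseless.add_prefix("tau_true_")], axis=1)
    gt_table.index.name = "subject_id"
    gt_table.to_csv(out / "ground_truth.tsv", sep="\t")
    cfg = asdict(cohort.config)
    cfg["n_per_group"] = dict(cfg["n_per_group"])
    cfg["severity_ranges"] = {k: list(v) for k, v in cfg["severity_ranges"].items()}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    if include_recordings:
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for cond in cohort.conditions:
            for rec in cohort.iter_recordings(cond):
                tio.write_recording(rec, rec_dir / f"{rec.subject_id}_{cond}")
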