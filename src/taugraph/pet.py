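"""Region-level PET arithmetic.

Amyloid: tracer-specific linear SUVR -> Centiloid (CL) conversion and
binary positivity at a pathologically validated CL cut-off of 23.5.
Tau: voxel-count-weighted composite VOIs (the early metaVOI covering the
medial-temporal regions affected first, and a neocortical VOI), and a
normative positivity threshold of mean + 1 SD over an amyloid-negative
cognitively unimpaired reference sample.

The pipeline starts from region-level values; no image-domain processing
happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AmyloidMeasure",
    "RegionTau",
    "VOIDefinition",
    "TRACER_CALIBRATIONS",
    "EARLY_METAVOI",
    "NEOCORTICAL_VOI",
    "CL_CUTOFF",
    "suvr_to_centiloid",
    "classify_amyloid",
    "aggregate_voi",
    "tau_positivity_threshold",
    "classify_tau",
    "pet_summary",
]

#: slope/intercept of the published SUVR -> Centiloid calibration per tracer
TRACER_CALIBRATIONS: dict[str, tuple[float, float]] = {
    "PiB": (132.53, -147.64),          # 11C-PiB, SUVR(40-60)
    "NAV4694": (107.78, -114.71),      # 18F-NAV4694, SUVR(50-70)
    "florbetaben": (147.0, -166.5),    # 18F-florbetaben, SUVR(90-110)
}

#: validated Centiloid cut-off for amyloid positivity
CL_CUTOFF = 23.5


@dataclass(frozen=True)
class VOIDefinition:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a VOI needs at least one member region")


#: earliest tau-vulnerable territory (medial temporal composite)
EARLY_METAVOI = VOIDefinition(
    "early_metaVOI",
    ("entorhinal", "perirhinal", "hippocampus", "parahippocampus", "fusiform"),
)

#: neocortical spread composite (temporal + parietal association cortex)
NEOCORTICAL_VOI = VOIDefinition("neocortical_VOI", ("neocortical",))


@dataclass
class RegionTau:
    """Tau DVR of one region with its voxel count (aggregation weight)."""

    region: str
    dvr: float
    voxel_count: int

    def __post_init__(self) -> None:
        if self.dvr <= 0:
            raise ValueError(f"DVR must be positive, got {self.dvr} for {self.region}")
        if self.voxel_count < 0:
            raise ValueError("voxel_count must be >= 0")


@dataclass
class AmyloidMeasure:
    suvr: float
    tracer: str
    cl: float
    status: str  # "positive" | "negative"


def suvr_to_centiloid(suvr: float, tracer: str) -> float:
    """Exact linear map CL = a * SUVR + b with published per-tracer (a, b)."""
    if suvr <= 0:
        raise ValueError(f"SUVR must be positive, got {suvr}")
    try:
        a, b = TRACER_CALIBRATIONS[tracer]
    except KeyError:
        supported = ", ".join(sorted(TRACER_CALIBRATIONS))
        raise KeyError(
            f"unknown tracer {tracer!r}; supported tracers: {supported}"
        ) from None
    return a * suvr + b


def classify_amyloid(cl: float, cutoff: float = CL_CUTOFF) -> str:
    """Positive iff CL strictly exceeds the cut-off (tie -> negative)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return "positive" if cl > cutoff else "negative"


def amyloid_measure(suvr: float, tracer: str, cutoff: float = CL_CUTOFF,
                    ) -> AmyloidMeasure:
    cl = suvr_to_centiloid(suvr, tracer)
    return AmyloidMeasure(suvr=suvr, tracer=tracer, cl=cl,
                          status=classify_amyloid(cl, cutoff))


def aggregate_voi(regions: Iterable[RegionTau], voi: VOIDefinition) -> float:
    """Voxel-count-weighted mean DVR over the VOI's member regions."""
    by_name: dict[str, RegionTau] = {}
    for r in regions:
        by_name[r.region] = r
    missing = [m for m in voi.members if m not in by_name]
    if missing:
        raise KeyError(f"VOI '{voi.name}' missing region(s): {missing}")
    members = [by_name[m] for m in voi.members]
    weights = np.array([r.voxel_count for r in members], dtype=float)
    if weights.sum() <= 0:
        raise ValueError(f"VOI '{voi.name}' has zero total voxel count")
    values = np.array([r.dvr for r in members])
    return float(np.average(values, weights=weights))


def tau_positivity_threshold(cu_neg_dvr: Sequence[float]) -> float:
    """Mean + 1 sample SD (n-1 denominator) of the reference sample."""
    x = np.asarray(cu_neg_dvr, dtype=float)
    if x.size < 2:
        raise ValueError("threshold requires at least 2 reference values")
    return float(x.mean() + x.std(ddof=1))


def classify_tau(dvr: float, threshold: float) -> str:
    """Positive iff DVR strictly exceeds the threshold (tie -> negative)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return "positive" if dvr > threshold else "negative"


def pet_summary(amyloid: pd.DataFrame, tau_regions: pd.DataFrame,
                cu_neg_ids: Sequence[str] | None = None,
                cutoff: float = CL_CUTOFF) -> pd.DataFrame:
    """Per-subject PET summary table from the two input TSV layouts.

    Parameters
    ----------
    amyloid : DataFrame with columns (subject_id, tracer, suvr)
    tau_regions : DataFrame with columns (subject_id, region, dvr, voxel_count)
    cu_neg_ids : amyloid-negative cognitively unimpaired reference subjects
        used for the tau-positivity thresholds; defaults to all subjects
        classified amyloid-negative here.
    """
    amy = amyloid.set_index("subject_id")
    rows = []
    for sid, sub in tau_regions.groupby("subject_id", sort=True):
        regions = [RegionTau(r.region, r.dvr, int(r.voxel_count))
                   for r in sub.itertuples()]
        row: dict[str, object] = {"subject_id": sid}
        if sid in amy.index:
            m = amyloid_measure(float(amy.loc[sid, "suvr"]),
                                str(amy.loc[sid, "tracer"]), cutoff)
            row.update(cl=m.cl, amyloid_status=m.status, tracer=m.tracer)
        row["dvr_early_metaVOI"] = aggregate_voi(regions, EARLY_METAVOI)
        row["dvr_neocortical"] = aggregate_voi(regions, NEOCORTICAL_VOI)
        for r in regions:
            row[f"dvr_{r.region}"] = r.dvr
        rows.append(row)
    out = pd.DataFrame(rows).set_index("subject_id")

    if cu_neg_ids is None and "amyloid_status" in out.columns:
        cu_neg_ids = list(out.index[out["amyloid_status"] == "negative"])
    if cu_neg_ids:
        ref = out.loc[[s for s in cu_neg_ids if s in out.index]]
        for col, status_col in [("dvr_early_metaVOI", "tau_status_early"),
                                ("dvr_neocortical", "tau_status_neocortical")]:
            thr = tau_positivity_threshold(ref[col].to_numpy())
            out[status_col] = [classify_tau(v, thr) for v in out[col]]
            out.attrs[f"threshold_{col}"] = thr
            out.attrs[f"threshold_n_{col}"] = len(ref)
    return out.reset_index()
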