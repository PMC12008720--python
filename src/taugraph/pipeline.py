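"""End-to-end analysis: recordings -> features -> statistical report.

Feature extraction runs the fixed conditioning chain (down-sample to
256 Hz if needed, average re-reference, 0.5-40 Hz zero-phase band-pass,
60 s discard + 20 s epochs), estimates the alpha- and theta-band wPLI
adjacency per subject, and computes the two weighted global graph
outcomes, optionally on reduced electrode subsets.

The statistical report mirrors the study battery: whole-group tau
regressions for both outcomes, gatekept subgroup and per-region
correlation tables, group contrasts, the amyloid regression in
cognitively unimpaired subjects, exploratory band/condition and
electrode-subset reruns, tau-positivity two-group contrasts, and
factor-score correlations.  Per-region analyses run only when the
corresponding primary regression's tau term is significant (gatekeeping).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import wpli_matrix
from .factor import FactorAdequacyError, factor_analysis
from .graph import graph_metrics, subset_metrics
from .montage import ElectrodeSubset, standard_subsets
from .pet import tau_positivity_threshold, classify_tau
from .preprocess import (BANDS, Recording, bandpass, epoch_recording,
                         rereference_average, resample, relative_band_power,
                         welch_psd)
from .stats import (fit_primary_regression, fdr_adjust, kruskal_dunn,
                    spearman_partial, two_group_compare)
from .synthetic import Cohort, TEST_NAMES

__all__ = [
    "AnalysisConfig",
    "subject_features",
    "build_feature_table",
    "run_full_analysis",
]

TAU_REGIONS = ("entorhinal", "perirhinal", "hippocampus",
               "parahippocampus", "fusiform")


@dataclass
class AnalysisConfig:
    """Knobs of the feature-extraction and statistics stages."""

    target_fs: float = 256.0
    broadband: tuple[float, float] = (0.5, 40.0)
    discard_s: float = 60.0
    epoch_s: float = 20.0
    welch_window_s: float = 0.5
    welch_overlap: float = 0.5
    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"alpha": BANDS["alpha"],
                                 "theta": BANDS["theta"]})
    electrode_subsets: Sequence[int] = (64, 32, 24)
    tau_var: str = "tau_early_metavoi"
    covariates: tuple[str, ...] = ("age", "sex", "apoe4")
    partial_covariates: tuple[str, ...] = ("age", "sex")
    alpha: float = 0.05
    seed: int = 0


def subject_features(rec: Recording, config: AnalysisConfig | None = None,
                     subsets: Mapping[int, ElectrodeSubset] | None = None,
                     ) -> dict[str, float]:
    """Graph metrics (per band, per electrode set) and relative band powers
    for one recording; keys like ``C_alpha_128`` / ``L_theta_64`` /
    ``relpow_theta``."""
    cfg = config or AnalysisConfig()
    if rec.fs > cfg.target_fs:
        rec = resample(rec, cfg.target_fs)
    rec = rereference_average(rec)
    rec = bandpass(rec, *cfg.broadband)
    ep = epoch_recording(rec, cfg.discard_s, cfg.epoch_s)

    out: dict[str, float] = {}
    ps = welch_psd(ep, cfg.welch_window_s, cfg.welch_overlap)
    for band_name, band in cfg.bands.items():
        out[f"relpow_{band_name}"] = float(
            relative_band_power(ps, band, cfg.broadband).mean())
        W = wpli_matrix(ep, band, cfg.welch_window_s, cfg.welch_overlap)
        gm = graph_metrics(W)
        nch = rec.n_channels
        out[f"C_{band_name}_{nch}"] = gm.C
        out[f"L_{band_name}_{nch}"] = gm.L
        if subsets and band_name == "alpha":
            for size, subset in subsets.items():
                if set(subset.labels) <= set(rec.channel_labels):
                    sm = subset_metrics(W, subset)
                    out[f"C_{band_name}_{size}"] = sm.C
                    out[f"L_{band_name}_{size}"] = sm.L
    return out


def build_feature_table(cohort: Cohort, config: AnalysisConfig | None = None,
                        include_subsets: bool = True,
                        progress: bool = False) -> pd.DataFrame:
    """Per-subject feature table: cohort covariates + PET + graph metrics.

    Primary outcome columns ``C`` and ``L`` alias the eyes-closed
    alpha-band full-montage metrics.
    """
    cfg = config or AnalysisConfig()
    subsets = None
    if include_subsets and cohort.config.n_channels == 128:
        all_subs = standard_subsets()
        subsets = {s: all_subs[s] for s in cfg.electrode_subsets}
    rows = []
    n_full = cohort.config.n_channels
    for i, sid in enumerate(cohort.subjects["subject_id"]):
        row: dict[str, float] = {"subject_id": sid}
        for cond in cohort.conditions:
            rec = cohort.recording(sid, cond)
            feats = subject_features(rec, cfg, subsets)
            suffix = "" if cond == "eyes_closed" else "_eo"
            row.update({f"{k}{suffix}": v for k, v in feats.items()})
        rows.append(row)
        if progress and (i + 1) % 10 == 0:
            print(f"  processed {i + 1} subjects", flush=True)
    feats_df = pd.DataFrame(rows)
    feats_df["C"] = feats_df[f"C_alpha_{n_full}"]
    feats_df["L"] = feats_df[f"L_alpha_{n_full}"]
    return cohort.subjects.merge(feats_df, on="subject_id")


def _corr_row(name: str, res) -> dict:
    return {"variable": name, "rho": res.rho, "ci_lo": res.ci95[0],
            "ci_hi": res.ci95[1], "p": res.p, "n": res.n,
            "covariates": ",".join(res.covariates)}


def _subgroup_corr(table: pd.DataFrame, tau_var: str, outcomes, covs,
                   ) -> pd.DataFrame:
    rows = []
    for group, sub in table.groupby("group", sort=False):
        for outcome in outcomes:
            for use_cov in (False, True):
                Z = None
                if use_cov:
                    Z = sub[list(covs)].copy()
                    if "sex" in Z.columns:
                        Z["sex"] = (Z["sex"] == "M").astype(float)
                try:
                    res = spearman_partial(sub[tau_var], sub[outcome], Z)
                except ValueError as exc:
                    rows.append({"group": group, "outcome": outcome,
                                 "skipped": str(exc)})
                    continue
                rows.append({"group": group, "outcome": outcome,
                             **_corr_row(tau_var, res)})
    return pd.DataFrame(rows)


def run_full_analysis(table: pd.DataFrame, config: AnalysisConfig | None = None,
                      out_dir=None, neuropsych: pd.DataFrame | None = None,
                      ) -> dict:
    """The full statistical battery over a complete feature table.

    Returns a dict of result tables (also written as TSVs plus a JSON run
    manifest when ``out_dir`` is given).  Stages with missing inputs are
    skipped with a logged reason instead of failing the run.
    """
    cfg = config or AnalysisConfig()
    results: dict[str, object] = {}
    manifest: dict[str, object] = {"version": __version__, "seed": cfg.seed,
                                   "n_input_rows": int(len(table)),
                                   "skipped": {}, "decisions": {
        "sex_coding": "F=0, M=1", "apoe_coding": "noncarrier=0, carrier=1",
        "partial_spearman": "Pearson on ranked residuals",
        "dunn_adjust": "holm (post hoc pairs), BH (per-region family)",
    }}

    def skip(stage: str, reason: str) -> None:
        manifest["skipped"][stage] = reason
        warnings.warn(f"stage {stage!r} skipped: {reason}", stacklevel=2)

    outcomes = ("C", "L")
    tau_var = cfg.tau_var

    # (a) whole-group primary regressions
    primary = {}
    reg_rows = []
    for outcome in outcomes:
        try:
            res = fit_primary_regression(table, outcome, tau_var,
                                         cfg.covariates)
        except ValueError as exc:
            skip(f"primary_{outcome}", str(exc))
            continue
        primary[outcome] = res
        for reg, row in res.coefficients.iterrows():
            reg_rows.append({"outcome": outcome, "regressor": reg,
                             "beta": row["beta"], "p": row["p"],
                             "model_p": res.model_p, "n": res.n})
    results["table3_regression"] = pd.DataFrame(reg_rows)

    # (b) per-subgroup Spearman / partial correlations for the metaVOI
    try:
        results["table4_subgroup_corr"] = _subgroup_corr(
            table, tau_var, outcomes, cfg.partial_covariates)
    except KeyError as exc:
        skip("table4", f"missing column {exc}")

    # gatekept per-region analyses
    region_cols = [f"tau_{r}" for r in TAU_REGIONS if f"tau_{r}" in table.columns]
    gate_open = {o: o in primary and primary[o].p(tau_var) < cfg.alpha
                 for o in outcomes}
    manifest["gatekeeping"] = {o: bool(v) for o, v in gate_open.items()}
    region_rows = []
    for outcome in outcomes:
        if not gate_open[outcome]:
            skip(f"table6_{outcome}",
                 "gatekeeping: primary tau term not significant")
            continue
        for col in region_cols:
            try:
                res = fit_primary_regression(table, outcome, col,
                                             cfg.covariates)
            except ValueError as exc:
                skip(f"table6_{outcome}_{col}", str(exc))
                continue
            region_rows.append({"outcome": outcome, "region": col,
                                "beta_tau": res.beta(col), "p": res.p(col),
                                "model_p": res.model_p, "n": res.n})
    table6 = pd.DataFrame(region_rows)
    if len(table6):
        table6["p_adj"] = np.concatenate([
            fdr_adjust(table6.loc[table6["outcome"] == o, "p"].to_numpy())
            for o in outcomes if (table6["outcome"] == o).any()])
        # subgroup correlations per region, also behind the gate
        per_region_corr = []
        for col in region_cols:
            sub = _subgroup_corr(table, col, outcomes, cfg.partial_covariates)
            sub.insert(0, "region", col)
            per_region_corr.append(sub)
        results["table6_region_corr"] = pd.concat(per_region_corr,
                                                  ignore_index=True)
    results["table6_regions"] = table6

    # (c) group means + Kruskal-Wallis / Dunn
    t5_rows = []
    for var in (*outcomes, tau_var):
        if var not in table.columns:
            continue
        try:
            kd = kruskal_dunn(table[var], table["group"], adjust="holm")
        except ValueError as exc:
            skip(f"table5_{var}", str(exc))
            continue
        means = table.groupby("group")[var].agg(["mean", "std"])
        row = {"variable": var, "H": kd.H, "p": kd.p}
        for g, m in means.iterrows():
            row[f"mean_{g}"] = m["mean"]
            row[f"sd_{g}"] = m["std"]
        for r in kd.dunn.itertuples():
            row[f"dunn_p_{r.group1}_vs_{r.group2}"] = r.p_adj
        t5_rows.append(row)
    results["table5_group_metrics"] = pd.DataFrame(t5_rows)

    # (d) amyloid-CL regression in cognitively unimpaired subjects
    cu = table[table["group"].isin(["CU-", "CU+"])]
    amy_rows = []
    if len(cu) >= 8 and "cl_amyloid" in cu.columns:
        for outcome in outcomes:
            try:
                res = fit_primary_regression(cu, outcome, "cl_amyloid",
                                             ("age", "sex"))
            except ValueError as exc:
                skip(f"amyloid_{outcome}", str(exc))
                continue
            for reg, row in res.coefficients.iterrows():
                amy_rows.append({"outcome": outcome, "regressor": reg,
                                 "beta": row["beta"], "p": row["p"],
                                 "model_p": res.model_p, "n": res.n})
    else:
        skip("amyloid_regression", "too few cognitively unimpaired rows")
    results["amyloid_regression_cu"] = pd.DataFrame(amy_rows)

    # (e) exploratory theta-band and eyes-open reruns
    expl_rows = []
    n_full = None
    for col in table.columns:
        if col.startswith("C_alpha_") and not col.endswith("_eo"):
            n_full = max(int(col.rsplit("_", 1)[1]), n_full or 0)
    for label, (c_col, l_col) in {
        "theta": (f"C_theta_{n_full}", f"L_theta_{n_full}"),
        "alpha_eyes_open": (f"C_alpha_{n_full}_eo", f"L_alpha_{n_full}_eo"),
    }.items():
        if c_col not in table.columns:
            skip(f"exploratory_{label}", "metrics not present in table")
            continue
        for outcome_col, outcome in ((c_col, "C"), (l_col, "L")):
            try:
                res = fit_primary_regression(table, outcome_col, tau_var,
                                             cfg.covariates)
            except ValueError as exc:
                skip(f"exploratory_{label}_{outcome}", str(exc))
                continue
            expl_rows.append({"analysis": label, "outcome": outcome,
                              "beta_tau": res.beta(tau_var),
                              "p": res.p(tau_var), "model_p": res.model_p})
    results["exploratory"] = pd.DataFrame(expl_rows)

    # (f) electrode-subset reruns
    sub_rows = []
    for size in cfg.electrode_subsets:
        c_col, l_col = f"C_alpha_{size}", f"L_alpha_{size}"
        if c_col not in table.columns:
            skip(f"subset_{size}", "subset metrics not present in table")
            continue
        for outcome_col, outcome in ((c_col, "C"), (l_col, "L")):
            try:
                res = fit_primary_regression(table, outcome_col, tau_var,
                                             cfg.covariates)
            except ValueError as exc:
                skip(f"subset_{size}_{outcome}", str(exc))
                continue
            sub_rows.append({"electrodes": size, "outcome": outcome,
                             "beta_tau": res.beta(tau_var),
                             "p": res.p(tau_var), "model_p": res.model_p})
    results["subset_regressions"] = pd.DataFrame(sub_rows)

    # (g) tau-positivity two-group contrasts
    pos_rows = []
    ref = table[table["group"] == "CU-"]
    for voi_col in (tau_var, "tau_neocortical"):
        if voi_col not in table.columns or len(ref) < 2:
            skip(f"tau_positivity_{voi_col}", "missing column or reference")
            continue
        thr = tau_positivity_threshold(ref[voi_col].to_numpy())
        status = np.array([classify_tau(v, thr) for v in table[voi_col]])
        if len(set(status)) < 2 or min((status == "positive").sum(),
                                       (status == "negative").sum()) < 3:
            skip(f"tau_positivity_{voi_col}", "degenerate positive/negative split")
            continue
        for outcome in outcomes:
            res = two_group_compare(table[outcome], status)
            pos_rows.append({"voi": voi_col, "threshold": thr,
                             "n_positive": int((status == "positive").sum()),
                             "n_negative": int((status == "negative").sum()),
                             "outcome": outcome, "method": res.method,
                             "statistic": res.statistic, "p": res.p})
    results["tau_positivity"] = pd.DataFrame(pos_rows)

    # (h) factor scores vs tau and graph measures
    np_cols = [c for c in TEST_NAMES if c in table.columns]
    if neuropsych is None and len(np_cols) == len(TEST_NAMES):
        neuropsych = table[list(np_cols)]
    fs_rows = []
    if neuropsych is not None and len(neuropsych) >= 50:
        try:
            model = factor_analysis(neuropsych)
            scores = model.scores
            covs = [c for c in ("age", "sex", "education") if c in table.columns]
            Z = table[covs].copy()
            if "sex" in Z.columns:
                Z["sex"] = (Z["sex"] == "M").astype(float)
            for fac in scores.columns:
                for target in (tau_var, *outcomes):
                    res = spearman_partial(scores[fac].to_numpy(),
                                           table[target].to_numpy(), Z)
                    fs_rows.append({"factor": fac, "target": target,
                                    **_corr_row(target, res)})
            manifest["factor_model"] = {
                "variance_explained": model.variance_explained,
                "kmo": model.kmo, "bartlett_p": model.bartlett_p,
                "cfi": model.cfi, "rmsea": model.rmsea,
            }
        except (FactorAdequacyError, ValueError, np.linalg.LinAlgError) as exc:
            skip("factor_scores", str(exc))
    else:
        skip("factor_scores", "no neuropsych table with n >= 50")
    results["factor_score_corr"] = pd.DataFrame(fs_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            if isinstance(df, pd.DataFrame):
                df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
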