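"""Statistical battery over the per-subject feature table.

Primary model: OLS of a global graph measure on regional tau load plus
age, sex and APOEe4 carriership.  Subgroup associations use Spearman and
rank-based partial correlations (Pearson on ranked residuals) with Fisher-z
confidence intervals.  Group contrasts use tie-corrected Kruskal-Wallis
with Dunn's post hoc z tests; two-group contrasts pick Welch's t or the
rank-sum test by a Shapiro-Wilk normality gate.  Multiplicity is handled
with Benjamini-Hochberg FDR (or Holm for post hoc pairs).

Coding conventions (the reference levels): sex female = 0 / male = 1,
APOEe4 noncarrier = 0 / carrier = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "CorrelationResult",
    "KruskalDunnResult",
    "TwoGroupResult",
    "fit_primary_regression",
    "spearman_partial",
    "kruskal_dunn",
    "two_group_compare",
    "fdr_adjust",
]


@dataclass
class RegressionResult:
    outcome: str
    coefficients: pd.DataFrame  # index = regressor, columns = beta, p
    model_p: float
    n: int
    r_squared: float = float("nan")

    def beta(self, name: str) -> float:
        return float(self.coefficients.loc[name, "beta"])

    def p(self, name: str) -> float:
        return float(self.coefficients.loc[name, "p"])


@dataclass
class CorrelationResult:
    rho: float
    ci95: tuple[float, float]
    p: float
    n: int
    covariates: tuple[str, ...] = ()


@dataclass
class KruskalDunnResult:
    H: float
    p: float
    group_n: dict[str, int]
    dunn: pd.DataFrame  # columns: group1, group2, z, p, p_adj


@dataclass
class TwoGroupResult:
    method: str  # "welch_t" | "ranksum"
    statistic: float
    p: float
    shapiro_p: tuple[float, float]
    n: tuple[int, int]


def _encode_binary(series: pd.Series, name: str) -> pd.Series:
    """0/1 encoding with documented reference levels."""
    if series.dtype.kind in "ifb":
        vals = series.astype(float)
        if not set(np.unique(vals)) <= {0.0, 1.0}:
            raise ValueError(f"{name} must be binary 0/1")
        return vals
    mapping = {"F": 0.0, "M": 1.0, "female": 0.0, "male": 1.0,
               "noncarrier": 0.0, "carrier": 1.0}
    try:
        return series.map(lambda v: mapping[str(v)])
    except KeyError as exc:
        raise ValueError(f"cannot encode {name} level {exc}") from None


def fit_primary_regression(table: pd.DataFrame, outcome: str, tau_var: str,
                           covariates: Sequence[str] = ("age", "sex", "apoe4"),
                           ) -> RegressionResult:
    """OLS of ``outcome`` on tau load plus covariates.

    Rows with missing values in any model variable are excluded; the
    returned ``n`` is the analyzed sample size.
    """
    cols = [outcome, tau_var, *covariates]
    data = table[cols].copy()
    for c in ("sex", "apoe4"):
        if c in data.columns:
            data[c] = _encode_binary(data[c], c)
    data = data.dropna().astype(float)
    X = sm.add_constant(data[[tau_var, *covariates]], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        const = [c for c in X.columns
                 if c != "const" and X[c].nunique() <= 1]
        raise ValueError(
            f"rank-deficient design matrix (rank {rank} < {X.shape[1]}); "
            f"constant/collinear columns: {const or 'correlated regressors'}")
    if len(data) < X.shape[1] + 1:
        raise ValueError(f"n = {len(data)} too small for {X.shape[1]} parameters")
    fit = sm.OLS(data[outcome], X).fit()
    coefs = pd.DataFrame({"beta": fit.params, "p": fit.pvalues}).drop(index="const")
    return RegressionResult(outcome=outcome, coefficients=coefs,
                            model_p=float(fit.f_pvalue), n=int(fit.nobs),
                            r_squared=float(fit.rsquared))


def _fisher_ci(r: float, n_eff: int, alpha: float = 0.05,
               ) -> tuple[float, float]:
    """Fisher-z interval; n_eff is n - 3 for plain, n - k - 3 for partial."""
    if n_eff <= 0 or abs(r) >= 1:
        return (-1.0, 1.0)
    z = np.arctanh(r)
    half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(n_eff)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def spearman_partial(x: Sequence[float], y: Sequence[float],
                     covariates: pd.DataFrame | np.ndarray | None = None,
                     ) -> CorrelationResult:
    """Spearman correlation, optionally partialled for covariates.

    Without covariates: plain Spearman rho with the asymptotic t p-value
    and a Fisher-z 95% CI (n - 3).  With covariates: every variable is
    rank-transformed, x and y ranks are residualized on the rank covariates
    (plus intercept), and Pearson correlation of the residuals is reported,
    with the t test on n - k - 2 df and Fisher-z CI on n - k - 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input vector: correlation undefined")
    cov_names: tuple[str, ...] = ()
    if covariates is not None:
        Z = pd.DataFrame(covariates)
        cov_names = tuple(str(c) for c in Z.columns)
        if Z.shape[1] == 0:
            covariates = None
    n = x.size
    if covariates is None:
        if n < 4:
            raise ValueError("need n >= 4 observations")
        rho, p = sps.spearmanr(x, y)
        return CorrelationResult(rho=float(rho), ci95=_fisher_ci(rho, n - 3),
                                 p=float(p), n=n)
    Z = pd.DataFrame(covariates).to_numpy(dtype=float)
    k = Z.shape[1]
    if n < 4 + k:
        raise ValueError(f"need n >= {4 + k} observations with {k} covariates")
    for j in range(k):
        if np.unique(Z[:, j]).size < 2:
            raise ValueError(f"constant covariate column {cov_names[j]!r}")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rz = np.column_stack([np.ones(n)] +
                         [sps.rankdata(Z[:, j]) for j in range(k)])
    bx, *_ = np.linalg.lstsq(rz, rx, rcond=None)
    by, *_ = np.linalg.lstsq(rz, ry, rcond=None)
    ex, ey = rx - rz @ bx, ry - rz @ by
    denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
    if denom == 0:
        raise ValueError("residuals are constant after covariate adjustment")
    rho = float((ex * ey).sum() / denom)
    df = n - k - 2
    tval = rho * np.sqrt(df / max(1e-300, 1 - rho ** 2))
    p = float(2 * sps.t.sf(abs(tval), df))
    return CorrelationResult(rho=rho, ci95=_fisher_ci(rho, n - k - 3),
                             p=p, n=n, covariates=cov_names)


def _dunn_z(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Tie-corrected Dunn z statistics for all group pairs."""
    N = values.size
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    labels = pd.unique(groups)
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    n = {g: int((groups == g).sum()) for g in labels}
    rows = []
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / n[g1] + 1.0 / n[g2]))
        z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
        rows.append({"group1": g1, "group2": g2, "z": float(z),
                     "p": float(2 * sps.norm.sf(abs(z)))})
    return pd.DataFrame(rows)


def kruskal_dunn(values: Sequence[float], groups: Sequence,
                 adjust: str = "holm") -> KruskalDunnResult:
    """Kruskal-Wallis across >= 2 groups with Dunn's post hoc pairs."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    for g, s in zip(labels, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if np.unique(values).size == 1:
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*samples)
    dunn = _dunn_z(values, groups)
    dunn["p_adj"] = fdr_adjust(dunn["p"].to_numpy()) if adjust == "fdr_bh" \
        else multipletests(dunn["p"].to_numpy(), method=adjust)[1]
    return KruskalDunnResult(H=float(H), p=float(p),
                             group_n={str(g): int((groups == g).sum())
                                      for g in labels},
                             dunn=dunn)


def two_group_compare(values: Sequence[float], groups: Sequence,
                      alpha_normality: float = 0.05) -> TwoGroupResult:
    """Welch t-test when both groups pass Shapiro-Wilk, else rank-sum."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(labels)}")
    a, b = (values[groups == g] for g in labels)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    constant = np.unique(a).size == 1 or np.unique(b).size == 1
    if constant:
        warnings.warn("constant group: falling back to the rank-sum test",
                      stacklevel=2)
        sw = (float("nan"), float("nan"))
        normal = False
    else:
        sw = (float(sps.shapiro(a).pvalue), float(sps.shapiro(b).pvalue))
        normal = sw[0] > alpha_normality and sw[1] > alpha_normality
    if normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        method = "welch_t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
        method = "ranksum"
    return TwoGroupResult(method=method, statistic=float(res.statistic),
                          p=float(min(res.pvalue, 1.0)), shapiro_p=sw,
                          n=(int(a.size), int(b.size)))


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
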