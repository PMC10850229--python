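"""Pairwise statistical comparison of quantitation approaches.

Performance metrics from two approaches are paired observation-by-
observation and their log10 differences ``Y_ij = log10(metric_B) -
log10(metric_A)`` modeled with a one-way random-effects model

    Y_ij = mu + b_i + e_ij,   b_i ~ N(0, sigma_b^2), e_ij ~ N(0, sigma_w^2)

(compound-symmetry covariance within each chemical ``i``).  The model is
fitted by REML, profiling the variance ratio ``lambda = sigma_b^2 /
sigma_w^2``; the two-sided test of H0: mu = 0 uses Satterthwaite degrees
of freedom computed from the REML variance-component covariance (numeric
Hessian of the restricted deviance).  ``10^mu_hat`` approximates the
geometric-mean fold difference between approaches.

For comparisons where the per-chemical bootstrap makes all within-
chemical differences identical (e.g. CLFR between the two bounded-RF
approaches), each chemical collapses to its median difference and a
two-sided Wilcoxon signed-rank test is used instead, with the fold
reported from the Hodges-Lehmann pseudo-median.

UCQ/LCQ pairings exclude any observation with a sub-unity value in
either approach (an interval miss has no interpretable log-fold
comparison); exclusion counts are logged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import InsufficientDataError, logger

__all__ = [
    "ComparisonResult",
    "PairedComparison",
    "pair_observations",
    "reml_paired_test",
    "wilcoxon_per_chemical",
]

PAIR_KEYS = ["chemical_id", "level_index", "replicate_index"]
SUB_UNITY_METRICS = {"ucq", "lcq"}


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one pairwise approach comparison on one metric."""

    approach_pair: tuple[str, str]
    metric: str
    mu_hat: float          # log10 units
    fold: float            # 10^mu_hat (pseudo-median fold for wilcoxon)
    sigma_b2: float
    sigma_w2: float
    df: float
    statistic: float
    p_value: float
    n_used: int
    n_chemicals: int
    method: str            # "reml" or "wilcoxon"
    boundary: bool = False  # sigma_b^2 estimate hit the zero boundary


def pair_observations(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                      metric: str) -> pd.DataFrame:
    """Per-chemical log10 differences of one metric between approaches.

    Returns a DataFrame with ``chemical_id`` and ``diff`` (B minus A on
    the log10 scale) for observations present in both approaches.
    """
    metric = metric.lower()
    for df, name in ((metrics_a, "A"), (metrics_b, "B")):
        if metric not in df.columns:
            raise KeyError(f"metrics table {name} lacks column {metric!r}")
    merged = metrics_a[PAIR_KEYS + [metric]].merge(
        metrics_b[PAIR_KEYS + [metric]], on=PAIR_KEYS, suffixes=("_a", "_b")
    )
    if merged.empty:
        raise InsufficientDataError("no shared observations between approaches")
    n_shared = len(merged)
    if metric in SUB_UNITY_METRICS:
        keep = (merged[f"{metric}_a"] >= 1.0) & (merged[f"{metric}_b"] >= 1.0)
        n_excluded = int((~keep).sum())
        if n_excluded:
            logger.info(
                "pair_observations(%s): excluded %d of %d pairs with a "
                "sub-unity value in either approach", metric, n_excluded, n_shared,
            )
        merged = merged[keep]
        if merged.empty:
            raise InsufficientDataError(
                f"all {metric} pairs excluded as sub-unity"
            )
    out = merged[["chemical_id"]].copy()
    out["diff"] = np.log10(merged[f"{metric}_b"]) - np.log10(merged[f"{metric}_a"])
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# one-way random-effects REML


def _group_stats(differences: pd.DataFrame):
    g = differences.groupby("chemical_id")["diff"]
    ybar = g.mean().to_numpy(float)
    n = g.count().to_numpy(float)
    ssw = float(((differences["diff"] - g.transform("mean")) ** 2).sum())
    return ybar, n, ssw


def _profile_neg2relml(lam: float, ybar, n, ssw):
    """Restricted deviance profiled over mu and sigma_w^2, up to a constant."""
    d = 1.0 + n * lam
    w = n / d
    sw = w.sum()
    mu = float((w * ybar).sum() / sw)
    q = ssw + float((n * (ybar - mu) ** 2 / d).sum())
    N = n.sum()
    return (N - 1) * np.log(q) + float(np.log(d).sum()) + np.log(sw), mu, q


def _profile_score(lam: float, ybar, n, ssw) -> float:
    """d/d(lambda) of the profiled restricted deviance (envelope theorem)."""
    d = 1.0 + n * lam
    w = n / d
    sw = w.sum()
    mu = float((w * ybar).sum() / sw)
    q = ssw + float((n * (ybar - mu) ** 2 / d).sum())
    N = n.sum()
    dq = -float((n**2 * (ybar - mu) ** 2 / d**2).sum())
    ds = -float((n**2 / d**2).sum())
    return (N - 1) * dq / q + sw + ds / sw


def _neg2relml(sb2: float, sw2: float, ybar, n, ssw) -> float:
    """Restricted deviance in the (sigma_b^2, sigma_w^2) parametrization."""
    N = n.sum()
    a = n.size
    v = sw2 + n * sb2
    w = n / v
    sw = w.sum()
    mu = float((w * ybar).sum() / sw)
    return (
        (N - a) * np.log(sw2)
        + float(np.log(v).sum())
        + np.log(sw)
        + ssw / sw2
        + float((n * (ybar - mu) ** 2 / v).sum())
    )


def _numeric_hessian(f, theta, rel_step=5e-3):
    """Central-difference Hessian with one Richardson extrapolation."""
    theta = np.asarray(theta, dtype=float)
    k = theta.size
    h = np.maximum(np.abs(theta), 1e-8) * rel_step

    def hess_at(hvec):
        H = np.empty((k, k))
        f0 = f(theta)
        for i in range(k):
            ei = np.zeros(k); ei[i] = hvec[i]
            H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / hvec[i] ** 2
        for i in range(k):
            for j in range(i + 1, k):
                ei = np.zeros(k); ei[i] = hvec[i]
                ej = np.zeros(k); ej[j] = hvec[j]
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * hvec[i] * hvec[j])
        return H

    H1 = hess_at(h)
    H2 = hess_at(h / 2)
    return (4 * H2 - H1) / 3


def reml_paired_test(differences: pd.DataFrame,
                     approach_pair: tuple[str, str] = ("A", "B"),
                     metric: str = "") -> ComparisonResult:
    """REML fit and Satterthwaite t-test of the mean log10 difference.

    ``differences`` must have columns ``chemical_id`` and ``diff``.
    When the between-chemical variance estimate hits the zero boundary
    the model collapses to an ordinary one-sample t-test on the pooled
    differences (reported with ``boundary=True`` and ``sigma_b2=0``).
    """
    ybar, n, ssw = _group_stats(differences)
    a, N = n.size, int(n.sum())
    if a < 2 or N < 3:
        raise InsufficientDataError(
            f"REML needs >= 2 chemicals and >= 3 observations (got {a}, {N})"
        )
    y = differences["diff"].to_numpy(float)
    if np.allclose(y.var(), 0.0, atol=1e-30):
        mu = float(y.mean())
        p = 1.0 if mu == 0 else 0.0
        return ComparisonResult(approach_pair, metric, mu, 10**mu, 0.0, 0.0,
                                float(N - 1), 0.0 if mu == 0 else np.inf,
                                p, N, a, "reml", boundary=True)

    # profile over the variance ratio; stationary point by root finding
    score0 = _profile_score(0.0, ybar, n, ssw)
    lam_hat = 0.0
    if score0 < 0:  # deviance decreasing at 0: interior optimum exists
        hi = 1.0
        for _ in range(200):
            if _profile_score(hi, ybar, n, ssw) > 0:
                break
            hi *= 4.0
        else:
            raise RuntimeError("REML variance-ratio search failed to bracket "
                               "a stationary point (iteration limit)")
        lam_hat = optimize.brentq(_profile_score, 0.0, hi,
                                  args=(ybar, n, ssw), xtol=1e-14, rtol=1e-15)
    boundary = lam_hat == 0.0
    _, mu_hat, q = _profile_neg2relml(lam_hat, ybar, n, ssw)
    sw2 = q / (N - 1)
    sb2 = lam_hat * sw2
    v = sw2 + n * sb2
    var_mu = 1.0 / float((n / v).sum())
    se = np.sqrt(var_mu)
    t_stat = mu_hat / se

    if boundary:
        df = float(N - 1)
    else:
        hess = _numeric_hessian(
            lambda th: _neg2relml(th[0], th[1], ybar, n, ssw),
            np.array([sb2, sw2]),
        )
        # asymptotic covariance of the variance components under REML
        try:
            cov = 2.0 * np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = None
        if cov is None or not np.all(np.isfinite(cov)):
            df = float(N - 1)
        else:
            # gradient of Var(mu_hat) wrt (sigma_b^2, sigma_w^2)
            grad = var_mu**2 * np.array(
                [float((n**2 / v**2).sum()), float((n / v**2).sum())]
            )
            denom = float(grad @ cov @ grad)
            df = 2.0 * var_mu**2 / denom if denom > 0 else float(N - 1)
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    return ComparisonResult(
        approach_pair=approach_pair, metric=metric,
        mu_hat=float(mu_hat), fold=float(10**mu_hat),
        sigma_b2=float(sb2), sigma_w2=float(sw2),
        df=float(df), statistic=float(t_stat), p_value=float(min(p, 1.0)),
        n_used=N, n_chemicals=a, method="reml", boundary=boundary,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank on per-chemical medians


def _hodges_lehmann(x: np.ndarray) -> float:
    """Median of Walsh averages (pseudo-median of a symmetric location)."""
    x = np.asarray(x, dtype=float)
    i, j = np.triu_indices(x.size)
    return float(np.median((x[i] + x[j]) / 2.0))


def wilcoxon_per_chemical(differences: pd.DataFrame,
                          approach_pair: tuple[str, str] = ("A", "B"),
                          metric: str = "") -> ComparisonResult:
    """Two-sided signed-rank test on per-chemical median differences.

    Zeros are dropped before ranking (the classical treatment).  The
    exact null distribution is used for n <= 25 without ties; otherwise
    the normal approximation with continuity correction.  The reported
    fold is ``10^(Hodges-Lehmann pseudo-median)`` of the chemical
    medians.
    """
    med = differences.groupby("chemical_id")["diff"].median()
    if len(med) < 2:
        raise InsufficientDataError("wilcoxon needs >= 2 chemicals")
    x = med.to_numpy(float)
    hl = _hodges_lehmann(x)
    nz = x[x != 0.0]
    if nz.size == 0:  # all medians zero: perfectly degenerate
        return ComparisonResult(approach_pair, metric, 0.0, 1.0,
                                np.nan, np.nan, np.nan, 0.0, 1.0,
                                len(med), len(med), "wilcoxon")
    ranks_tied = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not ranks_tied) else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", zero_method="wilcox",
                         correction=(method == "approx"), method=method)
    return ComparisonResult(
        approach_pair=approach_pair, metric=metric,
        mu_hat=hl, fold=float(10**hl),
        sigma_b2=np.nan, sigma_w2=np.nan, df=np.nan,
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n_used=int(nz.size), n_chemicals=len(med), method="wilcoxon",
    )


class PairedComparison:
    """Model object pairing two approaches' metric tables for comparison.

    Parameters
    ----------
    metrics_a, metrics_b : DataFrame
        Per-observation metric tables (see :func:`qnta.metrics.add_metrics`)
        for the reference and comparison approaches.
    metric : {"aaq", "clfr", "ucq", "lcq"}
    """

    def __init__(self, metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                 metric: str, approach_pair: tuple[str, str] | None = None):
        self.metric = metric.lower()
        if approach_pair is None:
            approach_pair = (
                str(metrics_a["approach"].iloc[0]) if "approach" in metrics_a else "A",
                str(metrics_b["approach"].iloc[0]) if "approach" in metrics_b else "B",
            )
        self.approach_pair = approach_pair
        self.differences = pair_observations(metrics_a, metrics_b, self.metric)

    def fit(self, method: Literal["reml", "wilcoxon"] = "reml") -> ComparisonResult:
        if method == "reml":
            return reml_paired_test(self.differences, self.approach_pair, self.metric)
        if method == "wilcoxon":
            return wilcoxon_per_chemical(self.differences, self.approach_pair, self.metric)
        raise ValueError(f"unknown method {method!r}")
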