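"""Accuracy, uncertainty, and reliability metrics for quantitation.

Every approach produces, per observation, a point estimate ``conc_hat``
with limits ``conc_lcl``/``conc_ucl`` and a known truth ``conc_true``.
From these:

* ``AQ  = conc_hat / conc_true`` — directional accuracy quotient;
* ``AAQ = 10^|log10(AQ)|``       — fold-error magnitude, always >= 1;
* ``CLFR = conc_ucl / conc_lcl`` — confidence limit fold range;
* ``UCQ = conc_ucl / conc_true`` and ``LCQ = conc_true / conc_lcl`` —
  fold distance of each limit from the truth; a value below 1 flags an
  interval miss on that side.

Reliability summarizes empirical coverage: URP = %(truth <= UCL),
LRP = %(truth >= LCL), ORP = %(LCL <= truth <= UCL); boundary equality
counts as contained.  AAQ works in base 10 (independent of the base-2
calibration axes) so fold errors read directly in decades.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .data import InsufficientDataError
from .calibration import ConcentrationEstimate

__all__ = [
    "MetricRecord",
    "ReliabilitySummary",
    "compute_metrics",
    "add_metrics",
    "reliability",
    "threshold_summary",
    "theoretical_clfr",
]

ESTIMATE_COLUMNS = ["conc_true", "conc_hat", "conc_lcl", "conc_ucl"]


@dataclass(frozen=True)
class MetricRecord:
    """Per-observation metric values tied to one estimate."""

    chemical_id: str
    approach: str
    level_index: int
    replicate_index: int
    conc_true: float
    aq: float
    aaq: float
    clfr: float
    ucq: float
    lcq: float
    are: float  # legacy absolute relative error (%), reported but not used downstream
    extrapolation_flag: bool = False


@dataclass(frozen=True)
class ReliabilitySummary:
    approach: str
    urp: float  # percent
    lrp: float
    orp: float
    n: int


def compute_metrics(estimate: ConcentrationEstimate, conc_true: float,
                    chemical_id: str = "", level_index: int = 0,
                    replicate_index: int = 0,
                    extrapolation_flag: bool = False) -> MetricRecord:
    """Metrics for a single (estimate, truth) pair."""
    if conc_true <= 0:
        raise ValueError("conc_true must be > 0")
    aq = estimate.conc_hat / conc_true
    return MetricRecord(
        chemical_id=chemical_id,
        approach=estimate.source,
        level_index=level_index,
        replicate_index=replicate_index,
        conc_true=conc_true,
        aq=aq,
        aaq=10 ** abs(np.log10(aq)),
        clfr=estimate.conc_ucl / estimate.conc_lcl,
        ucq=estimate.conc_ucl / conc_true,
        lcq=conc_true / estimate.conc_lcl,
        are=abs(estimate.conc_hat - conc_true) / conc_true * 100,
        extrapolation_flag=extrapolation_flag,
    )


def add_metrics(estimates: pd.DataFrame) -> pd.DataFrame:
    """Vectorized metrics over a per-observation estimates table.

    Expects columns ``chemical_id, approach, level_index,
    replicate_index`` plus the estimate triple and ``conc_true``.
    """
    for col in ESTIMATE_COLUMNS:
        if col not in estimates.columns:
            raise KeyError(f"estimates table missing column {col!r}")
    df = estimates.copy()
    aq = df["conc_hat"] / df["conc_true"]
    df["aq"] = aq
    df["aaq"] = 10 ** np.abs(np.log10(aq))
    df["clfr"] = df["conc_ucl"] / df["conc_lcl"]
    df["ucq"] = df["conc_ucl"] / df["conc_true"]
    df["lcq"] = df["conc_true"] / df["conc_lcl"]
    df["are"] = np.abs(df["conc_hat"] - df["conc_true"]) / df["conc_true"] * 100
    return df


def reliability(estimates: pd.DataFrame, approach: str | None = None) -> ReliabilitySummary:
    """Empirical coverage percentages over an estimates table."""
    df = estimates
    if approach is not None and "approach" in df.columns:
        df = df[df["approach"] == approach]
    n = len(df)
    if n == 0:
        raise InsufficientDataError("reliability: no records")
    truth = df["conc_true"].to_numpy(float)
    ucl = df["conc_ucl"].to_numpy(float)
    lcl = df["conc_lcl"].to_numpy(float)
    upper = truth <= ucl
    lower = truth >= lcl
    return ReliabilitySummary(
        approach=approach or (df["approach"].iloc[0] if "approach" in df.columns else ""),
        urp=100.0 * upper.mean(),
        lrp=100.0 * lower.mean(),
        orp=100.0 * (upper & lower).mean(),
        n=n,
    )


def theoretical_clfr(cv: float, n_replicates: int,
                     confidence_level: float = 0.95) -> float:
    """Fold range of a t-based CI for the mean of replicate measures.

    For ``n_replicates`` measurements with relative standard deviation
    ``cv``, the two-sided CI for the mean has half-width (relative to the
    mean) ``t[n-1, 1-alpha/2] * cv / sqrt(n)``; the implied UCL/LCL fold
    range is ``(1 + h) / (1 - h)``.  This reconstructs the conventional
    targeted-analysis benchmark (2.19 at cv = 0.30, n = 5, 95%).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_replicates < 2:
        raise InsufficientDataError("n_replicates must be >= 2")
    t = stats.t.ppf(0.5 + confidence_level / 2, n_replicates - 1)
    h = t * cv / np.sqrt(n_replicates)
    if h >= 1:
        raise ValueError(
            f"t-based half-width {h:.3g} >= 1: fold range undefined"
        )
    return float((1 + h) / (1 - h))


def threshold_summary(
    metrics: pd.DataFrame,
    rel_error: float = 0.30,
    clfr_threshold: float | None = None,
    ucq_threshold: float = 10.0,
) -> pd.DataFrame:
    """Per-approach acceptance-threshold summary.

    Reports, per approach: percent of AQ within ``[1 - rel_error,
    1 + rel_error]`` (the targeted-method acceptance band, 0.700-1.30 at
    the default 30% relative error), percent of CLFR at or under the
    threshold (default: the theoretical fold range at cv = 0.30, n = 5),
    percent of UCQ at or under ``ucq_threshold``, and medians / 95th
    percentiles of AAQ, CLFR and UCQ (linear-interpolation quantiles).
    """
    if metrics.empty:
        raise InsufficientDataError("threshold_summary: no records")
    if clfr_threshold is None:
        clfr_threshold = theoretical_clfr(0.30, 5, 0.95)
    lo, hi = 1.0 - rel_error, 1.0 + rel_error
    rows = []
    for approach, g in metrics.groupby("approach", sort=True):
        rows.append(
            {
                "approach": approach,
                "n": len(g),
                "aq_lower_bound": lo,
                "aq_upper_bound": hi,
                "pct_aq_within": 100.0 * g["aq"].between(lo, hi).mean(),
                "clfr_threshold": clfr_threshold,
                "pct_clfr_within": 100.0 * (g["clfr"] <= clfr_threshold).mean(),
                "ucq_threshold": ucq_threshold,
                "pct_ucq_within": 100.0 * (g["ucq"] <= ucq_threshold).mean(),
                "median_aaq": float(g["aaq"].quantile(0.5)),
                "p95_aaq": float(g["aaq"].quantile(0.95)),
                "median_clfr": float(g["clfr"].quantile(0.5)),
                "p95_clfr": float(g["clfr"].quantile(0.95)),
                "median_ucq": float(g["ucq"].quantile(0.5)),
                "p95_ucq": float(g["ucq"].quantile(0.95)),
            }
        )
    return pd.DataFrame(rows)
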