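"""Chemical-specific log-log calibration curves with inverse estimation.

Abundance and concentration are both log2-transformed (base 2 matches a
twofold dilution series, so calibration points are evenly spaced on the x
axis) and an ordinary least-squares line is fitted per chemical.  Reading
a concentration off the curve at an observed abundance ("inverse
estimation") yields a point estimate; its confidence limits are the x
values where the two-sided prediction band for a single future
observation crosses the observed log2 abundance.

Three estimation approaches share this machinery and differ only in the
abundance column they consume:

* A1 - internal-standard normalized abundance (targeted workflow),
* A2 - raw abundance (targeted workflow),
* A3 - raw abundance (non-targeted workflow).

The prediction band for a single future observation at ``x`` has
half-width ``t[n-2, 1-alpha/2] * s * sqrt(1 + 1/n + (x - xbar)^2 / Sxx)``
with ``s`` the residual standard deviation on ``n - 2`` degrees of
freedom.  Mean-response bands would be narrower; the single-observation
band is the appropriate one for predicting a new injection and is the
convention adopted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import Dataset, InsufficientDataError

__all__ = [
    "CalibrationModel",
    "CalibrationResults",
    "ConcentrationEstimate",
    "DegenerateDesignError",
    "UnboundedIntervalError",
    "fit_calibration",
    "inverse_estimate",
    "loo_cv",
    "qc_summary",
    "run_calibration_approach",
    "ABUNDANCE_FIELD",
]

#: abundance column consumed by each calibration approach
ABUNDANCE_FIELD = {
    "A1": "normalized_abundance",
    "A2": "abundance",
    "A3": "abundance",
}


class DegenerateDesignError(ValueError):
    """All concentrations identical: the slope is not estimable."""


class UnboundedIntervalError(ValueError):
    """The prediction band never crosses the observed abundance."""

    def __init__(self, which: str, message: str = ""):
        self.which = which  # "lower" or "upper"
        super().__init__(message or f"{which} inverse limit is unbounded")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """A point concentration estimate with confidence limits (ng/mL)."""

    conc_hat: float
    conc_lcl: float
    conc_ucl: float
    confidence_level: float = 0.95
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.conc_lcl <= self.conc_hat <= self.conc_ucl):
            raise ValueError(
                f"limits out of order: {self.conc_lcl}, {self.conc_hat}, "
                f"{self.conc_ucl}"
            )


class CalibrationModel:
    """Simple linear regression of log2 abundance on log2 concentration.

    Parameters
    ----------
    concentration, abundance : array-like
        Positive values on the original (ng/mL, ion count) scales; the
        model log2-transforms internally.
    chemical_id, approach : str
        Labels carried through to the results object.
    """

    def __init__(self, concentration, abundance, chemical_id: str = "",
                 approach: str = ""):
        conc = np.asarray(concentration, dtype=float)
        abun = np.asarray(abundance, dtype=float)
        if conc.shape != abun.shape or conc.ndim != 1:
            raise ValueError("concentration and abundance must be 1-d and equal length")
        if np.any(conc <= 0) or np.any(abun <= 0) or np.any(~np.isfinite(conc)) \
                or np.any(~np.isfinite(abun)):
            raise ValueError("all concentrations and abundances must be positive and finite")
        if conc.size < 3:
            raise InsufficientDataError(
                f"{chemical_id}: need >= 3 calibration points, got {conc.size}"
            )
        if np.unique(conc).size < 2:
            raise DegenerateDesignError(
                f"{chemical_id}: all concentrations identical"
            )
        self.x = np.log2(conc)
        self.y = np.log2(abun)
        self.chemical_id = chemical_id
        self.approach = approach

    @classmethod
    def from_dataset(cls, dataset: Dataset, chemical_id: str,
                     approach: str = "A2") -> "CalibrationModel":
        obs = dataset.observations_for(chemical_id)
        col = ABUNDANCE_FIELD[approach]
        sub = obs.dropna(subset=[col])
        return cls(sub["true_concentration"], sub[col],
                   chemical_id=chemical_id, approach=approach)

    def fit(self) -> "CalibrationResults":
        x, y = self.x, self.y
        n = x.size
        x_mean = x.mean()
        y_mean = y.mean()
        sxx = float(np.sum((x - x_mean) ** 2))
        sxy = float(np.sum((x - x_mean) * (y - y_mean)))
        slope = sxy / sxx
        intercept = y_mean - slope * x_mean
        resid = y - (intercept + slope * x)
        sse = float(np.sum(resid**2))
        sst = float(np.sum((y - y_mean) ** 2))
        # convention: R^2 = 0 when the response is constant (SST = 0)
        r_squared = 0.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
        residual_sd = float(np.sqrt(max(sse, 0.0) / (n - 2)))
        return CalibrationResults(
            model=self,
            slope=slope,
            intercept=intercept,
            r_squared=r_squared,
            residual_sd=residual_sd,
            n_points=n,
            x_mean=float(x_mean),
            sxx=sxx,
        )


@dataclass
class CalibrationResults:
    """Fitted log2-log2 calibration line and its sufficient statistics."""

    model: CalibrationModel | None
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n_points: int
    x_mean: float
    sxx: float
    log_base: int = 2

    @property
    def chemical_id(self) -> str:
        return self.model.chemical_id if self.model is not None else ""

    @property
    def approach(self) -> str:
        return self.model.approach if self.model is not None else ""

    @property
    def df_resid(self) -> int:
        return self.n_points - 2

    def predict(self, x):
        """Fitted log2 abundance at log2 concentration ``x``."""
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def band_halfwidth(self, x, confidence_level: float = 0.95):
        """Half-width of the single-future-observation prediction band."""
        x = np.asarray(x, dtype=float)
        t = stats.t.ppf(0.5 + confidence_level / 2, self.df_resid)
        return t * self.residual_sd * np.sqrt(
            1 + 1 / self.n_points + (x - self.x_mean) ** 2 / self.sxx
        )

    @property
    def x_range(self) -> tuple[float, float]:
        x = self.model.x
        return float(x.min()), float(x.max())

    def inverse_estimate(self, abundance: float,
                         confidence_level: float = 0.95) -> ConcentrationEstimate:
        """Concentration (with limits) at an observed raw-scale abundance.

        The point estimate inverts the fitted line; the limits invert the
        prediction band exactly by solving the band equation's quadratic
        in x, with a bisection fallback when the quadratic is numerically
        unstable.  Raises :class:`UnboundedIntervalError` when the band
        never crosses the observed abundance (shallow slope relative to
        the residual noise).
        """
        if abundance <= 0:
            raise ValueError("abundance must be > 0")
        if self.slope == 0:
            raise ZeroDivisionError("zero slope: inverse estimate undefined")
        y0 = float(np.log2(abundance))
        x_hat = (y0 - self.intercept) / self.slope
        if self.residual_sd == 0.0:
            c = 2.0**x_hat
            return ConcentrationEstimate(c, c, c, confidence_level, self.approach)

        a = self.slope
        t = stats.t.ppf(0.5 + confidence_level / 2, self.df_resid)
        c2 = (t * self.residual_sd) ** 2
        # (d - a u)^2 = c2 (1 + 1/n + u^2/Sxx),  u = x - xbar
        d = y0 - self.predict(self.x_mean)
        qa = a * a - c2 / self.sxx
        qb = -2.0 * a * d
        qc = d * d - c2 * (1 + 1 / self.n_points)
        disc = qb * qb - 4 * qa * qc
        roots = None
        if qa > 0 and disc >= 0:
            sq = np.sqrt(disc)
            roots = sorted(((-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)))
        if roots is None:
            roots = self._bisect_roots(y0, confidence_level, x_hat)
        u_lo, u_hi = roots
        x_lo, x_hi = u_lo + self.x_mean, u_hi + self.x_mean
        # guard against a root bracketing failure leaving limits inverted
        if not (x_lo <= x_hat <= x_hi):
            x_lo, x_hi = min(x_lo, x_hat), max(x_hi, x_hat)
        return ConcentrationEstimate(
            conc_hat=float(2.0**x_hat),
            conc_lcl=float(2.0**x_lo),
            conc_ucl=float(2.0**x_hi),
            confidence_level=confidence_level,
            source=self.approach,
        )

    def _bisect_roots(self, y0: float, confidence_level: float,
                      x_hat: float) -> tuple[float, float]:
        """Numeric fallback: bisection on the band-crossing equations.

        For the upper limit, find x > x_hat where the lower band equals
        y0 (slope > 0); symmetric for the lower limit.
        """
        sgn = 1.0 if self.slope > 0 else -1.0

        def upper_gap(x):  # >0 once the lower band exceeds y0
            return sgn * (self.predict(x) - self.band_halfwidth(x, confidence_level) - y0)

        def lower_gap(x):  # >0 once y0 exceeds the upper band
            return sgn * (y0 - self.predict(x) - self.band_halfwidth(x, confidence_level))

        span = max(1.0, (self.x_range[1] - self.x_range[0]))
        out = []
        for gap, direction, which in ((lower_gap, -1.0, "lower"), (upper_gap, 1.0, "upper")):
            step = span
            lo = x_hat
            hi = None
            for _ in range(60):  # widened geometric search bracket
                cand = x_hat + direction * step * sgn
                if gap(cand) > 0:
                    hi = cand
                    break
                step *= 2.0
            if hi is None:
                raise UnboundedIntervalError(which)
            root = optimize.brentq(gap, *sorted((lo, hi)), xtol=1e-13, rtol=1e-14)
            out.append(root - self.x_mean)
        return tuple(sorted(out))

    def summary(self) -> str:
        lines = [
            "Calibration fit (log2 abundance ~ log2 concentration)",
            f"  chemical:      {self.chemical_id or '<unnamed>'}",
            f"  approach:      {self.approach or '<none>'}",
            f"  n points:      {self.n_points}",
            f"  slope:         {self.slope:.6g}",
            f"  intercept:     {self.intercept:.6g}",
            f"  R-squared:     {self.r_squared:.6g}",
            f"  residual SD:   {self.residual_sd:.6g} (log2 units, df={self.df_resid})",
        ]
        return "\n".join(lines)


def fit_calibration(concentration, abundance, chemical_id: str = "",
                    approach: str = "") -> CalibrationResults:
    """Functional form of ``CalibrationModel(...).fit()``."""
    return CalibrationModel(concentration, abundance, chemical_id, approach).fit()


def inverse_estimate(fit: CalibrationResults, abundance: float,
                     confidence_level: float = 0.95) -> ConcentrationEstimate:
    return fit.inverse_estimate(abundance, confidence_level)


def loo_cv(concentration, abundance, confidence_level: float = 0.95,
           chemical_id: str = "", approach: str = "") -> pd.DataFrame:
    """Leave-one-out cross-validated inverse estimates.

    Each observation is held out in turn; the curve is refitted on the
    rest and the held-out abundance inverse-estimated.  Folds that become
    degenerate (all remaining concentrations identical) are skipped with
    a logged reason, never silently.  Returns one row per retained fold:
    index of the held-out point, its true concentration, the estimate
    triple, and an extrapolation flag (held-out abundance maps outside
    the training concentration range).
    """
    from .data import logger

    conc = np.asarray(concentration, dtype=float)
    abun = np.asarray(abundance, dtype=float)
    n = conc.size
    if n < 4:
        raise InsufficientDataError(
            f"{chemical_id}: LOO-CV needs >= 4 observations, got {n}"
        )
    rows = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            fit = fit_calibration(conc[mask], abun[mask], chemical_id, approach)
            est = fit.inverse_estimate(abun[i], confidence_level)
        except (DegenerateDesignError, InsufficientDataError,
                UnboundedIntervalError) as exc:
            logger.warning("loo_cv %s: fold %d skipped (%s)", chemical_id, i, exc)
            continue
        x_hat = np.log2(est.conc_hat)
        lo, hi = fit.x_range
        rows.append(
            {
                "obs_index": i,
                "chemical_id": chemical_id,
                "approach": approach,
                "conc_true": conc[i],
                "conc_hat": est.conc_hat,
                "conc_lcl": est.conc_lcl,
                "conc_ucl": est.conc_ucl,
                "confidence_level": confidence_level,
                "extrapolated": bool(x_hat < lo or x_hat > hi),
            }
        )
    return pd.DataFrame(rows)


def qc_summary(fits: Iterable[CalibrationResults]) -> dict:
    """Per-fit slope/R^2 table plus a one-sample t-test of slopes vs 1.

    A mean slope statistically indistinguishable from unity indicates
    response factors stable across the concentration range; departures
    suggest saturation, censoring near the detection limit, or other
    non-linearity.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise InsufficientDataError("qc_summary needs >= 2 fits")
    table = pd.DataFrame(
        {
            "chemical_id": [f.chemical_id for f in fits],
            "approach": [f.approach for f in fits],
            "slope": [f.slope for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "n_points": [f.n_points for f in fits],
        }
    )
    slopes = table["slope"].to_numpy()
    mean_slope = float(slopes.mean())
    if np.allclose(slopes, slopes[0]):
        t_stat, p_value = float("nan"), float("nan")
        note = "slope variance is zero: t statistic undefined"
    else:
        t_stat, p_value = stats.ttest_1samp(slopes, popmean=1.0)
        t_stat, p_value = float(t_stat), float(p_value)
        note = ""
    return {
        "table": table,
        "mean_slope": mean_slope,
        "mean_r_squared": float(table["r_squared"].mean()),
        "t_statistic": t_stat,
        "p_value": p_value,
        "df": len(fits) - 1,
        "note": note,
    }


def run_calibration_approach(
    dataset: Dataset,
    approach: Literal["A1", "A2", "A3"],
    confidence_level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every chemical's curve and LOO-CV it under one approach.

    A1 uses internal-standard normalized abundance (chemicals lacking an
    ``is_abundance`` are excluded, with a logged count); A2/A3 use raw
    abundance.  Returns ``(fits, estimates)`` DataFrames; ``estimates``
    has one row per retained LOO fold with level/replicate bookkeeping.
    """
    from .data import logger

    col = ABUNDANCE_FIELD[approach]
    fits_rows = []
    est_frames = []
    skipped = []
    for chem_id in dataset.chemical_ids:
        obs = dataset.observations_for(chem_id).dropna(subset=[col])
        if len(obs) < 4:
            skipped.append(chem_id)
            continue
        fit = fit_calibration(obs["true_concentration"], obs[col], chem_id, approach)
        fits_rows.append(
            {
                "chemical_id": chem_id,
                "approach": approach,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "residual_sd": fit.residual_sd,
                "n_points": fit.n_points,
                "x_mean": fit.x_mean,
                "sxx": fit.sxx,
            }
        )
        est = loo_cv(obs["true_concentration"], obs[col], confidence_level,
                     chem_id, approach)
        est = est.merge(
            obs.reset_index(drop=True)[["level_index", "replicate_index"]]
            .reset_index(names="obs_index"),
            on="obs_index",
        )
        est_frames.append(est)
    if skipped:
        logger.info(
            "%s: %d chemical(s) excluded (insufficient %s data): %s",
            approach, len(skipped), col, skipped,
        )
    if not fits_rows:
        raise InsufficientDataError(f"{approach}: no chemical has enough data")
    fits = pd.DataFrame(fits_rows)
    estimates = pd.concat(est_frames, ignore_index=True)
    return fits, estimates
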