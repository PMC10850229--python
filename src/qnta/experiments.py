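"""Simulation experiments validating interval reliability end-to-end.

The central question for any interval-producing quantitation approach is
empirical coverage: how often the stated 95% limits actually contain the
true concentration.  :func:`loo_coverage_experiment` measures this on
synthetic panels whose analytes are exchangeable with one another — each
chemical is estimated leaving itself out, so the surrogate population
never contains the analyte's own data — for both interval families the
workflow produces:

* global-surrogate bounded-RF bootstrap intervals (the qNTA estimator),
* per-chemical calibration-curve LOO-CV inverse-prediction intervals.
"""

from __future__ import annotations

import numpy as np

from .calibration import run_calibration_approach
from .metrics import add_metrics, reliability
from .rfboot import run_qnta_approach
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["loo_coverage_experiment"]


def loo_coverage_experiment(
    n_repeats: int = 50,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    config: SyntheticConfig | None = None,
) -> dict:
    """Aggregate empirical coverage over repeated synthetic experiments.

    Each repeat draws a fresh panel from ``config`` (defaults: 26
    chemicals x 9 levels x 3 replicates), runs the global-surrogate
    bootstrap (leave-one-out by construction) and the raw-abundance
    calibration LOO-CV, and tallies how many true concentrations fall
    inside the respective 95% intervals.

    Returns a dict with per-family overall reliability percentages
    (``orp_bootstrap``, ``orp_calibration``), the pooled percentage over
    both families (``orp_pooled``), upper/lower percentages, and counts.
    """
    if config is None:
        config = SyntheticConfig()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    tallies = {"boot": [0, 0, 0, 0], "cal": [0, 0, 0, 0]}  # inside, upper, lower, n
    for rep_seed in child_seeds:
        ds = generate_dataset(config, seed=int(rep_seed))
        boot = run_qnta_approach(ds, "A5", n_boot=n_boot, alpha=alpha,
                                 seed=int(rep_seed))
        _, cal = run_calibration_approach(ds, "A3", confidence_level=1 - alpha)
        for key, est in (("boot", boot.estimates), ("cal", cal)):
            rel = reliability(est)
            t = tallies[key]
            t[0] += rel.orp * rel.n / 100.0
            t[1] += rel.urp * rel.n / 100.0
            t[2] += rel.lrp * rel.n / 100.0
            t[3] += rel.n
    nb, nc = tallies["boot"][3], tallies["cal"][3]
    out = {
        "orp_bootstrap": 100.0 * tallies["boot"][0] / nb,
        "urp_bootstrap": 100.0 * tallies["boot"][1] / nb,
        "lrp_bootstrap": 100.0 * tallies["boot"][2] / nb,
        "n_bootstrap": int(nb),
        "orp_calibration": 100.0 * tallies["cal"][0] / nc,
        "urp_calibration": 100.0 * tallies["cal"][1] / nc,
        "lrp_calibration": 100.0 * tallies["cal"][2] / nc,
        "n_calibration": int(nc),
        "orp_pooled": 100.0 * (tallies["boot"][0] + tallies["cal"][0]) / (nb + nc),
        "n_pooled": int(nb + nc),
        "n_repeats": n_repeats,
        "n_boot": n_boot,
        "alpha": alpha,
        "seed": seed,
    }
    return out
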