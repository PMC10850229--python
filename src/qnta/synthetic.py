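"""Synthetic calibration datasets with realistic PFAS-like RF structure.

The generator emulates the statistical features that drive every stage
of the quantitation workflow: a 26-chemical panel measured on a
nine-point ~twofold dilution series (0.98-250 ng/mL) with three
replicate injections; per-chemical response factors (RFs) approximately
log-normal, with chemical medians spanning a ~5000-fold range
(log-uniform) and modest within-chemical spread; and an internal
standard co-spiked at 50 ng/mL whose abundance shares the injection's
run-level error with the analyte, so that normalization cancels most of
the raw variability.

Error mechanism per injection of one chemical::

    abundance     = RF_med * conc * exp(e_drift + e_shared + e_analyte)
    is_abundance  = IS_RF * 50    * exp(e_drift + e_shared + e_is)

``e_drift`` (latent RF drift, sd ln(intra_fold)/6) and ``e_shared``
(measurement error common to analyte and IS) are cancelled by
normalization; the tiny independent ``e_analyte``/``e_is`` terms leave
the normalized abundance with residual CV ``is_noise_cv``.  The raw
abundance carries the full error, with ``raw_noise_cv`` setting the
measurement-noise share.  This sharing is exactly the mechanism that
makes the IS-normalized approach outperform raw-abundance approaches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .data import Dataset, logger

__all__ = ["SyntheticConfig", "generate_rf_space", "generate_dataset",
           "add_outlier_chemical", "DEFAULT_LEVELS"]

#: nine-point twofold series from 0.98 (=250/2^8) to 250 ng/mL
DEFAULT_LEVELS = tuple(float(250.0 / 2**k) for k in range(8, -1, -1))

DEFAULT_GROUP_MIX = {
    "carboxylic_acid": 0.42,
    "sulfonic_acid": 0.27,
    "sulfonamide": 0.12,
    "fluorotelomer_sulfonate": 0.08,
    "fluoroether": 0.11,
}

_CHAIN_RANGE = {
    "carboxylic_acid": (4, 14),
    "sulfonic_acid": (4, 10),
    "sulfonamide": (8, 10),
    "fluorotelomer_sulfonate": (4, 8),
    "fluoroether": (4, 8),
}


def _cv_to_sigma(cv: float) -> float:
    """ln-scale SD of a log-normal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic experiment; defaults mirror the study design."""

    n_chemicals: int = 26
    levels: tuple[float, ...] = DEFAULT_LEVELS
    replicates: int = 3
    inter_chemical_fold_span: float = 5000.0  # span of median RFs (log-uniform)
    rf_log10_floor: float = 4.3               # log10 of the lowest median RF
    intra_chemical_rf_fold_range: float = 4.0  # central 99.7% range of RF drift
    is_noise_cv: float = 0.05   # residual CV after IS normalization
    raw_noise_cv: float = 0.20  # measurement CV of raw abundance
    rolloff_strength: float = 0.0  # high-concentration RF attenuation in [0, 1]
    rt_range: tuple[float, float] = (2.0, 18.0)  # minutes
    group_mix: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_MIX))
    rf_rt_association: bool = False
    is_coverage: float = 1.0  # fraction of chemicals with a matched IS
    is_concentration: float = 50.0  # ng/mL spike of each internal standard
    min_top_abundance: float | None = None  # optional low-responder filter
    seed: int = 0

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if np.any(lv <= 0) or np.any(np.diff(lv) <= 0):
            raise ValueError("levels must be strictly increasing and positive")
        if min(self.is_noise_cv, self.raw_noise_cv) < 0:
            raise ValueError("noise CVs must be >= 0")
        if not 0 <= self.rolloff_strength <= 1:
            raise ValueError("rolloff_strength must be in [0, 1]")
        if self.intra_chemical_rf_fold_range < 1:
            raise ValueError("intra_chemical_rf_fold_range must be >= 1")


def _assign_groups(config: SyntheticConfig) -> list[str]:
    """Largest-remainder apportionment of the ionizing-group mix."""
    items = [(g, p) for g, p in config.group_mix.items() if p > 0]
    total = sum(p for _, p in items)
    raw = [(g, config.n_chemicals * p / total) for g, p in items]
    counts = {g: int(np.floor(x)) for g, x in raw}
    short = config.n_chemicals - sum(counts.values())
    for g, _ in sorted(raw, key=lambda t: t[1] - np.floor(t[1]), reverse=True)[:short]:
        counts[g] += 1
    out: list[str] = []
    for g, c in counts.items():
        out.extend([g] * c)
    return out


def generate_rf_space(config: SyntheticConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-chemical RF distribution parameters and chemical attributes.

    Median RFs are drawn log-uniformly across the configured fold span;
    the within-chemical log-normal scale is calibrated so the central
    99.7% range of the latent RF drift equals the configured fold range.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_chemicals
    span = np.log10(config.inter_chemical_fold_span)
    log10_med = config.rf_log10_floor + rng.uniform(0.0, span, n)
    sigma_drift = np.log(config.intra_chemical_rf_fold_range) / 6.0
    groups = _assign_groups(config)
    rng.shuffle(groups)
    chains = [int(rng.integers(*_CHAIN_RANGE[g])) for g in groups]
    rt = rng.uniform(*config.rt_range, n)
    if config.rf_rt_association:
        # low-RF chemicals elute early: order RTs by RF rank, keep jitter
        rt = np.sort(rt)[np.argsort(np.argsort(log10_med))]
    has_is = rng.random(n) < config.is_coverage
    is_rf = 10 ** (config.rf_log10_floor + rng.uniform(0.0, span, n))
    ids = [f"SYN{i:03d}" for i in range(1, n + 1)]
    return pd.DataFrame(
        {
            "chemical_id": ids,
            "name": [f"synthetic PFAS {i}" for i in range(1, n + 1)],
            "retention_time": rt,
            "ionizing_group": groups,
            "chain_length": chains,
            "internal_standard_id": [f"L-{cid}" if h else None
                                     for cid, h in zip(ids, has_is)],
            "rf_median": 10**log10_med,
            "sigma_drift": sigma_drift,
            "is_rf": is_rf,
        }
    )


def _simulate_observations(chem: pd.DataFrame, config: SyntheticConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    levels = np.asarray(config.levels, dtype=float)
    n_lvl, n_rep = levels.size, config.replicates
    conc_max = levels.max()
    sigma_norm = _cv_to_sigma(config.is_noise_cv)
    sigma_raw = _cv_to_sigma(config.raw_noise_cv)
    s_na = sigma_norm / np.sqrt(2.0)  # analyte-specific residual
    s_ni = sigma_norm / np.sqrt(2.0)  # IS-specific residual
    s_shared = float(np.sqrt(max(sigma_raw**2 - s_na**2, 0.0)))
    rows = []
    for row in chem.itertuples(index=False):
        shape = (n_lvl, n_rep)
        e_drift = rng.normal(0.0, row.sigma_drift, shape)
        e_shared = rng.normal(0.0, s_shared, shape)
        e_a = rng.normal(0.0, s_na, shape)
        e_i = rng.normal(0.0, s_ni, shape)
        atten = 1.0 - config.rolloff_strength * (levels / conc_max)
        abun = (row.rf_median * levels[:, None] * atten[:, None]
                * np.exp(e_drift + e_shared + e_a))
        has_is = isinstance(row.internal_standard_id, str)
        is_abun = (row.is_rf * config.is_concentration
                   * np.exp(e_drift + e_shared + e_i)) if has_is else None
        for li in range(n_lvl):
            for ri in range(n_rep):
                rows.append(
                    {
                        "chemical_id": row.chemical_id,
                        "level_index": li + 1,
                        "true_concentration": levels[li],
                        "replicate_index": ri + 1,
                        "abundance": abun[li, ri],
                        "is_abundance": is_abun[li, ri] if has_is else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def generate_dataset(config: SyntheticConfig,
                     seed: int | None = None) -> Dataset:
    """Simulate a full calibration experiment.

    Every chemical receives ``len(levels) * replicates`` observations
    (26 x 9 x 3 = 702 rows under the defaults).  With all noise terms at
    zero, abundance is exactly ``rf_median * concentration``.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    chem = generate_rf_space(config, rng)
    obs = _simulate_observations(chem, config, rng)
    if config.min_top_abundance is not None:
        top = obs.groupby("chemical_id")["abundance"].max()
        drop = set(top[top < config.min_top_abundance].index)
        if drop:
            logger.info("synthetic: dropped %d low-responding chemical(s): %s",
                        len(drop), sorted(drop))
            chem = chem[~chem["chemical_id"].isin(drop)].reset_index(drop=True)
            obs = obs[~obs["chemical_id"].isin(drop)].reset_index(drop=True)
    # rf_median is kept as a provenance column (the configured truth)
    return Dataset(
        chemicals=chem.drop(columns=["sigma_drift", "is_rf"]),
        observations=obs,
        label=f"synthetic(seed={config.seed})",
    )


def add_outlier_chemical(dataset: Dataset, config: SyntheticConfig,
                         mode: Literal["high_rf", "low_rf"],
                         factor: float = 50.0,
                         seed: int | None = None) -> Dataset:
    """Append one chemical whose median RF sits outside the population span.

    ``factor`` multiplies (high_rf) or divides (low_rf) the population
    edge, reproducing the reliability failures seen for analytes with
    little RF-distribution overlap with the rest of the panel.
    """
    if mode not in ("high_rf", "low_rf"):
        raise ValueError(f"unknown outlier mode {mode!r}")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    floor = 10.0**config.rf_log10_floor
    ceil = floor * config.inter_chemical_fold_span
    rf_med = ceil * factor if mode == "high_rf" else floor / factor
    cid = "SYN-OUT"
    outlier = pd.DataFrame(
        {
            "chemical_id": [cid],
            "name": [f"synthetic outlier ({mode})"],
            "retention_time": [rng.uniform(*config.rt_range)],
            "ionizing_group": ["other"],
            "chain_length": [int(rng.integers(4, 15))],
            "internal_standard_id": [f"L-{cid}"],
            "rf_median": [rf_med],
            "sigma_drift": [np.log(config.intra_chemical_rf_fold_range) / 6.0],
            "is_rf": [10 ** (config.rf_log10_floor + rng.uniform(
                0.0, np.log10(config.inter_chemical_fold_span)))],
        }
    )
    obs = _simulate_observations(outlier, config, rng)
    chemicals = pd.concat(
        [dataset.chemicals,
         outlier.drop(columns=["sigma_drift", "is_rf"])],
        ignore_index=True,
    )
    observations = pd.concat([dataset.observations, obs], ignore_index=True)
    return Dataset(chemicals=chemicals, observations=observations,
                   label=dataset.label + f"+outlier({mode})")
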