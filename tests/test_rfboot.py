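import itertools

import numpy as np
import pandas as pd
import pytest

from qnta import (
    BoundedRFModel,
    bootstrap_rf_percentiles,
    compute_rf_table,
    estimate_concentration_qnta,
    run_qnta_approach,
    select_expert_surrogates,
    select_global_surrogates,
)
from qnta.data import ChemicalRecord, InsufficientDataError, ReferentialError
from qnta.rfboot import RFPercentiles


def _records(df):
    from qnta import Dataset

    return Dataset(
        chemicals=df, observations=pd.DataFrame(
            {
                "chemical_id": df["chemical_id"],
                "level_index": 1,
                "true_concentration": 1.0,
                "replicate_index": 1,
                "abundance": 1.0,
                "is_abundance": np.nan,
            }
        )
    ).chemical_records()


class TestRfTable:
    def test_quotient_and_cardinality(self, synthetic_dataset):
        rf = compute_rf_table(synthetic_dataset)
        obs = synthetic_dataset.observations
        assert len(rf) == len(obs)
        np.testing.assert_allclose(
            rf["rf"], obs["abundance"] / obs["true_concentration"], rtol=1e-12
        )

    def test_scaling_abundance_scales_rf(self, synthetic_dataset):
        ds = synthetic_dataset
        scaled = ds.observations.copy()
        scaled["abundance"] *= 3.5
        from qnta import Dataset

        ds2 = Dataset(chemicals=ds.chemicals.copy(), observations=scaled)
        np.testing.assert_allclose(
            compute_rf_table(ds2)["rf"], 3.5 * compute_rf_table(ds)["rf"], rtol=1e-12
        )


class TestSurrogateSelection:
    def test_expert_prefers_same_group_nearest_rt(self, toy_chemicals):
        recs = {r.chemical_id: r for r in _records(toy_chemicals)}
        pool = list(recs.values())
        # target carboxylic RT 5.0; carboxylics at 4.8/5.1/6.0 beat the
        # sulfonate at 4.9 despite its closer RT
        chosen = select_expert_surrogates(recs["TARGET"], pool, k=3)
        assert set(chosen) == {"PFCA-1", "PFCA-2", "PFCA-3"}

    def test_chain_length_fallback_fills_missing_slots(self, toy_chemicals):
        df = toy_chemicals[toy_chemicals["chemical_id"] != "PFCA-3"].copy()
        recs = {r.chemical_id: r for r in _records(df)}
        # only 2 carboxylics left; the chain-8 sulfonate fills slot 3
        chosen = select_expert_surrogates(recs["TARGET"], list(recs.values()), k=3)
        assert chosen[:2] == ["PFCA-2", "PFCA-1"] or set(chosen[:2]) == {"PFCA-1", "PFCA-2"}
        assert "PFSA-1" in chosen

    def test_rt_tie_broken_by_earlier_elution(self):
        recs = [
            ChemicalRecord("T", "t", 5.0, "carboxylic_acid", 8),
            ChemicalRecord("EARLY", "e", 4.5, "carboxylic_acid", 6),
            ChemicalRecord("LATE", "l", 5.5, "carboxylic_acid", 6),
            ChemicalRecord("FAR1", "f", 9.0, "carboxylic_acid", 6),
            ChemicalRecord("FAR2", "g", 11.0, "carboxylic_acid", 6),
        ]
        chosen = select_expert_surrogates(recs[0], recs, k=1)
        assert chosen == ["EARLY"]

    def test_pool_too_small_errors(self, toy_chemicals):
        recs = _records(toy_chemicals.iloc[:3])
        with pytest.raises(InsufficientDataError):
            select_expert_surrogates(recs[0], recs, k=3)

    def test_global_excludes_target_only(self, toy_chemicals):
        recs = _records(toy_chemicals)
        ids = select_global_surrogates(recs[-1], recs)
        assert len(ids) == len(recs) - 1
        assert recs[-1].chemical_id not in ids
        # target absent from pool: full pool returned
        assert len(select_global_surrogates("NOT-THERE", recs)) == len(recs)


def _rf_table(mapping):
    rows = []
    for cid, vals in mapping.items():
        for v in vals:
            rows.append({"chemical_id": cid, "rf": float(v)})
    return pd.DataFrame(rows)


class TestBootstrap:
    def test_degenerate_constant_rf(self):
        table = _rf_table({"a": [7, 7], "b": [7], "c": [7, 7, 7]})
        p = bootstrap_rf_percentiles(table, ["a", "b", "c"], 5, n_boot=200, seed=1)
        assert (p.rf_lo, p.rf_med, p.rf_hi) == (7.0, 7.0, 7.0)

    def test_two_chemical_enumeration(self):
        # resampled sets {1,1},{1,3},{3,1},{3,3} equally likely:
        # medians 1,2,2,3 -> median 2; interpolated 2.5th percentiles
        # 1, 1.05, 1.05, 3 -> median 1.05
        table = _rf_table({"a": [1], "b": [3]})
        p = bootstrap_rf_percentiles(table, ["a", "b"], 2, n_boot=20_000, seed=11)
        assert p.rf_med == pytest.approx(2.0, abs=1e-12)
        assert p.rf_lo == pytest.approx(1.05, abs=1e-12)

    def test_three_chemical_enumeration_oracle(self):
        # exhaustive enumeration of the hierarchical resampling distribution
        pools = {"a": [1.0, 2.0], "b": [5.0], "c": [10.0, 20.0]}
        resample = 2
        draws = [(cid, v) for cid, vals in pools.items() for v in vals]
        probs = {(cid, v): 1 / (3 * len(pools[cid])) for cid, vals in pools.items()
                 for v in vals}
        med_dist = {}
        for combo in itertools.product(draws, repeat=resample):
            pr = np.prod([probs[d] for d in combo])
            med = float(np.median([v for _, v in combo]))
            med_dist[med] = med_dist.get(med, 0.0) + pr
        # median of the replicate-median distribution
        acc, expected_med = 0.0, None
        for v in sorted(med_dist):
            acc += med_dist[v]
            if acc >= 0.5:
                expected_med = v
                break
        table = _rf_table(pools)
        p = bootstrap_rf_percentiles(table, list(pools), resample, n_boot=50_000, seed=2)
        assert p.rf_med == pytest.approx(expected_med, abs=1e-12)

    def test_determinism_and_monotonicity(self, synthetic_dataset):
        rf = compute_rf_table(synthetic_dataset)
        ids = synthetic_dataset.chemical_ids[:5]
        p1 = bootstrap_rf_percentiles(rf, ids, 26, n_boot=500, seed=9)
        p2 = bootstrap_rf_percentiles(rf, ids, 26, n_boot=500, seed=9)
        assert (p1.rf_lo, p1.rf_med, p1.rf_hi) == (p2.rf_lo, p2.rf_med, p2.rf_hi)
        assert p1.rf_lo <= p1.rf_med <= p1.rf_hi

    def test_unknown_surrogate_errors(self, synthetic_dataset):
        rf = compute_rf_table(synthetic_dataset)
        with pytest.raises(ReferentialError):
            bootstrap_rf_percentiles(rf, ["NOPE"], 5, n_boot=10, seed=0)


class TestConcentrationEstimate:
    P = RFPercentiles(1.0, 10.0, 100.0, 0.05, ("s",), 26, 100, 0)

    def test_direct_quotients(self):
        est = estimate_concentration_qnta(100.0, self.P)
        assert (est.conc_lcl, est.conc_hat, est.conc_ucl) == (1.0, 10.0, 100.0)
        assert est.confidence_level == 0.95

    def test_homogeneity_in_abundance(self):
        e1 = estimate_concentration_qnta(50.0, self.P)
        e2 = estimate_concentration_qnta(100.0, self.P)
        assert e2.conc_hat == pytest.approx(2 * e1.conc_hat)
        assert e2.conc_lcl == pytest.approx(2 * e1.conc_lcl)
        assert e2.conc_ucl == pytest.approx(2 * e1.conc_ucl)

    def test_zero_width_interval(self):
        p = RFPercentiles(5.0, 5.0, 5.0, 0.05, ("s",), 26, 100, 0)
        est = estimate_concentration_qnta(10.0, p)
        assert est.conc_lcl == est.conc_hat == est.conc_ucl == 2.0


class TestRunApproach:
    def test_constant_rf_dataset_gives_aq_one(self, noiseless_dataset):
        # force every chemical onto the same RF
        from qnta import Dataset, add_metrics

        ds = noiseless_dataset
        obs = ds.observations.copy()
        obs["abundance"] = 1e6 * obs["true_concentration"]
        obs["is_abundance"] = np.nan
        flat = Dataset(chemicals=ds.chemicals.copy(), observations=obs)
        res = run_qnta_approach(flat, "A5", n_boot=200, seed=1)
        met = add_metrics(res.estimates)
        np.testing.assert_allclose(met["aq"], 1.0, rtol=1e-12)

    def test_per_chemical_percentiles_shared_across_observations(self, synthetic_dataset):
        res = run_qnta_approach(synthetic_dataset, "A5", n_boot=300, seed=4)
        est = res.estimates
        ratios = est["conc_ucl"] / est["conc_lcl"]
        for _, g in est.groupby("chemical_id"):
            np.testing.assert_allclose(
                g["conc_ucl"] / g["conc_lcl"],
                (g["conc_ucl"] / g["conc_lcl"]).iloc[0], rtol=1e-12,
            )

    def test_cardinality_and_defaults(self, synthetic_dataset):
        res = run_qnta_approach(synthetic_dataset, "A5", n_boot=300, seed=4)
        assert len(res.percentiles) == 26
        assert res.resample_size == 26
        assert len(res.estimates) == len(synthetic_dataset.observations)
        # surrogate pool always excludes the analyte itself
        for cid, p in res.percentiles.items():
            assert cid not in p.surrogate_ids
            assert len(p.surrogate_ids) == 25

    def test_expert_mode_uses_three_surrogates(self, synthetic_dataset):
        res = run_qnta_approach(synthetic_dataset, "A4", n_boot=300, seed=4)
        for cid, p in res.percentiles.items():
            assert len(p.surrogate_ids) == 3
            assert cid not in p.surrogate_ids

    def test_chemical_order_invariance(self, synthetic_dataset):
        from qnta import Dataset

        ds = synthetic_dataset
        rev = Dataset(
            chemicals=ds.chemicals.iloc[::-1].reset_index(drop=True),
            observations=ds.observations.copy(),
        )
        r1 = run_qnta_approach(ds, "A5", n_boot=200, seed=6)
        r2 = run_qnta_approach(rev, "A5", n_boot=200, seed=6)
        for cid in ds.chemical_ids:
            assert r1.percentiles[cid].rf_med == r2.percentiles[cid].rf_med
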