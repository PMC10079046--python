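import dataclasses

import numpy as np
import pytest

from submort.birth_history import cbh_u5mr_series
from submort.core import rw2_basis
from submort.synthetic_data import (
    SyntheticConfig,
    build_adjacency,
    generate_complete_birth_history,
    generate_drs,
    generate_summary_birth_history,
    generate_truth,
)


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="4 provinces"):
            SyntheticConfig(n_provinces=3)
        with pytest.raises(ValueError, match="3 years"):
            SyntheticConfig(year_start=2016, year_end=2017)
        with pytest.raises(ValueError, match="completeness_range"):
            SyntheticConfig(completeness_range=(0.0, 0.9))

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SyntheticConfig(n_provinces=6, spatial_sd=0.2)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SyntheticConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestGraphBuilders:
    @pytest.mark.parametrize("model", ["grid", "ring", "random-planar"])
    @pytest.mark.parametrize("n", [4, 8, 13])
    def test_connected(self, model, n):
        assert build_adjacency(n, model, seed=1).is_connected()


class TestGenerateTruth:
    def test_deterministic_given_seed(self, small_config):
        a = generate_truth(small_config)
        b = generate_truth(small_config)
        assert np.array_equal(a.true_u5mr, b.true_u5mr)
        assert np.array_equal(a.true_nmr, b.true_nmr)
        assert np.array_equal(a.completeness, b.completeness)

    def test_noise_free_limit_is_exact_covariate_predictor(self, flat_truth):
        assert np.allclose(flat_truth.true_u5mr, np.exp(3.0))

    def test_noise_free_with_covariates(self):
        cfg = SyntheticConfig(
            spatial_sd=0.0, temporal_sd=0.0, interaction_sd=0.0, seed=3
        )
        truth = generate_truth(cfg)
        b = np.asarray(cfg.mean_coefs)
        eta = b[0] + np.tensordot(truth.covariates, b[1:], axes=([2], [0]))
        assert np.allclose(truth.true_u5mr, np.exp(eta))

    def test_truncation_forced_when_relation_exceeds_unity(self):
        cfg = SyntheticConfig(nmr_quad_coefs=(2.0, 1.0, 0.0), seed=5)
        truth = generate_truth(cfg)  # untruncated NMR would be e² × U5MR
        assert np.all(truth.true_nmr <= truth.true_u5mr)
        assert np.any(truth.true_nmr == truth.true_u5mr)

    def test_rw2_lag1_autocorrelation_matches_direct_simulation(self):
        """The generator's temporal effects follow the constrained RW2 prior:
        oracle = double cumulative sum of innovations with the best-fitting
        line removed, which has the same law up to scale."""
        t = 13
        rng = np.random.default_rng(11)
        tt = np.arange(t, dtype=float)
        design = np.column_stack([np.ones(t), tt])
        proj = np.eye(t) - design @ np.linalg.inv(design.T @ design) @ design.T

        def lag1(x):
            return float(x[:-1] @ x[1:] / (x @ x))

        oracle = []
        for _ in range(500):
            innov = rng.standard_normal(t - 2)
            x = np.concatenate([[0.0, 0.0], np.cumsum(np.cumsum(innov))])
            oracle.append(lag1(proj @ x))
        basis = rw2_basis(t)
        sampled = [lag1(basis.sample(1.0, rng)) for _ in range(500)]
        se = np.hypot(np.std(oracle) / np.sqrt(500), np.std(sampled) / np.sqrt(500))
        assert np.mean(sampled) == pytest.approx(np.mean(oracle), abs=3.5 * se)


class TestGenerateDRS:
    def test_counts_never_exceed_births(self, default_truth):
        obs = generate_drs(default_truth, seed=1)
        births = default_truth.config.births_per_province_year
        for o in obs:
            assert o.value / 1000.0 * births <= births

    def test_neonatal_never_exceeds_under5(self, default_truth):
        obs = generate_drs(default_truth, seed=2)
        by_cell = {}
        for o in obs:
            by_cell.setdefault((o.province, o.reference_year), {})[o.measure] = o.value
        for cell in by_cell.values():
            assert cell["NMR"] <= cell["U5MR"]

    def test_expected_count_matches_binomial_mean(self):
        """completeness 0.5 with a known rate: mean registered count over
        replicates approximates births × rate × completeness."""
        cfg = SyntheticConfig(
            mean_coefs=(3.0, 0, 0, 0), spatial_sd=0, temporal_sd=0,
            interaction_sd=0, nmr_effect_sd=0,
            completeness_range=(0.5, 0.5), births_per_province_year=100_000,
            seed=8,
        )
        truth = generate_truth(cfg)
        rate = truth.true_u5mr[0, 0]  # exp(3) ≈ 20.09 per 1,000
        counts = []
        for s in range(200):
            obs = generate_drs(truth, seed=s)
            o = next(
                x for x in obs
                if x.province == truth.provinces[0]
                and x.reference_year == truth.years[0]
                and x.measure == "U5MR"
            )
            counts.append(o.value / 1000.0 * 100_000)
        expected = 100_000 * rate / 1000.0 * 0.5
        se = np.sqrt(expected) / np.sqrt(200)
        assert np.mean(counts) == pytest.approx(expected, abs=4 * se)

    def test_observed_rate_scales_with_completeness(self, default_truth):
        """Source consistency: mean DRS rate ≈ completeness × true rate."""
        ratios = []
        for s in range(200):
            obs = generate_drs(default_truth, seed=1000 + s)
            o = obs[0]  # province 0, first year, U5MR
            i, j = 0, 0
            ratios.append(
                o.value / (default_truth.true_u5mr[i, j] * default_truth.completeness[i, j])
            )
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)


class TestSummaryBirthHistory:
    def test_zero_mortality_gives_zero_children_dead(self):
        cfg = SyntheticConfig(
            mean_coefs=(-8.0, 0, 0, 0), spatial_sd=0, temporal_sd=0,
            interaction_sd=0, nmr_effect_sd=0, seed=2,
        )  # rate ≈ 0.0003 per 1,000 → death probability ≈ 3e-7
        truth = generate_truth(cfg)
        table = generate_summary_birth_history(truth, truth.provinces[0], 2017, 500, seed=1)
        assert table["cd"].sum() == 0

    def test_children_dead_never_exceed_children_born(self, default_truth):
        table = generate_summary_birth_history(
            default_truth, default_truth.provinces[0], 2017, 300, seed=4
        )
        assert (table["cd"] <= table["ceb"]).all()

    def test_doubling_mortality_doubles_proportion_dead(self):
        base = SyntheticConfig(
            mean_coefs=(2.5, 0, 0, 0), spatial_sd=0, temporal_sd=0,
            interaction_sd=0, nmr_effect_sd=0, seed=6,
        )
        doubled = dataclasses.replace(base, mean_coefs=(2.5 + np.log(2.0), 0, 0, 0))
        t1, t2 = generate_truth(base), generate_truth(doubled)
        r1, r2 = [], []
        for s in range(60):
            a = generate_summary_birth_history(t1, t1.provinces[0], 2017, 400, seed=s)
            b = generate_summary_birth_history(t2, t2.provinces[0], 2017, 400, seed=s)
            r1.append(a["cd"].sum() / a["ceb"].sum())
            r2.append(b["cd"].sum() / b["ceb"].sum())
        assert np.mean(r2) / np.mean(r1) == pytest.approx(2.0, rel=0.1)

    def test_survey_before_horizon_rejected(self, default_truth):
        with pytest.raises(ValueError, match="precedes"):
            generate_summary_birth_history(default_truth, "P00", 1999, 100, seed=0)


class TestCompleteBirthHistory:
    def test_zero_mortality_all_alive(self):
        cfg = SyntheticConfig(
            mean_coefs=(-8.0, 0, 0, 0), spatial_sd=0, temporal_sd=0,
            interaction_sd=0, nmr_effect_sd=0, seed=2,
        )
        truth = generate_truth(cfg)
        records = generate_complete_birth_history(truth, truth.provinces[0], 2017, 500, seed=3)
        assert all(r.alive for r in records)

    def test_death_ages_within_under5_window(self, default_truth):
        records = generate_complete_birth_history(
            default_truth, default_truth.provinces[0], 2017, 800, seed=5
        )
        deaths = [r for r in records if not r.alive]
        assert deaths, "expected some under-5 deaths at default mortality"
        assert all(0 <= r.age_at_death_months < 60 for r in deaths)

    def test_deterministic_given_seed(self, default_truth):
        a = generate_complete_birth_history(default_truth, "P01", 2017, 200, seed=9)
        b = generate_complete_birth_history(default_truth, "P01", 2017, 200, seed=9)
        assert [(r.birth_time, r.alive, r.age_at_death_months) for r in a] == [
            (r.birth_time, r.alive, r.age_at_death_months) for r in b
        ]

    def test_direct_estimator_recovers_truth(self, flat_truth):
        """Self-consistency: the direct period estimator applied to a large
        generated history recovers the flat true rate within Monte-Carlo
        error."""
        ests = []
        for s in range(20):
            records = generate_complete_birth_history(
                flat_truth, flat_truth.provinces[0], 2017, 4000, seed=100 + s,
                weight_sd=0.0,
            )
            obs = cbh_u5mr_series(records, flat_truth.years, "P00", survey_time=2017.5)
            ests.extend(o.value for o in obs)
        truth_rate = flat_truth.true_u5mr[0, 0]
        se = np.std(ests) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(truth_rate, abs=3 * se + 0.02 * truth_rate)
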