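import math

import numpy as np
import pandas as pd
import pytest

from submort.birth_history import (
    AGE_GROUPS,
    BirthRecord,
    CoefficientSet,
    cbh_u5mr,
    estimates_to_observations,
    mac_estimate,
    map_estimate,
    qc_gate,
    validate_sbh,
)
from submort.synthetic_data import SyntheticConfig, generate_summary_birth_history, generate_truth


def make_sbh(ceb, cd, n_mothers=100):
    return pd.DataFrame(
        {
            "maternal_age_group": list(AGE_GROUPS),
            "ceb": ceb,
            "cd": cd,
            "n_mothers": n_mothers,
            "missing_fraction": 0.0,
        }
    )


class TestQCGate:
    def test_high_missingness_and_implausible_sex_ratio_both_flagged(self):
        verdict = qc_gate(0.28, 1.08)
        assert not verdict
        assert len(verdict.reasons) == 2
        assert any("missing" in r for r in verdict.reasons)
        assert any("sex ratio" in r for r in verdict.reasons)

    def test_clean_source_accepted(self):
        assert qc_gate(0.0, 1.02)

    def test_boundaries_inclusive_on_accept_side(self):
        assert qc_gate(0.10, 1.06)
        assert qc_gate(0.05, 1.00)
        assert not qc_gate(0.101, 1.06)
        assert not qc_gate(0.10, 1.061)

    def test_missing_statistics_never_silently_accepted(self):
        with pytest.raises(ValueError):
            qc_gate(None, 1.02)
        with pytest.raises(ValueError, match="NaN"):
            qc_gate(float("nan"), 1.02)

    def test_cutoff_restricted_to_documented_band(self):
        assert not qc_gate(0.07, 1.02, missing_cutoff=0.05)
        with pytest.raises(ValueError, match="cutoff"):
            qc_gate(0.0, 1.02, missing_cutoff=0.2)


class TestBirthRecord:
    def test_death_age_presence_tied_to_alive_flag(self):
        with pytest.raises(ValueError, match="iff"):
            BirthRecord(2010.0, alive=True, age_at_death_months=3)
        with pytest.raises(ValueError, match="iff"):
            BirthRecord(2010.0, alive=False, age_at_death_months=None)


class TestDirectEstimator:
    def test_closed_form_single_death(self):
        """1 unweighted death among 1,000 person-years: m = 0.001 and
        5q0 = 1000·(1 − exp(−0.005)) ≈ 4.99."""
        records = [
            BirthRecord(2010.0, alive=True, age_at_death_months=None)
            for _ in range(200)
        ]
        records.append(BirthRecord(2010.0, alive=False, age_at_death_months=5))
        obs = cbh_u5mr(records, 2010)
        exposure = 200 * 1.0 + (5 + 0.5) / 12.0
        expected = 1000.0 * (1.0 - math.exp(-5.0 / exposure))
        assert obs.value == pytest.approx(expected)
        assert obs.design_variance == pytest.approx(1.0)

    def test_invariant_to_uniform_weight_rescaling(self):
        records = [
            BirthRecord(2010.0, alive=False, age_at_death_months=10, weight=1.0),
            BirthRecord(2010.0, alive=True, age_at_death_months=None, weight=1.0),
            BirthRecord(2010.2, alive=True, age_at_death_months=None, weight=1.0),
        ]
        halved = [
            BirthRecord(r.birth_time, r.alive, r.age_at_death_months, r.weight * 0.5)
            for r in records
        ]
        assert cbh_u5mr(records, 2010).value == pytest.approx(
            cbh_u5mr(halved, 2010).value
        )

    def test_monotone_in_deaths_at_fixed_exposure(self):
        def estimate(n_dead):
            records = [
                BirthRecord(2009.0, alive=False, age_at_death_months=15)
                for _ in range(n_dead)
            ] + [
                BirthRecord(2009.0, alive=True, age_at_death_months=None)
                for _ in range(50 - n_dead)
            ]
            return cbh_u5mr(records, 2010).value

        values = [estimate(k) for k in (1, 3, 6)]
        assert values[0] < values[1] < values[2]

    def test_zero_deaths_bounded_by_continuity_correction(self):
        records = [
            BirthRecord(2010.0, alive=True, age_at_death_months=None)
            for _ in range(100)
        ]
        obs = cbh_u5mr(records, 2010)
        bound = 1000.0 * (1.0 - math.exp(-5.0 * 0.5 / 100.0))
        assert obs.value == pytest.approx(bound)
        assert obs.design_variance == pytest.approx(2.0)

    def test_zero_exposure_is_an_error(self):
        records = [BirthRecord(2015.0, alive=True, age_at_death_months=None)]
        with pytest.raises(ValueError, match="exposure"):
            cbh_u5mr(records, 2000)


class TestIndirectEstimators:
    def test_identity_multipliers_return_raw_ratio(self):
        table = make_sbh([100] * 7, [2, 3, 4, 5, 5, 6, 6])
        est = mac_estimate(table, 2017.0, CoefficientSet.identity())
        assert np.allclose(est["q5_per_1000"], np.array([2, 3, 4, 5, 5, 6, 6]) * 10.0)

    def test_zero_children_dead_gives_zero_estimates(self):
        table = make_sbh([100] * 7, [0] * 7)
        est = mac_estimate(table, 2017.0, CoefficientSet.classical_default())
        assert (est["q5_per_1000"] == 0).all()

    def test_zero_ceb_rows_dropped(self):
        table = make_sbh([0, 100, 100, 100, 100, 100, 100], [0, 2, 3, 4, 4, 5, 5])
        est = mac_estimate(table, 2017.0, CoefficientSet.identity())
        assert len(est) == 6

    def test_too_few_usable_rows_rejected(self):
        table = make_sbh([100, 100, 0, 0, 0, 0, 0], [1, 1, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="at least 3"):
            mac_estimate(table, 2017.0, CoefficientSet.identity())

    def test_children_dead_exceeding_born_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            validate_sbh(make_sbh([10] * 7, [11] * 7))

    def test_map_pools_into_period_buckets(self):
        table = make_sbh([100] * 7, [2] * 7)
        est = map_estimate(table, 2017.0, CoefficientSet.identity())
        assert set(est["period"]) <= {"0-4", "5-9", "10-14"}
        assert (est["reference_year"] < 2017).all()

    def test_coefficient_csv_roundtrip(self, tmp_path):
        coefs = CoefficientSet.classical_default()
        coefs.to_csv(tmp_path / "c.csv")
        back = CoefficientSet.from_csv(tmp_path / "c.csv")
        pd.testing.assert_frame_equal(back.table, coefs.table)

    def test_observation_conversion_applies_horizon_and_sparse_filters(self):
        est = pd.DataFrame(
            {
                "cohort": ["a", "b", "c"],
                "reference_year": [2016.0, 1990.0, 2015.0],
                "q5_per_1000": [20.0, 20.0, 20.0],
                "design_variance": [0.1, 0.1, 0.9],
                "ceb": [500, 500, 20],
            }
        )
        obs = estimates_to_observations(est, "P", "SBH_MAC", horizon=(2005.0, 2017.5))
        assert len(obs) == 1 and obs[0].reference_year == 2016.0


class TestRecoveryAgainstGenerator:
    @pytest.fixture(scope="class")
    def flat(self):
        return generate_truth(
            SyntheticConfig(
                mean_coefs=(3.0, 0, 0, 0), spatial_sd=0, temporal_sd=0,
                interaction_sd=0, nmr_effect_sd=0, seed=7,
            )
        )

    def test_mac_and_map_recover_constant_truth(self, flat):
        """Calibrated coefficients on a large constant-surface sample recover
        the true rate within Monte-Carlo error, and the cohort and period
        routes agree with each other."""
        coefs = CoefficientSet.calibrated(seed=1)
        mac_vals, map_vals = [], []
        for s in range(30):
            table = generate_summary_birth_history(flat, flat.provinces[0], 2017, 800, seed=s)
            mac = mac_estimate(table, 2017.5, coefs)
            mapp = map_estimate(table, 2017.5, coefs)
            mac_vals.extend(mac[mac["cohort"] != "15-19"]["q5_per_1000"])
            map_vals.extend(mapp["q5_per_1000"])
        truth_rate = flat.true_u5mr[0, 0]
        for vals in (mac_vals, map_vals):
            se = np.std(vals) / np.sqrt(len(vals))
            assert np.mean(vals) == pytest.approx(truth_rate, abs=3 * se + 0.03 * truth_rate)
        assert np.mean(mac_vals) == pytest.approx(np.mean(map_vals), rel=0.05)
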