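"""Synthetic task data: streams, designs, DDM and psychometric generators."""

import math

import numpy as np
import pandas as pd
import pytest

import valenceddm as vd
from valenceddm import wfpt
from valenceddm.models import GroupParams
from valenceddm.simulate import default_stopping_rule


class TestDesign:
    def test_study_shape_is_valid(self):
        d = vd.generate_design({"n_subjects": 83, "n_trials_per_subject": 80,
                                "p_match": 0.6})
        assert d.n_subjects == 83 and d.p_match == 0.6

    @pytest.mark.parametrize("bad", [
        {"n_subjects": 10, "p_match": 1.0},
        {"n_subjects": 10, "p_match": 0.5},
        {"n_subjects": 0},
        {"n_subjects": 10, "p_desirable_state": 1.5},
        {"n_subjects": 10, "nonsense_field": 3},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            vd.generate_design(bad)

    def test_same_seed_same_design(self):
        cfg = {"n_subjects": 5, "seed": 9}
        assert vd.generate_design(cfg) == vd.generate_design(cfg)


class TestStream:
    def test_match_frequency_converges(self):
        """Law of large numbers: TV fraction ~ p_match at n = 1e5 within
        3 binomial standard errors."""
        d = vd.TaskDesign(n_subjects=1)
        rng = np.random.default_rng(0)
        s = vd.generate_stream("tv", 100_000, d, rng)
        frac = s.n_tv / len(s.items)
        se = math.sqrt(0.6 * 0.4 / 100_000)
        assert abs(frac - 0.6) < 3 * se

    def test_single_item_bernoulli(self):
        d = vd.TaskDesign(n_subjects=1)
        rng = np.random.default_rng(1)
        hits = sum(vd.generate_stream("tv", 1, d, rng).items[0] == "tv"
                   for _ in range(5000))
        se = math.sqrt(0.6 * 0.4 / 5000)
        assert abs(hits / 5000 - 0.6) < 3 * se

    def test_onsets_strictly_increasing(self):
        d = vd.TaskDesign(n_subjects=1)
        s = vd.generate_stream("phone", 3, d, np.random.default_rng(2))
        assert len(s.onsets_ms) == 3
        assert all(b > a for a, b in zip(s.onsets_ms, s.onsets_ms[1:]))

    def test_length_zero_rejected(self):
        d = vd.TaskDesign(n_subjects=1)
        with pytest.raises(ValueError):
            vd.generate_stream("tv", 0, d, np.random.default_rng(0))


def _flat_group(b0, b1, z=0.5, sz=0.0):
    """Group parameters with no between-subject heterogeneity."""
    return GroupParams(a=2.5, t0=7.4, z=z, sz=sz, b0=b0, b1=b1,
                       sd_log_a=0.0, sd_log_t0=0.0, sd_logit_z=0.0,
                       sd_b0=0.0, sd_b1=0.0)


class TestDDMDataset:
    def test_determinism(self):
        d = vd.TaskDesign(n_subjects=3, n_trials_per_subject=20, seed=4)
        ds1 = vd.simulate_ddm_dataset(vd.CONTROL_REFERENCE_PARAMS, d, 4,
                                      np.random.default_rng(4))
        ds2 = vd.simulate_ddm_dataset(vd.CONTROL_REFERENCE_PARAMS, d, 4,
                                      np.random.default_rng(4))
        ds3 = vd.simulate_ddm_dataset(vd.CONTROL_REFERENCE_PARAMS, d, 4,
                                      np.random.default_rng(5))
        assert ds1.df.equals(ds2.df)
        assert not ds1.df.equals(ds3.df)

    def test_unbiased_parameters_give_valence_symmetry(self):
        """With b1 = 0 and z = 0.5, accuracy is the same on desirable and
        undesirable trials up to Monte-Carlo error."""
        d = vd.TaskDesign(n_subjects=4, n_trials_per_subject=500, seed=6)
        ds = vd.simulate_ddm_dataset(_flat_group(0.5, 0.0), d, 4,
                                     np.random.default_rng(6))
        acc = ds.df.groupby("desirability_code")["correct"].mean()
        n = len(ds.df) / 2
        assert abs(acc[1] - acc[0]) < 3 * math.sqrt(2 * 0.25 / n)

    def test_zero_drift_splits_choices_evenly(self):
        d = vd.TaskDesign(n_subjects=4, n_trials_per_subject=500, seed=7)
        ds = vd.simulate_ddm_dataset(_flat_group(0.0, 0.0), d, 4,
                                     np.random.default_rng(7))
        p = (ds.df["choice"] == "desirable").mean()
        assert abs(p - 0.5) < 3 * math.sqrt(0.25 / len(ds.df))

    def test_choice_proportions_match_analytic_probability(self):
        """Empirical desirable-judgment rate on desirable trials matches
        the closed-form absorption probability within 3 SE at 1e4 trials."""
        gp = _flat_group(0.4, 0.2, z=0.55, sz=0.2)
        d = vd.TaskDesign(n_subjects=5, n_trials_per_subject=2000, seed=8)
        ds = vd.simulate_ddm_dataset(gp, d, 4, np.random.default_rng(8))
        des = ds.df[ds.df["desirability_code"] == 1]
        p_model = wfpt.choice_probability(
            wfpt.DDMParams(gp.a, gp.t0, gp.z, gp.sz, gp.b0 + gp.b1))
        p_emp = (des["choice"] == "desirable").mean()
        se = math.sqrt(p_model * (1 - p_model) / len(des))
        assert abs(p_emp - p_model) < 3 * se

    def test_stream_bookkeeping(self, small_control_dataset):
        df = small_control_dataset.df
        assert (df["n_tv_observed"] <= df["n_observed"]).all()
        assert (df["n_observed"] >= 1).all()
        assert (df["correct"] == (df["choice"] == df["true_state"])).all()
        assert small_control_dataset.provenance == "simulated-from-DDM"


class TestPsychometricDataset:
    def test_stopping_rule_minimum(self):
        rng = np.random.default_rng(0)
        assert all(default_stopping_rule(rng) >= 2 for _ in range(2000))

    def test_flat_function_gives_even_split(self):
        d = vd.TaskDesign(n_subjects=6, n_trials_per_subject=200, seed=9)
        ds = vd.simulate_psychometric_dataset((0.0, 0.0), d)
        tv = ((ds.df["choice"] == "desirable") ==
              ds.df["tv_desirable"].astype(bool)).mean()
        assert abs(tv - 0.5) < 3 * math.sqrt(0.25 / len(ds.df))

    def test_bad_stopping_rule_errors(self):
        d = vd.TaskDesign(n_subjects=1, n_trials_per_subject=5, seed=1)
        with pytest.raises(ValueError):
            vd.simulate_psychometric_dataset(
                (0.0, 25.0), d, stopping_rule=lambda rng: 1)


class TestCSV:
    def test_round_trip(self, small_control_dataset, tmp_path):
        path = tmp_path / "trials.csv"
        small_control_dataset.to_csv(path)
        back = vd.BehavioralDataset.from_csv(path)
        pd.testing.assert_frame_equal(
            back.df, small_control_dataset.df[back.df.columns],
            check_dtype=False)

    def test_missing_column_named_in_error(self, small_control_dataset,
                                           tmp_path):
        path = tmp_path / "bad.csv"
        small_control_dataset.df.drop(columns=["rt_ms"]).to_csv(
            path, index=False)
        with pytest.raises(ValueError, match="rt_ms"):
            vd.BehavioralDataset.from_csv(path)

    def test_inconsistent_group_labels_rejected(self, small_control_dataset):
        df = small_control_dataset.df.copy()
        df.loc[df.index[:5], "group"] = "threat"
        with pytest.raises(ValueError, match="inconsistent group"):
            vd.BehavioralDataset(df=df)
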