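"""Hierarchical MCMC machinery: diagnostics, DIC, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest

import valenceddm as vd
from valenceddm.diagnostics import DICResult, gelman_rubin
from valenceddm.models import GroupParams


class TestGelmanRubin:
    def test_well_mixed_chains_below_threshold(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(5, 10_000))
        assert gelman_rubin(chains) < 1.1

    def test_zero_between_chain_variance(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=5000)
        chains = np.stack([base, base, base])
        assert gelman_rubin(chains) <= 1.0

    def test_offset_chain_detected(self):
        """One chain displaced by 100x its spread inflates R-hat far past
        the 1.1 convergence criterion."""
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(5, 2000))
        chains[0] += 100.0
        assert gelman_rubin(chains) > 1.1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((3, 5)))

    def test_agrees_with_arviz_on_well_behaved_chains(self):
        """Cross-check against an independent implementation (the classic
        and rank-normalized variants agree closely for stationary normal
        chains)."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 5000))
        ours = gelman_rubin(chains)
        theirs = float(np.asarray(
            az.rhat(az.convert_to_dataset(chains[..., None]))
            .to_array().values).item())
        assert ours == pytest.approx(theirs, abs=0.01)


class TestDIC:
    def test_defining_identity(self):
        """Deviance samples {10,12,14} with deviance-at-mean 11 give
        pD = 1 and DIC = 13."""
        r = DICResult.from_deviances([10.0, 12.0, 14.0], 11.0)
        assert r.effective_params == pytest.approx(1.0)
        assert r.dic == pytest.approx(13.0)
        assert r.mean_deviance == pytest.approx(12.0)

    def test_inconsistent_fields_rejected(self):
        with pytest.raises(ValueError):
            DICResult(dic=10.0, mean_deviance=12.0, deviance_at_mean=11.0,
                      effective_params=1.0)


def _tiny_fit(data, spec=4, seed=0, n_chains=1, n_samples=300, n_burn=100):
    return vd.HierarchicalDDM(data, spec=spec).fit(
        n_samples=n_samples, n_burn=n_burn, n_chains=n_chains, seed=seed)


class TestSampler:
    def test_identical_seed_identical_chains(self, small_control_dataset):
        r1 = _tiny_fit(small_control_dataset, seed=3)
        r2 = _tiny_fit(small_control_dataset, seed=3)
        r3 = _tiny_fit(small_control_dataset, seed=4)
        for name, x in r1.group_chains().items():
            np.testing.assert_array_equal(x, r2.group_chains()[name])
        assert not np.array_equal(r1.group_chains()["a"],
                                  r3.group_chains()["a"])

    def test_identical_fits_identical_dic(self, small_control_dataset):
        d1 = _tiny_fit(small_control_dataset, seed=3).dic()
        d2 = _tiny_fit(small_control_dataset, seed=3).dic()
        assert d1.dic == d2.dic

    def test_low_information_warning(self):
        df = pd.DataFrame({
            "subject_id": [0] * 4, "group": ["control"] * 4,
            "trial_index": range(4),
            "true_state": ["desirable", "undesirable"] * 2,
            "desirability_code": [1, 0, 1, 0], "tv_desirable": [1] * 4,
            "n_observed": [4] * 4, "n_tv_observed": [2] * 4,
            "choice": ["desirable", "undesirable"] * 2,
            "rt_ms": [2500.0, 2700.0, 2900.0, 3100.0],
            "correct": [True] * 4,
        })
        with pytest.warns(UserWarning, match="low-information"):
            model = vd.HierarchicalDDM(df, spec=4)
        res = model.fit(n_samples=120, n_burn=40, n_chains=1, seed=0)
        assert np.isfinite(res.posterior_mean("v_bias"))

    def test_subject_with_single_trial_rejected(self):
        df = pd.DataFrame({
            "subject_id": [0], "group": ["control"], "trial_index": [0],
            "true_state": ["desirable"], "desirability_code": [1],
            "tv_desirable": [1], "n_observed": [4], "n_tv_observed": [2],
            "choice": ["desirable"], "rt_ms": [2500.0], "correct": [True],
        })
        with pytest.raises(ValueError, match="fewer than 2 trials"):
            vd.HierarchicalDDM(df)

    def test_posterior_draws_respect_support(self, small_control_dataset):
        res = _tiny_fit(small_control_dataset, seed=1)
        ch = res.group_chains()
        assert (ch["a"] > 0).all()
        assert ((ch["z"] > 0) & (ch["z"] < 1)).all()
        assert ((ch["sz"] >= 0) & (ch["sz"] < 0.6)).all()

    def test_posterior_predictive_deterministic(self, small_control_dataset):
        res = _tiny_fit(small_control_dataset, seed=2)
        p1 = res.posterior_predictive(seed=7)
        p2 = res.posterior_predictive(seed=7)
        assert p1.df.equals(p2.df)
        assert p1.n_subjects == small_control_dataset.n_subjects

    def test_degenerate_posterior_predictive_uses_that_point(
            self, small_control_dataset):
        """With all posterior mass at one point, predictive simulation is
        simulation at that point."""
        res = _tiny_fit(small_control_dataset, seed=5)
        for arr in (res._subj, res._mu, res._sig, res._sz, res._ll):
            arr[:] = arr[:1, :1]  # broadcast the first draw everywhere
        gp = res.to_group_params()
        gp_draw = res.to_group_params(draw=(0, 0))
        for fld in ("a", "t0", "z", "sz", "b0", "b1"):
            assert getattr(gp, fld) == pytest.approx(
                getattr(gp_draw, fld), rel=1e-12)

    def test_functional_entry_point(self, small_control_dataset):
        res = vd.sample_posterior(small_control_dataset, 4,
                                  vd.MCMCConfig(n_samples=150, n_burn=50,
                                                n_chains=1, seed=0))
        assert res.spec.model_id == 4
        assert vd.compute_dic(res, small_control_dataset).dic == \
            res.dic().dic
        other = small_control_dataset.df.iloc[:-80]
        with pytest.raises(ValueError, match="not fitted to this dataset"):
            vd.compute_dic(res, other)

    def test_save_round_trip(self, small_control_dataset, tmp_path):
        res = _tiny_fit(small_control_dataset, seed=6, n_chains=2)
        res.save(str(tmp_path / "post"))
        draws = pd.read_csv(tmp_path / "post.csv")
        assert {"chain", "draw", "a", "v_bias", "sz"} <= set(draws.columns)
        import json
        side = json.loads((tmp_path / "post.json").read_text())
        assert side["model_id"] == 4 and "rhat" in side


def test_null_data_does_not_prefer_valence_dependent_model():
    """Data simulated from the valence-independent model should not favour
    model 4 by more than a conventionally decisive DIC margin."""
    gp = GroupParams(a=2.5, t0=7.45, z=0.5, sz=0.15, b0=0.45, b1=0.0,
                     sd_b1=0.0)
    design = vd.TaskDesign(n_subjects=8, n_trials_per_subject=80, seed=21)
    data = vd.simulate_ddm_dataset(gp, design, 1, np.random.default_rng(21))
    cfg = dict(n_samples=700, n_burn=250, n_chains=1, seed=2)
    dic1 = vd.HierarchicalDDM(data, spec=1).fit(**cfg).dic().dic
    dic4 = vd.HierarchicalDDM(data, spec=4).fit(**cfg).dic().dic
    assert dic1 - dic4 < 10.0
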