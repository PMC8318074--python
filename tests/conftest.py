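import numpy as np
import pandas as pd
import pytest

import valenceddm as vd


def make_trials(rows):
    """Build a minimal trial table from (subject, group, n_obs, n_tv,
    desirability, correct) tuples."""
    recs = []
    for i, (sid, grp, n_obs, n_tv, desir, correct) in enumerate(rows):
        state = "desirable" if desir else "undesirable"
        choice = state if correct else (
            "undesirable" if desir else "desirable")
        recs.append({
            "subject_id": sid, "group": grp, "trial_index": i,
            "true_state": state, "desirability_code": desir,
            "tv_desirable": 1, "n_observed": n_obs, "n_tv_observed": n_tv,
            "choice": choice, "rt_ms": 2500.0 + 10 * i, "correct": correct,
        })
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def small_control_dataset():
    """A small diffusion-simulated control-style dataset."""
    design = vd.TaskDesign(n_subjects=8, n_trials_per_subject=80, seed=101)
    rng = np.random.default_rng(101)
    return vd.simulate_ddm_dataset(vd.CONTROL_REFERENCE_PARAMS, design, 4,
                                   rng, group_label="control")


@pytest.fixture(scope="session")
def recovery_fits():
    """Simulate both groups from the reference parameters at the study's
    own scale (43 control / 40 threat subjects x 80 trials) and refit the
    fully valence-dependent model (2,500 iterations of which 500 burn-in,
    3 chains).  Shared by the recovery, convergence and predictive-check
    tests."""
    out = {}
    for label, gp, n_subj in [("control", vd.CONTROL_REFERENCE_PARAMS, 43),
                              ("threat", vd.THREAT_REFERENCE_PARAMS, 40)]:
        design = vd.TaskDesign(n_subjects=n_subj, n_trials_per_subject=80,
                               seed=11)
        rng = np.random.default_rng(11)
        data = vd.simulate_ddm_dataset(gp, design, 4, rng, group_label=label)
        res = vd.HierarchicalDDM(data, spec=4).fit(
            n_samples=2500, n_burn=500, n_chains=3, seed=5)
        out[label] = (gp, data, res)
    return out
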