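"""Data hygiene, model-free statistics and the simulate->fit->recover
pipeline.

Exclusion rules (applied in this fixed order):

1. flag trials answered before the second item was observed
   (``n_observed < 2``);
2. drop subjects with flagged trials in *more than half* of their trials;
3. drop the remaining flagged trials;
4. drop subjects whose accuracy on the retained trials is strictly below
   chance (0.5).

The valence-dependent judgment bias is each subject's proportion of
correctly identified desirable factories minus the proportion of correctly
identified undesirable factories; its correlation with the subject-level
drift-rate bias (and starting-point bias) is the model-behavior link
statistic.  Group x valence effects on accuracy are assessed with a seeded
subject-level permutation test.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .models import GroupParams, build_model, CONTROL_REFERENCE_PARAMS, \
    THREAT_REFERENCE_PARAMS
from .simulate import BehavioralDataset, TaskDesign, simulate_ddm_dataset
from .hierarchical import HierarchicalDDM, HierarchicalDDMResults, MCMCConfig
from .psychometric import fit_all_conditions

__all__ = ["ExclusionReport", "JudgmentBias", "apply_exclusions",
           "judgment_bias", "judgment_bias_table", "correlate_bias",
           "group_valence_permutation_test", "compare_models",
           "RecoveryReport", "recovery_experiment", "run_pipeline"]

log = logging.getLogger("valenceddm")


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping of the exclusion cascade."""

    n_subjects_in: int
    n_subjects_out: int
    n_trials_in: int
    n_trials_out: int
    n_excluded_below_chance: int
    n_excluded_first_stim_majority: int
    n_trials_dropped_pre_second_item: int
    excluded_subjects: dict = field(default_factory=dict)  # id -> reason


def apply_exclusions(data: BehavioralDataset | pd.DataFrame
                     ) -> tuple[BehavioralDataset, ExclusionReport]:
    """Apply the task's exclusion rules; returns the cleaned dataset and a
    count-consistent report.  Idempotent: re-applying to the output changes
    nothing."""
    ds = data if isinstance(data, BehavioralDataset) else \
        BehavioralDataset(df=data)
    df = ds.df
    if len(df) == 0:
        raise ValueError("empty dataset")
    n_subj_in = df["subject_id"].nunique()
    n_trials_in = len(df)
    excluded: dict = {}

    flagged = df["n_observed"] < 2
    frac = flagged.groupby(df["subject_id"]).mean()
    majority = frac[frac > 0.5].index  # strictly more than half
    for sid in majority:
        excluded[int(sid)] = "responded before second item in over half of trials"
    df1 = df[~df["subject_id"].isin(majority)]

    dropped_trials = int((df1["n_observed"] < 2).sum())
    df2 = df1[df1["n_observed"] >= 2]

    acc = df2.groupby("subject_id")["correct"].mean()
    below = acc[acc < 0.5].index  # strictly below chance; exactly 0.5 kept
    for sid in below:
        excluded[int(sid)] = "accuracy below chance on retained trials"
    df3 = df2[~df2["subject_id"].isin(below)]

    report = ExclusionReport(
        n_subjects_in=n_subj_in,
        n_subjects_out=df3["subject_id"].nunique(),
        n_trials_in=n_trials_in,
        n_trials_out=len(df3),
        n_excluded_below_chance=len(below),
        n_excluded_first_stim_majority=len(majority),
        n_trials_dropped_pre_second_item=dropped_trials,
        excluded_subjects=excluded)
    out = BehavioralDataset(df=df3.reset_index(drop=True),
                            provenance=ds.provenance,
                            generating_params=ds.generating_params)
    return out, report


# ---------------------------------------------------------------------------
# judgment bias and its model correlate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JudgmentBias:
    """Per-subject valence-dependent judgment bias."""

    subject_id: int
    prop_correct_desirable: float
    prop_correct_undesirable: float

    @property
    def bias(self) -> float:
        return self.prop_correct_desirable - self.prop_correct_undesirable


def judgment_bias(data, subject_id) -> JudgmentBias:
    """Proportion correct per valence and their difference for one
    subject."""
    df = data.df if isinstance(data, BehavioralDataset) else data
    sub = df[df["subject_id"] == subject_id]
    des = sub[sub["desirability_code"] == 1]
    und = sub[sub["desirability_code"] == 0]
    if len(des) == 0 or len(und) == 0:
        raise ValueError(
            f"subject {subject_id} lacks trials of one valence")
    return JudgmentBias(subject_id=int(subject_id),
                        prop_correct_desirable=float(des["correct"].mean()),
                        prop_correct_undesirable=float(und["correct"].mean()))


def judgment_bias_table(data) -> pd.DataFrame:
    """Judgment bias for every subject, one row each."""
    df = data.df if isinstance(data, BehavioralDataset) else data
    rows = []
    for sid in np.sort(df["subject_id"].unique()):
        jb = judgment_bias(df, sid)
        rows.append({"subject_id": jb.subject_id,
                     "group": df.loc[df["subject_id"] == sid, "group"].iloc[0],
                     "prop_correct_desirable": jb.prop_correct_desirable,
                     "prop_correct_undesirable": jb.prop_correct_undesirable,
                     "bias": jb.bias})
    return pd.DataFrame(rows)


def correlate_bias(param_values, biases) -> float:
    """Pearson correlation between subject-level posterior-mean parameter
    values (e.g. drift bias) and judgment biases.  Returns nan with a
    warning when either input is constant."""
    x = np.asarray(param_values, dtype=float)
    y = np.asarray(biases, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("zero variance in one input; correlation undefined",
                      UserWarning, stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def group_valence_permutation_test(data, n_perm: int = 2000,
                                   seed: int = 0) -> dict:
    """Seeded permutation test for the group x valence interaction on
    per-subject proportions correct.

    The statistic is the difference between groups of the mean judgment
    bias; group labels are permuted across subjects.  Replaces the
    mixed-effects F-test with a self-contained resampling test.
    """
    tab = judgment_bias_table(data)
    groups = tab["group"].unique()
    if groups.size != 2:
        raise ValueError("permutation test needs exactly 2 groups")
    g0 = tab.loc[tab["group"] == groups[0], "bias"].to_numpy()
    g1 = tab.loc[tab["group"] == groups[1], "bias"].to_numpy()
    obs = g0.mean() - g1.mean()
    pooled = np.concatenate([g0, g1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = perm[:g0.size].mean() - perm[g0.size:].mean()
        if abs(stat) >= abs(obs):
            count += 1
    return {"statistic": float(obs), "p_value": (count + 1) / (n_perm + 1),
            "groups": tuple(groups)}


# ---------------------------------------------------------------------------
# model comparison and recovery
# ---------------------------------------------------------------------------

def compare_models(data, model_ids=(1, 2, 3, 4),
                   cfg: MCMCConfig | None = None) -> pd.DataFrame:
    """Fit each specification to the same data and tabulate DIC."""
    cfg = cfg or MCMCConfig()
    rows = []
    for mid in model_ids:
        t_start = time.perf_counter()
        res = HierarchicalDDM(data, spec=mid).fit(cfg)
        d = res.dic()
        log.info("model %d fitted in %.1fs (DIC %.1f)", mid,
                 time.perf_counter() - t_start, d.dic)
        rows.append({"model_id": mid, "model": build_model(mid).name,
                     "dic": d.dic, "mean_deviance": d.mean_deviance,
                     "deviance_at_mean": d.deviance_at_mean,
                     "pD": d.effective_params})
    return pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    """Simulate -> refit recovery of group-level parameters."""

    tables: dict                    # group label -> DataFrame
    results: dict                   # group label -> HierarchicalDDMResults
    dic_tables: dict | None = None  # group label -> DataFrame (optional)

    def all_recovered(self, level: float = 0.95) -> bool:
        """True when every generating group-level value lies inside its
        credible interval in every group."""
        return all(bool(row["recovered"]) for tab in self.tables.values()
                   for _, row in tab.iterrows())


_RECOVERY_PARAMS = {"a": "a", "t0": "t0", "z": "z", "sz": "sz",
                    "b0": "v_intercept", "b1": "v_bias"}


def recovery_experiment(group_params_control: GroupParams | None = None,
                        group_params_threat: GroupParams | None = None,
                        design: TaskDesign | None = None,
                        cfg: MCMCConfig | None = None,
                        seed: int = 0,
                        compare_dic: bool = False) -> RecoveryReport:
    """Per group: simulate from the generating parameters, refit the fully
    valence-dependent model, and tabulate recovered group-level posterior
    means and 95% credible intervals next to the generators.  Optionally
    also runs the four-model DIC comparison on each simulated dataset."""
    gps = {"control": group_params_control or CONTROL_REFERENCE_PARAMS,
           "threat": group_params_threat or THREAT_REFERENCE_PARAMS}
    cfg = cfg or MCMCConfig(n_samples=2000, n_burn=500, seed=seed)
    tables, results, dics = {}, {}, ({} if compare_dic else None)
    for i, (label, gp) in enumerate(gps.items()):
        t_start = time.perf_counter()
        des = design or TaskDesign(n_subjects=24, seed=seed + 17 * i)
        rng = np.random.default_rng([des.seed, i])
        data = simulate_ddm_dataset(gp, des, model_spec=4, rng=rng,
                                    group_label=label)
        res = HierarchicalDDM(data, spec=4).fit(
            MCMCConfig(**{**asdict(cfg), "seed": cfg.seed + i}))
        rows = []
        for short, name in _RECOVERY_PARAMS.items():
            gen = getattr(gp, short)
            lo, hi = res.credible_interval(name)
            rows.append({"parameter": name, "generating": gen,
                         "recovered_mean": res.posterior_mean(name),
                         "ci_lo": lo, "ci_hi": hi,
                         "recovered": bool(lo <= gen <= hi)})
        tables[label] = pd.DataFrame(rows)
        results[label] = res
        log.info("%s recovery fitted in %.1fs", label,
                 time.perf_counter() - t_start)
        if compare_dic:
            dics[label] = compare_models(data, cfg=cfg)
    return RecoveryReport(tables=tables, results=results, dic_tables=dics)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "profile": "quick",
    "seed": 0,
    "n_subjects_control": 24,
    "n_subjects_threat": 24,
    "n_trials_per_subject": 80,
    "n_samples": 2000,
    "n_burn": 500,
    "thin": 1,
    "n_chains": 2,
    "compare_models": False,
}

PAPER_PROFILE = {
    "n_subjects_control": 43,
    "n_subjects_threat": 40,
    "n_samples": 20000,
    "n_burn": 5000,
    "thin": 5,
    "n_chains": 5,
}


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """End-to-end: simulate both groups -> exclusions -> psychometric fits
    -> hierarchical DDM fit -> recovery table -> behavioral statistics.

    Returns the report bundle as a dict; when ``out_dir`` is given, every
    table is also written as CSV/JSON.  Fully seeded and deterministic.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    if cfg.get("profile") == "paper":
        cfg.update({k: cfg.get(k) if k in (config or {}) else v
                    for k, v in PAPER_PROFILE.items()})
    seed = int(cfg["seed"])
    mcfg = MCMCConfig(n_samples=int(cfg["n_samples"]),
                      n_burn=int(cfg["n_burn"]), thin=int(cfg["thin"]),
                      n_chains=int(cfg["n_chains"]), seed=seed)
    t_all = time.perf_counter()

    datasets = {}
    for i, (label, gp, n_subj) in enumerate([
            ("control", CONTROL_REFERENCE_PARAMS, cfg["n_subjects_control"]),
            ("threat", THREAT_REFERENCE_PARAMS, cfg["n_subjects_threat"])]):
        des = TaskDesign(n_subjects=int(n_subj),
                         n_trials_per_subject=int(cfg["n_trials_per_subject"]),
                         seed=seed + 17 * i)
        rng = np.random.default_rng(des.seed)
        ds = simulate_ddm_dataset(gp, des, model_spec=4, rng=rng,
                                  group_label=label)
        # disambiguate subject ids across groups
        ds.df["subject_id"] = ds.df["subject_id"] + 1000 * i
        datasets[label] = ds
    combined = BehavioralDataset(
        df=pd.concat([d.df for d in datasets.values()], ignore_index=True),
        provenance="simulated-from-DDM")
    log.info("simulated %d trials", combined.n_trials)

    cleaned, report = apply_exclusions(combined)
    log.info("exclusions: %s", report)

    psych = fit_all_conditions(cleaned, seed=seed)

    bundle = {"config": cfg, "exclusions": asdict(report),
              "psychometric": psych}

    fits = {}
    for label in datasets:
        sub = cleaned.df[cleaned.df["group"] == label]
        res = HierarchicalDDM(sub, spec=4).fit(
            MCMCConfig(**{**asdict(mcfg),
                          "seed": seed + (0 if label == "control" else 1)}))
        fits[label] = res
        log.info("%s fit: rhat %s", label,
                 res.rhat() if mcfg.n_chains > 1 else "n/a")
    bundle["fits"] = {k: v.summary() for k, v in fits.items()}

    # model-behavior link: drift-bias vs judgment bias per group
    links = {}
    for label, res in fits.items():
        sub = cleaned.df[cleaned.df["group"] == label]
        jb = judgment_bias_table(sub)
        vb = res.subject_means("b1")
        links[label] = {
            "r_drift_bias": correlate_bias(vb, jb["bias"]),
            "r_start_bias": correlate_bias(res.subject_means("z"),
                                           jb["bias"]),
        }
    bundle["bias_correlations"] = links
    bundle["permutation_test"] = group_valence_permutation_test(
        cleaned, seed=seed)

    if cfg.get("compare_models"):
        bundle["dic"] = {label: compare_models(datasets[label], cfg=mcfg)
                         for label in datasets}

    bundle["elapsed_s"] = time.perf_counter() - t_all
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        combined.to_csv(out / "simulated_trials.csv")
        cleaned.to_csv(out / "cleaned_trials.csv")
        psych.to_csv(out / "psychometric_fits.csv", index=False)
        for label, res in fits.items():
            res.summary().to_csv(out / f"ddm_summary_{label}.csv")
            res.save(str(out / f"posterior_{label}"))
        if "dic" in bundle:
            for label, tab in bundle["dic"].items():
                tab.to_csv(out / f"dic_{label}.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump({
                "config": cfg,
                "exclusions": asdict(report),
                "bias_correlations": links,
                "permutation_test": bundle["permutation_test"],
                "elapsed_s": bundle["elapsed_s"],
            }, fh, indent=2, default=float)
    return bundle
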