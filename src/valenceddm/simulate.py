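"""Synthetic factory-game data with the statistical structure the analyses
assume.

The task: on each trial the participant is in one of two hidden factory
states (TV or telephone factory), drawn with equal probability.  Items on
the conveyor belt match the true factory type independently with
probability 0.6.  One factory type is randomly assigned *desirable* per
subject; the participant judges the state whenever they wish and is
rewarded for accuracy.

Two generative paths produce datasets, each matching the model that is
later fitted to it:

* :func:`simulate_ddm_dataset` samples (choice, log-RT) directly from the
  two-boundary diffusion (subject parameters drawn from the group-level
  distribution) and attaches a stimulus stream whose length is the number
  of items presentable within the realized RT;
* :func:`simulate_psychometric_dataset` generates a stream, truncates it at
  a sampled stopping count, and draws the choice from the logistic
  psychometric function of the centered TV proportion.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit

from .models import GroupParams, ModelSpec, build_model
from . import wfpt

__all__ = [
    "TaskDesign",
    "StimulusStream",
    "TrialRecord",
    "BehavioralDataset",
    "generate_design",
    "generate_stream",
    "draw_subject_params",
    "simulate_ddm_dataset",
    "simulate_psychometric_dataset",
    "default_stopping_rule",
    "CSV_COLUMNS",
]

#: trial CSV schema (one row per trial); tv_desirable is constant within
#: subject and lets the psychometric stage recover TV/phone judgments
CSV_COLUMNS = [
    "subject_id", "group", "trial_index", "true_state", "desirability_code",
    "tv_desirable", "n_observed", "n_tv_observed", "choice", "rt_ms",
    "correct",
]

ITEM_TYPES = ("tv", "phone")


@dataclass(frozen=True)
class TaskDesign:
    """Structural parameters of the factory task.

    Defaults are the study's conditions: 80 trials per subject, item/state
    match probability 0.6, equal prior over the two states, ~521 ms mean
    stimulus presentation (uniformly jittered) with a 150 ms lag.
    """

    n_subjects: int
    n_trials_per_subject: int = 80
    p_match: float = 0.6
    p_desirable_state: float = 0.5
    mean_stim_ms: float = 521.0
    mean_lag_ms: float = 150.0
    stim_jitter_half_ms: float = 150.0
    seed: int = 0
    practice_session: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_subject < 1:
            raise ValueError("all counts must be positive")
        if not 0.5 < self.p_match < 1.0:
            raise ValueError("p_match must lie strictly between 0.5 and 1 "
                             "(streams must be informative but stochastic)")
        if not 0.0 <= self.p_desirable_state <= 1.0:
            raise ValueError("p_desirable_state must lie in [0, 1]")
        if self.mean_stim_ms <= 0 or self.mean_lag_ms < 0:
            raise ValueError("stimulus timing must be positive")
        if not 0 <= self.stim_jitter_half_ms < self.mean_stim_ms:
            raise ValueError("jitter half-width must be >= 0 and below the "
                             "mean presentation time")


def generate_design(config: dict | TaskDesign) -> TaskDesign:
    """Validate a configuration into a TaskDesign (reproducible by seed)."""
    if isinstance(config, TaskDesign):
        return config
    try:
        return TaskDesign(**config)
    except TypeError as exc:
        raise ValueError(f"invalid task configuration: {exc}") from None


@dataclass(frozen=True)
class StimulusStream:
    """An ordered item sequence with strictly increasing onset times."""

    items: tuple
    onsets_ms: tuple

    def __post_init__(self) -> None:
        if len(self.items) == 0:
            raise ValueError("stream must contain at least one item")
        if len(self.items) != len(self.onsets_ms):
            raise ValueError("items and onsets must have equal length")
        on = np.asarray(self.onsets_ms)
        if not (np.diff(on) > 0).all():
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_tv(self) -> int:
        return sum(1 for it in self.items if it == "tv")


def generate_stream(trial_type: str, length: int, design: TaskDesign,
                    rng: np.random.Generator) -> StimulusStream:
    """Generate a stream of ``length`` items for a trial of the given
    factory type; each item independently matches the type with probability
    ``design.p_match``.  Onsets are spaced by the jittered presentation time
    plus the fixed lag."""
    if trial_type not in ITEM_TYPES:
        raise ValueError(f"trial_type must be one of {ITEM_TYPES}")
    if length < 1:
        raise ValueError("stream length must be >= 1")
    other = "phone" if trial_type == "tv" else "tv"
    match = rng.random(length) < design.p_match
    items = tuple(trial_type if m else other for m in match)
    durations = design.mean_stim_ms + design.stim_jitter_half_ms * \
        (2.0 * rng.random(length) - 1.0)
    gaps = durations + design.mean_lag_ms
    onsets = np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    return StimulusStream(items=items, onsets_ms=tuple(onsets))


@dataclass(frozen=True)
class TrialRecord:
    """One task trial, as used by all downstream analyses."""

    subject_id: int
    group: str
    trial_index: int
    true_state: str           # "desirable" | "undesirable"
    desirability_code: int    # 1 if desirable else 0
    tv_desirable: int         # 1 if the TV factory is this subject's desirable type
    stream: StimulusStream | None
    n_observed: int
    n_tv_observed: int
    choice: str               # "desirable" | "undesirable" judgment
    rt_ms: float
    correct: bool

    def __post_init__(self) -> None:
        if self.correct != (self.choice == self.true_state):
            raise ValueError("correct flag inconsistent with choice/state")
        if self.stream is not None and len(self.stream.items) != self.n_observed:
            raise ValueError("n_observed inconsistent with stream length")


@dataclass
class BehavioralDataset:
    """A trial table plus provenance; thin wrapper around a DataFrame."""

    df: pd.DataFrame
    provenance: str = "external"
    generating_params: dict | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset is missing required columns: {missing}")
        grp = self.df.groupby("subject_id")["group"].nunique()
        if (grp > 1).any():
            bad = grp[grp > 1].index.tolist()
            raise ValueError(f"subjects with inconsistent group labels: {bad}")

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    @property
    def n_trials(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, columns=CSV_COLUMNS)

    @classmethod
    def from_csv(cls, path, provenance: str = "external") -> "BehavioralDataset":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(
                f"malformed trial CSV: missing column(s) {missing}")
        return cls(df=df, provenance=provenance)


def draw_subject_params(group_params: GroupParams, n_subjects: int,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-subject DDM parameters from the group-level distribution
    (normal on log/logit sampling scales, see GroupParams)."""
    logit = lambda p: np.log(p / (1 - p))
    a = np.exp(rng.normal(np.log(group_params.a), group_params.sd_log_a,
                          n_subjects))
    t0 = np.exp(rng.normal(np.log(group_params.t0), group_params.sd_log_t0,
                           n_subjects))
    z = expit(rng.normal(logit(group_params.z), group_params.sd_logit_z,
                         n_subjects))
    b0 = rng.normal(group_params.b0, group_params.sd_b0, n_subjects)
    b1 = rng.normal(group_params.b1, group_params.sd_b1, n_subjects)
    # keep the uniform starting-point range feasible for every subject
    half = group_params.sz / 2 + 1e-3
    z = np.clip(z, half + 1e-6, 1 - half - 1e-6)
    return pd.DataFrame({"a": a, "t0": t0, "z": z, "b0": b0, "b1": b1})


def _attach_stream(rng: np.random.Generator, design: TaskDesign,
                   trial_type: str, rt_ms: float) -> StimulusStream:
    """Stream truncated at the response: as many items as were presentable
    within the realized RT (at least one)."""
    mean_gap = design.mean_stim_ms + design.mean_lag_ms
    n = max(1, int(rt_ms // mean_gap) + 1)
    stream = generate_stream(trial_type, n, design, rng)
    keep = [i for i, on in enumerate(stream.onsets_ms) if on < rt_ms]
    if not keep:
        keep = [0]
    return StimulusStream(items=stream.items[:len(keep)],
                          onsets_ms=stream.onsets_ms[:len(keep)])


def simulate_ddm_dataset(group_params: GroupParams, design: TaskDesign,
                         model_spec: ModelSpec | int = 4,
                         rng: np.random.Generator | None = None,
                         group_label: str | None = None,
                         dt: float = 1.0e-4) -> BehavioralDataset:
    """Simulate a full behavioral dataset from the diffusion process.

    Subject-level parameters are drawn from the group-level distribution;
    per trial, (choice, log-RT) are sampled from the two-boundary Wiener
    process via the path simulator, with the signed drift set by the drift
    regression and the trial's desirability.  Frozen parameters of simpler
    model specifications (z = 0.5 and/or b1 = 0) are respected.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    spec = model_spec if isinstance(model_spec, ModelSpec) else \
        build_model(model_spec)
    label = group_label or group_params.label or "group"
    subj = draw_subject_params(group_params, design.n_subjects, rng)
    if not spec.free_starting_point:
        subj["z"] = 0.5
    if not spec.valence_dependent_drift:
        subj["b1"] = 0.0
    sz = group_params.sz
    nt = design.n_trials_per_subject
    rows = []
    for s in range(design.n_subjects):
        p = subj.iloc[s]
        tv_desirable = int(rng.random() < 0.5)
        desir = (rng.random(nt) < design.p_desirable_state).astype(np.int8)
        drifts = np.where(desir == 1, p.b0 + p.b1, -p.b0)
        params = wfpt.DDMParams(threshold_a=float(p.a),
                                nondecision_t0=float(p.t0),
                                start_z=float(p.z), start_var_sz=sz)
        bnd, td = wfpt.simulate_first_passage_batch(
            params, nt, rng, dt=dt, drifts=drifts)
        log_rt = p.t0 + td
        rt_ms = np.exp(log_rt)
        for i in range(nt):
            state = "desirable" if desir[i] == 1 else "undesirable"
            state_is_tv = (desir[i] == 1) == (tv_desirable == 1)
            trial_type = "tv" if state_is_tv else "phone"
            stream = _attach_stream(rng, design, trial_type, float(rt_ms[i]))
            choice = "desirable" if bnd[i] == 1 else "undesirable"
            rows.append((s, label, i, state, int(desir[i]), tv_desirable,
                         len(stream.items), stream.n_tv, choice,
                         float(rt_ms[i]), choice == state))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return BehavioralDataset(
        df=df, provenance="simulated-from-DDM",
        generating_params={"group_params": asdict(group_params),
                           "model_id": spec.model_id,
                           "design": asdict(design)})


def default_stopping_rule(rng: np.random.Generator) -> int:
    """Number of items observed before responding: 2 + Poisson(4).

    The real task does not report this distribution; any callable
    ``rng -> int`` with values >= 2 may be substituted.
    """
    return 2 + int(rng.poisson(4.0))


def simulate_psychometric_dataset(psy_params: tuple[float, float],
                                  design: TaskDesign,
                                  stopping_rule: Callable | None = None,
                                  rng: np.random.Generator | None = None,
                                  group_label: str = "group",
                                  max_retries: int = 100) -> BehavioralDataset:
    """Simulate choices from the logistic psychometric function.

    ``psy_params = (beta0, beta1)``; per trial a stream is generated,
    truncated at the sampled stopping count, and the TV judgment is drawn
    with probability ``1 / (1 + exp(-(beta1 * X - beta0)))`` where X is the
    centered TV proportion observed.
    """
    beta0, beta1 = float(psy_params[0]), float(psy_params[1])
    if not np.isfinite([beta0, beta1]).all():
        raise ValueError("psychometric parameters must be finite")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if stopping_rule is None:
        stopping_rule = default_stopping_rule
    nt = design.n_trials_per_subject
    rows = []
    for s in range(design.n_subjects):
        tv_desirable = int(rng.random() < 0.5)
        for i in range(nt):
            desirable = rng.random() < design.p_desirable_state
            state_is_tv = desirable == (tv_desirable == 1)
            trial_type = "tv" if state_is_tv else "phone"
            n_obs = 0
            for _ in range(max_retries):
                n_obs = int(stopping_rule(rng))
                if n_obs >= 2:
                    break
            else:
                raise ValueError("stopping rule kept producing fewer than "
                                 "2 observed items")
            stream = generate_stream(trial_type, n_obs, design, rng)
            x = stream.n_tv / n_obs - 0.5
            p_tv = expit(beta1 * x - beta0)
            judged_tv = rng.random() < p_tv
            choice_desirable = judged_tv == (tv_desirable == 1)
            choice = "desirable" if choice_desirable else "undesirable"
            state = "desirable" if desirable else "undesirable"
            rt_ms = float(stream.onsets_ms[-1] + design.mean_stim_ms +
                          rng.uniform(100.0, 400.0))
            rows.append((s, group_label, i, state, int(desirable),
                         tv_desirable, n_obs, stream.n_tv, choice, rt_ms,
                         choice == state))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return BehavioralDataset(
        df=df, provenance="simulated-from-psychometric",
        generating_params={"beta0": beta0, "beta1": beta1,
                           "design": asdict(design)})
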