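"""Hierarchical Bayesian estimation of the valence-dependent DDM family.

:class:`HierarchicalDDM` is built from a trial table (statsmodels style);
``fit()`` runs seeded Markov chain Monte Carlo and returns a
:class:`HierarchicalDDMResults` carrying the chains, posterior summaries,
convergence diagnostics (Gelman-Rubin R-hat), DIC, and posterior-predictive
simulation.

The hierarchy: each subject's (a, t0, z, b0, b1) are drawn from group-level
normal distributions on transformed scales (log a, log t0, logit z,
identity for the drift terms) with half-normal group spreads; group means
carry flat priors within generous physical bounds; the across-trial
starting-point range sz is a single group-level scalar with a flat prior on
[0, 0.6).  The sampler is an adaptive Metropolis-within-Gibbs scheme:
random-walk updates for subject-level parameters, conjugate draws for the
group means, random-walk updates on log group spreads and on sz.  Proposal
scales adapt toward a 0.44 acceptance rate during burn-in only, so the
retained chains form a valid time-homogeneous Markov chain.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import wfpt
from .diagnostics import DICResult, gelman_rubin, RHAT_THRESHOLD
from .models import (ModelSpec, build_model, GroupPrior, DEFAULT_PRIOR,
                     GroupParams, PARAM_BOUNDS)
from .simulate import BehavioralDataset, TaskDesign, simulate_ddm_dataset

__all__ = ["MCMCConfig", "HierarchicalDDM", "HierarchicalDDMResults",
           "Posterior", "sample_posterior", "compute_dic"]

_PARAM_NAMES = ("a", "t0", "z", "b0", "b1")
_GROUP_NAMES = {"a": "a", "t0": "t0", "z": "z", "b0": "v_intercept",
                "b1": "v_bias"}


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``n_samples`` is the total number of iterations per chain, of which the
    first ``n_burn`` are discarded and the remainder kept every ``thin``-th
    draw.  The study's settings were 20,000 / 5,000 / thin 5 with five
    chains for diagnostics; its recovery runs used 2,000 / 500.
    """

    n_samples: int = 2000
    n_burn: int = 500
    thin: int = 1
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_samples:
            raise ValueError("n_burn must be smaller than n_samples")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")


def _to_sampling(k: int, x):
    if k in (0, 1):
        return np.log(x)
    if k == 2:
        return logit(x)
    return x


def _to_natural(k: int, x):
    if k in (0, 1):
        return np.exp(x)
    if k == 2:
        return expit(x)
    return x


class HierarchicalDDM:
    """Hierarchical valence-dependent drift-diffusion model.

    Parameters
    ----------
    data : BehavioralDataset or DataFrame
        Trial table with the package's CSV schema; RTs in ms are modeled on
        the natural-log scale.
    spec : ModelSpec or int
        Which of the four specifications to estimate (default 4, the fully
        valence-dependent model).
    prior : GroupPrior
        Hyperprior settings (half-normal scales of the group spreads).
    """

    def __init__(self, data, spec: ModelSpec | int = 4,
                 prior: GroupPrior = DEFAULT_PRIOR):
        df = data.df if isinstance(data, BehavioralDataset) else data
        required = {"subject_id", "rt_ms", "choice", "desirability_code"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"data is missing columns {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("empty dataset")
        self.spec = spec if isinstance(spec, ModelSpec) else build_model(spec)
        self.prior = prior
        self.subject_ids = np.sort(df["subject_id"].unique())
        self._log_rt, self._choice_up, self._desir = [], [], []
        for sid in self.subject_ids:
            sub = df[df["subject_id"] == sid]
            if len(sub) < 2:
                raise ValueError(f"subject {sid} has fewer than 2 trials")
            self._log_rt.append(
                np.ascontiguousarray(np.log(sub["rt_ms"].to_numpy(float))))
            self._choice_up.append(np.ascontiguousarray(
                (sub["choice"] == "desirable").to_numpy().astype(np.int8)))
            self._desir.append(np.ascontiguousarray(
                sub["desirability_code"].to_numpy().astype(np.int8)))
        self.n_subjects = len(self.subject_ids)
        n_trials = [x.size for x in self._log_rt]
        if self.n_subjects < 5 or min(n_trials) < 10:
            warnings.warn(
                "low-information dataset (few subjects or trials); "
                "group-level estimates will be weakly constrained",
                UserWarning, stacklevel=2)
        fp = hashlib.sha256(
            pd.util.hash_pandas_object(
                df[sorted(required)].reset_index(drop=True)).values.tobytes()
        ).hexdigest()[:16]
        self.data_fingerprint = fp
        # free parameter slots: a, t0 and the drift intercept are always
        # estimated; z and the drift bias depend on the specification
        free = [0, 1, 3]
        if self.spec.free_starting_point:
            free.insert(2, 2)
        if self.spec.valence_dependent_drift:
            free.append(4)
        self._free = tuple(free)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec | int = 4,
                       **kwargs) -> "HierarchicalDDM":
        return cls(df, spec=spec, **kwargs)

    @classmethod
    def from_csv(cls, path, spec: ModelSpec | int = 4, **kwargs):
        return cls(BehavioralDataset.from_csv(path), spec=spec, **kwargs)

    # -- likelihood ------------------------------------------------------

    def _subject_ll(self, s: int, th_row: np.ndarray, sz: float) -> float:
        a = float(np.exp(th_row[0]))
        t0 = float(np.exp(th_row[1]))
        z = float(expit(th_row[2]))
        return wfpt.dataset_loglik(
            self._log_rt[s], self._choice_up[s], self._desir[s],
            a, t0, z, sz, float(th_row[3]), float(th_row[4]),
            wfpt.GL_NODES, wfpt.GL_WEIGHTS, wfpt.TRUNCATION_EPS)

    def loglik(self, th: np.ndarray, sz: float) -> float:
        """Joint data log-likelihood at subject parameters ``th``
        ((n_subjects, 5) on the sampling scale) and group-level sz."""
        return float(sum(self._subject_ll(s, th[s], sz)
                         for s in range(self.n_subjects)))

    def _in_bounds(self, k: int, x: float) -> bool:
        lo, hi = PARAM_BOUNDS[_PARAM_NAMES[k]]
        return lo < _to_natural(k, x) < hi

    # -- initialization --------------------------------------------------

    def _init_state(self, rng: np.random.Generator):
        S = len(self.subject_ids)
        th = np.zeros((S, 5))
        for s in range(S):
            min_lrt = float(self._log_rt[s].min())
            th[s, 0] = np.log(2.5)
            th[s, 1] = np.log(max(min_lrt - 0.3, 0.05))
            th[s, 2] = 0.0
            th[s, 3] = 0.3
            th[s, 4] = 0.0
            for k in self._free:
                th[s, k] += 0.05 * rng.standard_normal()
        sz = 0.1
        # bounded retries on non-finite starts: pull t0 down until the
        # likelihood is finite for every subject
        for s in range(S):
            for _ in range(30):
                if np.isfinite(self._subject_ll(s, th[s], sz)):
                    break
                th[s, 1] = np.log(max(np.exp(th[s, 1]) - 0.2, 0.02))
            else:
                raise RuntimeError(
                    f"could not find a finite starting point for subject "
                    f"{self.subject_ids[s]}")
        mu = th.mean(axis=0)
        sig = np.full(5, 0.1)
        return th, mu, sig, sz

    # -- sampler ---------------------------------------------------------

    def _run_chain(self, cfg: MCMCConfig, chain_idx: int):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(chain_idx,)))
        S = self.n_subjects
        free = self._free
        tau = np.asarray(self.prior.sd_scales)
        th, mu, sig, sz = self._init_state(rng)
        ll = np.array([self._subject_ll(s, th[s], sz) for s in range(S)])

        step_th = np.full((S, 5), 0.12)
        step_sig = np.full(5, 0.25)
        step_sz = 0.03
        acc_th = np.zeros((S, 5)); try_th = np.zeros((S, 5))
        acc_sig = np.zeros(5); try_sig = np.zeros(5)
        acc_sz = 0.0; try_sz = 0.0

        n_keep = (cfg.n_samples - cfg.n_burn) // cfg.thin
        keep_th = np.empty((n_keep, S, 5))
        keep_mu = np.empty((n_keep, 5))
        keep_sig = np.empty((n_keep, 5))
        keep_sz = np.empty(n_keep)
        keep_ll = np.empty(n_keep)
        kept = 0

        for it in range(cfg.n_samples):
            # subject-level random-walk updates
            for k in free:
                for s in range(S):
                    cur = th[s, k]
                    prop = cur + step_th[s, k] * rng.standard_normal()
                    try_th[s, k] += 1
                    if not self._in_bounds(k, prop):
                        continue
                    th[s, k] = prop
                    ll_new = self._subject_ll(s, th[s], sz)
                    dprior = (-(prop - mu[k]) ** 2 + (cur - mu[k]) ** 2) / \
                        (2.0 * sig[k] ** 2)
                    if np.log(rng.random()) < ll_new - ll[s] + dprior:
                        ll[s] = ll_new
                        acc_th[s, k] += 1
                    else:
                        th[s, k] = cur
            # group means: conjugate normal draw (flat prior within bounds)
            for k in free:
                for _ in range(100):
                    cand = rng.normal(th[:, k].mean(), sig[k] / np.sqrt(S))
                    if self._in_bounds(k, cand):
                        mu[k] = cand
                        break
            # group spreads: random-walk on log sigma, half-normal prior
            for k in free:
                cur = sig[k]
                prop = cur * np.exp(step_sig[k] * rng.standard_normal())
                try_sig[k] += 1
                dev = th[:, k] - mu[k]
                lp_cur = -S * np.log(cur) - (dev ** 2).sum() / (2 * cur ** 2) \
                    - cur ** 2 / (2 * tau[k] ** 2) + np.log(cur)
                lp_prop = -S * np.log(prop) - (dev ** 2).sum() / (2 * prop ** 2) \
                    - prop ** 2 / (2 * tau[k] ** 2) + np.log(prop)
                if np.log(rng.random()) < lp_prop - lp_cur:
                    sig[k] = prop
                    acc_sig[k] += 1
            # group-level sz: random walk against the full-data likelihood
            prop_sz = sz + step_sz * rng.standard_normal()
            try_sz += 1
            lo, hi = PARAM_BOUNDS["sz"]
            if lo <= prop_sz < hi:
                ll_new = np.array([self._subject_ll(s, th[s], prop_sz)
                                   for s in range(S)])
                if np.log(rng.random()) < ll_new.sum() - ll.sum():
                    sz = prop_sz
                    ll = ll_new
                    acc_sz += 1
            # diminishing adaptation, burn-in only
            if it < cfg.n_burn and (it + 1) % 25 == 0:
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = acc_th / np.maximum(try_th, 1)
                    step_th *= np.exp(0.3 * (r - 0.44))
                    r = acc_sig / np.maximum(try_sig, 1)
                    step_sig *= np.exp(0.3 * (r - 0.44))
                    if try_sz > 0:
                        step_sz *= np.exp(0.3 * (acc_sz / try_sz - 0.44))
                acc_th[:] = 0; try_th[:] = 0
                acc_sig[:] = 0; try_sig[:] = 0
                acc_sz = 0.0; try_sz = 0.0
            if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0 \
                    and kept < n_keep:
                keep_th[kept] = th
                keep_mu[kept] = mu
                keep_sig[kept] = sig
                keep_sz[kept] = sz
                keep_ll[kept] = ll.sum()
                kept += 1
        return keep_th, keep_mu, keep_sig, keep_sz, keep_ll

    def fit(self, cfg: MCMCConfig | None = None,
            **kwargs) -> "HierarchicalDDMResults":
        """Sample the posterior; returns the results object.

        Either pass an :class:`MCMCConfig` or its fields as keyword
        arguments (``n_samples``, ``n_burn``, ``thin``, ``n_chains``,
        ``seed``).  Identical seed and data give identical chains.
        """
        if cfg is None:
            cfg = MCMCConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either cfg or keyword settings, not both")
        chains = [self._run_chain(cfg, c) for c in range(cfg.n_chains)]
        return HierarchicalDDMResults(
            model=self, cfg=cfg,
            subj_chains=np.stack([c[0] for c in chains]),
            mu_chains=np.stack([c[1] for c in chains]),
            sig_chains=np.stack([c[2] for c in chains]),
            sz_chains=np.stack([c[3] for c in chains]),
            ll_chains=np.stack([c[4] for c in chains]))


class HierarchicalDDMResults:
    """Posterior sample of a hierarchical DDM fit.

    Group-level chains are exposed on the natural scale under the names
    ``a``, ``t0``, ``z``, ``sz``, ``v_intercept``, ``v_bias`` (plus
    ``*_sd`` group spreads on the sampling scale); subject-level draws are
    kept for posterior means and predictive simulation.
    """

    def __init__(self, model: HierarchicalDDM, cfg: MCMCConfig,
                 subj_chains, mu_chains, sig_chains, sz_chains, ll_chains):
        self.model = model
        self.spec = model.spec
        self.cfg = cfg
        self.data_fingerprint = model.data_fingerprint
        self._subj = subj_chains      # (C, N, S, 5) sampling scale
        self._mu = mu_chains          # (C, N, 5) sampling scale
        self._sig = sig_chains
        self._sz = sz_chains          # (C, N)
        self._ll = ll_chains          # (C, N)

    # -- chain access ----------------------------------------------------

    @property
    def free_params(self) -> tuple:
        return tuple(_PARAM_NAMES[k] for k in self.model._free)

    def group_chains(self, natural: bool = True) -> dict:
        """Group-level chains as a dict name -> (n_chains, n_draws)."""
        out = {}
        for k in self.model._free:
            name = _GROUP_NAMES[_PARAM_NAMES[k]]
            x = self._mu[:, :, k]
            out[name] = _to_natural(k, x) if natural else x.copy()
            out[name + "_sd"] = self._sig[:, :, k]
        out["sz"] = self._sz.copy()
        return out

    def subject_means(self, param: str) -> np.ndarray:
        """Posterior mean of one subject-level parameter (natural scale),
        ordered by subject id."""
        k = _PARAM_NAMES.index(param)
        vals = _to_natural(k, self._subj[:, :, :, k])
        return vals.mean(axis=(0, 1))

    def credible_interval(self, name: str, level: float = 0.95) -> tuple:
        x = self.group_chains()[name].ravel()
        alpha = (1 - level) / 2
        return (float(np.quantile(x, alpha)),
                float(np.quantile(x, 1 - alpha)))

    def posterior_mean(self, name: str) -> float:
        return float(self.group_chains()[name].mean())

    # -- diagnostics -----------------------------------------------------

    def rhat(self, natural: bool = False) -> dict:
        """Gelman-Rubin R-hat for every reported group-level parameter,
        computed on the sampling scale by default."""
        if self._mu.shape[0] < 2:
            raise ValueError("R-hat needs at least 2 chains")
        return gelman_rubin(self.group_chains(natural=natural))

    def converged(self, threshold: float = RHAT_THRESHOLD) -> bool:
        return all(v < threshold for v in self.rhat().values())

    def dic(self) -> DICResult:
        """Deviance information criterion of this fit.

        The deviance at the posterior mean evaluates the likelihood at the
        mean of each parameter on its sampling scale (DIC is not invariant
        to this choice; documented here).
        """
        dev = -2.0 * self._ll.ravel()
        th_bar = self._subj.mean(axis=(0, 1))
        sz_bar = float(self._sz.mean())
        d_hat = -2.0 * self.model.loglik(th_bar, sz_bar)
        return DICResult.from_deviances(dev, d_hat)

    # -- predictive simulation -------------------------------------------

    def to_group_params(self, draw: tuple | None = None,
                        label: str = "") -> GroupParams:
        """Collapse the posterior (or a single retained draw) into a
        GroupParams for simulation."""
        if draw is None:
            mu = self._mu.mean(axis=(0, 1))
            sig = self._sig.mean(axis=(0, 1))
            sz = float(self._sz.mean())
        else:
            c, i = draw
            mu, sig, sz = self._mu[c, i], self._sig[c, i], float(self._sz[c, i])
        free = self.model._free
        return GroupParams(
            a=float(np.exp(mu[0])), t0=float(np.exp(mu[1])),
            z=float(expit(mu[2])) if 2 in free else 0.5,
            sz=sz, b0=float(mu[3]),
            b1=float(mu[4]) if 4 in free else 0.0,
            sd_log_a=float(sig[0]), sd_log_t0=float(sig[1]),
            sd_logit_z=float(sig[2]) if 2 in free else 0.0,
            sd_b0=float(sig[3]),
            sd_b1=float(sig[4]) if 4 in free else 0.0,
            label=label)

    def posterior_predictive(self, design: TaskDesign | None = None,
                             seed: int = 0) -> BehavioralDataset:
        """Simulate a dataset from a randomly drawn posterior parameter
        vector, with the same number of subjects and trials as the data."""
        rng = np.random.default_rng(seed)
        if design is None:
            design = TaskDesign(
                n_subjects=self.model.n_subjects,
                n_trials_per_subject=int(np.median(
                    [x.size for x in self.model._log_rt])),
                seed=seed)
        c = int(rng.integers(self._mu.shape[0]))
        i = int(rng.integers(self._mu.shape[1]))
        gp = self.to_group_params(draw=(c, i), label="predictive")
        return simulate_ddm_dataset(gp, design, model_spec=self.spec,
                                    rng=rng)

    # -- reporting -------------------------------------------------------

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior summary table: mean, sd, credible interval and R-hat
        per group-level parameter (natural scale)."""
        chains = self.group_chains()
        rh = self.rhat() if self._mu.shape[0] > 1 else {}
        rows = []
        alpha = (1 - level) / 2
        for name, x in chains.items():
            flat = x.ravel()
            rows.append({
                "parameter": name,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                f"ci_{100 * alpha:.1f}%": np.quantile(flat, alpha),
                f"ci_{100 * (1 - alpha):.1f}%": np.quantile(flat, 1 - alpha),
                "rhat": rh.get(name, np.nan),
            })
        return pd.DataFrame(rows).set_index("parameter")

    def save(self, path_prefix: str) -> None:
        """Write retained draws as CSV (one row per draw per chain) plus a
        JSON sidecar with config, model, fingerprint and R-hat values."""
        chains = self.group_chains()
        C, N = self._sz.shape
        rec = {"chain": np.repeat(np.arange(C), N),
               "draw": np.tile(np.arange(N), C)}
        for name, x in chains.items():
            rec[name] = x.ravel()
        for k in self.model._free:
            name = _PARAM_NAMES[k]
            for s, sid in enumerate(self.model.subject_ids):
                rec[f"{name}_subj[{sid}]"] = _to_natural(
                    k, self._subj[:, :, s, k]).ravel()
        pd.DataFrame(rec).to_csv(f"{path_prefix}.csv", index=False)
        side = {
            "model_id": self.spec.model_id,
            "model_name": self.spec.name,
            "config": asdict(self.cfg),
            "data_fingerprint": self.data_fingerprint,
            "n_subjects": self.model.n_subjects,
            "rhat": {k: float(v) for k, v in self.rhat().items()}
            if self._mu.shape[0] > 1 else None,
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(side, fh, indent=2)

    def plot_posteriors(self, ax=None):
        """Kernel-density style histograms of the group-level posteriors."""
        import matplotlib.pyplot as plt
        chains = self.group_chains()
        names = [n for n in chains if not n.endswith("_sd")]
        fig, axes = plt.subplots(1, len(names),
                                 figsize=(3 * len(names), 2.5))
        for ax_, name in zip(np.atleast_1d(axes), names):
            ax_.hist(chains[name].ravel(), bins=40, density=True,
                     color="0.4")
            ax_.set_title(name)
        fig.tight_layout()
        return fig


#: spec-facing alias: the posterior object of a hierarchical fit
Posterior = HierarchicalDDMResults


def sample_posterior(data, spec: ModelSpec | int,
                     cfg: MCMCConfig) -> HierarchicalDDMResults:
    """Functional entry point: build the model and sample its posterior."""
    return HierarchicalDDM(data, spec=spec).fit(cfg)


def compute_dic(posterior: HierarchicalDDMResults, data=None,
                spec=None) -> DICResult:
    """DIC of a fitted posterior (data/spec are bound to the posterior)."""
    if data is not None:
        df = data.df if isinstance(data, BehavioralDataset) else data
        probe = HierarchicalDDM(df, spec=spec or posterior.spec)
        if probe.data_fingerprint != posterior.data_fingerprint:
            raise ValueError("posterior was not fitted to this dataset")
    return posterior.dic()
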