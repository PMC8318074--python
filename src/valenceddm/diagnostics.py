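"""Convergence and model-comparison diagnostics for MCMC output."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["gelman_rubin", "DICResult", "RHAT_THRESHOLD"]

#: conventional convergence criterion for the potential scale reduction
RHAT_THRESHOLD = 1.1


def gelman_rubin(chains) -> float | dict:
    """Gelman-Rubin potential scale reduction factor (R-hat).

    Compares the estimated between-chain and within-chain variances; values
    below 1.1 are conventionally taken as converged.  ``chains`` is an
    array of shape (n_chains, n_draws) (or a dict of such arrays, in which
    case a dict of R-hats is returned).
    """
    if isinstance(chains, dict):
        return {k: gelman_rubin(v) for k, v in chains.items()}
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("chains must be a 2-d array (n_chains, n_draws)")
    m, n = x.shape
    if m < 2:
        raise ValueError("at least 2 chains are required")
    if n < 10:
        raise ValueError("chains must have length >= 10")
    within = x.var(axis=1, ddof=1).mean()
    between = n * x.mean(axis=1).var(ddof=1)
    if within == 0.0:
        return 1.0 if between == 0.0 else np.inf
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))


@dataclass(frozen=True)
class DICResult:
    """Deviance information criterion for a hierarchical fit.

    DIC = D(theta_bar) + 2 pD with pD = mean(D) - D(theta_bar), where the
    deviance is -2 log-likelihood and theta_bar is the posterior mean of
    the parameters on their sampling (transformed) scale.  Lower is better.
    """

    dic: float
    mean_deviance: float
    deviance_at_mean: float
    effective_params: float

    def __post_init__(self) -> None:
        pd_ = self.mean_deviance - self.deviance_at_mean
        if not np.isclose(self.effective_params, pd_, atol=1e-6):
            raise ValueError("pD must equal mean deviance minus deviance at "
                             "the posterior mean")
        if not np.isclose(self.dic, self.deviance_at_mean +
                          2 * self.effective_params, atol=1e-6):
            raise ValueError("DIC must equal deviance-at-mean + 2 pD")

    @classmethod
    def from_deviances(cls, deviance_samples, deviance_at_mean: float) -> "DICResult":
        dbar = float(np.mean(deviance_samples))
        pd_ = dbar - deviance_at_mean
        return cls(dic=deviance_at_mean + 2 * pd_, mean_deviance=dbar,
                   deviance_at_mean=deviance_at_mean, effective_params=pd_)
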