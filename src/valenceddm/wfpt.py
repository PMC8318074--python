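"""Two-boundary Wiener diffusion numerics.

Everything in this module works on the *decision-time* scale of the model,
which for the factory task is the natural log of the response time in
milliseconds (a non-decision offset ``t0`` of ~7.5 corresponds to
``exp(7.5) ~ 1800 ms``).  The diffusion coefficient is fixed at sigma = 1,
so boundary separation, drift and starting point are all expressed in that
convention.

The first-passage density uses the classic small-time / large-time series
pair with an accuracy-based switch between the two expansions (truncation
tolerance 1e-7).  A Euler--Maruyama path simulator with Brownian-bridge
crossing correction serves as an independent brute-force oracle for both the
density and the absorption probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "DDMParams",
    "FirstPassage",
    "fpt_density",
    "choice_probability",
    "simulate_first_passage",
    "simulate_first_passage_batch",
    "trial_loglik",
    "dataset_loglik",
    "GL_NODES",
    "GL_WEIGHTS",
    "TRUNCATION_EPS",
]

#: truncation tolerance of the series representations
TRUNCATION_EPS = 1.0e-7

# 11-node Gauss-Legendre rule on [-1, 1]; used to integrate the uniform
# across-trial starting-point range z +/- sz/2 (smooth integrand, cheap,
# deterministic).
GL_NODES, GL_WEIGHTS = np.polynomial.legendre.leggauss(11)
GL_NODES = np.ascontiguousarray(GL_NODES)
GL_WEIGHTS = np.ascontiguousarray(GL_WEIGHTS)


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters on the log-RT scale (sigma fixed at 1).

    Parameters
    ----------
    threshold_a : float
        Boundary separation; the accumulator starts between 0 and
        ``threshold_a`` and is absorbed at either end.
    nondecision_t0 : float
        Non-decision time.  Observed log-RT = t0 + decision time.
    start_z : float
        Relative starting point in (0, 1); 0.5 is unbiased.
    start_var_sz : float
        Across-trial starting-point range; the realized start is uniform on
        ``z +/- sz/2`` (relative units).
    drift_v : float
        Mean drift toward the upper boundary.
    noise_sigma : float
        Diffusion coefficient.  Fixed at 1 by convention; parameter values
        are only meaningful relative to this choice.
    """

    threshold_a: float
    nondecision_t0: float
    start_z: float
    start_var_sz: float = 0.0
    drift_v: float = 0.0
    noise_sigma: float = field(default=1.0)

    def __post_init__(self) -> None:
        if not np.isfinite([self.threshold_a, self.nondecision_t0,
                            self.start_z, self.start_var_sz,
                            self.drift_v]).all():
            raise ValueError("DDM parameters must be finite")
        if self.threshold_a <= 0:
            raise ValueError(f"threshold_a must be > 0, got {self.threshold_a}")
        if not 0.0 < self.start_z < 1.0:
            raise ValueError(f"start_z must lie in (0, 1), got {self.start_z}")
        if self.start_var_sz < 0:
            raise ValueError("start_var_sz must be >= 0")
        if self.start_z - self.start_var_sz / 2 <= 0 or \
                self.start_z + self.start_var_sz / 2 >= 1:
            raise ValueError("z +/- sz/2 must stay inside (0, 1)")
        if self.nondecision_t0 < 0:
            raise ValueError("nondecision_t0 must be >= 0")
        if self.noise_sigma != 1.0:
            raise ValueError("only the sigma = 1 convention is supported")


@dataclass(frozen=True)
class FirstPassage:
    """A single absorption event of the diffusion."""

    boundary: str  # "upper" or "lower"
    decision_time: float

    def __post_init__(self) -> None:
        if self.boundary not in ("upper", "lower"):
            raise ValueError("boundary must be 'upper' or 'lower'")
        if self.decision_time <= 0:
            raise ValueError("decision_time must be positive")


# ---------------------------------------------------------------------------
# density kernels (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _phi_unit(u, w, eps):
    """First-passage density through the lower boundary for the unit
    (a=1, v=0) process at normalized time ``u``, start ``w``.

    Switches between the small-time and large-time series by comparing the
    number of terms each needs for accuracy ``eps``.
    """
    if u <= 0.0:
        return 0.0
    # terms required by the small-time expansion
    if 2.0 * math.sqrt(2.0 * math.pi * u) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * u)))
        if ks < math.sqrt(u) + 1.0:
            ks = math.sqrt(u) + 1.0
    else:
        ks = 2.0
    # terms required by the large-time expansion
    if math.pi * u * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * eps) / (math.pi * math.pi * u))
        if kl < 1.0 / (math.pi * math.sqrt(u)):
            kl = 1.0 / (math.pi * math.sqrt(u))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))

    p = 0.0
    if ks < kl:
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        for k in range(lo, hi + 1):
            ww = w + 2.0 * k
            p += ww * math.exp(-ww * ww / (2.0 * u))
        p /= math.sqrt(2.0 * math.pi * u * u * u)
    else:
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * \
                math.sin(k * math.pi * w)
        p *= math.pi
    if p < 0.0:
        p = 0.0  # series truncation can leave a tiny negative residue
    return p


@njit(cache=True)
def _wfpt_lower(t, v, a, w, eps):
    """Defective density of absorption at the *lower* boundary at decision
    time ``t`` for drift ``v``, separation ``a``, relative start ``w``."""
    if t <= 0.0:
        return 0.0
    u = t / (a * a)
    arg = -v * a * w - v * v * t / 2.0
    if arg < -700.0:
        return 0.0
    return _phi_unit(u, w, eps) * math.exp(arg) / (a * a)


@njit(cache=True)
def _density_sz(t, v_upper, a, z, sz, upper, nodes, wts, eps):
    """Boundary density at decision time t, averaging over the uniform
    starting-point range when sz > 0.  ``v_upper`` is the drift toward the
    upper boundary; ``upper`` selects which boundary was hit."""
    if upper:
        v_eff = -v_upper
        w_center = 1.0 - z
        sgn = -1.0
    else:
        v_eff = v_upper
        w_center = z
        sgn = 1.0
    if sz <= 0.0:
        return _wfpt_lower(t, v_eff, a, w_center, eps)
    half = sz / 2.0
    dens = 0.0
    for k in range(nodes.size):
        w = w_center + sgn * half * nodes[k]
        dens += 0.5 * wts[k] * _wfpt_lower(t, v_eff, a, w, eps)
    return dens


@njit(cache=True)
def dataset_loglik(log_rt, choice_upper, desir, a, t0, z, sz, b0, b1,
                   nodes, wts, eps):
    """Joint log-likelihood of one subject's trials under the
    valence-dependent drift regression.

    Per trial the signed drift toward the upper (desirable-judgment)
    boundary is ``+(b0 + b1)`` on desirable trials and ``-b0`` on
    undesirable trials; models without a drift bias are the b1 = 0 special
    case.  Returns -inf when any observed log-RT is at or below t0 or the
    starting-point range leaves (0, 1).
    """
    if a <= 0.0 or z <= 0.0 or z >= 1.0 or sz < 0.0:
        return -np.inf
    if z - sz / 2.0 <= 0.0 or z + sz / 2.0 >= 1.0:
        return -np.inf
    total = 0.0
    for i in range(log_rt.size):
        td = log_rt[i] - t0
        if td <= 0.0:
            return -np.inf
        if desir[i] == 1:
            mu = b0 + b1
        else:
            mu = -b0
        dens = _density_sz(td, mu, a, z, sz, choice_upper[i] == 1,
                           nodes, wts, eps)
        if dens < 1e-300:
            dens = 1e-300
        total += math.log(dens)
    return total


# ---------------------------------------------------------------------------
# path simulator (oracle + data generator)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _em_paths(v, a, z, sz, n, dt, seed):
    """Euler-Maruyama first-passage simulation with Brownian-bridge
    crossing correction (removes the O(sqrt(dt)) absorption bias).

    Returns (boundary, decision_time) arrays; boundary 1 = upper.
    ``v`` may be a length-n array of per-path drifts or length-1
    (broadcast).
    """
    np.random.seed(seed)
    out_b = np.empty(n, np.int8)
    out_t = np.empty(n, np.float64)
    sq = math.sqrt(dt)
    for i in range(n):
        vi = v[i] if v.size > 1 else v[0]
        w0 = z
        if sz > 0.0:
            w0 = z + sz * (np.random.random() - 0.5)
        x = w0 * a
        t = 0.0
        while True:
            xn = x + vi * dt + sq * np.random.normal()
            t += dt
            if xn >= a:
                out_b[i] = 1
                break
            if xn <= 0.0:
                out_b[i] = 0
                break
            # bridge probability of an unobserved crossing within the step
            pu = math.exp(-2.0 * (a - x) * (a - xn) / dt)
            pl = math.exp(-2.0 * x * xn / dt)
            r = np.random.random()
            if r < pu:
                out_b[i] = 1
                break
            if r < pu + pl:
                out_b[i] = 0
                break
            x = xn
        out_t[i] = t
    return out_b, out_t


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _check_boundary(boundary: str) -> bool:
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    return boundary == "upper"


def fpt_density(t, boundary: str, params: DDMParams) -> float | np.ndarray:
    """Defective first-passage density at observed log-RT ``t``.

    The density is zero for ``t <= t0`` and, summed over both boundaries and
    integrated over all times, totals one.  ``t`` may be a scalar or array.
    """
    upper = _check_boundary(boundary)
    t_arr = np.asarray(t, dtype=float)
    if not np.isfinite(t_arr).all():
        raise ValueError("t must be finite")
    td = t_arr - params.nondecision_t0
    out = np.zeros_like(td, dtype=float)
    it = np.nditer(td, flags=["multi_index"])
    for val in it:
        out[it.multi_index] = _density_sz(
            float(val), params.drift_v, params.threshold_a, params.start_z,
            params.start_var_sz, upper, GL_NODES, GL_WEIGHTS, TRUNCATION_EPS)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _choice_prob_point(v: float, a: float, z: float) -> float:
    if v == 0.0:
        return z
    # guard the exp ratio for large |v*a|
    num = -math.expm1(-2.0 * v * a * z)
    den = -math.expm1(-2.0 * v * a)
    if den == 0.0:
        return z
    if not math.isfinite(num) or not math.isfinite(den):
        # both overflow: limit for v -> -inf is 0, v -> +inf is 1
        return 1.0 if v > 0 else 0.0
    return num / den


def choice_probability(params: DDMParams) -> float:
    """Probability of absorption at the upper boundary.

    Closed form ``(1 - exp(-2 v a z)) / (1 - exp(-2 v a))`` for sz = 0
    (``z`` itself at zero drift); for sz > 0 the uniform starting-point
    range is averaged by Gauss-Legendre quadrature.
    """
    a, z, v, sz = (params.threshold_a, params.start_z, params.drift_v,
                   params.start_var_sz)
    if sz == 0.0:
        return _choice_prob_point(v, a, z)
    half = sz / 2.0
    zs = z + half * GL_NODES
    return float(sum(0.5 * w * _choice_prob_point(v, a, zi)
                     for w, zi in zip(GL_WEIGHTS, zs)))


def simulate_first_passage(params: DDMParams, rng: np.random.Generator,
                           dt: float = 1.0e-4) -> FirstPassage:
    """Simulate one absorption event by Euler-Maruyama with bridge
    correction; the starting point is drawn uniformly on z +/- sz/2."""
    b, t = simulate_first_passage_batch(params, 1, rng, dt=dt)
    return FirstPassage("upper" if b[0] == 1 else "lower", float(t[0]))


def simulate_first_passage_batch(params: DDMParams, n: int,
                                 rng: np.random.Generator,
                                 dt: float = 1.0e-4,
                                 drifts: np.ndarray | None = None):
    """Simulate ``n`` first passages; returns (boundary, decision_time)
    arrays with boundary coded 1 = upper.  ``drifts`` optionally overrides
    the drift per path (used when drift varies by trial)."""
    if dt <= 0:
        raise ValueError("step size dt must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    if drifts is None:
        v = np.array([params.drift_v], dtype=float)
    else:
        v = np.ascontiguousarray(drifts, dtype=float)
        if v.size != n:
            raise ValueError("drifts must have length n")
    seed = int(rng.integers(0, 2**31 - 1))
    return _em_paths(v, params.threshold_a, params.start_z,
                     params.start_var_sz, n, dt, seed)


def trial_loglik(log_rt: float, choice: str, params: DDMParams) -> float:
    """Log-likelihood of one (log-RT, choice) observation.

    ``choice`` maps to the boundary hit ('upper'/'lower').  Observations at
    or below t0 are impossible under the model and return -inf rather than
    raising.  sz > 0 is integrated by fixed-node quadrature.
    """
    upper = _check_boundary(choice)
    if not np.isfinite(log_rt):
        raise ValueError("log_rt must be finite")
    td = log_rt - params.nondecision_t0
    if td <= 0:
        return -np.inf
    dens = _density_sz(td, params.drift_v, params.threshold_a, params.start_z,
                       params.start_var_sz, upper, GL_NODES, GL_WEIGHTS,
                       TRUNCATION_EPS)
    if dens <= 0:
        return -np.inf
    return math.log(dens)
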