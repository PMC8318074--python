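"""Model space for the valence-dependent drift-diffusion family.

Four nested specifications of the factory-game DDM differ in whether the
starting point is free (a valence-dependent response bias toward the
desirable judgment) and whether the drift rate carries a valence bias
(``v = b0 + b1 * desirability``, desirability coded 1 on desirable-state
trials and 0 on undesirable-state trials):

====  ===============================================  =========  ==========
id    model                                            z          drift
====  ===============================================  =========  ==========
1     valence independent                              0.5        v, -v
2     valence-dependent starting point                 free       v, -v
3     valence-dependent drift rate                     0.5        b0 + b1*d
4     valence-dependent drift rate and starting point  free       b0 + b1*d
====  ===============================================  =========  ==========

Boundary convention (fixed throughout the package): the *upper* boundary is
the desirable-state judgment, so z > 0.5 and b1 > 0 both mean "biased
toward desirable conclusions".  The signed drift toward the upper boundary
is ``+(b0 + b1)`` on desirable trials and ``-b0`` on undesirable trials;
models 1-2 are exactly the ``b1 = 0`` special case of this regression, with
``b0`` playing the role of the symmetric drift magnitude v.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelSpec",
    "DriftRegression",
    "GroupPrior",
    "GroupParams",
    "build_model",
    "drift_rate",
    "signed_drift",
    "map_boundaries",
    "BOUNDARY_UPPER",
    "BOUNDARY_LOWER",
    "PARAM_BOUNDS",
    "DEFAULT_PRIOR",
    "CONTROL_REFERENCE_PARAMS",
    "THREAT_REFERENCE_PARAMS",
]

#: which judgment each absorbing boundary encodes, for every model
BOUNDARY_UPPER = "desirable"
BOUNDARY_LOWER = "undesirable"

#: hard support for each parameter on its natural scale; priors are flat
#: within these generous, physically sensible ranges
PARAM_BOUNDS = {
    "a": (0.3, 6.0),
    "t0": (0.01, 10.0),
    "z": (0.05, 0.95),
    "sz": (0.0, 0.6),
    "b0": (-5.0, 5.0),
    "b1": (-5.0, 5.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the four specifications: which parameters are free."""

    model_id: int
    free_starting_point: bool
    valence_dependent_drift: bool

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, 4):
            raise ValueError(f"unknown model id {self.model_id}")
        expect_z = self.model_id in (2, 4)
        expect_v = self.model_id in (3, 4)
        if (self.free_starting_point, self.valence_dependent_drift) != \
                (expect_z, expect_v):
            raise ValueError("free/fixed pattern inconsistent with model id")

    @property
    def name(self) -> str:
        return {
            1: "valence independent",
            2: "valence-dependent starting point",
            3: "valence-dependent drift rate",
            4: "valence-dependent drift rate and starting point",
        }[self.model_id]


def build_model(model_id: int) -> ModelSpec:
    """Return the ModelSpec for one of the four numbered specifications."""
    if model_id not in (1, 2, 3, 4):
        raise ValueError(f"unknown model id {model_id!r}")
    return ModelSpec(model_id,
                     free_starting_point=model_id in (2, 4),
                     valence_dependent_drift=model_id in (3, 4))


@dataclass(frozen=True)
class DriftRegression:
    """Drift regression ``v = v_intercept + v_bias * desirability``."""

    v_intercept: float
    v_bias: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.v_intercept) or not np.isfinite(self.v_bias):
            raise ValueError("drift regression coefficients must be finite")


def drift_rate(reg: DriftRegression, desirability_code: int) -> float:
    """Drift magnitude toward the correct boundary on a trial with the given
    desirability code (1 = desirable state, 0 = undesirable state)."""
    if desirability_code not in (0, 1):
        raise ValueError("desirability_code must be 0 or 1")
    return reg.v_intercept + reg.v_bias * desirability_code


def signed_drift(reg: DriftRegression, desirability_code: int) -> float:
    """Signed drift toward the *upper* (desirable-judgment) boundary.

    Evidence on a desirable-state trial pushes toward the desirable
    judgment (+) and on an undesirable-state trial toward the undesirable
    judgment (-); the regression sets the magnitude per valence.
    """
    v = drift_rate(reg, desirability_code)
    return v if desirability_code == 1 else -v


def map_boundaries(spec: ModelSpec, desirability_code: int,
                   reg: DriftRegression | None = None) -> dict:
    """Boundary assignment and effective signed drift for one trial.

    Upper always encodes the desirable-state judgment.  For models 1-2 pass
    the symmetric drift magnitude as ``reg.v_intercept`` (``v_bias`` must be
    0); the effective drift is +v on desirable trials and -v on undesirable
    trials.
    """
    if reg is None:
        reg = DriftRegression(0.0, 0.0)
    if not spec.valence_dependent_drift and reg.v_bias != 0.0:
        raise ValueError(f"model {spec.model_id} has no drift bias; "
                         "v_bias must be 0")
    return {
        "upper": BOUNDARY_UPPER,
        "lower": BOUNDARY_LOWER,
        "drift": signed_drift(reg, desirability_code),
    }


@dataclass(frozen=True)
class GroupPrior:
    """Hyperprior settings for hierarchical estimation.

    Group means are flat within PARAM_BOUNDS (mapped to each parameter's
    sampling scale); group spreads are half-normal on the sampling scale.
    Sampling scales: log(a), log(t0), logit(z), identity for the drift
    terms.  sz is a single group-level scalar with a flat prior on
    [0, 0.6).
    """

    sd_scales: tuple = (0.5, 0.5, 1.0, 0.5, 0.5)  # a, t0, z, b0, b1


DEFAULT_PRIOR = GroupPrior()


@dataclass(frozen=True)
class GroupParams:
    """Group-level generating parameters for simulation.

    Means are on the natural scale; subject-level values are drawn on the
    sampling scale (log a, log t0, logit z, identity drifts), matching the
    hierarchical model fitted to the data.  sz is shared across subjects.
    """

    a: float
    t0: float
    z: float
    sz: float
    b0: float
    b1: float
    sd_log_a: float = 0.08
    sd_log_t0: float = 0.013
    sd_logit_z: float = 0.15
    sd_b0: float = 0.15
    sd_b1: float = 0.12
    label: str = ""

    def __post_init__(self) -> None:
        lo, hi = PARAM_BOUNDS["a"]
        if not lo < self.a < hi:
            raise ValueError(f"a outside {PARAM_BOUNDS['a']}")
        if not 0 < self.z < 1:
            raise ValueError("z must lie in (0, 1)")
        if not 0 <= self.sz < min(2 * self.z, 2 * (1 - self.z)):
            raise ValueError("sz incompatible with z staying inside (0, 1)")
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        for s in (self.sd_log_a, self.sd_log_t0, self.sd_logit_z,
                  self.sd_b0, self.sd_b1):
            if s < 0:
                raise ValueError("subject-level spreads must be >= 0")

    def drift_regression(self) -> DriftRegression:
        return DriftRegression(self.b0, self.b1)


# Published group-level estimates for the incentivized factory task, used
# as the simulator's default generating conditions.  Subject-level spreads
# are not reported for the task; the defaults above are modest values
# consistent with the visible between-subject scatter of drift-bias
# estimates (see docs/methods.md).
CONTROL_REFERENCE_PARAMS = GroupParams(
    a=2.67, t0=7.55, z=0.48, sz=0.18, b0=0.46, b1=0.17, label="control")
THREAT_REFERENCE_PARAMS = GroupParams(
    a=2.47, t0=7.49, z=0.51, sz=0.19, b0=0.63, b1=-0.08, label="threat")
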