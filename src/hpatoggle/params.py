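"""Parameter and state containers for the HPA-CNS toggle-switch model.

The model tracks the three HPA hormones (CRH ``x1``, ACTH ``x2``, cortisol
``x3``), the functional masses of the pituitary corticotrophs ``P`` and the
adrenal cortex ``A``, and a lumped CNS inhibitory activity ``h``
(hippocampus / prefrontal cortex).  All quantities are dimensionless,
normalized so that the healthy (euthymic) baseline of every variable is 1.

The canonical time unit is **days**.  Hormone secretion/removal rates are
customarily quoted per minute (lifetimes of minutes); they are converted to
per-day at construction so that the fast hormone dynamics and the slow
(weeks-scale) gland/CNS dynamics share one clock.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

MINUTES_PER_DAY = 1440.0


class DomainError(ValueError):
    """A state or argument left the model's admissible domain."""


class ConfigError(ValueError):
    """Invalid configuration or parameter input."""


class IntegrationError(RuntimeError):
    """The ODE solver failed or did not converge."""


#: rate-constant fields (all strictly positive, units 1/day except the
#: secretion parameters which carry the normalized-ligand factors)
RATE_FIELDS = ("a1", "b1", "a2", "b2", "a3", "b3",
               "aP", "bP", "aA", "bA", "ah", "bh")

#: every numeric parameter field, in a stable order
PARAM_FIELDS = RATE_FIELDS + ("a", "b", "T", "KMR", "KGR", "n_GR")


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, receptor constants, and CNS parameters.

    Defaults are the nominal values of the model: hormone rates 0.17,
    0.035, 0.0086 per minute (CRH, ACTH, cortisol), gland turnover 0.049
    and 0.099 per day (pituitary, adrenal), CNS turnover 0.047 per day,
    CNS inhibition divisors a = 1 (below threshold) and a + b = 2 (above),
    and CNS GR activation threshold T = 1.5 normalized cortisol units.
    """

    # hormone secretion/removal (converted from per-minute to per-day)
    a1: float = 0.17 * MINUTES_PER_DAY   # CRH secretion
    b1: float = 0.17 * MINUTES_PER_DAY   # CRH removal
    a2: float = 0.035 * MINUTES_PER_DAY  # ACTH secretion (per unit CRH*P)
    b2: float = 0.035 * MINUTES_PER_DAY  # ACTH removal
    a3: float = 0.0086 * MINUTES_PER_DAY  # cortisol secretion (per ACTH*A)
    b3: float = 0.0086 * MINUTES_PER_DAY  # cortisol removal
    # gland functional-mass turnover, per day (the slow, weeks timescale)
    aP: float = 0.049   # pituitary mass production per unit CRH
    bP: float = 0.049   # pituitary mass removal
    aA: float = 0.099   # adrenal mass production per unit ACTH
    bA: float = 0.099   # adrenal mass removal
    # CNS inhibitory activity production/removal, per day
    ah: float = 0.047
    bh: float = 0.047
    # CNS inhibition of the HPA input: divisor a below the cortisol
    # threshold T, a + b above it (GR recruitment)
    a: float = 1.0
    b: float = 1.0
    T: float = 1.5
    # receptor dissociation constants, normalized cortisol units
    # (MR high-affinity, non-cooperative; GR low-affinity, Hill n_GR)
    KMR: float = 0.1
    KGR: float = 5.0
    n_GR: float = 3.0
    time_unit: str = "day"

    def __post_init__(self) -> None:
        for name in PARAM_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ConfigError(
                    f"parameter {name!r} must be a positive finite number, "
                    f"got {value!r}")
        if not self.KMR < self.KGR:
            raise ConfigError(
                f"KMR must be smaller than KGR (got KMR={self.KMR}, "
                f"KGR={self.KGR})")
        if self.time_unit != "day":
            raise ConfigError("only time_unit='day' is supported")

    # -- derived quantities -------------------------------------------------

    def h_high(self, D: float = 1.0) -> float:
        """CNS activity on the low-cortisol branch, ah*D/(bh*a)."""
        return self.ah * D / (self.bh * self.a)

    def h_low(self, D: float = 1.0) -> float:
        """CNS activity on the high-cortisol branch, ah*D/(bh*(a+b))."""
        return self.ah * D / (self.bh * (self.a + self.b))

    @property
    def cortisol_gain(self) -> float:
        """Prefactor of the slow cortisol steady state x3 = gain * u/h."""
        return self.a1 * self.aP / (self.b1 * self.bP)

    # -- plumbing -----------------------------------------------------------

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_FIELDS}

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "ModelParameters":
        unknown = set(values) - set(PARAM_FIELDS)
        if unknown:
            raise ConfigError(
                f"unknown parameter key(s): {sorted(unknown)}; "
                f"valid keys are {list(PARAM_FIELDS)}")
        return cls(**values)


#: order of SystemState components in flat arrays
STATE_FIELDS = ("x1", "x2", "x3", "P", "A", "h", "c_ex", "d_ex")


@dataclass(frozen=True)
class SystemState:
    """Instantaneous model state (all components normalized, >= 0).

    ``c_ex`` is exogenous (synthetic) CRH and ``d_ex`` the exogenous
    dexamethasone level in cortisol-equivalent GR units; both default to
    zero and are only nonzero during endocrine-test protocols.
    """

    x1: float = 1.0
    x2: float = 1.0
    x3: float = 1.0
    P: float = 1.0
    A: float = 1.0
    h: float = 1.0
    c_ex: float = 0.0
    d_ex: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise DomainError(
                    f"state component {name!r} must be non-negative, "
                    f"got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_FIELDS],
                        dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "SystemState":
        return cls(**dict(zip(STATE_FIELDS, map(float, values))))

    def replace(self, **changes: float) -> "SystemState":
        return replace(self, **changes)
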