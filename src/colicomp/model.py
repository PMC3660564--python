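"""Core two-strain bacteriocin competition model.

Two bacteriocin-producing strains, A and B, grow logistically toward a shared
carrying capacity (normalized to 1), die at a background rate, and poison each
other with diffusible toxins.  The defining feature of the model is
*cross-induction*: the competitor's toxin raises a strain's own toxin
production above the basal (SOS-leakage) level, mimicking the SOS-mediated
induction of colicin operons by DNA-damaging colicins.

State variables (all dimensionless, time units abstract):

    u_A, u_B  strain frequencies relative to carrying capacity, in [0, 1]
    c_A, c_B  density of the toxin produced by each strain, >= 0

Dynamics, for i in {A, B} and j the competitor:

    du_i/dt = beta_i*u_i*(1 - u_A - u_B) - delta*u_i
              - kill_jOni*c_j*u_i - epsilon*(s + induce_jOni*c_j)*u_i
    dc_i/dt = (s + induce_jOni*c_j)*u_i - d*c_i

Killing and induction are parameterized per ordered pair (toxin -> target
strain), which makes both published readings of the per-strain symbols
gamma_i / l_i expressible without ambiguity (see :func:`make_params`).

The optional ``epsilon`` term charges the lysis cost of toxin release to the
producer: colicin export requires the producing cell to lyse, so production
can be made intrinsically lethal.  The default ``epsilon = 0`` models
pure-benefit induction.

The equation system is a reconstruction: it is the minimal ODE system
consistent with every stated ingredient of the biology (logistic growth to a
shared carrying capacity, background death, killing by the competitor's toxin,
basal production ``s``, induction proportional to the competitor's toxin, and
first-order toxin decay ``d``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "CommunityParams",
    "State",
    "make_params",
    "rhs_homogeneous",
    "rhs_arrays",
]

#: Accepted values of the gamma/l interpretation flag.
SEMANTICS = ("strain_attributed", "toxin_attributed")


@dataclass(frozen=True)
class CommunityParams:
    """All constants of the two-strain cross-induction community.

    Rates are per unit (abstract) time; kill and induction coefficients are
    per (toxin density x time); ``D_u`` / ``D_c`` are length^2/time and only
    used by the spatial model.
    """

    beta_A: float = 1.0          # growth rate of strain A
    beta_B: float = 1.0          # growth rate of strain B
    delta: float = 0.1           # death rate without toxin exposure
    kill_AonB: float = 0.0       # toxin A killing strain B
    kill_BonA: float = 0.0       # toxin B killing strain A
    induce_AonB: float = 0.0     # toxin A inducing strain B's production
    induce_BonA: float = 0.0     # toxin B inducing strain A's production
    s: float = 0.05              # basal toxin production rate
    d: float = 1.0               # toxin disassembly rate (> 0)
    epsilon: float = 0.0         # lysis-cost coefficient
    D_u: float = 0.1             # bacterial surface-spreading coefficient
    D_c: float = 1.0             # toxin diffusion coefficient

    def __post_init__(self) -> None:
        for name in (
            "beta_A", "beta_B", "delta", "kill_AonB", "kill_BonA",
            "induce_AonB", "induce_BonA", "s", "epsilon", "D_u", "D_c",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"parameter {name!r} must be finite and >= 0, got {value}"
                )
        if not np.isfinite(self.d) or self.d <= 0:
            raise ValueError(
                f"parameter 'd' must be > 0 (toxin must decay), got {self.d}"
            )

    def replace(self, **changes: float) -> "CommunityParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))


@dataclass
class State:
    """Well-mixed community state: strain frequencies and toxin densities."""

    u_A: float
    u_B: float
    c_A: float = 0.0
    c_B: float = 0.0

    def __post_init__(self) -> None:
        for name in ("u_A", "u_B", "c_A", "c_B"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"state component {name!r} must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.u_A, self.u_B, self.c_A, self.c_B], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "State":
        return cls(*(float(v) for v in y))


# Aliases resolved by make_params on top of the raw per-pair field names.
_ALIAS_KEYS = {"beta", "gamma_A", "gamma_B", "l_A", "l_B", "semantics"}


def make_params(raw: Mapping[str, object]) -> CommunityParams:
    """Validate a flat mapping of model constants into :class:`CommunityParams`.

    Accepts either the explicit per-pair field names (``kill_AonB``,
    ``induce_BonA``, ...) or the conventional per-strain symbols ``gamma_i``
    and ``l_i`` together with a ``semantics`` flag that fixes their reading:

    ``strain_attributed`` (default)
        gamma_i is the *sensitivity of strain i* to the competitor's toxin
        (gamma_A -> kill_BonA) and l_i is strain i's *responsiveness*, i.e.
        how strongly the competitor's toxin induces strain i's own production
        (l_A -> induce_BonA).

    ``toxin_attributed``
        gamma_i is the *toxicity of toxin i* against the competitor
        (gamma_A -> kill_AonB) and l_i is the induction that toxin i exerts
        on the competitor (l_A -> induce_AonB).

    A bare ``beta`` sets both growth rates.  Unknown keys are rejected.
    """
    raw = dict(raw)
    semantics = str(raw.pop("semantics", "strain_attributed"))
    if semantics not in SEMANTICS:
        raise ValueError(
            f"semantics must be one of {SEMANTICS}, got {semantics!r}"
        )

    known = set(CommunityParams.field_names())
    unknown = set(raw) - known - _ALIAS_KEYS
    if unknown:
        raise ValueError(
            f"unknown parameter keys {sorted(unknown)}; "
            f"valid keys are {sorted(known | _ALIAS_KEYS)}"
        )

    values: dict[str, float] = {
        k: float(v) for k, v in raw.items() if k in known  # type: ignore[arg-type]
    }
    if "beta" in raw:
        b = float(raw["beta"])  # type: ignore[arg-type]
        values.setdefault("beta_A", b)
        values.setdefault("beta_B", b)

    if semantics == "strain_attributed":
        alias_map = {
            "gamma_A": "kill_BonA", "gamma_B": "kill_AonB",
            "l_A": "induce_BonA", "l_B": "induce_AonB",
        }
    else:
        alias_map = {
            "gamma_A": "kill_AonB", "gamma_B": "kill_BonA",
            "l_A": "induce_AonB", "l_B": "induce_BonA",
        }
    for alias, field in alias_map.items():
        if alias in raw:
            if field in values:
                raise ValueError(
                    f"both {alias!r} and {field!r} given; specify one"
                )
            values[field] = float(raw[alias])  # type: ignore[arg-type]

    return CommunityParams(**values)


def rhs_arrays(
    u_A, u_B, c_A, c_B, params: CommunityParams, epsilon: float | None = None
):
    """Reaction terms, vectorized over array-valued fields.

    Returns ``(du_A, du_B, dc_A, dc_B)`` with the same shape as the inputs.
    This is the single source of the reaction kinetics; the well-mixed and
    spatial integrators both call it.
    """
    p = params
    eps = p.epsilon if epsilon is None else epsilon
    crowding = 1.0 - u_A - u_B
    prod_A = p.s + p.induce_BonA * c_B   # per-capita toxin output of strain A
    prod_B = p.s + p.induce_AonB * c_A
    du_A = (p.beta_A * crowding - p.delta - p.kill_BonA * c_B - eps * prod_A) * u_A
    du_B = (p.beta_B * crowding - p.delta - p.kill_AonB * c_A - eps * prod_B) * u_B
    dc_A = prod_A * u_A - p.d * c_A
    dc_B = prod_B * u_B - p.d * c_B
    return du_A, du_B, dc_A, dc_B


def rhs_homogeneous(state: State | np.ndarray, params: CommunityParams) -> np.ndarray:
    """Time derivative of the well-mixed system as a length-4 array.

    Component order matches :meth:`State.as_array`:
    ``[du_A, du_B, dc_A, dc_B]``.  Pure function; never raises on valid input.
    """
    y = state.as_array() if isinstance(state, State) else np.asarray(state, float)
    return np.array(rhs_arrays(y[0], y[1], y[2], y[3], params), dtype=float)
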