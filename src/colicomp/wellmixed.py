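"""Well-mixed (unstructured-environment) competition dynamics.

Integrates the homogeneous cross-induction model, classifies the outcome of a
pairwise competition, locates the critical initial relative frequency rho_c
above which the focal strain excludes its competitor, and sweeps parameter
grids into phase diagrams.

The well-mixed community is bistable over much of parameter space: either
strain can dominate depending on the initial frequencies, so the basin
boundary along the initial-relative-frequency axis (rho_c) is the natural
summary of who wins from where.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import CommunityParams, State, rhs_homogeneous

__all__ = [
    "IntegrationControl",
    "Trajectory",
    "Outcome",
    "integrate_well_mixed",
    "classify_outcome",
    "single_strain_equilibrium",
    "find_critical_frequency",
    "CriticalFrequencyResult",
    "phase_diagram",
    "PhaseDiagram",
]

# Negative undershoots smaller than this are discretization noise and are
# clipped to zero; anything larger aborts the run.
_CLIP_TOL = 1e-12


@dataclass(frozen=True)
class IntegrationControl:
    """Integrator settings recorded alongside every trajectory."""

    rtol: float = 1e-8
    atol: float = 1e-13
    max_step: float = 1.0
    n_samples: int = 201
    method: str = "RK45"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


@dataclass
class Trajectory:
    """Time-indexed states of one well-mixed run.

    ``states`` has shape (n_times, 4) in the order (u_A, u_B, c_A, c_B).
    ``meta`` records the control settings, the terminal derivative norm and
    any clipping that occurred.
    """

    times: np.ndarray
    states: np.ndarray
    params: CommunityParams
    meta: dict = field(default_factory=dict)

    @property
    def u_A(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def u_B(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def c_A(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def c_B(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def final_state(self) -> State:
        return State.from_array(self.states[-1])


OutcomeLabel = Literal["A_wins", "B_wins", "coexistence", "both_extinct", "undecided"]


@dataclass
class Outcome:
    """Classification of a competition run."""

    label: OutcomeLabel
    final_state: State
    crash_depth: float          # min over time of u_A + u_B
    meta: dict = field(default_factory=dict)


class IntegrationError(RuntimeError):
    pass


def integrate_well_mixed(
    params: CommunityParams,
    init: State,
    horizon: float,
    control: IntegrationControl | None = None,
) -> Trajectory:
    """Integrate the homogeneous model from ``init`` for ``horizon`` time units.

    Uses an explicit adaptive Runge-Kutta scheme with a user-fixed maximum
    step.  Negative undershoots of magnitude below 1e-12 (pure discretization
    noise; every loss term in the model is proportional to the variable it
    depletes, so the exact flow preserves nonnegativity) are clipped to zero
    and counted in ``meta['clipped']``; larger undershoots or non-finite
    values abort with the time of failure.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    ctrl = control or IntegrationControl()

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return rhs_homogeneous(y, params)

    times = np.linspace(0.0, horizon, ctrl.n_samples)
    sol = solve_ivp(
        f,
        (0.0, horizon),
        init.as_array(),
        method=ctrl.method,
        t_eval=times,
        rtol=ctrl.rtol,
        atol=ctrl.atol,
        max_step=ctrl.max_step,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    y = sol.y.T
    if not np.all(np.isfinite(y)):
        t_bad = times[np.argmax(~np.isfinite(y).all(axis=1))]
        raise IntegrationError(f"non-finite state at t = {t_bad:g}")
    negative = y < 0
    if np.any(y < -_CLIP_TOL):
        t_bad = times[np.argmax((y < -_CLIP_TOL).any(axis=1))]
        raise IntegrationError(
            f"state undershot below -{_CLIP_TOL:g} at t = {t_bad:g}; "
            "reduce step size / tolerances"
        )
    n_clipped = int(negative.sum())
    y = np.clip(y, 0.0, None)

    terminal_rate = float(np.linalg.norm(rhs_homogeneous(y[-1], params)))
    meta = {
        "control": dataclasses.asdict(ctrl),
        "clipped": n_clipped,
        "terminal_derivative_norm": terminal_rate,
    }
    return Trajectory(times=times, states=y, params=params, meta=meta)


def classify_outcome(
    traj: Trajectory,
    extinction_threshold: float = 1e-6,
    persistence_threshold: float = 1e-2,
    settle_tol: float = 1e-5,
) -> Outcome:
    """Label the terminal state of a competition trajectory.

    A strain "wins" when it sits above the persistence threshold while its
    competitor is below the extinction threshold.  ``crash_depth`` is the
    minimum of the total density u_A + u_B over the run; a crash far below the
    initial total is the signature of mutual strong induction (a transiently
    highly toxic medium in which both strains decline before one recovers).
    A trajectory whose terminal derivative norm exceeds ``settle_tol`` is
    labelled ``undecided``.
    """
    if extinction_threshold >= persistence_threshold:
        raise ValueError(
            "extinction_threshold must be strictly below persistence_threshold"
        )
    final = traj.final_state
    total = traj.u_A + traj.u_B
    crash_depth = float(total.min())
    settled = traj.meta.get("terminal_derivative_norm", np.inf) < settle_tol

    label: OutcomeLabel
    if not settled:
        label = "undecided"
    elif final.u_A <= extinction_threshold and final.u_B <= extinction_threshold:
        label = "both_extinct"
    elif final.u_A >= persistence_threshold and final.u_B <= extinction_threshold:
        label = "A_wins"
    elif final.u_B >= persistence_threshold and final.u_A <= extinction_threshold:
        label = "B_wins"
    elif final.u_A >= persistence_threshold and final.u_B >= persistence_threshold:
        label = "coexistence"
    else:
        label = "undecided"
    meta = {
        "extinction_threshold": extinction_threshold,
        "persistence_threshold": persistence_threshold,
        "settle_tol": settle_tol,
        "settled": settled,
    }
    return Outcome(label=label, final_state=final, crash_depth=crash_depth, meta=meta)


def run_competition(
    params: CommunityParams,
    init: State,
    horizon: float = 200.0,
    control: IntegrationControl | None = None,
    max_doublings: int = 4,
    **classify_kw,
) -> tuple[Trajectory, Outcome]:
    """Integrate and classify, doubling the horizon while undecided.

    The horizon doubles up to ``max_doublings`` times before the run is
    accepted as ``undecided``.
    """
    h = horizon
    for _ in range(max_doublings + 1):
        traj = integrate_well_mixed(params, init, h, control)
        outcome = classify_outcome(traj, **classify_kw)
        if outcome.label != "undecided":
            return traj, outcome
        h *= 2.0
    return traj, outcome


def single_strain_equilibrium(params: CommunityParams) -> tuple[float, float]:
    """Positive fixed point (u*, c*) of the single-strain subsystem.

    With strain B absent there is no cross-induction, so strain A settles at

        u* = 1 - (delta + epsilon*s) / beta_A,   c* = s * u* / d.

    Returns (0, 0) with a warning when the strain cannot persist alone
    (beta <= delta + epsilon*s).
    """
    import warnings

    loss = params.delta + params.epsilon * params.s
    if params.beta_A <= loss:
        warnings.warn(
            "strain cannot persist alone (growth rate does not exceed losses)",
            stacklevel=2,
        )
        return 0.0, 0.0
    u_star = 1.0 - loss / params.beta_A
    c_star = params.s * u_star / params.d
    return u_star, c_star


def cumulative_growth(traj: Trajectory, strain: Literal["A", "B"] = "A") -> float:
    """Non-degradable-reporter readout: all cells of a strain ever produced.

    Emulates following a competition through a constitutive GFP label that
    is not degraded on cell death: the signal at the end of a run is the
    initial density plus the time-integral of gross growth
    ``beta * u * (1 - u_A - u_B)``, counting every division including those
    that merely replaced killed cells.  This is the quantity a plate reader
    tracking a labelled competitor reports, and unlike the instantaneous
    density it retains the history of the fight.
    """
    beta = traj.params.beta_A if strain == "A" else traj.params.beta_B
    u = traj.u_A if strain == "A" else traj.u_B
    gross = beta * u * (1.0 - traj.u_A - traj.u_B)
    return float(u[0] + np.trapezoid(gross, traj.times))


@dataclass
class CriticalFrequencyResult:
    """Result of the rho_c bisection.

    ``status`` is ``"ok"`` when a B->A outcome switch was bracketed and
    bisected, or ``"no_crossing"`` when both endpoints give the same winner
    (rho_c is then ``nan``).  ``monotone`` reports whether the coarse pre-scan
    showed a single B->A switch; a non-monotone scan is reported, not hidden.
    """

    rho_c: float
    bracket: tuple[float, float]
    status: Literal["ok", "no_crossing"]
    monotone: bool
    scan: list[tuple[float, str]]


def _outcome_at_rho(
    rho: float,
    params: CommunityParams,
    u_total: float,
    c_init: float,
    horizon: float,
    control: IntegrationControl | None,
    classify_kw: dict,
    lean: bool = False,
) -> str:
    init = State(u_A=rho * u_total, u_B=(1.0 - rho) * u_total, c_A=c_init, c_B=c_init)
    _, outcome = run_competition(params, init, horizon, control, **classify_kw)
    if outcome.label in ("A_wins", "B_wins") or not lean:
        return outcome.label
    # Bistable exclusion is the generic outcome; if a run near the basin
    # boundary fails to settle, lean on which strain is ahead.
    return "A_wins" if outcome.final_state.u_A >= outcome.final_state.u_B else "B_wins"


def find_critical_frequency(
    params: CommunityParams,
    u_total: float = 0.1,
    c_init: float = 0.0,
    tol: float = 1e-3,
    horizon: float = 200.0,
    control: IntegrationControl | None = None,
    n_scan: int = 5,
    **classify_kw,
) -> CriticalFrequencyResult:
    """Critical initial relative frequency of strain A by bisection.

    The system starts at fixed total density ``u_total`` split as
    u_A(0) = rho*u_total, u_B(0) = (1-rho)*u_total, with equal initial toxin
    densities ``c_init`` (default 0).  rho_c is the boundary between the
    B-wins basin (small rho) and the A-wins basin (large rho), bisected to a
    bracket width <= ``tol`` and reported as the bracket midpoint.

    A coarse ``n_scan``-point pre-scan checks that the outcome switches from
    B to A exactly once; violations are reported in the result rather than
    silently bisected over.
    """
    if not 0 < tol < 1:
        raise ValueError("tol must be in (0, 1)")
    rhos = np.linspace(0.0, 1.0, max(n_scan, 3))
    scan = [
        (float(r), _outcome_at_rho(r, params, u_total, c_init, horizon, control, classify_kw))
        for r in rhos
    ]
    labels = [lab for _, lab in scan]
    if not (labels[0] == "B_wins" and labels[-1] == "A_wins"):
        # no clean B-basin-to-A-basin transition along rho: either the same
        # strain wins at both ends, or an endpoint fails to resolve to a
        # single winner (e.g. a strain that cannot persist alone)
        return CriticalFrequencyResult(
            rho_c=float("nan"), bracket=(0.0, 1.0), status="no_crossing",
            monotone=all(l == labels[0] for l in labels), scan=scan,
        )
    # monotone: all B wins precede all A wins, with non-winner labels (the
    # knife-edge separatrix can classify as coexistence/undecided) allowed
    # only inside the transition zone
    b_idx = [i for i, l in enumerate(labels) if l == "B_wins"]
    a_idx = [i for i, l in enumerate(labels) if l == "A_wins"]
    other_idx = [i for i, l in enumerate(labels) if l not in ("A_wins", "B_wins")]
    monotone = (
        max(b_idx) < min(a_idx)
        and all(max(b_idx) < i < min(a_idx) for i in other_idx)
    )

    # bisect the (first) B->A switch interval
    lo, hi = 0.0, 1.0
    for (r0, l0), (r1, l1) in zip(scan, scan[1:]):
        if l0 != "A_wins" and l1 == "A_wins":
            lo, hi = r0, r1
            break
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lab = _outcome_at_rho(mid, params, u_total, c_init, horizon, control,
                              classify_kw, lean=True)
        if lab == "A_wins":
            hi = mid
        else:
            lo = mid
    return CriticalFrequencyResult(
        rho_c=0.5 * (lo + hi), bracket=(lo, hi), status="ok",
        monotone=monotone, scan=scan,
    )


@dataclass
class PhaseDiagram:
    """Grid of competition outcomes over two swept parameters.

    ``values`` is row-major with shape (len(axis1), len(axis2)): rows index
    ``axis1_values``, columns ``axis2_values``.  In ``winner`` mode entries
    are outcome labels; in ``rho_c`` mode they are critical frequencies.
    """

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    mode: Literal["winner", "rho_c"]
    values: np.ndarray
    base_params: CommunityParams


def phase_diagram(
    params: CommunityParams,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    mode: Literal["winner", "rho_c"] = "rho_c",
    init: State | None = None,
    u_total: float = 0.1,
    tol: float = 1e-2,
    horizon: float = 200.0,
    control: IntegrationControl | None = None,
) -> PhaseDiagram:
    """Sweep two named parameters and record the outcome in each cell.

    Each cell is computed independently from the same base parameter set, so
    cells may be evaluated in any order with identical results.  In
    ``winner`` mode each cell runs a single competition from ``init``
    (default: equal frequencies u_A = u_B = u_total/2, no initial toxin) and
    stores the outcome label; in ``rho_c`` mode each cell stores
    :func:`find_critical_frequency` (nan where there is no crossing).
    """
    valid = CommunityParams.field_names()
    for name, _ in (axis1, axis2):
        if name not in valid:
            raise ValueError(
                f"unknown parameter {name!r}; valid names: {sorted(valid)}"
            )
    a1_name, a1_vals = axis1[0], np.asarray(axis1[1], dtype=float)
    a2_name, a2_vals = axis2[0], np.asarray(axis2[1], dtype=float)
    if a1_vals.size == 0 or a2_vals.size == 0 or not (
        np.all(np.isfinite(a1_vals)) and np.all(np.isfinite(a2_vals))
    ):
        raise ValueError("axis grids must be non-empty and finite")

    if mode == "winner":
        grid = np.empty((a1_vals.size, a2_vals.size), dtype=object)
    elif mode == "rho_c":
        grid = np.full((a1_vals.size, a2_vals.size), np.nan)
    else:
        raise ValueError("mode must be 'winner' or 'rho_c'")

    base_init = init or State(u_A=u_total / 2, u_B=u_total / 2)
    for i, v1 in enumerate(a1_vals):
        for j, v2 in enumerate(a2_vals):
            p = params.replace(**{a1_name: float(v1), a2_name: float(v2)})
            if mode == "winner":
                _, outcome = run_competition(p, base_init, horizon, control)
                grid[i, j] = outcome.label
            else:
                res = find_critical_frequency(
                    p, u_total=u_total, tol=tol, horizon=horizon, control=control
                )
                grid[i, j] = res.rho_c
    return PhaseDiagram(
        axis1_name=a1_name, axis1_values=a1_vals,
        axis2_name=a2_name, axis2_values=a2_vals,
        mode=mode, values=grid, base_params=params,
    )
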