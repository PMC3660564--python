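"""Spatial (structured-environment) reaction-diffusion competition.

The well-mixed kinetics are applied per lattice site, bacteria spread with a
small surface coefficient ``D_u`` and toxins diffuse with ``D_c`` (toxins are
small molecules relative to colonies, so ``D_c`` >> ``D_u`` by default).  The
scheme is explicit forward-time centered-space (FTCS) on a 1D or 2D grid with
no-flux boundaries, mimicking the walls of an agar plate; periodic boundaries
are available behind a flag.

In a structured environment each strain holds its own territory and
competition concentrates at the fronts between territories (the "no man's
land"), where mutual induction piles up toxin.  The module tracks those
fronts, fits their velocity, and measures per-strain areal coverage — the
simulated counterpart of photographing a competition plate and measuring each
strain's share of the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CommunityParams, rhs_arrays
from .wellmixed import IntegrationControl  # noqa: F401  (re-export convenience)

__all__ = [
    "SpatialState",
    "SpatialRun",
    "FrontTrack",
    "init_spatial",
    "integrate_spatial",
    "detect_fronts",
    "track_front",
    "front_velocity",
    "coverage_fractions",
    "stable_dt",
]


@dataclass
class SpatialState:
    """Fields on a 1D (length-N) or 2D (N x M) lattice with spacing ``h``."""

    u_A: np.ndarray
    u_B: np.ndarray
    c_A: np.ndarray
    c_B: np.ndarray
    h: float = 1.0

    def __post_init__(self) -> None:
        shapes = {f.shape for f in (self.u_A, self.u_B, self.c_A, self.c_B)}
        if len(shapes) != 1:
            raise ValueError("all fields must share one grid shape")
        if self.u_A.ndim not in (1, 2):
            raise ValueError("grid must be 1D or 2D")
        if self.h <= 0:
            raise ValueError("grid spacing h must be > 0")

    @property
    def ndim(self) -> int:
        return self.u_A.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.u_A.shape

    def copy(self) -> "SpatialState":
        return SpatialState(
            self.u_A.copy(), self.u_B.copy(), self.c_A.copy(), self.c_B.copy(), self.h
        )

    def fields(self) -> dict[str, np.ndarray]:
        return {"u_A": self.u_A, "u_B": self.u_B, "c_A": self.c_A, "c_B": self.c_B}


@dataclass
class SpatialRun:
    """Snapshots of a reaction-diffusion run at a fixed cadence."""

    times: list[float]
    states: list[SpatialState]
    params: CommunityParams
    meta: dict = field(default_factory=dict)

    @property
    def final(self) -> SpatialState:
        return self.states[-1]


@dataclass
class FrontTrack:
    """Front position through time, with a least-squares velocity fit."""

    times: np.ndarray
    positions: np.ndarray
    velocity: float | None = None
    residual: float | None = None


def _empty_grid(shape: tuple[int, ...]) -> np.ndarray:
    return np.zeros(shape, dtype=float)


def init_spatial(
    pattern: str,
    shape: int | tuple[int, int],
    h: float = 1.0,
    inoculum: float = 0.5,
    n_droplets: int = 24,
    radius: float = 3.0,
    n_blocks: int = 4,
    rng: np.random.Generator | int | None = None,
) -> SpatialState:
    """Construct an initial condition on a fresh grid.

    Patterns
    --------
    ``half_split``
        Strain A occupies the left half of the domain (left columns in 2D),
        strain B the right half, each at density ``inoculum``.
    ``blocks``
        ``n_blocks`` alternating A/B stripes along the first axis.
    ``droplets``
        ``n_droplets`` discs of radius ``radius`` (length units) at uniformly
        random centers on a 2D grid, emulating inoculation of a plate by
        randomly deposited droplets of pure culture.  Strains alternate
        A,B,A,B,... in seeded-shuffled order, so each strain receives half of
        the droplets.  Requires a 2D grid and a seedable ``rng``.

    Toxin fields always start at zero.
    """
    if isinstance(shape, int):
        grid_shape: tuple[int, ...] = (shape,)
    else:
        grid_shape = tuple(shape)
    u_A, u_B = _empty_grid(grid_shape), _empty_grid(grid_shape)

    if pattern == "half_split":
        n0 = grid_shape[-1] // 2
        if len(grid_shape) == 1:
            u_A[:n0] = inoculum
            u_B[n0:] = inoculum
        else:
            u_A[:, :n0] = inoculum
            u_B[:, n0:] = inoculum
    elif pattern == "blocks":
        if n_blocks < 2:
            raise ValueError("blocks pattern needs n_blocks >= 2")
        edges = np.linspace(0, grid_shape[0], n_blocks + 1).astype(int)
        for k, (lo, hi) in enumerate(zip(edges, edges[1:])):
            target = u_A if k % 2 == 0 else u_B
            target[lo:hi] = inoculum
    elif pattern == "droplets":
        if len(grid_shape) != 2:
            raise ValueError("droplets pattern requires a 2D grid")
        if n_droplets < 1:
            raise ValueError("need at least one droplet")
        if radius < h:
            raise ValueError("droplet radius must be >= grid spacing h")
        ny, nx = grid_shape
        r_sites = radius / h
        if 2 * r_sites > min(ny, nx):
            raise ValueError(
                f"droplets of radius {radius} do not fit a {ny}x{nx} grid"
            )
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        centers_y = gen.uniform(r_sites, ny - r_sites, size=n_droplets)
        centers_x = gen.uniform(r_sites, nx - r_sites, size=n_droplets)
        strains = np.array([k % 2 for k in range(n_droplets)])  # 0 = A, 1 = B
        gen.shuffle(strains)
        yy, xx = np.mgrid[0:ny, 0:nx]
        for cy, cx, which in zip(centers_y, centers_x, strains):
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_sites**2
            target = u_A if which == 0 else u_B
            target[disc] = inoculum
    else:
        raise ValueError(
            f"unknown pattern {pattern!r}; expected half_split, blocks or droplets"
        )
    return SpatialState(u_A, u_B, _empty_grid(grid_shape), _empty_grid(grid_shape), h)


def _laplacian(f: np.ndarray, h: float, periodic: bool) -> np.ndarray:
    """Second-order Laplacian; no-flux (reflecting) or periodic boundaries."""
    if periodic:
        out = -2.0 * f.ndim * f
        for axis in range(f.ndim):
            out += np.roll(f, 1, axis=axis) + np.roll(f, -1, axis=axis)
        return out / h**2
    padded = np.pad(f, 1, mode="edge")  # ghost cells mirror the edge: zero flux
    if f.ndim == 1:
        out = padded[:-2] + padded[2:] - 2.0 * f
    else:
        core = padded[1:-1, 1:-1]
        out = (
            padded[:-2, 1:-1] + padded[2:, 1:-1]
            + padded[1:-1, :-2] + padded[1:-1, 2:]
            - 4.0 * core
        )
    return out / h**2


def stable_dt(params: CommunityParams, h: float, ndim: int) -> float:
    """Largest time step admitted by the explicit diffusion stability bound."""
    d_max = max(params.D_u, params.D_c)
    if d_max == 0:
        return np.inf
    return h**2 / (2.0 * ndim * d_max)


def integrate_spatial(
    params: CommunityParams,
    state: SpatialState,
    horizon: float,
    dt: float | None = None,
    snap_every: float | None = None,
    periodic: bool = False,
    reactions: bool = True,
    time_scheme: str = "euler",
) -> SpatialRun:
    """Explicit FTCS integration of the reaction-diffusion system.

    The time step must satisfy the diffusion stability bound
    ``dt <= h^2 / (2 * ndim * max(D_u, D_c))``; violations raise before any
    stepping, naming the maximal admissible step.  Reaction kinetics are
    exactly the well-mixed right-hand side applied per site (disable with
    ``reactions=False`` for pure-diffusion checks).  Snapshots are stored
    every ``snap_every`` time units (default: 20 snapshots over the horizon)
    plus the initial and final states.

    ``time_scheme`` selects the time integrator on the method-of-lines
    system: first-order forward Euler (default; cheapest per step, adequate
    for front dynamics) or classical ``rk4`` (fourth order; used when
    site-level trajectories must agree tightly with the well-mixed ODE
    solution, e.g. in the diffusion-free decoupled-sites limit).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    dt_max = stable_dt(params, state.h, state.ndim)
    if dt is None:
        dt = min(0.8 * dt_max, horizon / 10.0) if np.isfinite(dt_max) else horizon / 100.0
    if dt > dt_max:
        raise ValueError(
            f"dt = {dt:g} violates the explicit stability bound; "
            f"maximal admissible dt = {dt_max:g}"
        )
    if snap_every is None:
        snap_every = horizon / 20.0

    if time_scheme not in ("euler", "rk4"):
        raise ValueError("time_scheme must be 'euler' or 'rk4'")
    n_steps = int(np.ceil(horizon / dt))
    snap_stride = max(1, int(round(snap_every / dt)))

    def rates(u_A, u_B, c_A, c_B):
        if reactions:
            du_A, du_B, dc_A, dc_B = rhs_arrays(u_A, u_B, c_A, c_B, params)
        else:
            du_A = du_B = dc_A = dc_B = 0.0
        return (
            du_A + params.D_u * _laplacian(u_A, state.h, periodic),
            du_B + params.D_u * _laplacian(u_B, state.h, periodic),
            dc_A + params.D_c * _laplacian(c_A, state.h, periodic),
            dc_B + params.D_c * _laplacian(c_B, state.h, periodic),
        )

    cur = state.copy()
    times: list[float] = [0.0]
    states: list[SpatialState] = [cur.copy()]
    u_A, u_B, c_A, c_B = cur.u_A, cur.u_B, cur.c_A, cur.c_B
    for k in range(1, n_steps + 1):
        if time_scheme == "euler":
            k1 = rates(u_A, u_B, c_A, c_B)
            u_A = u_A + dt * k1[0]
            u_B = u_B + dt * k1[1]
            c_A = c_A + dt * k1[2]
            c_B = c_B + dt * k1[3]
        else:
            y = (u_A, u_B, c_A, c_B)
            k1 = rates(*y)
            k2 = rates(*(f + 0.5 * dt * df for f, df in zip(y, k1)))
            k3 = rates(*(f + 0.5 * dt * df for f, df in zip(y, k2)))
            k4 = rates(*(f + dt * df for f, df in zip(y, k3)))
            u_A, u_B, c_A, c_B = (
                f + dt / 6.0 * (a + 2 * b + 2 * c + d)
                for f, a, b, c, d in zip(y, k1, k2, k3, k4)
            )
        for name, f in (("u_A", u_A), ("u_B", u_B), ("c_A", c_A), ("c_B", c_B)):
            if not np.all(np.isfinite(f)):
                site = np.unravel_index(int(np.argmax(~np.isfinite(f))), f.shape)
                raise RuntimeError(
                    f"non-finite {name} at t = {k * dt:g}, site {site}"
                )
        np.clip(u_A, 0.0, None, out=u_A)
        np.clip(u_B, 0.0, None, out=u_B)
        np.clip(c_A, 0.0, None, out=c_A)
        np.clip(c_B, 0.0, None, out=c_B)
        if k % snap_stride == 0 or k == n_steps:
            times.append(k * dt)
            states.append(SpatialState(u_A.copy(), u_B.copy(), c_A.copy(), c_B.copy(), state.h))
    meta = {"dt": dt, "dt_max": dt_max, "periodic": periodic,
            "reactions": reactions, "time_scheme": time_scheme}
    return SpatialRun(times=times, states=states, params=params, meta=meta)


def detect_fronts(snapshot: SpatialState, level: float = 1e-3) -> np.ndarray:
    """Front positions in a 1D snapshot (length units).

    A front is a zero crossing of u_A - u_B between adjacent sites where the
    community is actually present (u_A + u_B > ``level`` on both sides);
    positions are linearly interpolated.  Returns an empty array when no
    occupied crossing exists.
    """
    if snapshot.ndim != 1:
        raise ValueError("detect_fronts expects a 1D snapshot")
    diff = snapshot.u_A - snapshot.u_B
    occupied = (snapshot.u_A + snapshot.u_B) > level
    positions = []
    for i in range(diff.size - 1):
        if not (occupied[i] and occupied[i + 1]):
            continue
        a, b = diff[i], diff[i + 1]
        if a == 0.0 and b == 0.0:
            continue
        if a * b < 0 or (a == 0.0 and b != 0.0):
            frac = a / (a - b) if a != b else 0.0
            positions.append((i + frac) * snapshot.h)
    return np.asarray(positions, dtype=float)


def track_front(run: SpatialRun, level: float = 1e-3) -> FrontTrack:
    """Follow the (first) front of a 1D run through its snapshots.

    Snapshots with no detectable front (the resolved endgame) are dropped.
    """
    times, positions = [], []
    for t, st in zip(run.times, run.states):
        fronts = detect_fronts(st, level=level)
        if fronts.size:
            times.append(t)
            positions.append(fronts[0])
    return FrontTrack(times=np.asarray(times), positions=np.asarray(positions))


def front_velocity(track: FrontTrack, discard_fraction: float = 0.2) -> FrontTrack:
    """Least-squares front velocity after discarding the initial transient.

    Sign convention: positive velocity moves toward strain B's territory
    (increasing coordinate in the half-split layout).  The residual is the
    RMS deviation of position about the fitted line.  Requires at least five
    retained time points.
    """
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must be in [0, 1)")
    n0 = int(np.floor(discard_fraction * track.times.size))
    t, x = track.times[n0:], track.positions[n0:]
    if t.size < 5:
        raise ValueError(
            f"need >= 5 time points after the transient, got {t.size}"
        )
    slope, intercept = np.polyfit(t, x, 1)
    resid = float(np.sqrt(np.mean((x - (slope * t + intercept)) ** 2)))
    return FrontTrack(times=t, positions=x, velocity=float(slope), residual=resid)


def coverage_fractions(
    snapshot: SpatialState, occupancy_threshold: float = 1e-2
) -> dict[str, float]:
    """Areal coverage of each strain plus the unoccupied fraction.

    A site counts for the strain with the larger local density there,
    provided that density exceeds ``occupancy_threshold``; exact ties and
    sub-threshold sites count as unoccupied.  Fractions sum to 1.
    """
    n = snapshot.u_A.size
    a_sites = (snapshot.u_A > snapshot.u_B) & (snapshot.u_A > occupancy_threshold)
    b_sites = (snapshot.u_B > snapshot.u_A) & (snapshot.u_B > occupancy_threshold)
    frac_a = float(a_sites.sum()) / n
    frac_b = float(b_sites.sum()) / n
    return {"A": frac_a, "B": frac_b, "unoccupied": 1.0 - frac_a - frac_b}
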