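"""Explicit position-Verlet time stepping with lagged velocities.

The update is ``x(t+dt) = 2 x(t) - x(t-dt) + (F/m) dt^2`` with the velocity
entering the drag force estimated one step behind, ``v(t) ~ [x(t) -
x(t-dt)]/dt``, which keeps the scheme fully explicit.

Stability of an explicit integrator requires the step to stay below the
critical step of the stiffest particle-pair "spring".  For a damped pair,

    dt_crit = (2/omega) (sqrt(1 + xi^2) - xi),
    omega   = sqrt(k_max / m_red),   xi = beta / (2 sqrt(k_max m_red)),

with ``m_red = m_I m_J / (m_I + m_J)`` and ``k_max`` the maximum tangent
stiffness of the pair's force law over the admissible overlap range (the
Hertz tangent ``(3/2) kr sqrt(Req alpha_max)``, or the linear adhesion
stiffness if that is larger).  The working step is ``safety_factor *
dt_crit``; quasi-static runs can use a factor close to one.

Because the published drag factors are large relative to the particle masses
(the pairs are massively overdamped, dt_crit ~ 2 m/beta ~ 1e-16 s), every
experiment driver scales the particle masses up to reach a prescribed target
step (:func:`mass_scale_for_dt`).  This is legitimate for quasi-static
loading: damping exists only to stabilise the numerics and the inertial time
scale m/beta is kept far below any loading time scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import _kernels
from .mechanics import (
    L0,
    CoefficientTables,
    NonFiniteForceError,
    PairList,
    _boundary_arrays,
)
from .params import particle_mass
from .species import PARTICLE_LABELS
from .state import SimulationState

__all__ = [
    "StepControl",
    "pair_critical_dt",
    "critical_time_step",
    "mass_scale_for_dt",
    "Stepper",
    "verlet_step",
    "settle",
    "SettleResult",
    "InstabilityError",
]


class InstabilityError(RuntimeError):
    """Non-finite coordinates during stepping; lower the safety factor."""


@dataclass
class StepControl:
    """Time-step bookkeeping for a run."""

    dt: float = 0.0
    dt_critical: float = 0.0
    safety_factor: float = 0.9
    residual_tol: float = 1e-11  # force residual for quasi-static convergence [N]

    def update(self, dt_critical: float) -> None:
        self.dt_critical = dt_critical
        self.dt = self.safety_factor * dt_critical


def pair_critical_dt(k_max: float, m_red: float, beta: float) -> float:
    """Critical step of one damped spring (closed form)."""
    if k_max <= 0.0 or m_red <= 0.0:
        raise ValueError("stiffness and reduced mass must be positive")
    omega = math.sqrt(k_max / m_red)
    xi = beta / (2.0 * math.sqrt(k_max * m_red))
    # (sqrt(1+xi^2) - xi) written cancellation-free for the overdamped regime
    return (2.0 / omega) / (math.sqrt(1.0 + xi * xi) + xi)


#: Default force cap used for tangent-stiffness estimates, as a multiple of
#: the largest constant attraction in play.  Contact forces transiently
#: exceed the cohesive scale during driven loading; the cap sets how far the
#: stability estimate follows the stiffening Hertz branch.
FORCE_CAP_FACTOR = 30.0


def default_force_cap(state) -> float:
    f = max(state.type_params[l].F_a for l in PARTICLE_LABELS)
    return FORCE_CAP_FACTOR * max(f, 1e-30)


def _pair_stiffness_mass(state, tables, f_cap):
    """Per species-pair (k_max, m_red, beta) over enabled pairs + boundaries.

    ``k_max`` is the maximum tangent stiffness of the pair's force law over
    the admissible overlap range: the Hertz tangent evaluated at the overlap
    where the contact force reaches ``f_cap`` (clamped at half the summed
    radii), or the linear adhesion stiffness if that is larger.  Masses use
    the smallest radius present per species (the smallest mass governs); a
    species with no particles falls back to its mean parameter radius.
    """
    ns = len(PARTICLE_LABELS)
    rmin = np.empty(ns)
    for s in range(ns):
        mask = state.species == s
        rmin[s] = state.r[mask].min() if mask.any() else state.type_params[
            PARTICLE_LABELS[s]
        ].R
    dens = np.array([state.type_params[l].density for l in PARTICLE_LABELS])
    mass = dens * (4.0 / 3.0) * np.pi * rmin**3 * state.mass_scale

    def hertz_tangent(kr, req, r_sum):
        c_h = kr * math.sqrt(req / L0)  # P = c_h * (alpha/L0)^1.5
        if c_h <= 0.0:
            return 0.0
        a_cap = min((f_cap / c_h) ** (2.0 / 3.0), 0.5 * r_sum / L0)
        return 1.5 * c_h * math.sqrt(a_cap) / L0

    out = []
    for a in range(ns):
        for b in range(a, ns):
            if not tables.enab[a, b]:
                continue
            req = rmin[a] * rmin[b] / (rmin[a] + rmin[b])
            k_hertz = hertz_tangent(tables.kr[a, b], req, rmin[a] + rmin[b])
            k_lin = tables.ka[a, b] / L0
            k_max = max(k_hertz, k_lin)
            m_red = mass[a] * mass[b] / (mass[a] + mass[b])
            beta = max(tables.beta[a], tables.beta[b])
            out.append((k_max, m_red, beta))
    for k in range(len(state.boundaries)):
        for a in range(ns):
            if not tables.b_enab[k, a]:
                continue
            k_hertz = hertz_tangent(tables.b_kr[k, a], rmin[a], 2.0 * rmin[a])
            k_lin = tables.b_ka[k, a] / L0
            k_max = max(k_hertz, k_lin)
            out.append((k_max, mass[a], tables.beta[a]))
    return out


def critical_time_step(
    state: SimulationState,
    tables: Optional[CoefficientTables] = None,
    f_cap: Optional[float] = None,
) -> float:
    """Minimum critical step over all potentially interacting pairs.

    Evaluated at species level with the smallest radius present per species,
    which bounds the per-pair minimum from below for pairs not yet in
    contact as well.
    """
    if tables is None:
        tables = CoefficientTables(state)
    if f_cap is None:
        f_cap = default_force_cap(state)
    entries = _pair_stiffness_mass(state, tables, f_cap)
    if not entries:
        raise ValueError("no enabled interactions; critical step undefined")
    return min(pair_critical_dt(k, m, b) for k, m, b in entries)


def mass_scale_for_dt(
    state: SimulationState,
    dt_target: float,
    f_cap: Optional[float] = None,
) -> float:
    """Mass-scaling factor that makes ``safety * dt_crit`` reach ``dt_target``.

    Inverting the damped-spring formula gives the reduced mass required for a
    step dt: ``m_red = dt^2 k / 4 + dt beta / 2``; the factor returned is the
    worst-case ratio to the physical reduced mass.
    """
    tables = CoefficientTables(state)
    if f_cap is None:
        f_cap = default_force_cap(state)
    dt_unsafe = dt_target / state.safety_factor
    entries = _pair_stiffness_mass(state, tables, f_cap)
    scale = 1.0
    for k_max, m_red, beta in entries:
        m_phys = m_red / state.mass_scale
        m_needed = dt_unsafe**2 * k_max / 4.0 + dt_unsafe * beta / 2.0
        scale = max(scale, m_needed / m_phys)
    return scale


def quasistatic_dt(
    state: SimulationState,
    T_char: float,
    v_drive: float = 0.0,
    eps: float = 0.05,
    c_drive: float = 0.02,
    f_cap: Optional[float] = None,
) -> float:
    """Largest step compatible with an inertia budget over a loading time.

    Mass scaling trades inertia for step size: granting each pair a reduced
    mass ``m = eps * beta * T_char`` keeps the inertial response time
    ``m / beta`` at a fraction ``eps`` of the characteristic loading (or
    relaxation) time ``T_char``, and the corresponding stable step follows
    from the damped-spring relation ``m = dt^2 k / 4 + dt beta / 2``.  A
    boundary driven at ``v_drive`` additionally caps the step so it moves at
    most ``c_drive`` of the smallest radius per step.
    """
    tables = CoefficientTables(state)
    if f_cap is None:
        f_cap = default_force_cap(state)
    dt = math.inf
    for k_max, _, beta in _pair_stiffness_mass(state, tables, f_cap):
        if beta <= 0.0:
            continue
        m_budget = eps * beta * T_char
        if k_max <= 0.0:
            dt_pair = 2.0 * m_budget / beta
        else:
            dt_pair = (
                -beta / 2.0 + math.sqrt(beta**2 / 4.0 + k_max * m_budget)
            ) * 2.0 / k_max
        dt = min(dt, dt_pair)
    if v_drive > 0.0 and state.n:
        dt = min(dt, c_drive * float(state.r.min()) / v_drive)
    if not math.isfinite(dt):
        raise ValueError("could not determine a quasi-static step")
    return dt


def overdamped_dt(
    state: SimulationState,
    v_drive: float = 0.0,
    c_move: float = 0.02,
) -> float:
    """Pseudo-time step for the overdamped (massless) stepping mode.

    Chosen so a particle pushed at the largest cohesive force scale moves a
    fraction ``c_move`` of the smallest radius per step, ``dt = c_move R
    beta / F_a,max``; a boundary driven at ``v_drive`` additionally caps the
    step at ``c_move R / v_drive``.  Weaker forces then advance
    proportionally more slowly, stronger (contact) forces are clamped.
    """
    present = np.unique(state.species) if state.n else np.arange(4)
    labels = [PARTICLE_LABELS[s] for s in present]
    r_min = float(state.r.min()) if state.n else min(
        state.type_params[l].R for l in labels
    )
    beta_min = min(state.type_params[l].beta for l in labels)
    f_max = max(max(state.type_params[l].F_a for l in labels), 1e-30)
    dt = c_move * r_min * beta_min / f_max
    if v_drive > 0.0:
        dt = min(dt, c_move * r_min / v_drive)
    return dt


def relaxation_time(state: SimulationState) -> float:
    """Time for the cohesive force scale to move a particle one radius.

    ``T = R beta / F_a,max`` is the slowest force-driven rearrangement scale
    and serves as the default ``T_char`` for free relaxation (cell building,
    spreading, settling); driven experiments use their loading duration
    instead.
    """
    present = np.unique(state.species) if state.n else np.arange(4)
    labels = [PARTICLE_LABELS[s] for s in present]
    r_min = float(state.r.min()) if state.n else min(
        state.type_params[l].R for l in labels
    )
    beta_min = min(state.type_params[l].beta for l in labels)
    f_max = max(max(state.type_params[l].F_a for l in labels), 1e-30)
    return r_min * beta_min / f_max


def prepare_quasistatic(
    state: SimulationState,
    T_char: float,
    v_drive: float = 0.0,
    eps: float = 0.05,
    c_drive: float = 0.02,
    f_cap: Optional[float] = None,
) -> float:
    """Set the mass scale for a quasi-static run over time scale ``T_char``.

    Returns the resulting target step; the caller's :class:`Stepper` then
    picks ``dt = safety * dt_crit ~ dt_target`` automatically.
    """
    dt_t = quasistatic_dt(state, T_char, v_drive, eps, c_drive, f_cap)
    state.mass_scale = max(1.0, mass_scale_for_dt(state, dt_t, f_cap))
    return dt_t


class Stepper:
    """Drives position-Verlet stepping of a :class:`SimulationState`.

    Maintains the lagged-position array, a skin-buffered neighbour list that
    is rebuilt when the accumulated displacement exceeds half the skin, and
    recomputes the critical step every ``dt_recompute_every`` steps and after
    any structural event (call :meth:`refresh`).
    """

    def __init__(
        self,
        state: SimulationState,
        control: Optional[StepControl] = None,
        external: Optional[np.ndarray] = None,
        skin: Optional[float] = None,
        same_type_only_attraction: bool = False,
        dt_recompute_every: int = 100,
        auto_dt: bool = True,
        disp_cap: float = 0.25,
        f_switch: Optional[float] = None,
        mode: str = "verlet",
    ):
        if mode not in ("verlet", "overdamped"):
            raise ValueError("mode must be 'verlet' or 'overdamped'")
        self.mode = mode
        if mode == "overdamped":
            auto_dt = False
        self.disp_cap = disp_cap
        self.drift_leak = 0.02
        self._f_switch_arg = f_switch
        self.state = state
        self.control = control if control is not None else StepControl(
            safety_factor=state.safety_factor
        )
        self.external = external
        self.same_type_only_attraction = same_type_only_attraction
        self.dt_recompute_every = dt_recompute_every
        self.auto_dt = auto_dt
        self._skin_arg = skin
        self.last_forces: Optional[np.ndarray] = None
        self.last_reactions: Optional[np.ndarray] = None
        self._steps_since_dt = 0
        self.refresh(reset_xprev=True)

    # -- bookkeeping -------------------------------------------------------

    def refresh(self, reset_xprev: bool = False) -> None:
        """Rebuild coefficient tables, masses and the neighbour list.

        Must be called after growth, division, insertion or parameter
        changes.  ``reset_xprev`` re-seeds the Verlet history from the
        current velocities with a half-step force correction.
        """
        st = self.state
        self.tables = CoefficientTables(st, self.same_type_only_attraction)
        if self.auto_dt:
            self.control.update(critical_time_step(st, self.tables))
            st.dt = self.control.dt
        elif self.control.dt > 0.0:
            st.dt = self.control.dt
        self.masses = st.masses()
        self.beta_p = self.tables.beta[st.species]
        rmin = st.r.min() if st.n else 1.0
        self.skin = self._skin_arg if self._skin_arg is not None else 0.6 * rmin
        self.dmax = self.disp_cap * rmin if self.disp_cap else 0.0
        self.f_switch = (
            self._f_switch_arg if self._f_switch_arg is not None
            else default_force_cap(st)
        )
        self.f_strong = 100.0 * self.f_switch if math.isfinite(self.f_switch) else 1.0
        self.f_clip = math.inf
        self.pairs = PairList(st, self.tables, self.skin)
        self._acc_disp = 0.0
        self._steps_since_dt = 0
        if reset_xprev and self.mode == "verlet":
            self._init_xprev()
        elif reset_xprev:
            self.xprev = st.x.copy()

    def _init_xprev(self) -> None:
        st = self.state
        F = self._forces_only()
        with np.errstate(invalid="ignore"):
            acc = F / self.masses[:, None]
        self.xprev = st.x - st.v * st.dt + 0.5 * acc * st.dt**2

    def _forces_only(self) -> np.ndarray:
        """Force evaluation without advancing positions."""
        st = self.state
        n = st.n
        F = np.zeros((n, 2))
        vsum = np.zeros((n, 2))
        ncnt = np.zeros(n, dtype=np.int64)
        react = np.zeros((max(len(st.boundaries), 1), 2))
        _kernels.accumulate_pairs(
            st.x, st.v, st.r, st.species, self.pairs.i, self.pairs.j,
            self.tables.ka, self.tables.kr, self.tables.fa, self.tables.dmin,
            self.tables.enab, self.tables.dspec, L0, F, vsum, ncnt,
            self.f_clip,
        )
        if st.boundaries:
            bpoint, bnormal, bvel = _boundary_arrays(st)
            _kernels.boundary_forces(
                st.x, st.v, st.r, st.species, bpoint, bnormal, bvel,
                self.tables.b_ka, self.tables.b_kr, self.tables.b_fa,
                self.tables.b_delta, self.tables.b_enab, L0,
                F, vsum, ncnt, react, self.f_clip,
            )
        ext = self.external if self.external is not None else np.zeros((n, 2))
        _kernels.finalize(
            st.x, st.x.copy(), st.v, F, ext, vsum, ncnt, self.beta_p,
            self.masses, st.dt, False, 0.0, st.mobile, 0.0, 1.0,
        )
        self.last_forces = F
        self.last_reactions = react[: len(st.boundaries)]
        return F

    # -- stepping ----------------------------------------------------------

    def step(self, nsteps: int = 1) -> None:
        """Advance ``nsteps`` Verlet steps."""
        st = self.state
        n = st.n
        ext = self.external if self.external is not None else np.zeros((n, 2))
        for _ in range(nsteps):
            if self._steps_since_dt >= self.dt_recompute_every and self.auto_dt:
                old_dt = st.dt
                self.control.update(critical_time_step(st, self.tables))
                if self.control.dt != old_dt:
                    # re-seed the Verlet history at the new step size
                    self.xprev = st.x - st.v * self.control.dt
                    st.dt = self.control.dt
                self._steps_since_dt = 0
            F = np.zeros((n, 2))
            vsum = np.zeros((n, 2))
            ncnt = np.zeros(n, dtype=np.int64)
            react = np.zeros((max(len(st.boundaries), 1), 2))
            _kernels.accumulate_pairs(
                st.x, st.v, st.r, st.species, self.pairs.i, self.pairs.j,
                self.tables.ka, self.tables.kr, self.tables.fa,
                self.tables.dmin, self.tables.enab, self.tables.dspec, L0,
                F, vsum, ncnt, self.f_clip,
            )
            if st.boundaries:
                bpoint, bnormal, bvel = _boundary_arrays(st)
                _kernels.boundary_forces(
                    st.x, st.v, st.r, st.species, bpoint, bnormal, bvel,
                    self.tables.b_ka, self.tables.b_kr, self.tables.b_fa,
                    self.tables.b_delta, self.tables.b_enab, L0,
                    F, vsum, ncnt, react, self.f_clip,
                )
            if self.mode == "overdamped":
                maxd2, finite = _kernels.overdamped_update(
                    st.x, st.v, F, ext, vsum, ncnt, self.beta_p, st.dt,
                    self.dmax, st.mobile, self.drift_leak,
                )
            else:
                maxd2, finite = _kernels.finalize(
                    st.x, self.xprev, st.v, F, ext, vsum, ncnt, self.beta_p,
                    self.masses, st.dt, True, self.dmax, st.mobile,
                    self.f_switch, self.f_strong,
                )
            if not finite:
                raise InstabilityError(
                    "non-finite coordinates during stepping; lower the "
                    "safety factor or the target time step"
                )
            self.last_forces = F
            self.last_reactions = react[: len(st.boundaries)]
            for b in st.boundaries:
                b.advance(st.t, st.dt)
            st.t += st.dt
            self._steps_since_dt += 1
            self._acc_disp += math.sqrt(maxd2)
            if self._acc_disp > 0.5 * self.skin:
                self.pairs = PairList(st, self.tables, self.skin)
                self._acc_disp = 0.0

    def max_residual(self) -> float:
        """Maximum net-force magnitude from the last evaluation."""
        if self.last_forces is None:
            self._forces_only()
        return float(np.linalg.norm(self.last_forces, axis=1).max()) if self.state.n else 0.0


def verlet_step(state: SimulationState, control: StepControl) -> SimulationState:
    """Advance one Verlet step (functional convenience wrapper).

    For long runs construct a :class:`Stepper` once instead; this wrapper
    rebuilds the neighbour list each call.
    """
    if control.dt <= 0.0:
        control.update(critical_time_step(state))
    if control.dt > control.safety_factor * critical_time_step(state) * (1 + 1e-9):
        raise ValueError("dt exceeds safety_factor * critical time step")
    stepper = Stepper(state, control, auto_dt=False, disp_cap=0.0, f_switch=math.inf)
    stepper.step(1)
    return state


@dataclass
class SettleResult:
    converged: bool
    steps: int
    residual: float
    elapsed: float


def settle(
    state: SimulationState,
    control: Optional[StepControl] = None,
    max_time: float = math.inf,
    max_steps: int = 200_000,
    check_every: int = 25,
    stepper: Optional[Stepper] = None,
    disp_tol: Optional[float] = None,
    callback: Optional[Callable[[Stepper], None]] = None,
) -> SettleResult:
    """Step until quasi-static convergence.

    The primary criterion is the force residual dropping below
    ``control.residual_tol``.  Near-tangent contacts park in a narrow band
    where the instantaneous force flickers between the cohesive scale and
    the steep contact branch, so ``disp_tol`` offers an alternative
    stationarity criterion: converged when no particle moved more than this
    distance over a whole check window.  An unconverged outcome (time/step
    budget exhausted) is reported in the result, not raised.
    """
    sp = stepper if stepper is not None else Stepper(state, control)
    ctl = sp.control
    t0 = state.t
    steps = 0
    res = sp.max_residual()
    if res < ctl.residual_tol:
        return SettleResult(True, 0, res, 0.0)
    while steps < max_steps and (state.t - t0) < max_time:
        x_before = state.x.copy()
        sp.step(check_every)
        steps += check_every
        if callback is not None:
            callback(sp)
        res = sp.max_residual()
        if res < ctl.residual_tol:
            return SettleResult(True, steps, res, state.t - t0)
        if disp_tol is not None:
            moved = float(np.abs(state.x - x_before).max())
            if moved < disp_tol:
                return SettleResult(True, steps, res, state.t - t0)
    return SettleResult(False, steps, res, state.t - t0)
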