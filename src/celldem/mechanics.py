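"""Pairwise and particle-boundary force laws, and the neighbour search.

The contact law between two particles I and J is a short-range nonlinear
spring acting along the line of centres:

    F_I-J = [Fa_IJ - P(alpha)] n_IJ

with the overlap/separation ``alpha = (R_I + R_J) - |x_I - x_J|`` and

    P(alpha) = 0                                      alpha <  -delta
             = ka_IJ * (alpha/L0)                     -delta <= alpha < 0
             = kr_IJ * sqrt(Req/L0) * (alpha/L0)^3/2  alpha >= 0

The whole force (including the constant attraction ``Fa``) vanishes beyond
the influence radius.  The repulsive branch is a Hertzian contact between two
elastic discs/spheres; the separated branch is a linear adhesion spring.

Combination rules for a pair: ``Req = R_I R_J / (R_I + R_J)``,
``ka_IJ = ka_I ka_J / (ka_I + ka_J)``, the Hertz coefficient
``kr_IJ = (4/3) [ (1 - nu_I^2)/E_I + (1 - nu_J^2)/E_J ]^-1``, and the
harmonic-style ``Fa_IJ = 2 Fa_I Fa_J / (Fa_I + Fa_J)`` which reduces to Fa
for a same-species pair and keeps the force symmetric for cross-species
pairs.  The pair cutoff is ``min(delta_I, delta_J)`` so the interaction set
is symmetric.

Unit convention: the tabulated constants are calibrated with lengths
measured in micrometres, so both branches of P are evaluated with ``Req`` and
``alpha`` as multiples of ``L0 = 1 um`` and the result is read in newtons.
Two observations force this choice.  With strict SI metres (a) the adhesion
spring constants (1e-12..1e-8 N/m) would produce forces of order 1e-18 N --
seven orders below the constant attractions -- so none of the
adhesion-controlled behaviours (cell spreading, cadherin-strength effects,
buckling suppression, nuclear-envelope stiffening) could occur; and (b) the
Hertz branch at the tabulated moduli would be so soft that cohesion
equilibrates pairs at ~60% diameter overlap, whereas the reference cell's
printed composition (726 cytoplasm particles of 0.25 um radius filling a 148
um^2 annulus, packing fraction ~1) requires near-tangent particles, i.e. a
contact that stiffens steeply within a small fraction of a micrometre.

Boundary objects enter the same law as spheres of infinite radius: the
equivalent radius degenerates to the particle's, the unit vector is the
negated domain normal and the cutoff is the boundary's own influence radius.

A viscous drag force ``D_I = -beta_I (v_I - mean_{J in N_I} v_J)`` acts
against the average velocity of the neighbours within range
(``alpha >= -delta_I``); a contacting boundary joins the average with its
scheduled velocity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .params import MICRON, ParticleTypeParams
from .species import PARTICLE_LABELS, ParticleSpecies
from .state import BoundaryObject, SimulationState

__all__ = [
    "PairGeometry",
    "PairCoefficients",
    "pair_geometry",
    "pair_coefficients",
    "elastic_pair_force",
    "drag_force",
    "boundary_force",
    "neighbor_search",
    "net_forces",
    "CoefficientTables",
    "PairList",
    "compute_forces",
    "NonFiniteForceError",
]

#: Length unit of the linear-attraction branch (see module docstring).
L0 = MICRON

_EPS_POS = 1e-15  # coincident-position threshold [m]


class NonFiniteForceError(RuntimeError):
    """A force evaluation produced NaN/inf (parameter blow-up)."""

    def __init__(self, indices):
        self.indices = np.asarray(indices)
        super().__init__(f"non-finite force on particles {self.indices[:10].tolist()}")


# ---------------------------------------------------------------------------
# scalar reference API
# ---------------------------------------------------------------------------


@dataclass
class PairGeometry:
    """Geometry of one interacting pair."""

    alpha: float  # overlap (>0) / separation (<0) [m]
    n: np.ndarray  # unit vector from I toward J
    R_eq: float  # equivalent radius R_I R_J / (R_I + R_J) [m]


@dataclass
class PairCoefficients:
    """Combined force-law coefficients of one pair."""

    k_a_pair: float  # N/m
    k_r_pair: float  # Pa
    F_a_pair: float  # N


def pair_geometry(
    xI, RI: float, xJ, RJ: float, rng: Optional[np.random.Generator] = None
) -> PairGeometry:
    """Overlap, direction and equivalent radius of a particle pair.

    Coincident positions leave the direction undefined; in that case a
    deterministic unit vector is drawn from the supplied seeded generator.
    """
    xI = np.asarray(xI, float)
    xJ = np.asarray(xJ, float)
    d = xJ - xI
    dist = float(np.linalg.norm(d))
    if dist < _EPS_POS:
        if rng is None:
            raise ValueError(
                "coincident particle positions and no rng supplied for the "
                "fallback direction"
            )
        theta = rng.uniform(0.0, 2.0 * math.pi)
        n = np.array([math.cos(theta), math.sin(theta)])
    else:
        n = d / dist
    alpha = (RI + RJ) - dist
    return PairGeometry(alpha=alpha, n=n, R_eq=RI * RJ / (RI + RJ))


def combine_F_a(fI: float, fJ: float) -> float:
    """Symmetric combination of the constant attractions (harmonic style)."""
    if fI <= 0.0 or fJ <= 0.0:
        return 0.0
    return 2.0 * fI * fJ / (fI + fJ)


def combine_k_a(kI: float, kJ: float) -> float:
    if kI <= 0.0 or kJ <= 0.0:
        return 0.0
    return kI * kJ / (kI + kJ)


def combine_k_r(EI: Optional[float], nuI: float, EJ: Optional[float], nuJ: float) -> float:
    """Hertz coefficient; ``E=None`` denotes a perfectly rigid partner."""
    cI = 0.0 if EI is None else (1.0 - nuI**2) / EI
    cJ = 0.0 if EJ is None else (1.0 - nuJ**2) / EJ
    if cI + cJ == 0.0:
        raise ValueError("both contact partners are rigid")
    return (4.0 / 3.0) / (cI + cJ)


def pair_coefficients(
    pI: ParticleTypeParams,
    pJ: ParticleTypeParams,
    same_type: Optional[bool] = None,
    same_type_only_attraction: bool = False,
) -> PairCoefficients:
    """Combined coefficients from the two species' parameters."""
    if same_type_only_attraction and same_type is False:
        fa = 0.0
    else:
        fa = combine_F_a(pI.F_a, pJ.F_a)
    return PairCoefficients(
        k_a_pair=combine_k_a(pI.k_a, pJ.k_a),
        k_r_pair=combine_k_r(pI.E, pI.nu, pJ.E, pJ.nu),
        F_a_pair=fa,
    )


def overlap_force_magnitude(
    alpha: float, R_eq: float, coeff: PairCoefficients, delta: float
) -> float:
    """P(alpha) of the piecewise law; 0 beyond the influence radius."""
    if alpha < -delta:
        return 0.0
    if alpha < 0.0:
        return coeff.k_a_pair * (alpha / L0)
    return coeff.k_r_pair * math.sqrt(R_eq / L0) * (alpha / L0) ** 1.5


def elastic_pair_force(
    geom: PairGeometry, coeff: PairCoefficients, delta: float
) -> np.ndarray:
    """Elastic force on particle I due to J; zero beyond the cutoff."""
    if geom.alpha < -delta:
        return np.zeros(2)
    p = overlap_force_magnitude(geom.alpha, geom.R_eq, coeff, delta)
    return (coeff.F_a_pair - p) * geom.n


def drag_force(vI, neighbor_velocities, beta: float) -> np.ndarray:
    """Viscous drag against the mean velocity of the in-range neighbours."""
    vI = np.asarray(vI, float)
    nv = np.atleast_2d(np.asarray(neighbor_velocities, float)) if len(neighbor_velocities) else None
    if nv is None or nv.size == 0:
        return np.zeros(2)
    return -beta * (vI - nv.mean(axis=0))


def boundary_force(p, b: BoundaryObject, state: Optional[SimulationState] = None) -> np.ndarray:
    """Force on a particle from a boundary line (infinite-radius sphere).

    ``p`` is a :class:`celldem.state.Particle` view.  Returns the zero vector
    when the pair is disabled in the interaction matrix.
    """
    st = state if state is not None else p.state
    if not st.interactions.enabled(p.species, b.species):
        return np.zeros(2)
    params = st.type_params[p.species]
    d = float(b.signed_distance(p.x))
    alpha = p.R - d
    if alpha < -b.delta:
        return np.zeros(2)
    coeff = PairCoefficients(
        k_a_pair=combine_k_a(params.k_a, b.k_a),
        k_r_pair=combine_k_r(params.E, params.nu, b.E, b.nu),
        F_a_pair=combine_F_a(params.F_a, b.F_a),
    )
    p_mag = overlap_force_magnitude(alpha, p.R, coeff, b.delta)
    return (coeff.F_a_pair - p_mag) * (-b.normal)


# ---------------------------------------------------------------------------
# vectorised engine
# ---------------------------------------------------------------------------


class CoefficientTables:
    """Pre-combined 4x4 species coefficient tables and boundary tables."""

    def __init__(self, state: SimulationState, same_type_only_attraction: bool = False):
        tp = [state.type_params[l] for l in PARTICLE_LABELS]
        ns = len(tp)
        self.ka = np.zeros((ns, ns))
        self.kr = np.zeros((ns, ns))
        self.fa = np.zeros((ns, ns))
        self.dmin = np.zeros((ns, ns))
        self.enab = state.interactions.particle_mask().astype(np.uint8)
        for a in range(ns):
            for b in range(ns):
                c = pair_coefficients(
                    tp[a], tp[b], same_type=(a == b),
                    same_type_only_attraction=same_type_only_attraction,
                )
                self.ka[a, b] = c.k_a_pair
                self.kr[a, b] = c.k_r_pair
                self.fa[a, b] = c.F_a_pair
                self.dmin[a, b] = min(tp[a].delta, tp[b].delta)
        self.dspec = np.array([p.delta for p in tp])
        self.beta = np.array([p.beta for p in tp])
        # boundary tables: one row per boundary object
        bmask = state.interactions.boundary_mask()
        nb = len(state.boundaries)
        self.b_ka = np.zeros((nb, ns))
        self.b_kr = np.zeros((nb, ns))
        self.b_fa = np.zeros((nb, ns))
        self.b_delta = np.zeros((nb, ns))
        self.b_enab = np.zeros((nb, ns), dtype=np.uint8)
        for k, b in enumerate(state.boundaries):
            brow = int(ParticleSpecies[b.species]) if b.species in PARTICLE_LABELS else (
                0 if b.species == "P" else 1
            )
            for a in range(ns):
                self.b_enab[k, a] = bmask[brow, a]
                self.b_ka[k, a] = combine_k_a(tp[a].k_a, b.k_a)
                self.b_kr[k, a] = combine_k_r(tp[a].E, tp[a].nu, b.E, b.nu)
                self.b_fa[k, a] = combine_F_a(tp[a].F_a, b.F_a)
                self.b_delta[k, a] = b.delta

    @property
    def max_delta(self) -> float:
        return float(self.dspec.max()) if self.dspec.size else 0.0


class PairList:
    """Candidate pair list built with a KD-tree at cutoff + skin.

    Candidates include *all* species pairs within range (the drag neighbour
    sets are not restricted by the interaction matrix); the per-pair exact
    cutoffs are applied inside the kernels every step.  The list is valid
    until the accumulated particle displacement exceeds half the skin.
    """

    def __init__(self, state: SimulationState, tables: CoefficientTables, skin: float):
        self.skin = skin
        r = state.r
        if state.n == 0:
            self.i = np.zeros(0, dtype=np.int64)
            self.j = np.zeros(0, dtype=np.int64)
            return
        cutoff = 2.0 * r.max() + tables.max_delta + skin
        tree = cKDTree(state.x)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if pairs.size:
            d = np.linalg.norm(state.x[pairs[:, 0]] - state.x[pairs[:, 1]], axis=1)
            dmax = np.maximum(
                tables.dspec[state.species[pairs[:, 0]]],
                tables.dspec[state.species[pairs[:, 1]]],
            )
            keep = d <= r[pairs[:, 0]] + r[pairs[:, 1]] + dmax + skin
            pairs = pairs[keep]
        self.i = np.ascontiguousarray(pairs[:, 0], dtype=np.int64) if pairs.size else np.zeros(0, np.int64)
        self.j = np.ascontiguousarray(pairs[:, 1], dtype=np.int64) if pairs.size else np.zeros(0, np.int64)


def _boundary_arrays(state: SimulationState):
    nb = len(state.boundaries)
    bpoint = np.zeros((nb, 2))
    bnormal = np.zeros((nb, 2))
    bvel = np.zeros((nb, 2))
    for k, b in enumerate(state.boundaries):
        bpoint[k] = b.point
        bnormal[k] = b.normal
        bvel[k] = b.motion.velocity_at(state.t)
    return bpoint, bnormal, bvel


def compute_forces(
    state: SimulationState,
    tables: Optional[CoefficientTables] = None,
    pairs: Optional[PairList] = None,
    external: Optional[np.ndarray] = None,
    check_finite: bool = True,
):
    """Total forces (elastic + drag + boundary + external) on every particle.

    Returns ``(F, reactions)`` where ``reactions`` is the (n_boundaries, 2)
    array of reaction forces on the boundary objects.
    """
    if tables is None:
        tables = CoefficientTables(state)
    if pairs is None:
        pairs = PairList(state, tables, skin=0.0)
    n = state.n
    F = np.zeros((n, 2))
    vsum = np.zeros((n, 2))
    ncnt = np.zeros(n, dtype=np.int64)
    react = np.zeros((max(len(state.boundaries), 1), 2))
    _kernels.accumulate_pairs(
        state.x, state.v, state.r, state.species, pairs.i, pairs.j,
        tables.ka, tables.kr, tables.fa, tables.dmin, tables.enab,
        tables.dspec, L0, F, vsum, ncnt, np.inf,
    )
    if state.boundaries:
        bpoint, bnormal, bvel = _boundary_arrays(state)
        _kernels.boundary_forces(
            state.x, state.v, state.r, state.species,
            bpoint, bnormal, bvel,
            tables.b_ka, tables.b_kr, tables.b_fa, tables.b_delta,
            tables.b_enab, L0, F, vsum, ncnt, react, np.inf,
        )
    ext = external if external is not None else np.zeros((n, 2))
    beta_p = tables.beta[state.species]
    m = state.masses()
    _kernels.finalize(
        state.x, state.x.copy(), state.v, F, ext, vsum, ncnt, beta_p, m,
        state.dt, False, 0.0, np.ones(n, dtype=np.uint8), 0.0, 1.0,
    )
    if check_finite and not np.all(np.isfinite(F)):
        raise NonFiniteForceError(np.flatnonzero(~np.isfinite(F).all(axis=1)))
    return F, react[: len(state.boundaries)]


def net_forces(
    state: SimulationState, external: Optional[dict | np.ndarray] = None
) -> np.ndarray:
    """Net force on every particle (``(n, 2)`` array).

    ``external`` may be an ``(n, 2)`` array or a mapping particle index ->
    force vector.
    """
    ext = None
    if external is not None:
        if isinstance(external, dict):
            ext = np.zeros((state.n, 2))
            for i, f in external.items():
                ext[i] = f
        else:
            ext = np.asarray(external, float)
    F, _ = compute_forces(state, external=ext)
    return F


def neighbor_search(state: SimulationState) -> dict[int, list[int]]:
    """Exact drag-neighbour sets: ``N_I = {J != I : alpha_IJ >= -delta_I}``.

    Implemented with a KD-tree at the global maximum cutoff followed by the
    exact per-pair test; equal to the all-pairs brute force by construction.
    """
    tables = CoefficientTables(state)
    out: dict[int, list[int]] = {i: [] for i in range(state.n)}
    if state.n < 2:
        return out
    cutoff = 2.0 * state.r.max() + tables.max_delta
    tree = cKDTree(state.x)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    for i, j in pairs:
        d = float(np.linalg.norm(state.x[i] - state.x[j]))
        alpha = state.r[i] + state.r[j] - d
        if alpha >= -tables.dspec[state.species[i]]:
            out[int(i)].append(int(j))
        if alpha >= -tables.dspec[state.species[j]]:
            out[int(j)].append(int(i))
    for lst in out.values():
        lst.sort()
    return out
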