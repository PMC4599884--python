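"""Construction of cells and epithelial layers.

A round cell is initialised in three stages: (i) the cell membrane and
nuclear membrane are laid out as closed rings of equally spaced particles on
the two circles; (ii) the cytoplasm and nucleoplasm are seeded at random
positions with half of their estimated target particle number; (iii) the
interior particles slowly grow and divide (a particle reaching twice its base
radius is reset to a fresh radius draw and a sibling is inserted at the same
location) while the assembly relaxes, until the membrane tension reaches a
prescribed threshold.  A 30% uniform variance on the particle radii prevents
crystalline packing.

Membrane rings are maintained throughout every simulation: whenever two
neighbouring ring particles separate by a gap larger than half a particle
size (i.e. one radius), a new particle is spliced in at the edge midpoint.
This mimics the regulation of membrane area under tension and is what allows
cells to spread and flatten.

Spread cells are produced by adding a basement membrane line with a
membrane-particle attraction; epithelial layers are rows of such cells placed
side by side on the basement membrane and settled into mutual contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from matplotlib.path import Path as MplPath

from . import _kernels
from .integrate import Stepper, StepControl, overdamped_dt
from .mechanics import L0, CoefficientTables
from .params import ParticleTypeParams, scale_resolution
from .species import InteractionMatrix, ParticleSpecies
from .state import BoundaryObject, MotionSchedule, SimulationState

__all__ = [
    "CellSpec",
    "MembraneRing",
    "BuildError",
    "build_round_cell",
    "build_isolated_nucleus",
    "grow_and_divide",
    "maintain_membrane",
    "membrane_tension",
    "spread_cell",
    "SpreadResult",
    "build_epithelial_layer",
    "cell_extent",
    "compartment_violations",
    "project_contacts",
]

_JITTER_FRAC = 1e-3  # positional jitter on division, as a fraction of R
_PHI_RCP = 0.84  # random-close-packing fraction of polydisperse tangent discs


class BuildError(RuntimeError):
    """Cell construction failed (e.g. tension threshold unreachable)."""


@dataclass
class CellSpec:
    """Geometry and initialisation parameters of one cell."""

    center: tuple[float, float] = (0.0, 0.0)
    diameter: float = 15e-6
    nucleus_diameter: float = 6e-6
    #: nucleus centre height above the cell's bottom; None = concentric,
    #: "basal" = tangent to the bottom, "elevated" = 2/3 of the cell height
    nucleus_center_height: Optional[float | str] = None
    growth_rate: Optional[float] = None  # m/s; None = auto from relax cadence
    tension_threshold: Optional[float] = None  # N; None = 0.5 * Fa_M
    radius_variance: float = 0.30

    def __post_init__(self):
        if not self.nucleus_diameter < self.diameter:
            raise ValueError("nucleus_diameter must be smaller than diameter")
        if not (0.0 <= self.radius_variance < 1.0):
            raise ValueError("radius_variance must be in [0, 1)")

    def nucleus_center(self) -> np.ndarray:
        cx, cy = self.center
        h = self.nucleus_center_height
        if h is None:
            return np.array([cx, cy])
        bottom = cy - self.diameter / 2.0
        if h == "basal":
            return np.array([cx, bottom + self.nucleus_diameter / 2.0])
        if h == "elevated":
            return np.array([cx, bottom + (2.0 / 3.0) * self.diameter])
        return np.array([cx, bottom + float(h)])


@dataclass
class MembraneRing:
    """Ordered view of one closed membrane ring."""

    state: SimulationState
    cell: int
    species: str = "M"

    def indices(self) -> np.ndarray:
        return self.state.ring_indices(self.cell, self.species)

    def gaps(self) -> np.ndarray:
        """Per-edge gap: centre distance minus the sum of radii (m)."""
        idx = self.indices()
        nxt = np.roll(idx, -1)
        d = np.linalg.norm(self.state.x[nxt] - self.state.x[idx], axis=1)
        return d - (self.state.r[idx] + self.state.r[nxt])

    @property
    def tension(self) -> float:
        return membrane_tension(self.state, self.cell, self.species)


# ---------------------------------------------------------------------------
# ring primitives
# ---------------------------------------------------------------------------


def _make_ring(
    state: SimulationState, center, radius: float, species: str, cell: int
) -> np.ndarray:
    """Equally spaced closed ring of membrane particles on a circle."""
    p = state.type_params[species]
    n = max(8, round(math.pi * (2.0 * radius) / (2.0 * p.R)))
    theta = 2.0 * math.pi * np.arange(n) / n
    xy = np.asarray(center) + radius * np.column_stack([np.cos(theta), np.sin(theta)])
    idx = state.add_particles(xy, species, cell)
    state.ring_next[idx] = np.roll(idx, -1)
    state.ring_prev[idx] = np.roll(idx, 1)
    return idx


def maintain_membrane(
    state: SimulationState, cell: int, species: str = "M",
    max_insert: Optional[int] = None,
) -> int:
    """Insert membrane particles into over-stretched ring edges.

    Any adjacent pair separated by a gap greater than one particle radius
    (half of a particle size) receives a new particle at the edge midpoint.
    Idempotent when no gap qualifies.  Returns the number of insertions.

    ``max_insert`` bounds the number of insertions per call (the widest gaps
    are served first); the spreading and layer drivers use a small budget per
    maintenance pass so that membrane area grows at the pace of genuine
    tension rather than amplifying transient ring wiggles.
    """
    p = state.type_params[species]
    idx = state.ring_indices(cell, species)
    if idx.size == 0:
        return 0
    # soft start: freshly inserted particles enter at the radius that fits
    # the gap tangentially (a full-size disc rammed into a just-qualifying
    # gap would inject a huge contact-force transient) and grow to the
    # species radius over subsequent maintenance passes
    undersized = np.flatnonzero(
        (state.cell_id == cell)
        & (state.species == int(ParticleSpecies[species]))
        & (state.r < p.R)
    )
    if undersized.size:
        state.r[undersized] = np.minimum(p.R, state.r[undersized] + 0.10 * p.R)
    nxt = np.roll(idx, -1)
    d = np.linalg.norm(state.x[nxt] - state.x[idx], axis=1)
    gaps = d - (state.r[idx] + state.r[nxt])
    stretched = np.flatnonzero(gaps > p.R)
    if max_insert is not None and stretched.size > max_insert:
        stretched = stretched[np.argsort(gaps[stretched])[::-1][:max_insert]]
    for e in stretched:
        i, j = int(idx[e]), int(nxt[e])
        mid = 0.5 * (state.x[i] + state.x[j])
        vel = 0.5 * (state.v[i] + state.v[j])
        r0 = min(p.R, 0.49 * float(gaps[e]))
        new = state.add_particles(
            mid, species, cell, r=r0, v=vel.reshape(1, 2),
            ring_prev=[i], ring_next=[j],
        )[0]
        state.ring_next[i] = new
        state.ring_prev[j] = new
    return int(stretched.size)


def membrane_tension(state: SimulationState, cell: int, species: str = "M") -> float:
    """Mean attractive force magnitude over the ring's edges.

    An edge at contact or separated (within range) contributes the magnitude
    of the attractive pair force ``Fa - P(alpha)``; an overlapping edge
    contributes zero, as does an edge stretched beyond the influence radius.
    The tension therefore rises from 0 (slack, overlapped ring) toward and
    past ``Fa`` as neighbouring membrane particles separate.
    """
    p = state.type_params[species]
    idx = state.ring_indices(cell, species)
    if idx.size == 0:
        return 0.0
    nxt = np.roll(idx, -1)
    d = np.linalg.norm(state.x[nxt] - state.x[idx], axis=1)
    alpha = (state.r[idx] + state.r[nxt]) - d
    req = state.r[idx] * state.r[nxt] / (state.r[idx] + state.r[nxt])
    k_pair = p.k_a / 2.0
    contrib = np.where(
        (alpha <= 0.0) & (alpha >= -p.delta),
        p.F_a - k_pair * (alpha / L0),
        0.0,
    )
    return float(contrib.mean())


# ---------------------------------------------------------------------------
# growth / division
# ---------------------------------------------------------------------------


def _fresh_radius(base_R: float, variance: float, rng: np.random.Generator) -> float:
    return base_R * rng.uniform(1.0 - variance, 1.0 + variance)


def _divide_particle(
    state: SimulationState, i: int, base_R: float, variance: float,
    rng: np.random.Generator,
) -> int:
    """Split particle ``i`` into a tangent daughter pair.

    Both radii are fresh draws from the +/-variance band.  The daughters are
    placed as an exactly tangent pair along a seeded random axis, centred on
    the parent position: the pair then fits (up to the radius variance)
    inside the footprint the grown parent already occupied, so a division
    never injects a deep disc-disc overlap.  The random axis also removes
    the coincident-position singularity of the pair direction.
    """
    x0 = state.x[i].copy()
    r1 = _fresh_radius(base_R, variance, rng)
    r2 = _fresh_radius(base_R, variance, rng)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    axis = np.array([math.cos(theta), math.sin(theta)])
    half = 0.5 * (r1 + r2)
    state.r[i] = r1
    state.x[i] = x0 - axis * half * (r2 / (r1 + r2)) * 2.0 * 0.5
    new = state.add_particles(
        x0 + axis * half * (r1 / (r1 + r2)) * 2.0 * 0.5,
        int(state.species[i]) * np.ones(1, dtype=np.int8),
        int(state.cell_id[i]),
        r=r2,
        v=state.v[i].reshape(1, 2),
    )[0]
    return int(new)


def grow_and_divide(
    state: SimulationState,
    i: int,
    dR: float,
    base_R: float,
    rng: np.random.Generator,
    variance: float = 0.30,
) -> Optional[int]:
    """Grow particle ``i`` by ``dR``; divide it if it reaches ``2 base_R``.

    Returns the index of the newly created particle, or None if no division
    occurred.  Only cytoplasm and nucleoplasm particles grow, and only during
    the initialisation phase.
    """
    sp = int(state.species[i])
    if sp not in (int(ParticleSpecies.C), int(ParticleSpecies.N)):
        raise ValueError("only cytoplasm and nucleoplasm particles grow")
    state.r[i] += dR
    if state.r[i] >= 2.0 * base_R:
        return _divide_particle(state, i, base_R, variance, rng)
    return None


# ---------------------------------------------------------------------------
# cell builders
# ---------------------------------------------------------------------------


def _seed_annulus(
    rng: np.random.Generator, center, r_in: float, r_out: float, n: int
) -> np.ndarray:
    u = rng.uniform(r_in**2, r_out**2, size=n)
    rad = np.sqrt(u)
    th = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.asarray(center) + np.column_stack([rad * np.cos(th), rad * np.sin(th)])


def project_contacts(stepper: Stepper, relax: float = 0.5, iters: int = 3) -> None:
    """Resolve residual pair overlaps geometrically (build phases only)."""
    st = stepper.state
    _kernels.project_overlaps(
        st.x, st.r, st.species, stepper.pairs.i, stepper.pairs.j,
        stepper.tables.enab, st.mobile, relax, iters,
    )


def _build_body(
    spec: CellSpec,
    params: dict[str, ParticleTypeParams],
    rng_seed: int,
    *,
    with_cell: bool,
    interactions: Optional[InteractionMatrix],
    packing: float,
    packing_nucleus: float,
    grow_frac: float,
    relax_steps: int,
    max_cycles: int,
    min_cycles: int,
    kick_frac: float,
    anneal_cycles: int,
    safety_factor: float,
) -> SimulationState:
    state = SimulationState(
        params,
        interactions.copy() if interactions is not None else None,
        rng_seed=rng_seed,
        safety_factor=safety_factor,
    )
    rng = state.rng
    var = spec.radius_variance
    ncen = spec.nucleus_center()

    compartments = []  # (ring species, inner species, target count, ring cell)
    if with_cell:
        m_idx = _make_ring(state, spec.center, spec.diameter / 2.0, "M", 0)
        pC, pM = params["C"], params["M"]
        r_cov = spec.diameter / 2.0 - pM.R  # outer edge reachable by C discs
        r_seed = spec.diameter / 2.0 - pM.R - 2.0 * pC.R
        r_nuc_cov = spec.nucleus_diameter / 2.0 + params["NM"].R
        r_nuc = r_nuc_cov + pC.R
        area = math.pi * max(r_cov, 0.0) ** 2 - math.pi * (
            r_nuc_cov**2 if spec.nucleus_diameter > 0 else 0.0
        )
        # mean disc area of the +/-variance radius distribution
        mean_a = math.pi * pC.R**2 * (1.0 + var**2 / 3.0)
        nC = max(4, round(packing * area / mean_a))
        xy = _seed_annulus(rng, spec.center, 0.0, r_seed, 4 * nC)
        keep = np.linalg.norm(xy - ncen, axis=1) > r_nuc
        xy = xy[keep][: nC // 2]
        rr = pC.R * rng.uniform(1.0 - var, 1.0 + var, size=xy.shape[0])
        state.add_particles(xy, "C", 0, r=rr)
        compartments.append(("M", "C", nC))
    if spec.nucleus_diameter > 0:
        _make_ring(state, ncen, spec.nucleus_diameter / 2.0, "NM", 0)
        pN, pNM = params["N"], params["NM"]
        r_in = spec.nucleus_diameter / 2.0 - pNM.R - pN.R
        areaN = math.pi * max(r_in, 0.0) ** 2
        mean_aN = math.pi * pN.R**2 * (1.0 + var**2 / 3.0)
        areaN_cov = math.pi * max(
            spec.nucleus_diameter / 2.0 - pNM.R, 0.0
        ) ** 2
        nN = max(2, round(packing_nucleus * areaN_cov / mean_aN))
        xyN = _seed_annulus(rng, ncen, 0.0, max(r_in, 0.0), max(nN // 2, 2))
        rrN = pN.R * rng.uniform(1.0 - var, 1.0 + var, size=xyN.shape[0])
        state.add_particles(xyN, "N", 0, r=rrN)
        compartments.append(("NM", "N", nN))

    thr = spec.tension_threshold
    if thr is None:
        thr = 0.9 * params["M" if with_cell else "NM"].F_a
    main_ring = "M" if with_cell else "NM"

    # Pin the membrane rings while the interior fills: without interior
    # pressure a free cohesive ring would crumple onto itself.  The rings are
    # released for the tension-building phase.
    ring_mask = np.isin(state.species, (0, 2))
    state.mobile[ring_mask] = 0

    state.dt = overdamped_dt(state)
    stepper = Stepper(state, mode="overdamped")
    stepper.step(relax_steps)

    def _mature_count(code: int, base_R: float) -> int:
        # particles past 1.35x base will be split by the maturation sweep
        mask = state.species == code
        return int(mask.sum()) + int((mask & (state.r >= 1.35 * base_R)).sum())

    def _grow_cycle(respect_caps: bool) -> None:
        for _, inner_sp, n_target in compartments:
            code = int(ParticleSpecies[inner_sp])
            mask = state.species == code
            if respect_caps and _mature_count(code, params[inner_sp].R) >= n_target:
                continue
            base_R = params[inner_sp].R
            if spec.growth_rate is not None:
                dR = spec.growth_rate * relax_steps * state.dt
            else:
                dR = grow_frac * base_R
            state.r[mask] += dR
            for i in np.flatnonzero(mask & (state.r >= 2.0 * base_R)):
                _divide_particle(state, int(i), base_R, var, rng)

    # Phase A: fill the pinned compartments up to the packing targets.  A
    # small seeded random agitation lets particles slide into voids instead
    # of jamming at the loose first-contact density.
    interior_codes = (int(ParticleSpecies.C), int(ParticleSpecies.N))
    kick_now = kick_frac
    for cycle in range(max_cycles):
        _grow_cycle(respect_caps=True)
        kick = np.isin(state.species, interior_codes)
        state.x[kick] += (
            kick_now * state.r[kick, None]
            * rng.normal(size=(int(kick.sum()), 2))
        )
        kick_now *= 0.995
        stepper.refresh(reset_xprev=True)
        stepper.step(relax_steps)
        project_contacts(stepper)
        filled = all(
            _mature_count(int(ParticleSpecies[sp]), params[sp].R) >= n
            for _, sp, n in compartments
        )
        if filled:
            break
    else:
        raise BuildError(
            f"interior failed to reach its fill target within {max_cycles} "
            f"growth cycles (n={state.n}, counts per species="
            f"{np.bincount(state.species, minlength=4).tolist()}); "
            "check the growth rate and cycle budget"
        )

    # Maturation sweep: the fill stops on total interior area, which leaves
    # some particles frozen mid-growth; split any particle still above 1.35x
    # its base radius so the final population carries the configured radius
    # distribution.
    for _ in range(8):
        split_any = False
        for _, inner_sp, _ in compartments:
            code = int(ParticleSpecies[inner_sp])
            base_R = params[inner_sp].R
            big = np.flatnonzero(
                (state.species == code) & (state.r >= 1.35 * base_R)
            )
            for i in big:
                _divide_particle(state, int(i), base_R, var, rng)
                split_any = True
        stepper.refresh(reset_xprev=True)
        stepper.step(relax_steps)
        project_contacts(stepper)
        if not split_any:
            break

    # Compaction press: with the rings still pinned to circles, seek the
    # zero-pressure radius of each compartment.  Every round the interior is
    # agitated, relaxed and overlap-projected; the mean radial force the
    # interior exerts on a ring then steers that ring's pinned radius (out if
    # pressed, in if slack) until the ring sits where the annealed tangent
    # packing just touches it.  Pinning to exact circles while compacting
    # prevents ring beads from wandering into interior voids (which would
    # leave interior particles stranded outside).
    ring_specs = [sp_ring for sp_ring, _, _ in compartments]
    radii = {}
    centers = {}
    for sp_ring in ring_specs:
        idx = state.ring_indices(0, sp_ring)
        centers[sp_ring] = state.x[idx].mean(axis=0)
        radii[sp_ring] = float(
            np.linalg.norm(state.x[idx] - centers[sp_ring], axis=1).mean()
        )
    # Steering target: the random-close-packing density of polydisperse
    # tangent discs (or the compartment's own fill target if lower, e.g. the
    # loosely packed nucleoplasm).
    inner_of = {"M": 1, "NM": 3}
    phi_target = {"M": packing, "NM": packing_nucleus}

    def _compartment_phi(sp_ring: str) -> float:
        inner = state.species == inner_of[sp_ring]
        area_in = math.pi * (radii[sp_ring] - params[sp_ring].R) ** 2
        if sp_ring == "M" and "NM" in radii:
            area_in -= math.pi * (radii["NM"] + params["NM"].R) ** 2
        return float(np.sum(math.pi * state.r[inner] ** 2) / max(area_in, 1e-30))

    settled = 0
    for _ in range(anneal_cycles):
        kick = np.isin(state.species, interior_codes)
        state.x[kick] += (
            0.5 * kick_frac * state.r[kick, None]
            * rng.normal(size=(int(kick.sum()), 2))
        )
        stepper.refresh(reset_xprev=True)
        stepper.step(relax_steps)
        project_contacts(stepper)
        stepper.step(relax_steps)
        balanced = True
        for sp_ring in ring_specs:
            idx = state.ring_indices(0, sp_ring)
            phi = _compartment_phi(sp_ring)
            if phi > phi_target[sp_ring] + 0.015:
                radii[sp_ring] *= 1.004
                balanced = False
            elif phi < phi_target[sp_ring] - 0.015:
                radii[sp_ring] *= 0.996
                balanced = False
            rad = state.x[idx] - centers[sp_ring]
            theta = np.arctan2(rad[:, 1], rad[:, 0])
            state.x[idx] = centers[sp_ring] + radii[sp_ring] * np.column_stack(
                [np.cos(theta), np.sin(theta)]
            )
        settled = settled + 1 if balanced else 0
        if settled >= 3:
            break

    # Release the rings gently (small displacement clamp while any residual
    # pressure equilibrates; a sudden release would burst interior particles
    # through transiently opened ring gaps), then keep growing (at a finer
    # rate) until the membrane tension threshold is sustained over two
    # consecutive checks.
    state.mobile[:] = 1
    stepper.refresh(reset_xprev=True)
    stepper.dmax *= 0.1
    stepper.step(6 * relax_steps)
    project_contacts(stepper)
    stepper.refresh(reset_xprev=True)
    stepper.step(2 * relax_steps)
    project_contacts(stepper)
    grow_frac *= 0.25
    relax_b = 3 * relax_steps
    n_cap = round(1.10 * sum(n for _, _, n in compartments))
    hits = 0
    for cycle in range(max_cycles):
        tension = membrane_tension(state, 0, main_ring)
        interior_n = int(np.isin(state.species, (1, 3)).sum())
        if tension >= thr or interior_n >= n_cap:
            hits += 1
            if hits >= 2 and cycle >= min_cycles:
                break
            # confirm without growing further
            stepper.step(relax_b)
            continue
        hits = 0
        _grow_cycle(respect_caps=False)
        for ring_sp in ring_specs:
            maintain_membrane(state, 0, ring_sp, max_insert=2)
        stepper.refresh(reset_xprev=True)
        stepper.step(relax_b)
        project_contacts(stepper)
    else:
        tension = membrane_tension(state, 0, main_ring)
        if tension < thr:
            raise BuildError(
                f"membrane tension {tension:.3e} N below threshold {thr:.3e} N "
                f"after {max_cycles} growth cycles "
                f"(n={state.n}, counts per species="
                f"{np.bincount(state.species, minlength=4).tolist()})"
            )
    stepper.refresh(reset_xprev=True)
    stepper.step(2 * relax_steps)
    # initialisation cleanup: the rare interior particle that was squeezed
    # through a ring by a transient force chain is removed rather than left
    # in the wrong compartment
    bad = _missorted_indices(state, 0)
    if bad.size:
        state.remove_particles(bad)
    state.v[:] = 0.0
    return state


def _membrane_short_range(
    params: dict[str, ParticleTypeParams], membrane_range: float
) -> dict[str, ParticleTypeParams]:
    """Cap the membrane species' influence radii at the cadherin range.

    The baseline influence radius (2 um) is appropriate for the fluid-like
    cytoplasm and nucleoplasm, but membrane-bound adhesion is short-range
    (0.2 um); with a micrometre-range membrane-membrane attraction a closed
    ring clumps onto itself instead of coating the cell surface.
    """
    out = dict(params)
    for sp_m in ("M", "NM"):
        out[sp_m] = out[sp_m].replace(
            delta=min(out[sp_m].delta, membrane_range)
        )
    return out


def build_round_cell(
    spec: CellSpec,
    params: dict[str, ParticleTypeParams],
    rng_seed: int = 0,
    resolution: float = 1.0,
    interactions: Optional[InteractionMatrix] = None,
    packing: float = 0.87,
    packing_nucleus: float = 0.50,
    grow_frac: float = 0.006,
    relax_steps: int = 15,
    max_cycles: int = 1500,
    min_cycles: int = 2,
    kick_frac: float = 0.04,
    anneal_cycles: int = 40,
    membrane_range: float = 0.2e-6,
    safety_factor: float = 0.9,
) -> SimulationState:
    """Grow a round cell (membrane + cytoplasm + nucleus) to target tension.

    ``resolution`` > 1 coarsens the discretisation (all particle radii and
    influence radii scaled up), trading fidelity for speed; the packing
    fractions control the interior target particle numbers (the growth loop
    starts from half of those and divides its way up, so the final count is
    emergent).
    """
    params_r = _membrane_short_range(
        scale_resolution(params, resolution), membrane_range * resolution
    )
    return _build_body(
        spec, params_r, rng_seed,
        with_cell=True, interactions=interactions,
        packing=packing, packing_nucleus=packing_nucleus,
        grow_frac=grow_frac, relax_steps=relax_steps,
        max_cycles=max_cycles, min_cycles=min_cycles,
        kick_frac=kick_frac, anneal_cycles=anneal_cycles,
        safety_factor=safety_factor,
    )


def build_isolated_nucleus(
    diameter: float = 6e-6,
    params: Optional[dict[str, ParticleTypeParams]] = None,
    rng_seed: int = 0,
    resolution: float = 1.0,
    interactions: Optional[InteractionMatrix] = None,
    **kw,
) -> SimulationState:
    """Grow an isolated nucleus (nuclear membrane ring + nucleoplasm)."""
    from .params import default_parameters

    if params is None:
        params = default_parameters("table2")
    params_r = _membrane_short_range(
        scale_resolution(params, resolution),
        kw.pop("membrane_range", 0.2e-6) * resolution,
    )
    spec = CellSpec(diameter=2 * diameter, nucleus_diameter=diameter)
    defaults = dict(
        packing=1.0, packing_nucleus=kw.pop("packing_nucleus", 0.40),
        grow_frac=kw.pop("grow_frac", 0.006),
        relax_steps=kw.pop("relax_steps", 15),
        max_cycles=kw.pop("max_cycles", 1500),
        min_cycles=kw.pop("min_cycles", 2),
        kick_frac=kw.pop("kick_frac", 0.04),
        anneal_cycles=kw.pop("anneal_cycles", 40),
        safety_factor=kw.pop("safety_factor", 0.9),
    )
    return _build_body(
        spec, params_r, rng_seed, with_cell=False,
        interactions=interactions, **defaults,
    )


# ---------------------------------------------------------------------------
# geometry probes
# ---------------------------------------------------------------------------


def cell_extent(state: SimulationState, cell: int) -> tuple[float, float]:
    """(width, height) of a cell's membrane-ring bounding box."""
    idx = state.ring_indices(cell, "M")
    if idx.size == 0:
        idx = state.ring_indices(cell, "NM")
    x = state.x[idx]
    r = state.r[idx]
    width = float((x[:, 0] + r).max() - (x[:, 0] - r).min())
    height = float((x[:, 1] + r).max() - (x[:, 1] - r).min())
    return width, height


def ring_polygon_area(state: SimulationState, cell: int, species: str = "M") -> float:
    idx = state.ring_indices(cell, species)
    x = state.x[idx]
    return 0.5 * abs(
        float(np.sum(x[:, 0] * np.roll(x[:, 1], -1) - np.roll(x[:, 0], -1) * x[:, 1]))
    )


def _missorted_indices(state: SimulationState, cell: int) -> np.ndarray:
    """Interior particles that ended up outside their compartment."""
    bad: list[int] = []
    mask_cell = state.cell_id == cell
    has_m = bool((mask_cell & (state.species == 0)).any())
    has_nm = bool((mask_cell & (state.species == 2)).any())
    c_idx = np.flatnonzero(mask_cell & (state.species == 1))
    n_idx = np.flatnonzero(mask_cell & (state.species == 3))
    if has_m and c_idx.size:
        poly = MplPath(state.x[state.ring_indices(cell, "M")])
        bad.extend(c_idx[~poly.contains_points(state.x[c_idx])].tolist())
    if has_nm:
        poly_n = MplPath(state.x[state.ring_indices(cell, "NM")])
        if n_idx.size:
            bad.extend(n_idx[~poly_n.contains_points(state.x[n_idx])].tolist())
        if c_idx.size:
            bad.extend(c_idx[poly_n.contains_points(state.x[c_idx])].tolist())
    return np.unique(np.asarray(bad, dtype=int))


def compartment_violations(state: SimulationState, cell: int) -> int:
    """Number of interior particles outside their membrane ring.

    Cytoplasm must stay inside the cell-membrane polygon (and outside the
    nuclear one); nucleoplasm must stay inside the nuclear-membrane polygon.
    """
    bad = 0
    mask_cell = state.cell_id == cell
    m_idx = state.ring_indices(cell, "M") if (
        (state.species[mask_cell] == 0).any()
    ) else np.zeros(0, int)
    nm_idx = state.ring_indices(cell, "NM") if (
        (state.species[mask_cell] == 2).any()
    ) else np.zeros(0, int)
    c_pts = state.x[mask_cell & (state.species == 1)]
    n_pts = state.x[mask_cell & (state.species == 3)]
    if m_idx.size and c_pts.size:
        poly = MplPath(state.x[m_idx])
        bad += int((~poly.contains_points(c_pts)).sum())
    if nm_idx.size:
        poly_n = MplPath(state.x[nm_idx])
        if n_pts.size:
            bad += int((~poly_n.contains_points(n_pts)).sum())
        if c_pts.size:
            bad += int(poly_n.contains_points(c_pts).sum())
    return bad


# ---------------------------------------------------------------------------
# spreading and layers
# ---------------------------------------------------------------------------


@dataclass
class SpreadResult:
    state: SimulationState
    aspect_ratio: float  # width / height
    attached: bool
    width: float
    height: float


def _translate_cells_above_line(state: SimulationState, y_line: float = 0.0) -> None:
    """Shift all particles so the assembly rests tangent on y = y_line."""
    ymin = float((state.x[:, 1] - state.r).min())
    state.x[:, 1] += y_line - ymin


def make_basement_membrane(
    k_a: float, delta: float, y: float = 0.0, F_a: float = 0.0
) -> BoundaryObject:
    return BoundaryObject(
        "BM", point=np.array([0.0, y]), normal=np.array([0.0, 1.0]),
        k_a=k_a, delta=delta, F_a=F_a, name="basement membrane",
    )


def spread_cell(
    cellstate: SimulationState,
    k_a_bm: float = 1e-11,
    delta_bm: float = 3e-6,
    bm: Optional[BoundaryObject] = None,
    sim_steps: int = 12_000,
    maintain_every: int = 50,
) -> SpreadResult:
    """Let a round cell attach to and spread on a basement membrane.

    The cell is placed tangent to the line, membrane-ring maintenance stays
    active while the attraction of membrane particles to the basement
    membrane flattens the cell.  Reports the final width/height aspect ratio
    and whether any membrane particle remains within the adhesion range.
    """
    state = cellstate
    if bm is None:
        bm = make_basement_membrane(k_a_bm, delta_bm)
    _translate_cells_above_line(state, float(bm.point[1]))
    state.boundaries.append(bm)
    state.dt = overdamped_dt(state)
    stepper = Stepper(state, mode="overdamped")
    # finite membrane reservoir: area regulation stops once the ring has
    # grown past this multiple of its initial length, which gives spreading
    # a stable endpoint
    m_budget = {
        int(c): round(1.8 * state.ring_indices(int(c), "M").size)
        for c in state.cell_ids()
    }
    for _ in range(max(1, sim_steps // maintain_every)):
        stepper.step(maintain_every)
        inserted = 0
        for c in state.cell_ids():
            if state.ring_indices(int(c), "M").size < m_budget[int(c)]:
                inserted += maintain_membrane(state, int(c), "M", max_insert=3)
        if inserted:
            stepper.refresh(reset_xprev=True)
    # normalise the final contact state (tangent packing) so spread and
    # round configurations are mechanically comparable
    for _ in range(5):
        project_contacts(stepper)
        stepper.step(50)
    state.v[:] = 0.0
    width, height = cell_extent(state, int(state.cell_ids()[0]))
    m_mask = state.species == 0
    dist = bm.signed_distance(state.x[m_mask]) - state.r[m_mask]
    attached = bool((dist <= bm.delta).any())
    return SpreadResult(state, width / height, attached, width, height)


def build_epithelial_layer(
    n_cells: int,
    cell_spec: CellSpec,
    params: dict[str, ParticleTypeParams],
    k_a_bm: float = 1e-11,
    delta_bm: float = 0.3e-6,
    k_a_m: Optional[float] = None,
    delta_m: Optional[float] = None,
    rng_seed: int = 0,
    resolution: float = 1.0,
    interactions: Optional[InteractionMatrix] = None,
    settle_steps: int = 4000,
    maintain_every: int = 100,
    bm_F_a: float = 0.0,
    **build_kw,
) -> SimulationState:
    """Row of ``n_cells`` cells resting on a basement membrane.

    One reference cell is grown to its tension threshold and replicated at
    the positions ``(i + 1/2) diameter`` along the line, with a small seeded
    jitter to break the artificial symmetry; the assembly is then settled to
    contact equilibrium under cell-cell (M-M) and cell-BM (M-BM) adhesion.
    Nucleus polarisation (``cell_spec.nucleus_center_height``) carries over
    from the reference cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    # cadherin overrides: the membrane species' adhesion spring constant and
    # influence radius control cell-cell adhesion
    params = dict(params)
    if k_a_m is not None:
        params["M"] = params["M"].replace(k_a=k_a_m)
    if delta_m is not None:
        params["M"] = params["M"].replace(delta=delta_m)
        build_kw.setdefault("membrane_range", delta_m)
    ref = build_round_cell(
        cell_spec, params, rng_seed=rng_seed, resolution=resolution,
        interactions=interactions, **build_kw,
    )
    D = cell_spec.diameter
    state = SimulationState(
        ref.type_params,
        ref.interactions.copy(),
        rng_seed=rng_seed,
        safety_factor=ref.safety_factor,
    )
    rng = state.rng
    ref_ymin = float((ref.x[:, 1] - ref.r).min())
    for c in range(n_cells):
        shift = np.array(
            [
                (c + 0.5) * D - float(ref.x[:, 0].mean()),
                -ref_ymin,
            ]
        ) + rng.normal(0.0, 0.02 * D, size=2) * np.array([1.0, 0.0])
        base = state.n
        state.add_particles(
            ref.x + shift,
            ref.species.copy(),
            cell_id=c,
            r=ref.r.copy(),
        )
        # splice ring links with the index offset
        state.ring_prev[base:] = np.where(
            ref.ring_prev >= 0, ref.ring_prev + base, -1
        )
        state.ring_next[base:] = np.where(
            ref.ring_next >= 0, ref.ring_next + base, -1
        )
    bm = make_basement_membrane(k_a_bm, delta_bm, F_a=bm_F_a)
    state.boundaries.append(bm)
    # sanity: initial placement must not overlap between neighbouring cells
    for c in range(n_cells - 1):
        wa, _ = cell_extent(state, c)
        if wa > 2.05 * D:
            raise BuildError("initial layer placement overlaps beyond tolerance")
    state.dt = overdamped_dt(state)
    stepper = Stepper(state, mode="overdamped")
    for _ in range(max(1, settle_steps // maintain_every)):
        stepper.step(maintain_every)
        inserted = sum(
            maintain_membrane(state, int(c), "M", max_insert=2)
            for c in state.cell_ids()
        )
        if inserted:
            stepper.refresh(reset_xprev=True)
    state.v[:] = 0.0
    return state
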