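"""Simulation state: particle arrays, boundary objects, time stepping data.

The state is stored struct-of-arrays (positions, velocities, radii, species
codes, cell ids, membrane-ring links) for efficient force evaluation; a
:class:`Particle` view object is provided for convenient per-particle access.

Boundary objects (testing plates, basement membrane, compression walls) are
contact *lines*: a point, a unit normal pointing into the simulation domain,
adhesion constants, and a piecewise-constant velocity schedule.  A boundary
behaves exactly like a particle of infinite radius in the contact law.

Checkpoints are HDF5 files that round-trip the full state bit-identically,
including the random generator state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np

from .params import ParticleTypeParams, particle_mass
from .species import InteractionMatrix, PARTICLE_LABELS, ParticleSpecies

__all__ = ["MotionSchedule", "BoundaryObject", "Particle", "SimulationState"]


@dataclass
class MotionSchedule:
    """Piecewise-constant velocity schedule v(t).

    ``times[i]`` is the start of segment ``i``; the velocity before
    ``times[0]`` is zero.  A static boundary has an empty schedule.
    """

    times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    velocities: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    @classmethod
    def static(cls) -> "MotionSchedule":
        return cls()

    @classmethod
    def constant(cls, velocity, start: float = 0.0) -> "MotionSchedule":
        return cls(np.array([start]), np.asarray(velocity, float).reshape(1, 2))

    def velocity_at(self, t: float) -> np.ndarray:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return np.zeros(2)
        return self.velocities[idx].copy()

    @property
    def is_static(self) -> bool:
        return self.times.size == 0 or not np.any(self.velocities)


@dataclass
class BoundaryObject:
    """Plate (``P``) or basement membrane (``BM``) as an adhesive contact line.

    ``normal`` is the unit normal pointing from the line into the simulation
    domain.  ``E is None`` means perfectly rigid (the Hertz compliance of the
    boundary side is zero).  ``k_a = 0`` together with ``F_a = 0`` gives a
    purely repulsive, non-adhesive boundary.
    """

    species: str  # "P" or "BM"
    point: np.ndarray
    normal: np.ndarray
    k_a: float = 0.0
    delta: float = 0.1e-6
    F_a: float = 0.0
    E: Optional[float] = None
    nu: float = 0.5
    beta: float = 0.0
    motion: MotionSchedule = field(default_factory=MotionSchedule.static)
    name: str = ""

    def __post_init__(self):
        self.point = np.asarray(self.point, float).copy()
        self.normal = np.asarray(self.normal, float).copy()
        n = np.linalg.norm(self.normal)
        if not math.isclose(n, 1.0, rel_tol=1e-9):
            if n == 0:
                raise ValueError("boundary normal must be non-zero")
            self.normal = self.normal / n
        if self.species not in ("P", "BM"):
            raise ValueError(f"boundary species must be 'P' or 'BM', got {self.species!r}")

    def signed_distance(self, x: np.ndarray) -> np.ndarray:
        """Distance of point(s) from the line, positive on the domain side."""
        return (np.asarray(x) - self.point) @ self.normal

    def advance(self, t: float, dt: float) -> None:
        """Move the line by its scheduled velocity over [t, t + dt)."""
        self.point = self.point + self.motion.velocity_at(t) * dt


@dataclass
class Particle:
    """Read/write view of one particle in a :class:`SimulationState`."""

    state: "SimulationState"
    index: int

    @property
    def species(self) -> str:
        return PARTICLE_LABELS[self.state.species[self.index]]

    @property
    def cell_id(self) -> int:
        return int(self.state.cell_id[self.index])

    @property
    def x(self) -> np.ndarray:
        return self.state.x[self.index]

    @property
    def v(self) -> np.ndarray:
        return self.state.v[self.index]

    @property
    def R(self) -> float:
        return float(self.state.r[self.index])

    @R.setter
    def R(self, value: float) -> None:
        self.state.r[self.index] = value

    @property
    def ring_prev(self) -> int:
        return int(self.state.ring_prev[self.index])

    @property
    def ring_next(self) -> int:
        return int(self.state.ring_next[self.index])


class SimulationState:
    """Full particle set + boundaries + stepping data.

    Arrays
    ------
    x : (n, 2) float64   positions [m]
    v : (n, 2) float64   velocities [m/s] (estimated one step behind)
    r : (n,) float64     current radii [m]
    species : (n,) int8  species codes (0=M, 1=C, 2=NM, 3=N)
    cell_id : (n,) int32
    ring_prev/ring_next : (n,) int64, -1 where the particle is not on a ring
    """

    def __init__(
        self,
        type_params: dict[str, ParticleTypeParams],
        interactions: Optional[InteractionMatrix] = None,
        rng_seed: int = 0,
        dt: float = 1e-4,
        safety_factor: float = 0.9,
        mass_scale: float = 1.0,
    ):
        self.type_params = type_params
        self.interactions = interactions if interactions is not None else InteractionMatrix.default()
        self.boundaries: list[BoundaryObject] = []
        self.t = 0.0
        self.dt = float(dt)
        if not (0.0 < safety_factor <= 1.0):
            raise ValueError("safety_factor must be in (0, 1]")
        self.safety_factor = float(safety_factor)
        self.mass_scale = float(mass_scale)
        self.rng_seed = int(rng_seed)
        self.rng = np.random.default_rng(rng_seed)

        self.x = np.zeros((0, 2))
        self.v = np.zeros((0, 2))
        self.r = np.zeros(0)
        self.species = np.zeros(0, dtype=np.int8)
        self.cell_id = np.zeros(0, dtype=np.int32)
        self.ring_prev = np.zeros(0, dtype=np.int64)
        self.ring_next = np.zeros(0, dtype=np.int64)
        self.mobile = np.zeros(0, dtype=np.uint8)

    # -- construction ------------------------------------------------------

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def add_particles(
        self,
        x: np.ndarray,
        species: str | Sequence[int],
        cell_id: int,
        r: np.ndarray | float | None = None,
        v: Optional[np.ndarray] = None,
        ring_prev=None,
        ring_next=None,
    ) -> np.ndarray:
        """Append particles; returns their indices."""
        x = np.atleast_2d(np.asarray(x, float))
        k = x.shape[0]
        if isinstance(species, str):
            sp = np.full(k, int(ParticleSpecies[species]), dtype=np.int8)
        else:
            sp = np.asarray(species, dtype=np.int8)
        if r is None:
            r = np.array([self.type_params[PARTICLE_LABELS[s]].R for s in sp])
        r = np.broadcast_to(np.asarray(r, float), (k,)).copy()
        v = np.zeros((k, 2)) if v is None else np.atleast_2d(np.asarray(v, float)).copy()
        start = self.n
        self.x = np.concatenate([self.x, x])
        self.v = np.concatenate([self.v, v])
        self.r = np.concatenate([self.r, r])
        self.species = np.concatenate([self.species, sp])
        self.cell_id = np.concatenate(
            [self.cell_id, np.full(k, cell_id, dtype=np.int32)]
        )
        rp = np.full(k, -1, dtype=np.int64) if ring_prev is None else np.asarray(ring_prev, np.int64)
        rn = np.full(k, -1, dtype=np.int64) if ring_next is None else np.asarray(ring_next, np.int64)
        self.ring_prev = np.concatenate([self.ring_prev, rp])
        self.ring_next = np.concatenate([self.ring_next, rn])
        self.mobile = np.concatenate([self.mobile, np.ones(k, dtype=np.uint8)])
        return np.arange(start, self.n)

    def remove_particles(self, indices) -> None:
        """Delete particles and renumber the membrane-ring links."""
        drop = np.zeros(self.n, dtype=bool)
        drop[np.asarray(indices, int)] = True
        if drop[np.isin(self.species, (0, 2))].any():
            raise ValueError("cannot remove membrane-ring particles")
        keep = ~drop
        remap = -np.ones(self.n, dtype=np.int64)
        remap[keep] = np.arange(int(keep.sum()))
        for name in ("x", "v", "r", "species", "cell_id", "mobile"):
            setattr(self, name, getattr(self, name)[keep])
        self.ring_prev = np.where(
            self.ring_prev[keep] >= 0, remap[self.ring_prev[keep]], -1
        )
        self.ring_next = np.where(
            self.ring_next[keep] >= 0, remap[self.ring_next[keep]], -1
        )

    def particle(self, i: int) -> Particle:
        return Particle(self, i)

    def masses(self) -> np.ndarray:
        """Per-particle masses from the mass rule, including the mass scale."""
        dens = np.array(
            [self.type_params[l].density for l in PARTICLE_LABELS], dtype=float
        )
        return dens[self.species] * (4.0 / 3.0) * np.pi * self.r**3 * self.mass_scale

    def params_of(self, i: int) -> ParticleTypeParams:
        return self.type_params[PARTICLE_LABELS[self.species[i]]]

    def cell_ids(self) -> np.ndarray:
        return np.unique(self.cell_id[self.cell_id >= 0])

    def ring_indices(self, cell: int, species: str = "M") -> np.ndarray:
        """Indices of a cell's membrane ring, in ring order."""
        code = int(ParticleSpecies[species])
        members = np.flatnonzero((self.cell_id == cell) & (self.species == code))
        if members.size == 0:
            return members
        start = members[0]
        order = [start]
        j = int(self.ring_next[start])
        while j != start:
            if j < 0 or len(order) > self.n:
                raise ValueError(f"ring of cell {cell} species {species} is not closed")
            order.append(j)
            j = int(self.ring_next[j])
        return np.asarray(order)

    def copy(self) -> "SimulationState":
        out = SimulationState(
            {k: v.replace() for k, v in self.type_params.items()},
            self.interactions.copy(),
            rng_seed=self.rng_seed,
            dt=self.dt,
            safety_factor=self.safety_factor,
            mass_scale=self.mass_scale,
        )
        out.t = self.t
        for name in ("x", "v", "r", "species", "cell_id", "ring_prev", "ring_next", "mobile"):
            setattr(out, name, getattr(self, name).copy())
        out.boundaries = [
            BoundaryObject(
                b.species, b.point.copy(), b.normal.copy(), b.k_a, b.delta, b.F_a,
                b.E, b.nu, b.beta,
                MotionSchedule(b.motion.times.copy(), b.motion.velocities.copy()),
                b.name,
            )
            for b in self.boundaries
        ]
        out.rng = np.random.default_rng()
        out.rng.bit_generator.state = self.rng.bit_generator.state
        return out

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        """Write a self-describing HDF5 checkpoint."""
        with h5py.File(path, "w") as f:
            for name in ("x", "v", "r", "species", "cell_id", "ring_prev", "ring_next", "mobile"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["t"] = self.t
            f.attrs["dt"] = self.dt
            f.attrs["safety_factor"] = self.safety_factor
            f.attrs["mass_scale"] = self.mass_scale
            f.attrs["rng_seed"] = self.rng_seed
            f.attrs["rng_state"] = json.dumps(self.rng.bit_generator.state)
            f.attrs["type_params"] = json.dumps(
                {k: vars(v) for k, v in self.type_params.items()}
            )
            f.attrs["interactions"] = json.dumps(sorted(self.interactions.pairs()))
            f.attrs["boundaries"] = json.dumps(
                [
                    {
                        "species": b.species,
                        "point": b.point.tolist(),
                        "normal": b.normal.tolist(),
                        "k_a": b.k_a,
                        "delta": b.delta,
                        "F_a": b.F_a,
                        "E": b.E,
                        "nu": b.nu,
                        "beta": b.beta,
                        "times": b.motion.times.tolist(),
                        "velocities": b.motion.velocities.tolist(),
                        "name": b.name,
                    }
                    for b in self.boundaries
                ]
            )

    @classmethod
    def load(cls, path) -> "SimulationState":
        with h5py.File(path, "r") as f:
            tp = {
                k: ParticleTypeParams(**v)
                for k, v in json.loads(f.attrs["type_params"]).items()
            }
            im = InteractionMatrix(
                [(p[0], p[-1]) for p in json.loads(f.attrs["interactions"])]
            )
            state = cls(
                tp,
                im,
                rng_seed=int(f.attrs["rng_seed"]),
                dt=float(f.attrs["dt"]),
                safety_factor=float(f.attrs["safety_factor"]),
                mass_scale=float(f.attrs["mass_scale"]),
            )
            state.t = float(f.attrs["t"])
            for name in ("x", "v", "r", "species", "cell_id", "ring_prev", "ring_next", "mobile"):
                setattr(state, name, f[name][...])
            state.rng.bit_generator.state = json.loads(f.attrs["rng_state"])
            for braw in json.loads(f.attrs["boundaries"]):
                state.boundaries.append(
                    BoundaryObject(
                        braw["species"],
                        np.asarray(braw["point"]),
                        np.asarray(braw["normal"]),
                        braw["k_a"],
                        braw["delta"],
                        braw["F_a"],
                        braw["E"],
                        braw["nu"],
                        braw["beta"],
                        MotionSchedule(
                            np.asarray(braw["times"], float),
                            np.asarray(braw["velocities"], float).reshape(-1, 2),
                        ),
                        braw["name"],
                    )
                )
        return state
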