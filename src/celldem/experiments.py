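"""Simulation experiment drivers and their metrics.

Implements the mechanical test protocols: strain-controlled microplate
compression of isolated nuclei and whole (round or spread) cells, with the
2D plate reaction force extrapolated to an axisymmetric 3D estimate;
wall-driven compression of an epithelial cell layer on a basement membrane,
with buckle detection; and the parameter sweeps that map how membrane and
basement-membrane adhesion control cell shape.

All drivers run in the overdamped quasi-static mode; boundaries move at the
prescribed rates (default 0.25 um/s) and results are sampled on a strain
grid (default every 1%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .assembly import (
    CellSpec,
    build_epithelial_layer,
    cell_extent,
    maintain_membrane,
    make_basement_membrane,
    project_contacts,
)
from .integrate import Stepper, overdamped_dt
from .params import ParticleTypeParams
from .state import BoundaryObject, MotionSchedule, SimulationState

__all__ = [
    "CompressionRecord",
    "BuckleReport",
    "plate_compression",
    "axisymmetric_force",
    "wall_compression",
    "count_buckles",
    "detect_buckle_runs",
    "nucleus_position_experiment",
    "shape_sweep",
]


@dataclass
class CompressionRecord:
    """Time series of a strain-controlled plate compression."""

    times: np.ndarray
    displacement: np.ndarray  # plate travel [m]
    strain: np.ndarray  # displacement / initial height
    F2d: np.ndarray  # total 2D reaction force on the moving plate [N]
    F3d: np.ndarray  # axisymmetric-extrapolated force [N]
    height0: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "displacement_m": self.displacement,
                "strain": self.strain,
                "F2d_N": self.F2d,
                "F3d_N": self.F3d,
            }
        )

    def force_at(self, strain: float, smooth: int = 3, which: str = "F3d") -> float:
        """Force at a given strain, averaged over ``smooth`` nearest samples."""
        f = getattr(self, which)
        order = np.argsort(np.abs(self.strain - strain))[:smooth]
        return float(f[order].mean())


@dataclass
class BuckleReport:
    """Detected delaminated regions of a compressed cell layer."""

    n_buckles: int
    spans: list[tuple[float, float, float]]  # (start x, end x, peak height)
    threshold: float
    basal_heights: dict[int, float] = field(default_factory=dict)


def axisymmetric_force(contacts, x_C) -> float:
    """Extrapolate 2D plate contact forces to an axisymmetric 3D total.

    Each contacting particle's force is weighted by the number of particle
    copies that would lie on its circle around the symmetry axis through
    ``x_C``: circumference ``2 pi |x_I - x_C|`` divided by the particle
    diameter, floored at one for the particle on the axis itself.
    """
    x_C = np.asarray(x_C, float)
    total = 0.0
    for F_I, x_I, R_I in contacts:
        rho = float(np.linalg.norm(np.asarray(x_I, float) - x_C))
        weight = max(1.0, 2.0 * math.pi * rho / (2.0 * R_I))
        total += float(F_I) * weight
    return total


def _plate_contacts(state, tables, plate, plate_index):
    """Per-particle normal force contributions pressing on a plate."""
    from . import _kernels
    from .mechanics import L0, _boundary_arrays

    n = state.n
    F = np.zeros((n, 2))
    vsum = np.zeros((n, 2))
    ncnt = np.zeros(n, dtype=np.int64)
    react = np.zeros((max(len(state.boundaries), 1), 2))
    bpoint, bnormal, bvel = _boundary_arrays(state)
    only = slice(plate_index, plate_index + 1)
    _kernels.boundary_forces(
        state.x, state.v, state.r, state.species,
        bpoint[only], bnormal[only], bvel[only],
        tables.b_ka[only], tables.b_kr[only], tables.b_fa[only],
        tables.b_delta[only], tables.b_enab[only], L0,
        F, vsum, ncnt, react, np.inf,
    )
    # a particle pressed by the plate is pushed along the plate's inward
    # normal; its (equal and opposite) push on the plate is the contribution
    fn = F @ plate.normal
    contacts = []
    for i in np.flatnonzero(fn > 0.0):
        contacts.append((float(fn[i]), state.x[i].copy(), float(state.r[i])))
    # total reaction on the plate, positive when pressed outward
    return contacts, -float(react[0] @ plate.normal)


def plate_compression(
    cellstate: SimulationState,
    target_strain: float,
    rate: float = 0.25e-6,
    sample_strain: float = 0.01,
    maintain: bool = True,
    x_C: Optional[float] = None,
) -> CompressionRecord:
    """Strain-controlled compression between parallel plates.

    The assembly is placed on a static lower plate; a moving upper plate
    advances at ``rate`` until ``target_strain`` of the initial height,
    recording the total 2D reaction force and the axisymmetric 3D
    extrapolation at every ``sample_strain`` increment.
    """
    state = cellstate
    # static support below, moving plate above
    ymin = float((state.x[:, 1] - state.r).min())
    ymax = float((state.x[:, 1] + state.r).max())
    have_support = any(
        b.normal[1] > 0.9 for b in state.boundaries
    )
    if not have_support:
        state.boundaries.append(
            BoundaryObject(
                "P", point=np.array([0.0, ymin]), normal=np.array([0.0, 1.0]),
                name="support plate",
            )
        )
    plate = BoundaryObject(
        "P", point=np.array([0.0, ymax]), normal=np.array([0.0, -1.0]),
        motion=MotionSchedule.constant([0.0, -rate], start=state.t),
        name="moving plate",
    )
    state.boundaries.append(plate)
    plate_index = len(state.boundaries) - 1
    height0 = ymax - ymin
    if x_C is None:
        x_C = float(state.x[:, 0].mean())

    state.dt = overdamped_dt(state, v_drive=rate)
    stepper = Stepper(state, mode="overdamped")
    steps_per_sample = max(1, round(sample_strain * height0 / (rate * state.dt)))

    times, disp, strain, F2, F3 = [], [], [], [], []
    t0 = state.t

    def measure():
        contacts, f2d = _plate_contacts(state, stepper.tables, plate, plate_index)
        f3d = axisymmetric_force(contacts, np.array([x_C, plate.point[1]]))
        return max(f2d, 0.0), f3d

    def record(samples):
        d = rate * (state.t - t0)
        times.append(state.t)
        disp.append(d)
        strain.append(d / height0)
        F2.append(float(np.mean([s[0] for s in samples])))
        F3.append(float(np.mean([s[1] for s in samples])))

    record([measure()])
    n_samples = max(0, round(target_strain / sample_strain))
    sub = max(1, steps_per_sample // 8)
    for k in range(n_samples):
        done = 0
        window = []
        while done < steps_per_sample:
            stepper.step(min(sub, steps_per_sample - done))
            done += sub
            # keep the interior volume: residual contact overlaps are
            # projected out so cells deform rather than silently compress
            project_contacts(stepper)
            # stiff contacts flicker; the reported force is the average of
            # several readings across the sampling window
            window.append(measure())
        if maintain:
            ins = sum(
                maintain_membrane(state, int(c), "M", max_insert=2)
                for c in state.cell_ids()
            )
            if ins:
                stepper.refresh(reset_xprev=True)
        record(window)
    return CompressionRecord(
        np.asarray(times), np.asarray(disp), np.asarray(strain),
        np.asarray(F2), np.asarray(F3), height0,
    )


# ---------------------------------------------------------------------------
# layer compression and buckling
# ---------------------------------------------------------------------------


def detect_buckle_runs(
    order_x: np.ndarray,
    heights: np.ndarray,
    height_threshold: float,
    min_span: float,
) -> list[tuple[float, float, float]]:
    """Maximal runs of contiguous lifted cells.

    ``order_x`` are cell centroid x positions sorted left to right and
    ``heights`` the matching basal heights.  A buckle is a maximal run of
    cells with basal height above the threshold whose horizontal span is at
    least ``min_span``; single-cell runs qualify through the span of the
    cell position set (span floor of one cell width is applied by the
    caller via ``min_span``).
    """
    spans = []
    i = 0
    ncell = len(order_x)
    while i < ncell:
        if heights[i] > height_threshold:
            j = i
            while j + 1 < ncell and heights[j + 1] > height_threshold:
                j += 1
            x0, x1 = float(order_x[i]), float(order_x[j])
            peak = float(heights[i : j + 1].max())
            width = x1 - x0
            if j > i:
                if width >= min_span:
                    spans.append((x0, x1, peak))
            else:
                # single lifted cell: its own footprint is its span
                spans.append((x0, x1, peak))
            i = j + 1
        else:
            i += 1
    return spans


def count_buckles(
    layerstate: SimulationState,
    bm: Optional[BoundaryObject] = None,
    height_threshold: Optional[float] = None,
    min_span: Optional[float] = None,
    cell_diameter: float = 15e-6,
) -> BuckleReport:
    """Detect delaminated (buckled) regions of a cell layer.

    Each cell's basal height is the smallest distance from its membrane
    particles to the basement-membrane line; a buckle is a contiguous run of
    cells lifted above ``height_threshold`` (default half a cell diameter)
    spanning at least ``min_span`` horizontally (default half a diameter).
    """
    if bm is None:
        bms = [b for b in layerstate.boundaries if b.species == "BM"]
        if not bms:
            raise ValueError("layer state has no basement membrane boundary")
        bm = bms[0]
    if height_threshold is None:
        height_threshold = 0.5 * cell_diameter
    if min_span is None:
        min_span = 0.5 * cell_diameter
    cells = layerstate.cell_ids()
    cx = np.empty(cells.size)
    hts = np.empty(cells.size)
    for k, c in enumerate(cells):
        m = (layerstate.cell_id == c) & (layerstate.species == 0)
        d = bm.signed_distance(layerstate.x[m]) - layerstate.r[m]
        hts[k] = float(d.min())
        cx[k] = float(layerstate.x[m, 0].mean())
    order = np.argsort(cx)
    spans = detect_buckle_runs(cx[order], hts[order], height_threshold, min_span)
    return BuckleReport(
        n_buckles=len(spans),
        spans=spans,
        threshold=height_threshold,
        basal_heights={int(c): float(h) for c, h in zip(cells, hts)},
    )


@dataclass
class WallCompressionResult:
    strains: np.ndarray
    reports: list[BuckleReport]
    state: SimulationState

    def onset_strain(self) -> Optional[float]:
        """Smallest sampled strain with at least one buckle, or None."""
        for s, rep in zip(self.strains, self.reports):
            if rep.n_buckles >= 1:
                return float(s)
        return None

    def report_at(self, strain: float) -> BuckleReport:
        k = int(np.argmin(np.abs(self.strains - strain)))
        return self.reports[k]


def wall_compression(
    layerstate: SimulationState,
    target_strain: float,
    rate: float = 0.25e-6,
    sample_strain: float = 0.01,
    cell_diameter: float = 15e-6,
    height_threshold: Optional[float] = None,
    min_span: Optional[float] = None,
    maintain: bool = False,
) -> WallCompressionResult:
    """Compress a cell layer between a moving left wall and a static right wall.

    The left wall advances rightward at ``rate``; the strain is the wall
    travel over the initial wall separation.  A buckle report is produced at
    every sampled strain.

    Membrane maintenance is off by default here: with a fixed membrane
    inventory (and overlap projection preserving the interior volume) cells
    resist shape change, so in-plane compression must be relieved by
    out-of-plane buckling -- the physics the experiment probes.
    """
    state = layerstate
    xmin = float((state.x[:, 0] - state.r).min())
    xmax = float((state.x[:, 0] + state.r).max())
    left = BoundaryObject(
        "P", point=np.array([xmin, 0.0]), normal=np.array([1.0, 0.0]),
        motion=MotionSchedule.constant([rate, 0.0], start=state.t),
        name="moving wall",
    )
    right = BoundaryObject(
        "P", point=np.array([xmax, 0.0]), normal=np.array([-1.0, 0.0]),
        name="static wall",
    )
    state.boundaries.extend([left, right])
    L0_len = xmax - xmin
    state.dt = overdamped_dt(state, v_drive=rate)
    stepper = Stepper(state, mode="overdamped")
    steps_per_sample = max(1, round(sample_strain * L0_len / (rate * state.dt)))

    strains, reports = [], []
    n_samples = max(1, round(target_strain / sample_strain))
    sub = max(1, steps_per_sample // 4)
    for k in range(n_samples):
        done = 0
        while done < steps_per_sample:
            stepper.step(min(sub, steps_per_sample - done))
            done += sub
            project_contacts(stepper)
        if maintain:
            ins = sum(
                maintain_membrane(state, int(c), "M", max_insert=2)
                for c in state.cell_ids()
            )
            if ins:
                stepper.refresh(reset_xprev=True)
        strains.append((k + 1) * sample_strain)
        reports.append(
            count_buckles(
                state, height_threshold=height_threshold,
                min_span=min_span, cell_diameter=cell_diameter,
            )
        )
    return WallCompressionResult(np.asarray(strains), reports, state)


def nucleus_position_experiment(
    params: dict[str, ParticleTypeParams],
    target_strain: float = 0.4,
    n_cells: int = 20,
    resolution: float = 3.0,
    rng_seed: int = 0,
    adhesion: Optional[dict] = None,
    cell_spec_kw: Optional[dict] = None,
    **wall_kw,
) -> dict[str, Optional[float]]:
    """Buckling onset strain for basal vs elevated nucleus positions.

    Builds two otherwise identical layers (shared seed) whose nuclei sit
    either at the base of each cell or elevated at two thirds of the cell
    height, compresses both to ``target_strain`` and returns the smallest
    sampled strain with a detected buckle per condition (None if none).
    """
    if adhesion is None:
        from .params import load_adhesion_preset

        adhesion = load_adhesion_preset("layer_control")
    out: dict[str, Optional[float]] = {}
    for label in ("basal", "elevated"):
        spec = CellSpec(nucleus_center_height=label, **(cell_spec_kw or {}))
        layer = build_epithelial_layer(
            n_cells, spec, params,
            k_a_bm=adhesion["k_a_bm"], delta_bm=adhesion["delta_bm"],
            k_a_m=adhesion.get("k_a_m"), delta_m=adhesion.get("delta_m"),
            rng_seed=rng_seed, resolution=resolution,
        )
        res = wall_compression(
            layer, target_strain, cell_diameter=spec.diameter, **wall_kw
        )
        out[label] = res.onset_strain()
    return out


def shape_sweep(
    params: dict[str, ParticleTypeParams],
    k_a_m_values,
    k_a_bm_values,
    n_cells: int = 6,
    resolution: float = 3.0,
    rng_seed: int = 0,
    delta_bm: float = 2e-6,
    delta_m: float = 0.2e-6,
    settle_steps: int = 4000,
    cell_spec: Optional[CellSpec] = None,
) -> pd.DataFrame:
    """Mean cell aspect ratio over a cadherin x BM-adhesion grid.

    For every (k_a_m, k_a_bm) combination a small layer is built and settled
    and the mean height/width aspect ratio of its cells recorded.  Increasing
    cell-cell adhesion drives columnar (tall) shapes; increasing BM adhesion
    drives spread (flat) shapes.
    """
    spec = cell_spec if cell_spec is not None else CellSpec()
    rows = []
    for k_m in k_a_m_values:
        for k_bm in k_a_bm_values:
            layer = build_epithelial_layer(
                n_cells, spec, params,
                k_a_bm=k_bm, delta_bm=delta_bm,
                k_a_m=k_m, delta_m=delta_m,
                rng_seed=rng_seed, resolution=resolution,
                settle_steps=settle_steps,
            )
            aspects = []
            for c in layer.cell_ids():
                w, h = cell_extent(layer, int(c))
                aspects.append(h / w)
            rows.append(
                {
                    "k_a_m": k_m,
                    "k_a_bm": k_bm,
                    "aspect_height_over_width": float(np.mean(aspects)),
                }
            )
    return pd.DataFrame(rows)
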