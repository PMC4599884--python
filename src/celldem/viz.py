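"""Snapshot rendering and geometry export.

Snapshots can be written as matplotlib figures (PNG/PDF) coloured by species
or by the magnitude of the net contact force on each particle, or as legacy
ASCII VTK polydata (points + per-point radius and scalar) for external
viewers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .mechanics import compute_forces
from .species import PARTICLE_LABELS
from .state import SimulationState

__all__ = ["render_snapshot", "write_vtk_polydata"]

_SPECIES_COLORS = {
    "M": "tab:blue",
    "C": "tab:orange",
    "NM": "tab:green",
    "N": "tab:red",
}


def _color_scalar(state: SimulationState, colour_by: str) -> np.ndarray:
    if colour_by == "species":
        return state.species.astype(float)
    if colour_by == "net_contact_force":
        if state.n == 0:
            return np.zeros(0)
        F, _ = compute_forces(state)
        return np.linalg.norm(F, axis=1)
    raise ValueError(
        f"colour_by must be 'species' or 'net_contact_force', got {colour_by!r}"
    )


def write_vtk_polydata(state: SimulationState, path, colour_by: str = "species") -> None:
    """Write particle centres as legacy-ASCII VTK polydata.

    Per-point data: ``radius`` and the selected colour scalar.  The format is
    plain text readable by standard VTK-based viewers.
    """
    scalar = _color_scalar(state, colour_by)
    n = state.n
    lines = [
        "# vtk DataFile Version 3.0",
        "celldem particle snapshot",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    for xy in state.x:
        lines.append(f"{xy[0]:.9e} {xy[1]:.9e} 0.0")
    lines.append(f"VERTICES {n} {2 * n}")
    lines.extend(f"1 {i}" for i in range(n))
    lines.append(f"POINT_DATA {n}")
    lines.append("SCALARS radius double 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{r:.9e}" for r in state.r)
    lines.append(f"SCALARS {colour_by} double 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{s:.9e}" for s in scalar)
    Path(path).write_text("\n".join(lines) + "\n")


def render_snapshot(
    state: SimulationState,
    path,
    colour_by: str = "species",
    dpi: int = 110,
    show_boundaries: bool = True,
    ax=None,
):
    """Render the particle assembly to an image file.

    ``colour_by='species'`` gives one colour per particle species;
    ``colour_by='net_contact_force'`` shades particles by the magnitude of
    their net contact force (darker = higher).  A ``.vtk`` suffix writes
    legacy polydata instead of an image.
    """
    if str(path).endswith(".vtk"):
        write_vtk_polydata(state, path, colour_by)
        return None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import Circle

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(8, 6))
    um = 1e6
    if state.n:
        if colour_by == "species":
            for code, label in enumerate(PARTICLE_LABELS):
                mask = state.species == code
                if not mask.any():
                    continue
                patches = [
                    Circle((x * um, y * um), r * um)
                    for (x, y), r in zip(state.x[mask], state.r[mask])
                ]
                ax.add_collection(
                    PatchCollection(
                        patches, facecolor=_SPECIES_COLORS[label],
                        edgecolor="none", alpha=0.7,
                    )
                )
        else:
            scalar = _color_scalar(state, colour_by)
            patches = [
                Circle((x * um, y * um), r * um)
                for (x, y), r in zip(state.x, state.r)
            ]
            coll = PatchCollection(patches, cmap="Greys", edgecolor="none")
            coll.set_array(scalar)
            ax.add_collection(coll)
            if own_fig:
                plt.colorbar(coll, ax=ax, label="|net contact force| [N]")
        pad = 2.0
        ax.set_xlim(
            (state.x[:, 0].min() - state.r.max()) * um - pad,
            (state.x[:, 0].max() + state.r.max()) * um + pad,
        )
        ax.set_ylim(
            (state.x[:, 1].min() - state.r.max()) * um - pad,
            (state.x[:, 1].max() + state.r.max()) * um + pad,
        )
    if show_boundaries:
        for b in state.boundaries:
            # draw the line through the boundary point, perpendicular to its
            # normal, across the current view
            t = np.array([-b.normal[1], b.normal[0]])
            p = b.point * um
            span = 1e3
            ax.plot(
                [p[0] - span * t[0], p[0] + span * t[0]],
                [p[1] - span * t[1], p[1] + span * t[1]],
                "k-", lw=1,
            )
    ax.set_aspect("equal")
    ax.set_xlabel("x [um]")
    ax.set_ylabel("y [um]")
    if own_fig:
        fig.savefig(path, dpi=dpi, bbox_inches="tight")
        plt.close(fig)
    return ax
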