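"""Run configuration: validation, unit-suffixed keys, experiment dispatch.

A run configuration is a flat mapping with explicit unit suffixes (``_um``,
``_N_per_m``, ...) selecting one experiment and its inputs.  Unknown keys are
rejected before any simulation starts.  :func:`run_experiment` executes the
selected experiment end-to-end, writing a configuration echo, a log with
parameter provenance, result tables (CSV), state checkpoints (HDF5) and
snapshot images into the output directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .assembly import (
    CellSpec,
    build_epithelial_layer,
    build_isolated_nucleus,
    build_round_cell,
    spread_cell,
)
from .params import MICRON, available_presets, default_parameters, load_adhesion_preset
from .experiments import (
    nucleus_position_experiment,
    plate_compression,
    shape_sweep,
    wall_compression,
)
from .viz import render_snapshot

__all__ = ["RunConfig", "ConfigError", "run_experiment", "EXPERIMENTS"]

EXPERIMENTS = (
    "init-cell",
    "spread",
    "compress-nucleus",
    "compress-cell",
    "layer",
    "shape-sweep",
    "nucleus-position",
)


class ConfigError(ValueError):
    """Invalid run configuration (lists every offending key)."""


#: key -> (attribute, SI conversion factor)
_KEYS = {
    "experiment": ("experiment", None),
    "preset": ("preset", None),
    "adhesion_preset": ("adhesion_preset", None),
    "seed": ("seed", None),
    "out_dir": ("out_dir", None),
    "resolution": ("resolution", 1.0),
    "n_cells": ("n_cells", None),
    "diameter_um": ("diameter", MICRON),
    "nucleus_diameter_um": ("nucleus_diameter", MICRON),
    "nucleus_position": ("nucleus_position", None),  # basal | elevated
    "target_strain": ("target_strain", 1.0),
    "rate_um_per_s": ("rate", MICRON),
    "sample_strain": ("sample_strain", 1.0),
    "k_a_bm_N_per_m": ("k_a_bm", 1.0),
    "delta_bm_um": ("delta_bm", MICRON),
    "k_a_m_N_per_m": ("k_a_m", 1.0),
    "delta_m_um": ("delta_m", MICRON),
    "spread_steps": ("spread_steps", None),
}


@dataclass
class RunConfig:
    """Validated, SI-converted experiment configuration."""

    experiment: str
    preset: str = "table2"
    adhesion_preset: Optional[str] = None
    seed: int = 0
    out_dir: str = "celldem_out"
    resolution: float = 3.0
    n_cells: int = 20
    diameter: float = 15e-6
    nucleus_diameter: float = 6e-6
    nucleus_position: Optional[str] = None
    target_strain: float = 0.3
    rate: float = 0.25e-6
    sample_strain: float = 0.01
    k_a_bm: float = 1e-11
    delta_bm: float = 3e-6
    k_a_m: Optional[float] = None
    delta_m: Optional[float] = None
    spread_steps: int = 10_000

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        unknown = sorted(set(raw) - set(_KEYS))
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
        if "experiment" not in raw:
            raise ConfigError("missing required key 'experiment'")
        kwargs = {}
        for key, value in raw.items():
            attr, factor = _KEYS[key]
            kwargs[attr] = value * factor if isinstance(factor, float) else value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_mapping(raw)

    def validate(self) -> None:
        errors = []
        if self.experiment not in EXPERIMENTS:
            errors.append(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}"
            )
        if self.preset not in available_presets():
            errors.append(f"unknown parameter preset {self.preset!r}")
        if not (0.0 <= self.target_strain < 1.0):
            errors.append("target_strain must be in [0, 1)")
        if self.n_cells < 1:
            errors.append("n_cells must be >= 1")
        if self.resolution <= 0:
            errors.append("resolution must be positive")
        if self.nucleus_position not in (None, "basal", "elevated"):
            errors.append("nucleus_position must be 'basal' or 'elevated'")
        if errors:
            raise ConfigError("; ".join(errors))

    def echo(self) -> dict:
        """Round-trippable raw mapping (unit-suffixed keys)."""
        out = {}
        for key, (attr, factor) in _KEYS.items():
            value = getattr(self, attr)
            if value is None:
                continue
            out[key] = value / factor if isinstance(factor, float) else value
        return out


def _cell_spec(cfg: RunConfig) -> CellSpec:
    return CellSpec(
        diameter=cfg.diameter,
        nucleus_diameter=cfg.nucleus_diameter,
        nucleus_center_height=cfg.nucleus_position,
    )


def run_experiment(cfg: RunConfig) -> Path:
    """Execute the configured experiment; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"# celldem run, experiment={cfg.experiment}",
        f"parameter preset: {cfg.preset}",
        f"adhesion preset: {cfg.adhesion_preset}",
        f"seed: {cfg.seed}",
        f"started: {time.strftime('%Y-%m-%d %H:%M:%S')}",
    ]
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(cfg.echo(), fh)
    params = default_parameters(cfg.preset)
    adhesion = (
        load_adhesion_preset(cfg.adhesion_preset) if cfg.adhesion_preset else {}
    )
    k_bm = adhesion.get("k_a_bm", cfg.k_a_bm)
    d_bm = adhesion.get("delta_bm", cfg.delta_bm)
    k_m = adhesion.get("k_a_m", cfg.k_a_m)
    d_m = adhesion.get("delta_m", cfg.delta_m)

    if cfg.experiment == "init-cell":
        state = build_round_cell(
            _cell_spec(cfg), params, rng_seed=cfg.seed, resolution=cfg.resolution
        )
        counts = np.bincount(state.species, minlength=4)
        log_lines.append(
            f"particle counts M/C/NM/N: {counts.tolist()} (total {state.n})"
        )
        state.save(out / "cell.h5")
        render_snapshot(state, out / "cell.png")
    elif cfg.experiment == "spread":
        state = build_round_cell(
            _cell_spec(cfg), params, rng_seed=cfg.seed, resolution=cfg.resolution
        )
        res = spread_cell(
            state, k_a_bm=k_bm, delta_bm=d_bm, sim_steps=cfg.spread_steps
        )
        log_lines.append(
            f"aspect ratio (width/height): {res.aspect_ratio:.3f}, "
            f"attached: {res.attached}"
        )
        res.state.save(out / "spread_cell.h5")
        render_snapshot(res.state, out / "spread_cell.png")
    elif cfg.experiment in ("compress-nucleus", "compress-cell"):
        if cfg.experiment == "compress-nucleus":
            state = build_isolated_nucleus(
                cfg.nucleus_diameter, params, rng_seed=cfg.seed,
                resolution=cfg.resolution,
            )
            state.interactions.enable("NM", "P")
        else:
            state = build_round_cell(
                _cell_spec(cfg), params, rng_seed=cfg.seed,
                resolution=cfg.resolution,
            )
        record = plate_compression(
            state, cfg.target_strain, rate=cfg.rate,
            sample_strain=cfg.sample_strain,
        )
        record.to_frame().to_csv(out / "compression.csv", index=False)
        log_lines.append(
            f"final strain {record.strain[-1]:.3f}, "
            f"F2d {record.F2d[-1]:.3e} N, F3d {record.F3d[-1]:.3e} N"
        )
        state.save(out / "compressed.h5")
        render_snapshot(state, out / "compressed.png")
    elif cfg.experiment == "layer":
        layer = build_epithelial_layer(
            cfg.n_cells, _cell_spec(cfg), params,
            k_a_bm=k_bm, delta_bm=d_bm, k_a_m=k_m, delta_m=d_m,
            rng_seed=cfg.seed, resolution=cfg.resolution,
        )
        res = wall_compression(
            layer, cfg.target_strain, rate=cfg.rate,
            sample_strain=cfg.sample_strain, cell_diameter=cfg.diameter,
        )
        rows = [
            {"strain": s, "n_buckles": rep.n_buckles}
            for s, rep in zip(res.strains, res.reports)
        ]
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "buckles.csv", index=False)
        final = res.reports[-1]
        log_lines.append(
            f"buckles at {res.strains[-1]:.2f} strain: {final.n_buckles}"
        )
        res.state.save(out / "layer_final.h5")
        render_snapshot(res.state, out / "layer_final.png")
    elif cfg.experiment == "shape-sweep":
        table = shape_sweep(
            params,
            k_a_m_values=[1e-10, 1e-9, 1e-8],
            k_a_bm_values=[1e-12, 1e-11, 1e-10],
            n_cells=min(cfg.n_cells, 6),
            resolution=cfg.resolution,
            rng_seed=cfg.seed,
        )
        table.to_csv(out / "shape_sweep.csv", index=False)
        log_lines.append(table.to_string(index=False))
    elif cfg.experiment == "nucleus-position":
        onsets = nucleus_position_experiment(
            params, target_strain=cfg.target_strain, n_cells=cfg.n_cells,
            resolution=cfg.resolution, rng_seed=cfg.seed,
        )
        with open(out / "onset_strains.json", "w") as fh:
            json.dump(onsets, fh, indent=2)
        log_lines.append(f"onset strains: {onsets}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
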