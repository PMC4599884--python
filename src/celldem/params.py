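"""Per-species mechanical parameters and the shipped presets.

Every particle species carries a small set of mechanical constants:

========  =========  =====================================================
field     unit       meaning
========  =========  =====================================================
R         m          mean particle radius
F_a       N          constant attractive force (cohesion between particles)
delta     m          influence radius: interactions vanish beyond it
k_a       N/m        linear attraction ("adhesion") spring constant
E         Pa         Young's modulus for the Hertz contact branch
nu        --         Poisson's ratio
beta      kg/s       viscous drag factor
density   kg/m^3     density used by the mass rule m = rho * (4/3) pi R^3
========  =========  =====================================================

All quantities are SI internally; the YAML preset files use explicit unit
suffixes (``R_um``, ``k_a_N_per_m``, ...) and are converted on load.

Presets cover the baseline parameter set, the three isolated-nucleus
stiffness calibrations (1, 5 and 30 kPa) and the four whole-cell calibration
endpoints (soft/stiff x round/spread).  A preset overrides only the fields it
names; everything else falls back to the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

from .species import PARTICLE_LABELS

__all__ = [
    "ParticleTypeParams",
    "default_parameters",
    "available_presets",
    "scale_resolution",
    "particle_mass",
    "UnknownPresetError",
]

#: Internal length unit, in metres, in which the linear attraction branch of
#: the contact law is evaluated (see :mod:`celldem.mechanics`).
MICRON = 1.0e-6


class UnknownPresetError(KeyError):
    """Raised when a preset name is not among the shipped parameter sets."""


@dataclass
class ParticleTypeParams:
    """Mechanical constants of one particle species."""

    R: float
    F_a: float
    delta: float
    k_a: float
    E: float
    nu: float
    beta: float
    density: float = 1000.0

    def validate(self) -> None:
        for name in ("R", "delta", "k_a", "E", "beta", "density"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if not (0.0 < self.nu <= 0.5):
            raise ValueError(f"nu must be in (0, 0.5], got {self.nu}")
        if self.F_a < 0:
            raise ValueError(f"F_a must be non-negative, got {self.F_a}")

    def replace(self, **kw) -> "ParticleTypeParams":
        return replace(self, **kw)


def particle_mass(R: float, density: float = 1000.0, mass_scale: float = 1.0) -> float:
    """Mass rule: sphere of radius ``R`` at the given density.

    ``mass_scale`` is a global numerical factor used for quasi-static runs,
    where inertia is irrelevant and scaling the mass up enlarges the stable
    time step (see :func:`celldem.integrate.mass_scale_for_dt`).
    """
    return density * (4.0 / 3.0) * math.pi * R**3 * mass_scale


_UNIT_KEYS = {
    "R_um": ("R", MICRON),
    "F_a_N": ("F_a", 1.0),
    "delta_um": ("delta", MICRON),
    "k_a_N_per_m": ("k_a", 1.0),
    "E_Pa": ("E", 1.0),
    "nu": ("nu", 1.0),
    "beta_kg_per_s": ("beta", 1.0),
    "density_kg_per_m3": ("density", 1.0),
}


def _parse_species(raw: dict) -> dict:
    out = {}
    for key, value in raw.items():
        if key not in _UNIT_KEYS:
            raise ValueError(f"unknown parameter key {key!r} in preset file")
        name, factor = _UNIT_KEYS[key]
        out[name] = float(value) * factor
    return out


def _load_preset_file() -> dict:
    with resources.files("celldem.data").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)


_CACHE: dict = {}


def available_presets() -> tuple[str, ...]:
    data = _CACHE.setdefault("raw", _load_preset_file())
    return tuple(data["presets"].keys())


def default_parameters(preset: str = "table2") -> dict[str, ParticleTypeParams]:
    """Return the complete species -> parameters map for a named preset.

    The preset overrides only the fields it lists; all other fields fall back
    to the baseline set.  Raises :class:`UnknownPresetError` for names not in
    :func:`available_presets`.
    """
    data = _CACHE.setdefault("raw", _load_preset_file())
    if preset not in data["presets"]:
        raise UnknownPresetError(
            f"unknown preset {preset!r}; available: {sorted(data['presets'])}"
        )
    out: dict[str, ParticleTypeParams] = {}
    overrides = data["presets"][preset] or {}
    for label in PARTICLE_LABELS:
        fields = _parse_species(data["baseline"][label])
        fields.update(_parse_species(overrides.get(label, {})))
        p = ParticleTypeParams(**fields)
        p.validate()
        out[label] = p
    return out


def load_adhesion_preset(name: str) -> dict[str, float]:
    """Named adhesion parameter sets (SI units) for the experiment drivers."""
    with resources.files("celldem.data").joinpath("adhesion.yaml").open() as fh:
        data = yaml.safe_load(fh)
    try:
        raw = data["adhesion_presets"][name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown adhesion preset {name!r}; available: "
            f"{sorted(data['adhesion_presets'])}"
        ) from None
    out = {}
    for key, value in raw.items():
        if key.endswith("_um"):
            out[key[:-3]] = float(value) * MICRON
        elif key.endswith("_N_per_m"):
            out[key[:-8]] = float(value)
        else:
            out[key] = float(value)
    return out


def scale_resolution(
    params: dict[str, ParticleTypeParams], factor: float
) -> dict[str, ParticleTypeParams]:
    """Coarsen the particle resolution by scaling particle radii.

    Radii are multiplied by ``factor`` (> 1 means fewer, larger particles
    per cell).  The membrane species' influence radii scale along with the
    bead size (ring cohesion must always reach the neighbouring beads),
    while the bulk (cytoplasm/nucleoplasm) influence radii are physical
    interaction ranges and stay fixed.  Force-scale parameters are left
    untouched: coarsened assemblies are not calibrated replicas but preserve
    the orderings that the qualitative experiments measure.
    """
    if factor == 1.0:
        return {k: v.replace() for k, v in params.items()}
    out = {}
    for k, v in params.items():
        if k in ("M", "NM"):
            out[k] = v.replace(R=v.R * factor, delta=v.delta * factor)
        else:
            out[k] = v.replace(R=v.R * factor)
    return out
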