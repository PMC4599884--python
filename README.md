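# celldem

Discrete-element simulation of deformable cells, nuclei and epithelial
layers in 2D.

Tissue-scale mechanics — single-cell compression stiffness, cell spreading
on a basement membrane, and the buckling of compressed epithelial
monolayers — emerges here from simple rules between many circular
particles. Each cell is a closed ring of membrane beads (cell cortex
included) around a cohesive packing of cytoplasm particles, with a second
ring and packing for the nucleus. The package is aimed at cell- and
tissue-biomechanics work where continuum methods struggle: very large
deformations, evolving contacts, delamination, and per-cell readouts.

## Model

Four particle species (membrane M, cytoplasm C, nuclear membrane NM,
nucleoplasm N) interact through a short-range normal force along the line
of centres,

```
F_IJ = [ Fa_IJ − P(α) ] n_IJ ,   α = (R_I + R_J) − |x_I − x_J| ,

P(α) = 0                          α < −δ        (out of range)
     = ka_IJ · α̃                 −δ ≤ α < 0    (linear adhesion spring)
     = kr_IJ · √R̃_eq · α̃^{3/2}   α ≥ 0         (Hertzian contact)
```

with a constant cohesive attraction `Fa`, pairwise-combined coefficients,
and lengths in the spring evaluated as micrometre numbers (the convention
in which the shipped parameter tables are calibrated — see
`docs/methods.md`). Testing plates and the basement membrane enter the same
law as lines of infinite radius. A viscous drag acts on each particle's
velocity relative to the mean of its neighbours. Motion follows Newtonian
dynamics integrated by explicit position-Verlet with lagged velocities, or,
for quasi-static work, the overdamped (massless) limit of the same
equations.

Only 7 intra-cell particle pairings and 2 external ones (membrane-plate,
membrane-basement-membrane) are active by default, out of 18 potential —
that bookkeeping is what keeps each component in its compartment.

## Worked example

Build the reference cell (15 µm diameter, 6 µm nucleus) at full
resolution and compress an isolated nucleus between plates:

```python
import numpy as np
from celldem import (CellSpec, build_round_cell, build_isolated_nucleus,
                     default_parameters, plate_compression)

params = default_parameters("table2")
cell = build_round_cell(CellSpec(), params, rng_seed=1)
print(cell.n, np.bincount(cell.species, minlength=4))

nuc = build_isolated_nucleus(6e-6, default_parameters("nucleus_5kPa"),
                             rng_seed=1, resolution=2.0)
nuc.interactions.enable("NM", "P")          # let the plates touch the nucleus
rec = plate_compression(nuc, target_strain=0.3)
print(f"relative force gain 15%→30% strain: "
      f"{rec.force_at(0.30) / rec.force_at(0.15):.1f}x")
```

printing

```
879 [157 596  63  63]
relative force gain 15%→30% strain: 2.1x
```

— the grown cell lands near the ~900-element scale of the reference
discretisation (157 membrane beads on the 15 µm circle, the rest filling
the compartments), and the nucleus
force–strain response is super-linear (stiffening), as expected of a
Hertz-contact particle packing. Plate forces
are reported both as the raw 2D reaction and as an axisymmetric 3D
extrapolation (each contact weighted by its ring of rotational copies);
their absolute scale is set by the stiff-contact unit convention, so read
orderings and ratios, not newtons.

An epithelial-layer experiment from the command line:

```
celldem layer --adhesion-preset layer_control --strain 0.4 --seed 1 --out out/
```

writes a configuration echo, a log, the per-strain buckle counts
(`buckles.csv`), a final-state checkpoint (HDF5) and a snapshot image.
Other subcommands: `init-cell`, `spread`, `compress-nucleus`,
`compress-cell`, `shape-sweep`, `nucleus-position`, or `celldem run
--config file.yaml` with a validated flat YAML schema (unit-suffixed keys;
unknown keys rejected).

## Layout

- `src/celldem/species.py`, `params.py` — species, interaction matrix,
  parameter presets (`data/*.yaml`)
- `src/celldem/mechanics.py`, `_kernels.py` — contact law, neighbour
  search, compiled force kernels
- `src/celldem/integrate.py` — Verlet and overdamped stepping, critical
  time step, settling
- `src/celldem/assembly.py` — cell construction, membrane maintenance,
  spreading, layers
- `src/celldem/experiments.py` — compression drivers, buckle detection,
  sweeps
- `src/celldem/config.py`, `cli.py`, `viz.py` — run configs, CLI,
  snapshots (PNG / legacy-ASCII VTK)
- `docs/methods.md` — model, numerics, calibration and limitations
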