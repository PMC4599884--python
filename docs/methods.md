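# Model and methods

`celldem` simulates deformable cells, their nuclei and surrounding
extracellular structures as collections of interacting circular particles in
two dimensions. This note documents the model, the numerical methods and the
design choices that were genuinely open, at the level of detail a user needs
to judge what a simulation result does and does not show.

## The particle model

A cell is built from four particle species: cell membrane including the
cortex (M), cytoplasm (C), nuclear membrane (NM) and nucleoplasm (N). Two
further species are reserved for boundary objects — a rigid testing plate
(P) and the basement membrane (BM) — modelled as contact lines, i.e.
spheres of infinite radius. Of the 18 potential species pairings (10
unordered particle pairs plus 8 particle-boundary combinations), the default
interaction matrix enables the seven intra-cell pairs M–M, M–C, C–C, C–NM,
NM–NM, NM–N, N–N and the two external pairs M–P and M–BM. The disabled
pairings (for example N–C or C–BM) are what keep nucleoplasm and cytoplasm
confined to their compartments: the membranes are the only species that
touch the outside world.

The force between two particles I and J acts along their line of centres,

    F_IJ = [ Fa_IJ − P(α) ] n_IJ,     α = (R_I + R_J) − |x_I − x_J|,

with a constant cohesive attraction `Fa` and a piecewise spring `P`:
zero beyond the influence radius (α < −δ), a linear adhesion spring
`ka_IJ · α̃` for separated pairs (−δ ≤ α < 0) and a Hertzian contact
`kr_IJ · sqrt(R̃_eq) · α̃^{3/2}` for overlapping pairs, where the tilde
denotes lengths measured in micrometres (see *Unit convention* below).
Pair coefficients combine the two species' constants: the equivalent radius
`R_eq = R_I R_J/(R_I + R_J)`, the series ("harmonic") spring combination for
`ka`, the standard Hertz effective modulus for `kr` from each side's Young's
modulus and Poisson's ratio, and a symmetric harmonic-style combination
`Fa_IJ = 2 Fa_I Fa_J/(Fa_I + Fa_J)` for the constant attraction, which
reduces to the species value for same-species pairs and preserves Newton's
third law for cross-species pairs (an optional switch restricts `Fa` to
same-species pairs only). The pair cutoff is `min(δ_I, δ_J)` so that the
interaction set is symmetric; boundary contacts use the boundary's own
influence radius, since boundary reach (e.g. a 3 µm basement-membrane
attraction range) is a model parameter in its own right.

A viscous drag `D_I = −β_I (v_I − v̄_I)` opposes each particle's motion
relative to the mean velocity `v̄_I` of its in-range neighbours; a
contacting boundary contributes its scheduled velocity to that mean with
weight one. The drag represents lumped dissipative processes and, for the
quasi-static experiments here, serves numerical stabilisation; note that its
per-neighbour weighting makes it inherently non-reciprocal, so momentum
bookkeeping applies to the elastic forces only.

### Unit convention for the contact law

All state is stored in SI units, but the spring `P(α)` is evaluated with
lengths as micrometre numbers and read in newtons. This is a deliberate,
load-bearing choice. With strict SI metres in `P`, the tabulated adhesion
spring constants (1e−12 … 1e−8 N/m) would produce forces of order 1e−18 N —
seven orders below the constant attractions — so none of the
adhesion-spring-controlled behaviours (cell spreading on the basement
membrane, cadherin-strength effects in layers, nuclear-envelope stiffening)
could exist; and the Hertz branch at kilopascal moduli would be so soft that
cohesion would equilibrate particle pairs at ~60% diameter overlap, which is
inconsistent with the reference cell's composition (≈730 cytoplasm particles
of 0.25 µm radius filling a ≈148 µm² annulus is a packing fraction near 1,
i.e. near-tangent particles). In the micrometre convention the same
constants give pN-scale adhesion forces comparable to the attractions and a
contact that stiffens steeply within a small fraction of a micrometre — the
regime in which every published behaviour of this model is mutually
consistent. A consequence worth remembering: absolute contact forces at
driven boundaries are on an arbitrary (large) scale, so plate-force results
should be read as orderings and ratios, not newton values.

The equivalent-radius factor is kept in the Hertz branch (`sqrt(R̃_eq)`)
but not in the linear branch: with it, every adhesion spring would again be
one to two orders too weak for its documented role (the membrane spring that
prevents seepage, the cadherin strength scale, basement-membrane
attachment).

## Parameters

The shipped baseline (preset `table2` in `src/celldem/data/presets.yaml`)
gives each species its mean radius (0.15 µm membrane, 0.25 µm interior),
attraction (1e−10 N membrane, 5e−11 N interior), influence radius (2 µm),
adhesion spring constant (1e−8 N/m), Young's modulus (10 MPa membranes, 1
kPa cytoplasm, 5 kPa nucleoplasm), Poisson's ratio 0.5 and drag factor 0.05
kg/s. Further presets cover the isolated-nucleus stiffness calibrations (1,
5, 30 kPa, with the attraction, nuclear-envelope spring and drag scaled
along) and the whole-cell calibration band (soft/stiff endpoints for round
and spread cells). A preset overrides only the fields it names.

Particle mass follows the sphere rule `m = ρ (4/3) π R³` with ρ = 1000
kg/m³ and an optional global mass-scaling factor; mass only matters in the
dynamic (Verlet) mode, where it is a numerical dial for the stable step of
quasi-static runs.

Membrane influence radii deserve one note: the baseline table lists 2 µm
for every species, but membrane-bound adhesion is physically short-range,
and with a micrometre-range membrane–membrane attraction a closed bead ring
clumps onto itself instead of coating the cell. The builders therefore cap
the membrane species' influence radii at the cadherin range (0.2 µm,
scaled with the discretisation), which is also the value used in all the
epithelial-layer work; the bulk species keep the 2 µm cohesion range.

## Time stepping

Two stepping modes share one force engine.

**Verlet mode** integrates the full equation of motion with the
position-Verlet update `x(t+Δt) = 2x(t) − x(t−Δt) + (F/m)Δt²`, the velocity
entering the drag estimated one step behind the displacements, which keeps
the update fully explicit. The critical step of each particle-pair "spring"
is `Δt_crit = (2/ω)(√(1+ξ²) − ξ)` with `ω = √(k_max/m_red)` and the damping
ratio `ξ = β/(2√(k_max m_red))`; `k_max` is the maximum tangent stiffness of
the pair's force law, taken as the Hertz tangent at the overlap where the
contact force reaches a force cap (a configurable multiple, default 30, of
the largest attraction), or the linear-spring stiffness if larger. The
working step is the minimum over pairs times a subunitary safety factor
(default 0.9). With half-step initialisation the scheme is exact for
constant forces and second-order on smooth conservative problems; the
lagged-velocity drag estimate reduces the damped components to first order,
which is immaterial for quasi-static work. Mass scaling
(`mass_scale_for_dt`) inverts the critical-step formula to reach a requested
step.

**Overdamped mode** integrates the massless limit `v_i = v̄_i + F_i/β_i`
(force balance with the neighbour-relative drag), used by all builders and
experiment drivers. The step is chosen so a particle pushed at the largest
cohesive force moves a small fraction (2%) of the smallest radius per step,
and so a driven boundary moves at most that fraction per step. Because the
near-tangent contacts of this parameter set are vastly stiffer than any
affordable explicit step, per-step displacements are clamped (default 25% of
the smallest radius) and a clamped move stores no velocity: particles park
in a narrow band around force balance instead of overshooting. A small
advection leak (2% per step) supplies the absolute-frame dissipation that
the purely relative drag lacks, so detached bodies do not coast
indefinitely.

**Overlap projection.** Force-based relaxation alone parks dense assemblies
in force-balanced but deeply overlapped states, silently destroying volume.
A Gauss–Seidel projection pass (`project_contacts`) moves overlapping
enabled pairs apart along their axes — the infinite-stiffness limit of the
contact — and is applied during construction and periodically during driven
experiments, which makes cell interiors effectively volume-preserving. It is
never applied to boundary contacts, so plate and wall reaction forces remain
pure force-law readings.

## Cell construction

A round cell is initialised in stages:

1. Membrane and nuclear-membrane rings are laid out as closed rings of
   equally spaced beads at one-diameter spacing (a 15 µm cell with 0.15 µm
   membrane beads starts with 157 of them).
2. Cytoplasm and nucleoplasm are seeded at random positions with half of
   their target particle numbers, radii drawn uniformly within ±30% of the
   species mean (this variance also prevents crystalline packing). The
   targets correspond to filling each compartment's coverage area at a
   packing fraction of 0.87 (cytoplasm) and 0.50 (nucleoplasm) — values
   calibrated once against the reference cell's published element count and
   then frozen.
3. With the rings pinned (a free cohesive ring would crumple before any
   interior pressure exists), the interior particles grow slowly and divide:
   a particle reaching twice its base radius is replaced by a tangent pair
   of fresh ±30% draws centred on its position. Tangent placement matters —
   literal same-position insertion creates transient contact forces large
   enough to fire neighbouring particles through the membrane rings. Seeded
   random agitation ("kicks") lets particles slide into voids. A maturation
   sweep splits any particle still above 1.35× base radius so the final
   population carries the configured radius distribution.
4. A compaction press then finds each ring's zero-pressure radius: the ring
   stays pinned to a circle whose radius is steered by the compartment's
   measured packing fraction (outward if overcrowded, inward if slack)
   while the interior anneals under kicks and projection.
5. The rings are released gently (reduced displacement clamp) and growth
   continues at a finer rate until the membrane tension — the mean
   attractive force over ring edges, counting edges at contact or separated
   and ignoring overlapped ones — sustains a threshold (default 0.9× the
   membrane attraction) over consecutive checks. Finally, the rare interior
   particle that a transient force chain pushed through a ring is removed.

At full resolution this produces 850–880 elements for the 15 µm / 6 µm
reference cell across seeds (157 membrane, ≈590 cytoplasm, 63 nuclear
membrane, ≈60 nucleoplasm), with the ring area within a few percent of the
nominal circle and zero compartment violations.

Membrane area regulation: whenever two neighbouring ring beads separate by
more than one bead radius, a new bead is spliced in at the edge midpoint.
Inserted beads enter at the radius that fits the gap tangentially and grow
to full size over subsequent maintenance passes; drivers give each pass a
small insertion budget (the widest gaps first) so membrane grows at the
pace of genuine tension rather than amplifying ring wiggles, and spreading
runs cap total membrane growth at 1.8× the initial ring length (a finite
membrane reservoir, which gives spreading a stable endpoint).

Spread cells place a round cell tangent to an adhesive basement-membrane
line and relax with maintenance active. Epithelial layers clone one grown
reference cell to `n` side-by-side positions with seeded jitter and settle
the row under cell-cell and cell-BM adhesion; nucleus polarisation (basal or
elevated at two-thirds height) is set at build time.

## Experiments

*Microplate compression*: the assembly rests on a static plate while an
upper plate advances at 0.25 µm/s to a target engineering strain
(displacement over initial height), sampling every 1% strain. The moving
plate's reaction is recorded both as the raw 2D force and as an
axisymmetric 3D extrapolation, in which each contacting particle's force is
weighted by the number of particle copies on its circle about the symmetry
axis (circumference over particle diameter, floored at one on the axis).
Because stiff contacts flicker, the recorded force is the mean of several
readings across each sampling window. Isolated-nucleus runs enable the
NM–P pairing so the plates can touch the nuclear envelope.

*Layer compression*: a rigid left wall advances at 0.25 µm/s against a
static right wall; strain is wall travel over initial separation. Membrane
maintenance is off during these runs: with a fixed membrane inventory and
volume-preserving interiors, cells resist shape change, so in-plane
compression must be relieved by out-of-plane buckling — the physics the
experiment probes. A buckle is a maximal run of contiguous cells whose
basal height (smallest membrane-bead distance to the BM line) exceeds half
a cell diameter, spanning at least half a diameter horizontally; both
thresholds are configurable. The same driver underlies the
nucleus-position experiment (buckling onset strain for basal vs elevated
nuclei, shared seeds) and the adhesion shape sweep (mean cell aspect ratio
over a cadherin × BM-adhesion grid).

## Scaled-down mode and problem sizes

Experiments accept a resolution factor that scales particle radii up
(membrane influence radii scale along; bulk cohesion ranges stay physical).
Defaults used by the test suite and the reproduction script: full
resolution for the reference-cell count; factor 2 for isolated nuclei
(≈40 elements); factor 3 for single-cell compression and spreading
(≈130 elements) and the shape sweep; factor 4 for 20-cell layers
(≈3200 elements). Coarsened assemblies are not calibrated replicas; they
preserve orderings and qualitative responses, which is what the scaled
experiments measure.

## Known limitations

- Absolute plate/wall forces are on the arbitrary stiff-contact scale of
  the micrometre unit convention; only orderings and ratios are
  interpretable. The published force–displacement curves are figure-only
  and are not reproduced numerically.
- Spreading under the weak reference adhesion (1e−11 N/m spring, 3 µm
  range) widens a cell (aspect ratio ≈1.3–1.5) by growing a basal membrane
  skirt but does not flatten the interior dome within affordable step
  budgets; very long runs destabilise (detachment, membrane frilling). As
  a result the spread-vs-round stiffness comparison comes out inverted in
  this reconstruction — the partially spread cell measures softer, and the
  reproduction script reports this honestly.
- Basement-membrane adhesion forces are orders of magnitude below the
  driven contact-force transients of wall compression, so the
  buckle-count differentiation between adhesion conditions is weak:
  buckles appear or are suppressed mainly through geometry, and the
  printed three-buckle weak-adhesion mode is not reliably reproduced.
- The drag law is non-reciprocal by construction; momentum is conserved by
  the elastic forces only.
- No tangential or friction contact forces, no bending stiffness, no cell
  proliferation or death during experiments, no 3D geometry.
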