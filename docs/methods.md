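# Methods

## Scope and representation

`msclkit` operates on coarse-grained pentamer structures at one backbone bead
per residue plus optional side-chain beads (`BB`, `SC1`, `SC2`, ...). The
container (`CGStructure`) stores subunit index (0–4), 1-based residue number,
role and position; the internal length unit is nm throughout, with Å and
degrees appearing only in reports. PDB and GRO files are read and written via
MDAnalysis; subunits come from chain ids when present and otherwise from an
equal-length split of the residue sequence into five blocks (both per-subunit
and continued residue numbering are accepted; the latter is renumbered to the
first block). Foreign bead naming is sniffed: a bead named `BB`/`BAS`/`CA`/`B`
is the backbone, and a residue with none of those has its first bead taken as
backbone.

Default domain intervals (inclusive, configurable): N-terminal 1–14,
TM1 15–45, periplasmic loop 46–74, TM2 75–107, C-terminal 108–136. The
hydrophobic gate is fixed at residues 20–28 and the kink-prone sub-intervals
(TM1 38–43, TM2 90–107) follow the experimental literature; the remaining
boundaries are declared defaults.

## Restraint construction

One measured inter-subunit distance expands into 10 pairwise restraints:
adjacent pairs {(0,1),(1,2),(2,3),(3,4),(0,4)} at the measured distance and
second-neighbour pairs {(0,2),(1,3),(2,4),(0,3),(1,4)} at φ = (1+√5)/2 times
it (widths scaled likewise). This is the minimal geometric completion of the
count under the assumption that the measurement is the adjacent-pair
separation of a regular pentagon; a regular pentagon at the measured distance
therefore has exactly zero restraint energy (an invariant the tests assert).
The expansion is deliberately pentamer-specific and rejects other subunit
counts.

Potential forms: FRET → flat-bottom harmonic (zero inside the uncertainty
band), EPR → lower half-harmonic (zero above the bound). Restraints attach to
the backbone bead of the named residue: experimental labels sit on side
chains, but backbone attachment is well-defined for structures with zero side
chain beads and the attachment particle is not dictated by the data.

Defaults, all configurable:

| parameter | default | note |
|---|---|---|
| force constant k | 10 kJ·mol⁻¹·nm⁻² | deliberately soft, suited to staged introduction |
| EPR lower bound | 1.5 nm | the ≥ 15 Å open-state statement |
| ΔΠ → ε_water scale | clip(1 + 0.5·ΔΠ, 0.5, 2.0) | pluggable mapping; sign convention: ΔΠ > 0 = more water-exposed when open |
| table grid | dr = 0.002 nm, r_max = 6 nm | the emitter grows r_max per table when a flat region (large diagonals) would not fit |
| λ schedule | linear, 5 windows | λ multiplies k and the ε shifts, so energy is exactly linear in λ at fixed coordinates |

Solvent patches have no energetic role in this package: they are emitted as
new particle-type declarations (one per significant residue, applied to all
five subunits) for a simulation engine to consume. Significance is an input
flag, not recomputed: the upstream significance criterion is not part of the
data tables this package reads.

Emission is deterministic (fixed float formats, sorted table ids): re-running
`emit` on the same restraint set is byte-identical, and `load_manifest`
reconstructs the exact restraint set.

## Structural metrics

**Pore radius.** Per gate residue, the apothem of the pentagon formed by the
five backbone beads: the minimum distance from the projected centroid to the
five edge *segments*. This equals R·cos 36° for a regular pentagon of
circumradius R and stays well-defined (with a warning) for irregular or
self-intersecting rings. Projection is onto the xy plane by default (the
structures are membrane-aligned; pore axis = z through the TM backbone
centroid), with a least-squares-plane option for tilted inputs. The gate
radius is the unweighted mean over residues 20–28; per-residue apothems are
computed first and averaged, not the coordinates.

**Helix tilt.** Angle between the first principal axis of a helix's backbone
beads and +z, folded to [0°, 90°]. The closed-state fixture convention is
TM1 = 42°, TM2 = 28°.

**RMSD.** All superpositions are least-squares with proper rotations only
(scipy's Kabsch implementation). `domain_rmsd` aligns on the whole protein or
on the domain itself; `segment_rmsd` superposes each consecutive 5-residue
backbone segment independently (non-overlapping by default, stride
configurable) and records its RMSD at the central residue, separating
internal deformation from rigid-body domain motion. Note that a deformation
located exactly on a window boundary is invisible to non-overlapping windows;
use stride 1 when localising features.

**Kink detection.** Per subunit, the TM1 backbone is split at every candidate
residue with at least four beads on each side; two principal axes are fitted
(the vertex bead belongs to both arms), the split with the lowest combined
straight-line fit residual is the kink position, and the angle between the
two axes is the kink angle. Selecting the split by maximum angle instead is
biased upward by positional noise, which is why the residual criterion is
used. A kink is *present* when the angle reaches the threshold (default 20°)
and the helix genuinely deviates from the reference: after aligning the
sub-kink part onto the reference helix, the largest per-residue displacement
above the kink must exceed a threshold (default 0.15 nm). The displacement
criterion is deliberately measured against the reference helix as a whole
rather than by windowed segment RMSD: a 5-residue window centred on the
vertex of an ideal two-armed kink is nearly straight (internal RMSD ≈ 0.07 nm
for a 30° kink), so a windowed criterion under-detects exactly the feature of
interest. Both thresholds are declared defaults; the upstream analysis was a
visual inspection plus an RMSD criterion without published numbers.

**Symmetry deviation.** The five subunits are rotated into a common frame by
multiples of 72° about the centroid z axis, averaged bead-by-bead, the C5
counterpart is rebuilt and optimally superposed onto the input, and the RMSD
(optionally per subunit) is reported. Exactly C5 inputs score 0.

## Synthetic fixtures

The generator emulates the pentamer architecture — five subunits at 72°
about z, TM1 through the gate, antiparallel TM2 on an outer ring, a loop arc,
terminal segments — with every metric's ground truth as a parameter. Helices
are straight bead lines at 0.36 nm per residue (one CG bond length): the
helical wrap is omitted because no implemented metric depends on it at one
bead per residue. Helix tilt is applied in the radial-z plane with the pivot
at the gate centre (residue 24 for TM1); per-residue ring radii are then
linear and symmetric about the pivot, so the mean gate apothem equals
cos 36°·gate_circumradius *exactly* for any tilt — the closed convention
(circumradius 1.0513 nm → 8.5 Å) holds without special-casing. Gaussian
positional noise is applied last under a fixed seed; identical parameters and
seed give bit-identical structures.

What the fixtures do **not** emulate: helical backbone geometry, side-chain
packing, lipids and water, thermal ensembles with correlated fluctuations,
and genuinely asymmetric gating intermediates. Passing ground-truth-recovery
tests therefore demonstrates correctness of the metrics' geometry, not
robustness to every artefact of real trajectories.

Stochastic tests use noise σ = 0.02 nm over ≥ 20 seeds, a mild positional
jitter at which recovery is expected: tilt (31- and 33-bead helices) to
within 1°, kink position exactly, and the per-structure kink angle (mean of
the five identically built subunits; per-subunit estimates from the 6-bead
upper arm have ~0.8° standard error) to within 2°.

## Toy relaxer

The relaxer demonstrates that built restraints drive structures to the
intended geometry. Subunits move as rigid bodies — licensed by the
observation that adjacent TM helix pairs show little relative motion during
gating — and a greedy, seeded stochastic minimiser (random single-subunit
translation + small rotation; accepted only when the objective strictly
decreases; step sizes annealed after rejection streaks) runs for an equal
share of iterations in each λ window. The objective is
λ·E_restraint + E_membrane, where the membrane term is a weak harmonic on TM
backbone z coordinates (k = 1 kJ·mol⁻¹·nm⁻²) that prevents degenerate
sliding along the pore axis; it is plumbing, not physics. Strict-decrease
acceptance makes the per-window energy trace non-increasing by construction
and leaves an already-satisfied structure untouched. Default problem size
(5 windows, 3000 iterations, ~100 restraints on 680 beads) runs in about a
second; the end-to-end check — closed fixture relaxed under flat-bottom
restraints measured from an open fixture with a 15 Å gate apothem — lands
the final gate radius inside the 1 Å flat-bottom band.

## Degenerate inputs and numerical choices

Coincident pentagon vertices, all-coincident helix coordinates, helices under
4 beads (axis fit) or 8 residues (kink split), ragged subunits, and residues
missing backbone beads all raise typed errors rather than returning values.
Finite-difference force consistency is asserted to 1e-6 away from the flat
boundaries (the kink of the potential makes central differences meaningless
across it). Flat-bottom energies are exactly zero at grid points inside the
band; a boundary given as a decimal literal (e.g. 1.7 for target 2.0, width
0.3) can round a half-ulp outside it, producing energies of order 1e-31 —
tests treat those boundary points as approximately zero.

## Known limitations

No MD engine is run: λ schedules and topology patches are emitted, never
integrated. Trajectory-scale observables (time-averaged pore radii, kink
fractions of simulation ensembles, tension effects) are out of reach of the
rigid-body relaxer by design; the package's ensemble statistics
(`kink_fraction`) operate on user-supplied structure lists. The pentagon
expansion assumes the measured distance is an adjacent-pair separation; if a
dataset instead reports circumradii, convert before building data objects.
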