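# Methods

This note documents the models, conventions and numerical choices behind
`memdomain`: what the analyses compute, what the synthetic-trajectory
generator emulates (and deliberately does not), and where the design was
genuinely open.

Units are nm and ns throughout; diffusion coefficients are converted to
cm²/s (1 nm²/ns = 10⁻⁵ cm²/s) only at the reporting layer, and no
coarse-grained time-scaling factor is ever applied.

## System representation

A system is a `Topology` (molecules composed of named beads with a closed
role vocabulary: ROH, GL1/AM1, PO4, NC3/CNO/NH3, tail, backbone, sidechain,
water, ion) plus a dense `(frames, beads, 3)` coordinate array with a
periodic box and a uniform frame stride. Species tokens are
`HEAD_sn1/sn2` strings (e.g. `PC_16:0/18:2`); the saturation class is the
maximum tail double-bond count (0 saturated, 1 mono, ≥ 2 poly, so
PC 16:0/18:2 is polyunsaturated), PS carries −1 e, plasmalogen-PE is marked
ether-ester. The protein is two 24-residue chains with one backbone and one
side-chain bead per residue.

Phospholipids use a 7-bead template (head, PO4, linker, 4 tail beads),
cholesterol 3 beads (ROH + 2 ring/tail beads). These are deliberately
minimal: every analysis in the package keys on roles (linker band, ROH
position, any-bead distances), not on force-field bead counts.

On disk, coordinates are fixed-column GRO (single- or concatenated
multi-frame; the title line carries the time) and the species metadata a
molecule-level TSV, both plain text and byte-stable under
read-write-read.

## Membrane construction

The starting system follows the published recipe deterministically per
seed: a placeholder bilayer (DOPC-like PC 18:1/18:1 plus cholesterol, split
evenly between leaflets, odd remainders to the outer leaflet) is relabelled
into the target composition by a uniform random permutation per leaflet
under the leaflet constraints (PE/PE-pl/PS inner only, SM outer only), and
water beads are exchanged for Na⁺ until the net charge is zero (90 ions for
the native recipe's 90 PS). Unlike the original self-assembly procedure,
molecules are placed on a jittered square lattice at fixed leaflet depths
(~0.64 nm² per site; boxes default to that area), with solvent filling the
z-slabs outside the membrane. The geometry is topologically valid for every
downstream analysis but not physically relaxed — no energies exist in this
package.

Transverse geometry: head beads at |z| = 2.30 nm, PO4 2.00, linkers 1.60,
cholesterol-OH 1.45, tails inside. These depths put the two ROH density
peaks 2.9 nm apart and the head-group peaks 4.6 nm apart, consistent with
the experimental RBC membrane (head-to-head ~4.8 nm, hydrophobic core
~2.5 nm).

## The synthetic-trajectory generator

The generator produces CG-like trajectories whose statistical structure
matches 10 µs production runs, with every parameter planted and recorded:

* **Lateral motion** is per-molecule 2D Brownian displacement with
  species-specific D under periodic wrapping. Defaults (nm²/ns): saturated
  0.014, mono 0.019, poly 0.025, CHOL 0.020, protein 0.00614 — the
  composition-weighted lipid mean is ~2.0 × 10⁻⁷ cm²/s and the protein
  6.1 × 10⁻⁸ cm²/s, the values measured in the original simulations. A
  per-leaflet scale (outer 0.85, inner 1.15) encodes the slower, more
  saturated outer leaflet.
* **Transverse coordinates** are drawn per bead per frame around the role
  depth (Gaussian; linkers SD 0.25 nm, ROH 0.10 nm, heads 0.25 nm),
  uncorrelated in time.
* **Cholesterol flip-flop** is an asymmetric two-state telegraph process.
  The resident outer fraction is 0.5905 (= 274/(274+190), the observed
  outer/inner occupancy split), the event rate 0.3 flips/µs per molecule
  (~3 flips per molecule per 10 µs; the source reports only "high
  frequency"), and each flip moves the whole molecule linearly through the
  mid-plane over a 25 ns transit. A short ballistic transit keeps the
  instantaneous core population small (a ~200 ns transit would reproduce
  the reported ~26 molecules in the core, but swallows short dwells and
  biases flip-flop counting by ~12%; the 25 ns default keeps detection
  unbiased and preserves the 274:190 occupancy ratio).
* **Ordered patches** (the L<sub>o</sub>-like domains) are rigid discs that
  drift slowly (D = 5 × 10⁻⁴ nm²/ns). Cholesterol and saturated/mono
  lipids are assigned into the discs and polyunsaturated lipids out of them
  so the in/out concentration ratio is 4 for both groups (reflective disc
  boundaries maintain the contrast); molecules not in the ordered/disordered
  classes are unconstrained.
* **Dimer contacts** follow a scripted schedule of interface templates
  (sets of inter-monomer residue pairs; the bundled library has an
  "nmr"-like template on the GxxxG-motif face and two alternatives).
  Per frame, each pair of the template universe flips independently with
  the noise probability; the side-chain beads are then placed so the
  realized pair set — and only it — falls under the 0.6 nm contact cutoff.
  The placement is exact for star-shaped contact components (always the
  case for the bundled diagonal templates); an arbitrary bipartite pair
  graph is realized as the closure of its components, and the emitted
  ground truth is always the realized set.
* **Planted protein–lipid interactions**: a "sticky" molecule pinned at the
  protein surface for a scheduled interval (binding-time analyses), a
  cholesterol tethered to a chosen residue's side-chain bead for an exact
  fraction of frames (occupancy analyses), and a cholesterol "halo"
  confined to a disc around the dimer (shell-enrichment analyses).

What the generator does **not** emulate: excluded volume and bead–bead
forces, membrane undulations, correlated z-motion, hydrodynamics, and any
coupling between the dimer's interface state and its surroundings. Passing
tests therefore demonstrate that the analyses recover what was planted
under realistic geometry and sampling noise — not that the physics of a
force-field simulation is reproduced.

## Analysis conventions

* **Leaflet assignment**: per frame, the linker band of each leaflet is the
  sample mean ± 2 SD of its GL1/AM1 z positions; a cholesterol whose ROH
  lies within or beyond a band belongs to that leaflet, strictly between
  the bands it is "core". One internally consistent convention serves both
  the band figure and the occupancy statistics.
* **Flip-flop detection** debounces with a 2-resident-frame persistence
  (default): core frames are transparent, and an excursion shorter than the
  persistence neither counts nor resets the accepted leaflet.
* **Contact cutoff** 0.6 nm, any-bead minimum distance, lateral minimum
  image — the conventional CG first-shell contact scale; configurable.
* **Interface clustering**: average-linkage on the Dice matrix, cut at
  0.25; deterministic and seed-free. Frames with an empty map are labelled
  `apart` and excluded from frequency vectors. Reference-interface presence
  uses Dice-to-reference ≤ 0.33 so the trace is independent of clustering
  granularity. Episode durations count frames × stride; the reformation
  gap is measured from the last present frame (default 0.5 µs).
* **Protein–lipid distances** are lateral (xy, minimum-image) per-molecule
  minimum bead distances — shells and leaflet-resolved composition are
  lateral concepts; a `3d` mode exists. Residue-contact occupancy uses 3D
  distances instead: cholesterol spans both leaflets, and a lateral-only
  criterion would count opposite-leaflet molecules as side-chain contacts.
* **RDF normalization** divides the distance histogram by the empirically
  accessible area per distance bin (periodic Euclidean distance transform
  of the rasterized protein footprint, 0.05 nm grid, averaged over sampled
  frames) — iso-distance contours around an extended dimer are not
  circles, and annulus normalization would bias g(r) upward by ~10%.
  Uniform placement then gives g ≈ 1 within noise. Shell radii fall back
  to 0.658/0.918/1.178 nm when fewer than three minima are detected.
* **Shell enrichment** direction uses a ±0.05 neutrality band around
  ratio 1 to avoid flagging sampling noise.
* **Density maps** bin one reference bead per lipid (linker; ROH for
  cholesterol) on a 0.5 nm grid by default (all-beads and cell size are
  flags). The 2/3-of-maximum rule is scale-invariant. The merged map gives
  protein precedence; the protein's own domain residence is read from the
  lipid-only map under the protein footprint, modal over the footprint
  weighted by protein occupancy so grazed cells do not dominate.
  The 2/3-max rule is sensitive to counting noise: the maximum over cells
  is an upper order statistic, so sparse maps (few frames, small cells)
  under-call enrichment. Domain analyses in the acceptance script
  therefore use 10 ns frames over 2–4 µs windows and 1.0 nm cells, sizes
  at which a uniform field is correctly classified as uniformly enriched
  and a planted disc is recovered cell-for-cell.
* **MSD** uses one reference bead per molecule, nearest-image displacement
  accumulation (valid while per-stride displacements stay below half the
  box — true for all defaults), removal of the per-frame mean displacement
  of all molecules, and time+molecule averaging at ≤ 200 lags. The fit
  window defaults to 10–50% of the maximum lag; for the protein — a single
  slow walker whose time-averaged MSD decorrelates at long lags — the
  acceptance analyses average ~40 replicate runs and fit 2–20%.

## Conditions and the pipeline

`derive_condition`/`derive_composition` implement the condition algebra:
`nFA+CHOL` swaps every head group to PC keeping the tails (merging species
that collide, e.g. SM 16:0/16:0 → PC 16:0/16:0) and returns ions to water;
`nFA+head` deletes cholesterol; `nFA` does both. Both operations are
idempotent. In the pipeline's planted dynamics, cholesterol-containing
conditions carry the ordered patches, slower lipid diffusion (×1 vs ×4.3
without cholesterol, after the measured ratio 2.05/8.74), a dimer placed
outside the patches, and a longer-lived reference interface (template dwell
means 1500/750/250 ns for native vs 450/300/1750 ns without cholesterol,
chosen so template frequencies favour the reference interface with
cholesterol and the alternative without, with the cholesterol-free pair of
conditions more similar to each other than to the native pair).
`run_pipeline` is driven by a YAML config (conditions, replicates — default
10, mirroring the ten production runs —, seeds, analysis sizes), logs
per-stage failures into the report instead of aborting, and writes TSV
tables plus a deterministic `summary.json`.

## Problem sizes

The default synthetic runs use the full native composition
(510 phospholipids + 490 CHOL, ~5000 beads) over 200 frames × 50 ns
(10 µs). Dedicated runs per analysis follow the per-analysis stride the
method prescribes: 2000 × 5 ns for diffusion and flip-flop counting,
2000 × 0.5 ns (1 µs, composition scaled ×0.2) for binding times,
400 × 10 ns for domain maps. The acceptance script completes in a few
minutes on one CPU.

## Known limitations

* No excluded volume: local densities can exceed physical packing, and
  residue-contact occupancy in a full-density membrane picks up incidental
  3D contacts; the occupancy validation uses a sparse tracer configuration
  for that reason.
* Lipid (non-cholesterol) flip-flop is out of scope.
* The telegraph transit underpopulates the hydrophobic core relative to the
  reported steady-state core occupancy (see above).
* Interface templates are diagonal residue pairings; arbitrary contact
  graphs are realized only up to bipartite closure.
* `neutralize` models Na⁺ counterions only; a net-positive membrane raises
  an error.
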