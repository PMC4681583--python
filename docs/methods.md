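# Methods

This note documents the models, conventions and numerical choices behind
`asymmem`, and what the synthetic fixtures do and do not establish.

## Lipid templates

Each supported species (POPC, POPE, POPS, PPCS, DPPC, CHOL, PIP2, plus W
water and NA sodium) ships as a bead template: ordered bead names with
MARTINI-style bead types and charges, a bonded topology, and an
idealized internal geometry. The geometry is a straight-chain layout —
head-group beads stacked above the PO4 (or ROH) reference bead, two acyl
tails below the glycerol/amide linkers at ±0.11 nm lateral offset, with
0.47 nm bead spacing (the standard CG bond length). This geometry is
used **only for initial packing**; self-assembly erases it, so its exact
shape is noncritical. The head reference bead sits at the origin of the
internal frame, which is what anchors substitutions and leaflet
assignment.

Charges follow common CG conventions: POPS −1 (PO4 −1, neutral serine
bead), PIP2 −5 (PO4 −1 plus two −2 ring phosphates), zwitterionic lipids
and cholesterol 0, NA +1. The exact bead decomposition per species is an
implementation choice documented in the plain-text species format
(`templates.write_species_file`), through which users can also register
their own lipids.

## Builders

**Packing** is seeded rejection sampling: each molecule draws a position
(uniform in the box, or radius-cubed-uniform in a shell) and a uniform
random orientation (normalized Gaussian quaternion), and is rejected if
any bead leaves the region or comes within the clash cutoff
(default 0.3 nm) of a previously placed molecule; a cell list makes the
clash test O(1) per bead. Retries are bounded (default 1000 per
molecule) and a volume-heuristic feasibility check runs first. Identical
spec + seed gives bit-identical output; the high-level builders derive
per-stage child seeds from one global seed via a stable hash, so stages
are individually reproducible.

**Stacking** lifts the upper (CP) slab by (slab height − overlap) and
centers the merged system in the taller box. Overlap defaults to 0.5 nm
because a zero-overlap seam is lipid-poor and fills with water, which is
known to split the self-assembling membrane in two. At t = 0 the
species-to-slab assignment is exact by construction and is reported from
builder bookkeeping (lower molecule ids are IV-origin), not from a
geometric leaflet test — before assembly there is no bilayer midplane to
test against.

**PIP2 enrichment** replaces n randomly chosen POPC molecules in place:
the new template is anchored at the old head-bead position and aligned
with the old head-to-tail axis. When a fraction is given instead of a
count, n = round(frac × CP-slab phospholipids). The source text for this
construction is ambiguous about both the 3 %-mol base population and
which box the POPC pool belongs to; we substitute from the global POPC
pool and default the count to the CP-slab phospholipid base, and expose
the explicit count for anyone wanting a different reading.

**Protein placement.** Planar: the principal axis is aligned with z,
flipped so the C-terminal bead (last bead of the highest residue) points
toward the requested slab, and the protein is translated so that bead
falls inside the slab's z-range; clashing lipids are removed and
reported. Vesicle: copies are placed along random directions with a
minimum pairwise angular separation (default 30°), each slid along its
direction until every anchor residue's radial distance falls inside its
band (e.g. C-terminus in the IV shell, Trp anchor in the CP shell,
SNARE motif unbounded outside). Infeasible bands raise rather than
silently misplace.

**Solvation** fills a jittered cubic lattice (spacing 0.47 nm, the CG
water density) with W beads, discarding lattice points within the
exclusion distance (default 0.47 nm) of existing beads; neutralization
swaps randomly chosen waters for NA until the net charge is zero. The
merged system is solvated once, after stacking.

## Water-lined pores

A pore axis defines a half-space cylinder from the lipid center of mass
outward, so the default ±x, ±y axes give four distinct pores rather than
two channels. Removal tests **any bead** of a lipid against the
cylinder (radius 1.5 nm); conversion tests the **head bead** against the
shell (1.5, 1.5 + 1.7] nm around the pore surface — the head bead is
also the restrained particle, which keeps the two choices consistent.
Both tests are exposed as options because the source description does
not distinguish them. wlipids keep species, bonded identity and
positions; only bead types change to the water type (P4). One isotropic
restraint (default 300 kJ mol⁻¹ nm⁻²) per wlipid head bead is emitted.
The printed source value carries the unit kJ mol⁻¹ nm⁻¹; a position
restraint constant is kJ mol⁻¹ nm⁻², and the writer uses nm⁻² semantics
with the value 300. Reverting restores template bead types and clears
restraints; removed lipids stay removed.

## Analyses

* **Leaflet assignment.** Planar: head-bead z against the bilayer
  midplane, defined as the lipid tail-bead center of mass. Vesicle:
  head-bead radius against the mid-radius, the mean per-lipid head
  radius. Heads within a dead zone (default 0.5 nm full width) are
  labeled `midplane` — cholesterol resident in the membrane center is
  reported as such, not forced into a leaflet. IV shares exclude
  midplane lipids from the denominator and report them separately.
* **Voronoi APL.** Sites are lateral head-bead coordinates; the diagram
  is computed once on a 3×3 periodic tiling and the central cells kept,
  so cell areas sum to the patch area exactly. Vesicle patches are
  excised at a pole (default 14 × 14 nm), rotated so the local normal is
  z, and treated as flat. On a perfect sphere this flat-patch projection
  compresses cell areas by the local cos θ of the projection, a few
  percent at the default patch size — one reason a patch-based APL sits
  slightly below the closed-form 4πr²/N value.
* **Order parameters.** S₂ = (3⟨cos²θ⟩ − 1)/2 per species and
  consecutive-bond label, averaged over molecules and frames, against
  the z axis or the local radial direction. The second-rank form is
  bounded by [−1/2, 1] and vanishes for isotropic orientations; degenerate
  zero-length bonds are skipped with a warning.
* **Profiles.** Density profiles are mass histograms (uniform 72 amu
  per bead, the 4-to-1 CG mapping mass) per bin volume, centered on the
  per-frame tail-COM midplane. The center-of-mass RDF is shell-volume
  normalized against the mean density of the bounding ball, so a uniform
  ball gives g = 1; vesicle radii are the two largest smoothed local
  maxima at least 5 bins apart (3-bin moving average, ties toward larger
  g), reported with their separation and without reconciling the
  head-peak separation against any independently stated thickness.
* **Lateral diffusion.** 2-D MSD over all time origins; D is the
  least-squares slope over the fit window divided by 4 (default window:
  first half of the lag range). Dimensionality is exposed for anyone
  wanting the 3-D convention.
* **Contacts.** A residue–frame contact exists when any ligand bead is
  within the cutoff (default 0.6 nm, a typical CG first-shell distance;
  no value is stated in the source) of any bead of the residue.
  Per-ligand traces are retained. Aligned densities superpose each frame
  on the first frame's reference selection (Kabsch) before accumulating
  target positions on a regular grid.

## Synthetic fixtures

The fixtures are geometric idealizations with embedded ground truth, not
physical configurations, and must not be used as simulation inputs:
lattice bilayers with heads exactly at ±thickness/2; Fibonacci-sphere
vesicles with heads exactly on the stated shells; Walsh/Gaussian walkers
with the stated diffusion coefficient (per-step 2-D displacement
variance 4 D dt); scripted ligand schedules with known occupancy.
Passing tests on them establishes the **estimators** (zero leaflet
errors, exact Voronoi conservation, peak recovery to half a bin,
unbiased D within the stated tolerance, exact contact counting) — they
say nothing about whether a given force field reproduces real membrane
asymmetry, which only simulation can show.

## Problem sizes and defaults

Full-scale constructions (889-lipid planar box with ~77k waters;
17 880-lipid vesicle) build in seconds; the validation suites use
1/10-scale shells and ≤ 50-lipid systems where an O(N²) brute-force
oracle is compared against, and 1000 walkers × 500 frames for diffusion
recovery. The acceptance script builds the planar system and the vesicle
at full scale.

## Known limitations

* No dynamics, minimization, or force-field parameters: the output is a
  pre-assembly configuration plus analysis of whatever trajectories the
  user supplies.
* Orthorhombic boxes only; triclinic input is rejected explicitly.
* Clash detection during packing is non-periodic (molecules are wholly
  inside their region), matching the brute-force oracle definition.
* The flat-patch Voronoi APL underestimates the spherical value by the
  projection factor noted above.
* Protein placement treats the molecule as rigid; flexible-chain
  repositioning is left to the subsequent simulation.
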