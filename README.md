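# asymmem

Builders and analyses for coarse-grained (CG) membrane systems with
**physiological lipid composition and leaflet asymmetry**.

Most membrane-building tools decide in advance how many lipids go into
each leaflet, which requires assuming an area per lipid (APL) for every
mixture. An alternative is to let the membrane *self-assemble* in a CG
simulation from a starting configuration in which the two leaflet
mixtures are spatially separated: two stacked lipid slabs for a planar
bilayer, or two concentric spherical shells for a vesicle. `asymmem`
constructs exactly those starting configurations — with MARTINI-style
bead templates, seeded random packing, protein co-placement, solvation
and neutralization — and implements the accompanying analyses: leaflet
assignment and composition accounting, Voronoi-tessellation APL, order
parameters, density and radial-distribution profiles, lateral diffusion,
and lipid–residue contact statistics. It is aimed at molecular-modelling
practitioners who set up and audit such self-assembly simulations
(`asymmem` itself does not run dynamics).

## The constructions in brief

**Planar bilayer.** Two lipid boxes (default 16 × 16 × 5 nm) are packed
independently — one with the cytoplasmic (CP) mixture, one with the
intravesicular/extracellular (IV) mixture — then stacked into a taller
box with a small vertical **overlap** (default 0.5 nm). With zero
overlap the seam between the slabs is lipid-poor, fills with water
during solvation, and the self-assembly tends to split into two
membranes; the overlap keeps the seam lipid-dense. The box is then
solvated with CG water (P4 beads) and neutralized with Na⁺.

**Vesicle.** The IV mixture is packed into an inner spherical shell and
the CP mixture into an outer shell whose inner radius overlaps the IV
shell by 0.5 nm; the assembly is centered in a cubic box.

**Water-lined pores.** To let lipid and water densities equilibrate
across a closed vesicle, transmembrane cylinders (radius 1.5 nm along
±x, ±y) are emptied of lipids and the surviving lipids whose head beads
lie within 1.7 nm of a pore surface have all bead types switched to the
water type (*wlipids*), with one position restraint
(300 kJ mol⁻¹ nm⁻²) on each wlipid's head bead. After equilibration the
wlipids are reverted to their template types.

**Key quantities.** Leaflet asymmetry is reported as the *IV share*:
the percentage of a species' molecules in the IV leaflet over its IV+CP
total. Per-lipid areas come from a periodic Voronoi tessellation of
head-bead positions (PO4 for phospholipids, ROH for cholesterol), or in
closed form for a spherical monolayer, APL = 4πr²/N. Bond order is the
second-rank parameter S₂ = (3⟨cos²θ⟩ − 1)/2 with θ the angle between a
bond vector and the membrane normal. Lateral diffusion follows from the
2-D mean-squared displacement, MSD = 4Dt.

## Worked example

```python
from asymmem.planar import build_planar
from asymmem.analysis import sphere_apl

result = build_planar(
    iv_composition={"PPCS": 36, "POPC": 180, "CHOL": 144},
    cp_composition={"POPS": 63, "POPE": 210, "CHOL": 256},
    seed=12,
)
print(result.iv_share())
print("Na+ ions:", result.system.species_counts()["NA"])
print("inner APL:", round(sphere_apl(15.6, 8231), 1), "A^2")
```

prints

```
{'CHOL': 36.0, 'POPC': 100.0, 'POPE': 0.0, 'POPS': 0.0, 'PPCS': 100.0}
Na+ ions: 63
inner APL: 37.2 A^2
```

At t = 0 the construction is exactly asymmetric: all sphingomyelin
(PPCS) and POPC sit in the IV slab, all POPS/POPE in the CP slab, and
cholesterol is split 144/256 (36 % IV). The 63 Na⁺ ions balance the 63
POPS charges (−1 e each). The closed-form APL evaluates a spherical
monolayer of 8231 lipids at radius 15.6 nm to 37.2 Å² per lipid.

The same constructions are available from the shell:

```bash
asymmem build-planar --cp "POPS:63,POPE:210,CHOL:256" \
    --iv "PPCS:36,POPC:180,CHOL:144" --box 16,16,13 --overlap 0.5 \
    --seed 12 --out system.gro --top system.top
asymmem build-vesicle --iv "PPCS:720,POPC:3600,CHOL:2880" --iv-radii 15,20 \
    --cp "POPS:1260,POPE:4300,CHOL:5120" --cp-radii 19.5,24.5 \
    --box 53 --seed 12 --out vesicle.gro
asymmem carve-pores --in vesicle.gro --out pored.gro \
    --posre posre.itp --report carve.json
asymmem analyze --topof vesicle.gro --geometry vesicle --leaflets --rdf \
    --out report.json
```

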