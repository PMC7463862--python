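# siechit

Endpoint binding free-energy scoring and trajectory contact analysis for
GH18 chitinase–chitin oligomer complexes.

Bacterial family-18 chitinases recognize the nonreducing end of chitin and
hydrolyze it into short GlcNAc oligomers; their conserved active-site motif
DXXDXDXE supplies the two catalytic residues — the last aspartate
hydrogen-bonds the substrate's acetamido nitrogen and the glutamate cleaves
the glycosidic bond. This package implements the computational stack used to
characterize that recognition for the *Chitinibacter tainanensis* enzyme
chitinase 1198: a solvated interaction energy (SIE) scoring function over
trajectory snapshots, radial-distribution-function and hydrogen-bond
analysis of the Asp440–GlcNAc contact, motif location in protein sequences,
and seeded synthetic structure/trajectory generators so every stage runs and
is testable with no external data.

## The model

The SIE estimator combines four interaction terms with calibrated
coefficients:

    ΔG_bind(ρ, D_in, α, γ, C) = α·[ E_C(D_in) + ΔG_RF(ρ, D_in) + E_vdw + γ·ΔMSA(ρ) ] + C

* `E_C(D_in)` — intermolecular Coulomb energy screened by the solute
  dielectric D_in,
* `ΔG_RF` — reaction-field (electrostatic solvation) change upon binding,
  from a finite-difference Poisson solver with a two-dielectric boundary on
  the ρ-scaled union of atom spheres,
* `E_vdw` — intermolecular 12-6 Lennard-Jones energy,
* `γ·ΔMSA` — cavity term: change in probe-inflated molecular surface area
  scaled by γ,

with the calibration α = 0.1048, D_in = 2.25, ρ = 1.1,
γ = 0.0129 kcal/(mol·Å²), C = −2.89 kcal/mol, solvent dielectric 78.5.
Trajectory scoring reports each term as mean ± SEM over snapshots.

The trajectory side computes g(r) between atom selections (normalized so an
ideal gas gives g = 1), locates its peak, and scores hydrogen-bond occupancy
with a pure 3.0 Å distance criterion.

## Worked example

Recombining the published per-term SIE components for the three chitinase
1198 complexes (shipped as `siechit/data/sie_components_chitinase1198.tsv`):

```sh
siechit score --components-only src/siechit/data/sie_components_chitinase1198.tsv
```

```
term	glcnac12_unit2	glcnac12_unit3	glcnac3_unit2
inter_vdw	-92.3600	-90.2600	-66.4400
inter_coulomb	-23.3300	-36.7200	-23.9100
reaction_field	39.1400	58.2600	33.6400
cavity	-14.8100	-15.9800	-11.0900
constant	-2.8900	-2.8900	-2.8900
total	-12.4645	-11.7666	-9.9954
```

The totals are the binding free energies (kcal/mol) of the 12-mer contacted
through its second GlcNAc unit, the 12-mer through its third unit, and the
trimer through its second unit: the second-unit 12-mer binds most strongly,
the ordering that rationalizes why (GlcNAc)₂ is the enzyme's main product.

The same pipeline runs structure-based from coordinates:

```sh
siechit simulate --units 3 --contact-unit 2 --mu 2.75 --sigma 0.1 \
    --frames 100 --seed 7 -o traj.pdb
siechit score --complex traj.pdb --receptor-sel "chain A" --ligand-sel "chain B"
siechit rdf --traj traj.pdb --sel-a "resid 440 and name OD1 OD2" \
    --sel-b "resname NAG and resid 2 and name N2"
siechit born-check --spacing 0.5   # Poisson solver vs the analytic Born ion
```

The numbered drivers under `analysis/` run the full study workflow on the
three emulated conditions (generate trajectories, score SIE, recover RDF
peaks and hydrogen-bond occupancies, scan the motif) and write their tables
under `results/`.

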