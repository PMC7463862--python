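# Methods

This note records the models implemented in `siechit`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Units and conventions

Coordinates in Å (nm accepted on input with an explicit flag and rescaled),
energies in kcal/mol, charges in elementary charge units. The Coulomb
constant is k = 332.0716 kcal·Å·mol⁻¹·e⁻². Residue numbers are taken
verbatim from the PDB with no re-indexing, so the catalytic aspartate of
chitinase 1198 is addressed as residue 440 everywhere, and sequence
coordinates are 1-based. ATOM and HETATM records are treated identically;
alternate locations other than blank/'A' are dropped with a warning.

## SIE scoring function

ΔG_bind = α·[E_C(D_in) + ΔG_RF(ρ,D_in) + E_vdw + γ·ΔMSA(ρ)] + C with
defaults α = 0.1048, D_in = 2.25, ρ = 1.1, γ = 0.0129 kcal/(mol·Å²),
C = −2.89 kcal/mol. Two readings of the published per-term components were
possible — cavity inside or outside the α bracket; only the inside-bracket
reading reproduces all three published totals from the published
components, so that is the implemented combination. The solvent dielectric
(78.5) is the standard value of the SIE calibration; it is not printed with
the parameter set.

Per-snapshot terms:

* **E_C** — Σ k·q_i·q_j/(D_in·r_ij) over all receptor × ligand pairs,
  constant dielectric screening (the literal form of the function; no
  distance-dependent dielectric), no cutoff. Endpoint sums are exact; the
  MD engine's neighbour-list cutoff is integration machinery, not part of
  the endpoint definition. An optional cutoff exists but defaults off.
* **E_vdw** — 12-6 Lennard-Jones with Rmin-based parameters,
  Rmin_ij = Rmin_i/2 + Rmin_j/2, ε_ij = √(ε_i·ε_j).
* **ΔG_RF** — RF(complex) − RF(receptor) − RF(ligand) with all three
  solves on the identical grid and frozen coordinates (single-trajectory
  endpoint convention).
* **cavity** — γ·[MSA(complex) − MSA(receptor) − MSA(ligand)].

Trajectory aggregation reports mean ± SEM per term, SEM = sample standard
deviation/√n, defined as 0 (and logged) for n = 1. The snapshot count of
the original study is not stated; the stride is therefore user-set and
defaults to every stored frame. SEM magnitudes — not means — depend on it.

## Finite-difference Poisson reaction field

∇·(ε∇φ) = −4πkρ_q is discretized on a uniform Cartesian grid (default
spacing 0.5 Å, padding 6 Å, odd node counts so the box center lies on a
node). The dielectric is D_in inside the union of spheres of radius
ρ·boundary_radius and D_solv outside. The boundary is the ρ-scaled
union-of-spheres accessible surface, not a reentrant molecular surface:
the variable-radius construction of the original SIE calibration is
approximated at desk scale, and the Born/Kirkwood validation suite bounds
the resulting error (0.3% Born error at 0.4 Å spacing; 0.8% against the
40-term Kirkwood expansion for off-center charges).

Numerical choices:

* Face dielectrics are harmonic means weighted by the **exact** fraction of
  each grid edge inside the cavity union (per-sphere chord lengths with an
  interval-union correction where several spheres cover one edge). The
  exact-fraction boundary is what makes the discretization error decrease
  smoothly and monotonically under grid refinement.
* Charges spread to nodes trilinearly; φ read back at atom positions
  trilinearly.
* Dirichlet boundary values from the analytic solvent-screened monopole
  sum; the same analytic form doubles as the initial guess.
* Red–black successive over-relaxation, ω = 2/(1 + sin(π/n));
  convergence when the maximum per-sweep potential change falls below the
  grid tolerance (default 1e-4 kcal/(mol·e)); non-convergence raises with
  the final residual.
* The self-energy of the lattice charge distribution cancels by
  subtracting a second solve with ε = D_in everywhere, so
  ΔG_RF = ½·Σ q_i(φ_i − φ_i^vac) is finite and grid-convergent.

One physical subtlety: the reaction field of a complex includes the
solvent-screening correction to the partner–partner Coulomb interaction,
a term decaying as (1/D_solv − 1/D_in)/r. For net-charged partners the
binding ΔG_RF therefore does **not** vanish at large separation — that
long-range piece is exactly the counterpart of the D_in-screened E_C term
and the two cancel in the α bracket. The non-interacting-limit test is
accordingly posed with net-neutral (dipolar) partners.

## Molecular surface area

Probe-inflated accessible area over spheres of radius
ρ·boundary_radius + probe (probe default 1.4 Å), by deterministic
generalized-spiral (golden-angle) point sampling, default 960 points per
atom; any convention difference against the original calibration's surface
definition is absorbed by γ. Per-atom areas are returned alongside the
total, and all surface numbers are bit-reproducible for a given n_points.

## Radial distribution function and hydrogen bonds

g(r) histograms all cross-pair distances over frames. Shell-volume
normalization divides by 4πr²Δr and by the mean pair density inside the
r_max sphere (ideal gas ⇒ g ≈ 1, verified against uniform points in a
periodic box); counts-only mode returns the probability-density histogram.
Defaults: bin width 0.05 Å, r_max 8 Å. The peak is the center of the
maximal-g bin, ties broken toward smaller r. No minimum-image convention
is applied to protein–ligand selections (complexes are compact); an
orthorhombic periodic mode exists for the ideal-gas validation.

Hydrogen bonding is a pure distance criterion (default 3.0 Å, the
constraint distance convention of the modeled systems; no angle term), with
the per-frame minimum cross-pair distance recorded. Which atoms define the
"Asp440 side" is not fixed by the source analysis; carboxylate oxygens
OD1/OD2 are the documented default and selections are user-suppliable.

## Motif scanning

DXXDXDXE is matched by direct sliding-window comparison; all overlapping
occurrences are reported in ascending order. Pattern 'X' is a wildcard;
sequence 'X' (unknown residue) matches only wildcards. For a match at
1-based start s the catalytic pair is (s+5, s+7) — last Asp, then Glu.
Protein molecular weight uses average residue masses plus one water
(via Biopython); the empty sequence is rejected rather than returning the
mass of water.

## Synthetic data generator

The generator stands in for the study's homology model, docking pose, and
100-ns MD trajectories, which cannot be redistributed or re-run at desk
scale. It emulates exactly the statistical structure the analysis consumes:

* a rigid pocket (8-atom ring, half of them carrying +0.25 e so the
  complex is net neutral) plus an Asp440 carboxylate (−1 e, united-atom
  charges),
* a linear chain of 4-atom pseudo-GlcNAc caricatures (ring-center carbon,
  acetamido N2, amide O, hydroxyl O; each unit net neutral,
  5 Å spacing; unit 1 = nonreducing end) — not real carbohydrate topology
  or GLYCAM-style parameters,
* one designed contact: the chosen unit's N2 against the nearer
  carboxylate oxygen, at an i.i.d. truncated-normal distance per frame
  imposed along a fixed axis, with Gaussian jitter (default σ = 0.05 Å) on
  all other atoms.

The three emulated study conditions (`study_conditions()`) place the
designed modes at the three reported contact-distance peaks: 12-mer/unit-2
at 2.75 Å, 12-mer/unit-3 at 2.25 Å, trimer/unit-2 at 3.25 Å, each with
σ = 0.1 Å — spreads chosen as a realistic width for a maintained
protein–ligand hydrogen bond. Everything is deterministic under the seed,
down to the written PDB bytes.

What passing tests therefore show: the estimators recover distributions
they were designed to see (peak positions to one bin, occupancies to
binomial error, energies to oracle precision). What they do not show:
agreement with the original trajectories' RDF curves or per-term SIE
values, which depend on the study's homology model and force field and are
not desk-reproducible; those published per-term components enter only as a
worked-example input whose recombination to the published totals is
verified exactly.

## Problem sizes

Defaults used by the analysis drivers: 2000-frame trajectories for the
distribution analyses (binomial error ~1%), 20 frames at 1.0 Å grid
spacing for the structure-based SIE demonstration — spacings and frame
counts chosen so the whole workflow runs in minutes on one core while the
validation suite separately pins solver accuracy at finer grids.

## Known limitations

* No Poisson–Boltzmann ionic-strength term (the scoring function has
  none), no reentrant/SES surface, no boundary-element solver.
* No intramolecular energetics, 1-4 scaling, bonded terms, or PME; the
  package scores endpoints, it does not integrate dynamics.
* The shipped parameter table is a minimal self-consistent set for the toy
  chemotypes (carboxylate, amide, aliphatic/ring carbon, hydroxyl, water
  plus element fallbacks); importing a full force field is out of scope.
* Hydrogen-bond scoring is distance-only by design; no angular or
  energetic definitions, no lifetime/kinetics analysis.
* Sequence utilities do not align or build trees; motif location is exact
  pattern matching, not a profile/HMM search.
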