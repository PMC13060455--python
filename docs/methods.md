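# Methods

`qrcryst` implements reciprocal-space quantum refinement (QR) at desk scale:
crystallographic refinement whose target function augments the experimental
residual and the empirical (MM) restraints with the energy of a small,
chemically interesting region — here a di-iron site with a solvent-derived
bridging ligand — evaluated by a pluggable energy backend.

## The target function

Plain restrained refinement minimizes

    E = w_x * E_exp + E_MM

and quantum refinement replaces the empirical description of the QM region by
the backend energy:

    E = w_x * E_exp + E_MM - E_MM1 + w_QM * E_QM1

where `E_MM1` is the empirical-restraint energy of the QM region (a restraint
counts towards `E_MM1` iff *all* of its atoms are in the region — this is the
package's definition of the subtraction and makes the cancellation for a
whole-model region exact) and `E_QM1` is the backend energy of the region
capped with hydrogen link atoms.  `w_QM` defaults to 7.5 (kcal mol⁻¹)⁻¹; the
backend reports kJ mol⁻¹ and the conversion factor 4.184 is fixed.

**Experimental term.**  `E_exp = Σ_work ((F_obs − k|F_calc|)/σ)²`, a
σ-weighted least-squares amplitude residual over working-set reflections only;
free reflections never contribute to the value or gradient.  This replaces the
maximum-likelihood targets of production packages — acceptable here because
every supported conclusion is a *relative* comparison on synthetic data.  The
scale `k = Σ F_obs|F_c| / Σ|F_c|²` is the closed-form least-squares minimizer,
held fixed within each minimization leg.

**Weight normalization.**  The synthetic crystals are far more over-determined
than real macromolecular data at the same resolution (~1300 reflections
against ~250 refinable coordinates), so the raw least-squares `E_exp` would
swamp the restraint side at `w_x ≈ 1` and the protonation-state signal in the
metal–ligand distances would vanish.  Following the gradient-ratio weighting
used by CNS and Phenix, the experimental term is multiplied by

    w_auto = ||∇(E_MM − E_MM1 + w_QM E_QM1)|| / ||∇E_exp||

computed once per run on a deterministic 0.05 Å shake of the movable atoms;
the user-facing `w_x` multiplies this normalized weight, restoring its
conventional meaning (w_x ≈ 1: experiment and restraints comparable).  With an
empty QM region `w_auto = 1` — there is nothing to balance and the target is
exactly `w_x·E_exp + E_MM`.  No claim of numerical equivalence between this
`w_x` scale and any other package's is made.

## Scattering

Structure factors are computed by direct summation over symmetry operators and
atoms with the convention `s = sinθ/λ = 1/(2d)` and isotropic Debye–Waller
factor `exp(−B s²)`.  Two neutral-atom form-factor tables are supported:

- **xray** — Cromer–Mann 4-Gaussian + constant (International Tables / IT92);
- **electron** — 5-Gaussian neutral-atom parameterization (Peng-style), used
  for MicroED-like data; electrons scatter off the electrostatic potential,
  so the two tables are related by the Mott–Bethe formula, which the test
  suite checks to 5% for C, N, O and Fe.

Coefficients are read from gemmi's built-in tables at run time rather than
shipped as data files (one authoritative source; the `ScatteringCoefficients`
type exposes them).  Charged/aspherical scattering factors, anomalous terms,
bulk solvent and dynamical scattering are out of scope.  Analytic derivatives
of `F(h)` with respect to coordinates and B values feed all refinement
gradients; correctness is established against central finite differences.

Difference maps use model phases: `Δρ = (1/V) Σ (F_obs/k − |F_c|) e^{iφ_c}`,
Friedel mates included so the map is real, F(000) excluded, synthesized by FFT
(an equivalent direct summation is kept as a cross-check); the grid spacing
defaults to d_min/4 and is refused above d_min/3.

## Empirical restraints

Harmonic bonds and angles only, driven by an editable YAML dictionary
(`data/restraints.yaml`; regenerate with `scripts/make_dictionary.py`).
Dihedral and planarity classes of full Engh–Huber-style dictionaries are
deliberately omitted — the rigid toy fragments do not need them.  Ideal values
are measured from the fragment templates in `qrcryst.fragments`, which keeps
dictionary, templates and surrogate backend mutually consistent (a site built
from templates is exactly at the dictionary optimum).  Nonbonded interactions
are a one-sided soft-sphere repulsion between inter-residue pairs (2.2 Å
cutoff, 1.7 Å when a metal is involved so coordination bonds are not
penalized).  Metal–ligand interactions carry **no** bonded restraints: as in
production refinement, the metal site is otherwise unrestrained and its
geometry comes from the experimental data and the QM term.

## The surrogate QM backend

Real DFT is out of scope.  The `EnergyBackend` contract —
`(elements, coords, charge, spin) → (energy kJ mol⁻¹, gradient)`,
deterministic — admits any external engine; the shipped surrogate is a
harmonic force field over the site topology:

- fragment-internal bonds/angles (same ideals/constants as the dictionary);
- metal–donor stretches detected by coordination distance (≤ 2.6 Å) at build
  time: Fe–O(carboxylate) 2.00 Å, Fe–N(imidazole) 2.15 Å, Fe–O(water) 2.20 Å,
  Fe–Fe 3.35 Å, k = 1200 kJ mol⁻¹ Å⁻² for Fe–donor (typical of DFT stretch
  force constants for first-row transition-metal–O/N bonds), 400 for Fe–Fe;
- the **bridging-ligand equilibrium depends on the protonation state**:
  Fe–O(bridge) = 1.88 / 1.98 / 2.08 Å for O²⁻ / OH⁻ / H₂O, the physical trend
  (more negative species bind shorter) that carries the discrimination signal;
- a short-range soft-sphere repulsion (2.2 Å, 1.8 Å for pairs with H) between
  non-bonded, non-1-3 pairs, scaled up for like-charged pairs — a point-charge
  stand-in that is inactive at sane geometries, so vacuum-optimum bond lengths
  reproduce the configured equilibria exactly.

Spin multiplicity is carried as metadata and **ignored** by the surrogate (the
real system is a broken-symmetry antiferromagnetic singlet; no surrogate
analogue is attempted).  Link atoms cap cut covalent bonds at 1.09 Å along the
host→neighbor ray; their gradients are distributed onto host and neighbor by
the chain rule of the placement function.

**Strain energy** is the backend energy of the refined region minus that of a
copy relaxed in vacuum with the link hydrogens fixed (same local minimum as in
the protein).  It is non-negative up to optimizer tolerance and zero at the
vacuum optimum; for a single stretched bond it reduces to the harmonic closed
form k·δ².

## Refinement protocol

Three macrocycles by default (configurable), each:

1. closed-form scale fit;
2. coordinate refinement of the QM region plus the stubs of residues with cut
   bonds (L-BFGS-B on analytic gradients, ≤200 iterations, never accepts an
   uphill result; all other coordinates bit-identical);
3. isotropic ADP refinement of the whole model, alternating closed-form scale
   fits with bounded B minimizations until the scale stabilizes (a uniform B
   shift and k are nearly degenerate, so a single fixed-k leg cannot converge),
   with a weak bonded-pair B-similarity restraint (weight 0.05) and a 0.5 Ų
   positivity floor.

Runs are deterministic for fixed inputs; the only randomness (data simulation,
free-set choice, perturbations, the weight-determination shake) is seeded.

**w_x scanning** runs one full QR per grid point from the same input state and
selects the argmin of min-max-normalized strain plus normalized average RSZD
(ties towards smaller w_x) — a concrete rule standing in for the informal
"compromise between strain energies and average RSZD scores".

**Ligand discrimination** swaps the bridging species (O²⁻/OH⁻/H₂O: hydrogens,
residue name and region net charge change; the oxygen keeps its position),
reruns the full QR per candidate, and ranks by the same equal-weight combined
criterion; the maximum RSZD and the refined Fe–O_X distances are reported but
not used for ranking.

## Evaluation

**RSZD** here is a defined surrogate for the edstats statistic: per residue,
the maximum of |Δρ|/σ over voxels within 1.5 Å of any residue atom, with σ the
standard deviation of the whole difference map (computed from working-set
reflections; σ floored at a negligible fraction of the total-density scale so
a numerically null map scores zero).  Grid spacing d_min/4 and mask radius are
configurable.  Good models score ≲ 3.  Distances use the minimum-image
convention; `mean_absolute_deviation` compares labelled distance tables.

## The synthetic generator

`build_toy_site` assembles a dimetal cluster patterned on the R2a di-iron
site: two Fe ions 3.35 Å apart bridged by the solvent species, four
carboxylate fragments (Asp/Glu named as in the protein, modelled as acetate),
two methylimidazoles (His), and two (oxidized) or one (reduced) terminal
waters, all hydrogens explicit, 55–63 atoms in a 16×17×18 ų P1 cell
(P2₁2₁2₁ by flag).  Fragments are placed on octahedral axes and relaxed under
the surrogate, so **ground truth is the surrogate's vacuum optimum by
construction** — parameter-recovery and discrimination experiments have an
exactly known answer, and the truth has zero strain.

`simulate_reflections` forward-computes Friedel-unique amplitudes to d_min and
applies `F_obs = |F_c|(1 + f·ε)` with standard-normal ε (default f = 5%,
σ = f|F_c| with a floor), a completeness mask, and — in electron mode — an
index-space cone exclusion around a chosen axis emulating the missing wedge.
The default study conditions for every end-to-end test are d_min = 2.0 Å, 5%
noise, 5% free set, three macrocycles.

What the generator does **not** emulate: solvent continuum, model
incompleteness, anomalous signal, radiation damage/photoreduction, dynamical
scattering, intensity-statistics pathologies, and the vastly lower
data-to-parameter ratio of real protein crystals.  Passing tests therefore
demonstrate the internal correctness and the relative-comparison logic of the
QR machinery, not its performance on deposited data.

## Numerical choices and degenerate inputs

- Minimizations: L-BFGS-B with analytic gradients; vacuum optimization
  restarts the optimizer up to 5 times and errors if the free-atom gradient
  norm stays above 1e-4 kJ mol⁻¹ Å⁻¹.
- Friedel merging: canonical index is the lexicographically larger of
  (h,k,l)/(−h,−k,−l); inverse-variance weighted mean; a merged reflection is
  free if either mate was; singletons pass through re-indexed; merging is
  idempotent.
- Free-set selection: seeded uniform sampling without replacement (deposited
  test sets are not reproducible here).
- Completeness denominators enumerate Friedel-unique indices in P1 over the
  resolution sphere (no space-group reduction — documented limitation).
- Reflections with σ ≤ 0 are rejected on read with a logged count; simulated
  amplitudes truncated at zero are counted and logged.
- Zero-amplitude reflections contribute no phase (and no gradient) to maps
  and targets.

## Known limitations

- The surrogate backend is harmonic: no anharmonicity, charge transfer,
  Jahn–Teller effects or spin-state energetics; strain magnitudes are not
  comparable to DFT values.
- The least-squares target and the w_auto normalization make w_x values
  comparable only within this package.
- RSZD is a surrogate statistic, not the edstats algorithm.
- P1 completeness counting; no mmCIF/MTZ, anisotropic ADPs, alternate
  conformations or occupancy refinement.
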