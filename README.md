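# qrcryst

Quantum refinement (QR) of crystal structures at desk scale, with switchable
X-ray and electron (MicroED-style) scattering.

Standard macromolecular refinement minimizes `E = w_x·E_exp + E_MM`: an
experimental residual plus empirical restraints.  Empirical restraints are
unreliable exactly where structures are most interesting — metal sites, whose
geometry depends on oxidation state, spin state and the protonation of every
ligand.  Quantum refinement replaces the restraints for a small region by a
physical energy:

    E = w_x·E_exp + E_MM − E_MM1 + w_QM·E_QM1

where `E_QM1` is the energy of the QM region (capped with hydrogen link
atoms), `E_MM1` removes the now-redundant empirical terms, and
`w_QM = 7.5 (kcal mol⁻¹)⁻¹` scales a physical energy against statistical
restraints.  Two structure quality measures discriminate between chemical
hypotheses: the **strain energy** (region energy relative to its
vacuum-relaxed copy — chemical plausibility) and the per-residue **RSZD**
score (unexplained difference density — agreement with the data).

The flagship use case is the one QR is best known for: deciding whether the
solvent species bridging a di-iron site is O²⁻, OH⁻ or H₂O.  Different
protonation states imply different Fe–O distances (≈1.88/1.98/2.08 Å), a
signal invisible to global R values but visible to strain + RSZD after one QR
run per hypothesis — including with electron-diffraction data, where neutral-
atom electron scattering factors replace the X-ray table.

This package is aimed at method developers and students: everything runs in
seconds-to-minutes on one CPU against *synthetic* dimetal-site crystals whose
ground truth is known exactly (the QM backend is a deterministic harmonic
surrogate honouring the full backend contract — real DFT engines can be
plugged in).  See `docs/methods.md` for the model, all defaults, and what the
synthetic data do and do not emulate.

## Worked example

Simulate a crystal whose bridging ligand is truly OH⁻, then ask the
discrimination protocol to recover that from the electron-diffraction data:

```bash
qr simulate --ligand OH- --seed 7 --out-dir sim
qr discriminate --model sim/truth.pdb --hkl sim/electron.hkl \
                --mode electron --seed 7 --out-dir disc
```

which prints (amplitudes carry 5% noise; three macrocycles per candidate):

```
ligand  charge   strain  avg_rszd  max_rszd  fe_ox_mean   r_work   r_free  combined
   O2-      -2 1.330957  5.657015 12.381821    1.900670 0.058135 0.070102  2.000000
   OH-      -1 0.005068  2.476536  3.286645    1.979849 0.037428 0.045529  0.000000
   H2O       0 0.024536  3.433150  5.234537    2.078204 0.041720 0.049194  0.315459
best interpretation: OH-
```

Reading the table: each row is one full QR with the bridging species
re-modelled (composition, hydrogens and region net charge change).  The true
interpretation has near-zero strain (kJ mol⁻¹) *and* the lowest average RSZD;
wrong protonation states pay on both axes, and the refined Fe–O_X distances
(`fe_ox_mean`, Å) order O²⁻ < OH⁻ < H₂O as the ligand charge decreases.  The
ranking uses the sum of min-max-normalized strain and average RSZD
(`combined`).

The other subcommands: `qr refine` (one QR run, reports R factors, strain,
RSZD and metal–ligand distances per macrocycle), `qr scan-weight` (one QR per
w_x grid point; selects the strain/RSZD compromise), `qr score` (RSZD table
for a model against data).  Every run writes a `manifest.json` with all
effective parameters, seeds and input checksums.

## Library surface

```python
from qrcryst import (build_toy_site, ToySiteConfig, simulate_reflections,
                     NoiseModel, RefinementState, run_macrocycles,
                     discriminate_ligand)

site = build_toy_site(ToySiteConfig(ligand="OH-"))        # truth = vacuum optimum
refl = simulate_reflections(site.model, 2.0, "electron", NoiseModel(f=0.05, seed=7))
```

Modules: `model_io` (PDB subset, hkl text, Friedel merging, merging stats),
`scattering` (form factors, structure factors, difference maps), `targets`
(E_exp, scale, R factors), `restraints` (dictionary-driven harmonic MM),
`qm_region` (link atoms, formal charges, backend contract, surrogate, strain),
`refine` (composite target, macrocycles, w_x scan, discrimination),
`evaluate` (RSZD, distance tables), `synthetic` (generator), `cli`.

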