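"""Shared fixtures: toy sites, noisy data, and the grid-density FFT oracle.

The structure-factor oracle is independent of the direct-summation code path:
it samples each atom's real-space Gaussian density (Debye-Waller width folded
in) on a fine periodic grid and Fourier-transforms the grid.
"""

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from qrcryst.model_io import Atom, StructureModel, SymmetryOps, UnitCell, assign_free_set

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")
from qrcryst.scattering import scattering_coefficients
from qrcryst.synthetic import NoiseModel, ToySiteConfig, build_toy_site, simulate_reflections


@pytest.fixture(scope="session")
def site_oh():
    """Oxidized toy site with an OH- bridge at the surrogate vacuum optimum."""
    return build_toy_site(ToySiteConfig(ligand="OH-", oxidation_state="oxidized"))


@pytest.fixture(scope="session")
def noisy_xray(site_oh):
    """5% amplitude noise to 2.0 Å, 5% free set (the standard study condition)."""
    refl = simulate_reflections(site_oh.model, 2.0, "xray", NoiseModel(f=0.05, seed=7))
    return assign_free_set(refl, 0.05, seed=3)


@pytest.fixture(scope="session")
def clean_xray(site_oh):
    """Noise-free data from the truth model (f = 0)."""
    refl = simulate_reflections(site_oh.model, 2.0, "xray", NoiseModel(f=0.0, seed=0))
    return assign_free_set(refl, 0.05, seed=3)


def random_p1_model(n_atoms: int, seed: int, spacegroup: str = "P1") -> StructureModel:
    """Seeded toy model with well-separated atoms and B >= 15 (oracle-friendly)."""
    rng = np.random.default_rng(seed)
    if spacegroup == "P1":
        cell = UnitCell(10.0, 11.0, 12.0, 90.0, 90.0, 90.0)
        ops = SymmetryOps.p1()
    else:
        cell = UnitCell(14.0, 15.0, 16.0, 90.0, 90.0, 90.0)
        ops = SymmetryOps.from_spacegroup(spacegroup)
    elements = rng.choice(["C", "N", "O", "S", "Fe", "H"], size=n_atoms)
    frac = rng.uniform(0.1, 0.45, size=(n_atoms, 3))  # keep sym copies apart
    atoms = [
        Atom("A", i + 1, "TOY", f"X{i + 1}", el, cell.orthogonalize(f),
             occ=float(rng.uniform(0.5, 1.0)), b_iso=float(rng.uniform(15.0, 40.0)))
        for i, (el, f) in enumerate(zip(elements, frac))
    ]
    return StructureModel(cell, ops, atoms)


def fft_structure_factor_oracle(model: StructureModel, hkl: np.ndarray, mode: str,
                                spacing: float = 0.18) -> np.ndarray:
    """Grid-density FFT oracle for |F(h)|.

    Each Gaussian term a*exp(-b s^2) (with s = sin(theta)/lambda and b_eff =
    b + B_iso) corresponds to the real-space density
    a * (4 pi / b_eff)^(3/2) * exp(-4 pi^2 r^2 / b_eff); the X-ray constant
    term c is folded in with b = 0 (pure Debye-Waller width).  The density is
    sampled over all symmetry copies with periodic wrapping and transformed.
    """
    cell = model.cell
    shape = tuple(int(np.ceil(L / spacing)) for L in (cell.a, cell.b, cell.c))
    grid = np.zeros(shape)
    fr = [np.arange(n) / n for n in shape]
    g = np.stack(np.meshgrid(*fr, indexing="ij"), axis=-1)  # (n1,n2,n3,3)
    for atom in model.atoms:
        coeff = scattering_coefficients(atom.element, mode)
        terms = list(coeff.gaussians)
        if coeff.c:
            terms.append((coeff.c, 0.0))
        afrac_all = model.ops.expand(cell.fractionalize(atom.pos)[None, :])[:, 0, :]
        for afrac in afrac_all:
            d = g - afrac % 1.0
            d -= np.round(d)
            r2 = np.einsum("...i,...i->...", d @ cell.orth_matrix.T, d @ cell.orth_matrix.T)
            for a, b in terms:
                beff = b + atom.b_iso
                grid += atom.occ * a * (4.0 * np.pi / beff) ** 1.5 * np.exp(
                    -4.0 * np.pi**2 * r2 / beff
                )
    fbox = cell.volume * np.fft.ifftn(grid)
    idx = tuple((np.asarray(hkl) % shape).T)
    return np.abs(fbox[idx])
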