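"""Synthetic dimetal-site crystals and noisy diffraction data in both modes.

The toy site emulates a di-iron cluster like the R2a metal site: two Fe ions
bridged by a solvent species (O2-, OH- or H2O), decorated with carboxylate
fragments (Asp/Glu modelled as acetate), methylimidazole fragments (His) and
terminal waters, all hydrogens explicit, in a P1 (or P2_1 2_1 2_1) cell.

Ground truth is *defined* as the surrogate backend's vacuum optimum for the
configured ligand: fragments are placed on octahedral axes around the metals
and relaxed under the surrogate, so parameter-recovery experiments have an
exactly known answer and zero strain by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._geom import rotation_to
from .fragments import bridge_hydrogens, fragment
from .model_io import Atom, ReflectionSet, StructureModel, SymmetryOps, UnitCell, theoretical_reflections
from .qm_region import (
    QMRegionSpec,
    SurrogateBackendParams,
    build_region_spec,
    build_surrogate_backend,
    optimize_vacuum,
    place_link_atoms,
)
from .restraints import build_restraints
from .scattering import calc_structure_factors

logger = logging.getLogger(__name__)

__all__ = [
    "ToySiteConfig",
    "ToySite",
    "NoiseModel",
    "build_toy_site",
    "simulate_reflections",
    "perturb_model",
]


@dataclass
class ToySiteConfig:
    """Composition and lattice of the synthetic dimetal site."""

    ligand: str = "OH-"
    oxidation_state: str = "oxidized"
    cell: UnitCell = None
    spacegroup: str = "P1"
    terminal_waters: int = None  # default: 2 oxidized, 1 reduced
    n_carboxylates: int = 4
    n_imidazoles: int = 2
    b_iso: float = 20.0
    seed: int = 0
    backend_params: SurrogateBackendParams = field(default_factory=SurrogateBackendParams)

    def __post_init__(self):
        if self.oxidation_state not in ("oxidized", "reduced"):
            raise ValueError("oxidation_state must be 'oxidized' or 'reduced'")
        if self.terminal_waters is None:
            self.terminal_waters = 2 if self.oxidation_state == "oxidized" else 1
        if self.cell is None:
            if self.spacegroup == "P1":
                self.cell = UnitCell(16.0, 17.0, 18.0, 90.0, 90.0, 90.0)
            else:
                self.cell = UnitCell(24.0, 26.0, 28.0, 90.0, 90.0, 90.0)


@dataclass
class ToySite:
    """Ground-truth model bundled with its region spec, backend and restraints."""

    model: StructureModel
    spec: QMRegionSpec
    backend: object
    restraints: object
    config: ToySiteConfig


def _place_fragment(fr, donor_pos, direction, chain, resnum):
    """Instantiate a fragment with its donor at donor_pos, body along direction."""
    rot = rotation_to(direction)
    coords = donor_pos + fr.coords @ rot.T
    return [
        Atom(chain=chain, resnum=resnum, resname=fr.resname, name=nm,
             element=el, pos=xyz)
        for nm, el, xyz in zip(fr.names, fr.elements, coords)
    ]


def build_toy_site(config: ToySiteConfig = None) -> ToySite:
    """Assemble and relax the synthetic site; returns model + spec + backend.

    The returned model's coordinates are the surrogate vacuum optimum, so the
    metal-O(bridge) distances equal the configured ligand equilibria.
    """
    if config is None:
        config = ToySiteConfig()
    params = config.backend_params
    cell = config.cell
    if config.spacegroup == "P1":
        ops = SymmetryOps.p1()
        center = cell.orthogonalize([0.5, 0.5, 0.5])
    else:
        ops = SymmetryOps.from_spacegroup(config.spacegroup)
        center = cell.orthogonalize([0.3, 0.3, 0.3])

    half = params.fe_fe / 2.0
    fe1 = center + np.array([-half, 0.0, 0.0])
    fe2 = center + np.array([half, 0.0, 0.0])
    atoms = [
        Atom("A", 501, "FE", "FE", "Fe", fe1),
        Atom("A", 502, "FE", "FE", "Fe", fe2),
    ]

    # bridging solvent: O above the Fe-Fe midpoint at the ligand equilibrium
    from .qm_region import LIGANDS

    lig = LIGANDS[config.ligand]
    eq = params.fe_x_eq[config.ligand]
    h = np.sqrt(max(eq**2 - half**2, 0.25))
    o_pos = center + np.array([0.0, h, 0.0])
    atoms.append(Atom("A", 503, lig.resname, "O", "O", o_pos))
    for i, hp in enumerate(bridge_hydrogens(o_pos, fe1, fe2, lig.n_hydrogens), start=1):
        atoms.append(Atom("A", 503, lig.resname, f"H{i}", "H", hp))

    # decoration: carboxylates, imidazoles, terminal waters on octahedral axes
    carbox = [
        ("ASP", 84, fe1, np.array([-1.0, 0.0, 0.0])),
        ("GLU", 204, fe2, np.array([1.0, 0.0, 0.0])),
        ("GLU", 115, fe1, np.array([0.0, -1.0, 0.0])),
        ("GLU", 238, fe2, np.array([0.0, -1.0, 0.0])),
    ][: config.n_carboxylates]
    for resname, resnum, fe, d in carbox:
        fr = fragment(resname)
        atoms += _place_fragment(fr, fe + params.fe_carboxylate * d, d, "A", resnum)
    imid = [
        ("HIS", 118, fe1, np.array([0.0, 0.0, 1.0])),
        ("HIS", 241, fe2, np.array([0.0, 0.0, -1.0])),
    ][: config.n_imidazoles]
    for resname, resnum, fe, d in imid:
        fr = fragment(resname)
        atoms += _place_fragment(fr, fe + params.fe_imidazole * d, d, "A", resnum)
    waters = [
        (601, fe1, np.array([0.0, 0.0, -1.0])),
        (602, fe2, np.array([0.0, 0.0, 1.0])),
    ][: config.terminal_waters]
    for resnum, fe, d in waters:
        fr = fragment("HOH")
        atoms += _place_fragment(fr, fe + params.fe_water * d, d, "A", resnum)

    for a in atoms:
        a.b_iso = config.b_iso
        a.in_qm_region = True
    model = StructureModel(cell, ops, atoms)

    spec = build_region_spec(model, config.oxidation_state, ligand_label=config.ligand)
    backend = build_surrogate_backend(model, spec, params)
    restraints = build_restraints(model)

    # relax to the surrogate vacuum optimum: ground truth is self-consistent
    elements, coords, _ = place_link_atoms(model, spec)
    opt = optimize_vacuum(elements, coords, backend, charge=spec.net_charge)
    pos = model.positions
    pos[spec.selection] = opt[: spec.n_region]
    model.set_positions(pos)
    return ToySite(model, spec, backend, restraints, config)


@dataclass
class NoiseModel:
    """Amplitude noise, sigma floor, completeness and missing-wedge settings."""

    f: float = 0.05  # fractional amplitude noise
    sigma_floor: float = 1e-4
    completeness: float = 1.0
    wedge_axis: tuple = None  # reciprocal axis of the cone exclusion
    wedge_half_angle: float = 0.0  # degrees
    seed: int = 0

    def __post_init__(self):
        if self.f < 0:
            raise ValueError("fractional noise must be non-negative")
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness target must lie in (0, 1]")


def simulate_reflections(
    model: StructureModel, d_min: float, mode: str = "xray", noise: NoiseModel = None
) -> ReflectionSet:
    """Noisy Friedel-unique amplitudes to d_min from the model (forward simulation).

    fobs = |Fcalc| (1 + f eps) with standard-normal eps (seeded), truncated at
    zero with a logged count; sigma = max(f |Fcalc|, floor).  A completeness
    mask and (electron mode) an index-space cone exclusion around the wedge
    axis are applied.
    """
    if d_min < 0.8:
        raise ValueError("d_min below 0.8 Å is not supported by the toy generator")
    if noise is None:
        noise = NoiseModel()
    hkl = theoretical_reflections(model.cell, d_min)
    if noise.wedge_axis is not None and noise.wedge_half_angle > 0 and mode == "electron":
        axis = np.asarray(noise.wedge_axis, dtype=float)
        svec = hkl @ model.cell.frac_matrix  # reciprocal-space vectors
        cosang = np.abs(svec @ axis) / (
            np.linalg.norm(svec, axis=1) * np.linalg.norm(axis)
        )
        keep = cosang < np.cos(np.radians(noise.wedge_half_angle))
        hkl = hkl[keep]
    rng = np.random.default_rng(noise.seed)
    if noise.completeness < 1.0:
        n_keep = int(round(noise.completeness * len(hkl)))
        idx = np.sort(rng.choice(len(hkl), size=n_keep, replace=False))
        hkl = hkl[idx]
    amps = np.abs(calc_structure_factors(model, hkl, mode).f)
    eps = rng.standard_normal(len(amps))
    fobs = amps * (1.0 + noise.f * eps)
    n_neg = int(np.sum(fobs < 0))
    if n_neg:
        logger.warning("truncated %d negative simulated amplitudes at zero", n_neg)
        fobs = np.maximum(fobs, 0.0)
    sigma = np.maximum(noise.f * amps, noise.sigma_floor)
    return ReflectionSet(
        hkl=hkl, fobs=fobs, sigma=sigma,
        free=np.zeros(len(hkl), bool), cell=model.cell, merged=True,
    )


def perturb_model(model: StructureModel, target_rmsd: float, selection, seed: int) -> StructureModel:
    """Seeded Gaussian displacement of selected atoms, scaled to the target RMSD."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    if target_rmsd < 0:
        raise ValueError("target RMSD must be non-negative")
    out = model.copy()
    if target_rmsd == 0:
        return out
    rng = np.random.default_rng(seed)
    disp = rng.standard_normal((len(selection), 3))
    disp *= target_rmsd / np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    pos = out.positions
    pos[selection] += disp
    out.set_positions(pos)
    return out
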