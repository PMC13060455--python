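"""Empirical (MM) restraints: harmonic bonds and angles plus soft nonbonded repulsion.

The restraint dictionary is editable structured text (YAML, see
``data/restraints.yaml``): per-residue topology with ideal values and force
constants.  Bonds are detected by dictionary connectivity, never by distance.
Metal-ligand interactions carry no bonded restraints - only the nonbonded
repulsion applies to pairs involving a metal, with a reduced minimum distance
so that coordination bonds are not penalized.

The same functional form serves E_MM (whole model) and E_MM1 (QM region): a
restraint contributes to a selection iff all of its atoms are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from . import _geom
from .fragments import FRAGMENTS
from .model_io import StructureModel
from .targets import TargetValue

__all__ = [
    "RestraintSet",
    "default_dictionary",
    "load_dictionary",
    "build_dictionary_from_fragments",
    "build_restraints",
    "mm_energy",
]

METALS = {"Fe", "Mn", "Cu", "Zn", "Ni", "Co", "Mg", "Ca"}

# force constants (restraint units A^-2 / rad^-2): stiffer for X-H stretches
BOND_K_H = 3500.0
BOND_K = 2500.0
ANGLE_K = 300.0
NB_RMIN = 2.2
NB_RMIN_METAL = 1.7
NB_K = 100.0


def build_dictionary_from_fragments() -> dict:
    """Default dictionary derived from the fragment templates (single source)."""
    residues = {}
    for resname, fr in FRAGMENTS.items():
        bonds = []
        for ni, nj in fr.bonds:
            k = BOND_K_H if "H" in (fr.elements[fr.index(ni)], fr.elements[fr.index(nj)]) else BOND_K
            bonds.append([ni, nj, round(fr.bond_length(ni, nj), 6), k])
        angles = [
            [ni, nj, nk, round(fr.angle_deg(ni, nj, nk), 6), ANGLE_K]
            for ni, nj, nk in fr.angles
        ]
        residues[resname] = {
            "charge": fr.charge,
            "atoms": list(fr.names),
            "bonds": bonds,
            "angles": angles,
        }
    return {
        "nonbonded": {"rmin": NB_RMIN, "rmin_metal": NB_RMIN_METAL, "k": NB_K},
        "residues": residues,
    }


_DEFAULT = None


def default_dictionary() -> dict:
    """The shipped dictionary (data/restraints.yaml)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("qrcryst").joinpath("data/restraints.yaml").read_text()
        _DEFAULT = yaml.safe_load(text)
    return _DEFAULT


def load_dictionary(path) -> dict:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "residues" not in d:
        raise ValueError(f"{path}: restraint dictionary must define 'residues'")
    return d


@dataclass
class RestraintSet:
    """Indexed harmonic restraints over a model's atom list."""

    bond_idx: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_idx: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))
    angle_theta0: np.ndarray = field(default_factory=lambda: np.zeros(0))  # radians
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    nb_idx: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    nb_rmin: np.ndarray = field(default_factory=lambda: np.zeros(0))
    nb_k: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_bonds(self) -> int:
        return len(self.bond_r0)

    @property
    def n_angles(self) -> int:
        return len(self.angle_theta0)


def build_restraints(model: StructureModel, dictionary: dict = None) -> RestraintSet:
    """Assemble the restraint set for a model from a dictionary.

    Every residue name in the model must have a dictionary entry; the entry's
    atoms must all be present in the residue (extra model atoms are an error,
    keeping topology and model in sync).
    """
    if dictionary is None:
        dictionary = default_dictionary()
    residues = dictionary["residues"]
    nb_conf = dictionary.get("nonbonded", {})
    rmin = float(nb_conf.get("rmin", NB_RMIN))
    rmin_metal = float(nb_conf.get("rmin_metal", NB_RMIN_METAL))
    nb_k = float(nb_conf.get("k", NB_K))

    b_idx, b_r0, b_k = [], [], []
    a_idx, a_t0, a_k = [], [], []
    seen = [False] * len(model)
    for (chain, resnum, resname), idxs in model.residues():
        entry = residues.get(resname)
        if entry is None:
            raise KeyError(f"residue {resname!r} ({chain} {resnum}) missing from restraint dictionary")
        byname = {model.atoms[i].name: i for i in idxs}
        missing = set(entry["atoms"]) - set(byname)
        extra = set(byname) - set(entry["atoms"])
        if missing or extra:
            raise KeyError(
                f"residue {resname} {chain} {resnum}: atoms do not match dictionary "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        for ni, nj, r0, k in entry.get("bonds", []):
            b_idx.append((byname[ni], byname[nj]))
            b_r0.append(float(r0))
            b_k.append(float(k))
        for ni, nj, nk, t0, k in entry.get("angles", []):
            a_idx.append((byname[ni], byname[nj], byname[nk]))
            a_t0.append(np.radians(float(t0)))
            a_k.append(float(k))
        for i in idxs:
            seen[i] = True

    # duplicate-bond guard
    pairs = {frozenset(p) for p in b_idx}
    if len(pairs) != len(b_idx):
        raise ValueError("duplicate bond restraint")

    # nonbonded repulsion: all inter-residue pairs (intra-residue geometry is
    # fully determined by bonds/angles); reduced rmin when a metal is involved
    res_of = np.zeros(len(model), dtype=int)
    for r, (_, idxs) in enumerate(model.residues()):
        for i in idxs:
            res_of[i] = r
    nb_idx, nb_rmin_list = [], []
    elements = model.elements
    for i in range(len(model)):
        for j in range(i + 1, len(model)):
            if res_of[i] == res_of[j]:
                continue
            nb_idx.append((i, j))
            metal = elements[i] in METALS or elements[j] in METALS
            nb_rmin_list.append(rmin_metal if metal else rmin)

    return RestraintSet(
        bond_idx=np.asarray(b_idx, int).reshape(-1, 2),
        bond_r0=np.asarray(b_r0),
        bond_k=np.asarray(b_k),
        angle_idx=np.asarray(a_idx, int).reshape(-1, 3),
        angle_theta0=np.asarray(a_t0),
        angle_k=np.asarray(a_k),
        nb_idx=np.asarray(nb_idx, int).reshape(-1, 2),
        nb_rmin=np.asarray(nb_rmin_list),
        nb_k=np.full(len(nb_idx), nb_k),
    )


def _term_mask(idx: np.ndarray, selected: np.ndarray) -> np.ndarray:
    if idx.size == 0:
        return np.zeros(0, dtype=bool)
    return np.all(selected[idx], axis=1)


def mm_energy(model: StructureModel, restraints: RestraintSet, selection=None) -> TargetValue:
    """Harmonic restraint energy and gradient over (a selection of) the model.

    ``selection`` is a boolean mask or index array; a restraint contributes iff
    all its atoms are selected.  Gradient is returned over all atoms (zero
    outside contributing terms).
    """
    coords = model.positions
    n = len(model)
    if selection is None:
        selected = np.ones(n, dtype=bool)
    else:
        selected = np.zeros(n, dtype=bool)
        selected[np.asarray(selection)] = True

    value = 0.0
    grad = np.zeros((n, 3))
    m = _term_mask(restraints.bond_idx, selected)
    if m.any():
        e, g = _geom.bond_energy(coords, restraints.bond_idx[m], restraints.bond_r0[m], restraints.bond_k[m])
        value += e
        grad += g
    m = _term_mask(restraints.angle_idx, selected)
    if m.any():
        e, g = _geom.angle_energy(coords, restraints.angle_idx[m], restraints.angle_theta0[m], restraints.angle_k[m])
        value += e
        grad += g
    m = _term_mask(restraints.nb_idx, selected)
    if m.any():
        e, g = _geom.softsphere_energy(coords, restraints.nb_idx[m], restraints.nb_rmin[m], restraints.nb_k[m])
        value += e
        grad += g
    return TargetValue(value, grad_xyz=grad)
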