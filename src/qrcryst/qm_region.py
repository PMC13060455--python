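"""QM-region definition, link atoms, formal charges, energy backends, strain energy.

The energy backend contract is a deterministic callable

    backend.energy_gradient(elements, coords, charge=..., spin=...)
        -> (energy in kJ mol^-1, gradient in kJ mol^-1 Å^-1)

Real quantum chemistry is out of scope; the shipped surrogate backend is a
harmonic force field over the site topology (fragment-internal bonds/angles,
metal-donor stretches with protonation-state-dependent Fe-O equilibria, and a
short-range charge-scaled repulsion).  It preserves every quantum-refinement
mechanism - link atoms, gradients, strain energies, vacuum optimization -
while staying desk-scale, and any engine honouring the contract can be plugged
in instead.

Spin multiplicity is carried as metadata only: the surrogate ignores it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _geom
from .fragments import RESIDUE_CHARGES
from .model_io import StructureModel
from .restraints import METALS, default_dictionary
from .targets import TargetValue

__all__ = [
    "KCAL",
    "LigandModel",
    "LIGANDS",
    "LIGAND_BY_RESNAME",
    "formal_charge",
    "composition_labels",
    "LinkAtom",
    "QMRegionSpec",
    "build_region_spec",
    "place_link_atoms",
    "qm_energy",
    "optimize_vacuum",
    "strain_energy",
    "SurrogateBackendParams",
    "SurrogateBackend",
    "build_surrogate_backend",
]

KCAL = 4.184  # kJ per kcal


# ---------------------------------------------------------------------------
# ligand models and formal charges


@dataclass(frozen=True)
class LigandModel:
    """Candidate interpretation of the bridging solvent species."""

    label: str  # 'O2-' | 'OH-' | 'H2O'
    charge: int
    n_hydrogens: int
    resname: str

    def __post_init__(self):
        expected = {"O2-": (-2, 0), "OH-": (-1, 1), "H2O": (0, 2)}[self.label]
        if (self.charge, self.n_hydrogens) != expected:
            raise ValueError(f"inconsistent ligand model for {self.label}")


LIGANDS = {
    "O2-": LigandModel("O2-", -2, 0, "OXO"),
    "OH-": LigandModel("OH-", -1, 1, "HYD"),
    "H2O": LigandModel("H2O", 0, 2, "HOH"),
}
LIGAND_BY_RESNAME = {lm.resname: lm for lm in LIGANDS.values()}

FORMAL_CHARGES = {
    "FE3+": 3,
    "FE2+": 2,
    "O2-": -2,
    "OH-": -1,
    "H2O": 0,
    **RESIDUE_CHARGES,  # ASP/GLU -1, HIS 0, HOH 0, HYD -1, OXO -2, FE 0 (placeholder)
}
del FORMAL_CHARGES["FE"]  # iron charge depends on oxidation state; use FE3+/FE2+


def formal_charge(composition) -> int:
    """Net formal charge of a composition given as constituent labels.

    Labels are residue/species names: 'FE3+', 'FE2+', 'ASP', 'GLU', 'HIS',
    'HOH', and the bridging-ligand species 'O2-'/'OH-'/'H2O' (or their residue
    names 'OXO'/'HYD').
    """
    total = 0
    for label in composition:
        if label not in FORMAL_CHARGES:
            raise KeyError(f"no formal charge defined for constituent {label!r}")
        total += FORMAL_CHARGES[label]
    return total


def composition_labels(model: StructureModel, oxidation_state: str, residues=None) -> list:
    """Constituent labels of (a subset of) a model for formal-charge bookkeeping."""
    fe_label = {"oxidized": "FE3+", "reduced": "FE2+"}[oxidation_state]
    labels = []
    for key, _ in model.residues():
        if residues is not None and key not in residues:
            continue
        labels.append(fe_label if key[2] == "FE" else key[2])
    return labels


# ---------------------------------------------------------------------------
# region spec and link atoms


@dataclass(frozen=True)
class LinkAtom:
    """Hydrogen cap on a cut covalent bond (host inside region, neighbor outside)."""

    host: int
    neighbor: int
    distance: float = 1.09


@dataclass
class QMRegionSpec:
    """Atom selection, link atoms and charge/spin metadata of the QM subsystem."""

    selection: np.ndarray
    net_charge: int = 0
    spin_multiplicity: int = 1
    link_atoms: list = field(default_factory=list)
    ligand: LigandModel = None
    bridge_residue: tuple = None  # (chain, resnum) of the bridging solvent
    distance_restraints: list = field(default_factory=list)  # (i, j, target Å, k)

    def __post_init__(self):
        self.selection = np.asarray(sorted(set(np.asarray(self.selection, int).tolist())), dtype=int)
        sel = set(self.selection.tolist())
        for la in self.link_atoms:
            if la.host not in sel:
                raise ValueError(f"link-atom host {la.host} outside the QM selection")
            if la.neighbor in sel:
                raise ValueError(f"link-atom cut neighbor {la.neighbor} inside the QM selection")

    @property
    def n_region(self) -> int:
        return len(self.selection)


def place_link_atoms(model: StructureModel, spec: QMRegionSpec):
    """Region coordinates augmented with link hydrogens, plus the gradient mapping.

    Returns ``(elements, coords, distribute)`` where coords has shape
    (n_region + n_links, 3) (links last) and ``distribute(g_region)`` maps a
    region-plus-links gradient back onto the full model's atoms by the chain
    rule of the link-placement function.
    """
    pos = model.positions
    elements = [model.atoms[i].element for i in spec.selection]
    coords = [pos[spec.selection]]
    jacobians = []
    for la in spec.link_atoms:
        h, nb = pos[la.host], pos[la.neighbor]
        u = nb - h
        r = np.linalg.norm(u)
        if r < 1e-6:
            raise ValueError(f"coincident host/neighbor atoms {la.host}/{la.neighbor}")
        uhat = u / r
        coords.append((h + la.distance * uhat)[None, :])
        elements.append("H")
        proj = (np.eye(3) - np.outer(uhat, uhat)) / r
        dL_dn = la.distance * proj
        dL_dh = np.eye(3) - dL_dn
        jacobians.append((la.host, la.neighbor, dL_dh, dL_dn))
    coords = np.vstack(coords)

    def distribute(g_region: np.ndarray) -> np.ndarray:
        g_full = np.zeros_like(pos)
        g_full[spec.selection] += g_region[: spec.n_region]
        for j, (host, neighbor, dL_dh, dL_dn) in enumerate(jacobians):
            gl = g_region[spec.n_region + j]
            g_full[host] += dL_dh.T @ gl
            g_full[neighbor] += dL_dn.T @ gl
        return g_full

    return elements, coords, distribute


def qm_energy(model: StructureModel, spec: QMRegionSpec, backend) -> TargetValue:
    """E_QM1 (kJ mol^-1) and its gradient mapped onto the real atoms.

    Optional intra-region distance restraints (e.g. to keep water protons on
    their oxygen) are added as harmonic terms.
    """
    elements, coords, distribute = place_link_atoms(model, spec)
    try:
        e, g = backend.energy_gradient(
            elements, coords, charge=spec.net_charge, spin=spec.spin_multiplicity
        )
    except Exception as exc:  # propagate with context
        raise RuntimeError(f"QM backend failed on {len(coords)}-atom region: {exc}") from exc
    g_full = distribute(np.asarray(g, dtype=float))
    if spec.distance_restraints:
        pairs = np.array([(i, j) for i, j, *_ in spec.distance_restraints], int)
        r0 = np.array([t for *_ij, t, _k in spec.distance_restraints])
        kk = np.array([k for *_ijt, k in spec.distance_restraints])
        e_r, g_r = _geom.bond_energy(model.positions, pairs, r0, kk)
        e += e_r
        g_full += g_r
    return TargetValue(float(e), grad_xyz=g_full)


def optimize_vacuum(
    elements,
    coords: np.ndarray,
    backend,
    fixed=None,
    charge: int = 0,
    spin: int = 1,
    gtol: float = 1e-4,
    max_iter: int = 5000,
) -> np.ndarray:
    """Minimize the backend energy with selected atoms held fixed.

    ``fixed`` is a boolean mask (typically the link hydrogens).  Raises on
    non-convergence (free-atom gradient norm above ``gtol`` kJ mol^-1 Å^-1).
    """
    coords = np.array(coords, dtype=float)
    n = len(coords)
    if fixed is None:
        fixed = np.zeros(n, dtype=bool)
    fixed = np.asarray(fixed, dtype=bool)
    free = ~fixed
    work = coords.copy()

    def fun(x):
        work[free] = x.reshape(-1, 3)
        e, g = backend.energy_gradient(elements, work, charge=charge, spin=spin)
        return e, np.asarray(g)[free].ravel()

    x = work[free].ravel()
    gnorm = np.inf
    for _ in range(5):  # L-BFGS restarts: refresh curvature when it stalls
        res = minimize(
            fun, x, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-16, "gtol": 1e-9, "maxcor": 30},
        )
        x = res.x
        work[free] = x.reshape(-1, 3)
        _, g = backend.energy_gradient(elements, work, charge=charge, spin=spin)
        gnorm = float(np.linalg.norm(np.asarray(g)[free]))
        if gnorm <= 0.1 * gtol:
            break
    if gnorm > gtol:
        raise RuntimeError(
            f"vacuum optimization did not converge: |grad| = {gnorm:.3e} kJ mol^-1 Å^-1"
        )
    return work


def strain_energy(model: StructureModel, spec: QMRegionSpec, backend) -> float:
    """QM energy of the refined region minus that of its vacuum-relaxed copy.

    Link hydrogens stay fixed at their refined positions, keeping the relaxed
    structure in the same local minimum as in the protein.
    """
    elements, coords, _ = place_link_atoms(model, spec)
    e_qr, _ = backend.energy_gradient(
        elements, coords, charge=spec.net_charge, spin=spec.spin_multiplicity
    )
    fixed = np.zeros(len(coords), dtype=bool)
    fixed[spec.n_region :] = True
    opt = optimize_vacuum(
        elements, coords, backend, fixed=fixed,
        charge=spec.net_charge, spin=spec.spin_multiplicity,
    )
    e_min, _ = backend.energy_gradient(
        elements, opt, charge=spec.net_charge, spin=spec.spin_multiplicity
    )
    return float(e_qr - e_min)


# ---------------------------------------------------------------------------
# surrogate backend


@dataclass
class SurrogateBackendParams:
    """Force-field parameters of the surrogate backend (kJ mol^-1, Å).

    Metal-O(bridge) equilibria follow the protonation-state trend seen for
    di-iron sites: more negative bridging species bind shorter.
    """

    fe_x_eq: dict = field(
        default_factory=lambda: {"O2-": 1.88, "OH-": 1.98, "H2O": 2.08}
    )
    fe_carboxylate: float = 2.00
    fe_imidazole: float = 2.15
    fe_water: float = 2.20
    fe_fe: float = 3.35
    k_metal: float = 1200.0
    k_fe_fe: float = 400.0
    coordination_cutoff: float = 2.6
    rep_rmin: float = 2.2
    rep_rmin_h: float = 1.8
    rep_k: float = 200.0

    def __post_init__(self):
        eq = [self.fe_x_eq[k] for k in ("O2-", "OH-", "H2O")]
        if not (eq[0] < eq[1] < eq[2]):
            raise ValueError("metal-O equilibria must increase across O2- < OH- < H2O")
        if min(eq) <= 0 or min(self.fe_carboxylate, self.fe_imidazole, self.fe_water) <= 0:
            raise ValueError("equilibrium distances must be positive")


class SurrogateBackend:
    """Deterministic harmonic stand-in for a quantum-chemistry engine.

    Holds a fixed topology (built once per region composition); the
    ``energy_gradient`` call evaluates bonds, angles and short-range repulsion
    at the supplied coordinates.  Rigid translations and rotations leave the
    energy unchanged (all terms are internal coordinates).
    """

    deterministic = True

    def __init__(self, n_atoms, bond_idx, bond_r0, bond_k,
                 angle_idx, angle_t0, angle_k, rep_idx, rep_rmin, rep_k):
        self.n_atoms = n_atoms
        self.bond_idx = np.asarray(bond_idx, int).reshape(-1, 2)
        self.bond_r0 = np.asarray(bond_r0, float)
        self.bond_k = np.asarray(bond_k, float)
        self.angle_idx = np.asarray(angle_idx, int).reshape(-1, 3)
        self.angle_t0 = np.asarray(angle_t0, float)
        self.angle_k = np.asarray(angle_k, float)
        self.rep_idx = np.asarray(rep_idx, int).reshape(-1, 2)
        self.rep_rmin = np.asarray(rep_rmin, float)
        self.rep_k = np.asarray(rep_k, float)

    def energy_gradient(self, elements, coords, charge=0, spin=1):
        coords = np.asarray(coords, dtype=float)
        if len(coords) != self.n_atoms:
            raise ValueError(
                f"surrogate backend built for {self.n_atoms} atoms, got {len(coords)}"
            )
        e1, g1 = _geom.bond_energy(coords, self.bond_idx, self.bond_r0, self.bond_k)
        e2, g2 = _geom.angle_energy(coords, self.angle_idx, self.angle_t0, self.angle_k)
        e3, g3 = _geom.softsphere_energy(coords, self.rep_idx, self.rep_rmin, self.rep_k)
        return e1 + e2 + e3, g1 + g2 + g3


def build_surrogate_backend(
    model: StructureModel,
    spec: QMRegionSpec,
    params: SurrogateBackendParams = None,
    dictionary: dict = None,
) -> SurrogateBackend:
    """Topology-aware surrogate for the current region composition.

    Fragment-internal terms come from the restraint dictionary; metal-donor
    stretches are detected by coordination distance at build time, with the
    Fe-O(bridge) equilibrium set by the candidate ligand model.  The repulsion
    term is scaled up for like-charged pairs (a short-range point-charge
    stand-in) and excludes bonded and 1-3 pairs.
    """
    if params is None:
        params = SurrogateBackendParams()
    if dictionary is None:
        dictionary = default_dictionary()
    residues = dictionary["residues"]

    sel = list(spec.selection)
    local = {ai: i for i, ai in enumerate(sel)}
    n_links = len(spec.link_atoms)
    n_aug = len(sel) + n_links
    pos = model.positions

    b_idx, b_r0, b_k = [], [], []
    a_idx, a_t0, a_k = [], [], []
    # fragment-internal topology, restricted to selected atoms
    for key, idxs in model.residues():
        inside = [i for i in idxs if i in local]
        if not inside:
            continue
        entry = residues.get(key[2])
        if entry is None:
            raise KeyError(f"residue {key[2]!r} missing from restraint dictionary")
        byname = {model.atoms[i].name: i for i in idxs}
        for ni, nj, r0, k in entry.get("bonds", []):
            i, j = byname[ni], byname[nj]
            if i in local and j in local:
                b_idx.append((local[i], local[j]))
                b_r0.append(float(r0))
                b_k.append(float(k))
        for ni, nj, nk, t0, k in entry.get("angles", []):
            i, j, kk = byname[ni], byname[nj], byname[nk]
            if i in local and j in local and kk in local:
                a_idx.append((local[i], local[j], local[kk]))
                a_t0.append(np.radians(float(t0)))
                a_k.append(float(k))

    # link hydrogens: capped C-H (or X-H) stretch to the host
    for j, la in enumerate(spec.link_atoms):
        b_idx.append((local[la.host], len(sel) + j))
        b_r0.append(la.distance)
        b_k.append(3500.0)

    # metal coordination stretches (detected by distance at build time)
    elements = [model.atoms[i].element for i in sel] + ["H"] * n_links
    metals_loc = [i for i, e in enumerate(elements) if e in METALS]
    bridge_atoms = set()
    if spec.bridge_residue is not None:
        for i in sel:
            a = model.atoms[i]
            if (a.chain, a.resnum) == spec.bridge_residue:
                bridge_atoms.add(local[i])
    for mi_pos, m in enumerate(metals_loc):
        for m2 in metals_loc[mi_pos + 1 :]:
            b_idx.append((m, m2))
            b_r0.append(params.fe_fe)
            b_k.append(params.k_fe_fe)
        for i in sel:
            li = local[i]
            a = model.atoms[i]
            if a.element not in ("O", "N"):
                continue
            d = np.linalg.norm(pos[i] - pos[sel[m]])
            if d > params.coordination_cutoff:
                continue
            if li in bridge_atoms:
                if spec.ligand is None:
                    raise ValueError("bridging donor found but spec.ligand is unset")
                r0 = params.fe_x_eq[spec.ligand.label]
            elif a.resname == "HOH":
                r0 = params.fe_water
            elif a.element == "N":
                r0 = params.fe_imidazole
            else:
                r0 = params.fe_carboxylate
            b_idx.append((m, li))
            b_r0.append(r0)
            b_k.append(params.k_metal)

    # repulsion: all pairs minus bonded and 1-3, rmin reduced when H involved,
    # constant scaled by (1 + max(q_i q_j, 0)) with heavy-handed unit charges
    excluded = {frozenset(p) for p in b_idx}
    for i, _, k in a_idx:
        excluded.add(frozenset((i, k)))
    charges = np.zeros(n_aug)
    for i in sel:
        a = model.atoms[i]
        if a.element in METALS:
            charges[local[i]] = 2.0
        elif a.element == "O":
            charges[local[i]] = -0.5
    r_idx, r_rmin, r_k = [], [], []
    for i in range(n_aug):
        for j in range(i + 1, n_aug):
            if frozenset((i, j)) in excluded:
                continue
            h_pair = elements[i] == "H" or elements[j] == "H"
            r_idx.append((i, j))
            r_rmin.append(params.rep_rmin_h if h_pair else params.rep_rmin)
            r_k.append(params.rep_k * (1.0 + max(charges[i] * charges[j], 0.0)))

    return SurrogateBackend(
        n_aug, b_idx, b_r0, b_k, a_idx, a_t0, a_k, r_idx, r_rmin, r_k
    )


# ---------------------------------------------------------------------------
# region-spec construction


def find_bridge_residue(model: StructureModel, cutoff: float = 2.9):
    """(chain, resnum) of the solvent species bridging two metals, or None."""
    pos = model.positions
    metal_idx = [i for i, a in enumerate(model.atoms) if a.element in METALS]
    for key, idxs in model.residues():
        if key[2] not in LIGAND_BY_RESNAME:
            continue
        o_idx = [i for i in idxs if model.atoms[i].element == "O"]
        if not o_idx:
            continue
        n_close = sum(
            1 for m in metal_idx if np.linalg.norm(pos[o_idx[0]] - pos[m]) <= cutoff
        )
        if n_close >= 2:
            return (key[0], key[1])
    return None


def build_region_spec(
    model: StructureModel,
    oxidation_state: str,
    ligand_label: str = None,
    selection=None,
    link_atoms=(),
    distance_restraints=(),
) -> QMRegionSpec:
    """Region spec with formal-charge bookkeeping for a (toy) dimetal site.

    By default the whole model is the QM region.  The bridging solvent residue
    is located geometrically; its ligand model fixes the Fe-O(bridge)
    equilibrium of the surrogate and contributes its formal charge.
    """
    if selection is None:
        selection = np.arange(len(model))
    selection = np.asarray(selection, int)
    bridge = find_bridge_residue(model)
    ligand = None
    if bridge is not None:
        resname = next(
            a.resname for a in model.atoms if (a.chain, a.resnum) == bridge
        )
        ligand = LIGAND_BY_RESNAME[resname]
        if ligand_label is not None and ligand_label != ligand.label:
            raise ValueError(
                f"requested ligand {ligand_label!r} but model contains {ligand.label!r}"
            )
    elif ligand_label is not None:
        ligand = LIGANDS[ligand_label]

    sel_keys = {model.atoms[i].residue_key for i in selection}
    labels = composition_labels(model, oxidation_state, residues=sel_keys)
    net = formal_charge(labels)
    for a in model.atoms:
        a.in_qm_region = False
    for i in selection:
        model.atoms[i].in_qm_region = True
    return QMRegionSpec(
        selection=selection,
        net_charge=net,
        spin_multiplicity=1,  # broken-symmetry open-shell singlet; metadata only
        link_atoms=list(link_atoms),
        ligand=ligand,
        bridge_residue=bridge,
        distance_restraints=list(distance_restraints),
    )
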