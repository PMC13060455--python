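"""Quantum-refinement driver: composite target, macrocycles, weight scan, discrimination.

The composite target is

    E = w_x * E_exp + E_MM - E_MM1 + w_QM * E_QM1

with E_QM1 converted from the backend's kJ mol^-1 to kcal mol^-1 before
applying w_QM (default 7.5 (kcal mol^-1)^-1).  Subtracting E_MM1 (the
empirical-restraint energy of the QM region; a restraint counts iff all its
atoms are in the region) avoids double counting.  With an empty QM region the
target reduces exactly to plain restrained refinement, w_x * E_exp + E_MM.

A macrocycle is scale fit -> coordinate refinement (QM region plus cut-bond
stubs movable) -> isotropic ADP refinement (whole model).  Minimization is
quasi-Newton (L-BFGS-B) on analytic gradients, so runs are deterministic for
fixed inputs.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .evaluate import average_rszd, metal_distance_table, rszd_per_residue
from .model_io import ReflectionSet, StructureModel
from .qm_region import (
    KCAL,
    LIGANDS,
    QMRegionSpec,
    SurrogateBackendParams,
    build_region_spec,
    build_surrogate_backend,
    qm_energy,
    strain_energy,
)
from .restraints import RestraintSet, build_restraints, mm_energy
from .scattering import calc_structure_factors
from .targets import TargetValue, exp_target, fit_scale, r_factors

logger = logging.getLogger(__name__)

__all__ = [
    "RefinementState",
    "RefinementReport",
    "qr_target",
    "refine_coordinates",
    "refine_adps",
    "run_macrocycles",
    "scan_wx",
    "discriminate_ligand",
    "swap_bridging_ligand",
    "movable_indices",
]

B_FLOOR = 0.5  # Å^2 positivity floor for isotropic ADPs
B_SIMILARITY_WEIGHT = 0.05  # weak bonded-B similarity restraint


@dataclass
class RefinementState:
    """Everything a QR run needs; mutated in place by the refinement legs."""

    model: StructureModel
    reflections: ReflectionSet
    spec: QMRegionSpec
    restraints: RestraintSet
    backend: object
    w_x: float = 1.0
    w_qm: float = 7.5  # (kcal mol^-1)^-1
    mode: str = "xray"
    k: float = None
    w_auto: float = None  # gradient-ratio normalization of E_exp (computed once)
    seed: int = 0

    def __post_init__(self):
        if self.w_x < 0 or self.w_qm < 0:
            raise ValueError("weights must be non-negative")
        if not self.reflections.merged:
            raise ValueError("refinement expects a Friedel-merged reflection set")

    def clone(self) -> "RefinementState":
        return RefinementState(
            model=self.model.copy(),
            reflections=self.reflections,
            spec=copy.deepcopy(self.spec),
            restraints=self.restraints,
            backend=self.backend,
            w_x=self.w_x,
            w_qm=self.w_qm,
            mode=self.mode,
            k=self.k,
            w_auto=self.w_auto,
            seed=self.seed,
        )


@dataclass
class RefinementReport:
    """Per-macrocycle statistics plus the final evaluation (mirrors a results table)."""

    cycles: pd.DataFrame = None
    strain: float = None
    rszd: pd.DataFrame = None
    avg_rszd: float = None
    max_rszd: float = None
    distances: pd.DataFrame = None
    r_work: float = None
    r_free: float = None
    extras: dict = field(default_factory=dict)


def movable_indices(spec: QMRegionSpec) -> np.ndarray:
    """QM selection plus the cut-bond neighbors (the residue stubs that may move)."""
    idx = set(spec.selection.tolist())
    idx.update(la.neighbor for la in spec.link_atoms)
    return np.asarray(sorted(idx), dtype=int)


def _ensure_scale(state: RefinementState) -> float:
    if state.k is None:
        sf = calc_structure_factors(state.model, state.reflections.hkl, state.mode)
        state.k = fit_scale(state.reflections, sf.f)
    if state.w_auto is None:
        state.w_auto = _auto_weight_scale(state) if state.spec.n_region else 1.0
    return state.k


WEIGHT_SHAKE = 0.05  # Å rms displacement used for gradient-ratio weighting


def _auto_weight_scale(state: RefinementState) -> float:
    """Gradient-ratio normalization of the experimental term.

    The toy crystals are far more over-determined than real macromolecular data
    at the same resolution, so the raw least-squares E_exp would swamp the
    restraint side at w_x ~ 1.  Like the weight determination of standard
    refinement packages, the experimental gradient is normalized against the
    restraint (QM + MM) gradient, both evaluated on a small deterministic shake
    of the movable atoms; the user-facing w_x multiplies this normalized weight.
    """
    mov = movable_indices(state.spec)
    if len(mov) == 0:
        return 1.0
    shaken = state.model.copy()
    rng = np.random.default_rng(state.seed + 7_777_777)
    disp = rng.standard_normal((len(mov), 3))
    disp *= WEIGHT_SHAKE / np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    pos = shaken.positions
    pos[mov] += disp
    shaken.set_positions(pos)

    sf = calc_structure_factors(shaken, state.reflections.hkl, state.mode, deriv_atoms=mov)
    g_exp = exp_target(state.reflections, sf, state.k).grad_xyz
    t_mm = mm_energy(shaken, state.restraints)
    t_mm1 = mm_energy(shaken, state.restraints, selection=state.spec.selection)
    t_qm = qm_energy(shaken, state.spec, state.backend)
    g_restr = (
        t_mm.grad_xyz - t_mm1.grad_xyz + (state.w_qm / KCAL) * t_qm.grad_xyz
    )[mov]
    n_exp = float(np.linalg.norm(g_exp))
    n_restr = float(np.linalg.norm(g_restr))
    if n_exp <= 0 or n_restr <= 0:
        return 1.0
    return n_restr / n_exp


def qr_target(state: RefinementState, deriv: str = None) -> TargetValue:
    """Composite QR target at the current model, optionally with gradients.

    deriv='xyz' returns the Cartesian gradient over movable atoms;
    deriv='b' the ADP gradient over all atoms.
    """
    k = _ensure_scale(state)
    mov = movable_indices(state.spec)
    sf = calc_structure_factors(
        state.model,
        state.reflections.hkl,
        state.mode,
        deriv_atoms=mov if deriv == "xyz" else None,
        deriv_b=(deriv == "b"),
    )
    t_exp = exp_target(state.reflections, sf, k)
    empty_region = state.spec.n_region == 0
    w_eff = state.w_x * (state.w_auto if not empty_region else 1.0)
    t_mm = mm_energy(state.model, state.restraints)
    if empty_region:
        value = state.w_x * t_exp.value + t_mm.value
    else:
        t_mm1 = mm_energy(state.model, state.restraints, selection=state.spec.selection)
        t_qm = qm_energy(state.model, state.spec, state.backend)
        value = (
            w_eff * t_exp.value
            + t_mm.value
            - t_mm1.value
            + state.w_qm * (t_qm.value / KCAL)
        )
    grad_xyz = grad_b = None
    if deriv == "xyz":
        g = t_mm.grad_xyz.copy()
        if not empty_region:
            g -= t_mm1.grad_xyz
            g += (state.w_qm / KCAL) * t_qm.grad_xyz
        g = g[mov]
        g += w_eff * t_exp.grad_xyz
        grad_xyz = g
    if deriv == "b":
        grad_b = w_eff * t_exp.grad_b
    return TargetValue(float(value), grad_xyz=grad_xyz, grad_b=grad_b, k=k)


def refine_coordinates(state: RefinementState, max_iter: int = 200) -> RefinementState:
    """Quasi-Newton coordinate refinement of the movable atoms (scale held fixed)."""
    if max_iter <= 0:
        return state
    mov = movable_indices(state.spec)
    if len(mov) == 0:
        return state
    _ensure_scale(state)
    start = state.model.positions
    x0 = start[mov].ravel().copy()
    e0 = qr_target(state).value

    def fun(x):
        pos = state.model.positions
        pos[mov] = x.reshape(-1, 3)
        state.model.set_positions(pos)
        t = qr_target(state, deriv="xyz")
        return t.value, t.grad_xyz.ravel()

    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-8, "maxcor": 30},
    )
    final = x0 if res.fun > e0 else res.x  # guard: never accept an uphill result
    pos = start.copy()
    pos[mov] = final.reshape(-1, 3)
    state.model.set_positions(pos)
    if res.fun > e0:
        logger.warning("coordinate leg did not improve the target; keeping input")
    return state


def refine_adps(state: RefinementState, max_iter: int = 200, max_rounds: int = 6) -> RefinementState:
    """Isotropic ADP refinement of the whole model, coordinates untouched.

    The overall scale k and a uniform B shift are strongly correlated, so the
    leg alternates closed-form scale fits with bounded quasi-Newton B
    minimizations (k held fixed within each minimization) until k stabilizes.
    A weak similarity restraint between bonded atoms' B values stabilizes the
    toy-scale fit; all B values respect the positivity floor.
    """
    if max_iter <= 0:
        return state
    _ensure_scale(state)
    bonds = state.restraints.bond_idx

    def fun(b):
        state.model.set_b_factors(b)
        t = qr_target(state, deriv="b")
        value = t.value
        grad = t.grad_b.copy()
        if len(bonds):
            diff = b[bonds[:, 0]] - b[bonds[:, 1]]
            value += B_SIMILARITY_WEIGHT * float(np.sum(diff**2))
            np.add.at(grad, bonds[:, 0], 2.0 * B_SIMILARITY_WEIGHT * diff)
            np.add.at(grad, bonds[:, 1], -2.0 * B_SIMILARITY_WEIGHT * diff)
        return value, grad

    b = np.maximum(state.model.b_factors, B_FLOOR)
    for _ in range(max_rounds):
        e0 = fun(b)[0]
        res = minimize(
            fun, b, jac=True, method="L-BFGS-B",
            bounds=[(B_FLOOR, None)] * len(b),
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-8},
        )
        if res.fun <= e0:
            b = res.x
        state.model.set_b_factors(b)
        sf = calc_structure_factors(state.model, state.reflections.hkl, state.mode)
        k_new = fit_scale(state.reflections, sf.f)
        converged = abs(k_new / state.k - 1.0) < 1e-6
        state.k = k_new
        if converged:
            break
    return state


def _final_evaluation(state: RefinementState, report: RefinementReport) -> None:
    sf = calc_structure_factors(state.model, state.reflections.hkl, state.mode)
    state.k = fit_scale(state.reflections, sf.f)
    report.r_work, report.r_free = r_factors(state.reflections, sf.f, state.k)
    if state.spec.n_region:
        report.strain = strain_energy(state.model, state.spec, state.backend)
        qm_keys = sorted({state.model.atoms[i].residue_key for i in state.spec.selection})
        scores = rszd_per_residue(state.model, state.reflections, state.mode, k=state.k)
        report.rszd = scores
        report.avg_rszd = average_rszd(scores, qm_keys)
        sel = scores[
            scores.apply(lambda r: (r["chain"], r["resnum"], r["resname"]) in set(qm_keys), axis=1)
        ]
        report.max_rszd = float(sel["rszd"].max())
    report.distances = metal_distance_table(state.model)


def run_macrocycles(state: RefinementState, n: int = 3, coord_iter: int = 200, adp_iter: int = 100):
    """n macrocycles of (scale fit -> coordinates -> ADPs), then a final evaluation."""
    rows = []
    for cycle in range(1, n + 1):
        sf = calc_structure_factors(state.model, state.reflections.hkl, state.mode)
        state.k = fit_scale(state.reflections, sf.f)
        refine_coordinates(state, max_iter=coord_iter)
        refine_adps(state, max_iter=adp_iter)
        sf = calc_structure_factors(state.model, state.reflections.hkl, state.mode)
        state.k = fit_scale(state.reflections, sf.f)
        r_work, r_free = r_factors(state.reflections, sf.f, state.k)
        t = qr_target(state)
        rows.append(
            {"cycle": cycle, "r_work": r_work, "r_free": r_free, "target": t.value, "scale": state.k}
        )
    report = RefinementReport(cycles=pd.DataFrame(rows))
    _final_evaluation(state, report)
    return state, report


# ---------------------------------------------------------------------------
# weight scanning


def _minmax(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    span = v.max() - v.min()
    if span <= 0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def scan_wx(state: RefinementState, grid, n_macrocycles: int = 3):
    """One full QR per w_x grid point (independent starts from the input state).

    Selection rule: argmin of the sum of min-max-normalized strain and
    normalized average RSZD; ties break toward the smaller w_x.
    """
    grid = sorted(grid)
    if len(grid) == 0:
        raise ValueError("empty w_x grid")
    rows = []
    for wx in grid:
        st = state.clone()
        st.w_x = float(wx)
        st.k = None
        _, rep = run_macrocycles(st, n=n_macrocycles)
        rows.append(
            {
                "w_x": wx,
                "strain": rep.strain,
                "avg_rszd": rep.avg_rszd,
                "r_work": rep.r_work,
                "r_free": rep.r_free,
            }
        )
    table = pd.DataFrame(rows)
    combined = _minmax(table["strain"].to_numpy()) + _minmax(table["avg_rszd"].to_numpy())
    table["combined"] = combined
    selected = float(table["w_x"].iloc[int(np.argmin(combined))])
    return table, selected


# ---------------------------------------------------------------------------
# bridging-ligand discrimination


def swap_bridging_ligand(model: StructureModel, bridge_residue: tuple, label: str) -> StructureModel:
    """New model with the bridging solvent re-interpreted as O2-, OH- or H2O.

    Only the bridging residue's hydrogens and name change; the oxygen keeps its
    position and B factor.  Hydrogens are placed deterministically pointing
    away from the two nearest metals.
    """
    from .fragments import bridge_hydrogens
    from .restraints import METALS

    lig = LIGANDS[label]
    chain, resnum = bridge_residue
    new_atoms = []
    o_atom = None
    for a in model.atoms:
        if (a.chain, a.resnum) == (chain, resnum):
            if a.element == "O":
                o_atom = a
            continue  # drop old bridge atoms; re-added below
        new_atoms.append(copy.deepcopy(a))
    if o_atom is None:
        raise ValueError(f"bridge residue {bridge_residue} has no oxygen")
    pos = model.positions
    metal_idx = [i for i, a in enumerate(model.atoms) if a.element in METALS]
    metal_idx.sort(key=lambda i: np.linalg.norm(pos[i] - o_atom.pos))
    if len(metal_idx) < 2:
        raise ValueError("need two metals to orient the bridging ligand")
    fe1, fe2 = pos[metal_idx[0]], pos[metal_idx[1]]

    o_new = copy.deepcopy(o_atom)
    o_new.resname = lig.resname
    o_new.name = "O"
    bridge_atoms = [o_new]
    for i, hp in enumerate(bridge_hydrogens(o_atom.pos, fe1, fe2, lig.n_hydrogens), start=1):
        bridge_atoms.append(
            type(o_atom)(
                chain=chain, resnum=resnum, resname=lig.resname, name=f"H{i}",
                element="H", pos=hp, occ=o_atom.occ, b_iso=o_atom.b_iso,
                in_qm_region=o_atom.in_qm_region, movable=o_atom.movable,
            )
        )
    return StructureModel(model.cell, model.ops, new_atoms + bridge_atoms)


def discriminate_ligand(
    model: StructureModel,
    reflections: ReflectionSet,
    mode: str,
    candidates=("O2-", "OH-", "H2O"),
    *,
    oxidation_state: str = "oxidized",
    backend_params: SurrogateBackendParams = None,
    w_x: float = 1.0,
    w_qm: float = 7.5,
    n_macrocycles: int = 3,
    dictionary: dict = None,
):
    """Full QR per candidate protonation state; rank by strain + RSZD.

    Returns (table, best_label, reports).  The combined criterion is the sum of
    min-max-normalized strain and normalized average RSZD (max RSZD and the
    metal-O(bridge) distances are reported but not used for ranking).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    if backend_params is None:
        backend_params = SurrogateBackendParams()
    from .qm_region import find_bridge_residue

    bridge = find_bridge_residue(model)
    if bridge is None:
        raise ValueError("no bridging solvent residue found in the model")

    rows, reports = [], {}
    for label in candidates:
        m = swap_bridging_ligand(model, bridge, label)
        spec = build_region_spec(m, oxidation_state, ligand_label=label)
        backend = build_surrogate_backend(m, spec, backend_params, dictionary)
        restr = build_restraints(m, dictionary)
        st = RefinementState(
            model=m, reflections=reflections, spec=spec, restraints=restr,
            backend=backend, w_x=w_x, w_qm=w_qm, mode=mode,
        )
        _, rep = run_macrocycles(st, n=n_macrocycles)
        fe_ox = rep.distances[rep.distances["kind"] == "bridge"]["distance"]
        rows.append(
            {
                "ligand": label,
                "charge": LIGANDS[label].charge,
                "strain": rep.strain,
                "avg_rszd": rep.avg_rszd,
                "max_rszd": rep.max_rszd,
                "fe_ox_mean": float(fe_ox.mean()) if len(fe_ox) else np.nan,
                "r_work": rep.r_work,
                "r_free": rep.r_free,
            }
        )
        reports[label] = rep
    table = pd.DataFrame(rows)
    table["combined"] = _minmax(table["strain"].to_numpy()) + _minmax(
        table["avg_rszd"].to_numpy()
    )
    best = table["ligand"].iloc[int(np.argmin(table["combined"].to_numpy()))]
    return table, best, reports
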