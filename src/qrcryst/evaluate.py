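"""Model-quality evaluation: per-residue RSZD scores, distances, deviations.

The RSZD score here is a defined surrogate for the edstats statistic: per
residue, the maximum of |difference density| / sigma(map) over voxels within a
mask radius of any residue atom, with sigma taken over the whole map.  Good
models score low (roughly below 3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model_io import ReflectionSet, StructureModel
from .scattering import difference_map

__all__ = [
    "rszd_per_residue",
    "average_rszd",
    "distance_table",
    "metal_distance_table",
    "mean_absolute_deviation",
    "min_image_distance",
]


def min_image_distance(cell, pos_a, pos_b) -> float:
    """Euclidean distance under the minimum-image convention."""
    dfrac = cell.fractionalize(np.asarray(pos_a) - np.asarray(pos_b))
    dfrac -= np.round(dfrac)
    return float(np.linalg.norm(cell.orthogonalize(dfrac)))


def rszd_per_residue(
    model: StructureModel,
    reflections: ReflectionSet,
    mode: str = "xray",
    spacing: float = None,
    mask_radius: float = 1.5,
    k: float = None,
    method: str = "fft",
) -> pd.DataFrame:
    """Per-residue difference-density Z scores.

    Columns: chain, resnum, resname, rszd, n_voxels.  Residues without atoms in
    the mask (empty residues) are absent from the table.
    """
    grid = difference_map(model, reflections, mode=mode, spacing=spacing, k=k, method=method)
    sigma = grid.sigma()
    # a numerically null map (perfect model) must score zero, not noise/noise:
    # floor sigma at a negligible fraction of the total-density scale
    density_scale = float(np.sum(reflections.fobs)) / model.cell.volume
    sigma = max(sigma, 1e-9 * density_scale, 1e-300)
    n1, n2, n3 = grid.shape
    f1, f2, f3 = grid.voxel_fractions()
    g1, g2, g3 = np.meshgrid(f1, f2, f3, indexing="ij")
    vox_frac = np.stack([g1.ravel(), g2.ravel(), g3.ravel()], axis=1)
    absz = np.abs(grid.values.ravel()) / sigma

    orth = model.cell.orth_matrix
    rows = []
    for (chain, resnum, resname), idxs in model.residues():
        mask = np.zeros(len(vox_frac), dtype=bool)
        for i in idxs:
            afrac = model.cell.fractionalize(model.atoms[i].pos)
            d = vox_frac - afrac
            d -= np.round(d)
            cart = d @ orth.T
            mask |= np.einsum("ij,ij->i", cart, cart) <= mask_radius**2
        if not mask.any():
            continue
        rows.append(
            {
                "chain": chain,
                "resnum": resnum,
                "resname": resname,
                "rszd": float(absz[mask].max()),
                "n_voxels": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def average_rszd(scores: pd.DataFrame, selection=None) -> float:
    """Arithmetic mean of the selected residues' scores.

    ``selection``: iterable of (chain, resnum, resname) keys; None = all rows.
    """
    if selection is not None:
        keys = set(selection)
        scores = scores[
            scores.apply(lambda r: (r["chain"], r["resnum"], r["resname"]) in keys, axis=1)
        ]
    if len(scores) == 0:
        raise ValueError("empty residue selection for average RSZD")
    return float(scores["rszd"].mean())


def distance_table(model: StructureModel, pairs) -> pd.DataFrame:
    """Labelled minimum-image distances.

    ``pairs``: iterable of (label, key_a, key_b) with key = (chain, resnum,
    atom name).  Missing atoms yield NaN for that label.  Row order follows the
    input (stable and deterministic).
    """
    rows = []
    for label, ka, kb in pairs:
        try:
            ia = model.atom_index(*ka)
            ib = model.atom_index(*kb)
            d = min_image_distance(model.cell, model.atoms[ia].pos, model.atoms[ib].pos)
        except KeyError:
            d = np.nan
        rows.append({"label": label, "distance": d})
    return pd.DataFrame(rows)


def metal_distance_table(model: StructureModel, cutoff: float = 2.9) -> pd.DataFrame:
    """Metal-ligand distance table (detected by distance, labelled by residue).

    kind is 'bridge' for donors of the bridging solvent species, 'metal' for
    metal-metal, else 'donor'.
    """
    from .qm_region import find_bridge_residue
    from .restraints import METALS

    pos = model.positions
    metal_idx = [i for i, a in enumerate(model.atoms) if a.element in METALS]
    bridge = find_bridge_residue(model)
    rows = []
    for mi, m in enumerate(metal_idx):
        am = model.atoms[m]
        for m2 in metal_idx[mi + 1 :]:
            a2 = model.atoms[m2]
            rows.append(
                {
                    "label": f"{am.resname}{am.resnum}-{a2.resname}{a2.resnum}",
                    "kind": "metal",
                    "distance": min_image_distance(model.cell, pos[m], pos[m2]),
                }
            )
        for i, a in enumerate(model.atoms):
            if a.element not in ("O", "N") or i == m:
                continue
            d = min_image_distance(model.cell, pos[m], pos[i])
            if d > cutoff:
                continue
            kind = "bridge" if bridge is not None and (a.chain, a.resnum) == bridge else "donor"
            rows.append(
                {
                    "label": f"{am.resname}{am.resnum}-{a.resname}{a.resnum}:{a.name}",
                    "kind": kind,
                    "distance": d,
                }
            )
    return pd.DataFrame(rows)


def mean_absolute_deviation(table_a: pd.DataFrame, table_b: pd.DataFrame) -> float:
    """Mean |a - b| over shared labels of two distance tables."""
    merged = table_a.merge(table_b, on="label", suffixes=("_a", "_b")).dropna()
    if len(merged) == 0:
        raise ValueError("no shared labels between distance tables")
    return float(np.abs(merged["distance_a"] - merged["distance_b"]).mean())
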