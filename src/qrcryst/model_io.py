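"""Structure and reflection data model, PDB-subset and columnar hkl IO.

Coordinates are stored in Cartesian Å; fractional coordinates are computed on
demand through the unit cell using the PDB orthogonalization convention
(``a`` along x).  Reflection data are exchanged as plain columnar text
``h k l fobs sigma free`` (extra trailing columns tolerated, ``#`` comments
skipped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UnitCell",
    "SymmetryOps",
    "Atom",
    "StructureModel",
    "ReflectionSet",
    "read_model",
    "write_model",
    "read_reflections",
    "write_reflections",
    "d_spacing",
    "merge_friedel",
    "assign_free_set",
    "merging_stats",
    "theoretical_reflections",
]


# ---------------------------------------------------------------------------
# unit cell and symmetry


@dataclass
class UnitCell:
    """Triclinic unit cell (lengths in Å, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")
        g = gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        if g.volume <= 0:
            raise ValueError("cell volume must be positive")
        self._gemmi = g
        self._orth = np.array(g.orth.mat.tolist(), dtype=float)
        self._frac = np.array(g.frac.mat.tolist(), dtype=float)

    @property
    def volume(self) -> float:
        return self._gemmi.volume

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix mapping fractional -> Cartesian (PDB convention)."""
        return self._orth

    @property
    def frac_matrix(self) -> np.ndarray:
        """3x3 matrix mapping Cartesian -> fractional."""
        return self._frac

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self._frac.T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self._orth.T

    def d_spacings(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) of each reflection via the reciprocal metric."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        if np.any(np.all(hkl == 0, axis=1)):
            raise ValueError("d-spacing undefined for (0,0,0)")
        # reciprocal-lattice vectors: rows of frac_matrix are a*, b*, c*
        svec = hkl @ self._frac
        return 1.0 / np.linalg.norm(svec, axis=1)


def d_spacing(cell: UnitCell, hkl) -> float:
    """d-spacing (Å) of a single reflection."""
    return float(cell.d_spacings(np.asarray(hkl, dtype=float)[None, :])[0])


@dataclass
class SymmetryOps:
    """Crystallographic symmetry operators (integer rotations, fractional translations)."""

    rotations: np.ndarray  # (n, 3, 3) int
    translations: np.ndarray  # (n, 3) float
    name: str = "P 1"

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=int)
        self.translations = np.asarray(self.translations, dtype=float)
        ident = np.all(self.rotations == np.eye(3, dtype=int), axis=(1, 2)) & np.all(
            self.translations == 0.0, axis=1
        )
        if not np.any(ident):
            raise ValueError("identity operator missing from symmetry operator list")

    def __len__(self) -> int:
        return len(self.rotations)

    @classmethod
    def p1(cls) -> "SymmetryOps":
        return cls(np.eye(3, dtype=int)[None], np.zeros((1, 3)), name="P 1")

    @classmethod
    def from_spacegroup(cls, name: str) -> "SymmetryOps":
        sg = gemmi.find_spacegroup_by_name(name)
        if sg is None:
            raise ValueError(f"unknown space group {name!r}")
        rots, trans = [], []
        for op in sg.operations():
            rots.append(np.asarray(op.rot, dtype=float) / op.DEN)
            trans.append(np.asarray(op.tran, dtype=float) / op.DEN)
        return cls(np.rint(rots).astype(int), np.asarray(trans), name=sg.hm)

    def expand(self, frac: np.ndarray) -> np.ndarray:
        """Symmetry-expanded fractional positions, shape (n_ops, N, 3)."""
        frac = np.atleast_2d(frac)
        return np.einsum("oij,nj->oni", self.rotations.astype(float), frac) + self.translations[:, None, :]


# ---------------------------------------------------------------------------
# atoms and models


@dataclass
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    pos: np.ndarray
    occ: float = 1.0
    b_iso: float = 20.0
    in_qm_region: bool = False
    movable: bool = False

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if not 0.0 <= self.occ <= 1.0:
            raise ValueError(f"occupancy {self.occ} outside [0, 1] for atom {self.name}")
        if self.b_iso < 0.0:
            raise ValueError(f"negative B factor for atom {self.name}")
        if gemmi.Element(self.element).name in ("X", ""):
            raise ValueError(f"unknown element symbol {self.element!r} for atom {self.name}")

    @property
    def key(self):
        return (self.chain, self.resnum, self.name)

    @property
    def residue_key(self):
        return (self.chain, self.resnum, self.resname)


@dataclass
class StructureModel:
    """Refinable object: unit cell, symmetry, ordered atom list."""

    cell: UnitCell
    ops: SymmetryOps
    atoms: list

    def __post_init__(self):
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue number, atom name) in model")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float).reshape(-1, 3)

    def set_positions(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        for a, p in zip(self.atoms, xyz):
            a.pos = p.copy()

    @property
    def elements(self) -> list:
        return [a.element for a in self.atoms]

    @property
    def b_factors(self) -> np.ndarray:
        return np.array([a.b_iso for a in self.atoms], dtype=float)

    def set_b_factors(self, b: np.ndarray) -> None:
        for a, bi in zip(self.atoms, np.asarray(b, dtype=float)):
            a.b_iso = float(bi)

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([a.occ for a in self.atoms], dtype=float)

    def residues(self):
        """Ordered (residue_key, atom index list) pairs."""
        out, order = {}, []
        for i, a in enumerate(self.atoms):
            k = a.residue_key
            if k not in out:
                out[k] = []
                order.append(k)
            out[k].append(i)
        return [(k, out[k]) for k in order]

    def atom_index(self, chain: str, resnum: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.key == (chain, resnum, name):
                return i
        raise KeyError(f"atom {(chain, resnum, name)} not in model")

    def copy(self) -> "StructureModel":
        atoms = [replace(a, pos=a.pos.copy()) for a in self.atoms]
        return StructureModel(self.cell, self.ops, atoms)


# ---------------------------------------------------------------------------
# PDB subset IO (via gemmi)


def read_model(path) -> StructureModel:
    """Read a PDB-subset file (CRYST1 + ATOM/HETATM records)."""
    text = open(path).read()
    if "CRYST1" not in text:
        raise ValueError(f"{path}: missing CRYST1 record")
    st = gemmi.read_pdb_string(text)
    c = st.cell
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    sg_name = st.spacegroup_hm or "P 1"
    try:
        ops = SymmetryOps.from_spacegroup(sg_name)
    except ValueError:
        logger.warning("unknown space group %r, assuming P 1", sg_name)
        ops = SymmetryOps.p1()
    atoms = []
    for chain in st[0]:
        for res in chain:
            for at in res:
                if at.element.name in ("X", ""):
                    raise ValueError(
                        f"unknown element for atom {at.name} in residue "
                        f"{res.name} {res.seqid.num}"
                    )
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name.strip(),
                        name=at.name,
                        element=at.element.name,
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occ=at.occ,
                        b_iso=at.b_iso,
                    )
                )
    return StructureModel(cell, ops, atoms)


def write_model(model: StructureModel, path) -> None:
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(
        model.cell.a, model.cell.b, model.cell.c,
        model.cell.alpha, model.cell.beta, model.cell.gamma,
    )
    st.spacegroup_hm = model.ops.name
    md = gemmi.Model("1")
    chains = {}
    for a in model.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            md.add_chain(ch)
            # gemmi copies the chain on add; fetch the stored one
            ch = md[a.chain]
            chains[a.chain] = ch
        if len(ch) == 0 or ch[-1].seqid.num != a.resnum or ch[-1].name != a.resname:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resnum, " ")
            res.het_flag = "H"
            ch.add_residue(res)
        res = ch[-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.pos)
        at.occ = a.occ
        at.b_iso = a.b_iso
        res.add_atom(at)
    st.add_model(md)
    st.setup_entities()
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())


# ---------------------------------------------------------------------------
# reflections


@dataclass
class ReflectionSet:
    """Indexed amplitudes with sigmas and free-set flags (array-of-columns)."""

    hkl: np.ndarray  # (N, 3) int
    fobs: np.ndarray  # (N,)
    sigma: np.ndarray  # (N,)
    free: np.ndarray  # (N,) bool
    cell: UnitCell
    merged: bool = False
    d_min: float = field(default=None)
    d_max: float = field(default=None)

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.fobs = np.asarray(self.fobs, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.free = np.asarray(self.free, dtype=bool)
        if np.any(self.sigma <= 0):
            raise ValueError("all sigmas must be positive")
        if np.any(self.fobs < 0):
            raise ValueError("amplitudes must be non-negative")
        if len(self.hkl) and np.any(np.all(self.hkl == 0, axis=1)):
            raise ValueError("(0,0,0) not allowed in working data")
        d = self.d_spacings() if len(self.hkl) else np.array([])
        if self.d_min is None:
            self.d_min = float(d.min()) if len(d) else None
        if self.d_max is None:
            self.d_max = float(d.max()) if len(d) else None

    def __len__(self) -> int:
        return len(self.fobs)

    def d_spacings(self) -> np.ndarray:
        return self.cell.d_spacings(self.hkl)

    @property
    def work(self) -> np.ndarray:
        return ~self.free

    def replace(self, **kw) -> "ReflectionSet":
        base = dict(
            hkl=self.hkl.copy(), fobs=self.fobs.copy(), sigma=self.sigma.copy(),
            free=self.free.copy(), cell=self.cell, merged=self.merged,
            d_min=self.d_min, d_max=self.d_max,
        )
        base.update(kw)
        return ReflectionSet(**base)


def read_reflections(path, cell: UnitCell) -> ReflectionSet:
    """Read columnar text ``h k l fobs sigma free``; '#' comments skipped."""
    rows, rejected = [], 0
    for line in open(path):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
        fobs, sigma = float(parts[3]), float(parts[4])
        fr = bool(int(parts[5])) if len(parts) > 5 else False
        if sigma <= 0:
            rejected += 1
            continue
        rows.append((h, k, l, fobs, sigma, fr))
    if rejected:
        logger.warning("%s: rejected %d records with sigma <= 0", path, rejected)
    arr = np.array(rows, dtype=float).reshape(-1, 6)
    return ReflectionSet(
        hkl=arr[:, :3].astype(int), fobs=arr[:, 3], sigma=arr[:, 4],
        free=arr[:, 5].astype(bool), cell=cell,
    )


def write_reflections(rset: ReflectionSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# h k l fobs sigma free\n")
        for (h, k, l), f, s, fr in zip(rset.hkl, rset.fobs, rset.sigma, rset.free):
            fh.write(f"{h:5d} {k:5d} {l:5d} {f:14.6f} {s:12.6f} {int(fr):2d}\n")


def _canonical_friedel(hkl: np.ndarray) -> tuple:
    """Map each index to the lexicographically larger of (h,k,l) and (-h,-k,-l)."""
    hkl = np.asarray(hkl, dtype=int)
    neg = -hkl
    take_neg = (neg[:, 0] > hkl[:, 0]) | (
        (neg[:, 0] == hkl[:, 0])
        & ((neg[:, 1] > hkl[:, 1]) | ((neg[:, 1] == hkl[:, 1]) & (neg[:, 2] > hkl[:, 2])))
    )
    canon = np.where(take_neg[:, None], neg, hkl)
    return canon, take_neg


def merge_friedel(rset: ReflectionSet) -> ReflectionSet:
    """Merge Friedel mates by inverse-variance weighting.

    The representative index is the lexicographically larger of (h,k,l) and
    (-h,-k,-l); singletons pass through (re-indexed to the canonical choice).
    A merged reflection is flagged free if either mate was.
    """
    canon, _ = _canonical_friedel(rset.hkl)
    df = pd.DataFrame({
        "h": canon[:, 0], "k": canon[:, 1], "l": canon[:, 2],
        "fobs": rset.fobs, "w": 1.0 / rset.sigma**2, "free": rset.free,
    })
    df["wf"] = df["w"] * df["fobs"]
    g = df.groupby(["h", "k", "l"], sort=True)
    agg = g.agg(wf=("wf", "sum"), w=("w", "sum"), free=("free", "any"))
    hkl = np.array(list(agg.index), dtype=int)
    return ReflectionSet(
        hkl=hkl,
        fobs=(agg["wf"] / agg["w"]).to_numpy(),
        sigma=1.0 / np.sqrt(agg["w"].to_numpy()),
        free=agg["free"].to_numpy(),
        cell=rset.cell,
        merged=True,
    )


def assign_free_set(rset: ReflectionSet, fraction: float, seed: int) -> ReflectionSet:
    """Flag round(fraction*N) reflections free by seeded sampling without replacement."""
    if not 0.0 < fraction < 0.5:
        raise ValueError("free fraction must lie in (0, 0.5)")
    n = len(rset)
    n_free = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_free, replace=False)
    free = np.zeros(n, dtype=bool)
    free[idx] = True
    return rset.replace(free=free)


def theoretical_reflections(cell: UnitCell, d_min: float) -> np.ndarray:
    """All Friedel-unique indices with d >= d_min, enumerated in P1.

    The canonical representative satisfies (h,k,l) > (-h,-k,-l) lexicographically,
    which also excludes the origin.
    """
    hmax = int(np.floor(cell.a / d_min))
    kmax = int(np.floor(cell.b / d_min))
    lmax = int(np.floor(cell.c / d_min))
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1), np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1), indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    # canonical half: first nonzero component positive
    gt = (hkl[:, 0] > 0) | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0)) | (
        (hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0)
    )
    hkl = hkl[gt]
    d = cell.d_spacings(hkl)
    return hkl[d >= d_min]


def merging_stats(obs: pd.DataFrame, cell: UnitCell, d_min: float, seed: int = 0) -> dict:
    """Merging statistics for an unmerged multi-observation table.

    ``obs`` columns: h, k, l, value (and optionally sigma).  Uniques are
    Friedel-reduced in P1.  Returns completeness %, multiplicity, Rmeas %
    (with the sqrt(n/(n-1)) correction; absent when every unique is a
    singleton), CC1/2 % (seeded random half splits) and I/sigma (mean
    value/sigma; absent without a sigma column).
    """
    if len(obs) == 0:
        raise ValueError("empty observation table")
    canon, _ = _canonical_friedel(obs[["h", "k", "l"]].to_numpy(dtype=int))
    df = obs.copy()
    df[["h", "k", "l"]] = canon
    groups = df.groupby(["h", "k", "l"], sort=True)["value"]
    n_unique = groups.ngroups
    n_obs = len(df)
    n_theor = len(theoretical_reflections(cell, d_min))
    completeness = 100.0 * n_unique / n_theor
    multiplicity = n_obs / n_unique

    rng = np.random.default_rng(seed)
    num = 0.0
    den = 0.0
    half1, half2 = [], []
    any_multi = False
    for _, vals in groups:
        v = vals.to_numpy(dtype=float)
        n = len(v)
        den += v.sum()
        if n >= 2:
            any_multi = True
            num += np.sqrt(n / (n - 1.0)) * np.abs(v - v.mean()).sum()
            perm = rng.permutation(n)
            mid = n // 2
            half1.append(v[perm[:mid]].mean())
            half2.append(v[perm[mid:]].mean())
    r_meas = 100.0 * num / den if any_multi else None
    if len(half1) >= 2 and np.std(half1) > 0 and np.std(half2) > 0:
        cc_half = 100.0 * float(np.corrcoef(half1, half2)[0, 1])
    elif len(half1) >= 2:
        # zero-variance halves: identical means <=> perfect agreement
        cc_half = 100.0 if np.allclose(half1, half2) else None
    else:
        cc_half = None
    i_over_sigma = None
    if "sigma" in obs.columns:
        i_over_sigma = float((obs["value"] / obs["sigma"]).mean())
    return {
        "completeness": completeness,
        "multiplicity": multiplicity,
        "r_meas": r_meas,
        "cc_half": cc_half,
        "i_over_sigma": i_over_sigma,
        "n_unique": n_unique,
        "n_obs": n_obs,
    }
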