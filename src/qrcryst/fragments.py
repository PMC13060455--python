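"""Reference geometries for the toy ligand fragments.

Each fragment is a small rigid template in a local frame: the metal-donor atom
sits at the origin and the fragment body extends along +z (the metal approaches
from -z).  Carboxylate ligands reuse Asp/Glu residue names (modelled as
acetate), His is modelled as methylimidazole, and the bridging solvent species
are OXO (O2-), HYD (OH-) and HOH (H2O).

The default restraint dictionary and the surrogate backend both derive their
ideal bond lengths and angles from these templates, so a site assembled from
them is exactly at the dictionary optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geom import rotation_to

__all__ = ["Fragment", "FRAGMENTS", "fragment", "bridge_hydrogens", "RESIDUE_CHARGES"]

_TET = np.degrees(np.arccos(-1.0 / 3.0))  # 109.47


@dataclass(frozen=True)
class Fragment:
    resname: str
    names: tuple
    elements: tuple
    coords: np.ndarray  # (N, 3), donor at origin
    donor: str
    charge: int
    bonds: tuple  # ((name_i, name_j), ...)
    angles: tuple  # ((name_i, apex, name_k), ...)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def bond_length(self, ni: str, nj: str) -> float:
        return float(np.linalg.norm(self.coords[self.index(ni)] - self.coords[self.index(nj)]))

    def angle_deg(self, ni: str, nj: str, nk: str) -> float:
        u = self.coords[self.index(ni)] - self.coords[self.index(nj)]
        v = self.coords[self.index(nk)] - self.coords[self.index(nj)]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.degrees(np.arccos(np.clip(c, -1, 1))))


def _methyl_h(c_pos, toward_heavy, bond=1.09, phase=0.0):
    """Three staggered methyl hydrogens around C, attached heavy atom along u."""
    u = np.asarray(toward_heavy, dtype=float) - c_pos
    u /= np.linalg.norm(u)
    frame = rotation_to(u)
    e1, e2 = frame[:, 0], frame[:, 1]
    cos_t, sin_t = -1.0 / 3.0, np.sqrt(8.0) / 3.0
    out = []
    for i in range(3):
        ang = phase + 2.0 * np.pi * i / 3.0
        d = cos_t * u + sin_t * (np.cos(ang) * e1 + np.sin(ang) * e2)
        out.append(c_pos + bond * d)
    return out


def _water() -> Fragment:
    half = np.radians(104.52 / 2.0)
    oh = 0.9572
    coords = np.array([
        [0.0, 0.0, 0.0],
        [oh * np.sin(half), 0.0, oh * np.cos(half)],
        [-oh * np.sin(half), 0.0, oh * np.cos(half)],
    ])
    return Fragment(
        "HOH", ("O", "H1", "H2"), ("O", "H", "H"), coords, "O", 0,
        bonds=(("O", "H1"), ("O", "H2")), angles=(("H1", "O", "H2"),),
    )


def _hydroxide() -> Fragment:
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.96]])
    return Fragment(
        "HYD", ("O", "H1"), ("O", "H"), coords, "O", -1,
        bonds=(("O", "H1"),), angles=(),
    )


def _oxo() -> Fragment:
    return Fragment(
        "OXO", ("O",), ("O",), np.zeros((1, 3)), "O", -2, bonds=(), angles=(),
    )


def _acetate(resname: str) -> Fragment:
    """Acetate fragment with Asp (CB,CG,OD1,OD2) or Glu (CG,CD,OE1,OE2) naming."""
    if resname == "ASP":
        n_c, n_od1, n_od2, n_cm, hs = "CG", "OD1", "OD2", "CB", ("HB1", "HB2", "HB3")
    else:
        n_c, n_od1, n_od2, n_cm, hs = "CD", "OE1", "OE2", "CG", ("HG1", "HG2", "HG3")
    co, cc = 1.26, 1.52
    od1 = np.zeros(3)
    cg = np.array([0.0, 0.0, co])
    a2 = np.radians(123.0)
    od2 = cg + co * np.array([np.sin(a2), 0.0, -np.cos(a2)])
    a3 = np.radians(118.5)
    cm = cg + cc * np.array([-np.sin(a3), 0.0, -np.cos(a3)])
    hpos = _methyl_h(cm, cg)
    names = (n_od1, n_c, n_od2, n_cm) + hs
    elements = ("O", "C", "O", "C", "H", "H", "H")
    coords = np.vstack([od1, cg, od2, cm] + hpos)
    bonds = (
        (n_c, n_od1), (n_c, n_od2), (n_c, n_cm),
        (n_cm, hs[0]), (n_cm, hs[1]), (n_cm, hs[2]),
    )
    angles = (
        (n_od1, n_c, n_od2), (n_od1, n_c, n_cm), (n_od2, n_c, n_cm),
        (n_c, n_cm, hs[0]), (n_c, n_cm, hs[1]), (n_c, n_cm, hs[2]),
        (hs[0], n_cm, hs[1]), (hs[0], n_cm, hs[2]), (hs[1], n_cm, hs[2]),
    )
    return Fragment(resname, names, elements, coords, n_od1, -1, bonds, angles)


def _methylimidazole() -> Fragment:
    """Methylimidazole with His naming; NE2 is the metal donor.

    Ring is a regular pentagon of side 1.37 Å in the xz plane (internal angles
    108 degrees, geometrically consistent by construction).
    """
    side = 1.37
    R = side / (2.0 * np.sin(np.pi / 5.0))
    center = np.array([0.0, 0.0, R])
    ring_names = ("NE2", "CD2", "CG", "ND1", "CE1")
    ring = {}
    for i, nm in enumerate(ring_names):
        phi = 2.0 * np.pi * i / 5.0
        ring[nm] = center + R * np.array([np.sin(phi), 0.0, -np.cos(phi)])

    def outward(nm, dist):
        d = ring[nm] - center
        return ring[nm] + dist * d / np.linalg.norm(d)

    cb = outward("CG", 1.50)
    hd2 = outward("CD2", 1.08)
    he1 = outward("CE1", 1.08)
    hd1 = outward("ND1", 1.01)
    hb = _methyl_h(cb, ring["CG"])
    names = ring_names + ("CB", "HD2", "HE1", "HD1", "HB1", "HB2", "HB3")
    elements = ("N", "C", "C", "N", "C", "C", "H", "H", "H", "H", "H", "H")
    coords = np.vstack([ring[nm] for nm in ring_names] + [cb, hd2, he1, hd1] + hb)
    bonds = (
        ("NE2", "CD2"), ("CD2", "CG"), ("CG", "ND1"), ("ND1", "CE1"), ("CE1", "NE2"),
        ("CG", "CB"), ("CD2", "HD2"), ("CE1", "HE1"), ("ND1", "HD1"),
        ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3"),
    )
    angles = (
        ("CE1", "NE2", "CD2"), ("NE2", "CD2", "CG"), ("CD2", "CG", "ND1"),
        ("CG", "ND1", "CE1"), ("ND1", "CE1", "NE2"),
        ("CD2", "CG", "CB"), ("ND1", "CG", "CB"),
        ("CG", "CD2", "HD2"), ("NE2", "CD2", "HD2"),
        ("ND1", "CE1", "HE1"), ("NE2", "CE1", "HE1"),
        ("CG", "ND1", "HD1"), ("CE1", "ND1", "HD1"),
        ("CG", "CB", "HB1"), ("CG", "CB", "HB2"), ("CG", "CB", "HB3"),
        ("HB1", "CB", "HB2"), ("HB1", "CB", "HB3"), ("HB2", "CB", "HB3"),
    )
    return Fragment("HIS", names, elements, coords, "NE2", 0, bonds, angles)


def _iron() -> Fragment:
    return Fragment(
        "FE", ("FE",), ("Fe",), np.zeros((1, 3)), "FE", 0, bonds=(), angles=(),
    )


FRAGMENTS = {
    "HOH": _water(),
    "HYD": _hydroxide(),
    "OXO": _oxo(),
    "ASP": _acetate("ASP"),
    "GLU": _acetate("GLU"),
    "HIS": _methylimidazole(),
    "FE": _iron(),
}

# fragment formal charges (FE handled via oxidation state, see qm_region)
RESIDUE_CHARGES = {name: fr.charge for name, fr in FRAGMENTS.items()}


def fragment(resname: str) -> Fragment:
    try:
        return FRAGMENTS[resname]
    except KeyError:
        raise KeyError(f"no fragment template for residue {resname!r}") from None


def bridge_hydrogens(o_pos, fe1_pos, fe2_pos, n_h: int, oh: float = 0.96) -> list:
    """Deterministic hydrogen positions for a bridging solvent oxygen.

    Hydrogens point away from both metals; for water the two protons open the
    104.52 degree angle in the plane perpendicular to the Fe-Fe axis component.
    """
    o = np.asarray(o_pos, dtype=float)
    u1 = (np.asarray(fe1_pos) - o)
    u2 = (np.asarray(fe2_pos) - o)
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    z = -(u1 + u2)
    z /= np.linalg.norm(z)
    if n_h == 0:
        return []
    if n_h == 1:
        return [o + oh * z]
    # spread the two protons out of the Fe-O-Fe plane (along its normal)
    n = np.cross(u1, u2)
    if np.linalg.norm(n) < 1e-8:
        n = rotation_to(z)[:, 0]
    n = n / np.linalg.norm(n)
    n -= np.dot(n, z) * z
    n /= np.linalg.norm(n)
    half = np.radians(104.52 / 2.0)
    return [
        o + oh * (np.cos(half) * z + np.sin(half) * n),
        o + oh * (np.cos(half) * z - np.sin(half) * n),
    ]
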