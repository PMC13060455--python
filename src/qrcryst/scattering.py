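"""Atomic form factors, kinematic structure factors and difference maps.

Two scattering modes are supported: ``xray`` (Cromer-Mann 4-Gaussian + constant,
International Tables vol. C / IT92) and ``electron`` (5-Gaussian neutral-atom
parameterization).  Coefficients are taken from gemmi's built-in tables at run
time.  The convention throughout is s = sin(theta)/lambda = 1/(2d) with the
isotropic Debye-Waller factor exp(-B s^2).

Structure factors are computed by direct summation over symmetry operators and
atoms:

    F(h) = sum_ops sum_atoms occ * f(s_h) * exp(-B s_h^2)
           * exp(2 pi i h . (R x_frac + t))

Analytic derivatives with respect to Cartesian coordinates and isotropic B
values are returned on request; they feed the refinement targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .model_io import StructureModel, ReflectionSet, UnitCell

__all__ = [
    "ScatteringCoefficients",
    "scattering_coefficients",
    "form_factor",
    "calc_structure_factors",
    "StructureFactors",
    "MapGrid",
    "difference_map",
]

MODES = ("xray", "electron")


@dataclass(frozen=True)
class ScatteringCoefficients:
    """Gaussian form-factor parameterization for one element and mode."""

    element: str
    mode: str
    gaussians: tuple  # ((a_i, b_i), ...)
    c: float = 0.0

    def evaluate(self, s):
        """f(s) with s = sin(theta)/lambda in Å^-1."""
        s2 = np.asarray(s, dtype=float) ** 2
        out = np.full_like(s2, self.c, dtype=float)
        for a, b in self.gaussians:
            out = out + a * np.exp(-b * s2)
        return out


def scattering_coefficients(element: str, mode: str) -> ScatteringCoefficients:
    if mode not in MODES:
        raise ValueError(f"unknown scattering mode {mode!r}")
    el = gemmi.Element(element)
    if el.name in ("X", ""):
        raise ValueError(f"unknown element {element!r}")
    if mode == "xray":
        t = el.it92
        if t is None:
            raise ValueError(f"no X-ray scattering table for element {element!r}")
        return ScatteringCoefficients(el.name, mode, tuple(zip(t.a, t.b)), c=t.c)
    t = el.c4322
    if t is None:
        raise ValueError(f"no electron scattering table for element {element!r}")
    return ScatteringCoefficients(el.name, mode, tuple(zip(t.a, t.b)), c=0.0)


def form_factor(element: str, s, mode: str):
    """Atomic form factor at s = sin(theta)/lambda (Å^-1)."""
    if np.any(np.asarray(s) < 0):
        raise ValueError("s must be non-negative")
    return scattering_coefficients(element, mode).evaluate(s)


@dataclass
class StructureFactors:
    """Complex structure factors and optional analytic derivatives.

    dF_dxyz has shape (n_hkl, n_deriv_atoms, 3) (complex, per Cartesian Å);
    dF_dB has shape (n_hkl, n_deriv_atoms) (complex, per Å^2).  ``deriv_atoms``
    records which atom indices the derivative axes refer to.
    """

    hkl: np.ndarray
    f: np.ndarray
    dF_dxyz: np.ndarray = None
    dF_dB: np.ndarray = None
    deriv_atoms: np.ndarray = None

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.f)


def calc_structure_factors(
    model: StructureModel,
    hkl: np.ndarray,
    mode: str = "xray",
    deriv_atoms=None,
    deriv_b: bool = False,
) -> StructureFactors:
    """Direct-summation structure factors for the given Miller indices.

    deriv_atoms: optional index array; coordinate derivatives are returned for
    those atoms.  deriv_b: also return d|F|/dB inputs (dF/dB) for *all* atoms.
    """
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    n_h = len(hkl)
    n_at = len(model)
    if n_at == 0:
        import logging

        logging.getLogger(__name__).warning("empty model: all structure factors zero")
        return StructureFactors(hkl, np.zeros(n_h, dtype=complex))

    cell = model.cell
    s = 1.0 / (2.0 * cell.d_spacings(hkl))  # (H,)
    s2 = s**2

    elements = model.elements
    uniq = sorted(set(elements))
    coeff = {e: scattering_coefficients(e, mode) for e in uniq}
    f_elem = np.column_stack([coeff[e].evaluate(s) for e in uniq])  # (H, E)
    eidx = np.array([uniq.index(e) for e in elements])
    f_at = f_elem[:, eidx]  # (H, N)

    occ = model.occupancies
    b = model.b_factors
    dw = np.exp(-np.outer(s2, b))  # (H, N)
    pref = occ[None, :] * f_at * dw  # (H, N)

    frac = cell.fractionalize(model.positions)  # (N, 3)
    want_grad = deriv_atoms is not None
    if want_grad:
        deriv_atoms = np.asarray(deriv_atoms, dtype=int)

    F = np.zeros(n_h, dtype=complex)
    dF_dxyz = np.zeros((n_h, len(deriv_atoms), 3), dtype=complex) if want_grad else None
    dF_dB = np.zeros((n_h, n_at), dtype=complex) if deriv_b else None

    two_pi_i = 2j * np.pi
    for R, t in zip(model.ops.rotations, model.ops.translations):
        hR = hkl @ R  # (H, 3)
        phase = two_pi_i * (hR @ frac.T + (hkl @ t)[:, None])  # (H, N)
        contrib = pref * np.exp(phase)
        F += contrib.sum(axis=1)
        if want_grad:
            # d phase / d x_cart = 2 pi i (hR . frac_matrix)
            hRF = hR.astype(float) @ cell.frac_matrix  # (H, 3)
            dF_dxyz += contrib[:, deriv_atoms, None] * (two_pi_i * hRF)[:, None, :]
        if deriv_b:
            dF_dB += contrib * (-s2)[:, None]
    return StructureFactors(hkl, F, dF_dxyz, dF_dB, deriv_atoms)


# ---------------------------------------------------------------------------
# real-space maps


@dataclass
class MapGrid:
    """Real scalar map sampled on a regular fractional grid over the cell."""

    cell: UnitCell
    values: np.ndarray  # (n1, n2, n3)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def voxel_fractions(self) -> tuple:
        n1, n2, n3 = self.shape
        return (np.arange(n1) / n1, np.arange(n2) / n2, np.arange(n3) / n3)

    def sigma(self) -> float:
        return float(np.std(self.values))

    def export_text(self, path) -> None:
        n1, n2, n3 = self.shape
        with open(path, "w") as fh:
            fh.write(f"# map grid {n1} {n2} {n3}\n")
            fh.write(
                f"# cell {self.cell.a} {self.cell.b} {self.cell.c} "
                f"{self.cell.alpha} {self.cell.beta} {self.cell.gamma}\n"
            )
            np.savetxt(fh, self.values.ravel()[:, None])


def _grid_shape(cell: UnitCell, spacing: float) -> tuple:
    return tuple(max(int(np.ceil(L / spacing)), 2) for L in (cell.a, cell.b, cell.c))


def difference_map(
    model: StructureModel,
    reflections: ReflectionSet,
    mode: str = "xray",
    spacing: float = None,
    k: float = None,
    method: str = "fft",
    work_only: bool = True,
) -> MapGrid:
    """Fo-Fc difference density with model phases.

    delta_rho(x) = (1/V) sum_h (fobs/k - |Fc|) exp(i phi_c) exp(-2 pi i h.x),
    Friedel mates included so the map is real.  F(000) excluded.  ``spacing``
    defaults to d_min/4 and must not exceed d_min/3 (aliasing guard).
    """
    from .targets import fit_scale

    if not reflections.merged:
        raise ValueError("difference_map expects a Friedel-merged reflection set")
    d_min = float(np.min(reflections.d_spacings()))
    if spacing is None:
        spacing = d_min / 4.0
    if spacing > d_min / 3.0 + 1e-12:
        raise ValueError(f"grid spacing {spacing} exceeds d_min/3 = {d_min / 3.0:.3f}")

    sel = reflections.work if work_only else np.ones(len(reflections), bool)
    hkl = reflections.hkl[sel]
    sf = calc_structure_factors(model, hkl, mode)
    if k is None:
        k = fit_scale(reflections, sf.f, work_only=work_only)
    amp = np.abs(sf.f)
    phase = np.where(amp > 0, sf.f / np.where(amp > 0, amp, 1.0), 0.0)
    dF = (reflections.fobs[sel] / k - amp) * phase  # complex delta-F

    cell = model.cell
    shape = _grid_shape(cell, spacing)
    if method == "fft":
        arr = np.zeros(shape, dtype=complex)
        idx = tuple((hkl % shape).T)
        np.add.at(arr, idx, dF)
        idx_neg = tuple(((-hkl) % shape).T)
        np.add.at(arr, idx_neg, np.conj(dF))
        # rho(x_j) = (1/V) sum_h F_h exp(-2 pi i h.j/n) -> forward FFT
        rho = np.real(np.fft.fftn(arr)) / cell.volume
    elif method == "direct":
        fr = [np.arange(n) / n for n in shape]
        g1, g2, g3 = np.meshgrid(*fr, indexing="ij")
        rho = np.zeros(shape)
        chunk = 256
        for i0 in range(0, len(hkl), chunk):
            hh = hkl[i0 : i0 + chunk].astype(float)
            ff = dF[i0 : i0 + chunk]
            ph = (
                hh[:, 0, None, None, None] * g1
                + hh[:, 1, None, None, None] * g2
                + hh[:, 2, None, None, None] * g3
            )
            # h and -h combined: 2 Re(F exp(-2 pi i phi))
            rho += 2.0 * (
                ff.real[:, None, None, None] * np.cos(2 * np.pi * ph)
                + ff.imag[:, None, None, None] * np.sin(2 * np.pi * ph)
            ).sum(axis=0)
        rho /= cell.volume
    else:
        raise ValueError(f"unknown map synthesis method {method!r}")
    return MapGrid(cell, rho)
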