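"""Experimental target E_exp, overall scale and R factors, with analytic gradients.

The experimental term is a sigma-weighted least-squares amplitude residual

    E_exp = sum_work ((fobs - k |Fcalc|) / sigma)^2

evaluated over working-set reflections only; free reflections never enter the
value or the gradient.  The scale k is the closed-form least-squares minimizer
and is held fixed within a minimization leg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import ReflectionSet
from .scattering import StructureFactors

__all__ = ["TargetValue", "fit_scale", "exp_target", "r_factors"]


@dataclass
class TargetValue:
    """Target value with gradients over movable parameters.

    grad_xyz: (n_deriv_atoms, 3) Cartesian gradient (units: value Å^-1), or None.
    grad_b:   (n_atoms,) ADP gradient (units: value Å^-2), or None.
    """

    value: float
    grad_xyz: np.ndarray = None
    grad_b: np.ndarray = None
    k: float = None


def fit_scale(reflections: ReflectionSet, fcalc: np.ndarray, work_only: bool = True) -> float:
    """Least-squares scale k = sum(fobs |Fc|) / sum(|Fc|^2) over the working set.

    ``fcalc`` must align with the reflection order of ``reflections`` when
    ``work_only`` is False, or with the working subset otherwise (an array of
    full length is subset automatically).
    """
    amp = np.abs(np.asarray(fcalc))
    fobs = reflections.fobs
    if work_only:
        mask = reflections.work
        fobs = fobs[mask]
        if len(amp) == len(mask):
            amp = amp[mask]
    if len(amp) != len(fobs):
        raise ValueError("fcalc length does not match reflection selection")
    den = float(np.sum(amp**2))
    if den <= 0.0:
        raise ValueError("cannot fit scale: all calculated amplitudes are zero")
    return float(np.sum(fobs * amp) / den)


def exp_target(reflections: ReflectionSet, sf: StructureFactors, k: float) -> TargetValue:
    """E_exp and its analytic gradients at fixed scale k.

    Reflections flagged free are excluded from both the value and the gradient.
    Gradients are returned when the StructureFactors object carries derivatives.
    """
    work = reflections.work
    if not np.any(work):
        raise ValueError("no working reflections")
    amp = np.abs(sf.f)
    resid = reflections.fobs - k * amp
    w = 1.0 / reflections.sigma**2
    value = float(np.sum(w[work] * resid[work] ** 2))

    grad_xyz = grad_b = None
    # d|F|/dp = Re(conj(F)/|F| * dF/dp); zero-amplitude reflections contribute 0
    safe = np.where(amp > 0, amp, 1.0)
    unit = np.conj(sf.f) / safe
    coef = np.where(work & (amp > 0), -2.0 * k * w * resid, 0.0)
    if sf.dF_dxyz is not None:
        damp = np.real(unit[:, None, None] * sf.dF_dxyz)
        grad_xyz = np.einsum("h,hij->ij", coef, damp)
    if sf.dF_dB is not None:
        damp_b = np.real(unit[:, None] * sf.dF_dB)
        grad_b = coef @ damp_b
    return TargetValue(value, grad_xyz=grad_xyz, grad_b=grad_b, k=k)


def r_factors(reflections: ReflectionSet, fcalc: np.ndarray, k: float):
    """(R_work, R_free) = sum|fobs - k|Fc|| / sum fobs over each set, as fractions.

    R_free is None (with a warning) when no free reflections are flagged.
    """
    import logging

    amp = np.abs(np.asarray(fcalc))
    resid = np.abs(reflections.fobs - k * amp)

    def _r(mask):
        den = reflections.fobs[mask].sum()
        return float(resid[mask].sum() / den) if den > 0 else float("nan")

    work = reflections.work
    r_work = _r(work)
    if np.any(reflections.free):
        r_free = _r(reflections.free)
    else:
        logging.getLogger(__name__).warning("empty free set: R_free not computed")
        r_free = None
    return r_work, r_free
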