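"""Low-level geometry terms shared by the empirical restraints and the surrogate backend.

All functions take an (N, 3) Cartesian coordinate array and index arrays and
return ``(energy, gradient)`` with the gradient accumulated into an (N, 3)
array.  Energies are quadratic (harmonic) in the internal coordinate; the
soft-sphere term is one-sided harmonic in the pair distance.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "bond_energy",
    "angle_energy",
    "softsphere_energy",
    "rotation_to",
]


def bond_energy(coords, pairs, r0, k):
    """Sum of k_b * (|r_i - r_j| - r0)^2 over bonded pairs.

    pairs : (M, 2) int array; r0, k : (M,) arrays (Å, energy Å^-2).
    """
    grad = np.zeros_like(coords)
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size == 0:
        return 0.0, grad
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    r = np.linalg.norm(d, axis=1)
    dev = r - np.asarray(r0)
    e = float(np.sum(np.asarray(k) * dev**2))
    # dE/dr_i = 2k (r - r0) * d / r
    coef = (2.0 * np.asarray(k) * dev / r)[:, None] * d
    np.add.at(grad, pairs[:, 0], coef)
    np.add.at(grad, pairs[:, 1], -coef)
    return e, grad


def angle_energy(coords, triples, theta0, k):
    """Sum of k_a * (theta - theta0)^2 over angle triples (i, j, k) with apex j.

    theta0 in radians; k in energy rad^-2.
    """
    grad = np.zeros_like(coords)
    triples = np.asarray(triples, dtype=int)
    if triples.size == 0:
        return 0.0, grad
    i, j, l = triples[:, 0], triples[:, 1], triples[:, 2]
    u = coords[i] - coords[j]
    v = coords[l] - coords[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos_t = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    dev = theta - np.asarray(theta0)
    e = float(np.sum(np.asarray(k) * dev**2))
    # d(theta)/du = -1/sin(theta) * (v/(nu*nv) - cos_t*u/nu^2)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-12))
    pref = (2.0 * np.asarray(k) * dev / -sin_t)[:, None]
    dt_du = pref * (v / (nu * nv)[:, None] - (cos_t / nu**2)[:, None] * u)
    dt_dv = pref * (u / (nu * nv)[:, None] - (cos_t / nv**2)[:, None] * v)
    np.add.at(grad, i, dt_du)
    np.add.at(grad, l, dt_dv)
    np.add.at(grad, j, -(dt_du + dt_dv))
    return e, grad


def softsphere_energy(coords, pairs, rmin, k):
    """One-sided repulsion: k * (rmin - r)^2 for r < rmin, else 0."""
    grad = np.zeros_like(coords)
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size == 0:
        return 0.0, grad
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    r = np.linalg.norm(d, axis=1)
    rmin = np.asarray(rmin)
    k = np.asarray(k)
    act = r < rmin
    if not np.any(act):
        return 0.0, grad
    dev = (rmin - r)[act]
    e = float(np.sum(k[act] * dev**2))
    coef = (-2.0 * k[act] * dev / r[act])[:, None] * d[act]
    np.add.at(grad, pairs[act, 0], coef)
    np.add.at(grad, pairs[act, 1], -coef)
    return e, grad


def rotation_to(z_target, ref=(1.0, 0.0, 0.0)):
    """Deterministic rotation matrix mapping the +z axis onto ``z_target``.

    The image of +x is fixed by Gram-Schmidt against ``ref`` (falls back to +y
    when ``ref`` is parallel to the target), making fragment placement
    reproducible.
    """
    z = np.asarray(z_target, dtype=float)
    z = z / np.linalg.norm(z)
    ref = np.asarray(ref, dtype=float)
    x = ref - np.dot(ref, z) * z
    if np.linalg.norm(x) < 1e-8:
        ref = np.array([0.0, 1.0, 0.0])
        x = ref - np.dot(ref, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])
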