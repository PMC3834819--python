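"""Solvent-accessible surface area by the rolling-probe (Shrake-Rupley) method.

The probe sphere is sampled on a deterministic Fibonacci lattice, so repeated
runs give bit-identical areas; accuracy is controlled by ``n_points``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = ["fibonacci_sphere", "compute_sasa", "sasa_total"]

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def compute_sasa(
    s: Structure | tuple[np.ndarray, np.ndarray],
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    include_waters: bool = False,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (angstrom^2).

    Accepts either a :class:`Structure` (waters excluded by default) or a
    ``(coords, radii)`` pair.  A surface point on the expanded sphere of atom
    i counts as accessible when it lies outside every other atom's expanded
    sphere; the atom's area is the accessible fraction of ``4 pi (r+probe)^2``.
    """
    if isinstance(s, Structure):
        atoms = list(s.iter_atoms(include_waters=include_waters))
        coords = np.array([a.position for a in atoms])
        radii = np.array([a.vdw_radius for a in atoms])
    else:
        coords, radii = s
        coords = np.asarray(coords, dtype=float)
        radii = np.asarray(radii, dtype=float)
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a usable surface estimate")
    if len(coords) == 0:
        return np.zeros(0)
    if np.any(radii <= 0):
        raise ValueError("all atoms need a positive radius")

    sphere = fibonacci_sphere(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.zeros(len(coords))
    for i, (c, r) in enumerate(zip(coords, expanded)):
        pts = c + r * sphere
        neighbors = [j for j in tree.query_ball_point(c, r + max_r) if j != i]
        if neighbors:
            nb_c = coords[neighbors]
            nb_r = expanded[neighbors]
            d2 = ((pts[:, None, :] - nb_c[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * r * r
    return areas


def sasa_total(
    s: Structure | tuple[np.ndarray, np.ndarray],
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> float:
    return float(compute_sasa(s, probe_radius, n_points).sum())
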