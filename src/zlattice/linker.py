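"""Tandem-domain linker feasibility.

Two covalently linked Zalpha-family domains of one protein can only occupy a
pair of binding registers whose C-terminus -> N-terminus separation is
bridgeable by the inter-domain linker.  The minimal linker length is the
ceiling of that distance over the maximal span contributed per residue of an
extended chain (default 3.5 A, conservative; 3.8 A Calpha-Calpha is the
textbook fully-extended alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .placement import PlacedDomain

__all__ = [
    "LinkerReport",
    "termini_distance",
    "min_linker_residues",
    "rank_tandem_pairs",
    "DEFAULT_SPAN_PER_RESIDUE",
]

DEFAULT_SPAN_PER_RESIDUE = 3.5
ALT_SPAN_PER_RESIDUE = 3.8

#: straight-line path screen: a linker path passing closer than this to any
#: obstacle atom counts as blocked (approximate screen, off by default)
PATH_BLOCK_DISTANCE = 2.0


@dataclass(frozen=True)
class LinkerReport:
    pair: tuple[str, str]
    cterm_to_nterm_distance: float
    min_linker_residues: int
    feasible_at: int | None
    rank: int
    path_blocked: bool | None = None


def termini_distance(a: PlacedDomain, b: PlacedDomain) -> float:
    """Euclidean C-terminus(a) -> N-terminus(b) distance in angstrom."""
    if a.cterm is None or b.nterm is None:
        raise ValueError("both domains must expose terminal backbone positions")
    return float(np.linalg.norm(a.cterm - b.nterm))


def min_linker_residues(distance: float, span_per_residue: float = DEFAULT_SPAN_PER_RESIDUE) -> int:
    """Minimal residue count bridging ``distance`` at ``span_per_residue``."""
    if span_per_residue <= 0:
        raise ValueError("span_per_residue must be positive")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return math.ceil(distance / span_per_residue - 1e-12)


def _segment_blocked(p0: np.ndarray, p1: np.ndarray, obstacles: np.ndarray) -> bool:
    seg = p1 - p0
    L2 = float(seg @ seg)
    if L2 == 0:
        return False
    t = np.clip(((obstacles - p0) @ seg) / L2, 0.0, 1.0)
    closest = p0 + t[:, None] * seg
    d = np.linalg.norm(obstacles - closest, axis=1)
    return bool((d < PATH_BLOCK_DISTANCE).any())


def rank_tandem_pairs(
    domains: list[PlacedDomain],
    span_per_residue: float = DEFAULT_SPAN_PER_RESIDUE,
    residue_budget: int = 15,
    clash_check: bool = False,
    obstacle_coords: np.ndarray | None = None,
) -> list[LinkerReport]:
    """Rank every ordered C->N domain pair by required linker length.

    Pairs are sorted by minimal linker residues, then distance; rank 1 is the
    shortest (the topologically preferred tandem pair).  ``feasible_at`` is
    the residue budget when the pair fits inside it.  With ``clash_check`` a
    straight C->N segment is screened against ``obstacle_coords`` (e.g. the
    DNA heavy atoms) as an approximate path-obstruction flag.
    """
    if len(domains) < 2:
        raise ValueError("need at least 2 domains")
    rows = []
    for a in domains:
        for b in domains:
            if a.domain_id == b.domain_id:
                continue
            d = termini_distance(a, b)
            n = min_linker_residues(d, span_per_residue)
            blocked = None
            if clash_check and obstacle_coords is not None and len(obstacle_coords):
                blocked = _segment_blocked(a.cterm, b.nterm, obstacle_coords)
            rows.append(((a.domain_id, b.domain_id), d, n, blocked))
    rows.sort(key=lambda r: (r[2], r[1], r[0]))
    return [
        LinkerReport(
            pair=pair,
            cterm_to_nterm_distance=d,
            min_linker_residues=n,
            feasible_at=residue_budget if n <= residue_budget else None,
            rank=i + 1,
            path_blocked=blocked,
        )
        for i, (pair, d, n, blocked) in enumerate(rows)
    ]
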