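"""Enumeration of (s + o) domain arrangements and clash-free propagation.

An arrangement ``s + o`` places a domain every ``s`` bp along the reference
strand and every ``s`` bp along the second strand offset by ``o`` bp
(0 <= o < s).  ``o`` and ``s - o`` describe mirror-image lattices under
strand exchange and are flagged as equivalent.  Propagation asks whether the
lattice can tile an effectively infinite helix with no inter-domain steric
clash.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .placement import PlacedDomain, PoseRule, place_domain
from .zdna import BindingRegister, HelixFrame

__all__ = [
    "Arrangement",
    "ClashReport",
    "ArrangementScanResult",
    "enumerate_registers",
    "detect_clashes",
    "propagation_test",
    "scan_arrangements",
    "DEFAULT_CLASH_DISTANCE",
    "DEFAULT_WINDOW_BP",
]

#: heavy-atom inter-domain distance below which two domains clash
DEFAULT_CLASH_DISTANCE = 2.5
DEFAULT_WINDOW_BP = 48


@dataclass(frozen=True)
class Arrangement:
    """Binding-site lattice: spacing ``s`` bp on the reference strand and
    second-strand offset ``o`` bp, written ``"s + o"``."""

    s: int
    o: int

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("spacing s must be a positive integer")
        if not (0 <= self.o < self.s):
            raise ValueError("offset o must satisfy 0 <= o < s")

    @property
    def label(self) -> str:
        return f"{self.s} + {self.o}"

    @staticmethod
    def from_label(label: str) -> "Arrangement":
        m = re.fullmatch(r"\s*(\d+)\s*\+\s*(\d+)\s*", label)
        if not m:
            raise ValueError(f"cannot parse arrangement label {label!r}")
        return Arrangement(int(m.group(1)), int(m.group(2)))

    @property
    def strand_exchange_partner(self) -> "Arrangement":
        return Arrangement(self.s, (self.s - self.o) % self.s)

    @property
    def canonical_label(self) -> str:
        o = min(self.o, (self.s - self.o) % self.s)
        return f"{self.s} + {o}"


@dataclass(frozen=True)
class ClashReport:
    clashing_pairs: tuple
    threshold: float

    @property
    def is_clash_free(self) -> bool:
        return len(self.clashing_pairs) == 0


@dataclass
class ArrangementScanResult:
    rows: list[dict] = field(default_factory=list)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def propagating(self) -> list[str]:
        return [r["label"] for r in self.rows if r["propagates"]]

    def propagating_classes(self) -> list[str]:
        return sorted({r["canonical_label"] for r in self.rows if r["propagates"]})


def enumerate_registers(a: Arrangement, helix_length_bp: int) -> list[BindingRegister]:
    """Binding registers of an arrangement on a finite helix.

    Reference-strand registers sit at 0, s, 2s, ...; second-strand registers
    at o, o + s, ...; both within the helix.  Sorted by bp index then strand.
    """
    if helix_length_bp < 1:
        raise ValueError("helix_length_bp must be positive")
    regs = [
        BindingRegister(strand=1, anchor_bp_index=i)
        for i in range(0, helix_length_bp, a.s)
    ]
    regs += [
        BindingRegister(strand=2, anchor_bp_index=i)
        for i in range(a.o, helix_length_bp, a.s)
    ]
    return sorted(regs, key=lambda r: (r.anchor_bp_index, r.strand))


# ---------------------------------------------------------------------------
# clash detection
# ---------------------------------------------------------------------------

def _pair_min_distances(ca: np.ndarray, cb: np.ndarray, pairs: np.ndarray):
    d = np.linalg.norm(ca[pairs[:, 0]] - cb[pairs[:, 1]], axis=1)
    return d


def _candidates_all(ca: np.ndarray, cb: np.ndarray, cutoff: float) -> np.ndarray:
    ia, ib = np.meshgrid(np.arange(len(ca)), np.arange(len(cb)), indexing="ij")
    return np.column_stack([ia.ravel(), ib.ravel()])


def _candidates_grid(ca: np.ndarray, cb: np.ndarray, cutoff: float) -> np.ndarray:
    ta, tb = cKDTree(ca), cKDTree(cb)
    pairs = ta.query_ball_tree(tb, r=cutoff)
    out = [(i, j) for i, js in enumerate(pairs) for j in js]
    if not out:
        return np.zeros((0, 2), dtype=int)
    return np.array(out, dtype=int)


def detect_clashes(
    domains: list[PlacedDomain],
    d_clash: float = DEFAULT_CLASH_DISTANCE,
    method: str = "grid",
) -> ClashReport:
    """Report all inter-domain heavy-atom pairs closer than ``d_clash``.

    ``method="grid"`` prunes candidate pairs with a k-d tree; ``"all_pairs"``
    checks every pair.  Both end in the identical distance computation, so
    their reports are identical.
    """
    if len(domains) < 2:
        raise ValueError("clash detection needs at least 2 domains")
    heavy = [d.heavy()[0] for d in domains]
    for h in heavy:
        if not np.all(np.isfinite(h)):
            raise ValueError("non-finite coordinates in placed domain")
    cand_fn = _candidates_grid if method == "grid" else _candidates_all
    clashes = []
    for i in range(len(domains)):
        for j in range(i + 1, len(domains)):
            pairs = cand_fn(heavy[i], heavy[j], d_clash)
            if len(pairs) == 0:
                continue
            d = _pair_min_distances(heavy[i], heavy[j], pairs)
            mask = d < d_clash
            if not mask.any():
                continue
            clashes.append(
                (
                    domains[i].domain_id,
                    domains[j].domain_id,
                    float(d[mask].min()),
                    int(mask.sum()),
                )
            )
    return ClashReport(clashing_pairs=tuple(clashes), threshold=d_clash)


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def _required_window(a: Arrangement, frame: HelixFrame) -> int:
    return 2 * math.lcm(a.s, frame.period_bp)


def propagation_test(
    a: Arrangement,
    rule: PoseRule,
    frame: HelixFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    d_clash: float = DEFAULT_CLASH_DISTANCE,
) -> tuple[bool, ClashReport]:
    """Can the arrangement tile a long helix without inter-domain clashes?

    Domains are placed at every register inside ``window_bp`` on a
    pseudo-infinite helix; one extra helical period is tiled on each side so
    that edge domains see the same environment as interior ones.  The
    arrangement propagates iff the placed set is clash-free.
    """
    need = _required_window(a, frame)
    if window_bp < need:
        raise ValueError(
            f"window_bp={window_bp} too small for arrangement {a.label}: "
            f"needs >= 2 * lcm(s, period) = {need}"
        )
    margin = frame.period_bp
    lo, hi = -margin, window_bp + margin
    regs = []
    start1 = -((margin) // a.s + 1) * a.s
    for i in range(start1, hi + 1, a.s):
        if lo <= i <= hi:
            regs.append(BindingRegister(strand=1, anchor_bp_index=i))
    start2 = a.o - ((margin + a.s) // a.s) * a.s
    for i in range(start2, hi + 1, a.s):
        if lo <= i <= hi:
            regs.append(BindingRegister(strand=2, anchor_bp_index=i))
    domains = [place_domain(rule, frame, r) for r in regs]
    report = detect_clashes(domains, d_clash=d_clash)
    return report.is_clash_free, report


def scan_arrangements(
    s_values,
    rule: PoseRule,
    frame: HelixFrame,
    d_clash: float = DEFAULT_CLASH_DISTANCE,
    window_bp: int | None = None,
) -> ArrangementScanResult:
    """Propagation verdict for every (s, o) with s in ``s_values``.

    Strand-exchange equivalents (o and s - o) are both scanned and share a
    canonical label; by symmetry their verdicts agree.
    """
    s_values = list(s_values)
    if not s_values:
        raise ValueError("s_values must be non-empty")
    result = ArrangementScanResult()
    for s in s_values:
        for o in range(s):
            a = Arrangement(s, o)
            w = window_bp if window_bp is not None else max(
                DEFAULT_WINDOW_BP, _required_window(a, frame)
            )
            propagates, report = propagation_test(
                a, rule, frame, window_bp=w, d_clash=d_clash
            )
            first = report.clashing_pairs[0] if report.clashing_pairs else None
            result.rows.append(
                {
                    "label": a.label,
                    "s": s,
                    "o": o,
                    "canonical_label": a.canonical_label,
                    "propagates": propagates,
                    "first_clash": (
                        f"{first[0]}|{first[1]}@{first[2]:.2f}" if first else ""
                    ),
                    "domains_per_12bp": len(enumerate_registers(a, 12)),
                }
            )
    return result
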