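"""Idealized left-handed (CG)_n duplex construction and helix-frame fitting.

The helix is modeled as a screw lattice: base pair i is the image of base
pair 0 under a screw about a common axis (rotation ``i * twist_per_bp``,
negative for left-handed helices, translation ``i * rise_per_bp``).  Each
base pair carries an in-plane pseudo-dyad through the helix axis; the second
strand is the image of the first under a 180 degree rotation about the bp-0
dyad, which makes strand exchange an exact symmetry of the built duplex.

Nucleotides are rigid idealized templates: planar base rings with the
glycosidic torsion chi built in exactly (syn guanosine, anti cytidine, the
Z-form signature), and a sugar/phosphate arm constructed from internal
coordinates.  Inter-residue backbone linkage is approximate (templates are
rigid); base pairing, stacking geometry, chi and phosphate placement are the
modeled quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .geometry import RigidTransform, nerf, superpose, screw_decompose
from .nucleic import pair_duplex, DuplexMap, _is_purine
from .structure import AtomRecord, Chain, Residue, Structure, VDW_RADII

__all__ = [
    "HelixFrame",
    "BindingRegister",
    "build_ideal_zdna",
    "fit_helix_frame",
    "screw_transform",
    "register_transform",
    "DEFAULT_TWIST_PER_BP",
    "DEFAULT_RISE_PER_BP",
]

#: Canonical Z-form defaults: a 12 bp left-handed turn of -30 deg/bp and a
#: 3.7 A rise.  Config-pinned; override via HelixFrame.
DEFAULT_TWIST_PER_BP = -30.0
DEFAULT_RISE_PER_BP = 3.7
DEFAULT_PERIOD_BP = 12

#: built-in glycosidic torsions (degrees): purines syn, pyrimidines anti
CHI_SYN_PURINE = 68.0
CHI_ANTI_PYRIMIDINE = -159.0

_COMPLEMENT = {"C": "G", "G": "C", "A": "T", "T": "A"}


@dataclass(frozen=True)
class BindingRegister:
    """Base-pair position (0-based along the reference strand) and strand of
    an anchor syn-guanosine."""

    strand: int
    anchor_bp_index: int

    def __post_init__(self) -> None:
        if self.strand not in (1, 2):
            raise ValueError("strand must be 1 or 2")


@dataclass(frozen=True)
class HelixFrame:
    """Screw-axis description of a duplex.

    ``origin`` sits on the axis at base-pair 0; ``ref_x`` is the bp-0
    pseudo-dyad direction (perpendicular to the axis) used for second-strand
    placement.  ``dinucleotide_step_params`` optionally splits the helical
    repeat into two alternating (twist, rise) steps; ``twist_per_bp`` /
    ``rise_per_bp`` are then their means.
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    rise_per_bp: float = DEFAULT_RISE_PER_BP
    twist_per_bp: float = DEFAULT_TWIST_PER_BP
    dinucleotide_step_params: tuple[tuple[float, float], tuple[float, float]] | None = None
    period_bp: int = DEFAULT_PERIOD_BP
    ref_x: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        a = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("axis must be non-zero")
        a = a / n
        x = np.asarray(self.ref_x, dtype=float).reshape(3)
        x = x - (x @ a) * a
        nx = np.linalg.norm(x)
        if nx < 1e-9:
            raise ValueError("ref_x must not be parallel to the axis")
        x = x / nx
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axis", a)
        object.__setattr__(self, "ref_x", x)
        if self.dinucleotide_step_params is not None:
            (t0, r0), (t1, r1) = self.dinucleotide_step_params
            object.__setattr__(self, "twist_per_bp", (t0 + t1) / 2.0)
            object.__setattr__(self, "rise_per_bp", (r0 + r1) / 2.0)
        if self.twist_per_bp == 0:
            raise ValueError("twist_per_bp must be non-zero")
        closure = self.period_bp * abs(self.twist_per_bp)
        if abs(closure - 360.0) > 5.0:
            raise ValueError(
                f"period_bp * |twist_per_bp| = {closure:.2f} is not within 5 deg of 360"
            )

    @property
    def is_left_handed(self) -> bool:
        return self.twist_per_bp < 0

    # -- screw lattice -----------------------------------------------------
    def cumulative(self, k: int) -> tuple[float, float]:
        """(total twist deg, total rise A) over k bp steps from bp 0."""
        if self.dinucleotide_step_params is None:
            return k * self.twist_per_bp, k * self.rise_per_bp
        steps = self.dinucleotide_step_params
        theta = 0.0
        z = 0.0
        if k >= 0:
            for j in range(k):
                t, r = steps[j % 2]
                theta += t
                z += r
        else:
            for j in range(-1, k - 1, -1):
                t, r = steps[j % 2]
                theta -= t
                z -= r
        return theta, z

    def bp_transform(self, k: int) -> RigidTransform:
        """Screw taking base pair 0 to base pair k."""
        theta, z = self.cumulative(k)
        return RigidTransform.screw(self.axis, theta, z, point=self.origin)

    def dyad(self) -> RigidTransform:
        """180 deg rotation about the bp-0 pseudo-dyad (through the axis)."""
        return RigidTransform.from_axis_angle(self.ref_x, 180.0, point=self.origin)


def screw_transform(frame: HelixFrame, k: int) -> RigidTransform:
    """Rigid transform advancing k base-pair steps along the helix."""
    return frame.bp_transform(k)


def register_transform(frame: HelixFrame, register: BindingRegister) -> RigidTransform:
    """Rigid frame of a binding register.

    Strand-1 registers are screw images of the bp-0 frame; strand-2 registers
    apply the duplex pseudo-dyad before the screw, so a domain template bound
    on strand 1 maps onto the complementary strand with the same local
    geometry.
    """
    base = frame.bp_transform(register.anchor_bp_index)
    if register.strand == 1:
        return base
    return base @ frame.dyad()


# ---------------------------------------------------------------------------
# idealized nucleotide templates
# ---------------------------------------------------------------------------

# Design constants (angstrom, bp-local frame: helix axis = z through origin,
# bp pseudo-dyad = x, base planes ~ z=0).  Every base shares the same C1' and
# glycosidic-N position, in the spirit of the standard base reference frame,
# so a Watson-Crick pair is exactly the union of a base and the 180-degree
# x-rotation of its complement; bp midpoints then sit exactly on the dyad.
# The central WC-edge atoms (purine N1 / pyrimidine N3) are pinned at heights
# above the dyad summing to 2.9 A (the central H-bond); the split was chosen
# so the outer H-bond partners (O6/N4 and N2/O2) also land in H-bond range.
_C1_POINT = np.array([-2.477, 5.399, 0.0])
_GLYC_POINT = np.array([-1.289, 4.551, 0.0])
_WC_EDGE_Y_PURINE = 0.5552
_WC_EDGE_Y_PYRIMIDINE = 2.9 - _WC_EDGE_Y_PURINE

_RING_BOND = 1.37


def _pentagon_hexagon_purine(base: str = "G") -> dict[str, np.ndarray]:
    """2D purine scaffold: pentagon N9-C8-N7-C5-C4 fused to hexagon
    C4-N3-C2-N1-C6-C5, plus exocyclics (O6/N2 for G, N6 for A)."""
    r5 = _RING_BOND / (2.0 * np.sin(np.pi / 5.0))
    names5 = ["N9", "C8", "N7", "C5", "C4"]
    coords: dict[str, np.ndarray] = {}
    for k, nm in enumerate(names5):
        ang = np.deg2rad(90.0 + 72.0 * k)
        coords[nm] = r5 * np.array([np.cos(ang), np.sin(ang)])
    mid = (coords["C4"] + coords["C5"]) / 2.0
    u = mid / np.linalg.norm(mid)
    apothem = _RING_BOND * np.cos(np.pi / 6.0)
    c6 = mid + apothem * u
    # hexagon vertices at 60 deg steps, starting at C5
    a5 = np.arctan2(*(coords["C5"] - c6)[::-1])
    a4 = np.arctan2(*(coords["C4"] - c6)[::-1])
    # walk from C4 away from C5
    step = a4 - a5
    step = np.arctan2(np.sin(step), np.cos(step))  # signed 60 deg
    names_rest = ["N3", "C2", "N1", "C6"]
    for k, nm in enumerate(names_rest, start=1):
        ang = a4 + step * k
        coords[nm] = c6 + _RING_BOND * np.array([np.cos(ang), np.sin(ang)])
    exo = (("O6", "C6", 1.23), ("N2", "C2", 1.34)) if base == "G" else (("N6", "C6", 1.34),)
    for nm, parent, blen in exo:
        v = coords[parent] - c6
        coords[nm] = coords[parent] + blen * v / np.linalg.norm(v)
    # mirror so that, once the WC edge is oriented into the pair, O6 sits on
    # the major-groove side facing the pyrimidine N4
    return {nm: xy * np.array([1.0, -1.0]) for nm, xy in coords.items()}


def _hexagon_pyrimidine(base: str) -> dict[str, np.ndarray]:
    """2D pyrimidine scaffold N1-C2-N3-C4-C5-C6 with exocyclics."""
    coords: dict[str, np.ndarray] = {}
    for k, nm in enumerate(["N1", "C2", "N3", "C4", "C5", "C6"]):
        ang = np.deg2rad(90.0 + 60.0 * k)
        coords[nm] = _RING_BOND * np.array([np.cos(ang), np.sin(ang)])
    def exo(nm, parent, blen):
        v = coords[parent]
        coords[nm] = v + blen * v / np.linalg.norm(v)
    exo("O2", "C2", 1.23)
    if base == "C":
        exo("N4", "C4", 1.34)
    elif base in ("T", "U"):
        exo("O4", "C4", 1.23)
        if base == "T":
            exo("C7", "C5", 1.50)
    return coords


def _rot2(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _place_ring(
    ring2d: dict[str, np.ndarray], glyc: str, wc: str, wc_y: float
) -> dict[str, np.ndarray]:
    """Pin the glycosidic N at its shared frame position and rotate the ring
    in-plane so the central WC-edge atom sits at height ``wc_y`` with the
    ring extending toward +x (into the pair)."""
    g2 = ring2d[glyc]
    d = float(np.linalg.norm(ring2d[wc] - g2))
    # solve rotation: wc atom on circle of radius d around the glyc point
    dy = wc_y - _GLYC_POINT[1]
    if abs(dy) > d:
        raise ValueError("ring cannot reach the WC edge height")
    dx = np.sqrt(d * d - dy * dy)  # +x solution: edge toward the pair center
    target = _GLYC_POINT + np.array([dx, dy, 0.0])
    tvec = ring2d[wc] - g2
    dtheta = np.arctan2(dy, dx) - np.arctan2(tvec[1], tvec[0])
    R2 = _rot2(dtheta)
    out = {}
    for nm, xy in ring2d.items():
        p2 = R2 @ (xy - g2)
        out[nm] = _GLYC_POINT + np.array([p2[0], p2[1], 0.0])
    assert np.allclose(out[wc], target, atol=1e-9)
    return out


@lru_cache(maxsize=16)
def _nucleotide_template(base: str, chi: float) -> tuple[tuple[str, tuple[float, float, float]], ...]:
    """Full-atom idealized nucleotide in the bp-local frame (strand 1, bp 0)."""
    purine = base in ("A", "G")
    if purine:
        ring2d = _pentagon_hexagon_purine(base)
        glyc, wc, wc_y = "N9", "N1", _WC_EDGE_Y_PURINE
        chi_ref = "C4"  # chi = O4'-C1'-N9-C4
    else:
        ring2d = _hexagon_pyrimidine(base)
        glyc, wc, wc_y = "N1", "N3", _WC_EDGE_Y_PYRIMIDINE
        chi_ref = "C2"  # chi = O4'-C1'-N1-C2
    atoms = _place_ring(ring2d, glyc, wc, wc_y)
    c1 = _C1_POINT.copy()
    atoms["C1'"] = c1
    # sugar + backbone from internal coordinates; chi exact by construction
    a_ref = atoms[chi_ref]
    g = atoms[glyc]
    atoms["O4'"] = nerf(a_ref, g, c1, 1.42, 108.5, chi)
    atoms["C2'"] = nerf(a_ref, g, c1, 1.53, 114.0, chi + 120.0)
    # backbone torsions per base class, fitted once so that successive
    # rigid templates under the default screw leave near-bonded O3'(i) to
    # P(i+1) gaps and Z-DNA-like phosphate radii
    tC5, tO5, tP, tO3 = (
        (-83.94, 20.86, -162.73, -174.0) if purine else (56.68, 80.78, -58.41, 147.0)
    )
    atoms["C3'"] = nerf(atoms["O4'"], c1, atoms["C2'"], 1.53, 101.5, -35.0)
    atoms["C4'"] = nerf(c1, atoms["C2'"], atoms["C3'"], 1.53, 102.5, 35.0)
    atoms["C5'"] = nerf(atoms["C2'"], atoms["C3'"], atoms["C4'"], 1.51, 115.0, tC5)
    atoms["O5'"] = nerf(atoms["C3'"], atoms["C4'"], atoms["C5'"], 1.42, 110.0, tO5)
    atoms["P"] = nerf(atoms["C4'"], atoms["C5'"], atoms["O5'"], 1.60, 121.0, tP)
    atoms["OP1"] = nerf(atoms["C5'"], atoms["O5'"], atoms["P"], 1.48, 107.0, -120.0)
    atoms["OP2"] = nerf(atoms["C5'"], atoms["O5'"], atoms["P"], 1.48, 107.0, 123.0)
    atoms["O3'"] = nerf(atoms["C5'"], atoms["C4'"], atoms["C3'"], 1.42, 110.0, tO3)
    order = [
        "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
    ]
    if purine:
        order += ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6", "O6", "N2", "N6"]
    else:
        order += ["N1", "C2", "O2", "N3", "C4", "C5", "C6"]
        if base == "C":
            order.append("N4")
        elif base in ("T", "U"):
            order.append("O4")
            if base == "T":
                order.append("C7")
    order = [nm for nm in order if nm in atoms]
    return tuple((nm, tuple(atoms[nm])) for nm in order)


def _make_residue(base: str, number: int, chain_id: str, pose: RigidTransform,
                  chi: float, serial_start: int) -> tuple[Residue, int]:
    resname = "D" + base
    res = Residue(resname, number)
    serial = serial_start
    for nm, xyz in _nucleotide_template(base, chi):
        serial += 1
        pos = pose.apply(np.array(xyz))
        el = nm[0]
        res.atoms.append(
            AtomRecord(
                serial=serial, name=nm, element=el, residue_name=resname,
                residue_number=number, chain_id=chain_id, position=pos,
                vdw_radius=VDW_RADII.get(el, 1.70),
            )
        )
    return res, serial


def _validate_sequence(sequence: str) -> tuple[str, bool]:
    seq = sequence.strip().upper()
    overhang = False
    if seq.startswith("T"):
        overhang = True
        seq = seq[1:]
    if len(seq) < 2:
        raise ValueError("sequence must contain at least 2 bp after any T overhang")
    if any(b not in ("C", "G") for b in seq):
        raise ValueError(
            "Z-form builder accepts strict C/G alternation (optional leading T)"
        )
    for a, b in zip(seq, seq[1:]):
        if a == b:
            raise ValueError(
                f"sequence is not a strict pyrimidine/purine alternation ({a}{b}); "
                "the Z conformation requires alternating Py/Pu"
            )
    return seq, overhang


def build_ideal_zdna(
    sequence: str,
    frame: HelixFrame | None = None,
    chain_ids: tuple[str, str] = ("A", "B"),
    chi_syn: float = CHI_SYN_PURINE,
    chi_anti: float = CHI_ANTI_PYRIMIDINE,
) -> tuple[Structure, HelixFrame]:
    """Build an idealized left-handed duplex for an alternating C/G sequence.

    ``sequence`` is the reference strand 5'->3' (an optional leading T is
    treated as an unpaired overhang, as in the T(CG)_n crystallization
    constructs, and excluded from bp indexing).  Returns the duplex and the
    frame that generated it; ``fit_helix_frame`` on the result round-trips
    the frame parameters.
    """
    core, overhang = _validate_sequence(sequence)
    if frame is None:
        frame = HelixFrame()
    n = len(core)
    dyad = frame.dyad()

    def chi_for(base: str) -> float:
        return chi_syn if base in ("A", "G") else chi_anti

    serial = 0
    chain1 = Chain(chain_ids[0])
    chain2 = Chain(chain_ids[1])
    num = 0
    if overhang:
        num += 1
        res, serial = _make_residue(
            "T", num, chain1.id, frame.bp_transform(-1), chi_anti, serial
        )
        chain1.residues.append(res)
    for i, base in enumerate(core):
        num_i = num + i + 1
        res, serial = _make_residue(
            base, num_i, chain1.id, frame.bp_transform(i), chi_for(base), serial
        )
        chain1.residues.append(res)
    # second strand, 5'->3': optional overhang T beyond bp n-1, then the
    # complement of the core read backwards; residue at 5' position k pairs
    # with bp n-1-k.
    num2 = 0
    if overhang:
        num2 += 1
        pose = frame.bp_transform(n) @ dyad
        res, serial = _make_residue("T", num2, chain2.id, pose, chi_anti, serial)
        chain2.residues.append(res)
    for k in range(n):
        i = n - 1 - k  # paired bp index
        base = _COMPLEMENT[core[i]]
        num_k = num2 + k + 1
        pose = frame.bp_transform(i) @ dyad
        res, serial = _make_residue(base, num_k, chain2.id, pose, chi_for(base), serial)
        chain2.residues.append(res)
    st = Structure(
        chains=[chain1, chain2],
        provenance=f"zlattice ideal Z-DNA {sequence.strip().upper()}",
    )
    return st, frame


# ---------------------------------------------------------------------------
# helix-frame fitting
# ---------------------------------------------------------------------------

def _bp_points(pair) -> np.ndarray:
    pts = []
    for res in (pair.strand1, pair.strand2):
        c1 = res.atom("C1'")
        gl = res.atom("N9") if _is_purine(res) else res.atom("N1")
        if c1 is None or gl is None:
            raise ValueError(
                f"base pair {pair.index}: residue {res.name}{res.number} lacks "
                "C1'/glycosidic atoms"
            )
        pts.append(c1.position)
        pts.append(gl.position)
    return np.array(pts)


def fit_helix_frame(
    dna: Structure,
    duplex: DuplexMap | None = None,
    reference_chain: str | None = None,
    split_tolerance: float = 1e-6,
) -> HelixFrame:
    """Least-squares screw-axis fit of a duplex.

    The axis comes from superposing each base pair onto the pair two steps
    along (the dinucleotide repeat) and averaging the screw axes; per-step
    twist and rise come from the azimuth/height of base-pair midpoints about
    that axis.  The twist sign encodes handedness (negative = left-handed).
    Requires at least 4 identified base pairs.
    """
    if duplex is None:
        duplex = pair_duplex(dna, reference_chain=reference_chain)
    n = len(duplex)
    if n < 4:
        raise ValueError(f"helix fitting needs >= 4 base pairs, got {n}")
    point_sets = [_bp_points(p) for p in duplex.pairs]
    mids = np.array([p.midpoint for p in duplex.pairs])

    axes = []
    axis_points = []
    for i in range(n - 2):
        sup = superpose(point_sets[i], point_sets[i + 2])
        ax, ang, rise, pt = screw_decompose(sup.transform)
        d = mids[i + 2] - mids[i]
        if ax @ d < 0:
            ax = -ax
        axes.append(ax)
        axis_points.append(pt)
    axis = np.mean(axes, axis=0)
    axis /= np.linalg.norm(axis)
    p0 = np.mean(axis_points, axis=0)

    rel = mids - p0
    heights = rel @ axis
    radial = rel - np.outer(heights, axis)
    r0 = radial[0]
    nr0 = np.linalg.norm(r0)
    if nr0 < 1e-6:
        raise ValueError("degenerate duplex: bp midpoints lie on the axis")
    e1 = r0 / nr0
    e2 = np.cross(axis, e1)
    phi = np.unwrap(np.arctan2(radial @ e2, radial @ e1))
    twists = np.degrees(np.diff(phi))
    rises = np.diff(heights)
    if np.any(rises <= 0):
        raise ValueError("base pairs are not monotonically ordered along the axis")
    even_t, odd_t = twists[0::2], twists[1::2]
    even_r, odd_r = rises[0::2], rises[1::2]
    steps = None
    if len(odd_t):
        # balanced per-class means (step counts can differ by one)
        twist_bp = float((np.mean(even_t) + np.mean(odd_t)) / 2.0)
        rise_bp = float((np.mean(even_r) + np.mean(odd_r)) / 2.0)
        if (
            abs(np.mean(even_t) - np.mean(odd_t)) > split_tolerance
            or abs(np.mean(even_r) - np.mean(odd_r)) > split_tolerance
        ):
            steps = (
                (float(np.mean(even_t)), float(np.mean(even_r))),
                (float(np.mean(odd_t)), float(np.mean(odd_r))),
            )
    else:
        twist_bp = float(np.mean(twists))
        rise_bp = float(np.mean(rises))
    period = max(2, int(round(360.0 / abs(twist_bp))))
    origin = p0 + heights[0] * axis
    return HelixFrame(
        origin=origin,
        axis=axis,
        rise_per_bp=rise_bp,
        twist_per_bp=twist_bp,
        dinucleotide_step_params=steps,
        period_bp=period,
        ref_x=e1,
    )
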