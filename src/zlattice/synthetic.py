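"""Synthetic fixtures: dummy binding domains and planted-truth complexes.

A dummy domain is a compact atom cloud standing in for the ~65-residue
winged-helix fold: a convex envelope (sphere or ellipsoid) of pseudo-atoms,
a tyrosine-like six-membered ring stacked over the syn-guanine of its
register (so anchor detection works on it), N/C termini at deterministic
interior positions, and optional planted DNA-contact atoms at exact target
distances.  Everything is reproducible from (spec, seed), and part of the
cloud is placed exactly on the envelope surface so that inter-domain clash
verdicts follow the analytic envelope criterion.

Dummy domains validate machinery; they are not shaped like the real domain
and are not meant to reproduce crystallographic numbers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .arrangements import Arrangement, enumerate_registers
from .placement import PlacedDomain, PoseRule, place_domain
from .sasa import fibonacci_sphere
from .structure import AtomRecord, Chain, Residue, Structure, VDW_RADII, write_structure
from .zdna import (
    BindingRegister,
    HelixFrame,
    build_ideal_zdna,
    register_transform,
    _nucleotide_template,
    CHI_SYN_PURINE,
)

__all__ = [
    "DummyDomainSpec",
    "FixtureManifest",
    "make_dummy_domain",
    "dummy_pose_rule",
    "make_fixture_complex",
    "DEFAULT_DOMAIN_RADIUS",
]

#: Default envelope radius: a compact ~65-residue domain occupies roughly
#: 65 x 135 A^3, i.e. an equivalent sphere of ~13 A radius.
DEFAULT_DOMAIN_RADIUS = 13.0

_RING_STACK_DISTANCE = 3.4
_RING_LATERAL_OFFSET = 1.0
_TYR_RING_NAMES = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]


@dataclass(frozen=True)
class DummyDomainSpec:
    n_atoms: int = 200
    envelope: str = "sphere"  # sphere | ellipsoid
    radii: tuple[float, ...] = (DEFAULT_DOMAIN_RADIUS,)
    nterm: tuple[float, float, float] | None = None  # register-local coords
    cterm: tuple[float, float, float] | None = None
    planted_contact_atoms: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.envelope not in ("sphere", "ellipsoid"):
            raise ValueError("envelope must be sphere or ellipsoid")
        if self.envelope == "sphere" and len(self.radii) != 1:
            raise ValueError("sphere takes a single radius")
        if self.envelope == "ellipsoid" and len(self.radii) != 3:
            raise ValueError("ellipsoid takes three radii")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if self.n_atoms < 20:
            raise ValueError("n_atoms must be >= 20")

    @property
    def bounding_radius(self) -> float:
        return max(self.radii)


def _anchor_geometry(frame: HelixFrame | None = None):
    """Ring centroid, envelope direction and envelope-center recipe in the
    register-local frame.

    The local frame is the bp-0 strand-1 register frame: the template
    guanosine of the helix builder lives there, so the ring is stacked a
    fixed distance above its base plane and nudged radially outward.  The
    envelope center sits at base-pair-plane height (the domain is centered
    beside its binding site, not above the stack), one envelope radius
    radially out from the ring.
    """
    g_atoms = {nm: np.array(xyz) for nm, xyz in _nucleotide_template("G", CHI_SYN_PURINE)}
    ring_names = ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"]
    centroid = np.mean([g_atoms[nm] for nm in ring_names], axis=0)
    radial = centroid.copy()
    radial[2] = 0.0
    radial /= np.linalg.norm(radial)
    ring_centroid = (
        centroid + _RING_STACK_DISTANCE * np.array([0.0, 0.0, 1.0])
        + _RING_LATERAL_OFFSET * radial
    )
    return g_atoms, ring_centroid, radial


def _envelope_center(ring_centroid: np.ndarray, radial: np.ndarray, radius: float) -> np.ndarray:
    center = ring_centroid + radius * radial
    center = center.copy()
    center[2] = ring_centroid[2] - _RING_STACK_DISTANCE  # base-plane height
    return center


def make_dummy_domain(spec: DummyDomainSpec, chain_id: str = "X") -> Structure:
    """Deterministic dummy domain in the register-local frame.

    Residue layout: GLY1 carries the N terminus, a TYR carries the anchor
    ring, ALA residues carry the envelope cloud (part of it exactly on the
    envelope surface), optional LYS residues carry planted contact atoms,
    and the final GLY carries the C terminus.
    """
    rng = np.random.default_rng(spec.seed)
    g_atoms, ring_centroid, radial = _anchor_geometry()
    radii = np.array(spec.radii if len(spec.radii) == 3 else spec.radii * 3)
    # local orthonormal basis: radial (away from helix), axis, and their cross
    e1 = radial
    e3 = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(e3, e1)
    basis = np.column_stack([e1, e2, e3])
    center = _envelope_center(ring_centroid, radial, radii[0])

    def to_world(local: np.ndarray) -> np.ndarray:
        return center + basis @ (radii * local)

    n_surface = min(spec.n_atoms // 2, 120)
    n_interior = spec.n_atoms - n_surface
    surface_pts = [to_world(u) for u in fibonacci_sphere(n_surface)]
    interior_pts = []
    while len(interior_pts) < n_interior:
        u = rng.uniform(-1.0, 1.0, size=3)
        if u @ u <= 1.0:
            interior_pts.append(to_world(u))

    chain = Chain(chain_id)
    serial = 0
    resnum = 0

    def add_residue(name: str, atom_specs):
        nonlocal serial, resnum
        resnum += 1
        res = Residue(name, resnum)
        for atom_name, pos in atom_specs:
            serial += 1
            el = atom_name[0]
            res.atoms.append(
                AtomRecord(
                    serial=serial, name=atom_name, element=el, residue_name=name,
                    residue_number=resnum, chain_id=chain_id, position=np.asarray(pos),
                    vdw_radius=VDW_RADII.get(el, 1.70),
                )
            )
        chain.residues.append(res)

    nterm = (
        np.asarray(spec.nterm) if spec.nterm is not None
        else center + basis @ (0.55 * radii * np.array([0.2, 0.6, 0.3]))
    )
    cterm = (
        np.asarray(spec.cterm) if spec.cterm is not None
        else center + basis @ (0.55 * radii * np.array([-0.5, -0.4, 0.4]))
    )
    add_residue("GLY", [("N", nterm), ("CA", nterm + np.array([1.2, 0.0, 0.0]))])

    # anchor tyrosine: planar hexagon parallel to the base plane
    ring = []
    for k, nm in enumerate(_TYR_RING_NAMES):
        ang = np.deg2rad(60.0 * k)
        ring.append(
            (nm, ring_centroid + 1.39 * (np.cos(ang) * e1 + np.sin(ang) * e2))
        )
    add_residue("TYR", [("CA", ring_centroid + 2.4 * e3)] + ring)

    for nm, target in spec.planted_contact_atoms:
        if target <= 0:
            raise ValueError(f"planted contact distance for {nm} must be positive")
        if target > 10.0:
            raise ValueError(
                f"planted contact distance {target} A for {nm} exceeds the "
                "10 A reach of a side-chain contact"
            )
        op1 = g_atoms["OP1"]
        outward = op1 - g_atoms["P"]  # away from the phosphate group
        pos = op1 + target * outward / np.linalg.norm(outward)
        add_residue("LYS", [("CA", pos + np.array([0.0, 0.0, 1.5])), (nm, pos)])

    for pos in surface_pts + interior_pts:
        add_residue("ALA", [("CA", pos)])

    add_residue("GLY", [("CA", cterm + np.array([-1.2, 0.0, 0.0])), ("C", cterm)])

    st = Structure(chains=[chain], provenance=f"zlattice dummy domain seed={spec.seed}")
    return st


def dummy_pose_rule(spec: DummyDomainSpec, frame: HelixFrame | None = None) -> PoseRule:
    """Pose rule whose template is a dummy domain bound at register (1, 0)."""
    if frame is None:
        frame = HelixFrame()
    domain = make_dummy_domain(spec)
    return PoseRule(
        template_chain=domain.chains[0],
        template_register=BindingRegister(strand=1, anchor_bp_index=0),
        frame=frame,
    )


# ---------------------------------------------------------------------------
# planted-truth complexes
# ---------------------------------------------------------------------------

@dataclass
class FixtureManifest:
    """Planted ground truth for a synthetic multi-domain complex."""

    arrangement: str
    helix_length_bp: int
    seed: int
    d_clash: float
    spec: dict
    files: dict = field(default_factory=dict)
    expected_registers: list = field(default_factory=list)  # (strand, bp)
    expected_anchor_count: int = 0
    expected_clash_pairs: list = field(default_factory=list)
    uncertain_pairs: list = field(default_factory=list)
    clash_margin: float = 0.0
    expected_termini_distances: dict = field(default_factory=dict)
    envelope_centers: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=lambda o: list(o))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _domain_chain_ids(n: int) -> list[str]:
    ids = []
    alphabet = "CDEFGHIJKLMNOPQRSTUVWXYZ"
    for i in range(n):
        ids.append(alphabet[i % len(alphabet)] + ("" if i < len(alphabet) else str(i)))
    return ids


def make_fixture_complex(
    a: Arrangement,
    spec: DummyDomainSpec,
    helix_length_bp: int = 12,
    seed: int | None = None,
    d_clash: float = 2.5,
    frame: HelixFrame | None = None,
    out_dir: str | Path | None = None,
) -> tuple[Structure, list[PlacedDomain], FixtureManifest]:
    """Build helix + placed dummy domains with planted ground truth.

    The manifest records the planted registers, the analytic envelope-overlap
    clash expectation (two spherical envelopes of radius R clash when their
    centers are closer than ``2 R + d_clash``), the worst-case margin of that
    criterion, and all pairwise termini distances computed directly from the
    register transforms.
    """
    if seed is not None:
        spec = dataclasses.replace(spec, seed=seed)
    if frame is None:
        frame = HelixFrame()
    n = helix_length_bp
    sequence = ("GC" * ((n + 1) // 2))[:n]
    helix, frame = build_ideal_zdna(sequence, frame=frame)
    registers = enumerate_registers(a, n)
    rule = dummy_pose_rule(spec, frame)
    chain_ids = _domain_chain_ids(len(registers))
    domains = []
    for reg, cid in zip(registers, chain_ids):
        d = place_domain(rule, frame, reg, domain_id=cid)
        d.chain.id = cid
        for r in d.chain.residues:
            for at in r.atoms:
                at.chain_id = cid
        domains.append(d)

    complex_st = helix.copy()
    complex_st.chains.extend(d.chain for d in domains)
    complex_st.provenance = (
        f"zlattice synthetic fixture {a.label} on {n} bp, seed={spec.seed}"
    )

    # certified analytic ground truth from envelopes, the deterministic
    # (seed-independent) atom skeleton, and the register transforms.  A pair
    # is a certain clash when two deterministic atoms are already closer
    # than d_clash; it is certainly clash-free when the deterministic atoms,
    # every deterministic-atom-to-envelope bound and the envelope-envelope
    # bound all clear d_clash.  Anything else is flagged uncertain (none of
    # the shipped fixture configurations produce uncertain pairs).
    _, ring_centroid, radial = _anchor_geometry()
    R = spec.bounding_radius
    local_center = _envelope_center(ring_centroid, radial, spec.radii[0])
    n_surface = min(spec.n_atoms // 2, 120)
    det_local = []
    ala_seen = 0
    for res in rule.template_chain.residues:
        if res.name == "ALA":
            ala_seen += 1
            if ala_seen > n_surface:
                continue  # seeded interior cloud
        det_local.extend(a.position for a in res.atoms)
    det_local = np.array(det_local)

    centers = {}
    det_world = {}
    for reg, cid in zip(registers, chain_ids):
        M = register_transform(frame, reg)
        centers[cid] = M.apply(local_center)
        det_world[cid] = M.apply(det_local)
    expected_clashes = []
    uncertain_pairs = []
    margin = np.inf
    ids = list(centers)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ca, cb = ids[i], ids[j]
            det_det = float(
                np.min(
                    np.linalg.norm(
                        det_world[ca][:, None, :] - det_world[cb][None, :, :], axis=2
                    )
                )
            )
            env_env = float(np.linalg.norm(centers[ca] - centers[cb])) - 2 * R
            det_env = min(
                float(np.min(np.linalg.norm(det_world[ca] - centers[cb], axis=1))) - R,
                float(np.min(np.linalg.norm(det_world[cb] - centers[ca], axis=1))) - R,
            )
            if det_det < d_clash:
                expected_clashes.append((ca, cb))
                margin = min(margin, d_clash - det_det)
            elif min(det_det, env_env, det_env) >= d_clash:
                margin = min(margin, min(det_det, env_env, det_env) - d_clash)
            else:
                uncertain_pairs.append((ca, cb))
    termini = {}
    for da in domains:
        for db in domains:
            if da.domain_id != db.domain_id:
                termini[f"{da.domain_id}->{db.domain_id}"] = float(
                    np.linalg.norm(da.cterm - db.nterm)
                )

    manifest = FixtureManifest(
        arrangement=a.label,
        helix_length_bp=n,
        seed=spec.seed,
        d_clash=d_clash,
        spec={
            "n_atoms": spec.n_atoms,
            "envelope": spec.envelope,
            "radii": list(spec.radii),
        },
        expected_registers=[(r.strand, r.anchor_bp_index) for r in registers],
        expected_anchor_count=len(registers),
        expected_clash_pairs=expected_clashes,
        uncertain_pairs=uncertain_pairs,
        clash_margin=float(margin),
        expected_termini_distances=termini,
        envelope_centers={k: list(map(float, v)) for k, v in centers.items()},
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pdb_path = out_dir / f"fixture_{a.s}p{a.o}_{n}bp_seed{spec.seed}.pdb"
        write_structure(complex_st, pdb_path)
        man_path = pdb_path.with_suffix(".json")
        manifest.files = {"complex": str(pdb_path), "manifest": str(man_path)}
        manifest.write(man_path)

    return complex_st, domains, manifest
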