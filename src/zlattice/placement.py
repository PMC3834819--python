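"""Anchor detection and rigid placement of domains at binding registers.

A Zalpha-family domain reads its register from the CH-pi stack of a tyrosine
ring on a syn-guanine base.  Detection uses standard stacking criteria
(ring-centroid distance and ring-normal angle); the derived pose rule
expresses the whole domain rigidly in the local frame of its anchor register
so that copies can be placed at any register of any helix frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RigidTransform
from .nucleic import (
    DuplexMap,
    base_centroid,
    base_normal,
    glycosidic_chi,
    one_letter,
    pair_duplex,
)
from .structure import Chain, Residue, Structure
from .zdna import BindingRegister, HelixFrame, register_transform

__all__ = [
    "AnchorRecord",
    "PoseRule",
    "PlacedDomain",
    "detect_anchor",
    "derive_pose_rule",
    "place_domain",
    "CHPI_MAX_CENTROID_DISTANCE",
    "CHPI_MAX_NORMAL_ANGLE",
]

#: CH-pi stacking criteria (config-exposed): tyrosine ring centroid within
#: this distance of the guanine ring centroid, ring normals within this angle.
CHPI_MAX_CENTROID_DISTANCE = 4.5
CHPI_MAX_NORMAL_ANGLE = 30.0

_TYR_RING = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]


@dataclass(frozen=True)
class AnchorRecord:
    """One tyrosine / syn-guanosine CH-pi anchor."""

    tyr_residue: tuple[str, int]
    g_residue: tuple[str, int]
    chi: float
    ring_centroid_distance: float
    normal_angle: float = 0.0
    register: BindingRegister | None = None
    alternates: tuple = ()


@dataclass
class PoseRule:
    """Rigid pose of a template domain relative to its anchor register."""

    template_chain: Chain
    template_register: BindingRegister
    frame: HelixFrame

    @property
    def anchor_to_domain(self) -> RigidTransform:
        """World -> register-local transform of the template's own anchor."""
        return register_transform(self.frame, self.template_register).inverse()

    def template_coords(self) -> np.ndarray:
        return np.array(
            [a.position for r in self.template_chain.residues for a in r.atoms]
        )


@dataclass
class PlacedDomain:
    """A rigid copy of the template positioned at a binding register."""

    domain_id: str
    register: BindingRegister
    pose: RigidTransform
    chain: Chain
    nterm: np.ndarray
    cterm: np.ndarray

    @property
    def atoms(self):
        return [a for r in self.chain.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def heavy(self) -> tuple[np.ndarray, list]:
        atoms = [a for a in self.atoms if a.element.upper() != "H"]
        return np.array([a.position for a in atoms]), atoms


def _tyr_ring(res: Residue):
    atoms = [res.atom(n) for n in _TYR_RING]
    atoms = [a for a in atoms if a is not None]
    if len(atoms) < 5:
        return None
    pts = np.array([a.position for a in atoms])
    centroid = pts.mean(axis=0)
    c = pts - centroid
    _, _, vt = np.linalg.svd(c)
    return centroid, vt[2] / np.linalg.norm(vt[2])


def _normal_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    cosv = abs(float(n1 @ n2))
    return float(np.degrees(np.arccos(min(1.0, cosv))))


def detect_anchor(
    complex: Structure,
    tyr_hint: tuple[str, int] | None = None,
    duplex: DuplexMap | None = None,
    max_centroid_distance: float = CHPI_MAX_CENTROID_DISTANCE,
    max_normal_angle: float = CHPI_MAX_NORMAL_ANGLE,
) -> list[AnchorRecord]:
    """Find tyrosine / syn-guanine CH-pi anchors, one per protein chain.

    For every protein chain, every tyrosine ring is tested against every
    syn-guanosine base; the minimum-distance hit within the stacking criteria
    becomes that chain's anchor and other hits are reported as alternates.
    Chains with no hit are omitted (an empty list is not an error).  Output
    is ordered by chain id.
    """
    protein_chains = complex.protein_chains()
    nucleic = complex.nucleic_chains()
    if not protein_chains or not nucleic:
        raise ValueError("anchor detection needs >= 1 protein chain and a nucleic chain")
    if duplex is None and len(nucleic) >= 2:
        try:
            duplex = pair_duplex(complex)
        except ValueError:
            duplex = None

    # collect syn guanines once
    syn_gs = []
    for ch in nucleic:
        for res in ch.residues:
            if res.is_water or one_letter(res) != "G":
                continue
            try:
                chi, label = glycosidic_chi(res)
            except ValueError:
                continue
            if label != "syn":
                continue
            syn_gs.append((ch.id, res, chi, base_centroid(res), base_normal(res)))

    records: list[AnchorRecord] = []
    for ch in sorted(protein_chains, key=lambda c: c.id):
        hits = []
        for res in ch.residues:
            if res.name.strip().upper() != "TYR":
                continue
            if tyr_hint is not None and (ch.id, res.number) != tyr_hint:
                continue
            ring = _tyr_ring(res)
            if ring is None:
                continue
            t_centroid, t_normal = ring
            for g_chain, g_res, chi, g_centroid, g_normal in syn_gs:
                d = float(np.linalg.norm(t_centroid - g_centroid))
                ang = _normal_angle(t_normal, g_normal)
                if d <= max_centroid_distance and ang <= max_normal_angle:
                    hits.append((d, ang, res, g_chain, g_res, chi))
        if not hits:
            continue
        hits.sort(key=lambda h: h[0])
        d, ang, tyr, g_chain, g_res, chi = hits[0]
        register = None
        if duplex is not None:
            hit = duplex.bp_index_of(g_chain, g_res.number)
            if hit is not None:
                register = BindingRegister(strand=hit[1], anchor_bp_index=hit[0])
        records.append(
            AnchorRecord(
                tyr_residue=(ch.id, tyr.number),
                g_residue=(g_chain, g_res.number),
                chi=chi,
                ring_centroid_distance=d,
                normal_angle=ang,
                register=register,
                alternates=tuple(
                    ((h[4].number, h[3]), round(h[0], 3)) for h in hits[1:]
                ),
            )
        )
    return records


def derive_pose_rule(
    complex: Structure,
    anchor: AnchorRecord,
    frame: HelixFrame,
    duplex: DuplexMap | None = None,
) -> PoseRule:
    """Express the anchored domain rigidly in its register-local frame."""
    if duplex is None:
        duplex = pair_duplex(complex)
    register = anchor.register
    if register is None:
        hit = duplex.bp_index_of(*anchor.g_residue)
        if hit is None:
            raise ValueError(
                f"anchor guanosine {anchor.g_residue} is not part of the duplex "
                "used for the helix frame"
            )
        register = BindingRegister(strand=hit[1], anchor_bp_index=hit[0])
    chain = complex.chain(anchor.tyr_residue[0])
    if chain is None:
        raise ValueError(f"no chain {anchor.tyr_residue[0]!r} in complex")
    return PoseRule(
        template_chain=chain.copy(), template_register=register, frame=frame
    )


def _termini(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    first, last = chain.residues[0], chain.residues[-1]
    n_at = first.atom("N") or first.atoms[0]
    c_at = last.atom("C") or last.atoms[-1]
    return n_at.position.copy(), c_at.position.copy()


def place_domain(
    rule: PoseRule,
    frame: HelixFrame,
    register: BindingRegister,
    domain_id: str | None = None,
    helix_length_bp: int | None = None,
) -> PlacedDomain:
    """Place a rigid copy of the template at a binding register.

    Strand-2 registers apply the duplex pseudo-dyad before the screw, so the
    copy binds the complementary strand.  ``helix_length_bp``, when given,
    bounds the register.
    """
    if helix_length_bp is not None and not (
        0 <= register.anchor_bp_index < helix_length_bp
    ):
        raise ValueError(
            f"register {register.anchor_bp_index} outside helix of "
            f"{helix_length_bp} bp"
        )
    M = register_transform(frame, register) @ rule.anchor_to_domain
    chain = rule.template_chain.copy()
    for r in chain.residues:
        for a in r.atoms:
            a.position = M.apply(a.position)
    nterm, cterm = _termini(chain)
    if domain_id is None:
        domain_id = f"s{register.strand}r{register.anchor_bp_index}"
    return PlacedDomain(
        domain_id=domain_id,
        register=register,
        pose=M,
        chain=chain,
        nterm=nterm,
        cterm=cterm,
    )
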