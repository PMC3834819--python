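"""High-level analysis recipes.

These compose the library stages into the analyses a user runs on a
Zalpha/Z-DNA co-crystal structure: anchor-register mapping, backbone
superposition against a reference domain, second-strand interface area,
arrangement scanning and tandem-linker ranking.  They accept any parsed
:class:`~zlattice.structure.Structure`, whether read from a deposited file
or built synthetically.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

import numpy as np

from .arrangements import ArrangementScanResult, scan_arrangements
from .contacts import InterfaceReport, interface_area
from .geometry import SuperpositionResult, superpose
from .linker import LinkerReport, rank_tandem_pairs
from .nucleic import pair_duplex
from .placement import AnchorRecord, detect_anchor, derive_pose_rule
from .structure import Chain, Structure
from .zdna import HelixFrame, fit_helix_frame

__all__ = [
    "backbone_superpose",
    "anchor_register_spacings",
    "second_strand_interface",
    "arrangement_scan_from_complex",
    "tandem_linker_ranking",
    "ComplexAnalysis",
    "analyze_complex",
]

_BACKBONE = ("N", "CA", "C")


def _backbone_residues(chain: Chain):
    out = []
    for r in chain.residues:
        atoms = [r.atom(n) for n in _BACKBONE]
        if all(a is not None for a in atoms):
            out.append((r, atoms))
    if len(out) < 3:
        # reduced models: fall back to CA-only matching
        out = [
            (r, [r.atom("CA")]) for r in chain.residues if r.atom("CA") is not None
        ]
    return out


def backbone_superpose(
    mobile: Structure | Chain,
    reference: Structure | Chain,
    mobile_chain: str | None = None,
    reference_chain: str | None = None,
) -> tuple[SuperpositionResult, int]:
    """Superpose protein backbones (N, CA, C) after sequence matching.

    Residues are paired by aligning the two residue-name sequences
    (longest-common-subsequence blocks), keeping only residues with a
    complete backbone triplet (or, for reduced models, a CA atom).  Returns
    the superposition and the number of matched residues;
    ``result.n_atom_pairs`` is 3x that count for full-backbone models.
    """

    def pick(obj, cid):
        if isinstance(obj, Chain):
            return obj
        chains = obj.protein_chains()
        if cid is not None:
            c = obj.chain(cid)
            if c is None:
                raise ValueError(f"no chain {cid!r}")
            return c
        if not chains:
            raise ValueError("no protein chain found")
        return chains[0]

    cm = pick(mobile, mobile_chain)
    cr = pick(reference, reference_chain)
    rm = _backbone_residues(cm)
    rr = _backbone_residues(cr)
    seq_m = [r.name for r, _ in rm]
    seq_r = [r.name for r, _ in rr]
    sm = difflib.SequenceMatcher(a=seq_m, b=seq_r, autojunk=False)
    pairs = []
    for block in sm.get_matching_blocks():
        for k in range(block.size):
            pairs.append((rm[block.a + k], rr[block.b + k]))
    if len(pairs) < 3:
        raise ValueError("fewer than 3 matched backbone residues")
    pm = np.array([a.position for (_, atoms), _ in pairs for a in atoms])
    pr = np.array([a.position for _, (_, atoms) in pairs for a in atoms])
    return superpose(pm, pr), len(pairs)


def anchor_register_spacings(anchors: list[AnchorRecord]) -> dict[int, list[int]]:
    """Per-strand sorted gaps (bp) between consecutive anchor registers."""
    by_strand: dict[int, list[int]] = {}
    for a in anchors:
        if a.register is None:
            continue
        by_strand.setdefault(a.register.strand, []).append(a.register.anchor_bp_index)
    return {
        s: [int(d) for d in np.diff(sorted(idx))]
        for s, idx in by_strand.items()
        if len(idx) > 1
    }


def second_strand_interface(
    complex_st: Structure,
    monomer_chain: str,
    anchor: AnchorRecord,
    probe: float = 1.4,
    n_points: int = 960,
) -> InterfaceReport:
    """Buried area between one monomer and the DNA strand opposite its anchor."""
    duplex = pair_duplex(complex_st)
    anchor_chain = anchor.g_residue[0]
    second = (
        duplex.second_chain
        if anchor_chain == duplex.reference_chain
        else duplex.reference_chain
    )
    mono = complex_st.chain(monomer_chain)
    strand = complex_st.chain(second)
    if mono is None or strand is None:
        raise ValueError("monomer or second-strand chain missing")
    ga = [a for r in mono.residues if not r.is_water for a in r.atoms]
    gb = [a for r in strand.residues if not r.is_water for a in r.atoms]
    return interface_area(complex_st, ga, gb, probe=probe, n_points=n_points)


def arrangement_scan_from_complex(
    complex_st: Structure,
    s_values=range(3, 9),
    d_clash: float = 2.5,
    anchor_index: int = 0,
) -> ArrangementScanResult:
    """Fit the helix, derive a pose rule from one anchored monomer, and scan
    all (s, o) arrangements for clash-free propagation."""
    duplex = pair_duplex(complex_st)
    frame = fit_helix_frame(complex_st, duplex=duplex)
    anchors = detect_anchor(complex_st, duplex=duplex)
    if not anchors:
        raise ValueError("no anchors detected in complex")
    rule = derive_pose_rule(complex_st, anchors[anchor_index], frame, duplex=duplex)
    return scan_arrangements(s_values, rule, frame, d_clash=d_clash)


def tandem_linker_ranking(
    domains, span_per_residue: float = 3.5, residue_budget: int = 15,
    dna_structure: Structure | None = None,
) -> list[LinkerReport]:
    obstacles = None
    if dna_structure is not None:
        obstacles = np.array(
            [a.position for c in dna_structure.nucleic_chains()
             for r in c.residues for a in r.atoms]
        )
    return rank_tandem_pairs(
        domains,
        span_per_residue=span_per_residue,
        residue_budget=residue_budget,
        clash_check=obstacles is not None,
        obstacle_coords=obstacles,
    )


@dataclass
class ComplexAnalysis:
    anchors: list[AnchorRecord] = field(default_factory=list)
    spacings: dict = field(default_factory=dict)
    frame: HelixFrame | None = None
    n_protein_chains: int = 0
    n_bp: int = 0


def analyze_complex(complex_st: Structure) -> ComplexAnalysis:
    """Anchor map, register spacings and helix frame of a Zalpha/DNA complex."""
    duplex = pair_duplex(complex_st)
    frame = fit_helix_frame(complex_st, duplex=duplex)
    anchors = detect_anchor(complex_st, duplex=duplex)
    return ComplexAnalysis(
        anchors=anchors,
        spacings=anchor_register_spacings(anchors),
        frame=frame,
        n_protein_chains=len(complex_st.protein_chains()),
        n_bp=len(duplex),
    )
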