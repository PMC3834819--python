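"""Protein-DNA and protein-protein contact mapping and buried interfaces.

Contacts are typed by geometry on heavy atoms (the deposited structures
carry no hydrogens): hydrogen bonds from donor/acceptor atom tables within a
distance cutoff, generic van der Waals proximity, water-mediated bridges
(one ordered water within reach of both groups), salt bridges between
charged-group nitrogens and oxygens, and the CH-pi tyrosine/guanine stack.
Every DNA contact is classified against the anchor strand: *primary* for the
strand carrying the anchor syn-guanosine, *secondary* for its complement.

Interface size follows the paired-surface convention: buried surface area
BSA = SASA(A) + SASA(B) - SASA(A u B), interface area = BSA / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nucleic import base_centroid, base_normal, one_letter
from .placement import AnchorRecord, _tyr_ring
from .sasa import DEFAULT_POINTS, DEFAULT_PROBE, compute_sasa
from .structure import AtomRecord, Structure

__all__ = [
    "ContactCriteria",
    "ContactRecord",
    "InterfaceReport",
    "RESIDUE_ROLES",
    "find_contacts",
    "classify_strand",
    "protein_protein_interface",
    "interface_area",
]


@dataclass(frozen=True)
class ContactCriteria:
    """Heavy-atom distance cutoffs (angstrom) for contact typing."""

    hbond_max: float = 3.5
    vdw_max: float = 4.0
    water_bridge_max: float = 3.5
    saltbridge_max: float = 4.0
    chpi_centroid_max: float = 4.5
    chpi_normal_max_deg: float = 30.0

    def __post_init__(self) -> None:
        for name in ("hbond_max", "vdw_max", "water_bridge_max", "saltbridge_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hbond_max > self.vdw_max:
            raise ValueError("hbond_max must not exceed vdw_max")


@dataclass(frozen=True)
class ContactRecord:
    kind: str  # hbond | vdw | water_mediated | salt_bridge | ch_pi
    protein_residue: tuple[str, str, int]  # chain, resname, number
    partner: tuple[str, str, int]
    atoms: tuple[str, str]
    distances: tuple[float, ...]
    strand_class: str = "n/a"  # primary | secondary | protein-protein | n/a
    water: tuple[str, int] | None = None


@dataclass
class InterfaceReport:
    bsa_total: float
    interface_area: float
    per_residue: dict = field(default_factory=dict)


#: Residue roles at the Zalpha/Z-DNA interface of the modeled kinase domain:
#: the conserved recognition triad plus wing residue contacts on the primary
#: strand, the second-strand set, and the dimerization (protein-protein)
#: residues.  Arg42 genuinely appears in two roles (primary-strand DNA
#: contact and inter-monomer salt bridge).
RESIDUE_ROLES: dict[str, tuple[str, ...]] = {
    "triad": ("TYR45", "ASN41", "TRP65"),
    "primary": ("TYR45", "ASN41", "TRP65", "ARG42", "ARG62"),
    "secondary": ("GLN27", "PHE30", "LYS31", "LYS37"),
    "protein_protein": ("GLU36", "SER38", "THR39", "ARG42"),
}


# -- donor/acceptor typing (heavy atoms, no hydrogen placement) -------------

_PROTEIN_DONORS = {
    "*": {"N"},
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "TRP": {"NE1"},
}
_PROTEIN_ACCEPTORS = {
    "*": {"O", "OXT"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}
_DNA_ACCEPTORS = {
    "*": {"OP1", "OP2", "O5'", "O3'", "O4'", "N7", "N3", "O2", "O6", "O4"},
}
_DNA_DONORS = {
    "*": set(),
    "DG": {"N1", "N2"},
    "G": {"N1", "N2"},
    "DC": {"N4"},
    "C": {"N4"},
    "DA": {"N6"},
    "A": {"N6"},
    "DT": {"N3"},
    "T": {"N3"},
}
_POSITIVE_GROUPS = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"}}
_NEGATIVE_GROUPS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "*DNA*": {"OP1", "OP2"},
}


def _norm_name(a: AtomRecord) -> str:
    return a.name.strip().replace("*", "'")


def _atom_in(table: dict, a: AtomRecord) -> bool:
    nm = _norm_name(a)
    res = a.residue_name.strip().upper()
    return nm in table.get("*", set()) or nm in table.get(res, set())


def _is_donor(a: AtomRecord, nucleic: bool) -> bool:
    return _atom_in(_DNA_DONORS if nucleic else _PROTEIN_DONORS, a)


def _is_acceptor(a: AtomRecord, nucleic: bool) -> bool:
    return _atom_in(_DNA_ACCEPTORS if nucleic else _PROTEIN_ACCEPTORS, a)


def _is_positive(a: AtomRecord) -> bool:
    return _norm_name(a) in _POSITIVE_GROUPS.get(a.residue_name.strip().upper(), set())


def _is_negative(a: AtomRecord, nucleic: bool) -> bool:
    if nucleic:
        return _norm_name(a) in _NEGATIVE_GROUPS["*DNA*"]
    return _norm_name(a) in _NEGATIVE_GROUPS.get(a.residue_name.strip().upper(), set())


def _res_key(a: AtomRecord) -> tuple[str, str, int]:
    return (a.chain_id, a.residue_name.strip(), a.residue_number)


def _is_nucleic_atom(a: AtomRecord) -> bool:
    from .structure import NUCLEIC_NAMES

    return a.residue_name.strip().upper() in NUCLEIC_NAMES


def _sort_key(rec: ContactRecord):
    return (rec.protein_residue, rec.partner, rec.kind, rec.atoms)


def find_contacts(
    s: Structure,
    group_a: list[AtomRecord],
    group_b: list[AtomRecord],
    criteria: ContactCriteria = ContactCriteria(),
) -> list[ContactRecord]:
    """Typed contacts between two disjoint atom selections.

    Group A is treated as the protein side for record naming when it contains
    protein atoms.  Hydrogen bonds require a donor/acceptor pairing within
    ``hbond_max``; remaining heavy-atom pairs within ``vdw_max`` are reported
    once per residue pair as van der Waals contacts.  Waters of the parent
    structure within ``water_bridge_max`` of polar atoms in both groups
    produce water-mediated records.  Deterministic ordering by residue then
    atom names.
    """
    ids_a = {id(a) for a in group_a}
    if any(id(b) in ids_a for b in group_b):
        raise ValueError("groups must be disjoint")
    records: list[ContactRecord] = []
    heavy_a = [a for a in group_a if a.element.upper() != "H" and not _is_water_atom(a)]
    heavy_b = [b for b in group_b if b.element.upper() != "H" and not _is_water_atom(b)]
    if not heavy_a or not heavy_b:
        return []
    pa = np.array([a.position for a in heavy_a])
    pb = np.array([b.position for b in heavy_b])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)

    typed_respairs = set()
    vdw_respairs = {}
    for i, a in enumerate(heavy_a):
        for j, b in enumerate(heavy_b):
            dist = float(d[i, j])
            if dist > max(criteria.vdw_max, criteria.saltbridge_max):
                continue
            a_nuc, b_nuc = _is_nucleic_atom(a), _is_nucleic_atom(b)
            key = (_res_key(a), _res_key(b))
            # salt bridge: charged-group N/O pair
            if dist <= criteria.saltbridge_max and (
                (_is_positive(a) and _is_negative(b, b_nuc))
                or (_is_negative(a, a_nuc) and _is_positive(b))
            ):
                records.append(
                    ContactRecord(
                        kind="salt_bridge",
                        protein_residue=key[0],
                        partner=key[1],
                        atoms=(_norm_name(a), _norm_name(b)),
                        distances=(dist,),
                    )
                )
                typed_respairs.add(key)
            if dist <= criteria.hbond_max and (
                (_is_donor(a, a_nuc) and _is_acceptor(b, b_nuc))
                or (_is_acceptor(a, a_nuc) and _is_donor(b, b_nuc))
            ):
                records.append(
                    ContactRecord(
                        kind="hbond",
                        protein_residue=key[0],
                        partner=key[1],
                        atoms=(_norm_name(a), _norm_name(b)),
                        distances=(dist,),
                    )
                )
                typed_respairs.add(key)
            elif dist <= criteria.vdw_max:
                cur = vdw_respairs.get(key)
                if cur is None or dist < cur[0]:
                    vdw_respairs[key] = (dist, _norm_name(a), _norm_name(b))
    for key, (dist, na, nb) in vdw_respairs.items():
        if key in typed_respairs:
            continue
        records.append(
            ContactRecord(
                kind="vdw",
                protein_residue=key[0],
                partner=key[1],
                atoms=(na, nb),
                distances=(dist,),
            )
        )

    records.extend(_water_bridges(s, heavy_a, heavy_b, criteria))
    records.extend(_chpi_contacts(heavy_a, heavy_b, criteria))
    records.sort(key=_sort_key)
    return records


def _is_water_atom(a: AtomRecord) -> bool:
    from .structure import WATER_NAMES

    return a.residue_name.strip().upper() in WATER_NAMES


def _water_bridges(s, heavy_a, heavy_b, criteria) -> list[ContactRecord]:
    waters = []
    for c in s.chains:
        for r in c.residues:
            if r.is_water:
                o = r.atom("O") or (r.atoms[0] if r.atoms else None)
                if o is not None:
                    waters.append((c.id, r.number, o.position))
    if not waters:
        return []
    out = []
    polar_a = [a for a in heavy_a if a.element.upper() in ("N", "O")]
    polar_b = [b for b in heavy_b if b.element.upper() in ("N", "O")]
    for wc, wn, wpos in waters:
        best_a = best_b = None
        for a in polar_a:
            da = float(np.linalg.norm(a.position - wpos))
            if da <= criteria.water_bridge_max and (best_a is None or da < best_a[0]):
                best_a = (da, a)
        if best_a is None:
            continue
        for b in polar_b:
            db = float(np.linalg.norm(b.position - wpos))
            if db <= criteria.water_bridge_max and (best_b is None or db < best_b[0]):
                best_b = (db, b)
        if best_b is None:
            continue
        out.append(
            ContactRecord(
                kind="water_mediated",
                protein_residue=_res_key(best_a[1]),
                partner=_res_key(best_b[1]),
                atoms=(_norm_name(best_a[1]), _norm_name(best_b[1])),
                distances=(best_a[0], best_b[0]),
                water=(wc, wn),
            )
        )
    return out


def _group_residues(atoms):
    by_res = {}
    for a in atoms:
        by_res.setdefault(_res_key(a), []).append(a)
    return by_res


def _chpi_contacts(heavy_a, heavy_b, criteria) -> list[ContactRecord]:
    """Tyrosine-ring / guanine-base stacking contacts across the groups."""
    from .structure import Residue

    out = []

    def rebuild(atoms):
        res = Residue(atoms[0].residue_name, atoms[0].residue_number, list(atoms))
        return res

    for a_atoms_key, a_atoms in _group_residues(heavy_a).items():
        if a_atoms_key[1].upper() != "TYR":
            continue
        ring = _tyr_ring(rebuild(a_atoms))
        if ring is None:
            continue
        t_centroid, t_normal = ring
        for b_key, b_atoms in _group_residues(heavy_b).items():
            res_b = rebuild(b_atoms)
            if one_letter(res_b) != "G":
                continue
            try:
                g_centroid = base_centroid(res_b)
                g_normal = base_normal(res_b)
            except ValueError:
                continue
            dist = float(np.linalg.norm(t_centroid - g_centroid))
            ang = float(
                np.degrees(np.arccos(min(1.0, abs(float(t_normal @ g_normal)))))
            )
            if dist <= criteria.chpi_centroid_max and ang <= criteria.chpi_normal_max_deg:
                out.append(
                    ContactRecord(
                        kind="ch_pi",
                        protein_residue=a_atoms_key,
                        partner=b_key,
                        atoms=("ring", "ring"),
                        distances=(dist,),
                    )
                )
    return out


def classify_strand(
    contacts: list[ContactRecord],
    anchor: AnchorRecord,
    duplex_structure: Structure,
) -> list[ContactRecord]:
    """Label each DNA contact primary (anchor strand) or secondary.

    The primary strand is the chain holding the anchor syn-guanosine; its
    complement is secondary.  Contacts to nucleotides on neither chain are
    labeled ``n/a``.
    """
    import warnings
    from dataclasses import replace

    anchor_chain = anchor.g_residue[0]
    nucleic_ids = {c.id for c in duplex_structure.nucleic_chains()}
    out = []
    for rec in contacts:
        chain_id = rec.partner[0]
        from .structure import NUCLEIC_NAMES

        partner_is_dna = rec.partner[1].strip().upper() in NUCLEIC_NAMES
        if not partner_is_dna:
            out.append(rec)
            continue
        if chain_id == anchor_chain:
            cls = "primary"
        elif chain_id in nucleic_ids:
            cls = "secondary"
        else:
            cls = "n/a"
            warnings.warn(
                f"contact partner {rec.partner} is outside the duplex", stacklevel=2
            )
        out.append(replace(rec, strand_class=cls))
    return out


def protein_protein_interface(
    s: Structure,
    chain_a: str,
    chain_b: str,
    criteria: ContactCriteria = ContactCriteria(),
) -> list[ContactRecord]:
    """Salt bridges and hydrogen bonds across a protein-protein interface."""
    ca, cb = s.chain(chain_a), s.chain(chain_b)
    if ca is None or cb is None:
        raise ValueError(f"chains {chain_a!r}/{chain_b!r} not both present")
    atoms_a = [a for r in ca.residues for a in r.atoms]
    atoms_b = [a for r in cb.residues for a in r.atoms]
    recs = find_contacts(s, atoms_a, atoms_b, criteria)
    from dataclasses import replace

    return [
        replace(r, strand_class="protein-protein")
        for r in recs
        if r.kind in ("hbond", "salt_bridge")
    ]


def interface_area(
    s: Structure,
    group_a: list[AtomRecord],
    group_b: list[AtomRecord],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> InterfaceReport:
    """Buried surface between two selections.

    ``bsa_total = SASA(A) + SASA(B) - SASA(A u B)`` with per-residue burial
    contributions; ``interface_area`` is the half-sum (paired-surface
    convention).  Symmetric in its arguments by construction.
    """
    ids_a = {id(a) for a in group_a}
    if any(id(b) in ids_a for b in group_b):
        raise ValueError("overlapping selections")
    heavy_a = [a for a in group_a if a.element.upper() != "H" and not _is_water_atom(a)]
    heavy_b = [b for b in group_b if b.element.upper() != "H" and not _is_water_atom(b)]

    def sasa_of(atoms):
        coords = np.array([a.position for a in atoms])
        radii = np.array([a.vdw_radius for a in atoms])
        return compute_sasa((coords, radii), probe_radius=probe, n_points=n_points)

    sa = sasa_of(heavy_a)
    sb = sasa_of(heavy_b)
    s_ab = sasa_of(heavy_a + heavy_b)
    buried = np.concatenate([sa, sb]) - s_ab
    bsa = float(buried.sum())
    per_res: dict = {}
    for a, contrib in zip(heavy_a + heavy_b, buried):
        key = _res_key(a)
        per_res[key] = per_res.get(key, 0.0) + float(contrib)
    return InterfaceReport(
        bsa_total=bsa, interface_area=bsa / 2.0, per_residue=per_res
    )
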