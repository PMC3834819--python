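"""Nucleotide geometry: glycosidic torsions, base rings, duplex pairing.

The glycosidic torsion chi is O4'-C1'-N9-C4 for purines and O4'-C1'-N1-C2 for
pyrimidines; chi in (-90, +90] is labeled *syn*, the rotamer diagnostic of the
Z conformation for guanosine, anything else *anti*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import dihedral
from .structure import Chain, Residue, Structure

__all__ = [
    "PURINES",
    "PYRIMIDINES",
    "glycosidic_chi",
    "base_ring_atoms",
    "base_centroid",
    "base_normal",
    "BasePair",
    "DuplexMap",
    "pair_duplex",
]

PURINES = {"DA", "DG", "A", "G", "ADE", "GUA"}
PYRIMIDINES = {"DC", "DT", "DU", "C", "T", "U", "CYT", "THY", "URA"}

#: default syn window on chi, degrees (half-open: lo < chi <= hi)
SYN_WINDOW = (-90.0, 90.0)

_PURINE_RING = ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"]
_PYRIMIDINE_RING = ["N1", "C2", "N3", "C4", "C5", "C6"]


def _is_purine(res: Residue) -> bool:
    name = res.name.strip().upper()
    if name in PURINES:
        return True
    if name in PYRIMIDINES:
        return False
    # fall back on atom content
    return res.atom("N9") is not None


def glycosidic_chi(
    nucleotide: Residue, syn_window: tuple[float, float] = SYN_WINDOW
) -> tuple[float, str]:
    """Glycosidic torsion (degrees) and its syn/anti label."""
    if _is_purine(nucleotide):
        names = ("O4'", "C1'", "N9", "C4")
    else:
        names = ("O4'", "C1'", "N1", "C2")
    pts = []
    for n in names:
        a = nucleotide.atom(n)
        if a is None:
            raise ValueError(
                f"residue {nucleotide.name}{nucleotide.number} is missing atom {n}"
            )
        pts.append(a.position)
    chi = dihedral(*pts)
    label = "syn" if syn_window[0] < chi <= syn_window[1] else "anti"
    return chi, label


def base_ring_atoms(res: Residue) -> list:
    names = _PURINE_RING if _is_purine(res) else _PYRIMIDINE_RING
    atoms = [res.atom(n) for n in names]
    return [a for a in atoms if a is not None]


def base_centroid(res: Residue) -> np.ndarray:
    atoms = base_ring_atoms(res)
    if len(atoms) < 3:
        raise ValueError(
            f"residue {res.name}{res.number} has too few base ring atoms"
        )
    return np.mean([a.position for a in atoms], axis=0)


def base_normal(res: Residue) -> np.ndarray:
    """Unit normal of the best plane through the base ring atoms."""
    atoms = base_ring_atoms(res)
    pts = np.array([a.position for a in atoms])
    c = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(c)
    n = vt[2]
    return n / np.linalg.norm(n)


# ---------------------------------------------------------------------------
# duplex pairing
# ---------------------------------------------------------------------------

#: Watson-Crick complements (one-letter, DNA)
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}


def one_letter(res: Residue) -> str:
    name = res.name.strip().upper()
    return name[-1] if name else "?"


@dataclass(frozen=True)
class BasePair:
    """One Watson-Crick pair: bp index along the reference strand."""

    index: int
    strand1: Residue
    strand2: Residue

    @property
    def c1_positions(self) -> tuple[np.ndarray, np.ndarray]:
        a1 = self.strand1.atom("C1'")
        a2 = self.strand2.atom("C1'")
        if a1 is None or a2 is None:
            raise ValueError(f"base pair {self.index} is missing a C1' atom")
        return a1.position, a2.position

    @property
    def midpoint(self) -> np.ndarray:
        p1, p2 = self.c1_positions
        return (p1 + p2) / 2.0


@dataclass
class DuplexMap:
    """Antiparallel pairing of two nucleic chains, indexed 0-based 5'->3'
    along the reference strand.  Overhang (unpaired) residues are excluded
    from base-pair indexing."""

    reference_chain: str
    second_chain: str
    pairs: list[BasePair]

    def __len__(self) -> int:
        return len(self.pairs)

    def bp_index_of(self, chain_id: str, residue_number: int) -> tuple[int, int] | None:
        """Return ``(bp_index, strand)`` for a nucleotide, or None if unpaired."""
        for p in self.pairs:
            if chain_id == self.reference_chain and p.strand1.number == residue_number:
                return p.index, 1
            if chain_id == self.second_chain and p.strand2.number == residue_number:
                return p.index, 2
        return None

    def strand_of(self, chain_id: str) -> int | None:
        if chain_id == self.reference_chain:
            return 1
        if chain_id == self.second_chain:
            return 2
        return None


def _c1_list(chain: Chain):
    out = []
    for r in chain.residues:
        if r.is_water:
            continue
        a = r.atom("C1'")
        if a is not None:
            out.append((r, a.position))
    return out


def pair_duplex(
    dna: Structure,
    reference_chain: str | None = None,
    max_c1_distance: float = 12.5,
    min_c1_distance: float = 8.0,
) -> DuplexMap:
    """Identify Watson-Crick pairing between two nucleic chains.

    Residue i of the reference strand is matched with residue n-1-i (+shift)
    of the second strand; the shift maximizing the number of C1'-C1' contacts
    inside the accepted distance window wins.  Unmatched edge residues (e.g.
    5' overhangs) are excluded from indexing.
    """
    nucleic = dna.nucleic_chains()
    if len(nucleic) < 2:
        raise ValueError("duplex pairing needs two nucleic chains")
    if reference_chain is None:
        ref = nucleic[0]
        other = nucleic[1]
    else:
        ref = dna.chain(reference_chain)
        if ref is None:
            raise ValueError(f"no chain {reference_chain!r}")
        other = next(c for c in nucleic if c.id != ref.id)
    ref_list = _c1_list(ref)
    oth_list = _c1_list(other)
    n, m = len(ref_list), len(oth_list)
    best_score, best_pairs = None, []
    for shift in range(-(m - 1), n):
        pairs = []
        n_comp = 0
        for i in range(n):
            j = (m - 1) - (i - shift)
            if not (0 <= j < m):
                continue
            d = np.linalg.norm(ref_list[i][1] - oth_list[j][1])
            if min_c1_distance <= d <= max_c1_distance:
                pairs.append((i, j))
                b1 = one_letter(ref_list[i][0])
                b2 = one_letter(oth_list[j][0])
                if _COMPLEMENT.get(b1) == b2:
                    n_comp += 1
        # Watson-Crick complementarity breaks ties between geometrically
        # plausible shifts (helical neighbors are also ~10 A apart)
        score = (n_comp, len(pairs))
        if best_score is None or score > best_score:
            best_score, best_pairs = score, pairs
    if len(best_pairs) < 2:
        raise ValueError("could not identify an antiparallel duplex pairing")
    bp = [
        BasePair(index=k, strand1=ref_list[i][0], strand2=oth_list[j][0])
        for k, (i, j) in enumerate(best_pairs)
    ]
    return DuplexMap(reference_chain=ref.id, second_chain=other.id, pairs=bp)
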