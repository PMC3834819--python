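# zlattice

Geometric modeling of Zalpha-domain lattices on left-handed Z-DNA helices.

Zalpha domains are compact (~65-residue) winged helix-turn-helix modules —
found in ADAR1, DAI, PKZ, E3L and ORF112 — that specifically recognize the
left-handed Z conformation of double-stranded DNA/RNA.  Each domain reads
its binding register from a single CH-π stack: a conserved tyrosine ring on
the *syn* guanosine that is diagnostic of the Z form.  On a CpG-repeat
helix longer than the minimal (CG)₃ site, many domains can bind at once,
and the central quantitative question is combinatorial: which lattices of
binding registers can tile an arbitrarily long helix without steric
clashes between the bound proteins, and which pairs of bound domains could
be joined into the tandem (Zαβ) unit that these proteins actually carry?

`zlattice` is a library + CLI for that analysis:

- **Helix geometry** — build idealized left-handed (CG)ₙ duplexes with
  exact syn/anti glycosidic torsions, fit screw-axis frames
  (twist/rise/handedness, optional unequal dinucleotide steps) to any
  duplex, and move along the helix with exact screw algebra.
- **Anchors and placement** — detect tyrosine/syn-G CH-π anchors, express
  a bound domain rigidly in its register frame, and place copies at any
  register on either strand (second-strand placement via the duplex
  pseudo-dyad).
- **Arrangement scans** — enumerate `s + o` lattices (a domain every `s`
  bp on the reference strand, second-strand domains offset `o` bp), detect
  inter-domain clashes with a k-d-tree identical to the all-pairs
  computation, and test clash-free propagation on a pseudo-infinite helix.
- **Tandem linkers** — rank every ordered C-terminus→N-terminus domain
  pair by the minimal residue count an extended linker would need.
- **Contacts and interfaces** — typed protein–DNA/protein–protein contacts
  (H-bond, van der Waals, water-mediated, salt bridge, CH-π) with
  primary/secondary strand classification, and buried-surface areas from a
  deterministic Shrake–Rupley SASA.
- **Synthetic fixtures** — seeded dummy domains with planted anchors,
  contacts, termini and certified clash ground truth, so the whole
  pipeline is testable without any external coordinates.

Structures are read and written as standard PDB/mmCIF (via gemmi), so the
same pipeline runs on deposited Zalpha/Z-DNA co-crystal structures when
local copies are provided (see `tests/test_acceptance.py` for the expected
`data/deposited/` layout).

## Worked example

Build a planted-truth (6 + 3) assembly — four spherical stand-in domains
on an ideal 12 bp CpG-repeat — then recover its geometry and rank the
tandem pairs:

```python
from zlattice import (Arrangement, DummyDomainSpec, make_fixture_complex,
                      rank_tandem_pairs)
from zlattice.workflows import analyze_complex

cplx, domains, manifest = make_fixture_complex(
    Arrangement(6, 3),
    DummyDomainSpec(n_atoms=80, radii=(5.0,), seed=7),
    helix_length_bp=12,
)
report = analyze_complex(cplx)
print("base pairs:", report.n_bp)
print("bound monomers:", report.n_protein_chains)
print("twist per bp:", round(report.frame.twist_per_bp, 1), "deg")
print("anchor spacings:", report.spacings)
top = rank_tandem_pairs(domains)[0]
print("top tandem pair:", top.pair,
      "C->N", round(top.cterm_to_nterm_distance, 1), "A",
      "->", top.min_linker_residues, "linker residues")
```

prints

```
base pairs: 12
bound monomers: 4
twist per bp: -30.0 deg
anchor spacings: {1: [6], 2: [6]}
top tandem pair: ('F', 'E') C->N 13.0 A -> 4 linker residues
```

Four monomers bind the 12 bp duplex (registers every 6 bp on each strand,
offset 3 — the 4:1 stoichiometry of the `6 + 3` lattice); the fitted frame
recovers the left-handed twist of −30°/bp; and the shortest C→N bridge
joins a domain to its dyad partner on the opposite strand, 3 bp away —
the topology expected for a covalent tandem pair.

The same analyses are exposed on the command line:

```sh
zlattice build-zdna --sequence CGCGCGCGCGCG --out helix.pdb
zlattice scan --complex complex.pdb --s-min 3 --s-max 8 --out scan.tsv
zlattice linker --assembly complex.pdb --span 3.5
zlattice contacts --complex complex.pdb --chain B
```

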