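# Methods

This note documents the geometric models behind `zlattice`, the defaults
and their rationale, and what the synthetic fixtures do and do not
establish about real structures.

## Helix model

A duplex is modeled as a screw lattice: base pair *i* is the image of base
pair 0 under a screw about a common axis with rotation `i·twist_per_bp`
and translation `i·rise_per_bp`.  Defaults are the canonical Z-form
values: twist −30°/bp (a 12 bp left-handed turn; the sign convention is
negative = left-handed) and rise 3.7 Å/bp.  The Z helix really advances in
dinucleotide steps with very unequal CpG/GpC twists; `HelixFrame`
supports an explicit `dinucleotide_step_params` split (e.g. −9°/−51°),
which the builder honors and the frame fitter recovers.  The *uniform*
parameterization is nevertheless the default, a deliberate convention:
with uniform steps the screw algebra is exact at every integer offset
(`screw(a+b) = screw(a)∘screw(b)`, placement commutes with the screw, and
the through-base-pair pseudo-dyad is an exact symmetry), whereas with
unequal steps those identities hold only dinucleotide-wise.  All register
arithmetic is therefore exact under the default and the unequal split is
an opt-in refinement.

Each base pair carries an in-plane pseudo-dyad through the helix axis.
The second strand is built as the 180° rotation of the first about the
bp-0 dyad, which makes strand exchange an exact symmetry of the built
duplex and gives every Watson–Crick pair identical internal geometry.

### Idealized nucleotides

Nucleotides are rigid idealized templates.  Base rings are regular
polygons (bond 1.37 Å) placed in a shared pair frame in the spirit of the
standard base reference frame: every base has its C1′ and glycosidic
nitrogen at the same position, the central WC-edge atoms (purine N1,
pyrimidine N3) sit at heights summing to 2.9 Å across the dyad (the
central H-bond is 2.9 Å by construction; the outer O6···N4 and N2···O2
pairs land at 3.3/2.7 Å).  The glycosidic torsion is built in exactly by
internal-coordinate construction: purines syn (χ = +68°), pyrimidines
anti (χ = −159°), the Z-form signature.  The syn window for labeling is
χ ∈ (−90°, +90°].

Sugar and phosphate atoms extend from C1′ by internal coordinates.  The
free backbone torsions were fitted once (per purine/pyrimidine class) so
that, under the default screw, consecutive rigid templates leave small
O3′(i)→P(i+1) gaps (2.9/3.5 Å) and Z-DNA-like phosphate radii
(6.9/7.7 Å) with no intra- or inter-residue steric overlap.  The
templates are rigid, so inter-residue backbone linkage is approximate —
the modeled quantities are base pairing, stacking geometry, glycosidic
conformation and phosphate placement, not covalent backbone continuity.
Duplex sequences must be strict C/G alternations (optionally with the
crystallization constructs' single 5′ T overhang, which is excluded from
base-pair indexing).

### Frame fitting

`fit_helix_frame` identifies antiparallel pairing from C1′–C1′ geometry
with Watson–Crick complementarity breaking ties between candidate
alignments (helical neighbors are also ~10 Å apart), then obtains the
axis by superposing each base pair onto the pair two steps along (the
dinucleotide repeat) and averaging the screw axes.  Per-step twist and
rise come from the azimuths and heights of base-pair midpoints about that
axis; midpoints lie on the local pseudo-dyads, so for ideal helices the
recovery is exact (≤1e-6) and the per-class means expose any dinucleotide
split.  The twist sign, taken about the axis oriented 5′→3′ along the
reference strand, encodes handedness.  At least four identified base
pairs are required.

## Anchors and placement

Binding registers are indexed 0-based along the reference strand, at the
base pair of the anchor *syn*-guanosine (not the 5′ cytosine).  Anchor
detection uses standard stacking criteria, config-exposed: tyrosine ring
centroid within 4.5 Å of the guanine ring centroid and ring normals
within 30°, guanosine required to be syn.  Per protein chain the
minimum-distance hit wins and alternates are reported.

A `PoseRule` expresses the whole bound domain rigidly in the frame of its
anchor register.  Strand-1 register frames are screw images of the bp-0
frame; strand-2 frames apply the bp-0 pseudo-dyad *before* the screw.
This is exactly the convention realized by the crystallographic two-folds
that relate opposite-strand monomers in the deposited assemblies, so a
rule derived from one monomer reproduces its symmetry siblings.

## Arrangements and propagation

An arrangement `s + o` places domains every `s` bp on the reference
strand and every `s` bp on the second strand offset `o` (0 ≤ o < s).
Propagation is operationalized as: place domains at every register of a
window (default 48 bp, and always ≥ 2·lcm(s, period) so every distinct
pair geometry appears), tile one extra helical period on each side so
edge domains see interior environments, and require every inter-domain
heavy-atom pair to clear the clash threshold (default 2.5 Å,
config-exposed; the tests include a 2.0–3.5 Å sensitivity scan).  The
k-d-tree acceleration prunes candidate pairs only and ends in the same
distance computation as the all-pairs path, so the two are bit-identical.

**Naming vs. geometry of o ↔ s−o.**  The labels `s + o` and `s + (s−o)`
describe the same lattice read from the other strand, and the scan groups
them under one canonical label.  As 3-D objects, however, the two
realizations of a *chiral* rigid domain are not congruent: every proper
isometry of the helix that exchanges strands has the form
screw(m)∘dyad, and each of these maps an (s,o) placed set onto an (s,o)
placed set — the offset is an invariant.  (Numerically, the pair-distance
spectra of the two realizations differ drastically.)  The equivalence
that *is* geometric — and that the tests assert — is reference
invariance: scan verdicts are identical whichever dyad-related monomer
(strand 1 or strand 2) seeds the pose rule.

## Tandem linkers

For every ordered pair the C-terminal carbonyl carbon → N-terminal
nitrogen distance is converted to a minimal residue count as
`ceil(d / span_per_residue)`.  The default span is 3.5 Å/residue (a
conservative extended-chain bound); 3.8 Å (the fully extended Cα–Cα
spacing) is exposed as the standard alternative, and reports carry a
feasibility flag against a residue budget (default 15).  An optional
straight-segment screen against the DNA (blocked if the segment passes
within 2.0 Å of an obstacle atom) is shipped as an explicitly approximate
path check, off by default.  In an ideal lattice the minimum-distance
pair is degenerate (screw copies and dyad partners are exact); only the
edge effects of a finite crystal break the tie.

## Contacts and interfaces

Contact typing is heavy-atom geometry with static donor/acceptor tables
(deposited structures carry no hydrogens): H-bond ≤ 3.5 Å
donor–acceptor, generic van der Waals ≤ 4.0 Å (reported once per residue
pair), water bridges with both legs ≤ 3.5 Å, salt bridges between
charged-group N/O ≤ 4.0 Å, CH-π per the anchor criteria.  All cutoffs are
config-exposed on `ContactCriteria`.  DNA contacts are classified
*primary* (the strand carrying the anchor syn-G) or *secondary* (its
complement).  The conserved interface roles of the modeled domain (triad
Tyr45/Asn41/Trp65; wing Arg62; Arg42; second strand Gln27, Phe30, Lys31,
Lys37; dimer contacts Glu36, Ser38, Thr39, Arg42 — Arg42 genuinely in two
roles) ship as a static `RESIDUE_ROLES` table.

Surface areas use the rolling-probe (Shrake–Rupley) construction with a
deterministic Fibonacci point lattice — no RNG, so areas are
reproducible bit-for-bit; defaults probe 1.4 Å, 960 points/atom, pinned
van der Waals radii (C 1.70, N 1.55, O 1.52, P 1.80, S 1.80 Å).  Buried
surface is `SASA(A) + SASA(B) − SASA(A∪B)`; the reported interface area
is the half-sum (the paired-surface convention used by interface servers,
whose exact radii and probe differ, hence the generous tolerance applied
when comparing to published interface figures).  Waters are excluded from
SASA and clash detection but retained for bridge detection.

## Synthetic fixtures

A dummy domain stands in for the ~65-residue fold: a convex envelope
(sphere by default, radius 13 Å — the equivalent sphere of a compact
65-residue domain at ~135 Å³/residue; ellipsoids optional) filled with a
seeded pseudo-atom cloud, a tyrosine-like ring parallel to and 3.4 Å
above its anchor guanine (nudged 1 Å radially outward), N/C termini at
deterministic interior points, and optional planted contact atoms at
exact distances from the anchor phosphate.  The envelope center sits at
base-pair-plane height beside the register — the domain is centered next
to its binding site, not above the base stack — one radius radially out
from the ring.  Part of the cloud is placed exactly on the envelope
surface (a deterministic lattice), which makes envelope-based clash
predictions sharp.

Fixture manifests carry *certified* ground truth: a pair of placed dummy
domains is recorded as a certain clash when two deterministic
(seed-independent) atoms are already closer than the threshold, as
certainly clash-free when the deterministic atoms, every
atom-to-envelope bound and the envelope–envelope bound all clear it, and
flagged uncertain otherwise.  The shipped fixture configurations produce
no uncertain pairs, so pipeline verdicts can be asserted equal to the
manifest exactly, across seeds.

What the fixtures do **not** show: spherical stand-ins of realistic size
cannot reproduce the deposited-structure finding that the `6 + 3` class
is the unique clash-free propagating arrangement — packing four domains
per 12 bp requires the real winged, non-spherical shape, which is only
available from deposited coordinates.  Synthetic scans validate the
machinery (enumeration, placement, clash detection, windows, symmetry),
not crystallographic packing results.

## Numerical choices

- Superposition is Kabsch (SVD with determinant correction); degenerate
  (collinear) selections and length mismatches are errors.  Residue
  matching for backbone superposition aligns residue-name sequences
  (longest-common-subsequence blocks) over N/CA/C triplets, with a
  CA-only fallback for reduced models.
- Screw decomposition handles the 180° rotation branch via the symmetric
  part of the rotation; pure translations return angle 0.
- Clash detection uses strict `d < threshold` on exact distances in both
  the grid and all-pairs paths.
- The helix-frame fitter requires monotone base-pair heights along the
  axis and at least 4 bp; midpoint azimuths are unwrapped, which is safe
  for per-step twists below 180°.
- `HelixFrame` enforces `period_bp · |twist_per_bp| = 360° ± 5°` and unit
  axis; `ref_x` is orthogonalized against the axis.

## Limitations

- Domains are rigid bodies; no side-chain repacking or backbone
  flexibility.
- The ideal duplex is a rigid-template model: glycosidic torsions, base
  pairing and phosphate placement are modeled; covalent backbone
  continuity between residues is approximate.
- Clash verdicts are geometry only; no energetics.
- The deposited-structure analyses (register spacings, superposition
  against the ADAR1 Zalpha reference, second-strand interface area,
  scan uniqueness, tandem linker budget) require local copies of the
  co-crystal coordinate files; they are exercised by
  `tests/test_acceptance.py` when present under `data/deposited/`.
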