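# Methods

This note documents the models, conventions and numerical choices behind
`rglatch`. The package analyses the "latch" of reverse gyrases — an
insertion in helicase subdomain H2 that bridges to the topoisomerase
domain — at two levels: backbone-level motif classification of the minimal
latch (a β-bulge loop capping a short two-stranded antiparallel β-sheet),
and survey-level statistics of latch regions across many sequences.

## Structure model

Coordinates are read with gemmi (PDB and mmCIF) into a minimal
chain → residue → atom hierarchy. Author residue numbering is the canonical
coordinate system: all spans (e.g. 387–400 for the minimal latch) are
1-based and inclusive. Only amino-acid residues are kept; waters and other
heteroatoms are excluded so residue counts match crystallographic "protein
residues" conventions. Alternate locations resolve to the highest-occupancy
conformer with ties broken in favour of altloc `A`; only the first model of
a multi-model file is used (the intended inputs are crystal structures).
Nonstandard residues map to their parent one-letter code when tabulated
(MSE → M), otherwise to `X`; a strict `x` policy is available.

## Hydrogen bonds

Backbone N–H···O=C bonds are detected with the Kabsch–Sander electrostatic
model rather than pure geometry, because the intended inputs are X-ray
models without hydrogens and the energy model is the de-facto standard for
secondary-structure work. Amide hydrogens are reconstructed 1.0 Å from N
along the reversed direction of the preceding carbonyl (C−O), the DSSP
convention; prolines and chain-start residues carry none. For candidate
pairs within a 5.2 Å N–O prefilter,

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol,

and pairs with E below −0.5 kcal/mol (configurable, must be negative) are
accepted. Donor and acceptor must be at least two residues apart in chain
position. Energies are invariant under rigid motion of the structure by
construction.

## Hairpin detection and loop taxonomy

Antiparallel bridges follow the Kabsch–Sander rule: residues (i, j) form a
bridge if the mutual bonds N(i)→O(j) and N(j)→O(i) exist, or the flanking
pattern N(i−1)→O(j+1) and N(j−1)→O(i+1) does. Consecutive bridges
(i+1, j−1) merge into ladders; a ladder whose strands lie on one chain and
enclose a contiguous loop of 4–8 residues is reported as a β-hairpin, with
an inter-strand axis angle (least-squares Cα axes, second strand reversed;
0° = flat sheet) reported as the twist.

One deliberate refinement: ladder extension stops before the enclosed loop
would drop below four residues. The loop-closing hydrogen bonds of β-bulge
loops — most visibly the mutual i ↔ i+4 pair of a doubly-bonded type 1
loop — satisfy the bridge rule themselves, and without the stop rule the
sheet would "eat" the loop and report a spurious 2–3-residue turn. Treating
loop-closing bonds as part of the loop, not the sheet, is what the
Milner-White/Sibanda taxonomy intends.

The loop capping a hairpin is classified by length and hydrogen bonding,
with residue *i* anchored at the first loop residue:

| label | loop length | required bond | recorded second bond |
|---|---|---|---|
| β-turn | 4 | — (length suffices) | NH(i+3)→CO(i) evidence |
| type 1 β-bulge loop | 5 | NH(i)→CO(i+4) | CO(i)→NH(i+4) |
| type 2 β-bulge loop | 6 | NH(i)→CO(i+5) | CO(i)→NH(i+4) |

Relaxed mode (default) requires only the characteristic bond and records
the second bond's presence and N↔O / H↔O distances — naturally occurring
bulge loops often lack the second bond yet keep the type label. Strict mode
requires both; loops of 3, 7 or 8 residues are `non_canonical`; lengths
outside 3–8 are refused as out of taxonomy.

## Superposition, probes, contacts

Atom pairing matches residues by (chain, author number, insertion code)
and atoms by name; unmatched entries are counted, never silently aligned.
Cα-only pairing is the default because quoted r.m.s.d.s in molecular
graphics conventionally use Cα traces; backbone and all-heavy modes exist.
The optimal rotation comes from the singular-value (Kabsch) solution with
reflection correction; coincident or collinear point sets raise a
degeneracy error rather than returning an arbitrary rotation.

`refine_superpose` iterates the fit, dropping pairs whose residual exceeds
a cutoff (default 2.0 Å, up to 5 cycles), approximating `align`-style
refinement. Rejection is monotone (the refined r.m.s.d. never exceeds the
plain fit on the same pairing) and cumulative; a biased first fit can
therefore discard a few genuine pairs along with planted outliers, which
the reported `n_rejected` makes visible. Displacement probes superpose on a
fit selection and report per-atom distances in the superposed frame, with
missing probes flagged per probe rather than failing the run.

Contacts between two disjoint regions are all heavy-atom pairs within a
cutoff, default 4.5 Å — chosen to operationalize van-der-Waals-range
interactions such as a phenylalanine side chain packing against glutamate
methylene groups. Contact counts are monotone in the cutoff.

## Sequence statistics

Latch regions are extracted from a multiple alignment by mapping reference
residue numbers to alignment columns and taking each row's ungapped span
between those columns (all-gap rows yield zero-length regions). Net charge
at pH 7 uses the survey approximation (#R + #K) + 0.5·#H − (#D + #E),
treating histidine (pKa ≈ 6.5) as half-protonated; `X` and gaps are
ignored, other unknown letters contribute zero with a warning. The charge
is exactly additive under concatenation. Hydrophobicity is the arithmetic
mean over a named scale, Kyte–Doolittle by default; reported tables always
name the scale.

Length clustering sorts the lengths and splits wherever consecutive sorted
values differ by more than a gap threshold, default 6 — one more than the
5-residue histogram bin width used in survey figures, so bona-fide clusters
separated by ≥ 7 unoccupied lengths never merge. Clustering is invariant
to input order and counts always sum to the input size.

Pairwise identity/similarity uses Smith–Waterman local alignment with
affine gaps via Biopython's `PairwiseAligner` configured to EMBOSS `water`
defaults (BLOSUM62, gap open 10, extend 0.5; a gap of length L costs
10 + 0.5·(L−1)). Percent identity is identical columns over alignment
length including gap columns; percent similarity counts columns with a
positive substitution score (EMBOSS convention); both round to one decimal.
When no positive-scoring local alignment exists the result is empty with
score 0. The test suite checks scores against an independent hand-written
Gotoh dynamic program, itself validated against a fully exhaustive
alignment-path enumeration at tiny lengths.

## Synthetic generators

The structure generator builds poly-alanine backbones from internal
coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å;
idealized β dihedrals φ = −139°, ψ = +135°; all-trans peptides) with the
standard NeRF construction. Hairpins are realized from curated per-residue
dihedral templates, one per (strand length, loop length, bond pattern):
each template was solved once by restrained least squares so that the
blueprint's hydrogen bonds form with near-ideal geometry (N···O ≈ 2.9 Å,
H···O ≈ 1.9 Å), steric floors hold, and — critically — the bonds that would
let the sheet ladder extend into the loop stay out of bonding range. A
template is only accepted if the full pipeline (H inference → bond
detection → hairpin finding → classification) returns the intended label
at zero noise with every planted bond at energy ≤ −1.5 kcal/mol, and the
label is recovered across seeded σ = 0.2 Å noise replicates. Templates are
frozen as package constants; building a hairpin is therefore deterministic,
with isotropic Gaussian coordinate noise applied under a mandatory seed.

The sequence generator plants length clusters and a charge-sign
composition. Within each cluster a ladder of lengths spaced at most the
gap threshold apart is always included (so planted clusters can never
fragment on recovery), with remaining lengths sampled uniformly; each
sequence is assigned a sign class and composed from K/R (+1), D/E (−1),
optional His pairs (+0.5 each) and neutral residues so that the survey
charge formula reproduces the planted class exactly. The default blueprint
emulates a 184-member eubacterial survey: clusters 3×13, 36×(59–82),
145×(89–119); signs 114 positive / 13 neutral / 57 negative.

What the generators do *not* emulate: side chains beyond the backbone
(contact analyses on synthetic structures use backbone atoms only), real
sheet twist statistics, correlated coordinate error, alignment errors in
real MSAs, or compositional biases of real thermophile proteomes. Passing
the synthetic suite therefore demonstrates the correctness of the
bookkeeping and the robustness of the classification logic to coordinate
noise, not field performance on arbitrary depositions.

## Recovery benchmark

The headline robustness number — label recovery on noisy synthetic
hairpins — uses blueprints that plant only the characteristic loop bond
and classifies in relaxed mode. This mirrors the motif the package was
built to analyse: the engineered minimal latch keeps its type 2 label on
the strength of the NH(i)→CO(i+5) bond alone, its second characteristic
bond being absent at ~5 Å. Doubly-bonded blueprints exist as well and are
exercised by the strict-mode tests at zero noise. Noise is isotropic
Gaussian per atom with the stated σ applied to each coordinate
independently (so σ = 0.2 Å implies a mean atomic displacement of
~0.32 Å, comparable to coordinate error in a ~3 Å-resolution model).

## Problem sizes and determinism

The test and acceptance runs use 200 noise replicates per motif class at
σ = 0.2 Å (and exact checks at σ = 0), 20-point clouds against a
rotation-grid superposition oracle (24-step Euler grid plus local polish),
all three-letter-alphabet sequence pairs up to length 6 against the Gotoh
oracle, and the 184-sequence survey blueprint. All stochastic paths take
explicit seeds; identical seeds give byte-identical generator output and
reports.

## Known limitations

* Hairpin detection targets two-stranded antiparallel sheets; parallel
  topologies and multi-strand sheets are out of scope.
* The curated templates cover strand length 4 (loops 4/5/6, with and
  without the second characteristic bond). Other strand lengths raise a
  construction error rather than silently extrapolating.
* The engineered-latch renumbering helper assumes the published 61-residue
  deletion geometry when comparing with full-length structures.
* Classification is hydrogen-bond-based only; no dihedral-based subtyping
  of bulge-loop conformers is attempted.
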