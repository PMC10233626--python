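# rglatch

Structural and sequence analysis of reverse-gyrase **latch** regions.

Reverse gyrase is the only enzyme known to introduce positive supercoils
into DNA, an ATP-dependent reaction carried out by a helicase domain fused
to a type IA topoisomerase domain. The two domains are bridged by the
*latch*, an insertion in helicase subdomain H2 that ranges from a large
globular domain down to a minimal β-bulge loop capping a short two-stranded
antiparallel β-sheet. `rglatch` packages the analyses needed to study such
latches quantitatively:

* **Motif classification** — backbone hydrogen bonds from the
  Kabsch–Sander electrostatic model (E = 0.084·332·(1/r_ON + 1/r_CH −
  1/r_OH − 1/r_CN) kcal/mol, accepted below −0.5), antiparallel-bridge
  ladder assembly, and classification of the loop capping a β-hairpin as a
  β-turn (4 residues), type 1 β-bulge loop (5 residues, NH(i)→CO(i+4)) or
  type 2 β-bulge loop (6 residues, NH(i)→CO(i+5)), with the second
  characteristic bond CO(i)→NH(i+4) recorded and optionally required.
* **Superposition & contacts** — Kabsch (SVD) least-squares fits with
  iterative outlier rejection, per-atom displacement probes in the
  superposed frame, and heavy-atom contact inventories between regions.
* **Latch sequence statistics** — region extraction from multiple
  alignments, net charge at pH 7 ((#R+#K) + 0.5·#H − (#D+#E)),
  Kyte–Doolittle hydrophobicity, gap-based length clustering, and
  Smith–Waterman identity/similarity with EMBOSS `water` conventions
  (BLOSUM62, gap open 10, extend 0.5).
* **Synthetic ground truth** — idealized hairpins with planted hydrogen-bond
  patterns and seeded coordinate noise, and FASTA sets with planted length
  clusters and charge-sign compositions, so every stage is testable without
  downloading depositions.

## Worked example

Classify the loop of a synthetic type 2 β-bulge-loop hairpin and print the
hydrogen-bond evidence:

```python
from rglatch import (MotifBlueprint, build_hairpin, backbone_hbonds,
                     find_beta_hairpins, classify_loop, net_charge)

structure, truth = build_hairpin(MotifBlueprint(loop_length=6, noise_sigma=0.1, seed=7))
hbonds = backbone_hbonds(structure)           # Kabsch-Sander, cutoff -0.5 kcal/mol
(motif,) = find_beta_hairpins(structure, hbonds)
cls = classify_loop(motif, structure, hbonds)
print(cls.label, cls.loop_length)
print(round(cls.characteristic_hbond.n_o_distance, 2),
      round(cls.characteristic_hbond.energy, 2))
print(net_charge("PSMRFSLEELIIPD"))
```

```
type2_bulge_loop 6
3.1 -1.26
-2.0
```

The motif is recovered as a type 2 β-bulge loop: a six-residue loop whose
first residue donates its amide N–H to the carbonyl of the last loop
residue (here, after 0.1 Å coordinate noise, at N···O 3.1 Å and
−1.26 kcal/mol, below the −0.5 kcal/mol acceptance threshold). The final
line applies the survey charge formula to the engineered minimal-latch
sequence (residues 387–400): two glutamates and one aspartate against one
arginine give a net charge of −2 e at pH 7.

The same analyses are scriptable from the shell:

```bash
rglatch simulate hairpin --loop-length 6 --sigma 0.1 --seed 7 --out hp.pdb
rglatch motifs hp.pdb --out run/
rglatch compare --ref a.pdb --mov b.pdb --fit "@all_minus_latch" --probe "A:364:OH"
rglatch survey --msa latches.aln --ref-id T_MARITIMA --ref-start 387 --ref-end 400
```

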