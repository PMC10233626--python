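"""Backbone hydrogen bonds and β-hairpin / β-bulge-loop classification.

Hydrogen bonds are detected with the Kabsch–Sander electrostatic model:
amide hydrogens are first reconstructed on the donor nitrogens (X-ray
structures usually carry none), then for every donor/acceptor pair within
a 5.2 Å N–O prefilter the energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   [kcal/mol]

is evaluated and pairs with E below a cutoff (default −0.5 kcal/mol) are
accepted. Antiparallel β-bridges assembled from these bonds yield two-stranded
hairpins, and the loop capping a hairpin is classified by its length and its
characteristic loop-closing hydrogen bonds:

* 4 residues                      -> β-turn
* 5 residues, NH(i)→CO(i+4)       -> type 1 β-bulge loop
* 6 residues, NH(i)→CO(i+5)       -> type 2 β-bulge loop

where residue i is the first residue of the loop span. The second
characteristic bond, CO(i)→NH(i+4), is recorded but in the default "relaxed"
mode not required — naturally occurring bulge loops frequently lack it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, LoopTaxonomyError
from .geometry import strand_axis, axis_angle
from .structures import Residue, ResidueId, ResidueSelection, Structure

KS_COUPLING = 0.084 * 332.0  # kcal/mol·Å, Kabsch–Sander dimensional factor
KS_DISTANCE_PREFILTER = 5.2  # Å, N–O candidate cutoff
DEFAULT_ENERGY_CUTOFF = -0.5  # kcal/mol
MIN_SEQUENCE_SEPARATION = 2  # |donor - acceptor| within a chain


@dataclass(frozen=True)
class HBond:
    """A backbone N–H···O=C hydrogen bond (donor provides the N–H)."""

    donor: ResidueId
    acceptor: ResidueId
    energy: float  # kcal/mol
    n_o_distance: float  # Å
    h_o_distance: float  # Å


class HBondSet:
    """Queryable collection of accepted hydrogen bonds."""

    def __init__(self, bonds: list[HBond]):
        self._by_pair = {(b.donor, b.acceptor): b for b in bonds}

    def has(self, donor: ResidueId, acceptor: ResidueId) -> bool:
        return (donor, acceptor) in self._by_pair

    def get(self, donor: ResidueId, acceptor: ResidueId) -> HBond | None:
        return self._by_pair.get((donor, acceptor))

    def __iter__(self) -> Iterator[HBond]:
        return iter(self._by_pair.values())

    def __len__(self) -> int:
        return len(self._by_pair)


@dataclass(frozen=True)
class HBondEvidence:
    """Presence and geometry of one candidate loop hydrogen bond."""

    donor: ResidueId
    acceptor: ResidueId
    present: bool
    n_o_distance: float | None  # Å, heavy-atom N↔O
    h_o_distance: float | None  # Å, amide H↔O when H is available
    energy: float | None  # kcal/mol when computable


@dataclass
class BetaHairpinMotif:
    """Two antiparallel strands joined by a chain-continuous loop."""

    structure_id: str
    chain_id: str
    strand1: list[Residue]
    loop: list[Residue]
    strand2: list[Residue]
    orientation: str = "antiparallel"
    twist_angle: float = 0.0  # deg between strand axes (0 = untwisted sheet)

    @property
    def loop_length(self) -> int:
        return len(self.loop)

    @property
    def strand1_span(self) -> ResidueSelection:
        return ResidueSelection.from_spans(
            [(self.chain_id, self.strand1[0].number, self.strand1[-1].number)]
        )

    @property
    def strand2_span(self) -> ResidueSelection:
        return ResidueSelection.from_spans(
            [(self.chain_id, self.strand2[0].number, self.strand2[-1].number)]
        )

    @property
    def loop_span(self) -> ResidueSelection:
        return ResidueSelection.from_spans(
            [(self.chain_id, self.loop[0].number, self.loop[-1].number)]
        )


@dataclass
class LoopClassification:
    """Motif label plus the hydrogen-bond evidence that produced it."""

    label: str  # beta_turn / type1_bulge_loop / type2_bulge_loop / non_canonical
    loop_length: int
    residue_i: ResidueId
    characteristic_hbond: HBondEvidence | None  # NH(i)→CO(i+4 or i+5)
    second_hbond: HBondEvidence | None  # CO(i)→NH(i+4)
    mode: str = "relaxed"

    def __post_init__(self) -> None:
        expected = {"beta_turn": 4, "type1_bulge_loop": 5, "type2_bulge_loop": 6}
        if self.label in expected and self.loop_length != expected[self.label]:
            raise ValueError(
                f"label {self.label} requires loop length {expected[self.label]}, "
                f"got {self.loop_length}"
            )


def infer_amide_hydrogens(structure: Structure) -> Structure:
    """Return a copy with backbone amide H reconstructed on each residue.

    Kabsch–Sander convention: H sits 1.0 Å from N along the C(i−1)→O(i−1)
    direction reversed (i.e. anti to the preceding carbonyl oxygen, in the
    peptide plane). Prolines and chain-start residues receive no hydrogen;
    a residue whose predecessor lacks C/O is skipped with a warning.
    """
    out = structure.copy()
    for chain in out.chains:
        for i in range(1, len(chain.residues)):
            res = chain.residues[i]
            prev = chain.residues[i - 1]
            if res.name == "PRO" or "N" not in res.atoms:
                continue
            if "C" not in prev.atoms or "O" not in prev.atoms:
                warnings.warn(
                    f"missing preceding carbonyl for {res!r}; amide H skipped",
                    stacklevel=2,
                )
                continue
            direction = prev.atoms["C"] - prev.atoms["O"]
            norm = np.linalg.norm(direction)
            if norm < 1e-9:
                continue
            res.atoms["H"] = res.atoms["N"] + direction / norm
    return out


def kabsch_sander_energy(donor: Residue, acceptor: Residue) -> tuple[float, float, float]:
    """(energy kcal/mol, r_NO, r_HO) for a candidate donor→acceptor bond."""
    n = donor.atoms["N"]
    h = donor.atoms["H"]
    c = acceptor.atoms["C"]
    o = acceptor.atoms["O"]
    r_on = float(np.linalg.norm(o - n))
    r_ch = float(np.linalg.norm(c - h))
    r_oh = float(np.linalg.norm(o - h))
    r_cn = float(np.linalg.norm(c - n))
    if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
        return np.inf, r_on, r_oh  # overlapping atoms: not a bond
    energy = KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return float(energy), r_on, r_oh


def _position_index(structure: Structure) -> dict[ResidueId, tuple[int, int]]:
    index: dict[ResidueId, tuple[int, int]] = {}
    for ci, chain in enumerate(structure.chains):
        for ri, res in enumerate(chain.residues):
            index[res.id] = (ci, ri)
    return index


def backbone_hbonds(
    structure: Structure, energy_cutoff: float = DEFAULT_ENERGY_CUTOFF
) -> HBondSet:
    """Detect all backbone hydrogen bonds with energy below ``energy_cutoff``.

    Amide hydrogens are inferred automatically when absent. Donor/acceptor
    pairs separated by fewer than two residues within a chain are excluded.
    """
    if energy_cutoff >= 0:
        raise ConfigurationError(
            f"H-bond energy cutoff must be negative, got {energy_cutoff}"
        )
    if not any("H" in res.atoms for res in structure.residues()):
        structure = infer_amide_hydrogens(structure)
    pos = _position_index(structure)
    residues = list(structure.residues())
    donors = [r for r in residues if "N" in r.atoms and "H" in r.atoms]
    acceptors = [r for r in residues if "C" in r.atoms and "O" in r.atoms]
    if not donors or not acceptors:
        return HBondSet([])
    tree = cKDTree(np.array([a.atoms["O"] for a in acceptors]))
    n_coords = np.array([d.atoms["N"] for d in donors])
    bonds: list[HBond] = []
    for di, neighbours in enumerate(
        tree.query_ball_point(n_coords, KS_DISTANCE_PREFILTER)
    ):
        donor = donors[di]
        dpos = pos[donor.id]
        for ai in neighbours:
            acceptor = acceptors[ai]
            apos = pos[acceptor.id]
            if dpos[0] == apos[0] and abs(dpos[1] - apos[1]) < MIN_SEQUENCE_SEPARATION:
                continue
            energy, r_no, r_ho = kabsch_sander_energy(donor, acceptor)
            if energy < energy_cutoff:
                bonds.append(HBond(donor.id, acceptor.id, energy, r_no, r_ho))
    return HBondSet(bonds)


def _twist(strand1: list[Residue], strand2: list[Residue]) -> float:
    ca1 = [r.atoms["CA"] for r in strand1 if "CA" in r.atoms]
    ca2 = [r.atoms["CA"] for r in strand2 if "CA" in r.atoms]
    if len(ca1) < 2 or len(ca2) < 2:
        return float("nan")
    # reverse strand 2 so that a flat antiparallel sheet gives ~0 deg
    return axis_angle(strand_axis(np.array(ca1)), strand_axis(np.array(ca2)[::-1]))


def find_beta_hairpins(
    structure: Structure, hbonds: HBondSet, max_loop: int = 8, min_loop: int = 4
) -> list[BetaHairpinMotif]:
    """Assemble antiparallel ladders and report β-hairpin motifs.

    A Kabsch–Sander antiparallel bridge joins residues (i, j) if either both
    mutual bonds N(i)→O(j) and N(j)→O(i) exist, or the flanking pattern
    N(i−1)→O(j+1) and N(j−1)→O(i+1) does. Consecutive bridges (i+1, j−1) are
    merged into ladders; a ladder whose two strands lie on one chain and
    enclose a contiguous loop of ``min_loop``..``max_loop`` residues is a
    hairpin. Ladder extension stops before the enclosed loop would shrink
    below ``min_loop`` residues: the loop-closing bonds of β-bulge loops
    (e.g. the mutual i↔i+4 pair of a type 1 loop) belong to the loop, not
    to the sheet.
    """
    motifs: list[BetaHairpinMotif] = []
    for chain in structure.chains:
        res = chain.residues
        n = len(res)

        def hb(i: int, j: int) -> bool:
            return hbonds.has(res[i].id, res[j].id)

        bridges: set[tuple[int, int]] = set()
        for i in range(n):
            for j in range(i + 3, n):
                direct = hb(i, j) and hb(j, i)
                flanked = (
                    i - 1 >= 0 and j + 1 < n and hb(i - 1, j + 1) and hb(j - 1, i + 1)
                )
                if direct or flanked:
                    bridges.add((i, j))
        for i, j in sorted(bridges):
            if (i - 1, j + 1) in bridges:
                continue  # not a ladder start
            k = 0
            while (
                (i + k + 1, j - k - 1) in bridges
                and (j - k - 1) - (i + k + 1) - 1 >= min_loop
            ):
                k += 1
            lo, hi = i + k, j - k  # innermost bridge retained for the sheet
            loop_len = hi - lo - 1
            if k < 1:
                continue  # strands of ≥2 residues require ≥2 bridges
            if not (min_loop <= loop_len <= max_loop):
                continue
            numbers = [r.number for r in res[i : j + 1]]
            if any(b - a != 1 for a, b in zip(numbers, numbers[1:])):
                continue  # chain break inside the motif
            motif = BetaHairpinMotif(
                structure_id=structure.id,
                chain_id=chain.id,
                strand1=res[i : lo + 1],
                loop=res[lo + 1 : hi],
                strand2=res[hi : j + 1],
            )
            motif.twist_angle = _twist(motif.strand1, motif.strand2)
            motifs.append(motif)
    return motifs


def _evidence(
    donor: Residue, acceptor: Residue, hbonds: HBondSet
) -> HBondEvidence:
    bond = hbonds.get(donor.id, acceptor.id)
    n_o = h_o = energy = None
    if "N" in donor.atoms and "O" in acceptor.atoms:
        n_o = float(np.linalg.norm(acceptor.atoms["O"] - donor.atoms["N"]))
    if "H" in donor.atoms and "O" in acceptor.atoms:
        h_o = float(np.linalg.norm(acceptor.atoms["O"] - donor.atoms["H"]))
        if "C" in acceptor.atoms:
            energy = kabsch_sander_energy(donor, acceptor)[0]
    return HBondEvidence(
        donor=donor.id,
        acceptor=acceptor.id,
        present=bond is not None,
        n_o_distance=bond.n_o_distance if bond else n_o,
        h_o_distance=bond.h_o_distance if bond else h_o,
        energy=bond.energy if bond else energy,
    )


def classify_loop(
    motif: BetaHairpinMotif,
    structure: Structure,
    hbonds: HBondSet | None = None,
    relaxed: bool = True,
    energy_cutoff: float = DEFAULT_ENERGY_CUTOFF,
) -> LoopClassification:
    """Classify the loop of a hairpin motif by length and hydrogen bonding.

    Residue i anchors the loop span (first loop residue). In relaxed mode
    (default) a 5- or 6-residue loop only needs its characteristic
    NH(i)→CO(i+4 / i+5) bond; strict mode additionally requires the
    CO(i)→NH(i+4) bond. Loops of 3, 7 or 8 residues are reported as
    non-canonical; lengths outside 3–8 are outside the taxonomy entirely.
    """
    n = motif.loop_length
    if not (3 <= n <= 8):
        raise LoopTaxonomyError(
            f"loop of {n} residues is outside the 3-8 residue taxonomy"
        )
    if hbonds is None:
        hbonds = backbone_hbonds(structure, energy_cutoff)
    loop = motif.loop
    # H positions for evidence distances even when bonds are absent
    struct_h = structure
    if not any("H" in r.atoms for r in loop):
        struct_h = infer_amide_hydrogens(structure)
        loop = [struct_h.residue(r.id) for r in loop]
    res_i = loop[0]
    mode = "relaxed" if relaxed else "strict"

    if n == 4:
        return LoopClassification(
            label="beta_turn",
            loop_length=4,
            residue_i=res_i.id,
            characteristic_hbond=_evidence(loop[3], loop[0], hbonds),  # NH(i+3)→CO(i)
            second_hbond=None,
            mode=mode,
        )

    label = "non_canonical"
    characteristic = second = None
    if n in (5, 6):
        # NH(i)→CO(i+4) for type 1, NH(i)→CO(i+5) for type 2
        characteristic = _evidence(loop[0], loop[n - 1], hbonds)
        # CO(i)→NH(i+4): donor is the amide of residue i+4
        second = _evidence(loop[4], loop[0], hbonds)
        candidate = "type1_bulge_loop" if n == 5 else "type2_bulge_loop"
        if characteristic.present and (relaxed or second.present):
            label = candidate
    return LoopClassification(
        label=label,
        loop_length=n,
        residue_i=res_i.id,
        characteristic_hbond=characteristic,
        second_hbond=second,
        mode=mode,
    )
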