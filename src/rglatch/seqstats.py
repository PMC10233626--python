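"""Latch-region sequence statistics.

Implements the latch-survey arithmetic: extraction of a region from a
multiple sequence alignment via reference-anchored columns, the pH-7 net
charge approximation (Arg/Lys +1, His +0.5 for pKa ≈ 6.5, Asp/Glu −1),
mean hydrophobicity (Kyte–Doolittle by default), gap-based length
clustering, and Smith–Waterman local alignment with EMBOSS-convention
percent identity/similarity (BLOSUM62, gap open 10, extend 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ConfigurationError, MappingError, RglatchError

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: Kyte & Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
HYDROPHOBICITY_SCALES = {"kyte-doolittle": KYTE_DOOLITTLE}

GAP_CHARS = set("-.")


@dataclass
class LatchRegion:
    """An extracted region of one sequence, in ungapped 1-based coordinates."""

    sequence_id: str
    region_sequence: str
    start: int  # 1-based inclusive; for an empty region end = start - 1
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.length != len(self.region_sequence):
            raise ValueError(
                f"{self.sequence_id}: span {self.start}-{self.end} inconsistent "
                f"with {len(self.region_sequence)}-residue sequence"
            )


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    percent_similarity: float


@dataclass
class LengthClusters:
    clusters: list[tuple[int, int, int]]  # (min_length, max_length, member_count)
    gap_threshold: int

    @property
    def counts(self) -> list[int]:
        return [c[2] for c in self.clusters]


def read_alignment(path: str | Path, format: str = "auto"):
    """Read a Clustal or (aligned) FASTA file via Bio.AlignIO."""
    path = Path(path)
    if format == "auto":
        head = path.read_text().lstrip()[:7].upper()
        format = "clustal" if head.startswith("CLUSTAL") else "fasta"
    try:
        return AlignIO.read(str(path), format)
    except ValueError as exc:
        raise RglatchError(f"failed to read alignment {path}: {exc}") from exc


def map_alignment_region(
    msa, reference_id: str, ref_start: int, ref_end: int
) -> list[LatchRegion]:
    """Extract, per sequence, the region aligned to reference residues
    ``ref_start``..``ref_end`` (1-based, inclusive, ungapped reference
    numbering). All-gap regions come back with length 0.
    """
    rows = {rec.id: str(rec.seq) for rec in msa}
    if reference_id not in rows:
        raise MappingError(f"reference {reference_id!r} not present in alignment")
    if ref_start > ref_end or ref_start < 1:
        raise MappingError(f"bad reference span {ref_start}-{ref_end}")
    ref = rows[reference_id]
    col_of: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref):
        if ch not in GAP_CHARS:
            pos += 1
            col_of[pos] = col
    for endpoint in (ref_start, ref_end):
        if endpoint not in col_of:
            raise MappingError(
                f"reference position {endpoint} beyond ungapped length {pos}"
            )
    c0, c1 = col_of[ref_start], col_of[ref_end]
    out: list[LatchRegion] = []
    for rec in msa:
        row = str(rec.seq)
        before = sum(1 for ch in row[:c0] if ch not in GAP_CHARS)
        segment = "".join(ch for ch in row[c0 : c1 + 1] if ch not in GAP_CHARS)
        start = before + 1
        out.append(
            LatchRegion(
                sequence_id=rec.id,
                region_sequence=segment.upper(),
                start=start,
                end=start + len(segment) - 1,
            )
        )
    return out


def net_charge(sequence: str) -> float:
    """Approximate net charge at pH 7: (#R + #K) + 0.5·#H − (#D + #E).

    ``X`` and gap characters are ignored; other unknown letters contribute
    zero with a warning.
    """
    seq = sequence.upper()
    unknown = {ch for ch in seq if ch not in AMINO_ALPHABET and ch != "X"
               and ch not in GAP_CHARS}
    if unknown:
        warnings.warn(
            f"unknown residue letters {sorted(unknown)} contribute no charge",
            stacklevel=2,
        )
    return (
        seq.count("R") + seq.count("K") + 0.5 * seq.count("H")
        - seq.count("D") - seq.count("E")
    )


def hydrophobicity_index(sequence: str, scale: str = "kyte-doolittle") -> float:
    """Arithmetic-mean hydropathy of a sequence under a named scale."""
    if scale not in HYDROPHOBICITY_SCALES:
        raise ConfigurationError(
            f"unknown hydrophobicity scale {scale!r}; have {list(HYDROPHOBICITY_SCALES)}"
        )
    values = [HYDROPHOBICITY_SCALES[scale][ch] for ch in sequence.upper()
              if ch in HYDROPHOBICITY_SCALES[scale]]
    if not values:
        raise RglatchError("hydrophobicity of an empty sequence is undefined")
    return float(np.mean(values))


def cluster_lengths(lengths: list[int], gap_threshold: int = 6) -> LengthClusters:
    """Split sorted lengths wherever consecutive values differ by more than
    ``gap_threshold`` residues; report (min, max, count) per cluster."""
    if not lengths:
        raise RglatchError("cannot cluster an empty length list")
    values = sorted(int(v) for v in lengths)
    clusters: list[tuple[int, int, int]] = []
    lo = values[0]
    count = 1
    prev = values[0]
    for v in values[1:]:
        if v - prev > gap_threshold:
            clusters.append((lo, prev, count))
            lo, count = v, 1
        else:
            count += 1
        prev = v
    clusters.append((lo, prev, count))
    return LengthClusters(clusters=clusters, gap_threshold=gap_threshold)


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    try:
        sub = substitution_matrices.load(matrix)
    except FileNotFoundError as exc:
        raise ConfigurationError(f"unknown substitution matrix {matrix!r}") from exc
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = sub
    # EMBOSS water convention: a gap of length L costs open + (L-1)·extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal local alignment with affine gaps (EMBOSS ``water`` defaults).

    Percent identity = identical columns / alignment length × 100; percent
    similarity = columns whose substitution score is positive / alignment
    length × 100 (gap columns count in the denominator only). Both are
    rounded to one decimal.
    """
    if not seq_a or not seq_b:
        raise RglatchError("cannot align empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    sub = aligner.substitution_matrix
    alignments = aligner.align(seq_a.upper(), seq_b.upper())
    if alignments.score <= 0:
        # no positive-scoring local alignment exists (all pairs penalised)
        return AlignmentResult("", "", 0.0, 0.0, 0.0)
    alignment = alignments[0]
    # format-independent extraction of gapped strings from indices
    a_gapped, b_gapped = [], []
    blocks_a = alignment.aligned[0]
    blocks_b = alignment.aligned[1]
    a, b = seq_a.upper(), seq_b.upper()
    for k in range(len(blocks_a)):
        if k > 0:
            gap_a = blocks_a[k][0] - blocks_a[k - 1][1]
            gap_b = blocks_b[k][0] - blocks_b[k - 1][1]
            a_gapped.append(a[blocks_a[k - 1][1] : blocks_a[k][0]] + "-" * gap_b)
            b_gapped.append("-" * gap_a + b[blocks_b[k - 1][1] : blocks_b[k][0]])
        a_gapped.append(a[blocks_a[k][0] : blocks_a[k][1]])
        b_gapped.append(b[blocks_b[k][0] : blocks_b[k][1]])
    aligned_a = "".join(a_gapped)
    aligned_b = "".join(b_gapped)
    if len(aligned_a) != len(aligned_b):  # defensive; should never trigger
        raise RglatchError("internal alignment reconstruction error")
    length = len(aligned_a)
    identical = similar = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            identical += 1
        try:
            positive = sub[ca, cb] > 0
        except (KeyError, IndexError):
            positive = False
        if positive:
            similar += 1
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        percent_identity=round(100.0 * identical / length, 1) if length else 0.0,
        percent_similarity=round(100.0 * similar / length, 1) if length else 0.0,
    )


@dataclass
class ChargeSummary:
    n_positive: int
    n_neutral: int
    n_negative: int
    table: pd.DataFrame  # id, length, net_charge, charge_per_length


def charge_summary(regions: list[LatchRegion]) -> ChargeSummary:
    """Partition regions by net-charge sign and tabulate charge per length."""
    if not regions:
        raise RglatchError("no regions to summarize")
    rows = []
    for region in regions:
        q = net_charge(region.region_sequence)
        rows.append(
            {
                "id": region.sequence_id,
                "length": region.length,
                "net_charge": q,
                "charge_per_length": q / region.length if region.length else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    return ChargeSummary(
        n_positive=int((table["net_charge"] > 0).sum()),
        n_neutral=int((table["net_charge"] == 0).sum()),
        n_negative=int((table["net_charge"] < 0).sum()),
        table=table,
    )


def length_histogram(lengths: list[int], bin_width: int = 5) -> pd.DataFrame:
    """Histogram-ready length table with fixed-width bins."""
    values = np.asarray(sorted(lengths))
    lo = (values.min() // bin_width) * bin_width
    edges = np.arange(lo, values.max() + bin_width + 1, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:] - 1, "count": counts}
    )
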