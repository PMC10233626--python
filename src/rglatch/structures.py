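"""Macromolecular structure model: chains, residues, atoms, selections.

Structures are read with gemmi (PDB and mmCIF) and normalised into a small
hierarchy that keeps author residue numbering, which is the coordinate system
used throughout: spans such as 387-400 are 1-based and inclusive at both ends.
Only amino-acid residues are retained; waters and other heteroatoms are
dropped so that "protein residues" counts match crystallographic convention.
Alternate locations are resolved to the highest-occupancy conformer (ties go
to altloc 'A'), and only the first model of multi-model files is used.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import gemmi
import numpy as np

from .errors import FormatError, ParseError, SelectionError

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: three-letter -> one-letter for the 20 standard amino acids
STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class ResidueId(NamedTuple):
    """Author-numbering identity of a residue within a structure."""

    chain: str
    number: int
    icode: str = ""


@dataclass
class Residue:
    """One amino-acid residue with a name -> position (Å) atom map."""

    name: str
    number: int
    icode: str = ""
    chain_id: str = ""
    one_letter: str = "X"
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def id(self) -> ResidueId:
        return ResidueId(self.chain_id, self.number, self.icode)

    @property
    def backbone_complete(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    def __repr__(self) -> str:  # compact: "PHE A391"
        return f"{self.name} {self.chain_id}{self.number}{self.icode}"


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """A parsed structure: ordered chains of amino-acid residues."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "pdb"

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        raise SelectionError(
            f"chain {chain_id!r} not present in structure {self.id!r} "
            f"(have {[c.id for c in self.chains]})"
        )

    def residues(self) -> Iterator[Residue]:
        for ch in self.chains:
            yield from ch.residues

    def residue(self, rid: ResidueId) -> Residue:
        for res in self.chain(rid.chain).residues:
            if res.number == rid.number and res.icode == rid.icode:
                return res
        raise SelectionError(f"residue {rid} not found in structure {self.id!r}")

    @property
    def n_residues(self) -> int:
        return sum(len(ch) for ch in self.chains)

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every atom mapped to R·x + t."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for res in out.residues():
            for name, pos in res.atoms.items():
                res.atoms[name] = R @ pos + t
        return out


@dataclass(frozen=True)
class ResidueSelection:
    """Inclusive author-numbered spans, optionally restricted to named atoms."""

    spans: tuple[tuple[str, int, int], ...]
    atom_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for chain, start, end in self.spans:
            if start > end:
                raise SelectionError(f"span {chain}:{start}-{end} has start > end")

    @classmethod
    def from_spans(
        cls,
        spans: Sequence[tuple[str, int, int]],
        atom_names: Sequence[str] | None = None,
    ) -> "ResidueSelection":
        return cls(tuple((c, int(s), int(e)) for c, s, e in spans),
                   tuple(atom_names) if atom_names is not None else None)

    @classmethod
    def parse(cls, text: str, atom_names: Sequence[str] | None = None) -> "ResidueSelection":
        """Parse "A:1-386,A:460-1104" (single numbers allowed: "A:391")."""
        spans = []
        for part in text.split(","):
            part = part.strip()
            if not part:
                continue
            try:
                chain, rng = part.split(":")
                if "-" in rng.lstrip("-"):
                    # split on the dash separating two (possibly negative) ints
                    lo, hi = rng.rsplit("-", 1)
                    spans.append((chain, int(lo), int(hi)))
                else:
                    spans.append((chain, int(rng), int(rng)))
            except ValueError as exc:
                raise SelectionError(f"cannot parse selection span {part!r}") from exc
        return cls.from_spans(spans, atom_names)


def _one_letter(name: str, nonstandard_policy: str = "map") -> str:
    if name in STANDARD_AA:
        return STANDARD_AA[name]
    if nonstandard_policy == "map":
        info = gemmi.find_tabulated_residue(name)
        if info is not None and info.is_amino_acid():
            code = info.one_letter_code.upper()
            if code.isalpha():
                return code
    return "X"


def _is_amino_acid(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        return bool(info.is_amino_acid())
    return name in STANDARD_AA


def _pick_altloc(atom_group: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved in favour of altloc 'A' (then by
    # altloc sort order, so blank/'A' precede 'B')
    return sorted(atom_group, key=lambda a: (-a.occ, a.altloc or "A"))[0]


def read_structure(
    path: str | Path,
    format: str = "auto",
    nonstandard_policy: str = "map",
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path:
        Coordinate file.
    format:
        ``pdb``, ``mmcif`` or ``auto`` (detect from content/extension).
    nonstandard_policy:
        ``map`` translates tabulated nonstandard residues (e.g. MSE -> M);
        ``x`` records them as ``X``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt_map = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }
    if format not in fmt_map:
        raise FormatError(f"unknown format {format!r}; expected pdb/mmcif/auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path} contains no models")
    st.setup_entities()

    source_format = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    out = Structure(id=st.name.lower() or path.stem, source_format=source_format)
    model = st[0]  # first model only
    for gchain in model:
        chain = Chain(id=gchain.name)
        seen_ids: set[tuple[int, str]] = set()
        for gres in gchain:
            if not _is_amino_acid(gres.name):
                continue
            key = (gres.seqid.num, gres.seqid.icode.strip())
            if key in seen_ids:  # microheterogeneity: keep first residue name
                continue
            seen_ids.add(key)
            res = Residue(
                name=gres.name,
                number=gres.seqid.num,
                icode=gres.seqid.icode.strip(),
                chain_id=gchain.name,
                one_letter=_one_letter(gres.name, nonstandard_policy),
            )
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in gres:
                by_name.setdefault(atom.name, []).append(atom)
            for name, group in by_name.items():
                a = _pick_altloc(group)
                res.atoms[name] = np.array([a.pos.x, a.pos.y, a.pos.z], dtype=float)
            chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)
    if not out.chains:
        raise ParseError(f"{path} contains no amino-acid residues")
    return out


def select(structure: Structure, selection: ResidueSelection) -> list[Residue]:
    """Resolve a selection to residues, in span order. Empty result is legal."""
    out: list[Residue] = []
    for chain_id, start, end in selection.spans:
        chain = structure.chain(chain_id)  # raises SelectionError if absent
        for res in chain.residues:
            if start <= res.number <= end:
                out.append(res)
    return out


def select_complement(structure: Structure, selection: ResidueSelection) -> list[Residue]:
    """All residues of the structure NOT covered by the selection spans."""
    selected = {res.id for res in select(structure, selection)}
    return [res for res in structure.residues() if res.id not in selected]


def sequence_of(structure: Structure, chain_id: str) -> str:
    """One-letter sequence of a chain in author-numbering order."""
    return "".join(res.one_letter for res in structure.chain(chain_id).residues)


def to_gemmi(structure: Structure) -> gemmi.Structure:
    """Convert back to a gemmi structure (for writing PDB/mmCIF)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for atom_name, pos in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(atom_name[0])
                atom.pos = gemmi.Position(*pos)
                atom.occ = 1.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Debug dump of a structure (or a selection promoted to a Structure)."""
    to_gemmi(structure).write_pdb(str(path))


def write_mmcif(structure: Structure, path: str | Path) -> None:
    doc = to_gemmi(structure).make_mmcif_document()
    doc.write_file(str(path))


def structure_from_residues(
    residues: Sequence[Residue], structure_id: str = "selection"
) -> Structure:
    """Build a standalone Structure from residues (used for debug dumps)."""
    out = Structure(id=structure_id)
    for res in residues:
        res = _copy.deepcopy(res)
        if not out.chains or out.chains[-1].id != res.chain_id:
            out.chains.append(Chain(id=res.chain_id or "A"))
        out.chains[-1].residues.append(res)
    return out
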