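"""Rigid-body superposition, displacement probes, and interface contacts.

The optimal rotation is obtained with the singular-value (Kabsch) method with
reflection correction. `refine_superpose` adds iterative outlier rejection:
atom pairs whose residual exceeds a cutoff (default 2.0 Å) are dropped and the
fit repeated, approximating the refinement cycles of molecular-graphics
`align`-style superpositions. Quoted r.m.s.d.s conventionally use Cα atoms
only, which is the default pairing mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegeneracyError,
    PairingError,
    RejectionCollapseError,
    SelectionError,
)
from .structures import Residue, ResidueId, ResidueSelection, Structure, select

ATOM_MODES = {
    "CA": ("CA",),
    "backbone": ("N", "CA", "C", "O"),
    "all_heavy": None,  # every non-hydrogen atom
}


def _is_heavy(atom_name: str) -> bool:
    return not atom_name.startswith("H")


@dataclass
class AtomPairing:
    """Matched atom coordinates from two structures."""

    coords_a: np.ndarray  # (n, 3)
    coords_b: np.ndarray  # (n, 3)
    labels: list[tuple[ResidueId, str]]  # (residue id, atom name) per pair
    n_unmatched_residues: int = 0
    n_unmatched_atoms: int = 0

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, mask: np.ndarray) -> "AtomPairing":
        return AtomPairing(
            coords_a=self.coords_a[mask],
            coords_b=self.coords_b[mask],
            labels=[lab for lab, keep in zip(self.labels, mask) if keep],
            n_unmatched_residues=self.n_unmatched_residues,
            n_unmatched_atoms=self.n_unmatched_atoms,
        )


@dataclass
class SuperpositionResult:
    """Least-squares fit of B onto A: x_B -> R·x_B + t."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å over the atoms used
    n_atoms_used: int
    n_rejected: int
    atom_pairing: list[tuple[ResidueId, str]] = field(default_factory=list)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class Contact:
    atom_a: tuple[ResidueId, str]
    atom_b: tuple[ResidueId, str]
    distance: float  # Å


@dataclass
class ContactSet:
    pairs: list[Contact]
    cutoff: float
    residues_a: list[ResidueId]
    residues_b: list[ResidueId]

    def __len__(self) -> int:
        return len(self.pairs)


def _residue_map(residues: list[Residue]) -> dict[ResidueId, Residue]:
    return {r.id: r for r in residues}


def pair_atoms(
    struct_a: Structure,
    struct_b: Structure,
    selection: ResidueSelection | None = None,
    atom_mode: str = "CA",
) -> AtomPairing:
    """Pair atoms of two structures by residue identity and atom name.

    Residues are matched on (chain, author number, insertion code) after
    applying ``selection`` (to structure A's numbering; the same spans are
    applied to B). Residues or atoms present on only one side are dropped
    and counted, never silently aligned.
    """
    if atom_mode not in ATOM_MODES:
        raise PairingError(f"unknown atom mode {atom_mode!r}")
    wanted = ATOM_MODES[atom_mode]
    res_a = select(struct_a, selection) if selection else list(struct_a.residues())
    if selection is not None:
        try:
            res_b_list = select(struct_b, selection)
        except SelectionError:
            res_b_list = []
    else:
        res_b_list = list(struct_b.residues())
    map_b = _residue_map(res_b_list)

    coords_a, coords_b, labels = [], [], []
    n_unmatched_res = n_unmatched_atoms = 0
    matched_b_ids = set()
    for ra in res_a:
        rb = map_b.get(ra.id)
        if rb is None:
            n_unmatched_res += 1
            continue
        matched_b_ids.add(rb.id)
        names = wanted if wanted is not None else tuple(
            n for n in ra.atoms if _is_heavy(n)
        )
        for name in names:
            if name in ra.atoms and name in rb.atoms:
                coords_a.append(ra.atoms[name])
                coords_b.append(rb.atoms[name])
                labels.append((ra.id, name))
            else:
                n_unmatched_atoms += 1
    n_unmatched_res += sum(1 for rid in map_b if rid not in matched_b_ids)
    if not labels:
        raise PairingError(
            f"no atoms could be paired between {struct_a.id!r} and {struct_b.id!r}"
        )
    return AtomPairing(
        coords_a=np.array(coords_a),
        coords_b=np.array(coords_b),
        labels=labels,
        n_unmatched_residues=n_unmatched_res,
        n_unmatched_atoms=n_unmatched_atoms,
    )


def kabsch_superpose(pairing: AtomPairing) -> SuperpositionResult:
    """Optimal least-squares rotation/translation of B onto A (Kabsch)."""
    a = pairing.coords_a
    b = pairing.coords_b
    if len(a) < 3:
        raise DegeneracyError(f"need at least 3 atom pairs, got {len(a)}")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    aa = a - cen_a
    bb = b - cen_b
    cov = bb.T @ aa
    u, s, vt = np.linalg.svd(cov)
    scale = np.linalg.norm(aa) * np.linalg.norm(bb)
    if scale < 1e-12 or s[1] / max(s[0], 1e-300) < 1e-9:
        raise DegeneracyError(
            "point sets are coincident or collinear; rotation is undetermined"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cen_a - rotation @ cen_b
    residuals = np.linalg.norm(bb @ rotation.T - aa, axis=1)
    rmsd = float(np.sqrt(np.mean(residuals**2)))
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        rmsd=rmsd,
        n_atoms_used=len(a),
        n_rejected=0,
        atom_pairing=list(pairing.labels),
    )


def residuals_after(pairing: AtomPairing, fit: SuperpositionResult) -> np.ndarray:
    return np.linalg.norm(fit.apply(pairing.coords_b) - pairing.coords_a, axis=1)


def refine_superpose(
    pairing: AtomPairing, reject_cutoff: float = 2.0, max_cycles: int = 5
) -> SuperpositionResult:
    """Kabsch fit with iterative rejection of pairs deviating > ``reject_cutoff`` Å.

    Stops when a cycle rejects nothing or after ``max_cycles`` refits. The
    reported r.m.s.d. covers retained pairs only; ``n_rejected`` counts the
    pairs dropped relative to the initial pairing.
    """
    current = pairing
    fit = kabsch_superpose(current)
    for _ in range(max_cycles):
        res = residuals_after(current, fit)
        keep = res <= reject_cutoff
        if keep.all():
            break
        if not keep.any():
            raise RejectionCollapseError(
                f"all {len(current)} pairs rejected at cutoff {reject_cutoff} Å"
            )
        current = current.subset(keep)
        if len(current) < 3:
            raise RejectionCollapseError(
                "fewer than 3 pairs retained during outlier rejection"
            )
        fit = kabsch_superpose(current)
    fit.n_rejected = len(pairing) - len(current)
    return fit


@dataclass
class ProbeDisplacement:
    residue: ResidueId
    atom: str
    distance: float | None  # Å in the superposed frame; None when missing
    missing_in: str | None = None  # "a", "b", or "both"


def probe_displacement(
    struct_a: Structure,
    struct_b: Structure,
    fit_selection: ResidueSelection,
    probes: list[tuple[ResidueId, str]],
    atom_mode: str = "CA",
    reject_cutoff: float = 2.0,
    max_cycles: int = 5,
) -> list[ProbeDisplacement]:
    """Superpose B onto A over ``fit_selection`` and measure probe-atom shifts."""
    pairing = pair_atoms(struct_a, struct_b, fit_selection, atom_mode)
    fit = refine_superpose(pairing, reject_cutoff, max_cycles)
    out = []
    for rid, atom in probes:
        pos_a = pos_b = None
        try:
            ra = struct_a.residue(rid)
            pos_a = ra.atoms.get(atom)
        except SelectionError:
            pass
        try:
            rb = struct_b.residue(rid)
            pos_b = rb.atoms.get(atom)
        except SelectionError:
            pass
        if pos_a is None or pos_b is None:
            missing = (
                "both" if pos_a is None and pos_b is None
                else ("a" if pos_a is None else "b")
            )
            out.append(ProbeDisplacement(rid, atom, None, missing))
            continue
        moved = fit.rotation @ pos_b + fit.translation
        out.append(ProbeDisplacement(rid, atom, float(np.linalg.norm(moved - pos_a))))
    return out


def contacts(
    structure: Structure,
    region_a: ResidueSelection,
    region_b: ResidueSelection,
    cutoff: float = 4.5,
) -> ContactSet:
    """All heavy-atom pairs between two disjoint regions within ``cutoff`` Å."""
    res_a = select(structure, region_a)
    res_b = select(structure, region_b)
    ids_a = {r.id for r in res_a}
    overlap = ids_a & {r.id for r in res_b}
    if overlap:
        raise SelectionError(f"regions overlap at {sorted(overlap)[:5]}")
    atoms_a = [
        (r.id, name, pos) for r in res_a for name, pos in r.atoms.items() if _is_heavy(name)
    ]
    atoms_b = [
        (r.id, name, pos) for r in res_b for name, pos in r.atoms.items() if _is_heavy(name)
    ]
    pairs: list[Contact] = []
    if atoms_a and atoms_b:
        tree_b = cKDTree(np.array([p for _, _, p in atoms_b]))
        coords_a = np.array([p for _, _, p in atoms_a])
        for ia, hits in enumerate(tree_b.query_ball_point(coords_a, cutoff)):
            rid_a, name_a, pos_a = atoms_a[ia]
            for ib in hits:
                rid_b, name_b, pos_b = atoms_b[ib]
                pairs.append(
                    Contact(
                        atom_a=(rid_a, name_a),
                        atom_b=(rid_b, name_b),
                        distance=float(np.linalg.norm(pos_a - pos_b)),
                    )
                )
    def _ordered(ids: set[ResidueId]) -> list[ResidueId]:
        return sorted(ids, key=lambda r: (r.chain, r.number, r.icode))

    return ContactSet(
        pairs=pairs,
        cutoff=cutoff,
        residues_a=_ordered({c.atom_a[0] for c in pairs}),
        residues_b=_ordered({c.atom_b[0] for c in pairs}),
    )
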