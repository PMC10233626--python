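"""Report assembly: flat tables (TSV) and structured records (JSON).

Every row carries the provenance of its inputs (structure/file id, chain,
spans, parameters), and report writing is deterministic so that reruns with
identical inputs and seeds produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .hbonds import BetaHairpinMotif, LoopClassification
from .superpose import ContactSet, ProbeDisplacement, SuperpositionResult


def _span_text(sel) -> str:
    return ",".join(f"{c}:{a}-{b}" for c, a, b in sel.spans)


def motif_record(
    motif: BetaHairpinMotif, classification: LoopClassification, source: str
) -> dict:
    char = classification.characteristic_hbond
    second = classification.second_hbond
    return {
        "source": source,
        "structure": motif.structure_id,
        "chain": motif.chain_id,
        "strand1": _span_text(motif.strand1_span),
        "loop": _span_text(motif.loop_span),
        "strand2": _span_text(motif.strand2_span),
        "loop_length": motif.loop_length,
        "label": classification.label,
        "mode": classification.mode,
        "residue_i": f"{classification.residue_i.chain}:{classification.residue_i.number}",
        "twist_angle_deg": round(motif.twist_angle, 1),
        "char_hbond_present": char.present if char else None,
        "char_hbond_NO_A": round(char.n_o_distance, 2)
        if char and char.n_o_distance is not None else None,
        "char_hbond_energy_kcal": round(char.energy, 2)
        if char and char.energy is not None else None,
        "second_hbond_present": second.present if second else None,
        "second_hbond_NO_A": round(second.n_o_distance, 2)
        if second and second.n_o_distance is not None else None,
    }


def superposition_record(
    result: SuperpositionResult, ref: str, mov: str, fit: str, atom_mode: str
) -> dict:
    return {
        "reference": ref,
        "mobile": mov,
        "fit_selection": fit,
        "atom_mode": atom_mode,
        "rmsd_A": round(result.rmsd, 3),
        "n_atoms_used": result.n_atoms_used,
        "n_rejected": result.n_rejected,
    }


def probe_records(
    probes: list[ProbeDisplacement], ref: str, mov: str
) -> list[dict]:
    out = []
    for p in probes:
        out.append(
            {
                "reference": ref,
                "mobile": mov,
                "residue": f"{p.residue.chain}:{p.residue.number}",
                "atom": p.atom,
                "displacement_A": round(p.distance, 2) if p.distance is not None else None,
                "missing_in": p.missing_in,
            }
        )
    return out


def contact_records(cset: ContactSet, source: str) -> list[dict]:
    rows = []
    for c in cset.pairs:
        rows.append(
            {
                "source": source,
                "cutoff_A": cset.cutoff,
                "residue_a": f"{c.atom_a[0].chain}:{c.atom_a[0].number}",
                "atom_a": c.atom_a[1],
                "residue_b": f"{c.atom_b[0].chain}:{c.atom_b[0].number}",
                "atom_b": c.atom_b[1],
                "distance_A": round(c.distance, 2),
            }
        )
    return rows


def write_report(rows: list[dict], stem: Path) -> tuple[Path, Path]:
    """Write rows as ``<stem>.tsv`` and ``<stem>.json``; returns both paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    tsv = stem.with_suffix(".tsv")
    js = stem.with_suffix(".json")
    pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)
    js.write_text(json.dumps(rows, indent=1, default=str) + "\n")
    return tsv, js
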