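"""Shared fixtures: tiny in-memory structures and on-the-fly PDB fixtures."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from rglatch.structures import Chain, Residue, Structure

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.155  -4.974  1.00  0.00           C
ATOM      4  O   ALA A   1      13.560   7.331  -5.836  1.00  0.00           O
END
"""


@pytest.fixture
def minimal_pdb(tmp_path) -> Path:
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


def make_structure(
    n_residues: int,
    chain_id: str = "A",
    start: int = 1,
    spacing: float = 3.8,
    structure_id: str = "toy",
) -> Structure:
    """A toy extended chain: backbone atoms at fixed offsets along x."""
    chain = Chain(id=chain_id)
    for k in range(n_residues):
        x = k * spacing
        # mild zig-zag keeps CA traces non-collinear for superposition tests
        y = 0.8 * np.sin(0.9 * k)
        z = 0.8 * np.cos(1.3 * k)
        chain.residues.append(
            Residue(
                name="ALA",
                number=start + k,
                chain_id=chain_id,
                one_letter="A",
                atoms={
                    "N": np.array([x, y, z]),
                    "CA": np.array([x + 1.0, y + 0.5, z]),
                    "C": np.array([x + 2.0, y, z]),
                    "O": np.array([x + 2.0, y - 1.2, z + 0.2]),
                },
            )
        )
    return Structure(id=structure_id, chains=[chain])


@pytest.fixture
def toy_chain() -> Structure:
    return make_structure(10)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
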