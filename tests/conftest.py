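import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


def _pdb_atom(serial, name, resname, chain, resseq, x, y, z, occ, b,
              altloc=" ", icode=" ", element="C"):
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def minimal_pdb(tmp_path):
    """Two-residue single-chain PDB with known coordinates/B-factors."""
    lines = [
        _pdb_atom(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, 1.0, 5.0, element="N"),
        _pdb_atom(2, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0, 1.0, 10.0),
        _pdb_atom(3, "CA", "GLY", "A", 2, 4.0, 5.0, 6.0, 1.0, 20.0),
        "END",
    ]
    path = tmp_path / "mini.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """One residue with A/B alternate CA locations (occupancies 0.6/0.4)."""
    lines = [
        _pdb_atom(1, "CA", "ALA", "A", 1, 1.0, 1.0, 1.0, 0.6, 11.0, altloc="A"),
        _pdb_atom(2, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0, 0.4, 99.0, altloc="B"),
        _pdb_atom(3, "CA", "GLY", "A", 2, 4.0, 5.0, 6.0, 1.0, 20.0),
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def three_chain_pdb(tmp_path):
    """Chains A (3 residues), B (2), C (1)."""
    lines = []
    serial = 1
    for chain, n_res in (("A", 3), ("B", 2), ("C", 1)):
        for r in range(1, n_res + 1):
            lines.append(
                _pdb_atom(serial, "CA", "ALA", chain, r,
                          float(serial), 0.0, 0.0, 1.0, 10.0 + serial)
            )
            serial += 1
    lines.append("END")
    path = tmp_path / "chains.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
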