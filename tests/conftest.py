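"""Shared fixtures: handwritten PDB snippets and synthetic structures."""

from __future__ import annotations

import numpy as np
import pytest

from kdalign.synthetic import SyntheticSpec, make_structure


def _pdb_atom(serial, name, resname, resnum, x, y, z, record="ATOM", chain="A"):
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:5d} {name_field} {resname:>3s} {chain}"
        f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        f"          {name.strip()[0]:>2s}"
    )


def make_pdb_text(residues, record="ATOM", chain="A", start_serial=1):
    """residues: list of (resnum, resname, {atom: (x,y,z)})."""
    lines = []
    serial = start_serial
    for resnum, resname, atoms in residues:
        for aname, (x, y, z) in atoms.items():
            rec = record if isinstance(record, str) else record(resname)
            lines.append(_pdb_atom(serial, aname, resname, resnum, x, y, z, rec, chain))
            serial += 1
    return lines


def backbone(x0):
    """A complete N/CA/C/O atom dict anchored at x offset `x0`."""
    return {
        "N": (x0 - 1.2, 0.5, 0.0),
        "CA": (x0, 0.0, 0.0),
        "C": (x0 + 1.2, 0.5, 0.0),
        "O": (x0 + 1.9, 1.4, 0.0),
    }


@pytest.fixture
def pdb_with_hetatm(tmp_path):
    """Three ATOM residues plus one HETATM residue with a full backbone."""
    lines = make_pdb_text(
        [(i + 1, "ALA", backbone(4.0 * i)) for i in range(3)]
    )
    lines += make_pdb_text(
        [(4, "MSE", backbone(12.0))], record="HETATM", start_serial=13
    )
    lines += ["TER", "END"]
    p = tmp_path / "het.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def pdb_two_models(tmp_path):
    """NMR-style file with two 5-residue models."""
    body1 = make_pdb_text([(i + 1, "GLY", backbone(4.0 * i)) for i in range(5)])
    body2 = make_pdb_text(
        [(i + 1, "GLY", backbone(4.0 * i + 100.0)) for i in range(5)]
    )
    lines = ["MODEL        1", *body1, "ENDMDL", "MODEL        2", *body2, "ENDMDL", "END"]
    p = tmp_path / "nmr.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def pdb_missing_o(tmp_path):
    """Four residues; residue 2 lacks its O atom."""
    residues = []
    for i in range(4):
        atoms = backbone(4.0 * i)
        if i == 1:
            atoms = {k: v for k, v in atoms.items() if k != "O"}
        residues.append((i + 1, "SER", atoms))
    p = tmp_path / "miss.pdb"
    p.write_text("\n".join(make_pdb_text(residues) + ["END"]) + "\n")
    return p


@pytest.fixture
def pdb_sidechain_only(tmp_path):
    """Residues carrying only a CB atom: nothing survives preprocessing."""
    residues = [(i + 1, "VAL", {"CB": (4.0 * i, 1.0, 1.0)}) for i in range(3)]
    p = tmp_path / "side.pdb"
    p.write_text("\n".join(make_pdb_text(residues) + ["END"]) + "\n")
    return p


@pytest.fixture(scope="session")
def helix_structure():
    s, ss = make_structure(SyntheticSpec(architecture=(("helix", 20),), seed=11))
    return s


@pytest.fixture(scope="session")
def strand_structure():
    s, ss = make_structure(SyntheticSpec(architecture=(("strand", 16),), seed=12))
    return s


@pytest.fixture(scope="session")
def mixed_structure():
    s, ss = make_structure(
        SyntheticSpec(
            architecture=(("helix", 14), ("coil", 6), ("strand", 10), ("coil", 8)),
            seed=13,
        )
    )
    return s


@pytest.fixture(scope="session")
def coil_structure():
    s, ss = make_structure(SyntheticSpec(architecture=(("coil", 30),), seed=14))
    return s


def brute_force_nearest(coords: np.ndarray, point: np.ndarray, cutoff=np.inf):
    """Independent nearest-neighbor oracle: argmin with lowest-index ties."""
    d = np.linalg.norm(coords - point, axis=1)
    best = int(np.argmin(d))  # argmin returns the first (lowest) index on ties
    if d[best] > cutoff:
        return None
    return best, float(d[best])
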