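"""Reading, preprocessing and writing of protein structures.

Structures are reduced to a single ordered residue list with one
representative atom per residue (C-alpha by default).  Preprocessing applies
the conventions that make cross-tool comparisons consistent: only the first
model of multi-model files is kept, chains are concatenated in file order
into a single sequence, residues missing any of the N, CA, C, O backbone
atoms are removed, and the remainder is renumbered sequentially from 1.

PDB input is parsed with gemmi (gzip handled transparently); output is
written as minimal fixed-width ATOM records so a file is bit-stable for a
fixed input and transform.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .geometry import Transform, apply_transform

__all__ = [
    "Residue",
    "Structure",
    "StructureFormatError",
    "EmptyStructureError",
    "read_structure",
    "preprocess",
    "write_superposed",
    "load",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parents
    "MSE": "M", "SEC": "C", "PYL": "K",
}


class StructureFormatError(ValueError):
    """Raised when a file cannot be interpreted as a PDB structure."""


class EmptyStructureError(ValueError):
    """Raised when no residues survive parsing or preprocessing."""


@dataclass
class Residue:
    number: int
    name: str
    atoms: dict[str, np.ndarray]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name.upper(), "X")

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)


@dataclass
class Structure:
    """An ordered protein chain with per-residue representative coordinates."""

    id: str
    residues: list[Residue]
    repr_atom: str = "CA"
    ss_states: np.ndarray | None = None  # per-residue {'H','E','C'}
    repr_coords: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.repr_coords is None:
            self.rebuild_repr_coords()

    def rebuild_repr_coords(self) -> None:
        coords = [
            r.atoms[self.repr_atom]
            for r in self.residues
            if self.repr_atom in r.atoms
        ]
        self.repr_coords = (
            np.array(coords, dtype=float) if coords else np.empty((0, 3))
        )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def transformed(self, t: Transform) -> "Structure":
        """A copy with every atom mapped through ``x -> R x + t``."""
        new_res = [
            Residue(
                r.number,
                r.name,
                {a: apply_transform(xyz[None, :], t)[0] for a, xyz in r.atoms.items()},
            )
            for r in self.residues
        ]
        out = replace(self, residues=new_res, repr_coords=None)
        out.rebuild_repr_coords()
        return out


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_structure(
    path: str | Path,
    hetatm_policy: str = "drop",
    model_policy: str = "first",
    repr_atom: str = "CA",
) -> Structure:
    """Parse a (possibly gzip-compressed) PDB file into a :class:`Structure`.

    Only the first model is retained; chains are concatenated in file order.
    HETATM residues are included only with ``hetatm_policy="keep"``.  For
    atoms with alternate locations the first encountered altloc is kept.
    """
    if hetatm_policy not in ("keep", "drop"):
        raise ValueError(f"hetatm_policy must be keep|drop, got {hetatm_policy!r}")
    if model_policy != "first":
        raise ValueError("only model_policy='first' is supported")
    path = Path(path)
    try:
        with _open_maybe_gzip(path) as fh:
            text = fh.read()
        st = gemmi.read_pdb_string(text)
    except (OSError, RuntimeError, ValueError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]  # first model of multi-model files is retained
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.het_flag == "H" and hetatm_policy == "drop":
                continue
            atoms: dict[str, np.ndarray] = {}
            seen_altloc: dict[str, str] = {}
            for atom in res:
                name = atom.name
                if name in atoms:
                    # keep the first altloc only
                    if atom.altloc and seen_altloc.get(name, "") != atom.altloc:
                        continue
                    continue
                atoms[name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                )
                seen_altloc[name] = atom.altloc or ""
            if atoms:
                residues.append(Residue(res.seqid.num, res.name, atoms))
    if not residues:
        raise EmptyStructureError(f"{path}: zero residues after parsing")
    sid = path.name
    for suffix in (".gz", ".pdb", ".ent"):
        if sid.endswith(suffix):
            sid = sid[: -len(suffix)]
    return Structure(id=sid, residues=residues, repr_atom=repr_atom)


def preprocess(s: Structure) -> Structure:
    """Apply the benchmark conventions to a parsed structure.

    Residues lacking any of the N, CA, C, O atoms are removed and the
    remainder is renumbered sequentially starting from 1.  Idempotent.
    """
    kept = [r for r in s.residues if r.has_backbone()]
    if not kept:
        raise EmptyStructureError(f"{s.id}: no residues with complete backbone")
    renumbered = [
        Residue(i + 1, r.name, dict(r.atoms)) for i, r in enumerate(kept)
    ]
    out = replace(s, residues=renumbered, ss_states=None, repr_coords=None)
    out.rebuild_repr_coords()
    return out


def write_superposed(s: Structure, t: Transform, path: str | Path) -> None:
    """Write the structure to `path` with every atom mapped through `t`.

    Residue numbering and names are preserved; coordinates are written at
    standard PDB precision (3 decimals).
    """
    path = Path(path)
    lines: list[str] = []
    serial = 1
    for res in s.residues:
        for aname, xyz in res.atoms.items():
            x, y, z = apply_transform(xyz[None, :], t)[0]
            # PDB columns: name left-padded for 1-3 char names per convention
            name_field = f" {aname:<3s}" if len(aname) < 4 else aname
            element = aname.strip()[0]
            lines.append(
                f"ATOM  {serial:5d} {name_field}{'':1s}{res.name:>3s} A"
                f"{res.number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def load(path: str | Path, hetatm_policy: str = "drop") -> Structure:
    """Read and preprocess in one step."""
    return preprocess(read_structure(path, hetatm_policy=hetatm_policy))
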