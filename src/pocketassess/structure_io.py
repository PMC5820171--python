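"""Read/write protein structures in PDB and CASP-TS dialects.

The CASP-TS dialect is ordinary PDB coordinate records preceded by
prediction header lines (``PFRMAT TS``, ``TARGET``, ``MODEL``); those
headers are tolerated in both dialects and parsed when present.

Conventions:

* author residue numbering (as printed in the file), insertion codes kept;
* for alternate locations only the highest-occupancy conformer is kept,
  ties broken alphabetically by altloc id;
* only the first ``MODEL``/``ENDMDL`` block of a multi-model file is read
  (a warning is emitted);
* hydrogens are preserved on read but ignored by downstream featurization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ResidueSelector",
    "PDBParseError",
    "read_structure",
    "write_structure",
    "resolve_selection",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    """Raised when a coordinate line cannot be parsed."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if not self.element:
            raise ValueError("element must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Residue:
    chain: str
    seqnum: int
    icode: str
    name3: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.name3 = self.name3.upper()

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seqnum, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """A single conformer with ensemble metadata.

    ``model_index`` 0 marks an experimental structure; predicted models
    carry indices 1-5 (CASP convention, model 1 = predictor's best).
    """

    target_id: str = ""
    source_id: str = "experimental"
    model_index: int = 0
    residues: list[Residue] = field(default_factory=list)
    hetero: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.model_index <= 5:
            raise ValueError("model_index must be in 0..5")

    def residue_map(self) -> dict[tuple[str, int, str], Residue]:
        return {r.key: r for r in self.residues}

    def get_residue(self, chain: str, seqnum: int, icode: str = "") -> Residue | None:
        return self.residue_map().get((chain, seqnum, icode))

    def iter_atoms(self, include_hetero: bool = False) -> Iterable[tuple[Residue, Atom]]:
        pools = [self.residues, self.hetero] if include_hetero else [self.residues]
        for pool in pools:
            for res in pool:
                for atom in res.atoms:
                    yield res, atom

    def n_atoms(self, include_hetero: bool = False) -> int:
        return sum(1 for _ in self.iter_atoms(include_hetero))


@dataclass(frozen=True)
class ResidueSelector:
    """Reference to a residue by author numbering. chain '*' is a wildcard."""

    chain: str
    seqnum: int
    icode: str = ""

    @classmethod
    def parse(cls, text: str) -> "ResidueSelector":
        """Parse 'A:123' or 'A:123B' (trailing letter = insertion code)."""
        chain, _, rest = text.partition(":")
        rest = rest.strip()
        icode = ""
        if rest and rest[-1].isalpha():
            icode = rest[-1]
            rest = rest[:-1]
        return cls(chain=chain.strip() or "*", seqnum=int(rest), icode=icode)

    def __str__(self) -> str:
        return f"{self.chain}:{self.seqnum}{self.icode}"


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():  # e.g. 1HB2
        name = name.lstrip("0123456789")
    # protein atom names (CA, CB, OG1, ...) start with the element letter;
    # two-letter elements are expected to use the element column instead
    return name[0].upper() if name else ""


def _parse_coord_line(line: str, lineno: int) -> tuple[str, Atom, str, str, int, str]:
    try:
        record = line[0:6].strip()
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        seqnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed coordinate record at line {lineno}: {line.rstrip()!r}") from exc
    if not element:
        element = _guess_element(name)
    atom = Atom(serial=serial, name=name, element=element.upper(),
                coords=np.array([x, y, z]), occupancy=occ, bfactor=bfac, altloc=altloc)
    return record, atom, resname, chain, seqnum, icode


def _prune_altlocs(residues: list[Residue]) -> None:
    """Keep one conformer per atom name: highest occupancy, tie 'A' < 'B'."""
    for res in residues:
        best: dict[str, Atom] = {}
        for atom in res.atoms:
            cur = best.get(atom.name)
            if cur is None:
                best[atom.name] = atom
            elif atom.occupancy > cur.occupancy or (
                atom.occupancy == cur.occupancy and (atom.altloc or "~") < (cur.altloc or "~")
            ):
                best[atom.name] = atom
        seen: set[str] = set()
        pruned = []
        for atom in res.atoms:
            if atom.name not in seen:
                pruned.append(best[atom.name])
                seen.add(atom.name)
        res.atoms = pruned


def read_structure(path: str | Path, dialect: str = "pdb") -> StructureModel:
    """Parse a PDB or CASP-TS file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"pdb"`` or ``"casp_ts"``. The CASP-TS header lines are parsed in
        both dialects when present; the flag only controls strictness of
        expectations, not the coordinate grammar.
    """
    if dialect not in ("pdb", "casp_ts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise PDBParseError(f"{path}: empty file")

    target_id = ""
    source_id = "experimental"
    model_index = 0
    residues: dict[tuple[str, int, str], Residue] = {}
    hetero: dict[tuple[str, int, str], Residue] = {}
    in_model = 0
    done = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "PFRMAT":
            continue
        if rec == "TARGET":
            target_id = line[6:].strip()
            continue
        if rec == "AUTHOR" and dialect == "casp_ts":
            source_id = line[6:].strip() or source_id
            continue
        if rec == "REMARK":
            continue
        if rec == "MODEL":
            in_model += 1
            if in_model > 1:
                warnings.warn(f"{path}: multiple MODEL blocks; reading the first only")
                done = True
                continue
            tail = line[6:].strip()
            if tail.isdigit():
                idx = int(tail)
                if dialect == "casp_ts" and 1 <= idx <= 5:
                    model_index = idx
            continue
        if rec == "ENDMDL":
            done = True
            continue
        if rec in ("ATOM", "HETATM") and not done:
            record, atom, resname, chain, seqnum, icode = _parse_coord_line(line, lineno)
            key = (chain, seqnum, icode)
            pool = residues if record == "ATOM" else hetero
            if key in residues and record == "HETATM":
                pool = residues  # e.g. MSE in polymer context stays with its residue
            res = pool.get(key)
            if res is None:
                res = Residue(chain=chain, seqnum=seqnum, icode=icode, name3=resname)
                pool[key] = res
            res.atoms.append(atom)

    if not residues and not hetero:
        raise PDBParseError(f"{path}: no coordinate records found")

    res_list = list(residues.values())
    het_list = list(hetero.values())
    _prune_altlocs(res_list)
    _prune_altlocs(het_list)
    if dialect != "casp_ts":
        model_index = 0
    return StructureModel(target_id=target_id, source_id=source_id,
                          model_index=model_index, residues=res_list, hetero=het_list)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(structure: StructureModel, path: str | Path,
                    casp_header: bool = False) -> None:
    """Write a structure as a PDB file (coordinates to 3 decimals).

    With ``casp_header`` a minimal CASP-TS preamble (PFRMAT/TARGET/MODEL)
    is emitted so the file round-trips through ``dialect="casp_ts"``.
    """
    if not structure.residues and not structure.hetero:
        raise ValueError("refusing to write an empty structure")
    lines: list[str] = []
    if casp_header:
        lines.append("PFRMAT TS")
        if structure.target_id:
            lines.append(f"TARGET {structure.target_id}")
        lines.append(f"MODEL  {max(structure.model_index, 1)}")
    serial = 0

    def emit(record: str, res: Residue, atom: Atom) -> None:
        nonlocal serial
        serial += 1
        name = _format_atom_name(atom.name, atom.element)
        x, y, z = atom.coords
        lines.append(
            f"{record:<6s}{serial:5d} {name}{atom.altloc or ' ':1s}{res.name3:>3s} "
            f"{res.chain or 'A':1s}{res.seqnum:4d}{res.icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
            f"          {atom.element:>2s}"
        )

    last_chain = None
    for res in structure.residues:
        if last_chain is not None and res.chain != last_chain:
            lines.append("TER")
        last_chain = res.chain
        for atom in res.atoms:
            emit("ATOM", res, atom)
    if structure.residues:
        lines.append("TER")
    for res in structure.hetero:
        for atom in res.atoms:
            emit("HETATM", res, atom)
    if casp_header:
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def resolve_selection(structure: StructureModel,
                      selectors: Sequence[ResidueSelector]) -> tuple[list[Residue], list[ResidueSelector]]:
    """Resolve selectors against a structure.

    Returns ``(hits, misses)``. Hits preserve selector order; a wildcard
    chain expands to all matching residues in chain-alphabetical order.
    Missing selectors are reported, never silently dropped.
    """
    hits: list[Residue] = []
    misses: list[ResidueSelector] = []
    by_key = structure.residue_map()
    for sel in selectors:
        if sel.chain == "*":
            matched = sorted(
                (r for r in structure.residues
                 if r.seqnum == sel.seqnum and r.icode == (sel.icode or "")),
                key=lambda r: r.chain,
            )
            if matched:
                hits.extend(matched)
            else:
                misses.append(sel)
        else:
            res = by_key.get((sel.chain, sel.seqnum, sel.icode or ""))
            if res is not None:
                hits.append(res)
            else:
                misses.append(sel)
    return hits, misses
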