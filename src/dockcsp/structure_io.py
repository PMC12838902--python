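"""Read/write protein–ligand complex structures and summarise pLDDT confidence.

This module wraps :mod:`gemmi` for PDB/mmCIF parsing and writing, exposing a
light-weight atom container tailored to contact profiling: heavy atoms carry
coordinates, residue identity in author numbering (the numbering NMR and
docking papers quote, e.g. ``N247``), and the B-factor column, which
AlphaFold-family models reuse as the per-residue pLDDT confidence score
(0–100, higher = more confident).

Receptor/ligand splitting uses a small selector grammar with three clause
forms::

    hetatm           all HETATM-flagged atoms
    chain <id>       all atoms in the named chain (peptide ligands)
    resname <name>   all atoms whose residue name matches

Altloc policy: one conformer per atom — the highest-occupancy alternate
location is kept, ties resolved in file order. Hydrogens are parsed and
flagged but excluded from all distance work downstream.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "ComplexStructure",
    "ParseError",
    "ResidueKey",
    "SelectorError",
    "parse_selector",
    "parse_structure",
    "plddt_region_confidence",
    "split_receptor_ligand",
    "write_structure",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {one: three for three, one in AA3_TO_1.items()}

_LABEL_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z]?)$")


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class SelectorError(ValueError):
    """Raised for an invalid or degenerate ligand selector."""


@dataclass(frozen=True)
class ResidueKey:
    """Identity of one residue in author (PDB) numbering.

    ``label`` is the compact one-letter form used throughout NMR titration
    work, e.g. ``R252`` for arginine 252.
    """

    chain: str
    seq_number: int
    res_name: str
    insertion_code: str = ""

    @property
    def label(self) -> str:
        one = AA3_TO_1.get(self.res_name.upper(), "X")
        return f"{one}{self.seq_number}{self.insertion_code}"

    def sort_key(self) -> tuple:
        return (self.chain, self.seq_number, self.insertion_code)

    @classmethod
    def from_label(cls, label: str, chain: str = "A") -> "ResidueKey":
        """Build a key from a compact label like ``"R252"``."""
        m = _LABEL_RE.match(label.strip())
        if not m:
            raise ValueError(f"unparsable residue label {label!r}")
        one, num, icode = m.group(1).upper(), int(m.group(2)), m.group(3)
        res_name = AA1_TO_3.get(one, "UNK")
        return cls(chain=chain, seq_number=num, res_name=res_name,
                   insertion_code=icode.upper())

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue: ResidueKey
    b_factor: float = 0.0
    is_ligand: bool = False
    is_hetero: bool = False
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")


@dataclass
class ComplexStructure:
    """An ordered atom collection for one predicted complex."""

    atoms: list[Atom]
    source_format: str = "PDB"
    source_path: str | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def receptor_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_ligand]

    def ligand_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_ligand]

    def residues(self) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue)
        return list(seen)

    def per_residue_plddt(self) -> dict[ResidueKey, float]:
        """Mean B-factor per residue — the pLDDT for AlphaFold-style models."""
        sums: dict[ResidueKey, list[float]] = {}
        for a in self.atoms:
            sums.setdefault(a.residue, []).append(a.b_factor)
        return {k: float(np.mean(v)) for k, v in sums.items()}


_FORMAT_MAP = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "cif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def parse_structure(path: str | Path, format: str = "auto") -> ComplexStructure:
    """Parse a PDB or mmCIF file into a :class:`ComplexStructure`.

    mmCIF author (``auth_``) numbering is used so residue keys match
    paper-style labels. Only the first model is read; alternate conformers
    are reduced to the highest-occupancy atom.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such structure file: {path}")
    fmt = format.lower()
    if fmt not in _FORMAT_MAP:
        raise ParseError(f"unknown format {format!r}; use pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=_FORMAT_MAP[fmt])
    except Exception as exc:  # gemmi raises RuntimeError/ValueError variants
        raise ParseError(f"could not parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ParseError(f"{path}: no models in structure")
    model = st[0]

    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            key = ResidueKey(
                chain=chain.name,
                seq_number=res.seqid.num,
                res_name=res.name,
                insertion_code=(res.seqid.icode or "").strip(),
            )
            het = res.het_flag == "H"
            # altloc reduction: best occupancy per atom name, first wins ties
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in best.values():
                atoms.append(Atom(
                    serial=at.serial,
                    name=at.name,
                    element=at.element.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue=key,
                    b_factor=at.b_iso,
                    is_hetero=het,
                    is_hydrogen=at.is_hydrogen(),
                ))
    if not atoms:
        raise ParseError(f"{path}: structure contains no atoms")
    detected = "mmCIF" if (fmt == "mmcif" or (fmt == "auto" and path.suffix.lower() in {".cif", ".mmcif"})) else "PDB"
    return ComplexStructure(atoms=atoms, source_format=detected, source_path=str(path))


def write_structure(s: ComplexStructure, path: str | Path) -> Path:
    """Write a structure to PDB (``.pdb``) or mmCIF (``.cif``/``.mmcif``)."""
    path = Path(path)
    # group atoms by chain, then residue, preserving encounter order
    grouped: dict[str, dict[ResidueKey, list[Atom]]] = {}
    for a in s.atoms:
        grouped.setdefault(a.residue.chain, {}).setdefault(a.residue, []).append(a)

    st = gemmi.Structure()
    st.name = "dockcsp"
    model = gemmi.Model("1")
    for chain_name, residues in grouped.items():
        ch = gemmi.Chain(chain_name)
        for rk, res_atoms in residues.items():
            res = gemmi.Residue()
            res.name = rk.res_name
            res.seqid = gemmi.SeqId(rk.seq_number, rk.insertion_code or " ")
            res.het_flag = "H" if res_atoms[0].is_hetero else "A"
            for a in res_atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.b_iso = a.b_factor
                ga.occ = 1.0
                res.add_atom(ga)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    if path.suffix.lower() in {".cif", ".mmcif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))
    return path


def parse_selector(expr: str) -> Callable[[Atom], bool]:
    """Compile a selector expression into an atom predicate.

    Grammar (one clause): ``hetatm`` | ``chain <id>`` | ``resname <name>``.
    """
    tokens = expr.strip().split()
    if not tokens:
        raise SelectorError("empty selector expression")
    head = tokens[0].lower()
    if head == "hetatm":
        if len(tokens) != 1:
            raise SelectorError(f"'hetatm' takes no argument: {expr!r}")
        return lambda a: a.is_hetero
    if head == "chain":
        if len(tokens) != 2:
            raise SelectorError(f"'chain' needs exactly one chain id: {expr!r}")
        want = tokens[1]
        return lambda a: a.residue.chain == want
    if head == "resname":
        if len(tokens) != 2:
            raise SelectorError(f"'resname' needs exactly one residue name: {expr!r}")
        want = tokens[1].upper()
        return lambda a: a.residue.res_name.upper() == want
    raise SelectorError(f"unknown selector clause {tokens[0]!r} in {expr!r}")


def split_receptor_ligand(
    s: ComplexStructure, ligand_selector: str
) -> tuple[list[Atom], list[Atom]]:
    """Partition atoms into (receptor, ligand) by a selector expression.

    The split is exhaustive and disjoint; ``is_ligand`` flags are set on the
    structure's atoms in place. A selector matching zero atoms or every atom
    is an error (no ligand, or no receptor left).
    """
    pred = parse_selector(ligand_selector)
    ligand: list[Atom] = []
    receptor: list[Atom] = []
    for a in s.atoms:
        if pred(a):
            a.is_ligand = True
            ligand.append(a)
        else:
            a.is_ligand = False
            receptor.append(a)
    if not ligand:
        raise SelectorError(f"selector {ligand_selector!r} matched no atoms")
    if not receptor:
        raise SelectorError(
            f"selector {ligand_selector!r} matched every atom; no receptor left"
        )
    return receptor, ligand


_CATEGORIES = ("very_low", "low", "high", "very_high")


def _categorise(plddt: float, thresholds: Sequence[float]) -> str:
    t1, t2, t3 = thresholds
    if plddt < t1:
        return "very_low"
    if plddt < t2:
        return "low"
    if plddt <= t3:
        return "high"
    return "very_high"


def plddt_region_confidence(
    s: ComplexStructure,
    chain: str,
    start: int,
    end: int,
    thresholds: Sequence[float] = (50.0, 70.0, 90.0),
) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-category residue fractions and per-residue pLDDT over a region.

    Categories follow the AlphaFold convention: very_low (< 50), low
    (50–70), high (70–90) and very_high (> 90); the boundaries are
    configurable. Per-residue pLDDT is the mean of the residue's atomic
    B-factors. Returns ``(fractions, table)`` where fractions sum to 1 over
    the residues in the inclusive ``[start, end]`` range of ``chain``.
    """
    if len(thresholds) != 3 or not (thresholds[0] < thresholds[1] < thresholds[2]):
        raise ValueError("thresholds must be three strictly increasing boundaries")
    if end < start:
        raise ValueError(f"empty residue range {start}..{end}")
    per_res = s.per_residue_plddt()
    in_range = {
        k: v for k, v in per_res.items()
        if k.chain == chain and start <= k.seq_number <= end
    }
    present = {k.seq_number for k in in_range}
    missing = sorted(set(range(start, end + 1)) - present)
    if missing:
        raise ValueError(
            f"residues missing from chain {chain} range {start}..{end}: {missing}"
        )
    over_100 = [k.label for k, v in in_range.items() if v > 100.0]
    if over_100:
        warnings.warn(
            f"B-factors exceed 100 for {over_100}; values may not be pLDDT scores",
            stacklevel=2,
        )
    rows = []
    for key in sorted(in_range, key=ResidueKey.sort_key):
        v = in_range[key]
        rows.append({
            "chain": key.chain,
            "seq_number": key.seq_number,
            "res_name": key.res_name,
            "plddt": v,
            "category": _categorise(v, thresholds),
        })
    table = pd.DataFrame(rows)
    n = len(table)
    counts = table["category"].value_counts()
    fractions = {c: float(counts.get(c, 0)) / n for c in _CATEGORIES}
    return fractions, table
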