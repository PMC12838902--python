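"""Distance-binned classification of receptor–ligand contacts.

The central operation of the package: enumerate heavy-atom contacts between
a receptor and a docked ligand, classify each by donor–acceptor distance
into three bins —

* ``moderate_hbond``   — a moderate hydrogen bond,
* ``weak_hbond_vdw``   — a weak hydrogen bond / van der Waals contact at the
  optimum of the attractive well,
* ``hydrophobic``      — a longer-range hydrophobic contact,

— and aggregate per-residue interaction profiles: counts per class, the
contact-bearing residue range, the total number of "binding sites" (one
classified residue↔ligand-atom interaction each), the mean contact
distance, and the hotspot residue with the most contacts.

The same classification/aggregation stage runs either from 3D coordinates
(:func:`enumerate_contacts` on a parsed complex) or directly from a
transcribed per-residue distance table (:func:`profile_from_distance_table`),
which is how published interaction tables are reproduced when pose files
are unavailable.

Bin edges are configurable (:class:`BinScheme`). The default scheme uses
inclusive upper edges at 3.3 / 4.0 / 7.0 Å; ``text`` (2.5–3.5 / 3.5–4.0 /
4.0–6.9 Å) and ``table`` (2.7–3.3 / 3.3–4.0 / 4–10 Å) presets cover the two
conventions found in the docking literature this tooling targets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import AA3_TO_1, Atom, ResidueKey

__all__ = [
    "AtomRole",
    "BinScheme",
    "ContactClass",
    "ContactRecord",
    "DockingSummary",
    "ResidueInteractionProfile",
    "SCHEMES",
    "assign_atom_roles",
    "classify_distance",
    "contacts_to_frame",
    "enumerate_contacts",
    "profile_from_distance_table",
    "read_distance_table",
    "summarize",
]


class ContactClass(str, Enum):
    MODERATE_HBOND = "moderate_hbond"
    WEAK_HBOND_VDW = "weak_hbond_vdw"
    HYDROPHOBIC = "hydrophobic"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class BinScheme:
    """Contiguous half-open distance bins ``(lo, hi]`` for contact classes.

    ``chemistry_gate=True`` additionally requires donor–acceptor pairing for
    the moderate class; a moderate-distance pair without it is demoted to
    ``weak_hbond_vdw`` so the contact count is conserved.
    """

    name: str = "default"
    lo: float = 0.0
    moderate_hi: float = 3.3
    weak_hi: float = 4.0
    hydrophobic_hi: float = 7.0
    chemistry_gate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.moderate_hi < self.weak_hi < self.hydrophobic_hi):
            raise ValueError(f"bin edges must strictly increase: {self}")
        if self.hydrophobic_hi > 10.0:
            raise ValueError("outer hydrophobic cutoff must be <= 10 A")

    def classify(self, d: float) -> ContactClass | None:
        if self.lo < d <= self.moderate_hi:
            return ContactClass.MODERATE_HBOND
        if self.moderate_hi < d <= self.weak_hi:
            return ContactClass.WEAK_HBOND_VDW
        if self.weak_hi < d <= self.hydrophobic_hi:
            return ContactClass.HYDROPHOBIC
        return None


DEFAULT_SCHEME = BinScheme()
TEXT_SCHEME = BinScheme(name="text", lo=2.5, moderate_hi=3.5, weak_hi=4.0,
                        hydrophobic_hi=6.9)
TABLE_SCHEME = BinScheme(name="table", lo=2.7, moderate_hi=3.3, weak_hi=4.0,
                         hydrophobic_hi=10.0)
SCHEMES: dict[str, BinScheme] = {
    "default": DEFAULT_SCHEME,
    "text": TEXT_SCHEME,
    "table": TABLE_SCHEME,
}


def classify_distance(d: float, scheme: BinScheme = DEFAULT_SCHEME) -> ContactClass | None:
    """Classify one contact distance (Å); ``None`` if outside every bin."""
    if not math.isfinite(d) or d <= 0:
        raise ValueError(f"contact distance must be positive and finite, got {d}")
    return scheme.classify(d)


# ---------------------------------------------------------------------------
# atom chemistry roles

@dataclass(frozen=True)
class AtomRole:
    donor: bool = False
    acceptor: bool = False
    hydrophobic: bool = False

    @property
    def polar_other(self) -> bool:
        return not (self.donor or self.acceptor or self.hydrophobic)


# Side-chain hydrogen-bonding atoms of the standard amino acids.
# Backbone N (donor; PRO excepted) and O/OXT (acceptor) are handled generically.
_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"},
}
_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASN": {"OD1"}, "GLN": {"OE1"}, "HIS": {"ND1", "NE2"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "MET": {"SD"}, "CYS": {"SG"},
}
_HBOND_COVALENT_CUTOFF = 1.25  # Å, X–H bond detection for explicit-H ligands


def assign_atom_roles(
    atoms: Sequence[Atom],
    hydrogens: Sequence[Atom] | None = None,
) -> list[AtomRole]:
    """Derive donor/acceptor/hydrophobic roles for each atom.

    Standard amino acids use a residue-chemistry table (backbone amide N is
    a donor, carbonyl O an acceptor; side-chain polar atoms per residue).
    Unknown residues (ligands) fall back to element rules: N/O acceptor, and
    donor either confirmed by an explicit hydrogen within 1.25 Å (when
    ``hydrogens`` is given) or over-approximated as donor from the element
    alone. Carbons and sulfur count as hydrophobic.
    """
    h_coords = None
    if hydrogens:
        h_coords = np.array([h.coords for h in hydrogens])
    warned: set[str] = set()
    roles: list[AtomRole] = []
    for a in atoms:
        el = a.element.upper()
        res = a.residue.res_name.upper()
        hydrophobic = el in {"C", "S"}
        donor = acceptor = False
        if res in AA3_TO_1:
            if el == "N":
                donor = (a.name == "N" and res != "PRO") or \
                    a.name in _SIDECHAIN_DONORS.get(res, set())
                acceptor = a.name in _SIDECHAIN_ACCEPTORS.get(res, set())
            elif el in {"O", "S"}:
                acceptor = a.name in {"O", "OXT"} or \
                    a.name in _SIDECHAIN_ACCEPTORS.get(res, set())
                donor = a.name in _SIDECHAIN_DONORS.get(res, set())
        else:
            if res not in warned:
                warned.add(res)
                warnings.warn(
                    f"unknown residue {res!r}: falling back to element-only "
                    "donor/acceptor rules", stacklevel=2)
            if el in {"N", "O"}:
                acceptor = True
                if h_coords is not None and len(h_coords):
                    d = np.linalg.norm(h_coords - a.coords, axis=1)
                    donor = bool(np.any(d <= _HBOND_COVALENT_CUTOFF))
                else:
                    donor = True  # no explicit H: over-approximate
        roles.append(AtomRole(donor=donor, acceptor=acceptor, hydrophobic=hydrophobic))
    return roles


# ---------------------------------------------------------------------------
# contact records and aggregation

@dataclass(frozen=True)
class ContactRecord:
    """One classified receptor-residue ↔ ligand-atom interaction."""

    residue: ResidueKey
    receptor_atom: str
    ligand_atom: str
    distance: float
    contact_class: ContactClass


@dataclass
class ResidueInteractionProfile:
    residue: ResidueKey
    counts: dict[ContactClass, int] = field(
        default_factory=lambda: {c: 0 for c in ContactClass})
    distances: list[float] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class DockingSummary:
    """Per-ligand aggregation of classified contacts.

    ``total_sites`` counts every classified interaction ("binding site" in
    the docking-table sense: a residue may contribute several).
    ``hotspot`` is the residue with the most contacts (ties broken toward
    the lowest sequence number; all tied residues listed in
    ``hotspot_ties``). ``mean_distance`` is the arithmetic mean over all
    contact distances, NaN for an empty contact list.
    """

    ligand_id: str
    profiles: dict[ResidueKey, ResidueInteractionProfile]
    contacts: list[ContactRecord]
    total_sites: int
    class_counts: dict[ContactClass, int]
    mean_distance: float
    binding_range: tuple[ResidueKey, ResidueKey] | None
    hotspot: ResidueKey | None
    hotspot_count: int
    hotspot_ties: list[ResidueKey]
    flags: list[str] = field(default_factory=list)

    @property
    def mean_distance_2dp(self) -> float:
        return round(self.mean_distance, 2)

    def residues_with_contacts(self) -> set[ResidueKey]:
        return {r for r, p in self.profiles.items() if p.total > 0}

    def to_dict(self) -> dict:
        return {
            "ligand_id": self.ligand_id,
            "total_sites": self.total_sites,
            "class_counts": {str(k): v for k, v in self.class_counts.items()},
            "mean_distance_A": self.mean_distance,
            "mean_distance_A_2dp": None if math.isnan(self.mean_distance)
            else self.mean_distance_2dp,
            "binding_range": None if self.binding_range is None
            else [self.binding_range[0].label, self.binding_range[1].label],
            "hotspot": None if self.hotspot is None else self.hotspot.label,
            "hotspot_count": self.hotspot_count,
            "hotspot_ties": [r.label for r in self.hotspot_ties],
            "per_residue": {
                r.label: {
                    "counts": {str(k): v for k, v in p.counts.items()},
                    "distances_A": list(p.distances),
                }
                for r, p in sorted(self.profiles.items(),
                                   key=lambda kv: kv[0].sort_key())
            },
            "flags": list(self.flags),
        }


REDUCTIONS = ("closest", "all", "closest_per_residue")


def enumerate_contacts(
    receptor: Sequence[Atom],
    ligand: Sequence[Atom],
    scheme: BinScheme = DEFAULT_SCHEME,
    reduction: str = "closest",
) -> list[ContactRecord]:
    """Enumerate classified heavy-atom contacts between receptor and ligand.

    Candidate pairs within the scheme's outer cutoff are found with a k-d
    tree, then reduced:

    * ``closest`` (default) — for each (receptor residue, ligand atom) pair
      keep only the closest receptor atom, so one ligand atom contributes at
      most one contact per residue;
    * ``all`` — keep every in-range pair;
    * ``closest_per_residue`` — one contact per receptor residue.

    Hydrogens are excluded. Records are sorted by residue, then distance.
    """
    if reduction not in REDUCTIONS:
        raise ValueError(f"unknown reduction {reduction!r}; use one of {REDUCTIONS}")
    rec = [a for a in receptor if not a.is_hydrogen]
    lig = [a for a in ligand if not a.is_hydrogen]
    if not rec or not lig:
        raise ValueError("receptor and ligand heavy-atom sets must be non-empty")

    rec_xyz = np.array([a.coords for a in rec])
    lig_xyz = np.array([a.coords for a in lig])
    tree = cKDTree(rec_xyz)
    neighbours = tree.query_ball_point(lig_xyz, r=scheme.hydrophobic_hi)

    # reduce candidate pairs
    best: dict[tuple, tuple[float, int, int]] = {}
    pairs: list[tuple[float, int, int]] = []
    for li, idxs in enumerate(neighbours):
        for ri in idxs:
            d = float(np.linalg.norm(lig_xyz[li] - rec_xyz[ri]))
            if reduction == "all":
                pairs.append((d, ri, li))
                continue
            if reduction == "closest":
                key = (rec[ri].residue, li)
            else:  # closest_per_residue
                key = (rec[ri].residue,)
            prev = best.get(key)
            if prev is None or d < prev[0]:
                best[key] = (d, ri, li)
    if reduction != "all":
        pairs = list(best.values())

    gate_roles = None
    if scheme.chemistry_gate:
        rec_roles = assign_atom_roles(rec)
        lig_h = [a for a in ligand if a.is_hydrogen]
        lig_roles = assign_atom_roles(lig, hydrogens=lig_h or None)
        gate_roles = (rec_roles, lig_roles)

    records: list[ContactRecord] = []
    for d, ri, li in pairs:
        cls = scheme.classify(d)
        if cls is None:
            continue
        if cls is ContactClass.MODERATE_HBOND and gate_roles is not None:
            rr, lr = gate_roles[0][ri], gate_roles[1][li]
            paired = (rr.donor and lr.acceptor) or (rr.acceptor and lr.donor)
            if not paired:
                cls = ContactClass.WEAK_HBOND_VDW
        records.append(ContactRecord(
            residue=rec[ri].residue,
            receptor_atom=rec[ri].name,
            ligand_atom=lig[li].name,
            distance=d,
            contact_class=cls,
        ))
    records.sort(key=lambda c: (c.residue.sort_key(), c.distance, c.ligand_atom))
    return records


def summarize(contacts: Sequence[ContactRecord], ligand_id: str) -> DockingSummary:
    """Aggregate classified contacts into a :class:`DockingSummary`.

    The summary is permutation-invariant in the input order: contacts are
    canonically sorted before aggregation.
    """
    contacts = sorted(contacts, key=lambda c: (c.residue.sort_key(), c.distance,
                                               c.receptor_atom, c.ligand_atom))
    profiles: dict[ResidueKey, ResidueInteractionProfile] = {}
    for c in contacts:
        p = profiles.setdefault(c.residue, ResidueInteractionProfile(c.residue))
        p.counts[c.contact_class] += 1
        p.distances.append(c.distance)

    class_counts = {cls: 0 for cls in ContactClass}
    for c in contacts:
        class_counts[c.contact_class] += 1
    total = len(contacts)
    flags: list[str] = []
    if total == 0:
        mean = math.nan
        rng = None
        hotspot, hotspot_count, ties = None, 0, []
        flags.append("no_contacts: binding range and hotspot undefined")
    else:
        mean = float(np.mean([c.distance for c in contacts]))
        keys = sorted(profiles, key=ResidueKey.sort_key)
        rng = (keys[0], keys[-1])
        max_count = max(p.total for p in profiles.values())
        ties = sorted((r for r, p in profiles.items() if p.total == max_count),
                      key=ResidueKey.sort_key)
        hotspot, hotspot_count = ties[0], max_count
        if len(ties) > 1:
            flags.append("hotspot_tie: " + ",".join(r.label for r in ties))
    return DockingSummary(
        ligand_id=ligand_id,
        profiles=profiles,
        contacts=list(contacts),
        total_sites=total,
        class_counts=class_counts,
        mean_distance=mean,
        binding_range=rng,
        hotspot=hotspot,
        hotspot_count=hotspot_count,
        hotspot_ties=ties,
        flags=flags,
    )


def read_distance_table(path: str | Path) -> pd.DataFrame:
    """Read a per-residue distance table CSV (``residue,distance_A``)."""
    df = pd.read_csv(path, comment="#")
    missing = {"residue", "distance_A"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: distance table lacks columns {sorted(missing)}")
    return df


def profile_from_distance_table(
    table: pd.DataFrame | str | Path,
    scheme: BinScheme = DEFAULT_SCHEME,
    ligand_id: str = "ligand",
    chain: str = "A",
) -> DockingSummary:
    """Classify and aggregate a labelled distance list, bypassing 3D geometry.

    Each row ``(residue label, distance in Å)`` — the form in which docking
    interaction tables are published — is classified with
    :func:`classify_distance` and aggregated with :func:`summarize`.
    Distances falling outside every bin are skipped with a warning.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_distance_table(table)
    records: list[ContactRecord] = []
    for i, row in table.iterrows():
        try:
            key = ResidueKey.from_label(str(row["residue"]), chain=chain)
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        d = float(row["distance_A"])
        cls = classify_distance(d, scheme)
        if cls is None:
            warnings.warn(
                f"row {i} ({key.label}, {d} A) outside every bin of scheme "
                f"{scheme.name!r}; skipped", stacklevel=2)
            continue
        records.append(ContactRecord(
            residue=key, receptor_atom="", ligand_atom="",
            distance=d, contact_class=cls))
    records.sort(key=lambda c: (c.residue.sort_key(), c.distance))
    return summarize(records, ligand_id)


def contacts_to_frame(contacts: Sequence[ContactRecord]) -> pd.DataFrame:
    """Contacts as a DataFrame (CSV-ready; distances at full precision)."""
    return pd.DataFrame([
        {
            "residue_label": c.residue.label,
            "chain": c.residue.chain,
            "receptor_atom": c.receptor_atom,
            "ligand_atom": c.ligand_atom,
            "distance_A": c.distance,
            "class": str(c.contact_class),
        }
        for c in contacts
    ])
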