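"""Synthetic toy complexes, CSP titration fixtures, and bundled reference tables.

Three generators make every pipeline stage testable without any external
download:

* :func:`make_toy_complex` builds a minimal receptor scaffold and places
  ligand atoms at exactly prescribed distances from chosen receptor atoms,
  emitting a PDB file plus an analytically known ground-truth contact table.
  The scaffold is deliberately unphysical (widely spaced backbone-only
  residues): geometry, not stereochemistry, is under test.
* :func:`make_csp_fixture` synthesises free/bound amide shift tables whose
  combined CSP profile has a prescribed shape — a single peak residue (the
  R252 analogue of a PSTD titration) on a contiguous elevated plateau (the
  N247–Y255 analogue) over a low background — with optional bounded noise
  that provably cannot displace the peak.
* :func:`paper_fixtures` returns the transcribed published interaction
  tables and CSP summary shipped with the package, with their recorded
  internal discrepancies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .contact_profiler import DEFAULT_SCHEME, BinScheme, classify_distance
from .structure_io import (AA1_TO_3, Atom, ComplexStructure, ResidueKey,
                           write_structure)

__all__ = [
    "CSPFixtureSpec",
    "FixtureBundle",
    "LigandPlacement",
    "PlacementError",
    "ToyComplexSpec",
    "make_csp_fixture",
    "make_toy_complex",
    "paper_fixtures",
    "scaffold_receptor",
    "spec_from_contacts",
]

MIN_PLACEMENT_D = 2.0
MAX_PLACEMENT_D = 10.0
# PSTD N-terminal residue identities (246K..255Y); padding beyond is synthetic.
PSTD_NTERM = "KNKLKVRTAY"
PSTD_START = 246


class PlacementError(ValueError):
    """A ligand placement violates the toy-complex geometry guarantees."""


@dataclass(frozen=True)
class LigandPlacement:
    """One ligand atom at a prescribed distance from a receptor atom."""

    target_residue: str          # compact label, e.g. "R252"
    target_atom: str             # atom name within that residue, e.g. "CA"
    distance: float              # Å, realized exactly
    direction: tuple[float, float, float]
    element: str = "C"


@dataclass
class ToyComplexSpec:
    receptor: list[tuple[ResidueKey, str, str, tuple[float, float, float]]]
    ligand_placements: list[LigandPlacement]
    ligand_resname: str = "LIG"
    ligand_chain: str = "L"
    seed: int = 0


def scaffold_receptor(
    labels: Sequence[str],
    chain: str = "A",
    spacing: float = 15.0,
) -> list[tuple[ResidueKey, str, str, tuple[float, float, float]]]:
    """Backbone-only (N, CA, C) residues spaced along x.

    The wide spacing isolates residues so each ligand placement interacts
    with exactly its target residue under any bin scheme with an outer
    cutoff below ``spacing/2``.
    """
    out = []
    for i, label in enumerate(labels):
        key = ResidueKey.from_label(label, chain=chain)
        x0 = i * spacing
        out.append((key, "N", "N", (x0, 0.0, 0.0)))
        out.append((key, "CA", "C", (x0 + 1.5, 0.0, 0.0)))
        out.append((key, "C", "C", (x0 + 3.0, 0.0, 0.0)))
    return out


def spec_from_contacts(
    rows: Sequence[tuple[str, float]],
    ligand_resname: str = "LIG",
    seed: int = 0,
    angle_step_deg: float = 40.0,
) -> ToyComplexSpec:
    """Build a toy-complex spec realizing a (residue label, distance) multiset.

    Residues appear once each in a widely spaced scaffold; multiple ligand
    atoms on one residue fan out in the y–z plane at ``angle_step_deg``
    increments from its CA, so placements stay mutually separated.
    """
    labels = list(dict.fromkeys(label for label, _ in rows))
    receptor = scaffold_receptor(labels)
    counts: dict[str, int] = {}
    placements = []
    for label, d in rows:
        k = counts.get(label, 0)
        counts[label] = k + 1
        theta = np.deg2rad(k * angle_step_deg)
        placements.append(LigandPlacement(
            target_residue=label, target_atom="CA", distance=float(d),
            direction=(0.0, float(np.cos(theta)), float(np.sin(theta)))))
    return ToyComplexSpec(receptor=receptor, ligand_placements=placements,
                          ligand_resname=ligand_resname, seed=seed)


def make_toy_complex(
    spec: ToyComplexSpec,
    path: str | Path | None = None,
    scheme: BinScheme = DEFAULT_SCHEME,
) -> tuple[ComplexStructure, pd.DataFrame]:
    """Realize a toy complex and its analytic ground-truth contact table.

    Guarantees checked at build time (raising :exc:`PlacementError`
    otherwise): prescribed distances lie in (2, 10) Å and are realized
    exactly; no placed atom comes within 2 Å of any non-target atom; the
    target atom is the strict nearest receptor atom to its ligand atom; and
    every other receptor residue lies beyond the scheme's outer cutoff, so
    the truth table is complete under that scheme.

    Returns the structure (written to ``path`` if given) and a table with
    one row per placement: ligand serial, residue, target atom, exact
    distance and expected contact class (empty for beyond-cutoff
    placements).
    """
    atoms: list[Atom] = []
    serial = 1
    coord_index: dict[tuple[str, str], np.ndarray] = {}
    for key, name, element, xyz in spec.receptor:
        atoms.append(Atom(serial=serial, name=name, element=element,
                          coords=np.asarray(xyz, float), residue=key))
        coord_index[(key.label, name)] = np.asarray(xyz, float)
        serial += 1
    if not atoms:
        raise PlacementError("spec has an empty receptor")

    rec_atoms = list(atoms)
    truth_rows = []
    lig_positions: list[np.ndarray] = []
    lig_key_cache: dict[str, ResidueKey] = {}
    for n, pl in enumerate(spec.ligand_placements, start=1):
        if not (MIN_PLACEMENT_D < pl.distance < MAX_PLACEMENT_D):
            raise PlacementError(
                f"placement {n}: distance {pl.distance} outside "
                f"({MIN_PLACEMENT_D}, {MAX_PLACEMENT_D}) A")
        direction = np.asarray(pl.direction, float)
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise PlacementError(f"placement {n}: zero direction vector")
        direction = direction / norm
        target = coord_index.get((pl.target_residue, pl.target_atom))
        if target is None:
            raise PlacementError(
                f"placement {n}: no receptor atom "
                f"{pl.target_residue}/{pl.target_atom}")
        pos = target + pl.distance * direction

        # geometry guarantees
        for a in rec_atoms:
            d_other = float(np.linalg.norm(pos - a.coords))
            same_target = (a.residue.label == pl.target_residue
                           and a.name == pl.target_atom)
            if same_target:
                continue
            if d_other < MIN_PLACEMENT_D:
                raise PlacementError(
                    f"placement {n}: collides with {a.residue.label}/{a.name} "
                    f"at {d_other:.2f} A")
            if a.residue.label == pl.target_residue:
                if d_other <= pl.distance:
                    raise PlacementError(
                        f"placement {n}: {a.residue.label}/{a.name} at "
                        f"{d_other:.2f} A is nearer than the target atom")
            elif d_other <= scheme.hydrophobic_hi:
                raise PlacementError(
                    f"placement {n}: residue {a.residue.label} intrudes within "
                    f"the {scheme.hydrophobic_hi} A cutoff ({d_other:.2f} A)")
        for m, prev in enumerate(lig_positions, start=1):
            if float(np.linalg.norm(pos - prev)) < MIN_PLACEMENT_D:
                raise PlacementError(
                    f"placement {n}: collides with ligand atom {m}")
        lig_positions.append(pos)

        lig_key = lig_key_cache.setdefault(
            spec.ligand_resname,
            ResidueKey(chain=spec.ligand_chain, seq_number=1,
                       res_name=spec.ligand_resname))
        atom_name = f"{pl.element}{n}"
        atoms.append(Atom(serial=serial, name=atom_name, element=pl.element,
                          coords=pos, residue=lig_key, is_ligand=True,
                          is_hetero=True))
        cls = scheme.classify(pl.distance)
        truth_rows.append({
            "ligand_atom": atom_name,
            "residue": pl.target_residue,
            "target_atom": pl.target_atom,
            "distance_A": pl.distance,
            "contact_class": "" if cls is None else str(cls),
        })
        serial += 1

    structure = ComplexStructure(atoms=atoms, source_format="PDB")
    if path is not None:
        write_structure(structure, path)
    truth = pd.DataFrame(truth_rows,
                         columns=["ligand_atom", "residue", "target_atom",
                                  "distance_A", "contact_class"])
    return structure, truth


# ---------------------------------------------------------------------------
# CSP fixtures

@dataclass
class CSPFixtureSpec:
    """Prescribed shape of a synthetic per-residue CSP profile.

    ``plateau_level`` and ``background_level`` are fractions of
    ``peak_value``. Noise is bounded (clipped at ±2 sd) and admissible only
    when ``2 * noise_sd < (peak - plateau) / 2``, which guarantees the noisy
    peak still exceeds every noisy plateau value.
    """

    span_start: int = 246
    span_end: int = 277
    peak_residue: str = "R252"
    peak_value: float = 0.151
    plateau_start: int = 247
    plateau_end: int = 255
    plateau_level: float = 0.6
    background_level: float = 0.1
    noise_sd: float = 0.0
    alpha: float = 5.0
    chain: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.peak_value > 0):
            raise ValueError("peak_value must be positive")
        if not (0.0 <= self.background_level < self.plateau_level < 1.0):
            raise ValueError(
                "need 0 <= background_level < plateau_level < 1 (fractions of peak)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (self.span_start <= self.plateau_start
                <= self.plateau_end <= self.span_end):
            raise ValueError("plateau must lie inside the residue span")


def _fixture_labels(spec: CSPFixtureSpec) -> list[str]:
    labels = []
    for seq in range(spec.span_start, spec.span_end + 1):
        offset = seq - PSTD_START
        one = PSTD_NTERM[offset] if 0 <= offset < len(PSTD_NTERM) else "A"
        labels.append(f"{one}{seq}")
    return labels


def make_csp_fixture(
    spec: CSPFixtureSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthesise ``(free, bound, truth_csp)`` tables for one titration.

    The bound table perturbs the free shifts so that the combined CSP of
    each residue equals its prescribed (noisy) target exactly, with the
    perturbation split between the ¹H and ¹⁵N dimensions at a random angle.
    Raises :class:`ValueError` when the noise is too large for the peak to
    be guaranteed.
    """
    sep = spec.peak_value * (1.0 - spec.plateau_level)
    if spec.noise_sd > 0 and spec.noise_sd >= sep / 4.0:
        raise ValueError(
            f"noise sd {spec.noise_sd} too large: must be < (peak - plateau)/4 "
            f"= {sep / 4.0:.4g} to guarantee peak recovery")
    # the plateau stays above the default 0.5x-of-peak significance
    # threshold only while 2 sd <= (plateau_level - 0.5) * peak; peak
    # recovery alone does not need this, so it warns instead of erroring
    plateau_margin = (spec.plateau_level - 0.5) * spec.peak_value
    if spec.noise_sd > 0 and 2 * spec.noise_sd > plateau_margin:
        warnings.warn(
            f"noise sd {spec.noise_sd} exceeds half the plateau margin "
            f"{plateau_margin:.4g}: the significant range is no longer "
            "guaranteed to cover the whole plateau", stacklevel=2)
    labels = _fixture_labels(spec)
    if spec.peak_residue not in labels:
        raise ValueError(
            f"peak residue {spec.peak_residue} outside span "
            f"{spec.span_start}..{spec.span_end} (labels are PSTD-style)")
    rng = np.random.default_rng(spec.seed)

    targets = []
    for label in labels:
        seq = int(label[1:])
        if label == spec.peak_residue:
            c = spec.peak_value
        elif spec.plateau_start <= seq <= spec.plateau_end:
            c = spec.plateau_level * spec.peak_value
        else:
            c = spec.background_level * spec.peak_value
        if spec.noise_sd > 0 and label != spec.peak_residue:
            # bounded noise: clipped at 2 sd, so plateau+noise < peak stays true
            c += float(np.clip(rng.normal(0.0, spec.noise_sd),
                               -2 * spec.noise_sd, 2 * spec.noise_sd))
            c = max(c, 0.0)
        targets.append(c)

    free_h = rng.uniform(7.8, 8.8, size=len(labels))
    free_n = rng.uniform(112.0, 126.0, size=len(labels))
    theta = rng.uniform(0.0, np.pi / 2, size=len(labels))
    sign_h = rng.choice([-1.0, 1.0], size=len(labels))
    sign_n = rng.choice([-1.0, 1.0], size=len(labels))
    c = np.asarray(targets)
    dh = sign_h * c * np.cos(theta)
    dn = sign_n * spec.alpha * c * np.sin(theta)

    free = pd.DataFrame({"residue": labels, "delta_H_ppm": free_h,
                         "delta_N_ppm": free_n})
    bound = pd.DataFrame({"residue": labels, "delta_H_ppm": free_h + dh,
                          "delta_N_ppm": free_n + dn})
    truth = pd.DataFrame({"residue": labels, "csp_ppm": c})
    return free, bound, truth


# ---------------------------------------------------------------------------
# bundled reference fixtures

@dataclass(frozen=True)
class FixtureBundle:
    cmp_distances: Path
    lmwh_distances_table: Path
    lfcinb11_distances: Path
    table2_summary: Path
    metadata: dict


def paper_fixtures() -> FixtureBundle:
    """Paths to the transcribed published tables shipped with the package.

    ``metadata`` records the internal discrepancies of the source tables
    (conflicting LMWH totals, means that do not match their distance lists,
    and the two reported LFcinB11 concentrations).
    """
    root = Path(__file__).parent / "data"
    meta = json.loads((root / "fixtures_meta.json").read_text())
    return FixtureBundle(
        cmp_distances=root / "cmp_distances.csv",
        lmwh_distances_table=root / "lmwh_distances_table.csv",
        lfcinb11_distances=root / "lfcinb11_distances.csv",
        table2_summary=root / "table2_summary.csv",
        metadata=meta,
    )
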