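"""Cross-check a docking-derived binding map against an NMR CSP profile.

A docking pose and a titration experiment each nominate a set of binding
residues: the contact-bearing residues of the pose, and the largest-CSP
range of the titration. Their agreement is scored with a Jaccard index over
residue sets, together with whether the two hotspots (most contacts vs
largest CSP) coincide. A qualitative verdict — consistent / partial /
inconsistent — follows from configurable Jaccard thresholds (defaults
0.8 / 0.4) plus hotspot agreement.

By default the docking residue set contains exactly the residues with at
least one classified contact, so interior gaps in the binding stretch count
against the overlap; ``residue_mode="interval"`` uses the min–max span
instead, matching the looser convention of reporting binding as a residue
range.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .contact_profiler import DockingSummary
from .csp_analysis import CSPProfile, significant_range
from .structure_io import ResidueKey

__all__ = ["ConsistencyReport", "compare", "render_report"]

VERDICTS = ("consistent", "partial", "inconsistent")


@dataclass
class ConsistencyReport:
    ligand_id: str
    docking_range: tuple[ResidueKey, ResidueKey] | None
    csp_range: tuple[ResidueKey, ResidueKey] | None
    range_jaccard: float
    hotspot_docking: ResidueKey | None
    hotspot_csp: ResidueKey | None
    hotspot_match: bool
    docking_hotspot_count: int
    csp_peak_value: float
    verdict: str
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        fmt_range = lambda r: None if r is None else f"{r[0].label}-{r[1].label}"
        return {
            "ligand_id": self.ligand_id,
            "docking_range": fmt_range(self.docking_range),
            "csp_range": fmt_range(self.csp_range),
            "range_jaccard": self.range_jaccard,
            "hotspot_docking": getattr(self.hotspot_docking, "label", None),
            "hotspot_csp": getattr(self.hotspot_csp, "label", None),
            "hotspot_match": self.hotspot_match,
            "docking_hotspot_count": self.docking_hotspot_count,
            "csp_peak_value": self.csp_peak_value,
            "verdict": self.verdict,
            "reasons": list(self.reasons),
        }


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def compare(
    docking: DockingSummary,
    csp: CSPProfile,
    jaccard_thresholds: tuple[float, float] = (0.8, 0.4),
    residue_mode: str = "contacts",
    fraction_of_max: float = 0.5,
) -> ConsistencyReport:
    """Score docking-vs-CSP agreement for one ligand.

    Residues are matched on (sequence number, insertion code); the two
    inputs are expected to describe the same ligand (differing ids produce
    a warning reason, not an error).
    """
    upper, lower = jaccard_thresholds
    if not (0.0 <= lower <= upper <= 1.0):
        raise ValueError(f"thresholds must satisfy 0 <= lower <= upper <= 1, "
                         f"got {jaccard_thresholds}")
    if residue_mode not in ("contacts", "interval"):
        raise ValueError(f"unknown residue_mode {residue_mode!r}")
    reasons: list[str] = []
    if docking.ligand_id != csp.ligand_id:
        reasons.append(f"ligand_id_mismatch: docking={docking.ligand_id!r} "
                       f"csp={csp.ligand_id!r}")

    # CSP side: significant range, if defined
    csp_rng = None
    csp_set: set[tuple[int, str]] = set()
    if csp.peak_index is not None:
        lo, hi = significant_range(csp, fraction_of_max)
        csp_rng = (lo, hi)
        csp_set = {(r.seq_number, r.insertion_code) for r in csp.residues
                   if lo.seq_number <= r.seq_number <= hi.seq_number
                   and r.chain == lo.chain}
    else:
        reasons.append("csp_profile_all_zero")

    # docking side
    dock_set: set[tuple[int, str]] = set()
    if docking.total_sites == 0:
        reasons.append("no_docking_contacts")
    elif residue_mode == "contacts":
        dock_set = {(r.seq_number, r.insertion_code)
                    for r in docking.residues_with_contacts()}
    else:
        lo, hi = docking.binding_range
        dock_set = {(n, "") for n in range(lo.seq_number, hi.seq_number + 1)}

    jac = _jaccard(dock_set, csp_set)
    hotspot_match = (docking.hotspot is not None and csp.peak_residue is not None
                     and docking.hotspot.seq_number == csp.peak_residue.seq_number
                     and docking.hotspot.insertion_code
                     == csp.peak_residue.insertion_code)

    if docking.total_sites == 0 or csp.peak_index is None:
        verdict = "inconsistent"
    elif jac >= upper and hotspot_match:
        verdict = "consistent"
    elif jac >= lower:
        verdict = "partial"
    else:
        verdict = "inconsistent"

    return ConsistencyReport(
        ligand_id=docking.ligand_id,
        docking_range=docking.binding_range,
        csp_range=csp_rng,
        range_jaccard=jac,
        hotspot_docking=docking.hotspot,
        hotspot_csp=csp.peak_residue,
        hotspot_match=hotspot_match,
        docking_hotspot_count=docking.hotspot_count,
        csp_peak_value=csp.peak_value,
        verdict=verdict,
        reasons=reasons,
    )


_COLUMNS = [
    "ligand_id", "docking_range", "csp_range", "range_jaccard",
    "hotspot_docking", "hotspot_csp", "hotspot_match",
    "docking_hotspot_count", "csp_peak_value", "verdict", "reasons",
]


def render_report(reports: Sequence[ConsistencyReport], format: str = "markdown") -> str:
    """Render reports as ``csv``, ``json`` or ``markdown``.

    Rows are ordered by descending CSP peak (ranking order), then ligand id.
    Numeric fields keep full precision in csv/json; markdown displays two
    decimals.
    """
    if not reports:
        raise ValueError("need at least one report to render")
    ordered = sorted(reports, key=lambda r: (-r.csp_peak_value, r.ligand_id))
    dicts = [r.to_dict() for r in ordered]
    if format == "json":
        return json.dumps(dicts, indent=2)
    if format == "csv":
        rows = [{**d, "reasons": ";".join(d["reasons"])} for d in dicts]
        return pd.DataFrame(rows, columns=_COLUMNS).to_csv(index=False)
    if format == "markdown":
        header = ("| ligand | docking range | CSP range | Jaccard | "
                  "docking hotspot | CSP hotspot | match | verdict |")
        sep = "|" + "---|" * 8
        lines = [header, sep]
        for d in dicts:
            lines.append(
                f"| {d['ligand_id']} | {d['docking_range'] or '—'} "
                f"| {d['csp_range'] or '—'} | {d['range_jaccard']:.2f} "
                f"| {d['hotspot_docking'] or '—'} "
                f"({d['docking_hotspot_count']}) "
                f"| {d['hotspot_csp'] or '—'} ({d['csp_peak_value']:.2f} ppm) "
                f"| {'yes' if d['hotspot_match'] else 'no'} "
                f"| {d['verdict']} |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}; use csv, json or markdown")
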