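"""Per-residue chemical-shift-perturbation (CSP) analysis of ligand titrations.

Amide CSPs from ¹H-¹⁵N HSQC titrations report, residue by residue, how much
a ligand perturbs the protein backbone. The two dimensions are combined on
a common ppm scale as

    CSP = sqrt( ΔδH² + (ΔδN / α)² )

with α = 5 by default (the ¹⁵N axis spans roughly five times the ppm range
of ¹H; the alternative convention sqrt(ΔδH² + (0.14·ΔδN)²) corresponds to
α ≈ 7.14 and is available by passing ``alpha=1/0.14``).

From a combined profile the module locates the peak residue, the maximal
contiguous run of residues above a fraction of the peak (the
"largest-CSP range"), and orders ligands by perturbation strength, using
ligand concentration as tie-break: an equal CSP reached at lower
concentration indicates the stronger binder.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .structure_io import ResidueKey

__all__ = [
    "CSPProfile",
    "RankingResult",
    "combined_csp",
    "csp_profile",
    "parse_concentration",
    "profile_from_csp_table",
    "rank_ligands",
    "read_csp_table",
    "read_shift_table",
    "significant_range",
]

DEFAULT_ALPHA = 5.0


def combined_csp(delta_h, delta_n, alpha: float = DEFAULT_ALPHA):
    """Combined amide CSP in ppm; accepts scalars or arrays.

    Non-negative, zero iff both shifts are zero, and invariant to the sign
    of either shift.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    dh = np.asarray(delta_h, dtype=float)
    dn = np.asarray(delta_n, dtype=float)
    out = np.sqrt(dh ** 2 + (dn / alpha) ** 2)
    return float(out) if out.ndim == 0 else out


_CONC_RE = re.compile(r"^\s*([0-9.]+)\s*(mM|uM|µM|nM|M)\s*$", re.IGNORECASE)
_CONC_SCALE = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}


def parse_concentration(text: str | float | None) -> float | None:
    """Parse ``"80uM"``/``"1mM"`` style concentrations to molar."""
    if text is None or isinstance(text, (int, float)):
        return None if text is None else float(text)
    m = _CONC_RE.match(text)
    if not m:
        raise ValueError(f"unparsable concentration {text!r}")
    return float(m.group(1)) * _CONC_SCALE[m.group(2).lower()]


@dataclass
class CSPProfile:
    """Combined CSPs over an ordered residue span for one ligand titration."""

    ligand_id: str
    residues: list[ResidueKey]
    values: np.ndarray
    concentration: float | None = None  # molar; metadata + ranking tie-break
    alpha: float = DEFAULT_ALPHA
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residues) != len(self.values):
            raise ValueError("residues and values must have equal length")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("CSP values must be finite and non-negative")

    @property
    def peak_index(self) -> int | None:
        if len(self.values) == 0 or float(self.values.max()) == 0.0:
            return None
        return int(np.argmax(self.values))

    @property
    def peak_residue(self) -> ResidueKey | None:
        i = self.peak_index
        return None if i is None else self.residues[i]

    @property
    def peak_value(self) -> float:
        return float(self.values.max()) if len(self.values) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": [r.label for r in self.residues],
            "csp_ppm": self.values,
        })


def read_shift_table(path: str | Path) -> pd.DataFrame:
    """Read an amide shift table (``residue,delta_H_ppm,delta_N_ppm``)."""
    df = pd.read_csv(path, comment="#")
    missing = {"residue", "delta_H_ppm", "delta_N_ppm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: shift table lacks columns {sorted(missing)}")
    if df["residue"].duplicated().any():
        dup = df.loc[df["residue"].duplicated(), "residue"].tolist()
        raise ValueError(f"{path}: duplicate residues {dup}")
    return df


def read_csp_table(path: str | Path) -> pd.DataFrame:
    """Read a pre-combined CSP table (``residue,csp_ppm``)."""
    df = pd.read_csv(path, comment="#")
    missing = {"residue", "csp_ppm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: CSP table lacks columns {sorted(missing)}")
    return df


def csp_profile(
    free: pd.DataFrame | str | Path,
    bound: pd.DataFrame | str | Path,
    ligand_id: str,
    concentration: str | float | None = None,
    alpha: float = DEFAULT_ALPHA,
    chain: str = "A",
) -> CSPProfile:
    """Combined per-residue CSPs from free and ligand-bound shift tables.

    Profiles are computed on the residue intersection, ordered by sequence
    number; unmatched residues on either side are reported in ``flags``
    (and as a warning), never silently dropped.
    """
    if not isinstance(free, pd.DataFrame):
        free = read_shift_table(free)
    if not isinstance(bound, pd.DataFrame):
        bound = read_shift_table(bound)
    merged = free.merge(bound, on="residue", suffixes=("_free", "_bound"))
    if merged.empty:
        raise ValueError("free and bound tables share no residues")
    flags: list[str] = []
    only_free = sorted(set(free["residue"]) - set(bound["residue"]))
    only_bound = sorted(set(bound["residue"]) - set(free["residue"]))
    for name, extra in (("free", only_free), ("bound", only_bound)):
        if extra:
            msg = f"residues only in {name} table: {','.join(map(str, extra))}"
            flags.append(msg)
            warnings.warn(msg, stacklevel=2)

    keys = [ResidueKey.from_label(str(r), chain=chain) for r in merged["residue"]]
    order = sorted(range(len(keys)), key=lambda i: keys[i].sort_key())
    keys = [keys[i] for i in order]
    dh = (merged["delta_H_ppm_bound"] - merged["delta_H_ppm_free"]).to_numpy()[order]
    dn = (merged["delta_N_ppm_bound"] - merged["delta_N_ppm_free"]).to_numpy()[order]
    values = combined_csp(dh, dn, alpha=alpha)
    profile = CSPProfile(
        ligand_id=ligand_id,
        residues=keys,
        values=values,
        concentration=parse_concentration(concentration),
        alpha=alpha,
        flags=flags,
    )
    if profile.peak_index is None:
        profile.flags.append("all_zero: peak undefined")
    return profile


def profile_from_csp_table(
    table: pd.DataFrame | str | Path,
    ligand_id: str,
    concentration: str | float | None = None,
    chain: str = "A",
) -> CSPProfile:
    """Build a profile from a pre-combined CSP table (published curve data)."""
    if not isinstance(table, pd.DataFrame):
        table = read_csp_table(table)
    keys = [ResidueKey.from_label(str(r), chain=chain) for r in table["residue"]]
    order = sorted(range(len(keys)), key=lambda i: keys[i].sort_key())
    return CSPProfile(
        ligand_id=ligand_id,
        residues=[keys[i] for i in order],
        values=table["csp_ppm"].to_numpy(dtype=float)[order],
        concentration=parse_concentration(concentration),
    )


def significant_range(
    profile: CSPProfile, fraction_of_max: float = 0.5
) -> tuple[ResidueKey, ResidueKey]:
    """Maximal contiguous residue run with CSP ≥ fraction×peak, containing the peak.

    Contiguity requires consecutive sequence numbers; a gap in the table
    breaks the run. The default fraction 0.5 delineates the
    "largest-CSP range" reported for titration curves.
    """
    if not (0.0 < fraction_of_max <= 1.0):
        raise ValueError(f"fraction_of_max must be in (0, 1], got {fraction_of_max}")
    i = profile.peak_index
    if i is None:
        raise ValueError("profile has no strictly positive maximum")
    threshold = fraction_of_max * profile.peak_value
    res, vals = profile.residues, profile.values

    def contiguous(j: int, k: int) -> bool:
        return (res[k].chain == res[j].chain
                and res[k].seq_number - res[j].seq_number == 1)

    lo = i
    while lo > 0 and contiguous(lo - 1, lo) and vals[lo - 1] >= threshold:
        lo -= 1
    hi = i
    while hi < len(res) - 1 and contiguous(hi, hi + 1) and vals[hi + 1] >= threshold:
        hi += 1
    return res[lo], res[hi]


@dataclass
class RankingResult:
    order: list[str]
    profiles: list[CSPProfile]
    flags: list[str] = field(default_factory=list)


def rank_ligands(profiles: Sequence[CSPProfile]) -> RankingResult:
    """Order ligands from strongest to weakest perturbation.

    Descending peak CSP; ties broken toward the lower ligand concentration
    (an equal perturbation at lower concentration implies tighter binding);
    residual ties alphabetical and flagged. Profiles with unknown
    concentration are flagged concentration-incomparable when a tie-break
    would need it.
    """
    if not profiles:
        raise ValueError("need at least one profile to rank")
    flags: list[str] = []

    def key(p: CSPProfile):
        conc = p.concentration if p.concentration is not None else math.inf
        return (-p.peak_value, conc, p.ligand_id)

    ordered = sorted(profiles, key=key)
    by_peak: dict[float, list[CSPProfile]] = {}
    for p in profiles:
        by_peak.setdefault(p.peak_value, []).append(p)
    for peak, group in by_peak.items():
        if len(group) < 2:
            continue
        ids = sorted(p.ligand_id for p in group)
        concs = [p.concentration for p in group]
        if any(c is None for c in concs):
            flags.append(f"concentration_incomparable: {','.join(ids)} @ peak {peak}")
        elif len(set(concs)) < len(concs):
            flags.append(f"tie_broken_alphabetically: {','.join(ids)} @ peak {peak}")
    return RankingResult(order=[p.ligand_id for p in ordered],
                         profiles=list(ordered), flags=flags)


def plot_profile(profile: CSPProfile, path: str | Path,
                 fraction_of_max: float = 0.5) -> Path:
    """Save a CSP-vs-residue curve with the significant range shaded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    x = [r.seq_number for r in profile.residues]
    ax.plot(x, profile.values, marker="o", ms=3, lw=1)
    if profile.peak_index is not None:
        lo, hi = significant_range(profile, fraction_of_max)
        ax.axvspan(lo.seq_number, hi.seq_number, alpha=0.15, color="tab:orange")
        ax.annotate(profile.peak_residue.label,
                    (profile.peak_residue.seq_number, profile.peak_value))
    ax.set_xlabel("residue number")
    ax.set_ylabel("combined CSP (ppm)")
    ax.set_title(profile.ligand_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
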