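"""Shared fixtures: random atom sets and an independent contact oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dockcsp.contact_profiler import BinScheme, ContactClass
from dockcsp.structure_io import Atom, ResidueKey

AA_NAMES = ["ALA", "LEU", "LYS", "ARG", "THR", "VAL", "ASN", "TYR", "SER", "GLY"]


def random_complex(rng: np.random.Generator, n_res: int = 40,
                   atoms_per_res: int = 5, n_lig: int = 20,
                   box: float = 30.0):
    """Random receptor residues and ligand atoms in a cubic box (Å)."""
    receptor = []
    serial = 1
    for i in range(n_res):
        key = ResidueKey(chain="A", seq_number=100 + i,
                         res_name=AA_NAMES[i % len(AA_NAMES)])
        centre = rng.uniform(0, box, 3)
        for j in range(atoms_per_res):
            receptor.append(Atom(
                serial=serial, name=f"X{j}", element="C",
                coords=centre + rng.normal(0, 1.5, 3), residue=key))
            serial += 1
    lig_key = ResidueKey(chain="L", seq_number=1, res_name="LIG")
    ligand = [
        Atom(serial=serial + k, name=f"L{k}", element="C",
             coords=rng.uniform(0, box, 3), residue=lig_key,
             is_ligand=True, is_hetero=True)
        for k in range(n_lig)
    ]
    return receptor, ligand


def brute_force_contacts(receptor, ligand, scheme: BinScheme,
                         reduction: str = "closest"):
    """All-pairs reference enumeration, written independently of the k-d tree
    path: plain double loop, plain dict reduction.

    Returns a set of (residue label, receptor atom, ligand atom,
    distance rounded to 1e-9, class value) tuples.
    """
    rec = [a for a in receptor if not a.is_hydrogen]
    lig = [a for a in ligand if not a.is_hydrogen]
    kept = {}
    all_pairs = []
    for la in lig:
        for ra in rec:
            d = math.dist(la.coords, ra.coords)
            if d > scheme.hydrophobic_hi:
                continue
            if reduction == "all":
                all_pairs.append((ra, la, d))
                continue
            key = (ra.residue, la.serial) if reduction == "closest" \
                else ra.residue
            if key not in kept or d < kept[key][2]:
                kept[key] = (ra, la, d)
    pairs = all_pairs if reduction == "all" else list(kept.values())
    out = set()
    for ra, la, d in pairs:
        if scheme.lo < d <= scheme.moderate_hi:
            cls = ContactClass.MODERATE_HBOND
        elif d <= scheme.weak_hi:
            cls = ContactClass.WEAK_HBOND_VDW
        else:
            cls = ContactClass.HYDROPHOBIC
        out.add((ra.residue.label, ra.name, la.name, round(d, 9), cls.value))
    return out


@pytest.fixture
def bundle():
    from dockcsp.synthetic_data import paper_fixtures
    return paper_fixtures()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
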