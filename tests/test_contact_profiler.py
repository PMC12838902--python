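"""Distance classification, contact enumeration and per-residue aggregation."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_contacts, random_complex
from dockcsp.contact_profiler import (DEFAULT_SCHEME, SCHEMES, AtomRole,
                                      BinScheme, ContactClass, ContactRecord,
                                      assign_atom_roles, classify_distance,
                                      enumerate_contacts,
                                      profile_from_distance_table, summarize)
from dockcsp.structure_io import Atom, ResidueKey


class TestClassify:
    @pytest.mark.parametrize("d,expected", [
        (2.4, ContactClass.MODERATE_HBOND),
        (2.9, ContactClass.MODERATE_HBOND),
        (3.2, ContactClass.MODERATE_HBOND),
        (3.3, ContactClass.MODERATE_HBOND),   # inclusive upper edge
        (3.4, ContactClass.WEAK_HBOND_VDW),
        (4.0, ContactClass.WEAK_HBOND_VDW),
        (4.1, ContactClass.HYDROPHOBIC),
        (6.9, ContactClass.HYDROPHOBIC),
        (7.0, ContactClass.HYDROPHOBIC),
        (7.5, None),
    ])
    def test_default_scheme(self, d, expected):
        assert classify_distance(d) is expected

    @pytest.mark.parametrize("bad", [0.0, -1.0, math.nan, math.inf])
    def test_nonpositive_distance_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_distance(bad)

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            BinScheme(moderate_hi=4.0, weak_hi=3.5)
        with pytest.raises(ValueError):
            BinScheme(hydrophobic_hi=12.0)

    @given(st.floats(min_value=1e-6, max_value=7.0, exclude_min=True))
    @settings(derandomize=True, max_examples=200)
    def test_partition_exactly_one_class(self, d):
        cls = classify_distance(d, DEFAULT_SCHEME)
        assert cls is not None
        in_bins = [
            DEFAULT_SCHEME.lo < d <= DEFAULT_SCHEME.moderate_hi,
            DEFAULT_SCHEME.moderate_hi < d <= DEFAULT_SCHEME.weak_hi,
            DEFAULT_SCHEME.weak_hi < d <= DEFAULT_SCHEME.hydrophobic_hi,
        ]
        assert sum(in_bins) == 1

    @given(st.floats(min_value=0.01, max_value=7.0),
           st.floats(min_value=0.01, max_value=7.0))
    @settings(derandomize=True, max_examples=200)
    def test_class_monotone_in_distance(self, d1, d2):
        order = [ContactClass.MODERATE_HBOND, ContactClass.WEAK_HBOND_VDW,
                 ContactClass.HYDROPHOBIC]
        lo, hi = sorted([d1, d2])
        assert order.index(classify_distance(lo)) <= order.index(
            classify_distance(hi))

    def test_presets_cover_both_published_conventions(self):
        assert SCHEMES["text"].classify(2.4) is None      # below 2.5 floor
        assert SCHEMES["text"].classify(3.4) is ContactClass.MODERATE_HBOND
        assert SCHEMES["table"].classify(8.0) is ContactClass.HYDROPHOBIC


class TestRoles:
    def _atom(self, name, element, res_name, xyz=(0, 0, 0)):
        return Atom(1, name, element, xyz, ResidueKey("A", 1, res_name))

    def test_backbone_amide_is_donor(self):
        role, = assign_atom_roles([self._atom("N", "N", "LEU")])
        assert role.donor and not role.hydrophobic

    def test_proline_backbone_n_is_not_donor(self):
        role, = assign_atom_roles([self._atom("N", "N", "PRO")])
        assert not role.donor

    def test_carbonyl_o_is_acceptor(self):
        role, = assign_atom_roles([self._atom("O", "O", "LEU")])
        assert role.acceptor and not role.donor

    def test_aliphatic_carbon_hydrophobic_only(self):
        role, = assign_atom_roles([self._atom("CB", "C", "ALA")])
        assert role.hydrophobic and not role.donor and not role.acceptor

    def test_ligand_phosphate_oxygen_is_acceptor(self):
        with pytest.warns(UserWarning, match="unknown residue"):
            role, = assign_atom_roles([self._atom("O1P", "O", "CMP")])
        assert role.acceptor

    def test_ligand_donor_requires_nearby_hydrogen_when_h_present(self):
        n = self._atom("N1", "N", "CMP", xyz=(0, 0, 0))
        h_near = Atom(2, "H1", "H", (1.0, 0, 0), n.residue, is_hydrogen=True)
        h_far = Atom(3, "H2", "H", (5.0, 0, 0), n.residue, is_hydrogen=True)
        with pytest.warns(UserWarning):
            with_h, = assign_atom_roles([n], hydrogens=[h_near])
            without, = assign_atom_roles([n], hydrogens=[h_far])
        assert with_h.donor and not without.donor


class TestEnumerate:
    def test_single_isolated_contact(self):
        key = ResidueKey("A", 247, "ASN")
        receptor = [Atom(1, "N", "N", (0, 0, 0), key)]
        lig_key = ResidueKey("L", 1, "LIG")
        ligand = [Atom(2, "C1", "C", (3.0, 0, 0), lig_key, is_hetero=True)]
        records = enumerate_contacts(receptor, ligand)
        assert len(records) == 1
        assert records[0].contact_class is ContactClass.MODERATE_HBOND
        assert records[0].distance == pytest.approx(3.0)

    def test_out_of_range_ligand_gives_no_contacts(self):
        key = ResidueKey("A", 247, "ASN")
        receptor = [Atom(1, "CA", "C", (0, 0, 0), key)]
        ligand = [Atom(2, "C1", "C", (8.0, 0, 0),
                       ResidueKey("L", 1, "LIG"), is_hetero=True)]
        assert enumerate_contacts(receptor, ligand) == []

    def test_empty_sets_rejected(self):
        key = ResidueKey("A", 1, "ALA")
        a = Atom(1, "CA", "C", (0, 0, 0), key)
        h = Atom(2, "HA", "H", (1, 0, 0), key, is_hydrogen=True)
        with pytest.raises(ValueError):
            enumerate_contacts([], [a])
        with pytest.raises(ValueError):
            enumerate_contacts([a], [h])  # hydrogens only -> empty heavy set

    @pytest.mark.parametrize("reduction", ["closest", "all", "closest_per_residue"])
    def test_matches_brute_force_oracle(self, rng, reduction):
        for trial in range(20):
            receptor, ligand = random_complex(
                rng, n_res=int(rng.integers(5, 40)),
                n_lig=int(rng.integers(1, 20)))
            records = enumerate_contacts(receptor, ligand,
                                         reduction=reduction)
            got = {(c.residue.label, c.receptor_atom, c.ligand_atom,
                    round(c.distance, 9), c.contact_class.value)
                   for c in records}
            expected = brute_force_contacts(receptor, ligand, DEFAULT_SCHEME,
                                            reduction=reduction)
            assert got == expected

    def test_hydrogens_never_enter_distances(self):
        key = ResidueKey("A", 247, "ASN")
        receptor = [
            Atom(1, "N", "N", (0, 0, 0), key),
            Atom(2, "H", "H", (2.0, 0, 0), key, is_hydrogen=True),
        ]
        ligand = [Atom(3, "C1", "C", (3.0, 0, 0),
                       ResidueKey("L", 1, "LIG"), is_hetero=True)]
        records = enumerate_contacts(receptor, ligand)
        assert [c.receptor_atom for c in records] == ["N"]


def _records_from_rows(rows):
    return [
        ContactRecord(ResidueKey.from_label(lbl), "", "", d,
                      classify_distance(d))
        for lbl, d in rows
    ]


class TestSummarize:
    ROWS = [("L249", 3.2), ("A254", 2.9), ("R252", 4.5), ("R252", 5.0),
            ("K248", 3.6)]

    def test_conservation_and_mean(self):
        s = summarize(_records_from_rows(self.ROWS), "x")
        assert s.total_sites == sum(s.class_counts.values()) == 5
        assert s.mean_distance == pytest.approx(
            sum(d for _, d in self.ROWS) / 5)
        assert sum(p.total for p in s.profiles.values()) == 5

    def test_permutation_invariance(self):
        recs = _records_from_rows(self.ROWS)
        s1 = summarize(recs, "x")
        shuffled = recs[:]
        random.Random(7).shuffle(shuffled)
        s2 = summarize(shuffled, "x")
        assert s1.to_dict() == s2.to_dict()

    def test_empty_contact_list(self):
        s = summarize([], "x")
        assert s.total_sites == 0
        assert s.binding_range is None and s.hotspot is None
        assert math.isnan(s.mean_distance)
        assert any("no_contacts" in f for f in s.flags)

    def test_hotspot_tie_breaks_to_lowest_seq(self):
        s = summarize(_records_from_rows(
            [("Y255", 4.5), ("N247", 4.5)]), "x")
        assert s.hotspot.label == "N247"
        assert [r.label for r in s.hotspot_ties] == ["N247", "Y255"]


class TestDistanceTable:
    def test_classes_match_printed_columns(self, bundle):
        import pandas as pd
        for path in (bundle.cmp_distances, bundle.lmwh_distances_table,
                     bundle.lfcinb11_distances):
            df = pd.read_csv(path, comment="#")
            for _, row in df.iterrows():
                assert classify_distance(row["distance_A"]).value == \
                    row["printed_class"], f"{path.name}: {row['residue']}"

    def test_cmp_fixture_summary(self, bundle):
        s = profile_from_distance_table(bundle.cmp_distances, ligand_id="CMP")
        assert s.total_sites == 17
        assert s.class_counts[ContactClass.HYDROPHOBIC] == 11
        assert (s.binding_range[0].label, s.binding_range[1].label) == \
            ("N247", "Y255")

    def test_bad_label_names_row(self, bundle):
        import pandas as pd
        df = pd.DataFrame({"residue": ["R252", "25X2"], "distance_A": [3.0, 3.0]})
        with pytest.raises(ValueError, match="row 1"):
            profile_from_distance_table(df)

    def test_out_of_bin_row_skipped_with_warning(self):
        import pandas as pd
        df = pd.DataFrame({"residue": ["R252", "Y255"],
                           "distance_A": [3.0, 9.5]})
        with pytest.warns(UserWarning, match="outside every bin"):
            s = profile_from_distance_table(df)
        assert s.total_sites == 1
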