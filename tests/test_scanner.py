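"""Window enumeration, scan minima, accessibility weighting and design search."""

import math

import pytest

from colbind import (
    ColbindError,
    KT_REF,
    ScanTable,
    apply_accessibility,
    compare_peptides,
    design_variants,
    multi_ph_scan,
    scan_pair,
)
from colbind.scale import default_policy

from conftest import oracle_position_minima


class TestScanPair:
    def test_site_count_formula(self):
        # no ionizable residues: one state combination per window
        table = scan_pair("TKKTLRT", "GPQGLLG", 7)
        assert len(table.sites) == 5 * 5
        assert sorted(table.per_position_min) == [1, 2, 3, 4, 5]

    def test_state_combinations_multiply_sites(self):
        # peptide window with H contributes 2 combinations at pH 7
        t7 = scan_pair("LHL", "GLL", 7)
        t9 = scan_pair("LHL", "GLL", 9)
        assert len(t7.sites) == 2
        assert len(t9.sites) == 1

    def test_deterministic_ordering(self):
        table = scan_pair("LHLH", "GLLG", 7)
        keys = [
            (s.target_start, s.pep_start, s.pep_window_states, s.target_window_states)
            for s in table.sites
        ]
        assert keys == sorted(keys)
        assert len(keys) == len(set(keys))

    def test_sense_antisense_pair_all_positive_at_ph7(self):
        table = scan_pair("TKKTLRT", "GPQGLLG", 7)
        assert all(s.result.dg > 0 for s in table.sites)
        assert table.min_dg() == pytest.approx(0.27, abs=1e-9)

    def test_lrr10_hydrophobic_site_at_ph9(self):
        table = scan_pair("LRELHLNNN", "GPQGLLG", 9)
        assert table.per_position_min[4] == pytest.approx(-1.2467, abs=5e-4)

    def test_designed_peptide_stable_at_ph2(self):
        designed = scan_pair("TKKLTLRT", "GPQGLLG", 2)
        parent = scan_pair("TKKTLRT", "GPQGLLG", 2)
        assert designed.count_below(-KT_REF) >= 1
        assert designed.min_dg() == pytest.approx(-1.20, abs=5e-3)
        assert parent.count_below(-KT_REF) == 0

    def test_short_sequence_rejected(self):
        with pytest.raises(ColbindError, match="too short"):
            scan_pair("TK", "GPQGLLG", 7)

    def test_non_canonical_residue_names_position(self):
        with pytest.raises(ColbindError, match="position 3"):
            scan_pair("TKXTLRT", "GPQGLLG", 7)

    def test_matches_brute_force_oracle_on_printed_fragments(self):
        for ph in (2, 4, 7, 9):
            table = scan_pair("LRELHLNNN", "GPQGLLG", ph)
            expected = oracle_position_minima("LRELHLNNN", "GPQGLLG", ph)
            for pos, dg in expected.items():
                assert table.per_position_min[pos] == pytest.approx(dg), (ph, pos)

    def test_ph2_basic_vs_neutral_acid_windows_never_stable(self):
        # K+/R+ windows cannot reach -kT against neutral D0/E0 windows
        table = scan_pair("KRKRK", "DEDED", 2)
        assert all(s.result.stability != "stable" for s in table.sites)

    def test_extra_allowed_states_cannot_raise_minima(self):
        strict = scan_pair("TKKTLRT", "GDEGLLG", 4)
        dual = scan_pair(
            "TKKTLRT", "GDEGLLG", 4, policy=default_policy(acidic_dual_ph4=True)
        )
        for pos, dg in strict.per_position_min.items():
            assert dual.per_position_min[pos] <= dg + 1e-12


class TestMultiPhScan:
    def test_ph_independence_without_ionizable_residues(self):
        tables = multi_ph_scan("TLLST", "GLLGA", [2, 4, 7, 9])
        energies = [
            [s.result.dg for s in t.sites] for t in tables.values()
        ]
        assert all(e == energies[0] for e in energies)

    def test_lrr10_best_energy_tracks_histidine_availability(self):
        tables = multi_ph_scan("LRELHLNNN", "GPQGLLG", [4, 7, 9])
        best = {ph: t.min_dg() for ph, t in tables.items()}
        assert best[7.0] == pytest.approx(-1.2467, abs=5e-4)
        assert best[9.0] == pytest.approx(best[7.0])
        assert best[4.0] > best[7.0]  # strictly worse when H0 is unavailable

    def test_designed_peptide_is_ph_independent(self):
        tables = multi_ph_scan("TKKLTLRT", "GPQGLLG", [2, 4, 7, 9])
        minima = {t.min_dg() for t in tables.values()}
        assert len(minima) == 1
        assert minima.pop() == pytest.approx(-1.20, abs=5e-3)

    def test_empty_ph_list_gives_empty_mapping(self):
        assert multi_ph_scan("TKKTLRT", "GPQGLLG", []) == {}


class TestComparePeptides:
    def test_designed_vs_parent_at_ph2(self):
        df = compare_peptides(["TKKTLRT", "TKKLTLRT"], "GPQGLLG", [2])
        by_id = df.set_index("peptide_id")
        assert by_id.loc["TKKTLRT", "n_stable"] == 0
        assert by_id.loc["TKKLTLRT", "n_stable"] >= 1

    def test_binding_motif_outranks_neutralized_variant(self):
        # GLKGHR binds a charged-acid window better than GLAGHA
        df = compare_peptides(["GLKGHR", "GLAGHA"], "AEEGLL", [7])
        by_id = df.set_index("peptide_id")
        assert by_id.loc["GLKGHR", "min_dg"] < by_id.loc["GLAGHA", "min_dg"]

    def test_empty_peptide_list_rejected(self):
        with pytest.raises(ColbindError, match="at least one"):
            compare_peptides([], "GPQGLLG", [7])


class TestAccessibility:
    def test_identity_weights_leave_table_unchanged(self):
        table = scan_pair("TKKTLRT", "GPQGLLG", 7)
        weighted = apply_accessibility(table, {p: 1.0 for p in range(1, 8)})
        assert [s.result.dg for s in weighted.sites] == [
            s.result.dg for s in table.sites
        ]

    def test_zero_weights_bury_everything(self):
        table = scan_pair("LRELHLNNN", "GPQGLLG", 9)
        weighted = apply_accessibility(table, {p: 0.0 for p in range(1, 8)})
        assert all(s.result.dg == 0.0 for s in weighted.sites)
        assert all(s.result.stability == "unfavorable" for s in weighted.sites)

    def test_linear_scaling_by_mean_window_weight(self):
        table = scan_pair("LLL", "WLL", 7)  # single site, dg = -(1.25 + 1.53)
        weights = {1: 0.5, 2: 1.0, 3: 1.0}
        weighted = apply_accessibility(table, weights)
        assert weighted.sites[0].result.dg == pytest.approx(
            table.sites[0].result.dg * (0.5 + 1.0 + 1.0) / 3
        )

    def test_out_of_range_weight_rejected(self):
        table = scan_pair("LLL", "LLL", 7)
        with pytest.raises(ColbindError, match="outside"):
            apply_accessibility(table, {1: 1.2, 2: 1.0, 3: 1.0})

    def test_missing_position_rejected(self):
        table = scan_pair("LLL", "LLLL", 7)
        with pytest.raises(ColbindError, match="missing"):
            apply_accessibility(table, {1: 1.0, 2: 1.0, 3: 1.0})


class TestDesignVariants:
    def test_leucine_insertion_recovers_designed_peptide(self):
        candidates = design_variants("TKKTLRT", "GPQGLLG", [2, 4, 7, 9], {"L"})
        designed = [c for c in candidates if c.sequence == "TKKLTLRT"]
        assert designed and designed[0].robustness <= -KT_REF
        # every candidate's score is attained by some (pH, site) pair
        best = candidates[0]
        attained = {
            t.min_dg()
            for t in multi_ph_scan(best.sequence, "GPQGLLG", [2, 4, 7, 9]).values()
        }
        assert best.robustness in attained

    def test_top_candidate_never_worse_than_parent(self):
        candidates = design_variants("LLL", "LLL", [7], {"L"})
        parent_score = scan_pair("LLL", "LLL", 7).min_dg()
        assert candidates[0].robustness <= parent_score

    def test_empty_edit_set_rejected(self):
        with pytest.raises(ColbindError, match="empty edit set"):
            design_variants("TKKTLRT", "GPQGLLG", [7], set())

    def test_ranking_is_ascending(self):
        candidates = design_variants("TKKTLRT", "GPQGLLG", [7], {"L", "E"})
        scores = [c.robustness for c in candidates]
        assert scores == sorted(scores)


class TestSerialization:
    def test_tsv_round_trip_is_bit_exact(self, tmp_path):
        table = scan_pair("LRELHLNNN", "GPQGLLG", 7)
        path = tmp_path / "sites.tsv"
        table.to_tsv(path)
        back = ScanTable.from_tsv(path)
        assert len(back.sites) == len(table.sites)
        for a, b in zip(table.sites, back.sites):
            assert a == b
        assert back.per_position_min == pytest.approx(table.per_position_min)

    def test_energies_are_finite_everywhere(self):
        table = scan_pair("LRELHLNNN", "GPQGLLG", 7)
        assert all(math.isfinite(s.result.dg) for s in table.sites)
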