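import numpy as np
import pytest

from barcodeaudit.distance import DistanceMatrix, distance_matrix
from barcodeaudit.errors import EmptyInputError, TreeLibraryMismatchError
from barcodeaudit.library_io import ReferenceLibrary, SequenceRecord, parse_newick
from barcodeaudit.species_audit import (
    audit_library,
    classify_monophyly,
    cryptic_flags,
    diagnosability,
    identify_query,
    intraspecific_stats,
    nearest_neighbor,
)
from barcodeaudit.synthetic_data import (
    IntrogressionEvent,
    SimulationConfig,
    simulate_library,
)

from oracles import conspecific_stats_oracle, nearest_neighbor_oracle


def _dm_from_pairs(labels, pairs_pct):
    """Distance matrix from percent distances keyed by sorted label pairs."""
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                values[i, j] = pairs_pct[tuple(sorted((labels[i], labels[j])))] / 100.0
    return DistanceMatrix(
        labels=list(labels), values=values, comparable_sites=np.full((n, n), 658)
    )


def _lib(species_of):
    return ReferenceLibrary(
        [SequenceRecord(sid, sp, "ACGT" * 10) for sid, sp in species_of.items()]
    )


class TestIntraspecificStats:
    def test_three_pair_arithmetic(self):
        lib = _lib({"a1": "A x", "a2": "A x", "a3": "A x", "b1": "B y"})
        dm = _dm_from_pairs(
            ["a1", "a2", "a3", "b1"],
            {
                ("a1", "a2"): 1.0, ("a1", "a3"): 2.0, ("a2", "a3"): 1.5,
                ("a1", "b1"): 8.0, ("a2", "b1"): 8.0, ("a3", "b1"): 8.0,
            },
        )
        stats = intraspecific_stats(dm, lib)
        assert stats["A x"].max_intra == pytest.approx(2.0)
        assert stats["A x"].mean_intra == pytest.approx(1.5)

    def test_singleton_undefined(self):
        lib = _lib({"a1": "A x", "b1": "B y"})
        dm = _dm_from_pairs(["a1", "b1"], {("a1", "b1"): 5.0})
        stats = intraspecific_stats(dm, lib)
        assert stats["A x"].max_intra is None
        assert stats["B y"].mean_intra is None

    def test_matches_oracle_on_simulation(self, small_sim_lib):
        lib, _ = small_sim_lib
        dm = distance_matrix(lib, min_overlap=1)
        pair_pct = {}
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1:]:
                pair_pct[tuple(sorted((a, b)))] = 100.0 * dm.get(a, b)
        stats = intraspecific_stats(dm, lib)
        for sp, ids in lib.species_index.items():
            mx, mn = conspecific_stats_oracle(pair_pct, ids)
            if mx is None:
                assert stats[sp].max_intra is None
            else:
                assert stats[sp].max_intra == pytest.approx(mx, abs=1e-12)
                assert stats[sp].mean_intra == pytest.approx(mn, abs=1e-12)


class TestNearestNeighbor:
    def test_two_singletons(self):
        lib = _lib({"a1": "A x", "b1": "B y"})
        dm = _dm_from_pairs(["a1", "b1"], {("a1", "b1"): 5.0})
        nn = nearest_neighbor(dm, lib)
        assert nn["A x"].nearest_neighbor == "B y"
        assert nn["A x"].nn_distance == pytest.approx(5.0)
        assert nn["B y"].nearest_neighbor == "A x"
        assert not nn["A x"].shares_barcode_with

    def test_zero_distance_shared_barcode(self):
        lib = _lib({"a1": "A x", "a2": "A x", "b1": "B y"})
        dm = _dm_from_pairs(
            ["a1", "a2", "b1"],
            {("a1", "a2"): 0.5, ("a1", "b1"): 0.0, ("a2", "b1"): 0.6},
        )
        nn = nearest_neighbor(dm, lib)
        assert nn["A x"].nn_distance == 0.0
        assert nn["A x"].shares_barcode_with == {"B y"}
        assert nn["B y"].shares_barcode_with == {"A x"}

    def test_matches_exhaustive_oracle(self, sim_lib):
        lib, _ = sim_lib
        dm = distance_matrix(lib, min_overlap=1)
        pair = {}
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1:]:
                pair[tuple(sorted((a, b)))] = 100.0 * dm.get(a, b)
        species_of = {r.specimen_id: r.species for r in lib.records}
        expected = nearest_neighbor_oracle(pair, species_of)
        nn = nearest_neighbor(dm, lib)
        for sp, (exp_sp, exp_d) in expected.items():
            assert nn[sp].nearest_neighbor == exp_sp
            assert nn[sp].nn_distance == pytest.approx(exp_d, abs=1e-9)

    def test_nn_consistency_attained_pair(self, sim_lib):
        # the reported minimum equals an actual matrix entry
        lib, _ = sim_lib
        dm = distance_matrix(lib, min_overlap=1)
        nn = nearest_neighbor(dm, lib)
        for sp, res in nn.items():
            found = False
            for sid in lib.species_index[sp]:
                for other in lib.species_index[res.nearest_neighbor]:
                    if 100.0 * dm.get(sid, other) == pytest.approx(
                        res.nn_distance, abs=1e-12
                    ):
                        found = True
            assert found

    def test_single_species_rejected(self):
        lib = _lib({"a1": "A x", "a2": "A x"})
        dm = _dm_from_pairs(["a1", "a2"], {("a1", "a2"): 1.0})
        with pytest.raises(ValueError):
            nearest_neighbor(dm, lib)


class TestClassifyMonophyly:
    def _lib_for(self, newick):
        tree = parse_newick(newick)
        ids = tree.leaf_names()
        return tree, _lib({sid: f"Sp {sid[0]}" for sid in ids})

    def test_reciprocal_monophyly(self):
        tree, lib = self._lib_for("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        mono = classify_monophyly(tree, lib)
        assert mono["Sp a"].status == "monophyletic"
        assert mono["Sp b"].status == "monophyletic"

    def test_paraphyly(self):
        tree, lib = self._lib_for("((((b1:1,b2:1):1,a1:1):1,a2:1):1,a3:1);")
        mono = classify_monophyly(tree, lib)
        assert mono["Sp a"].status == "paraphyletic"
        assert mono["Sp b"].status == "monophyletic"
        assert mono["Sp a"].entangled_with == {"Sp b"}

    def test_polyphyly_quartet(self):
        tree, lib = self._lib_for("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        mono = classify_monophyly(tree, lib)
        assert mono["Sp a"].status == "polyphyletic"
        assert mono["Sp b"].status == "polyphyletic"

    def test_singleton(self):
        tree, lib = self._lib_for("((a1:1,a2:1):1,(b1:1,c1:1):1);")
        mono = classify_monophyly(tree, lib)
        assert mono["Sp b"].status == "singleton"
        assert mono["Sp c"].status == "singleton"

    def test_leaf_mismatch_rejected(self):
        tree = parse_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        lib = _lib({"a1": "Sp a", "a2": "Sp a", "b1": "Sp b", "zz": "Sp z"})
        with pytest.raises(TreeLibraryMismatchError):
            classify_monophyly(tree, lib)

    def test_partition_property(self, sim_lib):
        lib, _ = sim_lib
        report = audit_library(lib)
        counts = report.summary()["monophyly_counts"]
        assert sum(counts.values()) == report.n_species


class TestDiagnosability:
    def test_monophyletic_no_share(self):
        tree, lib = (
            parse_newick("((a1:1,a2:1):2,(b1:1,b2:1):2);"),
            _lib({"a1": "Sp a", "a2": "Sp a", "b1": "Sp b", "b2": "Sp b"}),
        )
        mono = classify_monophyly(tree, lib)
        dm = _dm_from_pairs(
            ["a1", "a2", "b1", "b2"],
            {
                ("a1", "a2"): 0.5, ("b1", "b2"): 0.5,
                ("a1", "b1"): 4.0, ("a1", "b2"): 4.0,
                ("a2", "b1"): 4.0, ("a2", "b2"): 4.0,
            },
        )
        nn = nearest_neighbor(dm, lib)
        diag = diagnosability(mono, nn)
        assert diag["Sp a"] == (True, True)
        assert diag["Sp b"] == (True, True)

    def test_paraphyletic_with_unique_haplotypes(self):
        # cluster criterion fails, haplotype criterion holds
        tree = parse_newick("((((b1:1,b2:1):1,a1:1):1,a2:1):1,a3:1);")
        lib = _lib({s: f"Sp {s[0]}" for s in ["a1", "a2", "a3", "b1", "b2"]})
        mono = classify_monophyly(tree, lib)
        pairs = {}
        ids = ["a1", "a2", "a3", "b1", "b2"]
        for i in range(len(ids) - 1):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                pairs[(a, b)] = 0.5 if a[0] == b[0] else 1.0
        dm = _dm_from_pairs(ids, pairs)
        nn = nearest_neighbor(dm, lib)
        diag = diagnosability(mono, nn)
        assert diag["Sp a"] == (False, True)
        assert diag["Sp b"] == (True, True)

    def test_singleton_sharing_barcode_fails_both(self):
        # a singleton identical to another species' haplotype
        tree = parse_newick("((b1:0,c1:0):1,(b2:1,d1:4):1);")
        lib = _lib({"b1": "Sp b", "b2": "Sp b", "c1": "Sp c", "d1": "Sp d"})
        mono = classify_monophyly(tree, lib)
        dm = _dm_from_pairs(
            ["b1", "b2", "c1", "d1"],
            {
                ("b1", "b2"): 0.5, ("b1", "c1"): 0.0, ("b1", "d1"): 6.0,
                ("b2", "c1"): 0.5, ("b2", "d1"): 6.0, ("c1", "d1"): 6.0,
            },
        )
        nn = nearest_neighbor(dm, lib)
        diag = diagnosability(mono, nn)
        assert diag["Sp c"] == (False, False)

    def test_singleton_with_distinct_barcode_cluster_diagnostic(self):
        tree = parse_newick("((a1:1,a2:1):1,(b1:1,c1:1):1);")
        lib = _lib({"a1": "Sp a", "a2": "Sp a", "b1": "Sp b", "c1": "Sp c"})
        mono = classify_monophyly(tree, lib)
        dm = _dm_from_pairs(
            ["a1", "a2", "b1", "c1"],
            {
                ("a1", "a2"): 0.5, ("a1", "b1"): 5.0, ("a1", "c1"): 5.0,
                ("a2", "b1"): 5.0, ("a2", "c1"): 5.0, ("b1", "c1"): 3.0,
            },
        )
        nn = nearest_neighbor(dm, lib)
        diag = diagnosability(mono, nn)
        assert diag["Sp b"] == (True, True)

    def test_cluster_subset_of_haplotype(self, sim_lib):
        lib, _ = sim_lib
        report = audit_library(lib)
        for a in report.assessments.values():
            if a.cluster_diagnostic:
                assert a.haplotype_diagnostic


class TestCrypticFlags:
    def test_over_both_thresholds(self):
        from barcodeaudit.species_audit import IntraStats

        flags = cryptic_flags({"Sp z": IntraStats(5.63, 2.0)})
        assert flags["Sp z"] == {2.0: True, 3.0: True}

    def test_boundary_is_strict(self):
        from barcodeaudit.species_audit import IntraStats

        flags = cryptic_flags({"Sp z": IntraStats(2.0, 1.0)})
        assert flags["Sp z"][2.0] is False

    def test_singleton_never_flagged(self):
        from barcodeaudit.species_audit import IntraStats

        flags = cryptic_flags({"Sp z": IntraStats(None, None)})
        assert flags["Sp z"] == {2.0: False, 3.0: False}

    def test_custom_thresholds(self):
        from barcodeaudit.species_audit import IntraStats

        flags = cryptic_flags({"Sp z": IntraStats(1.5, 1.0)}, thresholds=(1.0,))
        assert flags["Sp z"] == {1.0: True}


class TestIdentifyQuery:
    @pytest.fixture
    def ref_lib(self):
        return ReferenceLibrary(
            [
                SequenceRecord("x1", "Sp x", "A" * 200),
                SequenceRecord("x2", "Sp x", "A" * 199 + "G"),
                SequenceRecord("y1", "Sp y", "A" * 100 + "G" * 100),
            ]
        )

    def test_unique_haplotype_match(self, ref_lib):
        res = identify_query("A" * 200, ref_lib)
        assert res.status == "match"
        assert res.species == ("Sp x",)
        assert res.distance == 0.0

    def test_tie_is_ambiguous(self):
        lib = ReferenceLibrary(
            [
                SequenceRecord("x1", "Sp x", "A" * 200),
                SequenceRecord("y1", "Sp y", "A" * 200),
            ]
        )
        res = identify_query("A" * 200, lib)
        assert res.status == "ambiguous"
        assert res.species == ("Sp x", "Sp y")

    def test_distant_query_no_match(self, ref_lib):
        query = "A" * 150 + "C" * 50  # >= 5% from everything
        res = identify_query(query, ref_lib, threshold=2.0)
        assert res.status == "no_match"

    def test_tie_margin_widens_ambiguity(self):
        lib = ReferenceLibrary(
            [
                SequenceRecord("x1", "Sp x", "A" * 200),  # 1 sub from query
                SequenceRecord("y1", "Sp y", "A" * 197 + "GGG"),  # 2 subs
            ]
        )
        query = "A" * 199 + "G"
        strict = identify_query(query, lib, tie_margin=0.0)
        assert strict.status == "match" and strict.species == ("Sp x",)
        loose = identify_query(query, lib, threshold=2.0, tie_margin=1.0)
        assert loose.status == "ambiguous"
        assert loose.species == ("Sp x", "Sp y")

    def test_empty_library(self):
        with pytest.raises((EmptyInputError, ValueError)):
            identify_query("ACGT", ReferenceLibrary([]))


class TestAuditReport:
    def test_summary_percentages_recomputable(self, sim_lib):
        lib, _ = sim_lib
        report = audit_library(lib)
        s = report.summary()
        n = s["n_species"]
        for status, count in s["monophyly_counts"].items():
            assert s["monophyly_percent"][status] == pytest.approx(100.0 * count / n)

    def test_tsv_roundtrip_columns(self, sim_lib, tmp_path):
        lib, _ = sim_lib
        report = audit_library(lib)
        report.to_tsv(tmp_path / "per_species.tsv")
        lines = (tmp_path / "per_species.tsv").read_text().splitlines()
        assert len(lines) == report.n_species + 1
        assert lines[0].startswith("species\tn_specimens")

    def test_shared_symmetry_on_introgression(self):
        cfg = SimulationConfig(
            n_species=4, specimens_per_species=3, seq_length=400, seed=2,
            introgression_events=[IntrogressionEvent("Species_03", "Species_01")],
        )
        lib, _ = simulate_library(cfg)
        report = audit_library(lib)
        a = report.assessments["Species_01"]
        b = report.assessments["Species_03"]
        assert "Species_03" in a.shares_barcode_with
        assert "Species_01" in b.shares_barcode_with
        assert a.nn_distance == 0.0 and b.nn_distance == 0.0
        assert not a.haplotype_diagnostic and not b.haplotype_diagnostic

    def test_nn_zero_iff_shares(self, sim_lib):
        lib, _ = sim_lib
        report = audit_library(lib)
        for a in report.assessments.values():
            assert (a.nn_distance == 0.0) == bool(a.shares_barcode_with)
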