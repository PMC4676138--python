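import itertools
import random

import pytest

from librank.chemio import (
    Library,
    LibrankError,
    analogue_series,
    clean_pool,
    records_from_smiles,
)
from librank.divsim import (
    LabeledSet,
    SubstructureQuery,
    compare_libraries,
    coverage_curve,
    enrichment_curve,
    maxmin_select,
    mean_pairwise_similarity,
    rank_by_similarity,
    substructure_search,
    threshold_search,
)
from librank.fingerprints import fingerprint, tanimoto


def recs(*smiles):
    return records_from_smiles(list(smiles))


class TestMeanPairwiseSimilarity:
    def test_identical_library_is_one(self):
        assert float(mean_pairwise_similarity(recs(*["CCO"] * 5), "ECFP_4")) == 1.0

    def test_two_records_equals_single_pair(self):
        pair = recs("CCO", "CCCN")
        expected = tanimoto(fingerprint(pair[0], "ECFP_4"), fingerprint(pair[1], "ECFP_4"))
        assert float(mean_pairwise_similarity(pair, "ECFP_4")) == pytest.approx(expected)

    def test_sampled_close_to_exhaustive(self):
        lib = records_from_smiles(clean_pool(200, seed=23))
        exact = mean_pairwise_similarity(lib, "ECFP_2")
        sampled = mean_pairwise_similarity(lib, "ECFP_2", max_pairs=5000, seed=1)
        assert exact.exhaustive and not sampled.exhaustive
        assert sampled.n_pairs == 5000
        assert abs(exact.value - sampled.value) < 0.02

    def test_too_few_records_error(self):
        with pytest.raises(LibrankError):
            mean_pairwise_similarity(recs("CCO"), "ECFP_4")


class TestMaxMin:
    def test_k_equals_n_returns_everything(self):
        lib = recs("CCO", "CCN", "c1ccccc1")
        assert sorted(maxmin_select(lib, "ECFP_4", 3)) == [0, 1, 2]

    def test_duplicate_avoided(self):
        lib = recs("CCO", "CCO", "c1ccccc1CCCCN")
        assert maxmin_select(lib, "ECFP_4", 2, first_index=0) == [0, 2]

    def test_greedy_property_vs_brute_force(self):
        lib = records_from_smiles(clean_pool(10, seed=31))
        fps = [fingerprint(r, "ECFP_4") for r in lib]
        dist = [[1.0 - tanimoto(a, b) for b in fps] for a in fps]
        picks = maxmin_select(lib, "ECFP_4", 6, first_index=0)
        min_dists = []
        for step in range(1, 6):
            selected = picks[:step]
            remaining = [i for i in range(10) if i not in selected]
            best = max(min(dist[i][j] for j in selected) for i in remaining)
            got = min(dist[picks[step]][j] for j in selected)
            assert got == pytest.approx(best)  # each pick is a true argmax
            min_dists.append(got)
        assert all(a >= b - 1e-12 for a, b in zip(min_dists, min_dists[1:]))

    def test_k_too_large_error(self):
        with pytest.raises(LibrankError):
            maxmin_select(recs("CCO", "CCN"), "ECFP_4", 3)


class TestCoverage:
    def test_full_size_full_coverage(self, clustered_labeled):
        records, labels = clustered_labeled
        ls = LabeledSet(records, labels)
        curve = coverage_curve(ls, "ECFP_2", [len(ls)])
        assert curve.points[-1][1] == 100.0

    def test_single_label_always_covered(self):
        lib = records_from_smiles(clean_pool(6, seed=2))
        ls = LabeledSet(lib, ["only"] * 6)
        curve = coverage_curve(ls, "ECFP_4", [1, 3, 6])
        assert all(p[1] == 100.0 for p in curve.points)

    def test_separated_clusters_beat_random(self, clustered_labeled):
        records, labels = clustered_labeled
        ls = LabeledSet(records, labels)
        maxmin = coverage_curve(ls, "ECFP_2", [10])
        rand = coverage_curve(ls, "ECFP_2", [10], random_baseline=True, seed=3, n_replicates=20)
        assert maxmin.points[0][1] == 100.0
        assert rand.points[0][1] < 100.0

    def test_monotone_in_size(self, clustered_labeled):
        records, labels = clustered_labeled
        ls = LabeledSet(records, labels)
        curve = coverage_curve(ls, "ECFP_4", [5, 10, 20, 40])
        covs = [p[1] for p in curve.points]
        assert covs == sorted(covs)

    def test_multilabel_filtering(self):
        lib = records_from_smiles(clean_pool(6, seed=4))
        label_lists = [["a"], ["a"], ["a", "b"], ["b"], ["c"], ["b"]]
        ls = LabeledSet.from_multilabel(lib, label_lists, min_label_members=2)
        # the multi-label record and the singleton label 'c' are dropped
        assert len(ls) == 4 and ls.n_labels == 2


class TestRankAndEnrichment:
    def test_reference_in_library_ranks_first(self):
        lib = recs("c1ccccc1CCO", "CCN", "CCOCC")
        ranked = rank_by_similarity(lib, lib[0], "ECFP_4")
        assert ranked.indices[0] == 0 and ranked.scores[0] == 1.0

    def test_all_identical_marked_tied(self):
        lib = recs(*["CCO"] * 4)
        ranked = rank_by_similarity(lib, lib[0], "ECFP_4")
        assert all(ranked.tied)

    def test_order_matches_brute_force(self):
        lib = recs("CCCCO", "c1ccccc1", "CCCCCO")
        ref = recs("CCCCCCO")[0]
        ranked = rank_by_similarity(lib, ref, "ECFP_4")
        rf = fingerprint(ref, "ECFP_4")
        expected = sorted(range(3), key=lambda i: -tanimoto(rf, fingerprint(lib[i], "ECFP_4")))
        assert ranked.indices == expected

    def test_all_actives_first(self):
        lib = recs("CCCCCO", "CCCCO", "c1ccccc1", "c1ccncc1", "CC(C)=O")
        ref = recs("CCCCCCO")[0]
        ranked = rank_by_similarity(lib, ref, "ECFP_4")
        actives = [i in ranked.indices[:2] for i in range(5)]
        curve = enrichment_curve(ranked, actives)
        xs = [p for p in curve.points if p[1] == 100.0]
        assert min(x for x, _ in xs) == pytest.approx(100.0 * 2 / 5)
        assert curve.points[-1] == (100.0, 100.0)

    def test_fully_tied_library_is_diagonal(self):
        lib = recs(*["CCO"] * 10)
        ranked = rank_by_similarity(lib, lib[0], "ECFP_4")
        curve = enrichment_curve(ranked, [True] * 3 + [False] * 7)
        assert curve.points == [(0.0, 0.0), (100.0, 100.0)]
        assert curve.auc == 0.5

    def test_random_permutations_average_half(self):
        lib = records_from_smiles(clean_pool(100, seed=8))
        ranked = rank_by_similarity(lib, lib[0], "ECFP_4")
        flags = [i < 10 for i in range(100)]
        rng = random.Random(0)
        aucs = []
        for _ in range(200):
            rng.shuffle(flags)
            aucs.append(enrichment_curve(ranked, flags).auc)
        assert sum(aucs) / len(aucs) == pytest.approx(0.5, abs=0.05)

    def test_reversed_ranking_complements_auc(self):
        lib = records_from_smiles(clean_pool(20, seed=12))
        ref = lib[0]
        ranked = rank_by_similarity(lib, ref, "ECFP_4")
        assert not any(ranked.tied), "fixture must be tie-free for this check"
        flags = [i % 3 == 0 for i in range(20)]
        from librank.divsim import RankedList

        reversed_ranked = RankedList(
            indices=list(reversed(ranked.indices)),
            scores=list(reversed(ranked.scores)),
            tied=list(reversed(ranked.tied)),
        )
        a = enrichment_curve(ranked, flags).auc
        b = enrichment_curve(reversed_ranked, flags).auc
        assert a + b == pytest.approx(1.0, abs=0.06)

    def test_zero_actives_error(self):
        lib = recs("CCO", "CCN")
        ranked = rank_by_similarity(lib, lib[0], "ECFP_4")
        with pytest.raises(LibrankError):
            enrichment_curve(ranked, [False, False])


class TestSearches:
    def test_threshold_zero_returns_all(self):
        lib = recs("CCO", "c1ccccc1", "CCN")
        assert threshold_search(lib, lib[0], "ECFP_4", 0.0) == [0, 1, 2]

    def test_threshold_one_only_identical(self):
        lib = recs("CCO", "OCC", "c1ccccc1")
        assert threshold_search(lib, lib[0], "ECFP_4", 1.0) == [0, 1]

    def test_planted_analogues_recovered(self):
        ref_smiles, analogues = analogue_series(5)
        lib = records_from_smiles(analogues + clean_pool(95, seed=9))
        ref = records_from_smiles([ref_smiles])[0]
        assert threshold_search(lib, ref, "ECFP_4", 0.7) == [0, 1, 2, 3, 4]

    def test_non_increasing_in_threshold(self):
        lib = records_from_smiles(clean_pool(30, seed=14))
        ref = lib[0]
        sizes = [len(threshold_search(lib, ref, "ECFP_4", t)) for t in (0.0, 0.2, 0.5, 0.8, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_substructure_single_carbon_matches_organics(self):
        lib = recs("CCO", "c1ccccc1", "CC(=O)N")
        assert substructure_search(lib, "[#6]") == [0, 1, 2]

    def test_variable_atom_query(self):
        lib = recs("O=c1cccc[nH]1", "O=c1cccco1", "c1ccccc1")
        both = SubstructureQuery.from_template("O=c1cccc{X}1", ["[nH]", "o"])
        assert substructure_search(lib, both) == [0, 1]
        fixed_n = SubstructureQuery.from_smarts("O=c1cccc[nH]1")
        assert substructure_search(lib, fixed_n) == [0]

    def test_empty_library_empty_result(self):
        assert substructure_search([], "[#6]") == []

    def test_invalid_query_fatal(self):
        with pytest.raises(LibrankError):
            SubstructureQuery.from_smarts("[[[")


class TestCompareLibraries:
    def test_self_comparison_full_overlap(self):
        lib = Library("a", records_from_smiles(clean_pool(10, seed=5)))
        count, pct = compare_libraries(lib, lib)
        assert count == 10 and pct == 100.0

    def test_disjoint_scaffolds_no_overlap(self):
        ref_smiles, analogues = analogue_series(4)
        a = Library("a", records_from_smiles(analogues + [ref_smiles]))
        b = Library("b", records_from_smiles(clean_pool(20, seed=6)))
        count, pct = compare_libraries(a, b)
        assert count == 0 and pct == 0.0

    def test_asymmetric(self):
        ref_smiles, analogues = analogue_series(4)
        decoys = clean_pool(16, seed=7)
        a = Library("a", records_from_smiles([ref_smiles] + decoys[:4]))
        b = Library("b", records_from_smiles(analogues + decoys))
        ab = compare_libraries(a, b)
        ba = compare_libraries(b, a)
        assert ab[1] != ba[1]

    def test_percentage_arithmetic(self):
        ref_smiles, analogues = analogue_series(1)
        cand = Library("c", records_from_smiles(analogues + clean_pool(49, seed=8)))
        house = Library("h", records_from_smiles([ref_smiles]))
        count, pct = compare_libraries(cand, house)
        assert count == 1 and pct == 2.0
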