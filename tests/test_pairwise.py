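import math

import numpy as np
import pytest

from conftest import matrix_from_calls, oracle_compare, random_matrix
from germfp.model import HOM_A, HOM_B, MISSING, SampleMeta
from germfp.pairwise import (
    IdentityRule,
    compare_pair,
    dosage_correlation_matrix,
    duplicate_statistics,
    find_duplicates,
    genepool_consistency_check,
    rank_by_similarity,
    similarity_matrix,
)
from germfp.simulate import DuplicateSpec, SimConfig, simulate_dataset


class TestComparePair:
    def test_hand_enumerated_toy_pair(self):
        mat = matrix_from_calls([
            ["A:A", "A:A", "A:G", "?", "G:G"],
            ["A:A", "G:G", "A:A", "G:G", "G:G"],
        ])
        pc = compare_pair(mat, "s1", "s2")
        assert pc.n_shared == 4
        assert pc.hom_diffs == 1 and pc.het_diffs == 1
        assert pc.similarity == pytest.approx((1 + 0 + 0.5 + 1) / 4)
        assert pc.pct_hom_diffs == pytest.approx(0.25)

    def test_self_comparison_is_identity(self, rng):
        mat = random_matrix(rng, 5, 40)
        pc = compare_pair(mat, "s1", "s1")
        assert pc.het_diffs == 0 and pc.hom_diffs == 0 and pc.similarity == 1.0

    def test_symmetric_under_label_swap(self, rng):
        mat = random_matrix(rng, 6, 50)
        ab = compare_pair(mat, "s2", "s5")
        ba = compare_pair(mat, "s5", "s2")
        assert (ab.n_a, ab.n_b) == (ba.n_b, ba.n_a)
        for f in ("n_shared", "het_diffs", "hom_diffs", "total_diffs", "similarity"):
            assert getattr(ab, f) == getattr(ba, f)

    def test_incomparable_pair_reports_none_not_zero(self):
        mat = matrix_from_calls([["A:A", "?"], ["?", "G:G"], ["A:A", "G:G"]])
        pc = compare_pair(mat, "s1", "s2")
        assert pc.n_shared == 0 and pc.similarity is None and pc.pct_hom_diffs is None

    def test_conservation_and_oracle_on_random_matrices(self, rng):
        mat = random_matrix(rng, 20, 50)
        sim = similarity_matrix(mat)
        for i in range(5):
            for j in range(i + 1, 8):
                a, b = mat.sample_names[i], mat.sample_names[j]
                pc = sim.pair(a, b)
                exp = oracle_compare(mat.codes[i], mat.codes[j])
                assert pc.hom_diffs + pc.het_diffs + (pc.n_shared - pc.total_diffs) \
                    == pc.n_shared
                for k, v in exp.items():
                    assert getattr(pc, k) == v, k

    def test_adding_missing_never_increases_shared_or_changes_rest(self, rng):
        mat = random_matrix(rng, 4, 60)
        before = compare_pair(mat, "s1", "s2")
        codes = mat.codes.copy()
        codes[0, :10] = MISSING
        mat2 = type(mat)(mat.samples, mat.markers, codes)
        after = compare_pair(mat2, "s1", "s2")
        assert after.n_shared <= before.n_shared
        # classification of the remaining shared markers is untouched
        exp = oracle_compare(codes[0], codes[1])
        assert after.hom_diffs == exp["hom_diffs"] and after.het_diffs == exp["het_diffs"]


class TestSimilarityMatrix:
    def test_pair_count_and_symmetry(self, rng):
        mat = random_matrix(rng, 12, 30)
        sim = similarity_matrix(mat)
        assert len(sim.to_dataframe()) == 12 * 11 // 2
        assert np.allclose(sim.similarity, sim.similarity.T, equal_nan=True)
        assert np.array_equal(sim.hom_diffs, sim.hom_diffs.T)

    def test_injected_hom_mismatches_are_monotone(self, rng):
        mat = random_matrix(rng, 2, 100, probs=(0.0, 0.5, 0.5, 0.0))
        mat.codes[1] = mat.codes[0]
        prev_sim, prev_pct = 1.0, -1.0
        for k in (2, 5, 9):
            codes = mat.codes.copy()
            codes[1, :k] = np.where(codes[0, :k] == HOM_A, HOM_B, HOM_A)
            pc = compare_pair(type(mat)(mat.samples, mat.markers, codes), "s1", "s2")
            assert pc.similarity < prev_sim and pc.pct_hom_diffs > prev_pct
            prev_sim, prev_pct = pc.similarity, pc.pct_hom_diffs

    def test_dosage_correlation_alternative_metric(self):
        mat = matrix_from_calls([
            ["A:A", "G:G", "A:G", "A:A"],
            ["A:A", "G:G", "A:G", "A:A"],
            ["G:G", "A:A", "A:G", "G:G"],
        ])
        corr = dosage_correlation_matrix(mat)
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)
        assert corr.loc["s1", "s3"] < 0


class TestRanking:
    def test_descending_with_name_tiebreak_and_incomparable_last(self):
        mat = matrix_from_calls([
            ["A:A", "A:A"], ["A:A", "A:A"], ["G:G", "G:G"], ["?", "?"],
        ], sample_names=["q", "twin", "far", "empty"])
        ranked = rank_by_similarity(similarity_matrix(mat), "q")
        assert [r[0] for r in ranked] == ["twin", "far", "empty"]
        assert math.isnan(ranked[-1][1])

    def test_single_sample_matrix_rejected(self):
        mat = matrix_from_calls([["A:A"]])
        with pytest.raises(ValueError):
            similarity_matrix(mat)

    def test_unknown_query_raises(self, rng):
        sim = similarity_matrix(random_matrix(rng, 3, 10))
        with pytest.raises(KeyError):
            rank_by_similarity(sim, "nope")

    def test_planted_duplicates_rank_first(self):
        cfg = SimConfig(seed=11, n_lines_per_pool=20, n_chromosomes=4,
                        markers_per_chromosome=40, n_sister_species=0,
                        mislabel_count=0,
                        duplicate_groups=[DuplicateSpec(3, 0.002)])
        mat, truth = simulate_dataset(cfg)
        group = truth.duplicate_groups[0]
        ranked = rank_by_similarity(similarity_matrix(mat), group[0])
        assert {r[0] for r in ranked[:2]} == set(group[1:])


class TestDuplicates:
    def test_boundary_is_strict_less_than(self):
        # exactly 1% homozygous mismatches must NOT count as identical
        rows = [["A:A"] * 100, ["G:G"] + ["A:A"] * 99]
        mat = matrix_from_calls(rows)
        sim = similarity_matrix(mat)
        groups = find_duplicates(sim, IdentityRule(min_shared=50))
        assert all(len(g) == 1 for g in groups.groups)

    def test_min_shared_guards_sparse_overlap(self):
        rows = [["A:A"] * 5 + ["?"] * 95, ["A:A"] * 5 + ["?"] * 95]
        mat = matrix_from_calls(rows)
        groups = find_duplicates(similarity_matrix(mat), IdentityRule())
        assert all(len(g) == 1 for g in groups.groups)

    def test_duplicate_statistics_hand_example(self):
        # 10 samples: one group of four plus six singletons
        rows = [["A:A"] * 120] * 4
        base = np.array([HOM_A, HOM_B], dtype=np.int8)
        rng = np.random.default_rng(5)
        for _ in range(6):
            rows.append(["A:A" if c == HOM_A else "G:G"
                         for c in rng.choice(base, size=120)])
        mat = matrix_from_calls(rows)
        groups = find_duplicates(similarity_matrix(mat), IdentityRule(min_shared=50))
        stats = duplicate_statistics(groups, 10)
        assert stats["fraction_no_duplicates"] == pytest.approx(0.6)
        assert stats["fraction_more_than_two"] == pytest.approx(0.4)

    def test_all_singletons_statistics(self, rng):
        mat = random_matrix(rng, 8, 200, probs=(0.0, 0.5, 0.5, 0.0))
        groups = find_duplicates(similarity_matrix(mat), IdentityRule(min_shared=50))
        stats = duplicate_statistics(groups, 8)
        assert stats == {"fraction_no_duplicates": 1.0, "fraction_more_than_two": 0.0}

    def test_borderline_flag_for_sister_line_signature(self):
        # identity rule met on hom mismatches, but similarity dragged below
        # 0.99 by many het differences (residual-heterozygosity signature)
        rows = [["A:A"] * 200, ["A:G"] * 10 + ["A:A"] * 190]
        mat = matrix_from_calls(rows)
        groups = find_duplicates(similarity_matrix(mat), IdentityRule())
        assert groups.groups == [["s1", "s2"]]
        assert groups.borderline_pairs == [("s1", "s2")]


class TestGenepoolCheck:
    @pytest.fixture()
    def pools(self):
        cfg = SimConfig(seed=21, n_lines_per_pool=15, n_chromosomes=4,
                        markers_per_chromosome=40, n_sister_species=0,
                        duplicate_groups=[], mislabel_count=2)
        return simulate_dataset(cfg)

    def test_planted_mislabels_flagged(self, pools):
        mat, truth = pools
        sim = similarity_matrix(mat)
        refs = {"Andean": ["AND000", "AND001"],
                "Mesoamerican": ["MES000", "MES001"]}
        flagged = genepool_consistency_check(sim, mat.samples, refs)
        assert set(truth.mislabels) == {f["sample"] for f in flagged}
        for f in flagged:
            assert f["declared"] == "Andean" and f["assigned"] == "Mesoamerican"

    def test_references_never_flagged(self, pools):
        mat, _ = pools
        sim = similarity_matrix(mat)
        refs = {"Andean": ["AND000"], "Mesoamerican": ["MES000"]}
        flagged = genepool_consistency_check(sim, mat.samples, refs)
        assert {"AND000", "MES000"}.isdisjoint({f["sample"] for f in flagged})

    def test_no_references_is_an_error(self, pools):
        mat, _ = pools
        with pytest.raises(ValueError):
            genepool_consistency_check(similarity_matrix(mat), mat.samples, {})
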