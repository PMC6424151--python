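import numpy as np
import pytest

from conftest import matrix_from_calls
from germfp.introgression import (
    HET_STATE,
    MISSING_STATE,
    P1,
    P2,
    UNEXPECTED,
    PaintedGenome,
    build_consensus,
    consensus_call,
    count_recombinations,
    detect_het_blocks,
    introgression_fraction,
    paint_offspring,
    plot_painting,
    select_polymorphic,
)
from germfp.model import HET, HOM_A, HOM_B, MISSING
from germfp.simulate import CrossDesign, SimConfig, simulate_dataset


def painted(states, chrom="Pv01", positions=None, name="off"):
    states = np.asarray(states, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, states.size + 1) * 1_000_000
    return PaintedGenome(name, [f"m{k}" for k in range(states.size)],
                         [chrom] * states.size,
                         np.asarray(positions, dtype=np.int64),
                         states, np.zeros(states.size, dtype=bool))


# all 16 ordered state pairs and the reconciliation each must produce
CONSENSUS_TABLE = [
    (HOM_A, HOM_A, HOM_A, None),
    (HOM_B, HOM_B, HOM_B, None),
    (HET, HET, HET, None),
    (MISSING, MISSING, MISSING, "both missing"),
    (HOM_A, MISSING, HOM_A, None),      # rule 1: fill from the called line
    (MISSING, HOM_A, HOM_A, None),
    (HOM_B, MISSING, HOM_B, None),
    (MISSING, HOM_B, HOM_B, None),
    (HET, MISSING, HET, None),
    (MISSING, HET, HET, None),
    (HOM_A, HET, HOM_A, None),          # rule 2: homozygote wins over het
    (HET, HOM_A, HOM_A, None),
    (HOM_B, HET, HOM_B, None),
    (HET, HOM_B, HOM_B, None),
    (HOM_A, HOM_B, MISSING, "conflicting homozygotes"),  # rule 3
    (HOM_B, HOM_A, MISSING, "conflicting homozygotes"),
]


class TestConsensus:
    @pytest.mark.parametrize("a,b,expected,reason", CONSENSUS_TABLE)
    def test_truth_table_exhaustive(self, a, b, expected, reason):
        code, why = consensus_call(a, b)
        assert code == expected and why == reason

    def test_build_consensus_records_drop_reasons(self):
        mat = matrix_from_calls([
            ["A:A", "A:A", "A:A", "?"],
            ["?", "A:G", "G:G", "?"],
        ], sample_names=["SER16_set1", "SER16_set3"])
        cons = build_consensus(mat, "SER16_set1", "SER16_set3", "SER16")
        assert cons.codes[0] == HOM_A          # rule 1
        assert cons.codes[1] == HOM_A          # rule 2
        assert cons.dropped["m3"] == "conflicting homozygotes"
        assert cons.dropped["m4"] == "both missing"


class TestSelectPolymorphic:
    def _consensuses(self, row1, row2, names=("P1a", "P2a")):
        loci = [("Pv01", 1_000_000 * (k + 1)) for k in range(len(row1))]
        mat = matrix_from_calls([row1, row2], sample_names=list(names), loci=loci)
        c1 = build_consensus(mat, names[0], names[0], "P1")
        c2 = build_consensus(mat, names[1], names[1], "P2")
        return mat, c1, c2

    def test_keeps_opposite_homozygotes_drops_monomorphic(self):
        mat, c1, c2 = self._consensuses(["A:A", "A:A", "A:G"],
                                        ["G:G", "A:A", "G:G"])
        poly, dom = select_polymorphic(c1, c2, mat.markers)
        assert poly == ["m1"] and dom == set()

    def test_missing_donor_kept_only_in_dominant_mode(self):
        mat, c1, c2 = self._consensuses(["A:A", "A:A"], ["G:G", "?"])
        poly, dom = select_polymorphic(c1, c2, mat.markers)
        assert poly == ["m1"]
        poly2, dom2 = select_polymorphic(c1, c2, mat.markers,
                                         allow_missing_donor=True)
        assert poly2 == ["m1", "m2"] and dom2 == {"m2"}

    def test_markers_ordered_by_position(self):
        loci = [("Pv02", 500), ("Pv01", 900), ("Pv01", 100)]
        mat = matrix_from_calls([["A:A"] * 3, ["G:G"] * 3],
                                sample_names=["p", "q"], loci=loci)
        c1 = build_consensus(mat, "p", "p", "P1")
        c2 = build_consensus(mat, "q", "q", "P2")
        poly, _ = select_polymorphic(c1, c2, mat.markers)
        assert poly == ["m3", "m2", "m1"]


class TestPainting:
    def test_offspring_identical_to_recurrent_parent(self):
        mat = matrix_from_calls([["A:A"] * 6, ["G:G"] * 6, ["A:A"] * 6],
                                sample_names=["p1", "p2", "off"],
                                loci=[("Pv01", 10 * k + 10) for k in range(6)])
        c1 = build_consensus(mat, "p1", "p1", "P1")
        c2 = build_consensus(mat, "p2", "p2", "P2")
        poly, dom = select_polymorphic(c1, c2, mat.markers)
        p = paint_offspring(mat, "off", c1, c2, poly, dom)
        assert (p.states == P1).all()
        s = introgression_fraction(p)
        assert s.donor_fraction_dosage == 0.0 and s.donor_fraction_simple == 0.0

    def test_painting_conservation(self):
        mat = matrix_from_calls(
            [["A:A"] * 5, ["G:G"] * 5, ["A:A", "G:G", "A:G", "?", "A:A"]],
            sample_names=["p1", "p2", "off"],
            loci=[("Pv01", 10 * k + 10) for k in range(5)])
        c1 = build_consensus(mat, "p1", "p1", "P1")
        c2 = build_consensus(mat, "p2", "p2", "P2")
        poly, dom = select_polymorphic(c1, c2, mat.markers)
        p = paint_offspring(mat, "off", c1, c2, poly, dom)
        counts = {s: int((p.states == s).sum())
                  for s in (P1, P2, HET_STATE, MISSING_STATE, UNEXPECTED)}
        assert sum(counts.values()) == len(poly)
        assert counts[P1] == 2 and counts[P2] == 1 and counts[HET_STATE] == 1

    def test_dominant_marker_modes(self):
        mat = matrix_from_calls(
            [["A:A", "A:A"], ["G:G", "?"], ["A:A", "?"], ["A:A", "G:G"]],
            sample_names=["p1", "p2", "off_missing", "off_called"],
            loci=[("Pv01", 10), ("Pv01", 20)])
        c1 = build_consensus(mat, "p1", "p1", "P1")
        c2 = build_consensus(mat, "p2", "p2", "P2")
        poly, dom = select_polymorphic(c1, c2, mat.markers, allow_missing_donor=True)
        p = paint_offspring(mat, "off_missing", c1, c2, poly, dom)
        assert p.states[1] == P2                 # shared assay failure = donor
        conservative = paint_offspring(mat, "off_missing", c1, c2, poly, dom,
                                       dominant_missing_as_donor=False)
        assert conservative.states[1] == MISSING_STATE
        unexpected = paint_offspring(mat, "off_called", c1, c2, poly, dom)
        assert unexpected.states[1] == UNEXPECTED

    def test_simulated_bc1_painting_equals_truth(self):
        cfg = SimConfig(seed=17, n_lines_per_pool=1, n_chromosomes=5,
                        markers_per_chromosome=50, pool_freq_low=1.0,
                        pool_freq_high=1.0, residual_het_rate=0.0,
                        missing_rate_normal=0.0, n_sister_species=0,
                        duplicate_groups=[], mislabel_count=0,
                        crosses=[CrossDesign("BC1", "AND000", "MES000", 10)])
        mat, truth = simulate_dataset(cfg)
        c1 = build_consensus(mat, "AND000", "AND000", "P1")
        c2 = build_consensus(mat, "MES000", "MES000", "P2")
        poly, dom = select_polymorphic(c1, c2, mat.markers)
        assert len(poly) == mat.n_markers       # fully polymorphic parents
        idx = [mat.marker_index(m) for m in poly]
        for name in truth.origin_states:
            p = paint_offspring(mat, name, c1, c2, poly, dom)
            expected = np.array(truth.origin_states[name])[idx]
            assert np.array_equal(p.states, expected)


class TestRecombinations:
    def test_constant_chromosome_has_zero(self):
        assert count_recombinations(painted([P1, P1, P1])) == {"Pv01": 0}

    def test_hand_count_skips_missing(self):
        p = painted([P1, MISSING_STATE, P2, P2, HET_STATE])
        assert count_recombinations(p) == {"Pv01": 2}

    def test_het_transition_counts_per_homolog(self):
        p = painted([P1, HET_STATE, P2])
        assert count_recombinations(p) == {"Pv01": 2}

    def test_invariant_to_inserting_missing(self, rng):
        states = rng.choice(np.array([P1, P2, HET_STATE], dtype=np.int8), size=30)
        base = count_recombinations(painted(states))
        spots = rng.choice(31, size=8, replace=False)
        with_missing = np.insert(states, sorted(spots),
                                 np.int8(MISSING_STATE))
        assert count_recombinations(painted(with_missing)) == base

    def test_unexpected_skipped_like_missing(self):
        p = painted([P1, UNEXPECTED, P1, P2])
        assert count_recombinations(p) == {"Pv01": 1}


class TestIntrogressionFraction:
    def test_toy_arithmetic(self):
        states = [P2] + [HET_STATE] * 2 + [P1] * 7
        s = introgression_fraction(painted(states))
        assert s.donor_fraction_dosage == pytest.approx((2 + 2) / 20)
        assert s.donor_fraction_simple == pytest.approx(0.1)

    def test_dosage_bounds_vs_simple(self, rng):
        states = rng.choice(np.array(
            [P1, P2, HET_STATE, MISSING_STATE], dtype=np.int8), size=60)
        if not ((states == P1) | (states == P2) | (states == HET_STATE)).any():
            states[0] = P1
        s = introgression_fraction(painted(states))
        het_share = (states == HET_STATE).sum() / s.n_scored
        assert s.donor_fraction_simple <= s.donor_fraction_dosage
        assert s.donor_fraction_dosage <= s.donor_fraction_simple + het_share

    def test_zero_scored_markers_is_an_error(self):
        with pytest.raises(ValueError):
            introgression_fraction(painted([MISSING_STATE, MISSING_STATE]))


class TestHetBlocks:
    def test_min_block_run_detected_with_extent(self):
        p = painted([HET_STATE] * 3, positions=[100, 200, 300])
        blocks, isolated = detect_het_blocks(p, min_block=3)
        assert blocks == [("Pv01", 100, 300, 3)] and isolated == []

    def test_isolated_het_flagged_not_blocked(self):
        p = painted([P1, HET_STATE, P1], positions=[10, 20, 30])
        blocks, isolated = detect_het_blocks(p, min_block=3)
        assert blocks == [] and isolated == [("Pv01", 20)]

    def test_missing_inside_run_is_ignored(self):
        p = painted([HET_STATE, MISSING_STATE, HET_STATE, HET_STATE],
                    positions=[10, 20, 30, 40])
        blocks, _ = detect_het_blocks(p, min_block=3)
        assert blocks == [("Pv01", 10, 40, 3)]

    def test_min_block_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            detect_het_blocks(painted([P1]), min_block=1)

    def test_simulated_residual_het_segment_recovered(self):
        cfg = SimConfig(seed=29, n_lines_per_pool=6, n_chromosomes=3,
                        markers_per_chromosome=40, pool_freq_low=1.0,
                        pool_freq_high=1.0, residual_het_rate=0.5,
                        het_block_markers=(12, 12), missing_rate_normal=0.0,
                        n_sister_species=0, duplicate_groups=[], mislabel_count=0)
        mat, truth = simulate_dataset(cfg)
        # reference parents must themselves be fully fixed lines
        ref_and = next(n for n in mat.sample_names
                       if n.startswith("AND") and n not in truth.het_blocks)
        ref_mes = next(n for n in mat.sample_names
                       if n.startswith("MES") and n not in truth.het_blocks)
        c1 = build_consensus(mat, ref_and, ref_and, "P1")
        c2 = build_consensus(mat, ref_mes, ref_mes, "P2")
        poly, dom = select_polymorphic(c1, c2, mat.markers)
        carriers = [n for n in truth.het_blocks if n.startswith("AND")]
        assert carriers, "seed produced no Andean residual-het carrier"
        for line in carriers:
            p = paint_offspring(mat, line, c1, c2, poly, dom)
            blocks, _ = detect_het_blocks(p, min_block=3)
            for chrom, start, end in truth.het_blocks[line]:
                assert any(b[0] == chrom and b[1] <= start and b[2] >= end
                           and b[3] >= 12 for b in blocks)


def test_plot_painting_writes_figure_with_empty_panel(tmp_path):
    p1 = painted([P1, P2, HET_STATE, P2], chrom="Pv01")
    out = plot_painting([p1], tmp_path / "paint.png",
                        chromosomes=["Pv01", "Pv02"])
    assert out.exists() and out.stat().st_size > 0
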