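"""Quantification-rule tests with hand-computed and oracle expectations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from cambiokit import (
    apl_ratio,
    chi_square,
    classify_edu,
    classify_spread,
    count_cell_types,
    fraction_reaching,
    gradient_end,
    index_positions,
    load_preset,
    make_cell_file,
    make_cell_files,
    normalize_by_control,
)
from cambiokit.positional_quant import NO_EXPRESSION, PositionDistribution
from cambiokit.synthetic_cambium import CellFile


def build_file(intensities, landmark_index, identities=None, edu=None, apl=None,
               channel="DR5"):
    """Hand-built cell file for rule tests."""
    n = len(intensities)
    return CellFile(
        identities=identities or ["xylem_parenchyma"] * n,
        intensities={channel: np.asarray(intensities, dtype=float)},
        landmark_index=landmark_index,
        edu_positive=np.asarray(edu if edu is not None else [False] * n, dtype=bool),
        apl_positive=np.asarray(apl if apl is not None else [False] * n, dtype=bool),
    )


class TestIndexPositions:
    def test_six_cell_file(self):
        f = build_file([0] * 6, landmark_index=3)
        assert list(index_positions(f).positions) == [-3, -2, -1, 1, 2, 3]

    def test_minimal_file(self):
        f = build_file([0, 0], landmark_index=1)
        assert list(index_positions(f).positions) == [-1, 1]

    def test_round_trip_with_generator(self):
        preset = load_preset("col0_mock")
        for seed in range(100):
            f = make_cell_file(preset, rng_seed=seed)
            pidx = index_positions(f)
            assert pidx[f.landmark_index - 1] == -1
            assert pidx[f.landmark_index] == 1

    @given(n=st.integers(2, 30), lm=st.data())
    @settings(max_examples=50, derandomize=True)
    def test_never_zero_and_reversal_negates(self, n, lm):
        k = lm.draw(st.integers(1, n - 1))
        f = build_file([0] * n, landmark_index=k)
        pos = list(index_positions(f).positions)
        assert 0 not in pos
        assert pos == sorted(pos)
        rev = build_file([0] * n, landmark_index=n - k)
        rpos = list(index_positions(rev).positions)
        assert rpos == [-p for p in reversed(pos)]


class TestGradientEnd:
    def test_clean_step_gradient(self):
        f = build_file([1000, 1000, 1000, 50, 50], landmark_index=3)
        assert gradient_end(f, "DR5", 0.25) == -1

    def test_saturated_file_reaches_outermost(self):
        f = build_file([1000] * 5, landmark_index=3)
        assert gradient_end(f, "DR5", 0.25) == 2

    def test_no_expression_sentinel(self):
        f = build_file([0, 0, 0, 0], landmark_index=2)
        assert gradient_end(f, "DR5", 0.25) == NO_EXPRESSION

    def test_discontinuous_expression_modes(self):
        f = build_file([1000, 50, 900, 50], landmark_index=2)
        assert gradient_end(f, "DR5", 0.25, contiguous=True) == -2
        assert gradient_end(f, "DR5", 0.25, contiguous=False) == 1

    def test_generator_round_trip_bulk(self):
        files = make_cell_files(load_preset("ga1_ga48h"), 400, rng_seed=17)
        assert all(
            gradient_end(f, "DR5", 0.25) == f.ground_truth["end_position"]
            for f in files
        )

    def test_threshold_insensitivity_on_synthetic_contrast(self):
        f = build_file([1000, 1000, 50, 50], landmark_index=2)
        assert {gradient_end(f, "DR5", t) for t in (0.1, 0.25, 0.4, 0.6)} == {-1}


class TestFractionReaching:
    def test_hand_counts(self):
        d = PositionDistribution({-2: 5, -1: 3, 1: 2})
        assert fraction_reaching(d, {-1, 1}) == 0.5
        assert fraction_reaching(d, {-2, -1, 1}) == 1.0

    def test_empty_distribution_errors(self):
        with pytest.raises(ValueError):
            fraction_reaching(PositionDistribution({}), {-1})

    def test_no_expression_stays_in_denominator(self):
        d = PositionDistribution({-1: 3, NO_EXPRESSION: 1})
        assert fraction_reaching(d, {-1, 1}) == 0.75

    @given(st.dictionaries(st.integers(-5, 5).filter(lambda p: p != 0),
                           st.integers(1, 20), min_size=1))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_target_set(self, counts):
        d = PositionDistribution(counts)
        targets = sorted(counts)
        fracs = [fraction_reaching(d, set(targets[:k])) for k in range(1, len(targets) + 1)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == 1.0


class TestClassifySpread:
    def test_both_daughters(self):
        f = build_file([50, 1000, 1000, 50], landmark_index=2, channel="ANT")
        assert classify_spread(f, "ANT") == "both_daughters"

    def test_phloem_only(self):
        f = build_file([50, 50, 1000, 1000], landmark_index=2, channel="ANT")
        assert classify_spread(f, "ANT") == "phloem_only"

    def test_other(self):
        f = build_file([1000, 1000, 50, 50], landmark_index=2, channel="ANT")
        assert classify_spread(f, "ANT") == "other"

    def test_classes_partition_cohort(self):
        files = make_cell_files(load_preset("ant_ga"), 300, rng_seed=8)
        labels = [classify_spread(f) for f in files]
        assert all(l in ("both_daughters", "phloem_only", "other") for l in labels)
        # generator only draws the two observed classes
        assert labels.count("both_daughters") + labels.count("phloem_only") == 300


class TestClassifyEdu:
    def test_overlap(self):
        f = build_file([50, 1000, 1000, 50], landmark_index=2, channel="ANT",
                       edu=[False, True, False, False])
        assert classify_edu(f, "ANT") == ["overlap_ant"]

    def test_xylem_side(self):
        f = build_file([50, 50, 1000, 50], landmark_index=2, channel="ANT",
                       edu=[True, False, False, False])
        assert classify_edu(f, "ANT") == ["xylem_side"]

    def test_phloemward_cells_marked_excluded(self):
        f = build_file([50, 1000, 50, 50], landmark_index=2, channel="ANT",
                       edu=[False, False, False, True])
        assert classify_edu(f, "ANT") == ["excluded"]

    def test_no_edu_cells_flagged_empty(self):
        f = build_file([50, 1000, 50, 50], landmark_index=2, channel="ANT")
        assert classify_edu(f, "ANT") == []

    def test_generator_round_trip(self):
        files = make_cell_files(load_preset("edu_mock"), 300, rng_seed=9)
        for f in files:
            labels = classify_edu(f)
            assert labels == [f.ground_truth["edu_class"]]


class TestCellTypeCounts:
    def test_hand_counted_file(self):
        f = build_file(
            [0] * 7, landmark_index=3,
            identities=["vessel", "xylem_parenchyma", "stem_daughter",
                        "stem_daughter", "phloem", "sieve_element", "periderm"],
            apl=[False, False, False, False, False, True, False],
        )
        c = count_cell_types(f)
        assert (c.vessels, c.xylem_total, c.phloem_total, c.sieve_elements) == (1, 3, 3, 1)
        assert c.xylem_parenchyma == 2 and c.apl_positive == 1 and c.periderm_found

    def test_all_xylem_file(self):
        f = build_file([0, 0, 0], landmark_index=2,
                       identities=["vessel", "xylem_parenchyma", "periderm"])
        c = count_cell_types(f)
        assert c.phloem_total == 0 and c.xylem_total == 2

    def test_missing_periderm_flagged(self):
        f = build_file([0, 0], landmark_index=1,
                       identities=["vessel", "phloem"])
        assert not count_cell_types(f).periderm_found

    def test_brute_force_recount_oracle(self):
        files = make_cell_files(load_preset("col0_mock"), 300, rng_seed=10)
        for f in files:
            c = count_cell_types(f)
            # independent recount straight from the raw labels
            lm = f.landmark_index
            assert c.vessels == sum(
                1 for i in range(lm) if f.identities[i] == "vessel")
            assert c.xylem_total == lm
            assert c.phloem_total == sum(
                1 for i in range(lm, f.n_cells) if f.identities[i] != "periderm")
            assert c.sieve_elements == sum(
                1 for i in range(lm, f.n_cells) if f.identities[i] == "sieve_element")
            assert c.apl_positive == sum(
                1 for i in range(lm, f.n_cells)
                if f.apl_positive[i] and f.identities[i] != "periderm")


class TestRatiosAndNormalization:
    def test_apl_ratio(self):
        from cambiokit.positional_quant import CellTypeCounts

        c = CellTypeCounts(2, 3, 5, 20, 4, 5)
        assert apl_ratio(c) == 0.25
        c0 = CellTypeCounts(2, 3, 5, 20, 4, 0)
        assert apl_ratio(c0) == 0.0
        with pytest.raises(ValueError):
            apl_ratio(CellTypeCounts(2, 3, 5, 0, 0, 0))

    def test_control_normalization(self):
        out = normalize_by_control({"col0": [2, 2], "treated": [3, 1]}, "col0")
        np.testing.assert_allclose(out["col0"], [1, 1])
        np.testing.assert_allclose(out["treated"], [1.5, 0.5])
        assert out["col0"].mean() == 1.0

    def test_batchwise_normalization_matches_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(4):  # four simulated experiment batches
            groups = {
                "col0": rng.uniform(1, 5, 6),
                "ga1": rng.uniform(1, 5, 6),
                "ga_treated": rng.uniform(1, 5, 6),
            }
            out = normalize_by_control(groups, "col0")
            m = np.mean(groups["col0"])
            for g in groups:
                np.testing.assert_allclose(out[g], np.asarray(groups[g]) / m)

    def test_zero_control_mean_errors(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_by_control({"col0": [0.0, 0.0], "t": [1.0]}, "col0")


class TestChiSquare:
    def test_homogeneous_table(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p == 1.0 and res.df == 1

    def test_perfect_association(self):
        res = chi_square([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0) and res.df == 1

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            r, c = rng.integers(2, 5, 2)
            tab = rng.integers(1, 60, (r, c))
            ours = chi_square(tab)
            ref = chi2_contingency(tab, correction=False)
            assert abs(ours.statistic - ref.statistic) < 1e-10
            assert abs(ours.p - ref.pvalue) < 1e-10
            assert ours.df == ref.dof

    def test_yates_correction_matches_reference(self):
        tab = [[12, 5], [7, 15]]
        ours = chi_square(tab, yates=True)
        ref = chi2_contingency(np.asarray(tab), correction=True)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_zero_expected_cell_errors(self):
        with pytest.raises(ValueError, match="merge"):
            chi_square([[0, 0], [5, 10]])
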