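import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bedsweep import (
    AlphaBetaGrid,
    RocCurve,
    SweepRow,
    TreatmentScheme,
    auc,
    auc_pvalue,
    compute_bed,
    corner_optimal,
    empirical_roc,
    optimal_cutpoint,
    select_best_alpha_beta,
    sweep_alpha_beta,
    sweep_to_frame,
    youden_j,
)
from bedsweep.errors import DegenerateLabelsError, EmptyInputError, InvalidParameterError

from conftest import concordance_auc, make_record

SIX_POINT = (np.array([5.0, 7.0, 7.0, 9.0, 11.0, 13.0]), np.array([0, 0, 1, 0, 1, 1]))


class TestEmpiricalRoc:
    def test_hand_counted_confusion_matrices(self):
        # brute-force TP/TN counts at every unique score of the 6-point set
        scores, labels = SIX_POINT
        curve = empirical_roc(scores, labels)
        expected = {
            13.0: (1 / 3, 1.0),
            11.0: (2 / 3, 1.0),
            9.0: (2 / 3, 2 / 3),
            7.0: (1.0, 1 / 3),
            5.0: (1.0, 0.0),
        }
        got = {t: (se, sp) for t, se, sp in curve.operating_points(include_degenerate=False)}
        assert got == pytest.approx(expected)

    def test_degenerate_endpoints_present(self):
        scores, labels = SIX_POINT
        curve = empirical_roc(scores, labels)
        assert (curve.sensitivity[0], curve.specificity[0]) == (0.0, 1.0)
        assert (curve.sensitivity[-1], curve.specificity[-1]) == (1.0, 0.0)

    def test_monotone_in_decreasing_threshold(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        curve = empirical_roc(scores, labels)
        assert np.all(np.diff(curve.sensitivity) >= 0)
        assert np.all(np.diff(curve.specificity) <= 0)

    def test_perfect_separation_contains_ideal_point(self):
        curve = empirical_roc([1, 2, 3, 4], [0, 0, 1, 1])
        pts = {(se, sp) for _, se, sp in curve.operating_points()}
        assert (1.0, 1.0) in pts

    def test_constant_scores(self):
        curve = empirical_roc([2.0, 2.0, 2.0], [0, 1, 1])
        finite = list(curve.operating_points(include_degenerate=False))
        assert finite == [(2.0, 1.0, 0.0)]

    def test_errors(self):
        with pytest.raises(DegenerateLabelsError):
            empirical_roc([1, 2, 3], [1, 1, 1])
        with pytest.raises(InvalidParameterError):
            empirical_roc([1, 2, 3], [0, 1])


class TestAuc:
    def test_perfect_and_constant(self):
        assert auc(empirical_roc([1, 2, 3, 4], [0, 0, 1, 1])) == pytest.approx(1.0)
        assert auc(empirical_roc([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])) == pytest.approx(0.5)

    def test_six_point_pairwise_oracle(self):
        scores, labels = SIX_POINT
        # exhaustive concordance over the 9 (+,-) pairs: 7.5 / 9
        assert concordance_auc(scores, labels) == pytest.approx(7.5 / 9)
        assert auc(empirical_roc(scores, labels)) == pytest.approx(7.5 / 9, abs=1e-12)

    def test_equals_concordance_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(4, 31)
            scores = rng.integers(0, 8, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            assert auc(empirical_roc(scores, labels)) == pytest.approx(
                concordance_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(25):
            n = rng.integers(6, 40)
            scores = rng.normal(size=n).round(1)
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            assert auc(empirical_roc(scores, labels)) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_label_inversion_maps_auc_to_complement(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=30).round(1)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        a = auc(empirical_roc(scores, labels))
        assert auc(empirical_roc(scores, 1 - labels)) == pytest.approx(1.0 - a, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_monotone_transform_invariance(self, data):
        n = data.draw(st.integers(4, 20))
        scores = np.array(data.draw(st.lists(st.integers(0, 9), min_size=n, max_size=n)), float)
        labels = np.zeros(n, int)
        labels[: n // 2] = 1
        transformed = np.exp(scores / 3.0)  # strictly increasing map
        a1 = auc(empirical_roc(scores, labels))
        a2 = auc(empirical_roc(transformed, labels))
        assert a1 == pytest.approx(a2, abs=1e-12)
        m1 = corner_optimal(empirical_roc(scores, labels))
        m2 = corner_optimal(empirical_roc(transformed, labels))
        assert (m1.sensitivity, m1.specificity) == (m2.sensitivity, m2.specificity)
        assert m2.threshold == pytest.approx(np.exp(m1.threshold / 3.0))


def _exact_permutation_pvalue(scores, labels):
    """Two-sided permutation p-value for the rank-sum of the positives."""
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n1 = int(np.sum(labels))
    observed = ranks[np.asarray(labels) == 1].sum()
    null = np.array(
        [sum(c) for c in itertools.combinations(ranks, n1)]
    )
    mu = null.mean()
    return float(np.mean(np.abs(null - mu) >= abs(observed - mu) - 1e-12))


class TestAucPvalue:
    def test_constant_scores_give_p_one(self):
        assert auc_pvalue([3.0, 3.0, 3.0, 3.0], [0, 1, 0, 1]) == 1.0

    def test_perfect_separation_is_significant(self):
        scores = list(range(16))
        labels = [0] * 8 + [1] * 8
        assert auc_pvalue(scores, labels) < 0.01

    def test_tracks_exact_permutation_distribution(self):
        # At n = 6 the exact two-sided null is discrete in steps of 0.1, so
        # only coarse agreement is possible; by n = 22 the normal
        # approximation tracks the exact permutation p within 0.02.
        scores, labels = SIX_POINT
        p_exact = _exact_permutation_pvalue(scores, labels)
        assert abs(auc_pvalue(scores, labels) - p_exact) < 0.12
        rng = np.random.default_rng(4)
        for _ in range(5):
            s = rng.normal(size=22).round(1)
            y = np.zeros(22, int)
            y[:8] = 1
            rng.shuffle(y)
            assert abs(auc_pvalue(s, y) - _exact_permutation_pvalue(s, y)) < 0.02


class TestCornerOptimal:
    def test_ideal_point_wins_with_zero_distance(self):
        m = corner_optimal(empirical_roc([1, 2, 3, 4], [0, 0, 1, 1]))
        assert m.corner_distance == 0.0
        assert m.youden_j == 1.0
        assert m.threshold == 3.0

    def test_symmetric_tie_broken_by_smaller_threshold(self):
        curve = RocCurve(
            thresholds=np.array([np.inf, 2.0, 1.0, -np.inf]),
            sensitivity=np.array([0.0, 0.6, 0.8, 1.0]),
            specificity=np.array([1.0, 0.8, 0.6, 0.0]),
            n_positive=5,
            n_negative=5,
        )
        m = corner_optimal(curve)
        assert m.threshold == 1.0  # equal distance and J at t=1 and t=2
        assert m.youden_j == pytest.approx(0.4)

    def test_matches_exhaustive_scan_on_large_curve(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=400)
        labels = (rng.random(400) < 1 / (1 + np.exp(-scores))).astype(int)
        curve = empirical_roc(scores, labels)
        m = corner_optimal(curve)
        dists = [
            (np.hypot(1 - se, 1 - sp), t)
            for t, se, sp in curve.operating_points(include_degenerate=False)
        ]
        assert m.corner_distance == pytest.approx(min(d for d, _ in dists), abs=1e-12)

    def test_metrics_internally_consistent(self):
        m = corner_optimal(empirical_roc(*SIX_POINT))
        assert m.youden_j == pytest.approx(m.sensitivity + m.specificity - 1.0)
        assert m.corner_distance == pytest.approx(
            np.hypot(1 - m.sensitivity, 1 - m.specificity)
        )


class TestYoudenJ:
    @pytest.mark.parametrize(
        "sens,spec,expected", [(0.750, 0.745, 0.495), (1.0, 1.0, 1.0), (0.5, 0.5, 0.0)]
    )
    def test_values(self, sens, spec, expected):
        assert youden_j(sens, spec) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            youden_j(1.2, 0.5)


class TestSweep:
    def test_default_grid_gives_19_ascending_rows(self, crossing_cohort):
        rows = sweep_alpha_beta(crossing_cohort)
        assert len(rows) == 19
        assert [r.alpha_beta for r in rows] == [float(v) for v in range(2, 21)]

    def test_dose_columns_round_trip_to_optimal_bed(self, crossing_cohort):
        for row in sweep_alpha_beta(crossing_cohort):
            for n, d in row.doses.items():
                back = compute_bed(TreatmentScheme(n, d), row.alpha_beta)
                assert back == pytest.approx(row.optimal_bed, abs=1e-9)

    def test_separable_only_at_alpha_beta_14(self, crossing_cohort):
        rows = {r.alpha_beta: r for r in sweep_alpha_beta(crossing_cohort)}
        assert rows[14.0].sensitivity == 1.0
        assert rows[14.0].specificity == 1.0
        assert rows[14.0].youden_j == pytest.approx(1.0)
        assert rows[13.0].youden_j < 1.0
        assert rows[15.0].youden_j < 1.0
        assert select_best_alpha_beta(list(rows.values())) == 14.0

    def test_single_class_cohort_rejected(self):
        cohort = [make_record(1, 18.0, 1, idx=i) for i in range(5)]
        with pytest.raises(DegenerateLabelsError):
            sweep_alpha_beta(cohort)

    def test_sweep_frame_columns(self, crossing_cohort):
        df = sweep_to_frame(sweep_alpha_beta(crossing_cohort, fraction_schemes=(1, 5)))
        assert list(df.columns) == [
            "alpha_beta",
            "auc",
            "p_value",
            "optimal_bed_gy",
            "sensitivity",
            "specificity",
            "youden_j",
            "dose_1fx_gy",
            "dose_5fx_gy",
        ]


def _row(ab, j):
    return SweepRow(
        alpha_beta=ab,
        auc=0.5,
        auc_p_value=1.0,
        optimal_bed=40.0,
        sensitivity=0.5,
        specificity=0.5 + j,
        youden_j=j,
    )


class TestSelectBestAlphaBeta:
    def test_tie_goes_to_smallest_ratio(self):
        rows = [_row(2.0, 0.3), _row(14.0, 0.5), _row(15.0, 0.5)]
        assert select_best_alpha_beta(rows) == 14.0

    def test_single_row(self):
        assert select_best_alpha_beta([_row(7.0, 0.2)]) == 7.0

    def test_joint_rule_intersects_maximizer_sets(self):
        overall = [_row(12.0, 0.1), _row(14.0, 0.5), _row(15.0, 0.5)]
        subgroup = [_row(12.0, 0.8), _row(13.0, 0.8), _row(14.0, 0.8), _row(15.0, 0.1)]
        assert select_best_alpha_beta(overall, subgroup) == 14.0

    def test_disjoint_maximizers_fall_back_to_overall(self):
        overall = [_row(14.0, 0.5), _row(15.0, 0.4)]
        subgroup = [_row(14.0, 0.1), _row(15.0, 0.9)]
        assert select_best_alpha_beta(overall, subgroup) == 14.0

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            select_best_alpha_beta([])


class TestOptimalCutpoint:
    def test_bundles_curve_metrics(self):
        scores, labels = SIX_POINT
        result = optimal_cutpoint(scores, labels)
        assert result.auc == pytest.approx(7.5 / 9)
        assert result.n_positive == 3 and result.n_negative == 3
        assert result.metrics.youden_j == pytest.approx(
            result.metrics.sensitivity + result.metrics.specificity - 1.0
        )
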