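import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from jetflow.stats import (
    AgreementResult,
    PairedMeasurements,
    bland_altman,
    cohens_kappa,
    compare_methods,
    icc_two_way_random,
    interpret_agreement,
    summarize_median_iqr,
    wilcoxon_signed_rank,
)


def icc21_oracle(a, b):
    """Independent ICC(2,1) via explicit sums of squares (textbook route)."""
    x = np.column_stack([a, b]).astype(float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def wilcoxon_oracle(d):
    """Exact two-sided p by explicit enumeration of all 2^m sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    m = len(d)
    w_all = np.array(
        [np.sum(ranks[np.array(signs, bool)]) for signs in itertools.product([0, 1], repeat=m)]
    )
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestICC:
    def test_perfect_agreement(self):
        icc, p = icc_two_way_random(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]))
        assert icc == pytest.approx(1.0)
        assert p < 0.05

    def test_constant_offset_penalized_by_absolute_agreement(self):
        a = np.array([1.0, 2, 3, 4, 5])
        icc, _ = icc_two_way_random(a, a + 2.0)
        assert icc < 1.0

    @pytest.mark.parametrize(
        "a,b",
        [
            ([9, 6, 8, 7, 10, 6], [2, 1, 4, 1, 5, 2]),
            ([18, 22, 30, 12, 41, 9], [20, 21, 33, 10, 39, 12]),
            ([3, 3, 3, 5], [3, 4, 3, 5]),
        ],
    )
    def test_matches_sums_of_squares_oracle(self, a, b):
        icc, _ = icc_two_way_random(np.array(a, float), np.array(b, float))
        assert icc == pytest.approx(icc21_oracle(a, b), abs=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        a = np.array([18.0, 22, 30, 12, 41, 9, 25, 33])
        b = np.array([20.0, 21, 33, 10, 39, 12, 22, 38])
        icc, p = icc_two_way_random(a, b)
        df = pd.DataFrame(
            {
                "subject": list(range(8)) * 2,
                "rater": ["a"] * 8 + ["b"] * 8,
                "score": np.concatenate([a, b]),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]  # absolute agreement, single rater
        assert icc == pytest.approx(row["ICC"], abs=1e-8)
        assert p == pytest.approx(row["pval"], abs=1e-8)

    def test_zero_variance_signaled(self):
        with pytest.raises(ValueError, match="variance"):
            icc_two_way_random(np.array([5.0, 5, 5]), np.array([5.0, 5, 5]))


class TestBlandAltman:
    def test_textbook_example(self):
        bias, lo, hi = bland_altman(np.array([3.0, 4, 5]), np.array([2.0, 2, 2]))
        assert bias == pytest.approx(2.0)
        assert lo == pytest.approx(0.04)
        assert hi == pytest.approx(3.96)

    def test_identical_values_zero_width(self):
        bias, lo, hi = bland_altman(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert bias == lo == hi == 0.0

    @given(
        st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=20),
        st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=20),
    )
    def test_antisymmetric_under_swap(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        bias1, lo1, hi1 = bland_altman(a, b)
        bias2, lo2, hi2 = bland_altman(b, a)
        assert bias2 == pytest.approx(-bias1, abs=1e-9)
        assert lo2 == pytest.approx(-hi1, abs=1e-9)
        assert hi2 == pytest.approx(-lo1, abs=1e-9)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]), np.array([2.0]))


class TestKappa:
    def test_perfect_agreement(self):
        labels = ["none", "mild", "moderate", "severe", "mild"]
        kappa, p, p_o, p_e = cohens_kappa(labels, labels)
        assert kappa == pytest.approx(1.0)
        assert p_o == 1.0

    def test_two_by_two_confusion_table(self):
        # table [[20, 5], [10, 15]] -> p_o = 0.70, p_e = 0.50, kappa = 0.40
        a = ["none"] * 25 + ["mild"] * 25
        b = ["none"] * 20 + ["mild"] * 5 + ["none"] * 10 + ["mild"] * 15
        kappa, p, p_o, p_e = cohens_kappa(a, b)
        assert p_o == pytest.approx(0.70)
        assert p_e == pytest.approx(0.50)
        assert kappa == pytest.approx(0.40, abs=1e-12)

    def test_matches_sklearn_reference(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        cats = ["none", "mild", "moderate", "severe"]
        a = rng.choice(cats, 200, p=[0.4, 0.3, 0.2, 0.1]).tolist()
        b = [x if rng.random() < 0.6 else rng.choice(cats) for x in a]
        kappa, *_ = cohens_kappa(a, b)
        assert kappa == pytest.approx(sk.cohen_kappa_score(a, b), abs=1e-12)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(0)
        cats = ["none", "mild", "moderate", "severe"]
        a = rng.choice(cats, 10_000).tolist()
        b = rng.choice(cats, 10_000).tolist()
        kappa, *_ = cohens_kappa(a, b)
        assert abs(kappa) < 0.05

    def test_degenerate_single_cell_signaled(self):
        with pytest.raises(ValueError, match="undefined"):
            cohens_kappa(["mild"] * 5, ["mild"] * 5)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="categories"):
            cohens_kappa(["huge"], ["mild"])


class TestWilcoxon:
    def test_five_positive_differences_exact(self):
        assert wilcoxon_signed_rank(np.array([1.0, 2, 3, 4, 5])) == pytest.approx(2 / 32)

    def test_perfectly_symmetric_differences(self):
        assert wilcoxon_signed_rank(np.array([1.0, -1, 2, -2])) == 1.0

    def test_all_zero_differences_convention(self):
        assert wilcoxon_signed_rank(np.array([0.0, 0.0])) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0.4, 1.0, 10), 2)
        assert wilcoxon_signed_rank(d) == pytest.approx(wilcoxon_oracle(d), abs=1e-12)

    def test_matches_scipy_exact_for_tie_free_data(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.5, 1.0, 12)
        ours = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, mode="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.3, 1.0, 15)
        exact = wilcoxon_signed_rank(d)
        approx = wilcoxon_signed_rank(d, exact_max_n=0)
        assert approx == pytest.approx(exact, abs=0.01)


class TestSummaries:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3, 4, 5], (3.0, 2.0, 4.0)),
            ([7.0], (7.0, 7.0, 7.0)),
            ([1, 2, 3, 4], (2.5, 1.75, 3.25)),
        ],
    )
    def test_median_iqr_linear_interpolation(self, values, expected):
        assert summarize_median_iqr(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_median_iqr([])


class TestInterpretation:
    @pytest.mark.parametrize(
        "metric,value,label",
        [
            ("icc", 0.80, "good"),
            ("icc", 0.97, "excellent"),
            ("icc", 0.69, "moderate"),
            ("icc", 0.91, "strong"),
            ("icc", 0.30, "below scale"),
            ("kappa", 0.27, "fair"),
            ("kappa", 0.84, "excellent"),
            ("kappa", 0.38, "fair"),
            ("kappa", 0.16, "slight"),
            ("kappa", 0.55, "moderate"),
            ("kappa", 0.70, "substantial"),
            ("kappa", 0.0, "poor"),
            ("kappa", -0.4, "poor"),
        ],
    )
    def test_band_labels(self, metric, value, label):
        assert interpret_agreement(metric, value) == label

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            interpret_agreement("correlation", 0.5)


class TestCompareMethods:
    def test_full_battery_with_labels(self):
        pairs = PairedMeasurements(
            subjects=list(range(6)),
            values_a=np.array([12.0, 18, 35, 8, 62, 25]),
            values_b=np.array([15.0, 22, 31, 5, 70, 28]),
            labels_a=["mild", "mild", "moderate", "none", "severe", "mild"],
            labels_b=["mild", "mild", "moderate", "none", "severe", "mild"],
        )
        res = compare_methods(pairs)
        assert res.n == 6
        assert res.loa_low <= res.bias <= res.loa_high
        assert res.kappa == pytest.approx(1.0)
        assert res.kappa_label == "excellent"
        assert 0.0 <= res.wilcoxon_p <= 1.0
        assert res.direction == "a_minus_b"

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            AgreementResult(n=3, bias=5.0, loa_low=6.0, loa_high=7.0)
        with pytest.raises(ValueError):
            AgreementResult(n=3, icc=1.5)

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "subject": ["p1", "p2", "p3"],
                "value_a": [10.0, 20.0, 30.0],
                "value_b": [12.0, 18.0, 33.0],
                "grade_a": ["mild", "mild", "moderate"],
                "grade_b": ["mild", "mild", "moderate"],
            }
        )
        df.to_csv(tmp_path / "p.csv", index=False)
        pairs = PairedMeasurements.from_csv(tmp_path / "p.csv")
        assert len(pairs) == 3
        assert pairs.labels_b == ["mild", "mild", "moderate"]
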