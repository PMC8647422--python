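"""Method- and observer-agreement statistics.

The battery used to compare two measurement methods (or two observers)
on the same subjects:

* ICC(2,1) — two-way random-effects, single-measure, absolute-agreement
  intraclass correlation, with a p-value from the F test of the
  between-subject mean square against error.
* Bland-Altman — bias (mean difference, first minus second) and limits of
  agreement bias ± 1.96 * sample SD of the differences.
* Cohen's kappa — unweighted, on the fixed ordered severity categories,
  with a large-sample normal p-value against kappa = 0.
* Paired Wilcoxon signed-rank test — exact distribution for up to 25
  nonzero differences, normal approximation with tie correction above.
* Median [IQR] summaries (linear-interpolation quantiles).

Interpretation bands for ICC (moderate 0.50-0.70, good 0.71-0.85, strong
0.86-0.95, excellent 0.96-1.00) and kappa (poor 0, slight 0.01-0.20,
fair 0.21-0.40, moderate 0.41-0.60, substantial 0.61-0.80, excellent
0.81-1.00) are applied as contiguous half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .severity import SEVERITY_GRADES

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "icc_two_way_random",
    "bland_altman",
    "cohens_kappa",
    "wilcoxon_signed_rank",
    "summarize_median_iqr",
    "interpret_agreement",
    "compare_methods",
]


@dataclass
class PairedMeasurements:
    """Per-subject paired values (and optional severity labels).

    The difference direction of every derived statistic is values_a minus
    values_b.
    """

    subjects: list
    values_a: np.ndarray
    values_b: np.ndarray
    labels_a: list[str] | None = None
    labels_b: list[str] | None = None

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        n = len(self.subjects)
        if not (len(self.values_a) == len(self.values_b) == n):
            raise ValueError("subjects, values_a and values_b must have equal length")
        for labels in (self.labels_a, self.labels_b):
            if labels is not None and len(labels) != n:
                raise ValueError("labels must match the number of subjects")

    def __len__(self) -> int:
        return len(self.subjects)

    @classmethod
    def from_csv(cls, path) -> "PairedMeasurements":
        """Read columns subject, value_a, value_b[, grade_a, grade_b]."""
        df = pd.read_csv(path)
        return cls(
            subjects=df["subject"].tolist(),
            values_a=df["value_a"].to_numpy(),
            values_b=df["value_b"].to_numpy(),
            labels_a=df["grade_a"].tolist() if "grade_a" in df else None,
            labels_b=df["grade_b"].tolist() if "grade_b" in df else None,
        )


@dataclass
class AgreementResult:
    """Bundle of agreement statistics for one paired comparison."""

    n: int
    direction: str = "a_minus_b"
    icc: float | None = None
    icc_p: float | None = None
    icc_label: str | None = None
    bias: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None
    kappa: float | None = None
    kappa_p: float | None = None
    kappa_label: str | None = None
    observed_agreement: float | None = None
    expected_agreement: float | None = None
    wilcoxon_p: float | None = None

    def __post_init__(self) -> None:
        if self.bias is not None and not (self.loa_low - 1e-12 <= self.bias <= self.loa_high + 1e-12):
            raise ValueError("limits of agreement must bracket the bias")
        for name in ("icc", "kappa"):
            v = getattr(self, name)
            if v is not None and not -1.0 - 1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{name} must lie in [-1, 1]")
        for name in ("observed_agreement", "expected_agreement"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def icc_two_way_random(
    values_a: np.ndarray | PairedMeasurements, values_b: np.ndarray | None = None
) -> tuple[float, float]:
    """ICC(2,1): two-way random, single measures, absolute agreement.

    From the two-way ANOVA mean squares (n subjects, k raters):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The p-value is from the F test of MSR/MSE with (n-1, (n-1)(k-1))
    degrees of freedom. Raises on zero total variance.
    """
    if isinstance(values_a, PairedMeasurements):
        data = np.column_stack([values_a.values_a, values_a.values_b])
    else:
        data = np.column_stack([np.asarray(values_a, float), np.asarray(values_b, float)])
    n, k = data.shape
    if n < 2:
        raise ValueError("ICC needs at least 2 subjects")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())
    if ss_total == 0:
        raise ValueError("ICC undefined: zero total variance")
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 0.0

    if mse == 0:
        p = 0.0 if msr > 0 else 1.0
    else:
        f = msr / mse
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def bland_altman(
    values_a: np.ndarray | PairedMeasurements, values_b: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of paired differences (a - b).

    bias = mean(d); LOA = bias ± 1.96 * sample SD(d).
    """
    if isinstance(values_a, PairedMeasurements):
        d = values_a.values_a - values_a.values_b
    else:
        d = np.asarray(values_a, float) - np.asarray(values_b, float)
    if len(d) < 2:
        raise ValueError("Bland-Altman needs at least 2 paired differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def cohens_kappa(
    labels_a: list[str],
    labels_b: list[str],
    categories: tuple[str, ...] = SEVERITY_GRADES,
) -> tuple[float, float, float, float]:
    """Unweighted Cohen's kappa over a fixed ordered category set.

    Returns (kappa, p, observed agreement p_o, expected agreement p_e)
    from the full cross-tabulation (empty rows/columns retained). The
    p-value is the large-sample normal test of kappa = 0, using the
    null-hypothesis standard error

        SE0 = sqrt(p_e + p_e^2 - sum_i p_i. p_.i (p_i. + p_.i))
              / ((1 - p_e) sqrt(n)).
    """
    if len(labels_a) != len(labels_b) or len(labels_a) == 0:
        raise ValueError("label vectors must be nonempty and of equal length")
    index = {c: i for i, c in enumerate(categories)}
    try:
        ia = np.array([index[l] for l in labels_a])
        ib = np.array([index[l] for l in labels_b])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in categories {categories}") from exc
    m = len(categories)
    table = np.zeros((m, m))
    np.add.at(table, (ia, ib), 1.0)
    n = table.sum()
    p_o = float(np.trace(table) / n)
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p_e = float(np.dot(row, col))
    if p_e >= 1.0:
        raise ValueError("kappa undefined: all mass in a single category for both raters")
    kappa = (p_o - p_e) / (1.0 - p_e)

    se0_sq = p_e + p_e**2 - float(np.sum(row * col * (row + col)))
    if se0_sq <= 0:
        p = 1.0
    else:
        se0 = np.sqrt(se0_sq) / ((1.0 - p_e) * np.sqrt(n))
        p = float(2.0 * sps.norm.sf(abs(kappa) / se0))
    return float(kappa), min(p, 1.0), p_o, p_e


def _exact_wplus_sf_cdf(doubled_ranks: np.ndarray, w2: int) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) over all 2^m equally likely sign patterns.

    Computed from the exact distribution of the doubled (hence integer)
    positive-rank sum, built by dynamic programming — identical to
    enumerating every sign assignment.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    counts /= counts.sum()
    return float(counts[: w2 + 1].sum()), float(counts[w2:].sum())


def wilcoxon_signed_rank(
    values_a: np.ndarray | PairedMeasurements,
    values_b: np.ndarray | None = None,
    exact_max_n: int = 25,
) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (p = 1 if none remain). With at most
    ``exact_max_n`` nonzero differences the exact permutation distribution
    of the positive-rank sum is used (midranks for ties); beyond that, the
    normal approximation with tie correction and continuity correction.
    """
    if isinstance(values_a, PairedMeasurements):
        d = values_a.values_a - values_a.values_b
    elif values_b is not None:
        d = np.asarray(values_a, float) - np.asarray(values_b, float)
    else:
        d = np.asarray(values_a, float)
    d = d[d != 0]
    m = len(d)
    if m == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if m <= exact_max_n:
        doubled = np.rint(2.0 * ranks).astype(int)
        w2 = int(round(2.0 * w_plus))
        cdf, sf = _exact_wplus_sf_cdf(doubled, w2)
        return min(1.0, 2.0 * min(cdf, sf))

    mean = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return 1.0
    diff = w_plus - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return min(1.0, float(2.0 * sps.norm.sf(abs(z))))


def summarize_median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    """Median and [25th, 75th] percentiles, linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return float(med), float(q25), float(q75)


_ICC_BANDS = ((0.96, "excellent"), (0.86, "strong"), (0.71, "good"), (0.50, "moderate"))
_KAPPA_BANDS = (
    (0.81, "excellent"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
    (0.005, "slight"),
)


def interpret_agreement(metric_name: str, value: float) -> str:
    """Interpretation band label for an ICC or kappa value in [-1, 1]."""
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"{metric_name} value {value} outside [-1, 1]")
    if metric_name == "icc":
        for lo, label in _ICC_BANDS:
            if value >= lo:
                return label
        return "below scale"
    if metric_name == "kappa":
        for lo, label in _KAPPA_BANDS:
            if value >= lo:
                return label
        return "poor"
    raise ValueError(f"unknown metric {metric_name!r}; expected 'icc' or 'kappa'")


def compare_methods(pairs: PairedMeasurements) -> AgreementResult:
    """Run the full battery on one paired comparison.

    ICC, Bland-Altman and the Wilcoxon test are computed from the values;
    kappa and the agreement proportions from the labels when present.
    All differences are values_a minus values_b.
    """
    icc, icc_p = icc_two_way_random(pairs)
    bias, lo, hi = bland_altman(pairs)
    result = AgreementResult(
        n=len(pairs),
        icc=icc,
        icc_p=icc_p,
        icc_label=interpret_agreement("icc", max(min(icc, 1.0), -1.0)),
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        wilcoxon_p=wilcoxon_signed_rank(pairs),
    )
    if pairs.labels_a is not None and pairs.labels_b is not None:
        kappa, kp, p_o, p_e = cohens_kappa(pairs.labels_a, pairs.labels_b)
        result.kappa = kappa
        result.kappa_p = kp
        result.kappa_label = interpret_agreement("kappa", max(min(kappa, 1.0), -1.0))
        result.observed_agreement = p_o
        result.expected_agreement = p_e
    return result
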