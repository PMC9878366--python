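"""Method-comparison battery for paired self-report vs validation measures.

For each paired sample (one value per subject from each of two fixed
"raters": self-assessment x and validation y) the battery computes
descriptives, a two-tailed paired t test, intraclass correlation
coefficients in both the absolute-agreement and consistency forms, the
tie-corrected Kendall rank correlation, per-subject ranks for scatter
plotting, and the Bland–Altman difference series with bias and 95 % limits
of agreement.

ICC forms are the two-way single-measurement coefficients, conventionally
ICC(A,1) (absolute agreement) and ICC(C,1) (consistency), computed from the
two-way ANOVA mean squares

    MSR (rows/subjects), MSC (columns/raters), MSE (residual):
    ICC(C,1) = (MSR - MSE) / (MSR + (k-1)·MSE)
    ICC(A,1) = (MSR - MSE) / (MSR + (k-1)·MSE + (k/n)·(MSC - MSE))

with k = 2 raters. Absolute agreement penalizes a systematic offset between
raters (through MSC); consistency does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


class DegenerateSampleError(ValueError):
    """Sample too small or too degenerate for the requested statistic."""


@dataclass(frozen=True)
class PairedSample:
    """Paired observations, one (x, y) per subject, in common units."""

    ids: tuple[str, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if not len(self.ids) == len(self.x) == len(self.y):
            raise ValueError("ids, x and y must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("subject ids must be unique")
        if any(v is None or not math.isfinite(v) for v in (*self.x, *self.y)):
            raise ValueError("missing/non-finite values are not allowed after pairing")

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_dicts(cls, x: dict, y: dict) -> "PairedSample":
        """Pair by subject id; subjects missing on either side are dropped."""
        ids = sorted(set(x) & set(y))
        return cls(tuple(ids), tuple(float(x[i]) for i in ids), tuple(float(y[i]) for i in ids))


@dataclass(frozen=True)
class BlandAltman:
    """Difference-plot series: abscissa (x+y)/2, ordinate y − x."""

    means: tuple[float, ...]
    diffs: tuple[float, ...]
    bias: float
    loa_lower: float
    loa_upper: float


@dataclass(frozen=True)
class AgreementResult:
    """Full battery output for one paired sample."""

    n: int
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    median_x: float
    iqr_x: tuple[float, float]
    median_y: float
    iqr_y: tuple[float, float]
    t_statistic: float
    p_value: float
    aa_icc: float
    ca_icc: float
    kendall_tau: float
    bland_altman: BlandAltman
    degenerate_t: bool = False


def paired_t(sample: PairedSample) -> tuple[float, float]:
    """Two-tailed t test for dependent samples on d = x − y.

    t = mean(d) / (sd(d)/√n), p from Student t with n−1 df. All-zero
    differences give (0, 1); zero-variance nonzero differences give an
    infinite t (flagged by the caller via non-finiteness).
    """
    if sample.n < 2:
        raise DegenerateSampleError("paired t needs n >= 2")
    d = np.asarray(sample.x, dtype=float) - np.asarray(sample.y, dtype=float)
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean_d), 0.0
    t = mean_d / (sd_d / math.sqrt(sample.n))
    p = 2.0 * float(stats.t.sf(abs(t), df=sample.n - 1))
    return t, p


def _two_way_mean_squares(sample: PairedSample) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way subject × rater layout, k = 2."""
    data = np.column_stack([sample.x, sample.y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * float(((data.mean(axis=1) - grand) ** 2).sum())
    ss_cols = n * float(((data.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_pair(sample: PairedSample) -> tuple[float, float]:
    """(absolute-agreement ICC, consistency ICC) for two fixed raters.

    Returns (nan, nan) when the between-subject signal is absent
    (MSR + MSE = 0, i.e. a constant table).
    """
    if sample.n < 3:
        raise DegenerateSampleError("ICC needs n >= 3 subjects")
    k = 2
    msr, msc, mse = _two_way_mean_squares(sample)
    denom_c = msr + (k - 1) * mse
    if denom_c == 0.0:
        return math.nan, math.nan
    ca = (msr - mse) / denom_c
    denom_a = denom_c + (k / sample.n) * (msc - mse)
    aa = (msr - mse) / denom_a if denom_a != 0.0 else math.nan
    return aa, ca


def kendall_tau(sample: PairedSample) -> float:
    """Tie-corrected Kendall rank correlation (τ-b); nan when one side is all ties."""
    if sample.n < 2:
        raise DegenerateSampleError("Kendall tau needs n >= 2")
    if len(set(sample.x)) < 2 or len(set(sample.y)) < 2:
        return math.nan
    tau = stats.kendalltau(sample.x, sample.y, variant="b").statistic
    return float(tau)


def bland_altman(sample: PairedSample) -> BlandAltman:
    """Per-subject (mean, difference) series with bias ± 1.96 sd limits.

    Ordinate is validation − self-assessment (y − x): overestimation by
    self-report shows as negative bias. Abscissa is the pair mean (x+y)/2.
    """
    if sample.n < 2:
        raise DegenerateSampleError("Bland-Altman needs n >= 2")
    x = np.asarray(sample.x, dtype=float)
    y = np.asarray(sample.y, dtype=float)
    means = (x + y) / 2.0
    diffs = y - x
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        means=tuple(means.tolist()),
        diffs=tuple(diffs.tolist()),
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
    )


def rank_series(sample: PairedSample) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Average ranks (ties shared) per side, for rank scatterplots."""
    rx = stats.rankdata(sample.x, method="average")
    ry = stats.rankdata(sample.y, method="average")
    return tuple(rx.tolist()), tuple(ry.tolist())


def _median_iqr(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def compute_agreement(sample: PairedSample) -> AgreementResult:
    """Run the whole battery on one paired sample (n ≥ 3)."""
    if sample.n < 3:
        raise DegenerateSampleError("agreement battery needs n >= 3")
    x = np.asarray(sample.x, dtype=float)
    y = np.asarray(sample.y, dtype=float)
    t, p = paired_t(sample)
    aa, ca = icc_pair(sample)
    med_x, iqr_x = _median_iqr(x)
    med_y, iqr_y = _median_iqr(y)
    return AgreementResult(
        n=sample.n,
        mean_x=float(x.mean()),
        sd_x=float(x.std(ddof=1)),
        mean_y=float(y.mean()),
        sd_y=float(y.std(ddof=1)),
        median_x=med_x,
        iqr_x=iqr_x,
        median_y=med_y,
        iqr_y=iqr_y,
        t_statistic=t,
        p_value=p,
        aa_icc=aa,
        ca_icc=ca,
        kendall_tau=kendall_tau(sample),
        bland_altman=bland_altman(sample),
        degenerate_t=not math.isfinite(t),
    )
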