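"""Intra-class correlation for repeated scores.

Test-retest reliability of per-module scores across repetitions is
quantified with the two-way random-effects, absolute-agreement,
average-measures intra-class correlation, ICC(A,k) (equivalently ICC(2,k)):
both subjects and repetitions are treated as random samples, and
systematic differences between repetitions count against agreement.

From the two-way ANOVA mean squares (MSR between subjects, MSC between
repetitions, MSE residual) over an ``n x k`` complete score matrix::

    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

Confidence intervals follow the F-based method of McGraw & Wong (1996):
the single-measure interval is computed with a Satterthwaite-approximated
denominator df and stepped up to average measures with the
Spearman-Brown relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_measurements: int


def icc_a_k(scores: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,k) of a complete subjects x repetitions score matrix.

    Parameters
    ----------
    scores : array-like, shape (n_subjects, k_measurements)
        Complete matrix (no missing cells), n >= 2 and k >= 2.
    alpha : float
        1 - confidence level for the interval (default 95% CI).
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2:
        raise ValueError("scores must be a 2-D subjects x repetitions matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 repetitions, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("missing cells are not allowed (complete-case analysis)")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0:
        raise ValueError("zero total variance: ICC undefined")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc_k = (msr - mse) / (msr + (msc - mse) / n)

    # CI via the single-measure interval + Spearman-Brown step-up.
    denom2 = msr + (k - 1) * mse + k * (msc - mse) / n
    icc_1 = (msr - mse) / denom2
    if mse > 0:
        fj = msc / mse
        a = k * icc_1 * fj + n * (1 + (k - 1) * icc_1) - k * icc_1
        vn = (k - 1) * (n - 1) * a**2
        vd = (n - 1) * k**2 * icc_1**2 * fj**2 + (
            n * (1 + (k - 1) * icc_1) - k * icc_1
        ) ** 2
        v = vn / vd if vd > 0 else np.inf
    else:
        # zero residual variance: fj diverges and the Satterthwaite df
        # reduces to its limiting value
        v = (k - 1) * (n - 1)
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lb1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    ub1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    lb = lb1 * k / (1 + lb1 * (k - 1))
    ub = ub1 * k / (1 + ub1 * (k - 1))

    return ICCResult(
        icc=float(icc_k),
        ci_low=float(min(lb, icc_k)),
        ci_high=float(max(ub, icc_k)),
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        n_subjects=n,
        k_measurements=k,
    )


def icc_by_module(
    features, score_field: str = "total_duration_s", alpha: float = 0.05
) -> dict[str, ICCResult]:
    """ICC(A,k) of a per-procedure feature table, per module.

    Only completers (participants with every repetition of the module)
    enter; participants with missing repetitions raise, matching the
    complete-case requirement.
    """
    results: dict[str, ICCResult] = {}
    for module, sub in features.groupby("module", sort=False):
        mat = sub.pivot(index="participant_id", columns="repetition", values=score_field)
        if mat.isna().any().any():
            raise ValueError(
                f"module {module}: incomplete repetition matrix; restrict to completers"
            )
        results[str(module)] = icc_a_k(mat.to_numpy(), alpha=alpha)
    return results
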