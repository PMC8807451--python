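"""Statistical tests for the paired two-arm comparison.

Implements the four procedures used in the arm comparison: paired t-test
(objective noise, CNR), Wilcoxon signed-rank test (ordinal subjective
grades; exact sign enumeration when feasible, normal approximation with tie
and continuity corrections otherwise), Welch's unpaired t-test (cohort
demographics) and weighted Cohen's kappa (inter-reviewer agreement on the
1–5 scale).  Every test returns a :class:`StatResult` carrying the
statistic, the p-value, the sample size, the method actually used and an
effect summary.

The Wilcoxon implementation is authored here (rather than delegated)
because the exact-p contract matters for small reading studies; the t-tests
delegate to scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateDataError

__all__ = [
    "StatResult",
    "paired_t",
    "unpaired_t",
    "wilcoxon_signed_rank",
    "weighted_kappa",
]


@dataclass(frozen=True)
class StatResult:
    """Outcome of one statistical comparison.

    ``p_value`` is ``None`` for pure effect measures (kappa); otherwise it
    lies in [0, 1].  ``effect`` is the mean difference for t-tests, the
    median nonzero difference for the signed-rank test, and the agreement
    coefficient itself for kappa.
    """

    test: str
    statistic: float
    p_value: float | None
    n: int
    method: str
    effect: float | None = None

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be 1-dimensional")
    return a


def paired_t(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided paired t-test on the differences ``x − y`` (df = n − 1).

    Raises :class:`DegenerateDataError` when the differences have zero
    variance (including ``x == y`` exactly), where the statistic is
    undefined.
    """

    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    if np.allclose(d.var(ddof=1), 0.0):
        raise DegenerateDataError("zero-variance differences: paired t undefined")
    res = sps.ttest_rel(x, y)
    return StatResult(
        test="paired_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(x),
        method=f"two-sided, df={len(x) - 1}",
        effect=float(d.mean()),
    )


def unpaired_t(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Welch's two-sided unpaired t-test (no equal-variance assumption)."""

    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.allclose(a.var(ddof=1), 0.0) and np.allclose(b.var(ddof=1), 0.0):
        if np.isclose(a.mean(), b.mean()):
            # identical degenerate groups: no evidence of difference
            return StatResult(
                test="unpaired_t",
                statistic=0.0,
                p_value=1.0,
                n=len(a) + len(b),
                method="welch, degenerate equal groups",
                effect=0.0,
            )
        raise DegenerateDataError("both groups constant with different means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return StatResult(
        test="unpaired_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(a) + len(b),
        method="welch, two-sided",
        effect=float(a.mean() - b.mean()),
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_null_counts(ranks: np.ndarray) -> np.ndarray:
    """Counts of each achievable W+ value over all 2^n sign patterns.

    ``ranks`` must be positive integers (untied case: a permutation of
    1..n).  Dynamic programming over the subset-sum polynomial; index k of
    the returned array is the number of sign patterns with W+ == k.
    """

    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    zero_method: str = "drop",
) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Differences ``d = x − y`` equal to zero are dropped (classic
    convention; ``zero_method="pratt"`` instead ranks them and then
    discards their contribution).  Tied absolute differences receive
    mid-ranks.  With ``mode="auto"`` the p-value is exact — by full
    enumeration of the 2^n sign patterns via dynamic programming — whenever
    the number of nonzero differences is ≤ 20 and no ties are present;
    otherwise the normal approximation with tie correction and a 0.5
    continuity correction is used.  ``mode="exact"`` / ``"approx"`` force
    the choice (exact requires integer-valued ranks, i.e. no ties).

    Raises :class:`DegenerateDataError` when every difference is zero and
    ``ValueError`` when fewer than 5 nonzero differences remain (no
    two-sided p below 0.05 is achievable and the test is uninformative).
    """

    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"mode must be auto/exact/approx, got {mode!r}")
    if zero_method not in ("drop", "pratt"):
        raise ValueError(f"zero_method must be drop/pratt, got {zero_method!r}")
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    nonzero = d != 0
    if not nonzero.any():
        raise DegenerateDataError("all differences zero: signed-rank test undefined")
    if nonzero.sum() < 5:
        raise ValueError(
            f"only {int(nonzero.sum())} nonzero differences; need >= 5 for a "
            "meaningful two-sided p"
        )

    if zero_method == "drop":
        dnz = d[nonzero]
        ranks = sps.rankdata(np.abs(dnz))
    else:  # pratt: rank with zeros included, then drop the zero ranks
        ranks_all = sps.rankdata(np.abs(d))
        dnz = d[nonzero]
        ranks = ranks_all[nonzero]
    n = len(dnz)
    w_plus = float(ranks[dnz > 0].sum())
    has_ties = len(np.unique(ranks)) != n or not np.allclose(ranks, np.round(ranks))

    use_exact = (mode == "exact") or (mode == "auto" and n <= 20 and not has_ties)
    if mode == "exact" and has_ties:
        raise ValueError("exact mode requires untied integer ranks")

    if use_exact:
        counts = _signed_rank_null_counts(np.round(ranks).astype(int))
        total = counts.sum()  # == 2^n
        w = int(round(w_plus))
        p_low = counts[: w + 1].sum() / total
        p_high = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact sign enumeration"
    else:
        mu = n * (n + 1) / 4.0
        # tie correction: subtract sum(t^3 - t)/48 over tie groups
        _, tie_counts = np.unique(ranks, return_counts=True)
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        if sigma2 <= 0:
            raise DegenerateDataError("zero variance in signed-rank statistic")
        # continuity correction toward the mean
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(sigma2)
        p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(1.0, p)
        method = "normal approximation, tie + continuity corrected"

    return StatResult(
        test="wilcoxon_signed_rank",
        statistic=w_plus,
        p_value=p,
        n=n,
        method=method + f", zeros {zero_method}ped" if zero_method == "drop" else method + ", pratt zeros",
        effect=float(np.median(dnz)),
    )


# ---------------------------------------------------------------------------
# weighted kappa


def weighted_kappa(
    r1: Sequence[int],
    r2: Sequence[int],
    weights: str = "linear",
    categories: Sequence[int] = (1, 2, 3, 4, 5),
) -> StatResult:
    """Weighted Cohen's kappa for two raters on an ordinal scale.

    ``κ_w = 1 − Σ w_ij O_ij / Σ w_ij E_ij`` with observed proportions
    ``O``, chance-expected proportions ``E`` from the marginal products,
    and disagreement weights ``w_ij = |i − j| / (k − 1)`` (linear, default)
    or its square (quadratic).  Identical ratings give κ = 1; independent
    ratings give κ ≈ 0.
    """

    if weights not in ("linear", "quadratic"):
        raise ValueError(f"weights must be linear/quadratic, got {weights!r}")
    cats = list(categories)
    k = len(cats)
    if k < 2:
        raise ValueError("need at least 2 categories")
    a1 = np.asarray(r1)
    a2 = np.asarray(r2)
    if a1.shape != a2.shape or a1.ndim != 1:
        raise ValueError("ratings must be equal-length 1D sequences")
    index = {c: i for i, c in enumerate(cats)}
    try:
        i1 = np.array([index[v] for v in a1.tolist()])
        i2 = np.array([index[v] for v in a2.tolist()])
    except KeyError as exc:
        raise ValueError(f"rating {exc.args[0]!r} outside categories {cats}") from exc

    O = np.zeros((k, k))
    np.add.at(O, (i1, i2), 1.0)
    O /= O.sum()
    E = np.outer(O.sum(axis=1), O.sum(axis=0))
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    W = np.abs(ii - jj) / (k - 1)
    if weights == "quadratic":
        W = W**2
    denom = (W * E).sum()
    kappa = 1.0 if denom == 0 else 1.0 - (W * O).sum() / denom
    return StatResult(
        test="weighted_kappa",
        statistic=float(kappa),
        p_value=None,
        n=len(a1),
        method=f"{weights} weights, {k} categories",
        effect=float(kappa),
    )
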