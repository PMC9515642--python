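"""Clusterability, distribution-comparison, and variance-explained statistics.

Three statistics carry the analysis:

* the Hopkins statistic H, a clusterability index on the rhythm-ratio
  distribution (H = 0.5 for a homogeneous Poisson sample, H -> 1 for
  tightly clustered data);
* the two-sample Kolmogorov-Smirnov test, comparing rhythm-ratio
  distributions without distributional assumptions, with Bonferroni
  control over the per-bird family of pairwise comparisons;
* the proportionate reduction of error (PRE),
  ``1 - SSE_groups / SSE_total``, the share of rhythm variance removed
  by predicting each ratio with its transition-group mean instead of
  the grand mean, judged against a label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Hopkins statistic


@dataclass
class HopkinsEstimate:
    """Mean Hopkins statistic over bootstrap replicates."""

    H: float
    m: int
    reps: int
    replicates: np.ndarray = field(repr=False)


def _nearest_other(sorted_data: np.ndarray, points: np.ndarray, exclude_self: bool) -> np.ndarray:
    """1-D nearest-neighbour distances via a sorted-array scan.

    With ``exclude_self`` each query point is assumed to be a member of
    ``sorted_data`` and its own zero distance is skipped.
    """
    n = sorted_data.size
    if not exclude_self:
        pos = np.searchsorted(sorted_data, points)
        left = np.clip(pos - 1, 0, n - 1)
        right = np.clip(pos, 0, n - 1)
        return np.minimum(
            np.abs(points - sorted_data[left]), np.abs(points - sorted_data[right])
        )
    # each query is a member of the data: its own zero distance is
    # skipped, but a duplicated value is a genuine zero-distance other
    lo = np.searchsorted(sorted_data, points, side="left")
    hi = np.searchsorted(sorted_data, points, side="right")
    best = np.where(hi - lo >= 2, 0.0, np.inf)
    has_left = lo > 0
    d_left = np.full(points.size, np.inf)
    d_left[has_left] = points[has_left] - sorted_data[lo[has_left] - 1]
    has_right = hi < n
    d_right = np.full(points.size, np.inf)
    d_right[has_right] = sorted_data[np.minimum(hi, n - 1)[has_right]] - points[has_right]
    return np.minimum(best, np.minimum(d_left, d_right))


def hopkins(
    values: np.ndarray | pd.Series,
    m_frac: float = 0.1,
    reps: int = 100,
    seed: int | np.random.Generator | None = None,
) -> HopkinsEstimate:
    """Mean 1-D Hopkins statistic of a value collection.

    Per replicate, ``m = ceil(m_frac * n)`` data points are sampled
    without replacement and m reference points are drawn uniformly on
    the observed [min, max].  With u_i the distance from each reference
    point to its nearest data point and w_i the distance from each
    sampled data point to its nearest *other* data point, the replicate
    statistic is ``sum(u) / (sum(u) + sum(w))`` (exponent d = 1 for
    scalar data); H is the mean over ``reps`` replicates.

    H is invariant to affine rescaling of the values.  Requires at
    least 20 values with a non-degenerate range.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 20:
        raise ValueError("hopkins requires at least 20 values")
    if not 0 < m_frac <= 0.5:
        raise ValueError("m_frac must be in (0, 0.5]")
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise ValueError("degenerate data: all values equal (zero range)")
    rng = np.random.default_rng(seed)
    m = int(np.ceil(m_frac * n))
    xs = np.sort(x)
    stats = np.empty(reps)
    for r in range(reps):
        sample = rng.choice(x, size=m, replace=False)
        refs = rng.uniform(lo, hi, size=m)
        u = _nearest_other(xs, refs, exclude_self=False)
        w = _nearest_other(xs, sample, exclude_self=True)
        su, sw = u.sum(), w.sum()
        stats[r] = su / (su + sw)
    return HopkinsEstimate(H=float(stats.mean()), m=m, reps=reps, replicates=stats)


# ---------------------------------------------------------------------------
# two-sample Kolmogorov-Smirnov


@dataclass
class KSResult:
    """Two-sample KS comparison of two rhythm-ratio samples."""

    D: float
    n: int
    m: int
    p: float
    alpha: float
    critical: float  # closed-form rejection bound on D at alpha

    @property
    def reject(self) -> bool:
        return self.D > self.critical


def ks_critical_value(n: int, m: int, alpha: float = 0.05) -> float:
    """Closed-form large-sample rejection bound for the two-sample D.

    D exceeding ``sqrt(-ln(alpha/2) * (1 + m/n) / (2m))`` rejects the
    null of a common parent distribution at level alpha.
    """
    return float(np.sqrt(-np.log(alpha / 2.0) * (1.0 + m / n) / (2.0 * m)))


def ks_2sample(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    alpha: float = 0.05,
) -> KSResult:
    """Two-sample KS test: D = sup |F1,n(t) - F2,m(t)| over pooled support.

    The p-value is the standard asymptotic two-sided Kolmogorov
    distribution; the closed-form critical bound at ``alpha`` is
    reported alongside.  Symmetric in its arguments.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return KSResult(
        D=float(res.statistic),
        n=x.size,
        m=y.size,
        p=float(res.pvalue),
        alpha=alpha,
        critical=ks_critical_value(x.size, y.size, alpha),
    )


def bonferroni(
    p_values: np.ndarray | list[float],
    alpha: float = 0.05,
    k: int | None = None,
) -> pd.DataFrame:
    """Bonferroni adjustment over a comparison family.

    ``k`` defaults to the number of p-values supplied; pass it
    explicitly when the family is larger than the values at hand.
    Returns adjusted p = min(1, p * k) and the decision at ``alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if k is None:
        k = p.size
    adj = np.minimum(1.0, p * k)
    return pd.DataFrame({"p": p, "p_adjusted": adj, "significant": adj < alpha})


# ---------------------------------------------------------------------------
# proportionate reduction of error


@dataclass
class PREResult:
    """Variance in values explained by group membership."""

    PRE: float
    grand_mean: float
    group_means: dict = field(repr=False)
    n: int = 0
    null_ci: tuple[float, float] | None = None


def pre(values: np.ndarray | pd.Series, groups: np.ndarray | pd.Series) -> PREResult:
    """Proportionate reduction of error of group-mean prediction.

    ``PRE = 1 - sum((Y_i - Yhat_i)^2) / sum((Y_i - Ybar)^2)`` where
    Yhat_i is the mean of Y_i's group and Ybar the grand mean.  1 means
    the groups absorb all variance, 0 means they explain nothing.
    Invariant to group relabelling and to affine transformation of the
    values; undefined (error) when the total variance is zero.
    """
    y = np.asarray(values, dtype=float).ravel()
    g = np.asarray(groups).ravel()
    if y.size < 2:
        raise ValueError("pre requires at least 2 values")
    if y.size != g.size:
        raise ValueError("values and groups must have equal length")
    grand = y.mean()
    sse_total = float(((y - grand) ** 2).sum())
    if sse_total == 0.0:
        raise ValueError("zero total variance: PRE undefined")
    codes, uniq = pd.factorize(g)
    sums = np.bincount(codes, weights=y)
    counts = np.bincount(codes)
    means = sums / counts
    sse_groups = float(((y - means[codes]) ** 2).sum())
    return PREResult(
        PRE=1.0 - sse_groups / sse_total,
        grand_mean=float(grand),
        group_means={lab: float(mu) for lab, mu in zip(uniq, means)},
        n=y.size,
    )


def pre_null_ci(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, np.ndarray]:
    """Shuffle-bootstrap null interval for PRE under dissociated labels.

    Each replicate permutes the group labels against the values —
    preserving both marginals while destroying their association — and
    recomputes PRE.  Returns ``(lo, hi, replicates)`` where the bounds
    are the level-central quantiles of the replicate PREs.
    """
    y = np.asarray(values, dtype=float).ravel()
    g = np.asarray(groups).ravel()
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        reps[b] = pre(y, rng.permutation(g)).PRE
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [tail, 1.0 - tail])
    return float(lo), float(hi), reps
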