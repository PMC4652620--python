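"""Eight count-normalization methods for miRNA-seq count matrices.

Scaling methods (cpm, total count, upper quartile, TMM, median-of-ratios)
return per-sample factors alongside the normalized matrix; the two MA-plot
regression methods (linear regression, cyclic loess) and quantile
normalization reshape the data without a single per-sample factor.

Throughout, x_{i,j} is the count of feature i in sample j, s_j the library
size (column sum), M the per-feature log2 ratio between two samples and
A the average log2 intensity (the MA-plot coordinates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .count_core import CountMatrix, library_sizes

__all__ = [
    "ScalingFactors",
    "MAStats",
    "METHODS",
    "normalize",
    "normalize_cpm",
    "normalize_total_count",
    "normalize_upper_quartile",
    "normalize_tmm",
    "normalize_median_ratio",
    "normalize_linear_regression",
    "normalize_cyclic_loess",
    "normalize_quantile",
    "ma_stats",
]

BASELINE = "baseline"


@dataclass
class ScalingFactors:
    """Per-sample multiplicative factors with provenance.

    ``factors[j]`` is the number the raw column j was multiplied by
    (x'_{.,j} = factors[j] * x_{.,j}).  ``params`` records method-specific
    quantities (e.g. DESeq-style size factors, the TMM reference sample).
    """

    method: str
    factors: pd.Series | None
    reference: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.factors is not None:
            f = np.asarray(self.factors, dtype=float)
            if not np.all(np.isfinite(f)) or np.any(f <= 0):
                raise ValueError(f"{self.method}: factors must be positive and finite")


@dataclass
class MAStats:
    """Per-feature MA-plot coordinates for one sample pair.

    M_i = log2(x_{i,1} / x_{i,2}),  A_i = 0.5 * log2(x_{i,1} * x_{i,2}).
    Features with a zero value in either member are excluded, so M and A are
    always finite.
    """

    features: pd.Index
    M: pd.Series
    A: pd.Series
    pair: tuple[str, str]


def _column_sums(m: CountMatrix) -> pd.Series:
    s = m.data.sum(axis=0)
    zero = s.index[s <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample column(s): {list(zero)}")
    return s.astype(float)


def _geometric_mean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def normalize_cpm(m: CountMatrix) -> tuple[CountMatrix, ScalingFactors]:
    """Counts per million: x' = x * 1e6 / s_j; every column sums to 1e6."""
    s = _column_sums(m)
    factors = 1e6 / s
    out = m.with_data(m.data * factors)
    return out, ScalingFactors("cpm", factors)


def normalize_total_count(m: CountMatrix) -> tuple[CountMatrix, ScalingFactors]:
    """Total count scaling to the median-library-size baseline.

    d_j = s_baseline / s_j and x' = d_j * x; every normalized column sums to
    the baseline library size.
    """
    s = _column_sums(m)
    libs = library_sizes(m)
    factors = libs.s_baseline / s
    out = m.with_data(m.data * factors)
    return out, ScalingFactors("total_count", factors, reference=libs.baseline)


def normalize_upper_quartile(m: CountMatrix) -> tuple[CountMatrix, ScalingFactors]:
    """Upper-quartile scaling.

    q_j is the 75th percentile (linear interpolation) of sample j's counts
    over features with nonzero total across the matrix.  Factors g / q_j with
    g the geometric mean of the q's have geometric mean 1 by construction.
    """
    expressed = m.data.loc[m.data.sum(axis=1) > 0]
    if expressed.empty:
        raise ValueError("no expressed features for upper-quartile scaling")
    q = expressed.quantile(0.75, axis=0, interpolation="linear")
    zero_q = q.index[q <= 0]
    if len(zero_q):
        raise ValueError(
            f"upper quartile is zero for sample(s) {list(zero_q)}; "
            "filter low-count features first"
        )
    g = _geometric_mean(q.to_numpy())
    factors = g / q
    out = m.with_data(m.data * factors)
    return out, ScalingFactors("upper_quartile", factors, params={"quartiles": q})


def _tmm_log2_factor(
    xk: np.ndarray,
    xr: np.ndarray,
    sk: float,
    sr: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference.

    Features positive in both samples enter; the upper and lower trim/2
    quantiles of M and of A are discarded by rank and the intersection of
    survivors is kept; weights are reciprocals of the delta-method variance.
    """
    both = (xk > 0) & (xr > 0)
    if not both.any():
        warnings.warn("TMM: no features positive in both samples; factor set to 1")
        return 0.0
    xk, xr = xk[both], xr[both]
    pk, pr = xk / sk, xr / sr
    M = np.log2(pk / pr)
    A = 0.5 * np.log2(pk * pr)
    v = (sk - xk) / (sk * xk) + (sr - xr) / (sr * xr)
    n = M.size
    if n == 1:
        return float(M[0])
    lo_m = int(np.floor(n * trim_m / 2.0)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a / 2.0)) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(M)
    rank_a = rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        warnings.warn("TMM: trimming removed every feature; factor set to 1")
        return 0.0
    w = 1.0 / v[keep]
    return float(np.sum(w * M[keep]) / np.sum(w))


def normalize_tmm(
    m: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> tuple[CountMatrix, ScalingFactors]:
    """Trimmed mean of M-values normalization.

    With the reference sample r (auto: sample whose 75th percentile of x/s is
    closest to the mean such percentile), each sample's log2 factor is the
    precision-weighted mean of M after trimming by M (default 30% total) and
    A (default 5% total).  Factors are rescaled to geometric mean 1 and the
    normalized counts are x'_{i,k} = x_{i,k} * N~ / (s_k f_k) with N~ the
    geometric mean library size, so a pure depth change leaves factors at 1.
    """
    if m.data.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    s = _column_sums(m)
    X = m.data.to_numpy(dtype=float)
    if reference is None:
        p75 = np.quantile(X / s.to_numpy(), 0.75, axis=0)
        reference = m.samples[int(np.argmin(np.abs(p75 - p75.mean())))]
    elif reference not in m.samples:
        raise ValueError(f"unknown reference sample {reference!r}")
    r = m.samples.index(reference)
    log2_f = np.zeros(X.shape[1])
    for k in range(X.shape[1]):
        if k == r:
            continue
        log2_f[k] = _tmm_log2_factor(X[:, k], X[:, r], s.iloc[k], s.iloc[r], trim_m, trim_a)
    f = 2.0 ** (log2_f - log2_f.mean())  # geometric mean 1
    f = pd.Series(f, index=m.data.columns)
    n_tilde = _geometric_mean(s.to_numpy())
    factors = n_tilde / (s * f)
    out = m.with_data(m.data * factors)
    return out, ScalingFactors(
        "tmm",
        factors,
        reference=reference,
        params={"tmm_factors": f, "trim_m": trim_m, "trim_a": trim_a},
    )


def normalize_median_ratio(m: CountMatrix) -> tuple[CountMatrix, ScalingFactors]:
    """Median-of-ratios (DESeq-style) size factors.

    Over features with strictly positive counts in every sample, g_i is the
    geometric mean across samples and the size factor of sample j is
    s*_j = median_i(x_{i,j} / g_i); x' = x / s*_j.
    """
    X = m.data.to_numpy(dtype=float)
    all_pos = (X > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "median-of-ratios needs at least one feature positive in every "
            "sample; apply low-count filtering first"
        )
    pos = X[all_pos]
    g = np.exp(np.mean(np.log(pos), axis=1))
    size_factors = pd.Series(np.median(pos / g[:, None], axis=0), index=m.data.columns)
    factors = 1.0 / size_factors
    out = m.with_data(m.data * factors)
    return out, ScalingFactors(
        "median_ratio", factors, params={"size_factors": size_factors}
    )


def _resolve_member(m: CountMatrix, member: str) -> pd.Series:
    if member == BASELINE:
        return m.data.median(axis=1)
    if member not in m.data.columns:
        raise ValueError(f"unknown sample {member!r}")
    return m.data[member]


def ma_stats(
    m: CountMatrix, pair: tuple[str, str], pseudocount: float = 0.0
) -> MAStats:
    """MA-plot coordinates for a pair of samples (or "baseline" vs a sample).

    The baseline member is the per-feature median across all samples.
    Features with a zero value (after pseudocount) in either member are
    excluded before computing M and A.
    """
    x1 = _resolve_member(m, pair[0]) + pseudocount
    x2 = _resolve_member(m, pair[1]) + pseudocount
    shared = (x1 > 0) & (x2 > 0)
    if not shared.any():
        raise ValueError(f"no shared positive features for pair {pair}")
    x1, x2 = x1[shared], x2[shared]
    M = np.log2(x1 / x2)
    A = 0.5 * np.log2(x1 * x2)
    return MAStats(features=x1.index, M=M, A=A, pair=pair)


def normalize_linear_regression(m: CountMatrix) -> CountMatrix:
    """MA-plot linear-regression normalization against the median baseline.

    Per sample: OLS fit M = b0 + b1*A over features positive in both the
    sample and the median profile, corrected M' = M - fitted, and the sample
    value rebuilt as x' = 2^(A + M'/2).  Only the sample channel is adjusted
    so the baseline stays common to all samples; excluded (zero) features
    pass through unchanged.  Degenerate A (zero spread) falls back to
    subtracting the mean M.
    """
    out = m.data.astype(float).copy()
    for sample in m.samples:
        stats = ma_stats(m, (sample, BASELINE))
        if len(stats.features) < 2:
            raise ValueError(f"fewer than 2 shared-positive features for {sample!r}")
        M, A = stats.M.to_numpy(), stats.A.to_numpy()
        if np.ptp(A) == 0:
            corrected = M - M.mean()
        else:
            b1, b0 = np.polyfit(A, M, 1)
            corrected = M - (b0 + b1 * A)
        out.loc[stats.features, sample] = 2.0 ** (A + corrected / 2.0)
    return m.with_data(out)


def normalize_cyclic_loess(
    m: CountMatrix, span: float = 0.7, iterations: int = 3
) -> CountMatrix:
    """Cyclic loess normalization on the log2(x+1) scale.

    For every unordered sample pair, the lowess smoother c(A) of M on A is
    estimated over features positive in both members and half the correction
    is applied with opposite signs to each sample; cycling over all pairs is
    repeated ``iterations`` times.  Output is returned on the count scale
    (2^L - 1, floored at 0).  Pairs with fewer than 10 shared positive
    features are skipped with a warning.
    """
    if m.data.shape[1] < 2:
        raise ValueError("cyclic loess requires at least two samples")
    L = np.log2(m.data.to_numpy(dtype=float) + 1.0)
    n_samples = L.shape[1]
    for _ in range(iterations):
        for j in range(n_samples - 1):
            for k in range(j + 1, n_samples):
                both = (L[:, j] > 0) & (L[:, k] > 0)
                if both.sum() < 10:
                    warnings.warn(
                        f"cyclic loess: fewer than 10 shared positive features "
                        f"for pair ({m.samples[j]}, {m.samples[k]}); skipped"
                    )
                    continue
                M = L[both, j] - L[both, k]
                A = 0.5 * (L[both, j] + L[both, k])
                c = lowess(M, A, frac=span, return_sorted=False)
                L[both, j] -= c / 2.0
                L[both, k] += c / 2.0
    counts = np.clip(2.0 ** L - 1.0, 0.0, None)
    return m.with_data(pd.DataFrame(counts, index=m.data.index, columns=m.data.columns))


def normalize_quantile(m: CountMatrix) -> CountMatrix:
    """Quantile normalization: identical count distributions in every sample.

    Each value is replaced by the mean across samples of the values at its
    rank; tied entries receive the average of the reference values over their
    tied ranks, so the result is stable under permutation of tied entries.
    """
    if m.data.shape[1] < 2:
        raise ValueError("quantile normalization requires at least two samples")
    X = m.data.to_numpy(dtype=float)
    n, k = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(k):
        assigned = np.empty(n)
        assigned[order[:, j]] = ref
        out[:, j] = pd.Series(assigned).groupby(X[:, j]).transform("mean").to_numpy()
    return m.with_data(pd.DataFrame(out, index=m.data.index, columns=m.data.columns))


def _normalize_none(m: CountMatrix) -> tuple[CountMatrix, ScalingFactors]:
    factors = pd.Series(1.0, index=m.data.columns)
    return m.copy(), ScalingFactors("none", factors)


METHODS = (
    "cpm",
    "total_count",
    "upper_quartile",
    "tmm",
    "median_ratio",
    "linear_regression",
    "cyclic_loess",
    "quantile",
)


def normalize(
    m: CountMatrix, method: str, **kwargs
) -> tuple[CountMatrix, ScalingFactors | None]:
    """Dispatch over the normalization methods (plus "none" passthrough).

    Returns (normalized matrix, factors); factors are None for the
    regression-based and quantile methods, which have no per-sample factor.
    """
    dispatch = {
        "none": _normalize_none,
        "cpm": normalize_cpm,
        "total_count": normalize_total_count,
        "upper_quartile": normalize_upper_quartile,
        "tmm": normalize_tmm,
        "median_ratio": normalize_median_ratio,
    }
    no_factor = {
        "linear_regression": normalize_linear_regression,
        "cyclic_loess": normalize_cyclic_loess,
        "quantile": normalize_quantile,
    }
    if method in dispatch:
        return dispatch[method](m, **kwargs)
    if method in no_factor:
        return no_factor[method](m, **kwargs), None
    valid = ("none",) + METHODS
    raise ValueError(f"unknown normalization method {method!r}; valid: {valid}")
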