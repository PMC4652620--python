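"""Benchmarking metrics for normalized spike-in count data.

Covers the diagnostics used to compare normalization methods: relative log
expression (RLE), per-feature variance summaries, the dilution-series bias
model log2(C) = b0 + b1*log2(a), absolute fold-change bias, precision-recall
curves for differential-expression calls, and fold-change concordance
clustering across methods.  All log transforms use a +1 pseudocount for
zero-safety.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from statsmodels.nonparametric.smoothers_lowess import lowess

from .count_core import CountMatrix
from .spikein_sim import SpikeInDesign

__all__ = [
    "BiasFit",
    "PRCurve",
    "rle",
    "variance_summary",
    "variance_ratio_trend",
    "fit_bias_model",
    "pairwise_log_ratios",
    "pr_curve",
    "pooled_pr_curve",
    "absolute_bias",
    "fc_concordance",
]


@dataclass
class BiasFit:
    """OLS fit of one spike-in dilution series: log2(count+1) ~ log2(amount)."""

    spikein: str
    beta0: float
    beta1: float
    r_squared: float
    n_points: int
    degenerate: bool = False


@dataclass
class PRCurve:
    """Precision-recall sweep over |log2 FC| thresholds (descending)."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def rle(m: CountMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative log expression grid and per-sample boxplot quartiles.

    RLE_{i,j} = log2(x_{i,j}+1) - median_j(log2(x_{i,j}+1)).  For comparable
    samples the distributions should be centered at zero.
    """
    if m.data.shape[1] < 2:
        raise ValueError("RLE requires at least two samples")
    logged = np.log2(m.data.astype(float) + 1.0)
    grid = logged.sub(logged.median(axis=1), axis=0)
    quartiles = grid.quantile([0.25, 0.5, 0.75], axis=0).T
    quartiles.columns = ["q1", "median", "q3"]
    return grid, quartiles


def _log_variances(m: CountMatrix) -> pd.Series:
    return np.log2(m.data.astype(float) + 1.0).var(axis=1, ddof=1)


def variance_summary(
    raw: CountMatrix, norm: CountMatrix, background_only: bool = True
) -> tuple[pd.DataFrame, float]:
    """Per-feature log2(x+1) variance before/after normalization.

    Returns the variance table and the fraction of (background) features
    whose variance strictly decreased after normalization; equality at the
    boundary does not count as lower.
    """
    if raw.shape != norm.shape or list(raw.features) != list(norm.features):
        raise ValueError("raw and normalized matrices must share features and samples")
    table = pd.DataFrame(
        {
            "var_raw": _log_variances(raw),
            "var_norm": _log_variances(norm),
            "is_spikein": raw.is_spikein,
        }
    )
    table["lower"] = table["var_norm"] < table["var_raw"]
    subset = table[~table["is_spikein"]] if background_only else table
    fraction_lower = float(subset["lower"].mean()) if len(subset) else 0.0
    return table, fraction_lower


def variance_ratio_trend(
    raw: CountMatrix, norm: CountMatrix, span: float = 2 / 3
) -> pd.DataFrame:
    """Variance ratio vs mean abundance with a lowess trend.

    Per feature: x = mean log2(raw+1), y = log2(var_norm / var_raw); points
    below y = 0 have decreased variance after normalization.  Features with
    zero raw variance are excluded.  With fewer than 10 usable features the
    smoother column is NaN (points only).
    """
    if raw.shape != norm.shape or list(raw.features) != list(norm.features):
        raise ValueError("raw and normalized matrices must share features and samples")
    var_raw = _log_variances(raw)
    var_norm = _log_variances(norm)
    usable = var_raw > 0
    x = np.log2(raw.data.astype(float) + 1.0).mean(axis=1)[usable]
    y = np.log2(var_norm[usable] / var_raw[usable])
    out = pd.DataFrame({"mean_log_count": x, "log2_var_ratio": y})
    if len(out) >= 10:
        out["smoother"] = lowess(
            y.to_numpy(), x.to_numpy(), frac=span, return_sorted=False
        )
    else:
        out["smoother"] = np.nan
    return out


def fit_bias_model(
    norm: CountMatrix,
    design: SpikeInDesign,
    exclude: Iterable[str] = (),
) -> list[BiasFit]:
    """Fit log2(count+1) = b0 + b1*log2(amount) per spike-in dilution series.

    Samples with amount 0 are excluded from each fit (the log regressor is
    undefined there).  A slope near 1 means the normalized counts track the
    designed amounts.  R^2 is the squared Pearson correlation of observed and
    fitted values.  Series listed in ``exclude`` are skipped; a degenerate
    series (no count spread) is flagged with slope 0, R^2 0.
    """
    exclude = set(exclude)
    fits: list[BiasFit] = []
    for spike in design.spikeins:
        if spike in exclude or spike not in norm.data.index:
            continue
        amounts = design.assignment[spike]
        used = amounts.index[amounts > 0]
        used = [s for s in used if s in norm.data.columns]
        if len(used) < 2:
            raise ValueError(f"dilution series {spike!r} has fewer than 2 usable points")
        x = np.log2(amounts[used].to_numpy(dtype=float))
        y = np.log2(norm.data.loc[spike, used].to_numpy(dtype=float) + 1.0)
        if np.ptp(y) == 0:
            fits.append(BiasFit(spike, float(y[0]), 0.0, 0.0, len(used), degenerate=True))
            continue
        b1, b0 = np.polyfit(x, y, 1)
        fitted = b0 + b1 * x
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        fits.append(BiasFit(spike, float(b0), float(b1), float(r2), len(used)))
    return fits


def pairwise_log_ratios(
    norm: CountMatrix, reference: str | None = None
) -> dict[tuple[str, str], pd.Series]:
    """Per-feature log2 fold-changes, all-vs-all or all-vs-reference.

    FC_{i,(j,k)} = log2((x_{i,j}+1) / (x_{i,k}+1)); antisymmetric in the pair
    orientation, which is recorded in the dict key (j, k).
    """
    logged = np.log2(norm.data.astype(float) + 1.0)
    samples = norm.samples
    out: dict[tuple[str, str], pd.Series] = {}
    if reference is not None:
        if reference not in samples:
            raise ValueError(f"unknown reference sample {reference!r}")
        for s in samples:
            if s != reference:
                out[(s, reference)] = logged[s] - logged[reference]
        return out
    for a in range(len(samples) - 1):
        for b in range(a + 1, len(samples)):
            out[(samples[a], samples[b])] = logged[samples[a]] - logged[samples[b]]
    return out


def pr_curve(
    estimated: pd.Series, truth: pd.DataFrame, fc_threshold: float = 2.0
) -> PRCurve:
    """Precision-recall curve for calling differential expression.

    ``estimated`` holds |log2 FC| (or signed; absolute value is taken) per
    feature for one sample pair.  ``truth`` is a frame indexed by feature with
    columns ``nominal`` (log2), ``infinite`` and ``is_spikein``.  Positives
    are spike-ins with nominal fold-change >= fc_threshold (or an infinite
    flag, e.g. the 0 amol comparisons); negatives are all background
    features.  Thresholds sweep the unique observed values (plus +inf);
    precision with zero predictions is 1 by convention; the area uses
    step-wise interpolation over recall.
    """
    truth = truth.loc[estimated.index]
    log_thr = np.log2(fc_threshold)
    positive = truth["is_spikein"] & (
        truth["infinite"] | (truth["nominal"].abs() >= log_thr)
    )
    negative = ~truth["is_spikein"]
    n_pos = int(positive.sum())
    n_neg = int(negative.sum())
    if n_pos == 0:
        raise ValueError("no true positives in truth table; degenerate pair")
    considered = positive | negative
    scores = estimated.abs()[considered].to_numpy()
    labels = positive[considered].to_numpy()
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    cum_tp = np.cumsum(labels[order])
    # one (precision, recall) point per unique threshold: last index of each run
    boundary = np.nonzero(np.diff(sorted_scores, append=-np.inf))[0]
    tp = cum_tp[boundary]
    n_pred = boundary + 1
    thresholds = np.concatenate(([np.inf], sorted_scores[boundary]))
    precision = np.concatenate(([1.0], tp / n_pred))
    recall = np.concatenate(([0.0], tp / n_pos))
    auc = float(np.sum(np.diff(recall) * precision[1:]))
    return PRCurve(thresholds, precision, recall, auc, n_pos, n_neg)


def pooled_pr_curve(
    estimated: Mapping[tuple[str, str], pd.Series],
    truth: Mapping[tuple[str, str], pd.DataFrame],
    fc_threshold: float = 2.0,
) -> PRCurve:
    """PR curve pooling every sample pair into one threshold sweep.

    Pooling (one curve over all pairwise comparisons together) is sensitive to
    between-pair inconsistency of the normalized scale, which per-pair curves
    cannot see: a method that shifts different pairs by different amounts
    mixes background and spike-in fold-changes across pairs.
    """
    est_parts, truth_parts = [], []
    for pair, est in estimated.items():
        t = truth[pair] if pair in truth else truth[(pair[1], pair[0])]
        est_parts.append(est.abs().to_numpy())
        truth_parts.append(t.loc[est.index])
    pooled_est = pd.Series(np.concatenate(est_parts))
    pooled_truth = pd.concat(truth_parts, ignore_index=True)
    return pr_curve(pooled_est, pooled_truth, fc_threshold)


@dataclass
class BiasSummary:
    """Distribution summary of absolute bias b = estimated - nominal log2 FC."""

    values: pd.Series
    median: float
    q1: float
    q3: float


def absolute_bias(
    estimated: Mapping[tuple[str, str], pd.Series],
    truth: Mapping[tuple[str, str], pd.DataFrame],
) -> BiasSummary:
    """Pooled deviation of estimated from nominal log2 fold-changes.

    Background features have nominal 0; spike-in entries with an infinite
    nominal (0 amol comparisons) are excluded since no finite truth exists.
    """
    pieces = []
    for pair, est in estimated.items():
        if pair in truth:
            t = truth[pair]
            orient = 1.0
        elif (pair[1], pair[0]) in truth:
            t = truth[(pair[1], pair[0])]
            orient = -1.0
        else:
            raise KeyError(f"no truth for pair {pair}")
        t = t.loc[est.index]
        finite = ~t["infinite"]
        pieces.append(est[finite] - orient * t.loc[finite, "nominal"])
    values = pd.concat(pieces)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return BiasSummary(values=values, median=float(med), q1=float(q1), q3=float(q3))


def fc_concordance(
    fc_vectors: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Spearman concordance of fold-change estimates across methods.

    ``fc_vectors`` has one column per method over a shared feature-pair
    index.  Returns the Spearman correlation matrix and the complete-linkage
    hierarchical clustering (Euclidean distance between correlation-matrix
    rows) as a scipy linkage matrix.
    """
    if fc_vectors.shape[1] < 2:
        raise ValueError("need at least two method variants")
    for col in fc_vectors.columns:
        if fc_vectors[col].nunique() <= 1:
            raise ValueError(
                f"fold-change vector for method {col!r} is constant; "
                "Spearman correlation undefined"
            )
    corr = fc_vectors.corr(method="spearman")
    z = linkage(corr.to_numpy(), method="complete", metric="euclidean")
    return corr, z
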