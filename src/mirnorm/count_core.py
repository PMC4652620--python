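"""Count-matrix data model, TSV I/O, filtering, transforms and subsampling.

The central container is :class:`CountMatrix`: a features x samples table of
non-negative counts with a per-feature spike-in flag.  Raw inputs are integer
read counts; normalized outputs may be fractional.  All per-sample statistics
in this package are column statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "LibrarySizes",
    "read_counts",
    "write_counts",
    "filter_low_counts",
    "log2_plus_one",
    "library_sizes",
    "downsample",
]

DEFAULT_SPIKEIN_PREFIX = "ath-"


@dataclass
class CountMatrix:
    """Non-negative feature x sample count table.

    Parameters
    ----------
    data
        DataFrame with feature ids as index and sample ids as columns.
        All entries must be finite and >= 0.
    is_spikein
        Boolean Series aligned to ``data.index`` flagging spike-in features.
        Defaults to all-False.
    """

    data: pd.DataFrame
    is_spikein: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("count matrix contains non-numeric entries")
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count {values[i, j]} at feature "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        if self.is_spikein is None:
            self.is_spikein = pd.Series(False, index=self.data.index)
        else:
            self.is_spikein = pd.Series(self.is_spikein).reindex(
                self.data.index, fill_value=False
            ).astype(bool)

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame) -> "CountMatrix":
        """New matrix with ``data``, spike-in flags carried over by feature id."""
        return CountMatrix(data, self.is_spikein.reindex(data.index, fill_value=False))

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.data.copy(), self.is_spikein.copy())

    def background_features(self) -> list[str]:
        return list(self.data.index[~self.is_spikein])

    def spikein_features(self) -> list[str]:
        return list(self.data.index[self.is_spikein])


@dataclass
class LibrarySizes:
    """Per-sample total mapped counts and the median-size baseline sample."""

    sizes: pd.Series
    baseline: str

    @property
    def s_baseline(self) -> float:
        return float(self.sizes[self.baseline])


def read_counts(path, spikein_prefix: str | None = DEFAULT_SPIKEIN_PREFIX) -> CountMatrix:
    """Read a tab-separated count matrix.

    Layout: header row of sample ids (first column holds feature ids), one
    feature per row.  Lines starting with ``#`` are treated as comments.
    Features whose id starts with ``spikein_prefix`` are flagged as spike-ins.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.columns.size == 0:
        raise ValueError(f"{path}: malformed header, no sample columns found")
    df.index = df.index.astype(str)
    df.index.name = None
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            bad = df.index[converted.isna()][0]
            raise ValueError(
                f"{path}: non-numeric count at feature {bad!r}, sample {col!r}: "
                f"{df.loc[bad, col]!r}"
            )
        if (converted < 0).any():
            bad = df.index[converted < 0][0]
            raise ValueError(
                f"{path}: negative count at feature {bad!r}, sample {col!r}: "
                f"{converted[bad]}"
            )
        numeric[col] = converted.astype(float)
    flags = None
    if spikein_prefix is not None:
        flags = pd.Series(
            [f.startswith(spikein_prefix) for f in numeric.index], index=numeric.index
        )
    return CountMatrix(numeric, flags)


def write_counts(m: CountMatrix, path, header_lines: list[str] | None = None) -> None:
    """Write a count matrix in the TSV dialect read by :func:`read_counts`."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df = m.data.copy()
        df.index.name = "feature"
        df.to_csv(fh, sep="\t")


def filter_low_counts(
    m: CountMatrix, min_count: int = 5, min_fraction: float = 0.25
) -> CountMatrix:
    """Keep features with >= min_count reads in at least ceil(min_fraction * n) samples.

    The boundary is inclusive: with 8 samples and the default 25%, a feature
    passing in exactly 2 samples is retained.  Feature order is preserved and
    the operation is idempotent.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    n_required = int(np.ceil(min_fraction * m.data.shape[1]))
    keep = (m.data >= min_count).sum(axis=1) >= n_required
    if not keep.any():
        warnings.warn("low-count filter removed every feature", stacklevel=2)
    return m.with_data(m.data.loc[keep])


def log2_plus_one(m: CountMatrix) -> CountMatrix:
    """log2(x + 1) transform; zero counts map to zero."""
    return m.with_data(np.log2(m.data + 1.0))


def library_sizes(m: CountMatrix) -> LibrarySizes:
    """Column sums plus the baseline (median library size) sample.

    For an even number of samples the lower of the two middle sizes is the
    baseline; exact ties break to the lexicographically smallest sample id.
    Both rules are deterministic and independent of column order.
    """
    if m.data.shape[1] < 1:
        raise ValueError("need at least one sample")
    sizes = m.data.sum(axis=0)
    ordered = sizes.sort_values(kind="stable")
    n = len(ordered)
    target = ordered.iloc[(n - 1) // 2]  # lower middle for even n
    candidates = sorted(sizes.index[sizes == target])
    return LibrarySizes(sizes=sizes.astype(float), baseline=candidates[0])


def downsample(m: CountMatrix, depth: int, seed: int) -> CountMatrix:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Each column is replaced by a multivariate-hypergeometric draw, so column
    sums equal ``depth`` exactly and no cell exceeds its original value.
    Requires integral counts (raw data, not normalized output).
    """
    values = m.data.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise ValueError("downsampling requires integral counts; matrix is fractional")
    counts = np.round(values).astype(np.int64)
    sums = counts.sum(axis=0)
    for j, sample in enumerate(m.samples):
        if depth > sums[j]:
            raise ValueError(
                f"depth {depth} exceeds library size {sums[j]} of sample {sample!r}"
            )
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        if sums[j] == depth:
            out[:, j] = counts[:, j]
        else:
            out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return m.with_data(pd.DataFrame(out, index=m.data.index, columns=m.data.columns))
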