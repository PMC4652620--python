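"""Synthetic spike-in dilution experiment generator.

Emulates the statistical structure of a 12 x 12 cyclic Latin-Square spike-in
design: 12 synthetic oligonucleotides at 12 known amounts (amol) over a
constant biological background of several hundred miRNAs, with variable
per-sample sequencing depth, negative-binomial count noise, and optional
composition and intensity-dependent bias scenarios that exercise the
normalization methods.

Because each spike-in keeps one capture efficiency across all samples, the
true slope of log2(count) on log2(amount) is exactly 1 for every dilution
series; deviations measured downstream are pipeline bias, not simulator
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .count_core import CountMatrix

__all__ = [
    "DILUTION_SERIES_AMOL",
    "SpikeInDesign",
    "SimulationConfig",
    "SimulatedDataset",
    "make_latin_square_design",
    "simulate_background",
    "simulate_spikein_counts",
    "simulate_dataset",
    "build_truth",
]

#: The 12-point dilution series (amol) of the spike-in experiment.
DILUTION_SERIES_AMOL: tuple[float, ...] = (
    0.0, 0.1, 0.2, 0.8, 1.6, 6.4, 12.8, 51.2, 102.4, 409.6, 819.2, 3276.8,
)


@dataclass
class SpikeInDesign:
    """Sample x spike-in assignment of amounts with Latin-Square structure."""

    concentrations: tuple[float, ...]
    assignment: pd.DataFrame  # rows: samples, columns: spike-ins, values: amol

    @property
    def n(self) -> int:
        return len(self.concentrations)

    @property
    def samples(self) -> list[str]:
        return list(self.assignment.index)

    @property
    def spikeins(self) -> list[str]:
        return list(self.assignment.columns)

    def validate(self) -> None:
        levels = set(self.concentrations)
        for sample, row in self.assignment.iterrows():
            if set(row) != levels:
                raise ValueError(f"row {sample!r} violates the Latin-Square property")
        for spike in self.assignment.columns:
            if set(self.assignment[spike]) != levels:
                raise ValueError(f"column {spike!r} violates the Latin-Square property")


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def _spikein_ids(n: int) -> list[str]:
    return [f"ath-spike-{i + 1:02d}" for i in range(n)]


def make_latin_square_design(
    n: int = 12,
    concentrations: Sequence[float] = DILUTION_SERIES_AMOL,
    sample_ids: Sequence[str] | None = None,
    spikein_ids: Sequence[str] | None = None,
) -> SpikeInDesign:
    """Cyclic Latin-Square design: sample i, spike-in j gets level (i + j) mod n."""
    concentrations = tuple(float(c) for c in concentrations)
    if len(concentrations) != n:
        raise ValueError(f"need exactly {n} concentrations, got {len(concentrations)}")
    if len(set(concentrations)) != n:
        raise ValueError("concentrations must be distinct")
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be non-negative")
    samples = list(sample_ids) if sample_ids is not None else _sample_ids(n)
    spikes = list(spikein_ids) if spikein_ids is not None else _spikein_ids(n)
    grid = np.array(
        [[concentrations[(i + j) % n] for j in range(n)] for i in range(n)]
    )
    return SpikeInDesign(
        concentrations=concentrations,
        assignment=pd.DataFrame(grid, index=samples, columns=spikes),
    )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic spike-in experiment.

    Depths are desk-scale (1e5–5e5 expected reads/sample by default) stand-ins
    for the real experiment's millions of reads; every conclusion drawn from
    the benchmark is scale-free.  ``dispersion`` is the negative-binomial
    phi with variance mu + phi * mu^2 (phi = 0 gives Poisson counts).
    """

    n_background: int = 500
    n_samples: int = 12
    concentrations: tuple[float, ...] = DILUTION_SERIES_AMOL
    depths: tuple[float, ...] | None = None  # explicit expected totals, optional
    mean_depth: float = 2e5
    variable_depth: bool = True
    depth_range: tuple[float, float] = (1e5, 5e5)
    abundance_log_sd: float = 2.5  # natural-log sd of background relative abundances
    dispersion: float = 0.05
    kappa_per_amol: float = 10.0  # expected spike counts per amol at reference depth
    kappa_log_sd: float = 0.5  # per-spike-in capture-efficiency spread
    composition_fraction: float = 0.0
    composition_fold: float = 1.0
    composition_samples: tuple[str, ...] | None = None  # default: second half
    intensity_amplitude: float = 0.0
    intensity_samples: tuple[str, ...] | None = None  # default: odd-indexed samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")
        if not (0 <= self.composition_fraction < 1):
            raise ValueError("composition_fraction must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("mean_depth", "abundance_log_sd", "kappa_per_amol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulatedDataset:
    """Counts, design, and per-pair nominal log2 fold-change truth."""

    counts: CountMatrix
    design: SpikeInDesign
    truth: Mapping[tuple[str, str], pd.DataFrame]
    config: SimulationConfig = field(repr=False)


def _resolve_depths(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.depths is not None:
        depths = np.asarray(cfg.depths, dtype=float)
        if depths.size != cfg.n_samples:
            raise ValueError("depths length must equal n_samples")
        return depths
    if cfg.variable_depth:
        lo, hi = cfg.depth_range
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_samples))
    return np.full(cfg.n_samples, cfg.mean_depth)


def _nb_draw(mu: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial with mean mu, variance mu + phi*mu^2; Poisson if phi=0."""
    counts = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if phi == 0:
        counts[pos] = rng.poisson(mu[pos])
    else:
        size = 1.0 / phi
        p = size / (size + mu[pos])
        counts[pos] = rng.negative_binomial(size, p)
    return counts


def _intensity_distortion(mu: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth bounded intensity-dependent log2 distortion g applied as 2^g."""
    a = np.log2(mu + 1.0)
    return mu * 2.0 ** (amplitude * np.sin(a * 0.8))


def simulate_background(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    depths: np.ndarray | None = None,
    sample_ids: Sequence[str] | None = None,
) -> CountMatrix:
    """Constant biological background: same expected composition in every sample.

    Relative abundances are log-normal; expected counts are abundance share
    times sample depth, modified by the configured bias scenarios; observed
    counts are negative-binomial.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    samples = list(sample_ids) if sample_ids is not None else _sample_ids(cfg.n_samples)
    if depths is None:
        depths = _resolve_depths(cfg, rng)
    shares = np.exp(rng.normal(0.0, cfg.abundance_log_sd, size=cfg.n_background))
    shares /= shares.sum()
    mu = shares[:, None] * depths[None, :]

    if cfg.composition_fraction > 0 and cfg.composition_fold != 1.0:
        # composition bias: a minority of *highly expressed* features changes,
        # consuming sequencing real estate in the affected samples
        n_affected = int(round(cfg.composition_fraction * cfg.n_background))
        affected_features = np.argsort(shares)[::-1][:n_affected]
        affected_samples = (
            list(cfg.composition_samples)
            if cfg.composition_samples is not None
            else samples[len(samples) // 2 :]
        )
        cols = [samples.index(s) for s in affected_samples]
        mu[np.ix_(affected_features, cols)] *= cfg.composition_fold

    if cfg.intensity_amplitude != 0.0:
        distorted = (
            list(cfg.intensity_samples)
            if cfg.intensity_samples is not None
            else samples[1::2]
        )
        for s in distorted:
            j = samples.index(s)
            mu[:, j] = _intensity_distortion(mu[:, j], cfg.intensity_amplitude)

    counts = _nb_draw(mu, cfg.dispersion, rng)
    features = [f"hsa-miR-bg{i + 1:04d}" for i in range(cfg.n_background)]
    df = pd.DataFrame(counts, index=features, columns=samples)
    return CountMatrix(df, pd.Series(False, index=df.index))


def simulate_spikein_counts(
    design: SpikeInDesign,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    depths: np.ndarray | None = None,
) -> CountMatrix:
    """Spike-in counts proportional to the designed amounts.

    Expected count of spike-in s in sample i is kappa_s * amount_{i,s} *
    (depth_i / reference depth), with one log-normal capture efficiency
    kappa_s per spike-in (shared across samples, so the true dilution slope
    is 1).  A 0 amol assignment yields exactly 0 counts.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if depths is None:
        depths = _resolve_depths(cfg, rng)
    samples = design.samples
    if len(samples) != depths.size:
        raise ValueError("depths length must match the design's sample count")
    kappa = cfg.kappa_per_amol * np.exp(
        rng.normal(0.0, cfg.kappa_log_sd, size=len(design.spikeins))
    )
    amounts = design.assignment.to_numpy(dtype=float)  # samples x spikes
    ref_depth = depths.mean()
    mu = (kappa[None, :] * amounts * (depths[:, None] / ref_depth)).T  # spikes x samples
    counts = _nb_draw(mu, cfg.dispersion, rng)
    df = pd.DataFrame(counts, index=design.spikeins, columns=samples)
    return CountMatrix(df, pd.Series(True, index=df.index))


def build_truth(
    design: SpikeInDesign, features: Sequence[str], is_spikein: pd.Series
) -> dict[tuple[str, str], pd.DataFrame]:
    """Nominal log2 fold-change tables for every unordered sample pair.

    Background features have nominal 0; spike-ins have the log2 ratio of
    their designed amounts.  Pairs where exactly one amount is 0 are flagged
    ``infinite`` (signed inf nominal): they count as true positives for
    precision-recall but are excluded from absolute-bias arithmetic.
    """
    samples = design.samples
    features = pd.Index(features)
    truth: dict[tuple[str, str], pd.DataFrame] = {}
    amounts = design.assignment
    for a in range(len(samples) - 1):
        for b in range(a + 1, len(samples)):
            sa, sb = samples[a], samples[b]
            nominal = pd.Series(0.0, index=features)
            infinite = pd.Series(False, index=features)
            for spike in design.spikeins:
                if spike not in features:
                    continue
                xa, xb = amounts.loc[sa, spike], amounts.loc[sb, spike]
                if xa == 0 and xb == 0:
                    nominal[spike] = 0.0
                elif xb == 0:
                    nominal[spike], infinite[spike] = np.inf, True
                elif xa == 0:
                    nominal[spike], infinite[spike] = -np.inf, True
                else:
                    nominal[spike] = np.log2(xa / xb)
            truth[(sa, sb)] = pd.DataFrame(
                {
                    "nominal": nominal,
                    "infinite": infinite,
                    "is_spikein": is_spikein.reindex(features, fill_value=False),
                }
            )
    return truth


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Assemble background + spike-in counts with design and truth tables."""
    rng = np.random.default_rng(cfg.seed)
    design = make_latin_square_design(cfg.n_samples, cfg.concentrations)
    depths = _resolve_depths(cfg, rng)
    background = simulate_background(cfg, rng=rng, depths=depths, sample_ids=design.samples)
    spikes = simulate_spikein_counts(design, cfg, rng=rng, depths=depths)
    data = pd.concat([background.data, spikes.data])
    flags = pd.concat([background.is_spikein, spikes.is_spikein])
    counts = CountMatrix(data, flags)
    truth = build_truth(design, counts.features, counts.is_spikein)
    return SimulatedDataset(counts=counts, design=design, truth=truth, config=cfg)


def config_echo(cfg: SimulationConfig) -> str:
    """Key-value text rendering of a simulation config (one `key = value` per line)."""
    lines = [f"{k} = {v}" for k, v in asdict(cfg).items()]
    return "\n".join(lines) + "\n"
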