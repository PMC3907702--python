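"""Nonparametric inference for group ISC maps via circular-shift resampling.

Pair correlations are not independent (each subject sits in several pairs)
and BOLD series are autocorrelated, so standard correlation tests are
invalid.  The null here is "no specific time structure shared across
subjects": each subject's series is circularly rotated by an independent
random lag, which destroys inter-subject alignment while preserving each
series' marginal distribution and circular autocorrelation.  One pooled,
brain-wide null is built by randomizing over both voxels and lags; voxelwise
p-values are read off the pooled null by linear interpolation and corrected
with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core import ISCMap, pairwise_correlations
from .datamodel import BrainMask, SessionDataset

__all__ = [
    "NullDistribution",
    "ThresholdedMap",
    "circular_shift",
    "sample_null_distribution",
    "empirical_p",
    "fdr_threshold",
    "threshold_isc_map",
]

#: Library default for the pooled-null size.  The reference cluster-scale
#: default is two orders of magnitude larger; analyses on small grids are
#: well served by far fewer realizations.
DEFAULT_N_REALIZATIONS = 1_000_000


@dataclass
class NullDistribution:
    """Pooled empirical null of the group statistic under circular shifts."""

    samples: np.ndarray
    rng_seed: int

    def __post_init__(self) -> None:
        self.samples = np.sort(np.asarray(self.samples, dtype=float))
        if self.samples.size < 1:
            raise ValueError("null distribution needs at least one sample")

    @property
    def n_realizations(self) -> int:
        return self.samples.size


@dataclass
class ThresholdedMap:
    source: ISCMap
    q_level: float
    critical_r: float
    rejected: np.ndarray
    p_map: np.ndarray


def circular_shift(series: np.ndarray, shift: int) -> np.ndarray:
    """Rotate a length-T series: output[t] = input[(t - shift) mod T]."""
    series = np.asarray(series)
    T = series.shape[-1]
    if not 0 <= shift < T:
        raise ValueError(f"shift must lie in [0, {T}), got {shift}")
    return np.roll(series, shift, axis=-1)


def _random_shift_matrix(rng: np.random.Generator, n_rows: int, n_subjects: int, T: int) -> np.ndarray:
    """Per-subject lags, uniform on {0..T-1}; the joint all-zero row is redrawn."""
    shifts = rng.integers(0, T, size=(n_rows, n_subjects))
    bad = np.all(shifts == 0, axis=1)
    while bad.any():
        shifts[bad] = rng.integers(0, T, size=(int(bad.sum()), n_subjects))
        bad = np.all(shifts == 0, axis=1)
    return shifts


def _null_samples_from_series(
    series: np.ndarray,
    n_realizations: int,
    rng: np.random.Generator,
    batch_size: int = 4096,
) -> np.ndarray:
    """Pooled null draws from an (N, V, T) series array.

    Each realization picks one voxel uniformly, rotates every subject's series
    at that voxel by an independent random lag, and evaluates the group mean
    pairwise correlation.
    """
    n_sub, n_vox, T = series.shape
    samples = np.empty(n_realizations)
    pos = 0
    t_idx = np.arange(T)
    while pos < n_realizations:
        b = min(batch_size, n_realizations - pos)
        vox = rng.integers(0, n_vox, size=b)
        shifts = _random_shift_matrix(rng, b, n_sub, T)
        block = series[:, vox, :]  # (N, b, T)
        gather = (t_idx[None, None, :] - shifts.T[:, :, None]) % T
        block = np.take_along_axis(block, gather, axis=2)
        samples[pos : pos + b] = pairwise_correlations(block).mean(axis=1)
        pos += b
    return samples


def sample_null_distribution(
    dataset: SessionDataset,
    n_realizations: int,
    seed: int,
    batch_size: int = 4096,
) -> NullDistribution:
    """Build the pooled brain-wide circular-shift null for a session."""
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if dataset.mask.n_voxels < 1:
        raise ValueError("empty mask")
    rng = np.random.default_rng(seed)
    series = dataset.masked_series()
    samples = _null_samples_from_series(series, n_realizations, rng, batch_size)
    samples = samples[np.isfinite(samples)]
    return NullDistribution(samples=samples, rng_seed=seed)


def empirical_p(value, null: NullDistribution):
    """Right-tail exceedance probability from the pooled null.

    The empirical CDF uses plotting positions F(s_(k)) = k/(n+1) with linear
    interpolation between order statistics; the result is clipped to
    [1/(n+1), 1], so a value above every null sample gets p = 1/(n+1).
    Monotone non-increasing in ``value``.
    """
    s = null.samples
    n = s.size
    cdf = np.interp(np.asarray(value, dtype=float), s, np.arange(1, n + 1) / (n + 1))
    return np.clip(1.0 - cdf, 1.0 / (n + 1), 1.0)


def fdr_threshold(p_values: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection set at FDR level ``q``."""
    p_values = np.asarray(p_values, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject


def threshold_isc_map(
    isc: ISCMap,
    null: NullDistribution,
    q: float,
    mask: BrainMask,
    negative_tail: bool = False,
) -> ThresholdedMap:
    """FDR-threshold a group ISC map against the pooled circular-shift null.

    The test is one-sided on high rbar by default (significant shared
    response); ``negative_tail`` tests low rbar instead.
    """
    values = isc.masked_values(mask)
    finite = np.isfinite(values)
    test_values = -values if negative_tail else values
    null_for_tail = (
        NullDistribution(samples=-null.samples, rng_seed=null.rng_seed)
        if negative_tail
        else null
    )
    p = np.ones_like(values)
    p[finite] = empirical_p(test_values[finite], null_for_tail)
    reject = np.zeros_like(values, dtype=bool)
    reject[finite] = fdr_threshold(p[finite], q)
    if reject.any():
        critical = float(np.min(np.abs(values[reject])))
    else:
        critical = float("nan")
    rejected_3d = np.zeros(mask.shape, dtype=bool)
    rejected_3d[mask.mask] = reject
    p_map = np.full(mask.shape, np.nan)
    p_map[mask.mask] = p
    return ThresholdedMap(
        source=isc, q_level=q, critical_r=critical, rejected=rejected_3d, p_map=p_map
    )
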