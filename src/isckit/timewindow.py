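"""Sliding-window ISC: short-time group ISC maps and ROI time curves.

The group mean pairwise correlation is evaluated inside consecutive, possibly
overlapping windows of W samples stepped by S samples, giving one ISC map per
window.  The circular-shift resampling null is randomized over windows as
well as voxels and lags, so a single pooled distribution yields one common
threshold for all windows.  ROI-averaged curves (mean rbar over atlas-region
voxels per window) summarize the temporal evolution for correlation with
stimulus features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ISCMap, mean_isc, pairwise_correlations, pair_order, PairwiseCorrelationSet
from .datamodel import AtlasDefinition, SessionDataset
from .resampling import NullDistribution, _random_shift_matrix

__all__ = [
    "WindowSpec",
    "WindowedISCMaps",
    "ROICurve",
    "make_windows",
    "windowed_isc",
    "pooled_window_null",
    "roi_curves",
    "curves_to_frame",
]

#: Below this window length the correlation estimate is very noisy; lengths
#: this short have been used in practice, so it is a warning, not an error.
MIN_RECOMMENDED_WINDOW = 10


@dataclass
class WindowSpec:
    length_samples: int
    step_samples: int

    def __post_init__(self) -> None:
        if self.length_samples < 2:
            raise ValueError("window length must be >= 2 samples")
        if self.step_samples < 1:
            raise ValueError("window step must be >= 1 sample")
        if self.length_samples < MIN_RECOMMENDED_WINDOW:
            warnings.warn(
                f"window length {self.length_samples} < {MIN_RECOMMENDED_WINDOW} "
                "samples gives very noisy correlation estimates",
                stacklevel=2,
            )


@dataclass
class WindowedISCMaps:
    maps: list[ISCMap]
    window_starts: np.ndarray
    window_length: int
    tr_seconds: float
    common_threshold: float = float("nan")

    @property
    def n_windows(self) -> int:
        return len(self.maps)

    @property
    def window_centers_seconds(self) -> np.ndarray:
        """Window center times, for aligning curves with stimulus features."""
        return (self.window_starts + (self.window_length - 1) / 2) * self.tr_seconds


@dataclass
class ROICurve:
    roi_name: str
    values: np.ndarray
    time_axis: np.ndarray = field(default_factory=lambda: np.array([]))


def make_windows(T: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open index ranges [start, start+W); trailing partials dropped."""
    W, S = spec.length_samples, spec.step_samples
    if W > T:
        raise ValueError(f"window length {W} exceeds series length {T}")
    return [(s, s + W) for s in range(0, T - W + 1, S)]


def windowed_isc(dataset: SessionDataset, spec: WindowSpec) -> WindowedISCMaps:
    """One group ISC map per window."""
    windows = make_windows(dataset.n_timepoints, spec)
    series = dataset.masked_series()  # (N, V, T)
    pairs = pair_order(dataset.n_subjects)
    maps = []
    for start, stop in windows:
        r = pairwise_correlations(series[:, :, start:stop])
        pcs = PairwiseCorrelationSet(r_values=r, pair_index=pairs, mask=dataset.mask)
        maps.append(mean_isc(pcs))
    return WindowedISCMaps(
        maps=maps,
        window_starts=np.array([s for s, _ in windows]),
        window_length=spec.length_samples,
        tr_seconds=dataset.tr_seconds,
    )


def pooled_window_null(
    dataset: SessionDataset,
    spec: WindowSpec,
    n_realizations: int,
    seed: int,
    batch_size: int = 4096,
) -> NullDistribution:
    """Circular-shift null pooled over voxels *and* windows.

    Each realization draws a voxel and a window uniformly, circularly shifts
    each subject's in-window segment by an independent lag in {0..W-1}, and
    evaluates the group statistic; the single pooled distribution gives one
    common threshold for every window.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    windows = make_windows(dataset.n_timepoints, spec)
    rng = np.random.default_rng(seed)
    series = dataset.masked_series()
    n_sub, n_vox, _ = series.shape
    W = spec.length_samples
    starts = np.array([s for s, _ in windows])
    samples = np.empty(n_realizations)
    pos = 0
    w_idx = np.arange(W)
    while pos < n_realizations:
        b = min(batch_size, n_realizations - pos)
        vox = rng.integers(0, n_vox, size=b)
        if len(windows) == 1:
            # reduces exactly to the basic pooled null on the windowed data
            # (no window draw, so the rng stream matches sample_null_distribution)
            win = np.zeros(b, dtype=int)
        else:
            win = rng.integers(0, len(windows), size=b)
        shifts = _random_shift_matrix(rng, b, n_sub, W)
        # gather in-window samples rotated per subject
        t = (starts[win][None, :, None] + (w_idx[None, None, :] - shifts.T[:, :, None]) % W)
        block = series[np.arange(n_sub)[:, None, None], vox[None, :, None], t]
        samples[pos : pos + b] = pairwise_correlations(block).mean(axis=1)
        pos += b
    samples = samples[np.isfinite(samples)]
    return NullDistribution(samples=samples, rng_seed=seed)


def roi_curves(maps: WindowedISCMaps, atlas: AtlasDefinition, dataset: SessionDataset) -> list[ROICurve]:
    """Per-ROI mean rbar per window (inclusion per the atlas threshold)."""
    time_axis = maps.window_centers_seconds
    curves = []
    for name in atlas.names:
        region = atlas.region_mask(name, dataset.mask)
        if not region.any():
            warnings.warn(f"ROI {name!r} is empty after thresholding", stacklevel=2)
            values = np.full(maps.n_windows, np.nan)
        else:
            values = np.array(
                [np.nanmean(m.rbar[region]) for m in maps.maps]
            )
        curves.append(ROICurve(roi_name=name, values=values, time_axis=time_axis))
    return curves


def curves_to_frame(curves: list[ROICurve]) -> pd.DataFrame:
    """Tabulate ROI curves (one column per ROI, time in seconds as index)."""
    if not curves:
        return pd.DataFrame()
    frame = pd.DataFrame(
        {c.roi_name: c.values for c in curves},
        index=pd.Index(curves[0].time_axis, name="time_s"),
    )
    return frame
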