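"""Inter-subject phase synchronization (IPS) of band-limited BOLD signals.

Where windowed ISC trades temporal resolution for a stable correlation
estimate, IPS compares subjects' instantaneous phases at every time point.
Each (demeaned, ideally band-limited) series is mapped to its analytic signal
with the Hilbert transform; the instantaneous phase is its argument.  The
pairwise dissimilarity at time t is the absolute angular distance

    p_ij(t) = |theta_i(t) - theta_j(t)| mod pi ,

averaged over all N(N-1)/2 subject pairs into p_bar(t) and normalized to

    ips(t) = 1 - p_bar(t) / pi  in [0, 1],

where 1 means complete phase agreement across subjects.  Note that the
printed ``mod pi`` distance scores an exact antiphase difference of pi as 0;
``mode="wrap"`` offers the alternative wrap to [0, pi] where antiphase is
maximally dissimilar.

The instantaneous phase of broadband BOLD is ill-defined; pass a filter-bank
spec (or pre-filtered band datasets) so IPS is computed per frequency band,
as is standard practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .core import pair_order
from .datamodel import AtlasDefinition, SessionDataset
from .frequency import FilterBankSpec, bandlimited_session
from .timewindow import ROICurve

__all__ = [
    "AnalyticPhaseSeries",
    "IPSMap",
    "analytic_phase",
    "pairwise_phase_distance",
    "ips",
    "ips_roi_curves",
]


@dataclass
class AnalyticPhaseSeries:
    """Instantaneous phases, shape (N, V, T), values in (-pi, pi]."""

    theta: np.ndarray
    edge_samples: int  # leading/trailing samples affected by Hilbert edge effects


@dataclass
class IPSMap:
    """Per-voxel, per-timepoint phase synchronization.

    ``p_bar`` is the mean absolute angular distance (X x Y x Z x T, in
    [0, pi]); ``ips`` its normalized complement 1 - p_bar/pi in [0, 1].
    The first/last ``edge_samples`` time points carry discrete-Hilbert edge
    effects and are flagged rather than removed.
    """

    p_bar: np.ndarray
    ips: np.ndarray
    edge_samples: int


def analytic_phase(series: np.ndarray) -> np.ndarray:
    """Instantaneous phase of the analytic signal, along the last axis.

    The series is demeaned internally.  An all-zero (constant) series has no
    defined phase and yields NaN.
    """
    series = np.asarray(series, dtype=float)
    T = series.shape[-1]
    if T < 4:
        raise ValueError("need T >= 4 time points")
    centered = series - series.mean(axis=-1, keepdims=True)
    theta = np.angle(hilbert(centered, axis=-1))
    dead = np.all(centered == 0, axis=-1, keepdims=True)
    if dead.any():
        warnings.warn("constant series encountered; phase set to NaN", stacklevel=2)
        theta = np.where(dead, np.nan, theta)
    return theta


def pairwise_phase_distance(
    theta_i: np.ndarray, theta_j: np.ndarray, mode: str = "printed"
) -> np.ndarray:
    """Absolute angular distance between two phase series.

    ``mode="printed"`` is |theta_i - theta_j| mod pi.  ``mode="wrap"`` wraps
    the difference to [0, pi] so that antiphase (difference pi) is maximal.
    """
    theta_i = np.asarray(theta_i, dtype=float)
    theta_j = np.asarray(theta_j, dtype=float)
    if theta_i.shape != theta_j.shape:
        raise ValueError("phase series must have equal shapes")
    d = np.abs(theta_i - theta_j)
    if mode == "printed":
        return np.mod(d, np.pi)
    if mode == "wrap":
        return np.pi - np.abs(np.mod(d, 2 * np.pi) - np.pi)
    raise ValueError(f"unknown mode {mode!r}")


def ips(
    dataset: SessionDataset,
    bank: FilterBankSpec | None = None,
    band: int | None = None,
    mode: str = "printed",
) -> IPSMap:
    """Group IPS map with per-timepoint resolution.

    When ``bank`` is given the session is band-limited first and IPS is
    computed on band ``band`` (default: the coarsest detail band); otherwise
    the demeaned raw series are used, with a warning, since broadband phase is
    hard to interpret.
    """
    if bank is not None:
        bands = bandlimited_session(dataset, bank)
        dataset = bands[1 if band is None else band]
    else:
        warnings.warn(
            "computing IPS on broadband series; band-limiting is recommended",
            stacklevel=2,
        )
    series = dataset.masked_series()  # (N, V, T)
    theta = analytic_phase(series)
    pairs = pair_order(dataset.n_subjects)
    V, T = series.shape[1], series.shape[2]
    p_sum = np.zeros((V, T))
    for i, j in pairs:
        p_sum += pairwise_phase_distance(theta[i], theta[j], mode=mode)
    p_bar = p_sum / len(pairs)
    ips_values = 1.0 - p_bar / np.pi
    edge = int(np.ceil(T / 20))
    return IPSMap(
        p_bar=dataset.embed_map(p_bar),
        ips=dataset.embed_map(ips_values),
        edge_samples=edge,
    )


def ips_roi_curves(
    ips_map: IPSMap, atlas: AtlasDefinition, dataset: SessionDataset
) -> list[ROICurve]:
    """Per-ROI mean IPS over time (per-timepoint resolution)."""
    T = ips_map.ips.shape[-1]
    time_axis = np.arange(T) * dataset.tr_seconds
    curves = []
    for name in atlas.names:
        region = atlas.region_mask(name, dataset.mask)
        if not region.any():
            warnings.warn(f"ROI {name!r} is empty after thresholding", stacklevel=2)
            values = np.full(T, np.nan)
        else:
            values = np.nanmean(ips_map.ips[region], axis=0)
        curves.append(ROICurve(roi_name=name, values=values, time_axis=time_axis))
    return curves
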