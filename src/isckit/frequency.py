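"""Octave filter bank via the stationary wavelet transform (SWT).

Band-specific ISC first splits every voxel time course into frequency
sub-bands and then runs the ordinary group ISC analysis within each band.
The filter bank is the undecimated (stationary) wavelet transform: unlike the
decimated DWT it is time-invariant, so a small hemodynamic delay between two
subjects maps to a similarly small delay in each filtered signal instead of a
large coefficient change — the property that makes between-subject
correlations of filtered signals consistent.

Daubechies filters are the default, with the QMF relationship K = 2V between
filter length and vanishing moments; the default K = 4 (V = 2) annihilates
constant and linear trends in the detail bands while staying short enough for
typical fMRI series lengths.  Boundary handling is circular (periodic), which
makes shift-invariance exact and matches the circular-shift resampling null;
series whose length is not a multiple of 2^L are periodically padded to the
next multiple and trimmed after reconstruction.

Each band is returned as a time-domain band-limited signal of length T,
obtained by inverting the transform with all other bands zeroed, so the L+1
bands sum exactly back to the input (perfect reconstruction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .datamodel import SessionDataset, SubjectTimeSeriesVolume
from .resampling import circular_shift

__all__ = [
    "FilterBankSpec",
    "SubBandSeries",
    "swt_decompose",
    "decompose_block",
    "shift_covariance_check",
    "bandlimited_session",
    "band_frequency_ranges",
]


@dataclass
class FilterBankSpec:
    """Wavelet filter-bank parameters.

    ``filter_length`` K and ``vanishing_moments`` V obey K = 2V for the
    Daubechies (QMF) families this package supports.  ``n_levels`` L yields
    L detail bands plus one approximation band (3 bands total by default).
    """

    family: str = "db"
    filter_length: int = 4
    n_levels: int = 2
    boundary_mode: str = "periodic"

    def __post_init__(self) -> None:
        if self.filter_length < 2 or self.filter_length % 2:
            raise ValueError("filter_length K must be a positive even integer")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.boundary_mode != "periodic":
            raise ValueError("only periodic (circular) boundary handling is supported")

    @property
    def vanishing_moments(self) -> int:
        return self.filter_length // 2

    @property
    def wavelet(self) -> str:
        return f"{self.family}{self.vanishing_moments}"

    @property
    def n_bands(self) -> int:
        return self.n_levels + 1


@dataclass
class SubBandSeries:
    """Time-domain band signals, coarsest first (approximation, then details
    from the deepest level up); each has the input's length T and the bands
    sum to the input."""

    bands: list[np.ndarray]
    band_labels: list[str] = field(default_factory=list)

    @property
    def n_bands(self) -> int:
        return len(self.bands)


def band_frequency_ranges(spec: FilterBankSpec, tr_seconds: float) -> list[str]:
    """Nominal octave frequency ranges per band given the sampling rate."""
    nyquist = 0.5 / tr_seconds
    L = spec.n_levels
    labels = [f"0-{nyquist / 2**L:.4g} Hz"]  # approximation band
    for level in range(L, 0, -1):  # coarsest detail first
        lo, hi = nyquist / 2**level, nyquist / 2 ** (level - 1)
        labels.append(f"{lo:.4g}-{hi:.4g} Hz")
    return labels


def _pad_periodic(x: np.ndarray, multiple: int) -> tuple[np.ndarray, int]:
    T = x.shape[-1]
    m = int(np.ceil(T / multiple)) * multiple
    if m == T:
        return x, T
    reps = int(np.ceil(m / T))
    tiled = np.concatenate([x] * reps, axis=-1)
    return tiled[..., :m], T


def decompose_block(block: np.ndarray, spec: FilterBankSpec) -> np.ndarray:
    """SWT band signals for a stack of series.

    ``block`` has shape (..., T); returns (n_bands, ..., T) with bands ordered
    coarsest first.  Vectorized over the leading axes via pywt's axis support.
    """
    block = np.asarray(block, dtype=float)
    T = block.shape[-1]
    if T < spec.filter_length:
        raise ValueError(f"series too short for K={spec.filter_length} filters")
    L = spec.n_levels
    padded, T0 = _pad_periodic(block, 2**L)
    coeffs = pywt.swt(padded, spec.wavelet, level=L, axis=-1, norm=False)
    # coeffs[k] = (cA, cD) at level L-k; iswt uses the first cA and all cDs.
    zeros = [
        (np.zeros_like(a), np.zeros_like(d)) for a, d in coeffs
    ]
    out = np.empty((L + 1,) + block.shape, dtype=float)

    def _recon(mod):
        return pywt.iswt(mod, spec.wavelet, norm=False, axis=-1)[..., :T0]

    approx = [(coeffs[0][0], zeros[0][1])] + zeros[1:]
    out[0] = _recon(approx)
    for k in range(L):  # k = 0 is the deepest (coarsest) detail level
        mod = list(zeros)
        mod[k] = (zeros[k][0], coeffs[k][1])
        out[1 + k] = _recon(mod)
    return out


def swt_decompose(
    series: np.ndarray,
    spec: FilterBankSpec,
    tr_seconds: float | None = None,
) -> SubBandSeries:
    """Decompose one series into L+1 time-domain band-limited signals."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("swt_decompose expects a single 1-D series")
    bands = decompose_block(series, spec)
    labels = (
        band_frequency_ranges(spec, tr_seconds) if tr_seconds else []
    )
    return SubBandSeries(bands=list(bands), band_labels=labels)


def shift_covariance_check(series: np.ndarray, delay: int, spec: FilterBankSpec) -> float:
    """Max band-wise discrepancy between band(shift(x)) and shift(band(x)).

    With circular boundary handling the filter bank commutes exactly with
    circular shifts (up to float rounding), so small hemodynamic delays pass
    through each band as the same small delay.  Requires T divisible by
    2^n_levels for the exact identity.
    """
    series = np.asarray(series, dtype=float)
    T = series.shape[-1]
    if not delay < T / 4:
        raise ValueError("delay must be < T/4")
    shifted_then_banded = decompose_block(circular_shift(series, delay), spec)
    banded_then_shifted = np.stack(
        [circular_shift(b, delay) for b in decompose_block(series, spec)]
    )
    return float(np.max(np.abs(shifted_then_banded - banded_then_shifted)))


def bandlimited_session(
    dataset: SessionDataset, spec: FilterBankSpec
) -> list[SessionDataset]:
    """Split a session into per-band sessions, coarsest band first.

    Each returned dataset has the original dims, mask and TR and can be fed
    unchanged into the ISC, resampling, difference, window and phase modules;
    summing the band datasets voxelwise recovers the original data.
    """
    n_bands = spec.n_bands
    band_subjects: list[list[SubjectTimeSeriesVolume]] = [[] for _ in range(n_bands)]
    for subj in dataset.subjects:
        bands = decompose_block(subj.data, spec)  # (n_bands, X, Y, Z, T)
        for k in range(n_bands):
            band_subjects[k].append(
                SubjectTimeSeriesVolume(
                    data=bands[k],
                    affine=subj.affine,
                    tr_seconds=subj.tr_seconds,
                    subject_id=subj.subject_id,
                )
            )
    return [
        SessionDataset(
            subjects=band_subjects[k],
            mask=dataset.mask,
            condition_label=f"{dataset.condition_label}:band{k}",
        )
        for k in range(n_bands)
    ]
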