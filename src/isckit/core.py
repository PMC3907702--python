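"""Group inter-subject correlation (ISC) statistics.

The group statistic at a voxel is the mean Pearson correlation over all
N(N-1)/2 unordered subject pairs,

    rbar = (1 / (N(N-1)/2)) * sum_{i<j} r_ij ,

an estimator of the (unknown) population ISC rho under the model
rho_ij = rho + eps_ij.  A simple parametric alternative Fisher-z-transforms
the pair correlations and runs a one-sample t-test with N(N-1)/2 - 1 degrees
of freedom; its independence assumption is violated in practice (subjects
appear in multiple pairs), which is why inference normally goes through the
nonparametric circular-shift test in :mod:`isckit.resampling` instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import BrainMask, SessionDataset, iter_voxel_blocks

__all__ = [
    "PairwiseCorrelationSet",
    "ISCMap",
    "ParametricTestResult",
    "pair_order",
    "pairwise_correlations",
    "mean_isc",
    "fisher_z",
    "inverse_fisher_z",
    "parametric_t_test",
    "session_pairwise_correlations",
    "isc_map",
]


def pair_order(n_subjects: int) -> list[tuple[int, int]]:
    """Unordered subject pairs (i, j), i < j, in lexicographic order."""
    return [(i, j) for i in range(n_subjects) for j in range(i + 1, n_subjects)]


@dataclass
class PairwiseCorrelationSet:
    """Per-voxel Pearson correlations over all subject pairs.

    ``r_values`` is V x P (V masked voxels, P = N(N-1)/2 pairs ordered
    lexicographically).  Zero-variance time courses produce NaN entries for
    their pairs; they are flagged, not raised, and excluded from inference.
    """

    r_values: np.ndarray
    pair_index: list[tuple[int, int]]
    mask: BrainMask | None = None

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=float)
        if self.r_values.ndim != 2:
            raise ValueError("r_values must be V x P")
        if self.r_values.shape[1] != len(self.pair_index):
            raise ValueError("pair count mismatch")
        finite = self.r_values[np.isfinite(self.r_values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlations outside [-1, 1]")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_index)

    @property
    def n_subjects(self) -> int:
        # P = N(N-1)/2  =>  N = (1 + sqrt(1+8P)) / 2
        return int(round((1 + np.sqrt(1 + 8 * self.n_pairs)) / 2))


@dataclass
class ISCMap:
    """Mean pairwise correlation per voxel (NaN outside the mask)."""

    rbar: np.ndarray
    n_subjects: int

    def masked_values(self, mask: BrainMask) -> np.ndarray:
        return self.rbar[mask.mask]


@dataclass
class ParametricTestResult:
    t_map: np.ndarray
    p_map: np.ndarray
    dof: int


def _standardize(block: np.ndarray) -> np.ndarray:
    """Demean and unit-norm time courses; zero-variance rows become NaN."""
    block = np.asarray(block, dtype=float)
    centered = block - block.mean(axis=-1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = centered / norm
    out[np.broadcast_to(norm == 0, out.shape)] = np.nan
    return out


def pairwise_correlations(block: np.ndarray) -> np.ndarray:
    """Pearson r for every subject pair of an (N, V, T) or (N, T) block.

    Returns a V x P (or length-P) array with pairs in lexicographic order.
    """
    block = np.asarray(block, dtype=float)
    squeeze = block.ndim == 2
    if squeeze:
        block = block[:, None, :]
    n = block.shape[0]
    if block.shape[-1] < 2:
        raise ValueError("need T >= 2 time points")
    z = _standardize(block)  # (N, V, T)
    pairs = pair_order(n)
    ii = np.array([i for i, _ in pairs])
    jj = np.array([j for _, j in pairs])
    r = np.einsum("pvt,pvt->vp", z[ii], z[jj])
    np.clip(r, -1.0, 1.0, out=r, where=np.isfinite(r))
    return r[0] if squeeze else r


def mean_isc(pcs: PairwiseCorrelationSet) -> ISCMap:
    """Average raw pair correlations (no z-averaging) into the group map.

    NaN pairs (zero-variance voxels) propagate NaN for that voxel.
    """
    if pcs.n_pairs < 1:
        raise ValueError("empty pair set")
    values = pcs.r_values.mean(axis=1)
    if pcs.mask is not None:
        rbar = np.full(pcs.mask.shape, np.nan)
        rbar[pcs.mask.mask] = values
    else:
        rbar = values
    return ISCMap(rbar=rbar, n_subjects=pcs.n_subjects)


def fisher_z(r):
    """Fisher's variance-stabilizing transform z = 0.5 log((1+r)/(1-r))."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r[np.isfinite(r)]) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher z transform")
    return np.arctanh(r)


def inverse_fisher_z(z):
    return np.tanh(np.asarray(z, dtype=float))


def parametric_t_test(pcs: PairwiseCorrelationSet) -> ParametricTestResult:
    """One-sample t-test of the Fisher-z pair values against zero.

    Degrees of freedom are N(N-1)/2 - 1; two-sided p-values.  The pair values
    are not independent, so this test is anti-conservative and is provided for
    parity with common practice, not as the primary inference.
    """
    if pcs.n_pairs < 2:
        raise ValueError("need at least two pairs for the t-test")
    z = fisher_z(pcs.r_values)
    dof = pcs.n_pairs - 1
    mean = z.mean(axis=1)
    sd = z.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(pcs.n_pairs))
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    p = 2 * stats.t.sf(np.abs(t), dof)
    if pcs.mask is not None:
        t_map = np.full(pcs.mask.shape, np.nan)
        p_map = np.full(pcs.mask.shape, np.nan)
        t_map[pcs.mask.mask] = t
        p_map[pcs.mask.mask] = p
    else:
        t_map, p_map = t, p
    return ParametricTestResult(t_map=t_map, p_map=p_map, dof=dof)


def session_pairwise_correlations(
    dataset: SessionDataset, block_size: int = 4096
) -> PairwiseCorrelationSet:
    """Pairwise correlations for every masked voxel, computed in blocks."""
    pairs = pair_order(dataset.n_subjects)
    r = np.empty((dataset.mask.n_voxels, len(pairs)))
    pos = 0
    for _, block in iter_voxel_blocks(dataset, block_size):
        r[pos : pos + block.shape[1]] = pairwise_correlations(block)
        pos += block.shape[1]
    return PairwiseCorrelationSet(r_values=r, pair_index=pairs, mask=dataset.mask)


def isc_map(dataset: SessionDataset, block_size: int = 4096) -> ISCMap:
    """Full-session group ISC map (mean pairwise r per masked voxel)."""
    return mean_isc(session_pairwise_correlations(dataset, block_size))
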