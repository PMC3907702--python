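"""Paired-condition ISC difference testing with the group sum-ZPF statistic.

For the same subjects scanned under two conditions a and b, the per-pair
statistic compares the two nonoverlapping but dependent correlations r_ij^a
and r_ij^b through their Fisher z transforms (ZPF, the z-based modified
Pearson-Filon statistic):

    ZPF_ij = (z_ij^a - z_ij^b) * sqrt((T-3)/2)
             / sqrt(1 - cov(r_ij^a, r_ij^b) / [(1-(r_ij^a)^2)(1-(r_ij^b)^2)])

where cov(., .) is the large-sample (T-scaled) Pearson-Filon covariance of
the two correlations, estimated by plugging the six pairwise sample
correlations among the four series into the asymptotic expression.  The
group statistic sums ZPF_ij over all N(N-1)/2 subject pairs per voxel.

Significance is assessed nonparametrically: pair-level signs are flipped at
random (one sign per pair, applied identically across voxels, preserving
spatial dependence), the voxelwise sum is recomputed, and image-wide maxima
and minima are recorded per relabeling.  Their empirical quantiles give
FWER-controlling thresholds for both directions (max/min-statistic logic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import fisher_z, pair_order, _standardize
from .datamodel import SessionDataset

__all__ = [
    "PairedConditionData",
    "ZPFStatistics",
    "PermutationExtrema",
    "estimate_pair_covariance",
    "zpf_term",
    "sum_zpf",
    "signflip_null",
    "fwer_thresholds",
    "threshold_difference_map",
]

DEFAULT_N_PERMUTATIONS = 25_000


@dataclass
class PairedConditionData:
    """Two sessions of the same subjects, in the same order, on one grid."""

    session_a: SessionDataset
    session_b: SessionDataset

    def __post_init__(self) -> None:
        a, b = self.session_a, self.session_b
        if a.n_subjects != b.n_subjects:
            raise ValueError("conditions must contain the same subjects")
        for sa, sb in zip(a.subjects, b.subjects):
            if sa.subject_id != sb.subject_id:
                raise ValueError(
                    "subject order must match across conditions "
                    f"({sa.subject_id!r} vs {sb.subject_id!r})"
                )
        if a.spatial_shape != b.spatial_shape:
            raise ValueError("conditions must share the spatial grid")
        if not np.array_equal(a.mask.mask, b.mask.mask):
            raise ValueError("conditions must share the brain mask")
        if a.n_timepoints != b.n_timepoints:
            raise ValueError("conditions must have equal series length T")

    @property
    def n_timepoints(self) -> int:
        return self.session_a.n_timepoints


@dataclass
class ZPFStatistics:
    """Per-pair ZPF terms and their voxelwise sum."""

    pair_zpf: np.ndarray  # V x P
    sum_map: np.ndarray  # 3-D, NaN outside mask
    cov_ab: np.ndarray  # V x P estimated large-sample covariances
    T: int
    pair_index: list[tuple[int, int]]
    n_excluded: int = 0  # pair terms dropped for a non-positive radicand


@dataclass
class PermutationExtrema:
    max_stats: np.ndarray
    min_stats: np.ndarray
    seed: int

    @property
    def n_perm(self) -> int:
        return self.max_stats.size


def _pearson_filon_k(r12, r34, r13, r14, r23, r24):
    """Large-sample (T-scaled) covariance of two nonoverlapping correlations.

    Asymptotic Pearson-Filon expression for cov(r12, r34) * T in terms of the
    six pairwise correlations of the underlying variables; here 1,2 are the
    two subjects in condition a and 3,4 the same subjects in condition b.
    """
    return 0.5 * (
        (r13 - r14 * r34) * (r24 - r14 * r12)
        + (r14 - r13 * r34) * (r23 - r13 * r12)
        + (r13 - r23 * r12) * (r24 - r34 * r23)
        + (r14 - r24 * r12) * (r23 - r34 * r24)
    )


def estimate_pair_covariance(
    series_i_a: np.ndarray,
    series_j_a: np.ndarray,
    series_i_b: np.ndarray,
    series_j_b: np.ndarray,
) -> float:
    """Plug-in large-sample covariance of (r_ij^a, r_ij^b) from four series.

    The six sample correlations among the four observed series are inserted
    into the asymptotic Pearson-Filon covariance.  When condition b is a copy
    of condition a this reduces to (1 - r^2)^2, the large-sample variance of a
    correlation with itself (on the same T-scaled convention).
    """
    stack = np.stack(
        [np.asarray(x, dtype=float) for x in (series_i_a, series_j_a, series_i_b, series_j_b)]
    )
    if stack.shape[-1] < 4:
        raise ValueError("need T >= 4 time points")
    z = _standardize(stack)
    if not np.isfinite(z).all():
        raise ValueError("zero-variance series")
    c = z @ z.T
    return float(
        _pearson_filon_k(c[0, 1], c[2, 3], c[0, 2], c[0, 3], c[1, 2], c[1, 3])
    )


def zpf_term(r_a, r_b, cov, T: int):
    """The per-pair ZPF summand for given correlations and covariance.

    (z_a - z_b) sqrt((T-3)/2) / sqrt(1 - cov/[(1-r_a^2)(1-r_b^2)]).
    """
    num = (fisher_z(r_a) - fisher_z(r_b)) * np.sqrt((T - 3) / 2.0)
    radicand = 1.0 - cov / ((1.0 - np.asarray(r_a, dtype=float) ** 2) * (1.0 - np.asarray(r_b, dtype=float) ** 2))
    return num / np.sqrt(radicand)


def sum_zpf(paired: PairedConditionData) -> ZPFStatistics:
    """Per-pair ZPF terms and their voxelwise sum over all subject pairs.

    Pairs whose radicand 1 - cov/[(1-r_a^2)(1-r_b^2)] is non-positive due to
    estimation noise are set to NaN and excluded from the sum (their count is
    reported); a pair with an exactly zero z-difference contributes exactly 0,
    covering the identical-conditions limit where the radicand also vanishes.
    """
    a, b = paired.session_a, paired.session_b
    T = paired.n_timepoints
    n = a.n_subjects
    pairs = pair_order(n)
    ii = np.array([i for i, _ in pairs])
    jj = np.array([j for _, j in pairs])

    za = _standardize(a.masked_series())  # (N, V, T)
    zb = _standardize(b.masked_series())

    def corr(x, y):
        r = np.einsum("pvt,pvt->vp", x, y)
        return np.clip(r, -1.0, 1.0)

    r_a = corr(za[ii], za[jj])  # r12
    r_b = corr(zb[ii], zb[jj])  # r34
    r13 = corr(za[ii], zb[ii])
    r14 = corr(za[ii], zb[jj])
    r23 = corr(za[jj], zb[ii])
    r24 = corr(za[jj], zb[jj])

    cov = _pearson_filon_k(r_a, r_b, r13, r14, r23, r24)

    with np.errstate(invalid="ignore", divide="ignore"):
        degenerate = (np.abs(r_a) >= 1) | (np.abs(r_b) >= 1)
        num = (np.arctanh(np.where(degenerate, 0.0, r_a))
               - np.arctanh(np.where(degenerate, 0.0, r_b))) * np.sqrt((T - 3) / 2.0)
        radicand = 1.0 - cov / ((1.0 - r_a**2) * (1.0 - r_b**2))
        term = num / np.sqrt(radicand)
    zero_limit = (num == 0.0) & ~degenerate  # 0/0 limit of identical conditions
    term = np.where(zero_limit, 0.0, term)
    bad = degenerate | (~zero_limit & ((radicand <= 0) | ~np.isfinite(term)))
    term[bad] = np.nan
    n_excluded = int(bad.sum())

    sums = np.nansum(term, axis=1)
    sums[np.all(np.isnan(term), axis=1)] = np.nan
    sum_map = np.full(a.mask.shape, np.nan)
    sum_map[a.mask.mask] = sums
    return ZPFStatistics(
        pair_zpf=term,
        sum_map=sum_map,
        cov_ab=cov,
        T=T,
        pair_index=pairs,
        n_excluded=n_excluded,
    )


def signflip_null(
    stats: ZPFStatistics,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    batch_size: int = 512,
) -> PermutationExtrema:
    """Image-wide max/min of the sign-flipped voxelwise sum per relabeling.

    One sign per subject pair, shared across voxels (a pair-level relabeling),
    sampled with replacement from the 2^P possible labelings.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    terms = np.nan_to_num(stats.pair_zpf, nan=0.0)  # excluded pairs contribute 0
    max_stats = np.empty(n_perm)
    min_stats = np.empty(n_perm)
    pos = 0
    while pos < n_perm:
        b = min(batch_size, n_perm - pos)
        flips = rng.integers(0, 2, size=(b, terms.shape[1])) * 2 - 1
        sums = terms @ flips.T  # (V, b)
        max_stats[pos : pos + b] = sums.max(axis=0)
        min_stats[pos : pos + b] = sums.min(axis=0)
        pos += b
    return PermutationExtrema(max_stats=max_stats, min_stats=min_stats, seed=seed)


def fwer_thresholds(extrema: PermutationExtrema, alpha: float, two_sided: bool = False):
    """FWER-controlling thresholds from the permutation extrema.

    ``upper`` is the (1-alpha) quantile of the image-wide maxima and ``lower``
    the alpha quantile of the minima: one threshold per direction at the
    user's alpha each by default, or alpha/2 per tail when ``two_sided``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    a = alpha / 2 if two_sided else alpha
    upper = float(np.quantile(extrema.max_stats, 1 - a))
    lower = float(np.quantile(extrema.min_stats, a))
    return upper, lower


def threshold_difference_map(stats: ZPFStatistics, upper: float, lower: float):
    """Boolean maps of voxels significant in each direction."""
    with np.errstate(invalid="ignore"):
        pos = stats.sum_map > upper
        neg = stats.sum_map < lower
    return pos, neg
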