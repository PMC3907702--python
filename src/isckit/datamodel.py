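"""Data containers and NIfTI I/O for multi-subject 4-D fMRI analysis.

All analyses in this package operate on a :class:`SessionDataset`: an ordered
collection of spatially registered per-subject 4-D BOLD volumes sharing one
grid, one repetition time and one brain mask.  Spatial semantics are carried
solely by the NIfTI affine; arrays are indexed 0-based and never reoriented —
inputs are assumed to be preprocessed and registered upstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "SubjectTimeSeriesVolume",
    "BrainMask",
    "SessionDataset",
    "AtlasDefinition",
    "DimensionalityError",
    "GridMismatchError",
    "HeaderError",
    "read_volume",
    "read_mask",
    "read_atlas",
    "assemble_session",
    "iter_voxel_blocks",
    "write_volume",
    "write_statmap",
    "write_series_map",
    "write_threshold_sidecar",
]


class DimensionalityError(ValueError):
    """Image does not have the dimensionality the operation requires."""


class GridMismatchError(ValueError):
    """Arrays that must share a spatial grid do not."""


class HeaderError(ValueError):
    """NIfTI header is unreadable or inconsistent."""


@dataclass
class SubjectTimeSeriesVolume:
    """One subject's preprocessed 4-D BOLD series (X x Y x Z x T)."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    subject_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DimensionalityError(
                f"subject {self.subject_id!r}: expected a 4-D array, got "
                f"{self.data.ndim}-D"
            )
        if self.data.shape[3] < 2:
            raise ValueError(f"subject {self.subject_id!r}: need T >= 2 time points")
        if min(self.data.shape[:3]) < 1:
            raise ValueError("all spatial dimensions must be >= 1")
        if np.isinf(self.data).any():
            raise ValueError(f"subject {self.subject_id!r}: data contains +/-inf")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be > 0")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """Boolean 3-D mask restricting computation to in-brain voxels."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise DimensionalityError("mask must be 3-D")
        if self.n_voxels < 1:
            raise ValueError("mask selects no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def voxel_indices(self) -> np.ndarray:
        """Flat indices of masked voxels in C order (the canonical voxel order)."""
        return np.flatnonzero(self.mask.reshape(-1))


@dataclass
class SessionDataset:
    """Aligned multi-subject data for one condition.

    Subject order is fixed at assembly and defines the pair indexing
    (lexicographic in (i, j), i < j) used by every pairwise statistic.
    """

    subjects: list[SubjectTimeSeriesVolume]
    mask: BrainMask
    condition_label: str = ""

    def __post_init__(self) -> None:
        if len(self.subjects) < 2:
            raise ValueError("a session needs at least two subjects")
        ref = self.subjects[0]
        for s in self.subjects[1:]:
            if s.data.shape != ref.data.shape:
                raise GridMismatchError(
                    f"subject {s.subject_id!r} has shape {s.data.shape}, "
                    f"expected {ref.data.shape}"
                )
            if s.tr_seconds != ref.tr_seconds:
                raise ValueError("all subjects must share the same TR")
        if self.mask.shape != ref.spatial_shape:
            raise GridMismatchError(
                f"mask shape {self.mask.shape} != volume spatial shape "
                f"{ref.spatial_shape}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_timepoints(self) -> int:
        return self.subjects[0].n_timepoints

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.subjects[0].spatial_shape

    @property
    def tr_seconds(self) -> float:
        return self.subjects[0].tr_seconds

    @property
    def reference(self) -> SubjectTimeSeriesVolume:
        return self.subjects[0]

    def masked_series(self, flat_indices: np.ndarray | None = None) -> np.ndarray:
        """Return an (N, V, T) array of the masked voxel time courses.

        ``flat_indices`` selects a subset (flat C-order indices); default is
        every masked voxel in canonical order.
        """
        if flat_indices is None:
            flat_indices = self.mask.voxel_indices()
        out = np.empty(
            (self.n_subjects, len(flat_indices), self.n_timepoints), dtype=float
        )
        for k, subj in enumerate(self.subjects):
            flat = subj.data.reshape(-1, self.n_timepoints)
            out[k] = flat[flat_indices]
        return out

    def embed_map(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter per-masked-voxel values back into a 3-D (or 3-D+k) volume."""
        values = np.asarray(values, dtype=float)
        extra = values.shape[1:]
        out = np.full(self.spatial_shape + extra, fill, dtype=float)
        out[self.mask.mask] = values
        return out


@dataclass
class AtlasDefinition:
    """Named regions, each a probability map in [0, 1] on the mask grid.

    A voxel belongs to a region when its probability is at least
    ``inclusion_threshold`` (0.25 by default, the common practice for the
    Harvard-Oxford probabilistic atlases).  Hard label atlases are represented
    with indicator (0/1) maps.
    """

    regions: list[tuple[str, np.ndarray]]
    inclusion_threshold: float = 0.25

    def __post_init__(self) -> None:
        names = [n for n, _ in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        if not 0.0 <= self.inclusion_threshold <= 1.0:
            raise ValueError("inclusion_threshold must lie in [0, 1]")
        for name, pm in self.regions:
            pm = np.asarray(pm)
            if pm.ndim != 3:
                raise DimensionalityError(f"region {name!r}: prob map must be 3-D")
            if pm.min() < 0 or pm.max() > 1:
                raise ValueError(f"region {name!r}: probabilities outside [0, 1]")

    def region_mask(self, name: str, brain: BrainMask) -> np.ndarray:
        """Boolean 3-D membership of ``name`` restricted to the brain mask."""
        for rname, pm in self.regions:
            if rname == name:
                if pm.shape != brain.shape:
                    raise GridMismatchError("atlas grid does not match mask grid")
                return (np.asarray(pm) >= self.inclusion_threshold) & brain.mask
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.regions]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike, subject_id: str | None = None) -> SubjectTimeSeriesVolume:
    """Read a 4-D NIfTI into a :class:`SubjectTimeSeriesVolume`.

    Dimensions and TR come from the header; voxel values are untouched.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        shape = img.shape
        zooms = img.header.get_zooms()
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable / corrupt header
        raise HeaderError(f"cannot parse NIfTI header of {path}: {exc}") from exc
    if len(shape) != 4:
        raise DimensionalityError(
            f"{path}: expected a 4-D image, header reports {len(shape)}-D"
        )
    tr = float(zooms[3]) if len(zooms) >= 4 and zooms[3] > 0 else 1.0
    data = np.asanyarray(img.dataobj)
    sid = subject_id if subject_id is not None else os.path.basename(str(path))
    return SubjectTimeSeriesVolume(
        data=data, affine=img.affine, tr_seconds=tr, subject_id=sid
    )


def read_mask(path: str | os.PathLike) -> BrainMask:
    """Read a 3-D NIfTI mask; any nonzero voxel is in-mask."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise DimensionalityError(f"{path}: mask must be 3-D")
    return BrainMask(mask=np.asanyarray(img.dataobj) != 0)


def read_atlas(
    path: str | os.PathLike,
    names: list[str] | None = None,
    inclusion_threshold: float = 0.25,
) -> AtlasDefinition:
    """Read an atlas NIfTI.

    A 4-D image is treated as stacked probability maps (values in [0, 1]);
    a 3-D integer image as hard labels, one region per nonzero label id.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    regions: list[tuple[str, np.ndarray]] = []
    if data.ndim == 4:
        for k in range(data.shape[3]):
            name = names[k] if names else f"region_{k}"
            regions.append((name, data[..., k].astype(float)))
    elif data.ndim == 3:
        labels = np.unique(data)
        labels = labels[labels != 0]
        for k, lab in enumerate(labels):
            name = names[k] if names else f"label_{int(lab)}"
            regions.append((name, (data == lab).astype(float)))
    else:
        raise DimensionalityError("atlas must be 3-D labels or 4-D probability maps")
    return AtlasDefinition(regions=regions, inclusion_threshold=inclusion_threshold)


def assemble_session(
    volumes: list[SubjectTimeSeriesVolume],
    mask: BrainMask,
    label: str = "",
) -> SessionDataset:
    """Validate and bundle per-subject volumes into a :class:`SessionDataset`."""
    return SessionDataset(subjects=list(volumes), mask=mask, condition_label=label)


def iter_voxel_blocks(dataset: SessionDataset, block_size: int):
    """Yield ``(flat_voxel_indices, (N, B, T) series block)`` over masked voxels.

    Blocks partition the masked voxels exactly; the order is the canonical
    C order of the mask and is identical on every iteration, so chunked and
    unchunked computations agree.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    idx = dataset.mask.voxel_indices()
    for start in range(0, len(idx), block_size):
        sel = idx[start : start + block_size]
        yield sel, dataset.masked_series(sel)


def write_volume(volume: SubjectTimeSeriesVolume, path: str | os.PathLike) -> None:
    """Write a 4-D series volume, preserving dtype and TR in the header."""
    img = nib.Nifti1Image(volume.data, volume.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (volume.tr_seconds,))
    nib.save(img, str(path))


def write_statmap(
    map3d: np.ndarray,
    reference: SubjectTimeSeriesVolume,
    path: str | os.PathLike,
) -> None:
    """Write a 3-D statistical map as float32 NIfTI with the reference affine."""
    map3d = np.asarray(map3d)
    if map3d.shape != reference.spatial_shape:
        raise GridMismatchError(
            f"map shape {map3d.shape} != reference spatial shape "
            f"{reference.spatial_shape}"
        )
    img = nib.Nifti1Image(map3d.astype(np.float32), reference.affine)
    nib.save(img, str(path))


def write_series_map(
    map4d: np.ndarray,
    reference: SubjectTimeSeriesVolume,
    path: str | os.PathLike,
) -> None:
    """Write an X x Y x Z x K map stack (windows or time points) as float32."""
    map4d = np.asarray(map4d)
    if map4d.ndim != 4 or map4d.shape[:3] != reference.spatial_shape:
        raise GridMismatchError("map stack does not match the reference grid")
    nib.save(nib.Nifti1Image(map4d.astype(np.float32), reference.affine), str(path))


def write_threshold_sidecar(path: str | os.PathLike, thresholds: dict) -> None:
    """Write critical thresholds as a plain-text ``key<TAB>value`` sidecar."""
    with open(path, "w") as fh:
        for key, value in thresholds.items():
            fh.write(f"{key}\t{value!r}\n")
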