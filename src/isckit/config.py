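"""Analysis configuration: the single document that drives a pipeline run.

The configuration maps 1:1 to a YAML file and collects everything the
pipeline needs: input paths per session, the mask, optional atlas, which
analyses to run, and the statistical parameters.  Validation is exhaustive
(a full error list, not fail-fast) so a user can fix a config in one pass.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import nibabel as nib
import yaml

from .frequency import FilterBankSpec
from .timewindow import WindowSpec

__all__ = ["SessionSpec", "AnalysisToggles", "AnalysisConfig", "load_config", "validate_config"]


@dataclass
class SessionSpec:
    label: str
    subject_paths: list[str]


@dataclass
class AnalysisToggles:
    basic: bool = True
    difference: bool = False
    frequency: bool = False
    timewindow: bool = False
    ips: bool = False


@dataclass
class AnalysisConfig:
    project_name: str
    output_dir: str
    sessions: list[SessionSpec]
    mask_path: str
    atlas_path: str | None = None
    analyses: AnalysisToggles = field(default_factory=AnalysisToggles)
    window_length: int = 30
    window_step: int = 30
    filter_length: int = 4
    n_levels: int = 2
    n_realizations: int = 1_000_000
    n_permutations: int = 25_000
    q_levels: list[float] = field(default_factory=lambda: [0.05])
    alpha: float = 0.05
    seed: int = 0
    n_workers: int = 1

    @property
    def window(self) -> WindowSpec:
        return WindowSpec(length_samples=self.window_length, step_samples=self.window_step)

    @property
    def bank(self) -> FilterBankSpec:
        return FilterBankSpec(filter_length=self.filter_length, n_levels=self.n_levels)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | os.PathLike) -> AnalysisConfig:
    """Parse a YAML config document into an :class:`AnalysisConfig`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    sessions = [
        SessionSpec(label=s["label"], subject_paths=list(s["subjects"]))
        for s in doc.get("sessions", [])
    ]
    toggles = AnalysisToggles(**doc.get("analyses", {}))
    known = {
        k: doc[k]
        for k in (
            "project_name output_dir mask_path atlas_path window_length "
            "window_step filter_length n_levels n_realizations n_permutations "
            "q_levels alpha seed n_workers"
        ).split()
        if k in doc
    }
    return AnalysisConfig(sessions=sessions, analyses=toggles, **known)


def _peek_T(path: str) -> int | None:
    try:
        shape = nib.load(path).shape
    except Exception:
        return None
    return shape[3] if len(shape) == 4 else None


def validate_config(cfg: AnalysisConfig) -> list[str]:
    """Check every invariant; return the full list of violations (empty = ok)."""
    errors: list[str] = []
    if not cfg.sessions:
        errors.append("sessions: at least one session is required")
    for k, sess in enumerate(cfg.sessions):
        if len(sess.subject_paths) < 2:
            errors.append(f"sessions[{k}].subjects: at least two subjects are required")
        for p in sess.subject_paths:
            if not os.path.exists(p):
                errors.append(f"sessions[{k}].subjects: missing file {p}")
    if cfg.analyses.difference and len(cfg.sessions) < 2:
        errors.append("analyses.difference: ISC difference maps need at least two sessions")
    if not os.path.exists(cfg.mask_path):
        errors.append(f"mask_path: missing file {cfg.mask_path}")
    if cfg.atlas_path is not None and not os.path.exists(cfg.atlas_path):
        errors.append(f"atlas_path: missing file {cfg.atlas_path}")
    if cfg.analyses.timewindow:
        if cfg.window_length < 2:
            errors.append("window_length: must be >= 2")
        if cfg.window_step < 1:
            errors.append("window_step: must be >= 1")
        first = next(
            (p for s in cfg.sessions for p in s.subject_paths if os.path.exists(p)), None
        )
        if first is not None:
            T = _peek_T(first)
            if T is not None and cfg.window_length > T:
                errors.append(
                    f"window_length: {cfg.window_length} exceeds series length {T}"
                )
    if cfg.filter_length < 2 or cfg.filter_length % 2:
        errors.append("filter_length: must be a positive even integer")
    if cfg.n_levels < 1:
        errors.append("n_levels: must be >= 1")
    if cfg.n_realizations < 1:
        errors.append("n_realizations: must be >= 1")
    if cfg.n_permutations < 1:
        errors.append("n_permutations: must be >= 1")
    for q in cfg.q_levels:
        if not 0 < q < 1:
            errors.append(f"q_levels: {q} outside (0, 1)")
    if not 0 < cfg.alpha < 1:
        errors.append("alpha: must lie in (0, 1)")
    if cfg.n_workers < 1:
        errors.append("n_workers: must be >= 1")
    return errors
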