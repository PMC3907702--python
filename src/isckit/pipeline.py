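"""Pipeline orchestration: stages 1-6 of a configured ISC analysis.

The run decomposes into the dependency stages of the original analysis
design: (1) output allocation, (2) wavelet band filtering, (3) ISC maps and
resampling null distributions, (4) multiple-comparison-corrected thresholds
(FDR for ISC maps, sign-flip FWER for difference maps), (5) ROI curves and
phase-synchronization maps, (6) NIfTI export with plain-text threshold
sidecars and a machine-readable manifest.  Stages execute strictly in order —
each consumes only artifacts its predecessors emitted — and only the stages
an enabled analysis needs are run.  Work inside a stage is split into
independent, individually seeded items executed through
:func:`isckit.parallel.parallel_map`, so outputs are bit-identical for any
worker count.
"""

from __future__ import annotations

import json
import os

import numpy as np

from . import core, datamodel, difference, frequency, phase, resampling, timewindow
from .config import AnalysisConfig, validate_config
from .parallel import chunk_sizes, derive_seeds, parallel_map
from .resampling import NullDistribution, _null_samples_from_series

__all__ = ["run_pipeline", "prune", "extract_curves", "StageFailure"]

NULL_CHUNK = 25_000


class StageFailure(RuntimeError):
    """A pipeline stage failed; earlier stages' artifacts remain on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _sample_null_parallel(
    dataset, n_realizations: int, seed: int, n_workers: int
) -> NullDistribution:
    """Pooled circular-shift null built from independently seeded chunks.

    The chunk decomposition and per-chunk seeds depend only on
    (n_realizations, seed), never on n_workers, and chunks are gathered in
    order, so the pooled distribution is identical for any worker count.
    """
    sizes = chunk_sizes(n_realizations, NULL_CHUNK)
    seeds = derive_seeds(seed, len(sizes))
    series = dataset.masked_series()

    def work(args):
        size, chunk_seed = args
        return _null_samples_from_series(
            series, size, np.random.default_rng(chunk_seed)
        )

    parts = parallel_map(work, list(zip(sizes, seeds)), n_workers)
    samples = np.concatenate(parts)
    return NullDistribution(samples=samples[np.isfinite(samples)], rng_seed=seed)


def _load_sessions(cfg: AnalysisConfig):
    mask = datamodel.read_mask(cfg.mask_path)
    sessions = []
    for sess in cfg.sessions:
        # subject identity is positional across sessions: the k-th path of
        # every session must belong to the same subject
        vols = [
            datamodel.read_volume(p, subject_id=f"sub-{k:02d}")
            for k, p in enumerate(sess.subject_paths)
        ]
        sessions.append(datamodel.assemble_session(vols, mask, sess.label))
    return sessions


class _Manifest:
    def __init__(self, cfg: AnalysisConfig):
        self.doc = {
            "project": cfg.project_name,
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "stages_completed": [],
            "artifacts": [],
        }
        self.path = os.path.join(cfg.output_dir, "manifest.json")

    def add(self, name: str, path: str, kind: str, intermediate: bool = False, **params):
        self.doc["artifacts"].append(
            {
                "name": name,
                "path": path,
                "kind": kind,
                "intermediate": intermediate,
                "params": params,
            }
        )

    def complete(self, stage: str):
        self.doc["stages_completed"].append(stage)
        self.write()

    def write(self):
        with open(self.path, "w") as fh:
            json.dump(self.doc, fh, indent=2, default=str)


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Execute the configured analyses; return the artifact manifest."""
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))

    os.makedirs(cfg.output_dir, exist_ok=True)
    manifest = _Manifest(cfg)
    state: dict = {}

    stages = [
        ("stage1_allocate", _stage_allocate),
        ("stage2_filter", _stage_filter),
        ("stage3_isc", _stage_isc),
        ("stage4_thresholds", _stage_thresholds),
        ("stage5_curves", _stage_curves),
        ("stage6_export", _stage_export),
    ]
    for name, fn in stages:
        try:
            fn(cfg, state, manifest)
        except Exception as exc:
            manifest.write()  # checkpoint: completed stages + their artifacts
            raise StageFailure(name, exc) from exc
        manifest.complete(name)
    return manifest.doc


def _stage_allocate(cfg, state, manifest):
    for sub in ("isc", "difference", "timewindow", "ips", "bands", "nulls"):
        os.makedirs(os.path.join(cfg.output_dir, sub), exist_ok=True)
    state["sessions"] = _load_sessions(cfg)
    state["atlas"] = (
        datamodel.read_atlas(cfg.atlas_path) if cfg.atlas_path else None
    )


def _stage_filter(cfg, state, manifest):
    """Wavelet band filtering; skipped unless frequency analysis is enabled."""
    if not cfg.analyses.frequency:
        return
    bank = cfg.bank
    state["band_sessions"] = {}
    for sess in state["sessions"]:
        bands = frequency.bandlimited_session(sess, bank)
        state["band_sessions"][sess.condition_label] = bands
        for k, bsess in enumerate(bands):
            for subj in bsess.subjects:
                path = os.path.join(
                    cfg.output_dir,
                    "bands",
                    f"{sess.condition_label}_{subj.subject_id}_band{k}.nii.gz",
                )
                datamodel.write_volume(subj, path)
                manifest.add(
                    f"band series {sess.condition_label}/{subj.subject_id}/band{k}",
                    path,
                    "band_series",
                    intermediate=True,
                    band=k,
                    band_range=frequency.band_frequency_ranges(bank, sess.tr_seconds)[k],
                )


def _analysis_units(cfg, state):
    """(label, dataset) pairs needing a basic ISC map + null: each session,
    broadband and per band when frequency analysis is on."""
    units = []
    for sess in state["sessions"]:
        if cfg.analyses.basic:
            units.append((sess.condition_label, sess))
        if cfg.analyses.frequency:
            for k, bsess in enumerate(state["band_sessions"][sess.condition_label]):
                units.append((f"{sess.condition_label}_band{k}", bsess))
    return units


def _stage_isc(cfg, state, manifest):
    units = _analysis_units(cfg, state)
    seeds = derive_seeds(cfg.seed, len(units) + len(state["sessions"]))

    state["isc"] = {}
    maps = parallel_map(lambda u: core.isc_map(u[1]), units, cfg.n_workers)
    for (label, dataset), m, seed in zip(units, maps, seeds[: len(units)]):
        null = _sample_null_parallel(dataset, cfg.n_realizations, seed, cfg.n_workers)
        np.save(os.path.join(cfg.output_dir, "nulls", f"{label}_null.npy"), null.samples)
        manifest.add(
            f"null distribution {label}",
            os.path.join(cfg.output_dir, "nulls", f"{label}_null.npy"),
            "null_samples",
            intermediate=True,
            n_realizations=cfg.n_realizations,
            seed=seed,
        )
        state["isc"][label] = {"dataset": dataset, "map": m, "null": null}

    if cfg.analyses.timewindow:
        state["timewindow"] = {}
        for sess, seed in zip(state["sessions"], seeds[len(units):]):
            wmaps = timewindow.windowed_isc(sess, cfg.window)
            wnull = timewindow.pooled_window_null(
                sess, cfg.window, cfg.n_realizations, seed
            )
            state["timewindow"][sess.condition_label] = {
                "maps": wmaps,
                "null": wnull,
                "dataset": sess,
            }


def _stage_thresholds(cfg, state, manifest):
    state["thresholds"] = {}
    for label, unit in state.get("isc", {}).items():
        per_q = {}
        for q in cfg.q_levels:
            per_q[q] = resampling.threshold_isc_map(
                unit["map"], unit["null"], q, unit["dataset"].mask
            )
        state["thresholds"][label] = per_q

    if cfg.analyses.timewindow:
        for label, tw in state.get("timewindow", {}).items():
            q = cfg.q_levels[0]
            crit = float(
                np.quantile(tw["null"].samples, 1 - q)
            )  # common uncorrected threshold across windows at level q
            tw["maps"].common_threshold = crit

    if cfg.analyses.difference:
        state["difference"] = {}
        sessions = state["sessions"]
        diff_seeds = derive_seeds(cfg.seed + 1, len(sessions) * len(sessions))
        k = 0
        for a in range(len(sessions)):
            for b in range(a + 1, len(sessions)):
                paired = difference.PairedConditionData(
                    session_a=sessions[a], session_b=sessions[b]
                )
                stats_ = difference.sum_zpf(paired)
                extrema = difference.signflip_null(
                    stats_, n_perm=cfg.n_permutations, seed=diff_seeds[k]
                )
                upper, lower = difference.fwer_thresholds(extrema, cfg.alpha)
                key = f"{sessions[a].condition_label}_vs_{sessions[b].condition_label}"
                state["difference"][key] = {
                    "stats": stats_,
                    "upper": upper,
                    "lower": lower,
                    "reference": sessions[a].reference,
                }
                k += 1


def _stage_curves(cfg, state, manifest):
    atlas = state.get("atlas")
    if cfg.analyses.timewindow and atlas is not None:
        for label, tw in state["timewindow"].items():
            curves = timewindow.roi_curves(tw["maps"], atlas, tw["dataset"])
            path = os.path.join(cfg.output_dir, "timewindow", f"{label}_roi_curves.tsv")
            timewindow.curves_to_frame(curves).to_csv(path, sep="\t")
            manifest.add(f"ROI ISC curves {label}", path, "roi_curves")

    if cfg.analyses.ips:
        state["ips"] = {}
        bank = cfg.bank if cfg.analyses.frequency else None
        for sess in state["sessions"]:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ips_map = phase.ips(sess, bank=bank)
            state["ips"][sess.condition_label] = {"map": ips_map, "dataset": sess}
            if atlas is not None:
                curves = phase.ips_roi_curves(ips_map, atlas, sess)
                path = os.path.join(
                    cfg.output_dir, "ips", f"{sess.condition_label}_roi_curves.tsv"
                )
                timewindow.curves_to_frame(curves).to_csv(path, sep="\t")
                manifest.add(
                    f"ROI IPS curves {sess.condition_label}", path, "roi_curves"
                )


def _stage_export(cfg, state, manifest):
    for label, unit in state.get("isc", {}).items():
        ref = unit["dataset"].reference
        map_path = os.path.join(cfg.output_dir, "isc", f"{label}_rbar.nii.gz")
        datamodel.write_statmap(unit["map"].rbar, ref, map_path)
        manifest.add(f"ISC map {label}", map_path, "isc_map")
        sidecar = {}
        for q, thr in state["thresholds"][label].items():
            rej_path = os.path.join(cfg.output_dir, "isc", f"{label}_rejected_q{q}.nii.gz")
            datamodel.write_statmap(thr.rejected.astype(float), ref, rej_path)
            manifest.add(f"rejections {label} q={q}", rej_path, "rejection_map", q=q)
            sidecar[f"critical_r_q{q}"] = thr.critical_r
        side_path = os.path.join(cfg.output_dir, "isc", f"{label}_thresholds.txt")
        datamodel.write_threshold_sidecar(side_path, sidecar)
        manifest.add(f"thresholds {label}", side_path, "threshold_sidecar")

    for key, d in state.get("difference", {}).items():
        path = os.path.join(cfg.output_dir, "difference", f"{key}_zpf_sum.nii.gz")
        datamodel.write_statmap(d["stats"].sum_map, d["reference"], path)
        manifest.add(f"sum-ZPF map {key}", path, "zpf_map")
        side = os.path.join(cfg.output_dir, "difference", f"{key}_thresholds.txt")
        datamodel.write_threshold_sidecar(
            side,
            {
                "fwer_upper": d["upper"],
                "fwer_lower": d["lower"],
                "alpha": cfg.alpha,
                "n_excluded_pairs": d["stats"].n_excluded,
            },
        )
        manifest.add(f"FWER thresholds {key}", side, "threshold_sidecar")

    for label, tw in state.get("timewindow", {}).items():
        ref = tw["dataset"].reference
        stack = np.stack([m.rbar for m in tw["maps"].maps], axis=-1)
        path = os.path.join(cfg.output_dir, "timewindow", f"{label}_windowed_rbar.nii.gz")
        datamodel.write_series_map(stack, ref, path)
        manifest.add(
            f"windowed ISC maps {label}",
            path,
            "windowed_isc",
            window_length=cfg.window_length,
            window_step=cfg.window_step,
        )
        side = os.path.join(cfg.output_dir, "timewindow", f"{label}_threshold.txt")
        datamodel.write_threshold_sidecar(
            side, {"common_threshold": tw["maps"].common_threshold, "q": cfg.q_levels[0]}
        )
        manifest.add(f"common window threshold {label}", side, "threshold_sidecar")

    for label, d in state.get("ips", {}).items():
        ref = d["dataset"].reference
        path = os.path.join(cfg.output_dir, "ips", f"{label}_ips.nii.gz")
        datamodel.write_series_map(d["map"].ips, ref, path)
        manifest.add(
            f"IPS map {label}", path, "ips_map", edge_samples=d["map"].edge_samples
        )


def prune(manifest_path: str) -> list[str]:
    """Remove intermediate artifacts listed in a manifest; return their paths."""
    with open(manifest_path) as fh:
        doc = json.load(fh)
    removed = []
    for art in doc["artifacts"]:
        if art.get("intermediate") and os.path.exists(art["path"]):
            os.remove(art["path"])
            removed.append(art["path"])
    with open(manifest_path, "w") as fh:
        doc["artifacts"] = [a for a in doc["artifacts"] if a["path"] not in removed]
        json.dump(doc, fh, indent=2, default=str)
    return removed


def extract_curves(cfg: AnalysisConfig, atlas_path: str) -> list[str]:
    """Recompute ROI curves from exported windowed-ISC / IPS map stacks."""
    import nibabel as nib
    import pandas as pd

    atlas = datamodel.read_atlas(atlas_path)
    mask = datamodel.read_mask(cfg.mask_path)
    written = []
    for sess in cfg.sessions:
        for kind, fname in (
            ("timewindow", f"{sess.label}_windowed_rbar.nii.gz"),
            ("ips", f"{sess.label}_ips.nii.gz"),
        ):
            path = os.path.join(cfg.output_dir, kind, fname)
            if not os.path.exists(path):
                continue
            stack = np.asanyarray(nib.load(path).dataobj)
            rows = {}
            for name in atlas.names:
                region = atlas.region_mask(name, mask)
                rows[name] = np.nanmean(stack[region], axis=0)
            out = os.path.join(cfg.output_dir, kind, f"{sess.label}_curves.tsv")
            pd.DataFrame(rows).to_csv(out, sep="\t", index_label="index")
            written.append(out)
    return written
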