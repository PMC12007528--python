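"""Experiment configuration, serialization and the end-to-end runner.

One :class:`ExperimentConfig` fully determines a simulated experiment —
paradigm, sequence, phantom, response/drift/noise/motion models and the
master seed — and round-trips losslessly through YAML/JSON.  ``run_experiment``
executes the whole chain (schedule, k-space simulation, per-trial
normalization, reconstruction, optional motion correction, trial-averaged
statistics) deterministically and, when given an output directory, writes the
standard artifact bundle (NIfTI series and maps, TSV time courses, a JSON
summary with the derived timing numbers, and a log carrying the config hash
and seeds).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import analysis, io
from .acquisition import (
    Paradigm,
    diana_schedule,
    get_paradigm,
    run_duration_s,
    scan_duration_s,
    simulate_acquisition,
)
from .bloch import SequenceParams
from .phantom import (
    DriftModel,
    MotionModel,
    NoiseModel,
    ResponseModel,
    make_default_phantom,
)
from .recon import motion_correct, reconstruct

__all__ = [
    "ExperimentConfig",
    "load_config",
    "save_config",
    "run_experiment",
    "experiment_summary",
]

_MODEL_TYPES = {
    "sequence": SequenceParams,
    "response": ResponseModel,
    "drift": DriftModel,
    "noise": NoiseModel,
    "motion": MotionModel,
}


def _build(cls, value, what: str):
    if value is None or isinstance(value, cls):
        return value
    if isinstance(value, dict):
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(value) - allowed
        if unknown:
            raise ValueError(f"unknown field(s) in {what}: {sorted(unknown)}")
        if "physio_components" in value and value["physio_components"] is not None:
            value = dict(value)
            value["physio_components"] = [
                tuple(c) for c in value["physio_components"]
            ]
        if "transforms" in value and value["transforms"] is not None:
            value = dict(value)
            value["transforms"] = [tuple(t) for t in value["transforms"]]
        return cls(**value)
    raise ValueError(f"{what} must be a mapping, got {type(value).__name__}")


@dataclass
class ExperimentConfig:
    """Fully serializable description of one simulated DIANA experiment."""

    paradigm: str | Paradigm = "paradigm_III"
    sequence: SequenceParams = field(
        default_factory=lambda: SequenceParams(tr_ms=5.0, te_ms=2.4, fa_deg=4.0)
    )
    phantom_preset: str = "brain_slice"
    matrix_size: int | None = None  # None: use the paradigm's matrix
    response: ResponseModel | None = None
    drift: DriftModel | None = None
    noise: NoiseModel | None = None
    motion: MotionModel | None = None
    n_dummy: int = 2000
    discard_first_run: bool = True
    normalize: str = "kspace"  # "kspace" | "image" | "none"
    motion_correction: bool = False
    quantize_16bit: bool = False
    rois: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.paradigm, dict):
            allowed = {f.name for f in dataclasses.fields(Paradigm)}
            unknown = set(self.paradigm) - allowed
            if unknown:
                raise ValueError(f"unknown field(s) in paradigm: {sorted(unknown)}")
            self.paradigm = Paradigm(**self.paradigm)
        for name, cls in _MODEL_TYPES.items():
            setattr(self, name, _build(cls, getattr(self, name), name))
        if self.normalize not in ("kspace", "image", "none"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")
        if self.n_dummy < 0:
            raise ValueError("n_dummy must be >= 0")

    # -- resolved views ----------------------------------------------------
    def resolved_paradigm(self) -> Paradigm:
        return (
            get_paradigm(self.paradigm)
            if isinstance(self.paradigm, str)
            else self.paradigm
        )

    def resolved_matrix(self) -> int:
        return (
            self.resolved_paradigm().matrix_n
            if self.matrix_size is None
            else self.matrix_size
        )

    def voxel_size_mm(self) -> tuple[float, float, float]:
        res = self.resolved_paradigm().resolution
        try:
            parts = res.replace("mm", "").split("x")
            return tuple(float(p) for p in parts)  # type: ignore[return-value]
        except Exception:
            return (2.0, 2.0, 5.0)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def plain(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                v = dataclasses.asdict(v)
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            return v

        return {f.name: plain(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_config(config: ExperimentConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)
    return path


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as f:
        d = yaml.safe_load(f)
    if not isinstance(d, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return ExperimentConfig.from_dict(d)


def experiment_summary(config: ExperimentConfig) -> dict:
    """Derived protocol timing numbers, without running any simulation."""
    par = config.resolved_paradigm()
    n = config.resolved_matrix()
    m = par.trial_timepoints_m
    tr = config.sequence.tr_ms
    return {
        "paradigm": par.name,
        "matrix_n": n,
        "trial_timepoints_m": m,
        "trial_duration_ms": par.trial_duration_ms,
        "n_dummy": config.n_dummy,
        "dummy_duration_s": config.n_dummy * tr / 1000.0,
        "run_duration_s": run_duration_s(n, m, tr),
        "scan_duration_s": scan_duration_s(par.n_runs_per_scan, config.n_dummy, n, m, tr),
        "n_runs_per_scan": par.n_runs_per_scan,
        "n_scans": par.n_scans,
        "trials_per_run": n,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate, reconstruct and analyze a full experiment.

    Returns a dict with the timing ``summary``, per-ROI :class:`ROIResponse`
    objects (``responses``), descriptive ``estimates``, ``tsnr`` summaries,
    the retained reconstructed runs and motion tables.  Deterministic given
    the config (all noise streams derive from ``config.seed`` unless the
    models carry explicit seeds).
    """
    from . import __version__

    par = config.resolved_paradigm()
    n = config.resolved_matrix()
    m = par.trial_timepoints_m
    seq = config.sequence
    if abs(seq.tr_ms - par.tr_ms) > 1e-9:
        raise ValueError(
            f"sequence TR {seq.tr_ms} ms != paradigm TR {par.tr_ms} ms"
        )
    phantom = make_default_phantom(n, config.phantom_preset)

    noise = config.noise
    if noise is not None and noise.seed == 0 and config.seed != 0:
        noise = dataclasses.replace(noise, seed=config.seed)
    motion = config.motion
    if motion is not None and motion.seed == 0 and config.seed != 0:
        motion = dataclasses.replace(motion, seed=config.seed)

    run_dur = run_duration_s(n, m, seq.tr_ms)
    dummy_s = config.n_dummy * seq.tr_ms / 1000.0
    scan_dur = scan_duration_s(par.n_runs_per_scan, config.n_dummy, n, m, seq.tr_ms)

    kspace_runs, labels = [], []
    for s in range(par.n_scans):
        scan_start = s * scan_dur
        for r in range(par.n_runs_per_scan):
            start = scan_start + (dummy_s if r > 0 else 0.0) + r * run_dur
            sched = diana_schedule(
                n, m, n_dummy=config.n_dummy if r == 0 else 0,
                tr_ms=seq.tr_ms, start_time_s=start,
            )
            ks = simulate_acquisition(
                phantom, seq, sched,
                response=config.response, drift=config.drift,
                noise=noise, motion=motion, run_key=(s, r),
            )
            kspace_runs.append(ks)
            labels.append((s, r))

    retained = [
        i
        for i, (s, r) in enumerate(labels)
        if not (config.discard_first_run and r == 0 and par.n_runs_per_scan > 1)
    ]
    discarded = [labels[i] for i in range(len(labels)) if i not in retained]

    kept = [kspace_runs[i] for i in retained]
    if config.normalize == "kspace":
        kept = analysis.normalize_trials(kept)

    voxel = config.voxel_size_mm()
    images = [
        reconstruct(
            ks,
            quantize_16bit=config.quantize_16bit,
            voxel_size_mm=voxel,
            run_index=labels[i][1],
            scan_index=labels[i][0],
        )
        for ks, i in zip(kept, retained)
    ]
    if config.normalize == "image":
        images = [analysis.normalize_images_per_run(im) for im in images]

    motion_tables = []
    if config.motion_correction:
        reference = images[0].run_mean()
        corrected = []
        for im in images:
            fixed, table = motion_correct(im, reference)
            corrected.append(fixed)
            motion_tables.append(table)
        images = corrected

    roi_names = config.rois if config.rois is not None else sorted(phantom.rois)
    responses, estimates = {}, {}
    for roi in roi_names:
        mask = phantom.rois[roi]
        courses = np.stack(
            [analysis.percent_change_pipeline(im, mask) for im in images]
        )
        resp = analysis.ci_across_runs(courses, tr_ms=seq.tr_ms, roi=roi)
        responses[roi] = resp
        estimates[roi] = analysis.estimate_response(resp)

    tsnr_map = analysis.tsnr(images[0])
    tsnr_summaries = {
        roi: analysis.roi_tsnr(tsnr_map, phantom.rois[roi]) for roi in roi_names
    }

    summary = experiment_summary(config)
    summary.update(
        n_runs_total=len(labels),
        n_runs_retained=len(retained),
        discarded_runs=[list(d) for d in discarded],
        version=__version__,
    )

    result = {
        "summary": summary,
        "responses": responses,
        "estimates": estimates,
        "tsnr": tsnr_summaries,
        "images": images,
        "motion": motion_tables,
        "phantom": phantom,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_config(config, out / "config.yaml")
        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=2)
        for roi, resp in responses.items():
            io.save_roi_response(resp, out / f"roi_{roi}.tsv")
        io.save_image_series(images[0], out / "run0.nii.gz")
        io.save_map(np.nan_to_num(tsnr_map.map), out / "tsnr.nii.gz", voxel)
        for roi in roi_names:
            io.save_mask(phantom.rois[roi], out / f"mask_{roi}.nii.gz", voxel)
        for table, (s, r) in zip(motion_tables, [labels[i] for i in retained]):
            table.to_csv(out / f"motion_s{s}_r{r}.tsv", sep="\t", index=False)
        with open(out / "log.txt", "w") as f:
            f.write(
                f"dianasim {__version__}\nconfig_hash {summary['config_hash']}\n"
                f"seed {config.seed}\nn_dummy {config.n_dummy}\n"
                f"discarded_runs {discarded}\n"
            )
    return result
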