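"""Job-file-driven orchestration.

The analysis is split into two units, mirroring how screening setups share
microscopes and compute: one creates a plain-ASCII job file describing the
positions, substrate and step parameters; the other reads it and executes
the steps strictly in order (focus → drift → displacement → fttc →
metrics), rewriting the job file after every completed step so an
interrupted analysis resumes exactly where it stopped.  A pristine backup
of the job file is kept from the first launch.

Job files are INI: a ``[job]`` section for globals, ``[position:<label>]``
sections for inputs, and ``[step:<name>]`` sections with per-step
parameters and a ``status`` of pending/done/failed.  Unknown keys are
preserved on round-trip.  Output paths are always
``<output_root>/<position>/<step>/...``, so every artifact is addressable
from the job file alone.
"""

from __future__ import annotations

import configparser
import shutil
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .core import GelSubstrate
from . import io as tio
from .cellmetrics import integrate_force, segment_adhesions, track_cell
from .displacement import hybrid_displacement
from .focus import select_best_focus
from .fttc import auto_lambda, build_fourier_kernel
from .registration import apply_drift_correction, build_drift_trace, crop_only

__all__ = ["JobSpec", "PositionSpec", "StepSpec", "STEP_ORDER", "write_job", "read_job", "run_job"]

STEP_ORDER = ("focus", "drift", "displacement", "fttc", "metrics")
STATUSES = ("pending", "done", "failed")

DEFAULT_STEP_PARAMS: dict[str, dict[str, str]] = {
    "focus": {"metric_beads": "edf", "metric_cell": "edf"},
    "drift": {"max_drift_px": "32"},
    "displacement": {
        "window_px": "32",
        "overlap_fraction": "0.75",
        "exploration_radius_px": "2.0",
        "radius_px": "3",
        "intensity_percentile": "90.0",
    },
    "fttc": {"noise_sigma_um": "", "pad_factor": "2"},
    "metrics": {"frame_interval_min": "5.0", "fa_threshold_k": "3.0", "segment_fa": "1"},
}


@dataclass
class PositionSpec:
    label: str
    bead_file: str
    ref_file: str
    cell_files: list[str] = dc_field(default_factory=list)
    extra: dict[str, str] = dc_field(default_factory=dict)


@dataclass
class StepSpec:
    name: str
    status: str = "pending"
    params: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in STEP_ORDER:
            raise ValueError(f"unknown step {self.name!r}; steps are {STEP_ORDER}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r} for step {self.name}")


@dataclass
class JobSpec:
    positions: list[PositionSpec]
    substrate: GelSubstrate
    output_root: str
    pixel_size_um: float | None = None
    n_z: int | None = None
    steps: list[StepSpec] = dc_field(default_factory=list)
    extra: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        have = [s.name for s in self.steps]
        if len(set(have)) != len(have):
            raise ValueError("duplicate step in job")
        # fill in any missing steps with defaults, in canonical order
        by_name = {s.name: s for s in self.steps}
        self.steps = [
            by_name.get(name, StepSpec(name=name, params=dict(DEFAULT_STEP_PARAMS[name])))
            for name in STEP_ORDER
        ]
        if have != [n for n in STEP_ORDER if n in have]:
            raise ValueError(f"step order violated: {have}; required order is {STEP_ORDER}")
        # status monotonicity: done-steps must form a prefix
        seen_not_done = False
        for s in self.steps:
            if s.status == "done" and seen_not_done:
                raise ValueError(
                    f"step {s.name!r} marked done after an unfinished earlier step; "
                    "steps execute strictly in order"
                )
            if s.status != "done":
                seen_not_done = True
        for name, defaults in DEFAULT_STEP_PARAMS.items():
            sp = self.step(name)
            for k, v in defaults.items():
                sp.params.setdefault(k, v)

    def step(self, name: str) -> StepSpec:
        for s in self.steps:
            if s.name == name:
                return s
        raise KeyError(name)


def write_job(spec: JobSpec, path) -> None:
    """Serialize the job to its ASCII (INI) file; lossless round-trip."""
    cp = configparser.ConfigParser(delimiters=("=",), interpolation=None)
    cp.optionxform = str
    cp["job"] = {}
    cp["job"]["output_root"] = spec.output_root
    cp["job"]["young_modulus_Pa"] = repr(spec.substrate.young_modulus_Pa)
    cp["job"]["poisson_ratio"] = repr(spec.substrate.poisson_ratio)
    if spec.pixel_size_um is not None:
        cp["job"]["pixel_size_um"] = repr(spec.pixel_size_um)
    if spec.n_z is not None:
        cp["job"]["n_z"] = str(spec.n_z)
    for k, v in spec.extra.items():
        cp["job"][k] = v
    for pos in spec.positions:
        sec = f"position:{pos.label}"
        cp[sec] = {"bead_file": pos.bead_file, "ref_file": pos.ref_file}
        if pos.cell_files:
            cp[sec]["cell_files"] = ";".join(pos.cell_files)
        for k, v in pos.extra.items():
            cp[sec][k] = v
    for s in spec.steps:
        sec = f"step:{s.name}"
        cp[sec] = {"status": s.status}
        for k, v in s.params.items():
            cp[sec][k] = v
    with open(path, "w") as fh:
        cp.write(fh)


def read_job(path) -> JobSpec:
    """Parse a job file; malformed sections and duplicate steps raise errors
    carrying line numbers (via configparser's strict mode)."""
    cp = configparser.ConfigParser(delimiters=("=",), interpolation=None, strict=True)
    cp.optionxform = str
    with open(path) as fh:
        cp.read_file(fh, source=str(path))
    if "job" not in cp:
        raise ValueError(f"{path}: missing [job] section")
    job = dict(cp["job"])
    known = {"output_root", "young_modulus_Pa", "poisson_ratio", "pixel_size_um", "n_z"}
    substrate = GelSubstrate(
        float(job.get("young_modulus_Pa", "nan")), float(job.get("poisson_ratio", "0.5"))
    )
    positions, steps = [], []
    for sec in cp.sections():
        if sec.startswith("position:"):
            d = dict(cp[sec])
            positions.append(
                PositionSpec(
                    label=sec.split(":", 1)[1],
                    bead_file=d.pop("bead_file"),
                    ref_file=d.pop("ref_file"),
                    cell_files=[f for f in d.pop("cell_files", "").split(";") if f],
                    extra=d,
                )
            )
        elif sec.startswith("step:"):
            d = dict(cp[sec])
            steps.append(
                StepSpec(name=sec.split(":", 1)[1], status=d.pop("status", "pending"), params=d)
            )
    return JobSpec(
        positions=positions,
        substrate=substrate,
        output_root=job["output_root"],
        pixel_size_um=float(job["pixel_size_um"]) if "pixel_size_um" in job else None,
        n_z=int(job["n_z"]) if "n_z" in job else None,
        steps=steps,
        extra={k: v for k, v in job.items() if k not in known},
    )


# ------------------------------------------------------------------ execution

def _outdir(spec: JobSpec, pos: PositionSpec, step: str) -> Path:
    p = Path(spec.output_root) / pos.label / step
    p.mkdir(parents=True, exist_ok=True)
    return p


def _read_channels(spec: JobSpec, pos: PositionSpec):
    bz, bt, px = tio.read_ome_series(
        pos.bead_file, n_z=spec.n_z, pixel_size_um=spec.pixel_size_um, channel_tag="beads"
    )
    rz, _, _ = tio.read_ome_series(
        pos.ref_file, n_z=spec.n_z, pixel_size_um=spec.pixel_size_um, channel_tag="beads_ref"
    )
    cells = []
    for cf in pos.cell_files:
        cz, ct, _ = tio.read_ome_series(
            cf, pixel_size_um=spec.pixel_size_um, channel_tag="cell"
        )
        cells.append((cz, ct))
    return bz, bt, rz, cells, px


def _step_focus(spec: JobSpec, pos: PositionSpec, params: dict) -> None:
    bz, bt, rz, cells, px = _read_channels(spec, pos)
    out = _outdir(spec, pos, "focus")
    rep_b = select_best_focus(bz, params.get("metric_beads", "edf"))
    rep_r = select_best_focus(rz, params.get("metric_beads", "edf"))
    tio.write_tiff(bz[rep_b.best_index], out / "beads_best.tif")
    tio.write_tiff(rz[rep_r.best_index], out / "ref_best.tif")
    tio.write_focus_scores(rep_b, out / "beads_scores.txt")
    tio.write_focus_scores(rep_r, out / "ref_scores.txt")
    for k, (cz, _) in enumerate(cells):
        rep_c = select_best_focus(cz, params.get("metric_cell", "edf"))
        tio.write_tiff(cz[rep_c.best_index], out / f"cell{k}_best.tif")
        tio.write_focus_scores(rep_c, out / f"cell{k}_scores.txt")


def _step_drift(spec: JobSpec, pos: PositionSpec, params: dict) -> None:
    _, bt, _, cells, px = _read_channels(spec, pos)
    focus_dir = Path(spec.output_root) / pos.label / "focus"
    ref = tio.read_tiff_stack(focus_dir / "ref_best.tif", px)[0]
    trace = build_drift_trace(bt, ref, max_drift_px=float(params.get("max_drift_px", "32")))
    out = _outdir(spec, pos, "drift")
    tio.write_drift_ascii(trace, out / "drift.txt")
    tio.write_tiff(apply_drift_correction(bt, trace), out / "beads_aligned.tif", px)
    tio.write_tiff(crop_only(ref, trace), out / "ref_aligned.tif", px)
    for k, (_, ct) in enumerate(cells):
        if ct:
            tio.write_tiff(apply_drift_correction(ct, trace), out / f"cell{k}_aligned.tif", px)


def _step_displacement(spec: JobSpec, pos: PositionSpec, params: dict) -> None:
    px = _pixel_size(spec, pos)
    drift_dir = Path(spec.output_root) / pos.label / "drift"
    ref = tio.read_tiff_stack(drift_dir / "ref_aligned.tif", px)[0]
    frames = tio.read_tiff_stack(drift_dir / "beads_aligned.tif", px)
    out = _outdir(spec, pos, "displacement")
    for t, frame in enumerate(frames):
        res = hybrid_displacement(
            frame,
            ref,
            window_px=int(params.get("window_px", "32")),
            overlap_fraction=float(params.get("overlap_fraction", "0.75")),
            exploration_radius_um=float(params.get("exploration_radius_px", "2.0")) * px,
            radius_px=int(params.get("radius_px", "3")),
            intensity_percentile=float(params.get("intensity_percentile", "90.0")),
        )
        tio.write_field_ascii(
            res.field,
            out / f"displacement_t{t:04d}.txt",
            extra_meta={"noise_sigma_um": res.noise_sigma_um},
        )
        if t == 0:
            tio.overlay_beads_jpeg(ref, frame, out / "beads_overlay.jpg")
            tio.quiver_overlay_jpeg(ref, res.field, out / "displacement_quiver.jpg")


def _pixel_size(spec: JobSpec, pos: PositionSpec) -> float:
    import tifffile as tf

    from .io import _pixel_size_from_ome

    with tf.TiffFile(pos.bead_file) as t:
        px = _pixel_size_from_ome(t.ome_metadata)
    return px or spec.pixel_size_um


def _step_fttc(spec: JobSpec, pos: PositionSpec, params: dict) -> None:
    disp_dir = Path(spec.output_root) / pos.label / "displacement"
    files = sorted(disp_dir.glob("displacement_t*.txt"))
    if not files:
        raise FileNotFoundError(f"no displacement tables under {disp_dir}")
    out = _outdir(spec, pos, "fttc")
    op = None
    noise = params.get("noise_sigma_um", "").strip()
    noise_sigma = float(noise) if noise else None
    log_lines = ["# t lambda residual_norm solution_norm n_iterations converged"]
    mags = []
    for t, f in enumerate(files):
        u = tio.read_displacement_ascii(f)
        if noise_sigma is None:
            meta = tio.read_field_meta(f)
            frame_noise = meta.get("noise_sigma_um")
        else:
            frame_noise = noise_sigma
        if op is None:
            op = build_fourier_kernel(
                u.n_rows, u.n_cols, u.spacing_um, spec.substrate,
                pad_factor=int(params.get("pad_factor", "2")),
            )
        res = auto_lambda(u, op, noise_sigma_um=frame_noise)
        res.traction.origin_um = u.origin_um
        tio.write_traction_ascii(res.traction, out / f"traction_t{t:04d}.txt")
        mags.append(res.traction.magnitude.astype(np.float32))
        log_lines.append(
            f"{t} {res.lambda_opt:.9e} {res.residual_norm:.9e} "
            f"{res.solution_norm:.9e} {res.n_iterations} {int(res.converged)}"
        )
    tio.write_tiff(np.stack(mags), out / "traction_magnitude.tif")
    (out / "regularization_log.txt").write_text("\n".join(log_lines) + "\n")


def _step_metrics(spec: JobSpec, pos: PositionSpec, params: dict) -> None:
    import pandas as pd

    px = _pixel_size(spec, pos)
    drift_dir = Path(spec.output_root) / pos.label / "drift"
    fttc_dir = Path(spec.output_root) / pos.label / "fttc"
    tfiles = sorted(fttc_dir.glob("traction_t*.txt"))
    if not tfiles:
        raise FileNotFoundError(f"no traction tables under {fttc_dir}")
    cell_stacks = sorted(drift_dir.glob("cell*_aligned.tif"))
    if not cell_stacks:
        raise FileNotFoundError(
            f"metrics step needs an aligned cell channel under {drift_dir}"
        )
    frames = tio.read_tiff_stack(cell_stacks[0], px)
    masks = track_cell(frames)
    out = _outdir(spec, pos, "metrics")
    tio.write_tiff(
        np.stack([m.mask.astype(np.float32) for m in masks]), out / "cell_masks.tif", px
    )
    dt = float(params.get("frame_interval_min", "5.0"))
    segment_fa = params.get("segment_fa", "1") not in ("0", "false", "no")
    rows = []
    for t, (tf_path, mask) in enumerate(zip(tfiles, masks)):
        traction = tio.read_traction_ascii(tf_path)
        fa = None
        if segment_fa:
            fa = segment_adhesions(
                frames[t], cell_mask=mask.mask,
                threshold_k=float(params.get("fa_threshold_k", "3.0")),
            )
        rec = integrate_force(traction, mask, fa_labels=fa)
        rows.append(
            {
                "position": pos.label,
                "t_index": t,
                "time_min": t * dt,
                "area_um2": round(rec.area_um2, 4),
                "total_force_nN": round(rec.total_force_nN, 6),
                "force_ratio_Pa": round(rec.force_ratio_Pa, 6),
                "n_FA": rec.n_FA,
            }
        )
    pd.DataFrame(rows).to_csv(out / "force_time.csv", index=False)


_STEP_FUNCS = {
    "focus": _step_focus,
    "drift": _step_drift,
    "displacement": _step_displacement,
    "fttc": _step_fttc,
    "metrics": _step_metrics,
}


def run_job(spec_or_path, resume: bool = False, job_path=None) -> dict:
    """Execute the job's pending steps in order across all positions.

    The job file is rewritten after every completed step (full
    traceability and restartability); a pristine backup of the job file is
    made on first launch.  On a step failure the status is set to
    ``failed``, the error recorded, and subsequent steps are left
    untouched.  With ``resume=True`` steps already marked done are skipped;
    otherwise all statuses are reset and everything re-runs.
    """
    if isinstance(spec_or_path, (str, Path)):
        job_path = Path(spec_or_path)
        spec = read_job(job_path)
    else:
        spec = spec_or_path
        job_path = Path(job_path) if job_path else None
    if job_path is not None:
        backup = job_path.with_suffix(job_path.suffix + ".bak")
        if not backup.exists():
            shutil.copyfile(job_path, backup)
    if not resume:
        for s in spec.steps:
            s.status = "pending"
    summary = {"steps": {}, "failed": None}
    for s in spec.steps:
        if s.status == "done":
            summary["steps"][s.name] = "skipped (done)"
            continue
        try:
            for pos in spec.positions:
                _STEP_FUNCS[s.name](spec, pos, s.params)
        except Exception as exc:  # noqa: BLE001 - any step failure is recorded
            s.status = "failed"
            summary["steps"][s.name] = f"failed: {exc}"
            summary["failed"] = s.name
            if job_path is not None:
                write_job(spec, job_path)
            break
        s.status = "done"
        summary["steps"][s.name] = "done"
        if job_path is not None:
            write_job(spec, job_path)
    return summary
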