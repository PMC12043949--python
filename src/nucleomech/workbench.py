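"""Shared I/O, run configuration, and the pipeline runner.

All tables are comma-delimited UTF-8 CSV with a single header row and strict
column names; fitted parameters go to JSON.  Physical calibration (pixel
size, z-step, frame interval) always comes from the configuration, never
from image metadata, because TIFF tag conventions vary between microscopes
and a silent unit error is the main hazard in this kind of pipeline.  Every
pipeline run writes its fully resolved configuration and a provenance
record (config hash, seed, package version) next to its outputs, and reruns
with the same configuration and seed reproduce all numeric outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .dynamics import Trajectory
from .errors import DataError, SchemaError, ShapeError
from .frap import FrapProtocol, FrapTrace
from .morphometry import ZStack
from .rheology import FrequencySweep, RelaxationCurve, StressStrainCurve

__all__ = ["RunConfig", "read_table", "read_stack", "write_table", "run_pipeline"]

_SCHEMAS = {
    "curves": ["time_s", "stress_kpa"],
    "ramps": ["strain", "stress_kpa"],
    "sweeps": ["omega_rad_s", "g_storage", "g_loss"],
    "traces": ["time_s", "intensity", "phase"],
    "tracks": ["track_id", "frame", "t_s", "x_um", "y_um"],  # z_um optional
}


def _load_csv(path, schema: str) -> pd.DataFrame:
    required = _SCHEMAS[schema]
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    optional = {"tracks": ["z_um"]}.get(schema, [])
    extra = [c for c in df.columns if c not in required + optional]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {', '.join(extra)}")
    numeric = [c for c in df.columns if c not in ("phase", "track_id")]
    for c in numeric:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(f"{path}: non-numeric value in column {c}, row {row}")
        if col.isna().any():
            row = int(col.isna().idxmax())
            raise SchemaError(f"{path}: missing value in column {c}, row {row}")
        df[c] = col
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def read_table(path, schema: str):
    """Read a typed CSV table.

    ``schema`` is one of ``curves`` (relaxation), ``ramps`` (stress-strain),
    ``sweeps`` (frequency sweep), ``traces`` (FRAP), ``tracks`` (particle
    trajectories).  Returns the corresponding domain object(s).
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown table schema {schema!r}")
    df = _load_csv(path, schema)
    if schema == "curves":
        return RelaxationCurve(time=df["time_s"].to_numpy(), stress=df["stress_kpa"].to_numpy())
    if schema == "ramps":
        return StressStrainCurve(strain=df["strain"].to_numpy(), stress=df["stress_kpa"].to_numpy())
    if schema == "sweeps":
        return FrequencySweep(
            omega=df["omega_rad_s"].to_numpy(),
            g_storage=df["g_storage"].to_numpy(),
            g_loss=df["g_loss"].to_numpy(),
        )
    if schema == "traces":
        phases = set(df["phase"].astype(str))
        if not phases <= {"prescan", "post"}:
            raise SchemaError(f"{path}: phase must be 'prescan' or 'post'")
        pre = df[df["phase"] == "prescan"]
        post = df[df["phase"] == "post"]
        if post.empty:
            raise SchemaError(f"{path}: no post-bleach rows")
        return FrapTrace(
            time=post["time_s"].to_numpy(),
            intensity=post["intensity"].to_numpy(),
            prescan_intensity=pre["intensity"].to_numpy(),
            protocol=FrapProtocol(
                n_prescan=max(len(pre), 1), n_post=max(len(post), 10)
            ),
        )
    # tracks
    dims = ["x_um", "y_um"] + (["z_um"] if "z_um" in df.columns else [])
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                id=str(tid),
                time=grp["t_s"].to_numpy(),
                position=grp[dims].to_numpy(),
            )
        )
    return out


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_stack(path, voxel_xy: float = 0.1, z_step: float = 0.3):
    """Read a single- or multi-page TIFF.

    Multi-page files become a :class:`ZStack` with the supplied physical
    spacing; single pages are returned as a 2-D float array.  RGB input is
    rejected — extract a single channel upstream.
    """
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise DataError(
            "RGB/multi-channel page detected; extract a single channel before loading"
        )
    arr = arr.astype(float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        return ZStack(voxels=arr, voxel_xy=voxel_xy, z_step=z_step)
    raise DataError(f"unsupported TIFF dimensionality {arr.ndim}")


# ---------------------------------------------------------------------------
# run configuration and pipeline


_CONFIG_KEYS = {"seed", "out_dir", "units", "stages"}
_UNIT_KEYS = {"pixel_um", "z_step_um", "frame_interval_s"}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run description; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "."
    units: dict = field(
        default_factory=lambda: {"pixel_um": 0.1, "z_step_um": 0.3, "frame_interval_s": 120.0}
    )
    stages: list = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        units = dict(cls().units)
        bad = set(raw.get("units", {})) - _UNIT_KEYS
        if bad:
            raise SchemaError(f"unknown unit key(s): {', '.join(sorted(bad))}")
        units.update(raw.get("units", {}))
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", ".")),
            units=units,
            stages=list(raw.get("stages", [])),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_simulate(params: dict, cfg: RunConfig, out: Path) -> dict:
    from . import simkit

    what = params.get("what")
    seed = int(params.get("seed", cfg.seed))
    name = params.get("name", what)
    if what == "relaxation":
        curve, truth = simkit.gen_relaxation(
            amplitudes=params.get("amplitudes", [1.0]),
            taus=params.get("taus", [1442.695]),
            sigma0=params.get("sigma0", 2.0),
            t_max=params.get("t_max", 4000.0),
            dt=params.get("dt", 1.0),
            noise_sd=params.get("noise_sd", 0.0),
            seed=seed,
        )
        path = out / f"{name}.csv"
        write_table(path, pd.DataFrame({"time_s": curve.time, "stress_kpa": curve.stress}))
    elif what == "frap":
        trace, truth = simkit.gen_frap_trace(
            tau_r=params.get("tau_r", 14.427),
            noise_sd=params.get("noise_sd", 0.0),
            seed=seed,
        )
        path = out / f"{name}.csv"
        n_pre = trace.prescan_intensity.size
        pre_t = -trace.protocol.prescan_interval * np.arange(n_pre, 0, -1)
        write_table(
            path,
            pd.DataFrame(
                {
                    "time_s": np.concatenate([pre_t, trace.time]),
                    "intensity": np.concatenate([trace.prescan_intensity, trace.intensity]),
                    "phase": ["prescan"] * n_pre + ["post"] * trace.time.size,
                }
            ),
        )
    elif what == "tracks":
        tracks, truth = simkit.gen_tracks(
            n_tracks=params.get("n_tracks", 50),
            n_steps=params.get("n_steps", 20),
            dt=params.get("dt", cfg.units["frame_interval_s"]),
            alpha=params.get("alpha", 1.0),
            D=params.get("D", 0.01),
            dim=params.get("dim", 2),
            seed=seed,
        )
        path = out / f"{name}.csv"
        rows = []
        for tr in tracks:
            for f, (t, p) in enumerate(zip(tr.time, tr.position)):
                row = {"track_id": tr.id, "frame": f, "t_s": t, "x_um": p[0], "y_um": p[1]}
                if p.size == 3:
                    row["z_um"] = p[2]
                rows.append(row)
        write_table(path, pd.DataFrame(rows))
    elif what == "stack":
        stack, truth = simkit.gen_nucleus_stack(
            semi_axes=params.get("semi_axes", (5.0, 5.0, 3.0)),
            voxel_xy=params.get("voxel_xy", cfg.units["pixel_um"]),
            z_step=params.get("z_step", cfg.units["z_step_um"]),
            noise_sd=params.get("noise_sd", 0.0),
            seed=seed,
        )
        path = out / f"{name}.tif"
        tifffile.imwrite(path, stack.voxels.astype(np.float32))
    elif what == "lamin":
        image, _, truth = simkit.gen_lamin_image(
            radius=params.get("radius", 4.0),
            fold_amplitude=params.get("fold_amplitude", 1.0),
            n_folds=params.get("n_folds", 4),
            pixel=params.get("pixel", cfg.units["pixel_um"]),
            noise_sd=params.get("noise_sd", 2.0),
            seed=seed,
        )
        path = out / f"{name}.tif"
        tifffile.imwrite(path, image.astype(np.float32))
    else:
        raise SchemaError(f"unknown simulate target {what!r}")
    truth_path = out / f"{name}.truth.json"
    truth_path.write_text(json.dumps({"kind": truth.kind, "params": truth.params}, indent=1))
    return {"output": str(path), "truth": str(truth_path)}


def _stage_rheo(params: dict, cfg: RunConfig, out: Path) -> dict:
    from . import rheology

    curve = read_table(params["in"], "curves")
    fit = rheology.fit_relaxation(curve)
    rec = {
        "sigma0_kpa": fit.sigma0,
        "a1": fit.weights[0],
        "a2": fit.weights[1],
        "tau1_s": fit.taus[0],
        "tau2_s": fit.taus[1],
        "plateau": fit.plateau,
        "tau_half_s": fit.tau_half,
        "residual_rmse_kpa": fit.residual_rmse,
    }
    path = out / params.get("name", "rheo_fit.json")
    path.write_text(json.dumps(rec, indent=1))
    return {"output": str(path), "tau_half_s": fit.tau_half}


def _stage_frap(params: dict, cfg: RunConfig, out: Path) -> dict:
    from . import frap as frapmod

    trace = read_table(params["in"], "traces")
    fit = frapmod.fit_recovery(frapmod.normalize_trace(trace))
    rec = {
        "I_bleach": fit.I_bleach,
        "I_plateau": fit.I_plateau,
        "tau_r_s": fit.tau_r,
        "t_half_s": fit.t_half,
        "mobile_fraction": fit.mobile_fraction,
        "recovered": fit.recovered,
    }
    path = out / params.get("name", "frap_fit.json")
    path.write_text(json.dumps(rec, indent=1))
    return {"output": str(path), "t_half_s": fit.t_half}


def _stage_msd(params: dict, cfg: RunConfig, out: Path) -> dict:
    from . import dynamics

    tracks = read_table(params["in"], "tracks")
    center = None
    if params.get("center"):
        centers = read_table(params["center"], "tracks")
        center = centers[0]
    rows = []
    for tr in tracks:
        if center is not None:
            tr = dynamics.correct_drift(tr, center)
        msd = dynamics.time_avg_msd(tr)
        fit = dynamics.fit_powerlaw(
            msd,
            fit_fraction=params.get("fit_fraction", 0.5),
            r2_min=params.get("r2_min", 0.8),
        )
        rows.append(
            {
                "track_id": tr.id,
                "alpha": fit.alpha,
                "D_um2_s_alpha": fit.D,
                "r_squared": fit.r_squared,
                "accepted": fit.accepted,
                "T_s": fit.T,
            }
        )
    df = pd.DataFrame(rows)
    path = out / params.get("name", "msd_fits.csv")
    write_table(path, df)
    return {
        "output": str(path),
        "n_accepted": int(df["accepted"].sum()),
        "n_rejected": int((~df["accepted"]).sum()),
    }


def _stage_nucleus(params: dict, cfg: RunConfig, out: Path) -> dict:
    from . import morphometry

    stack = read_stack(
        params["in"],
        voxel_xy=params.get("voxel_xy", cfg.units["pixel_um"]),
        z_step=params.get("z_step", cfg.units["z_step_um"]),
    )
    if not isinstance(stack, ZStack):
        raise DataError("nucleus stage needs a multi-page TIFF stack")
    mask = morphometry.segment_stack(stack)
    res = morphometry.compaction_index(stack, mask)
    df = pd.DataFrame(
        [
            {
                "nucleus_id": 1,
                "volume_um3": res.volume,
                "integrated_intensity": res.integrated_intensity,
                "compaction_index": res.compaction_index,
            }
        ]
    )
    path = out / params.get("name", "nucleus.csv")
    write_table(path, df)
    return {"output": str(path), "volume_um3": res.volume}


def _stage_wrinkle(params: dict, cfg: RunConfig, out: Path) -> dict:
    from . import wrinkling

    image = read_stack(params["in"])
    if isinstance(image, ZStack):
        image = image.voxels.max(axis=0)
    res = wrinkling.wrinkling_index(image, pixel_um=params.get("pixel", cfg.units["pixel_um"]))
    df = pd.DataFrame(
        [
            {
                "nucleus_id": 1,
                "wrinkling_index": res.index,
                "area_um2": res.nucleus_area,
                "intensity_cv": res.nucleoplasm_intensity_cv,
            }
        ]
    )
    path = out / params.get("name", "wrinkle.csv")
    write_table(path, df)
    return {"output": str(path), "wrinkling_index": res.index}


_STAGES = {
    "simulate": _stage_simulate,
    "rheo": _stage_rheo,
    "frap": _stage_frap,
    "msd": _stage_msd,
    "nucleus": _stage_nucleus,
    "wrinkle": _stage_wrinkle,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order.

    Writes each stage's outputs under ``config.out_dir`` plus a structured
    ``run_log.json`` with provenance (config hash, seed, package version)
    and the resolved configuration.  A stage failure aborts the run with
    the failing stage named; outputs written so far are retained next to a
    ``run_log.json.partial`` marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
    }
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    for i, stage in enumerate(config.stages):
        stage = dict(stage)
        kind = stage.pop("stage", None)
        if kind not in _STAGES:
            raise SchemaError(f"unknown pipeline stage {kind!r}")
        try:
            result = _STAGES[kind](stage, config, out)
        except Exception as err:
            (out / "run_log.json.partial").write_text(json.dumps(log, indent=1))
            raise RuntimeError(f"stage {i} ({kind}) failed: {err}") from err
        log["stages"].append({"stage": kind, **result})
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return log
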