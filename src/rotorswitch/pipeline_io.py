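"""File formats, run configuration and end-to-end orchestration.

Traces travel as headered TSV with unit-bearing column names
(``time_s``, ``x_um``, ``y_um`` for trajectories; ``time_s``,
``speed_hz`` for speed traces).  Ring images are TIFF with the pixel
size (Å) carried in the image description as JSON.  A YAML/JSON
manifest names the inputs of each analysis stage; ``run_pipeline``
executes the stages, isolating per-input failures, and ``write_report``
emits a JSON report plus TSV tables mirroring the figure data
(bias-vs-frequency scatter, torque-speed curve, stability table,
symmetry population histogram).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .ringsym import DEFAULT_SEARCH_BAND, analyze_ring
from .stator import CombFitError, estimate_stator_number, fit_gaussian_comb, make_histogram, speed_stability
from .switching import binarize, compute_switch_stats, population_summary
from .torque import BeadSpec, build_curve, extrapolate_limits
from .trace import SpeedTrace, Trajectory, trajectory_to_speed
from .synth import RingImage

__all__ = [
    "ManifestError",
    "RunConfig",
    "RunReport",
    "read_trajectory",
    "write_trajectory",
    "read_speed_trace",
    "write_speed_trace",
    "read_ring_image",
    "write_ring_image",
    "load_manifest",
    "run_pipeline",
    "write_report",
]


# ---------------------------------------------------------------- trace I/O

def read_trajectory(path: str | Path) -> Trajectory:
    """Read a centroid trajectory TSV (columns time_s, x_um, y_um)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return Trajectory(
        time_s=df["time_s"].to_numpy(),
        x_um=df["x_um"].to_numpy(),
        y_um=df["y_um"].to_numpy(),
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": traj.time_s, "x_um": traj.x_um, "y_um": traj.y_um}
    ).to_csv(path, sep="\t", index=False)


def read_speed_trace(path: str | Path) -> SpeedTrace:
    """Read a speed trace TSV (columns time_s, speed_hz)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "speed_hz"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy()
    dt = float(np.median(np.diff(t))) if t.size >= 2 else 1.0
    return SpeedTrace(time_s=t, speed_hz=df["speed_hz"].to_numpy(),
                      frame_rate_hz=1.0 / dt)


def write_speed_trace(trace: SpeedTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "speed_hz": trace.speed_hz}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------- image I/O

def write_ring_image(img: RingImage, path: str | Path) -> None:
    """Write a ring image as float32 TIFF; pixel size (Å) goes into the
    image description as JSON."""
    meta = {"pixel_size_angstrom": img.pixel_size_angstrom}
    tifffile.imwrite(
        path, img.pixels.astype(np.float32), description=json.dumps(meta)
    )


def read_ring_image(
    path: str | Path, pixel_size_angstrom: float | None = None
) -> RingImage:
    """Read a TIFF ring image; the pixel size comes from the description
    JSON unless overridden by ``pixel_size_angstrom``."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        pixels = page.asarray().astype(float)
        apix = pixel_size_angstrom
        if apix is None:
            desc = page.tags.get("ImageDescription")
            if desc is not None:
                try:
                    apix = json.loads(desc.value).get("pixel_size_angstrom")
                except (json.JSONDecodeError, AttributeError):
                    apix = None
    if apix is None:
        raise ValueError(
            f"{path}: no pixel size in metadata; pass pixel_size_angstrom"
        )
    return RingImage(pixels=pixels, pixel_size_angstrom=float(apix))


# ---------------------------------------------------------------- manifest

class ManifestError(ValueError):
    """Invalid run manifest; ``problems`` lists every issue found."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid manifest:\n  " + "\n  ".join(problems))


_STAGE_KEYS = {
    "switching": {"traces", "hysteresis_hz", "min_dwell_s", "window_s"},
    "torque": {"records", "knee_speed_hz"},
    "resurrection": {"traces", "bin_width_hz", "max_components"},
    "stability": {"traces"},
    "ringsym": {"images", "pixel_size_angstrom", "search_band", "n_angles"},
}
_TOP_KEYS = {"seed", "output_dir"} | set(_STAGE_KEYS)

_DEFAULTS = {
    "switching": {"hysteresis_hz": None, "min_dwell_s": None, "window_s": 30.0},
    "torque": {"knee_speed_hz": "auto"},
    "resurrection": {"bin_width_hz": 1.0, "max_components": 12},
    "stability": {},
    "ringsym": {
        "pixel_size_angstrom": None,
        "search_band": list(DEFAULT_SEARCH_BAND),
        "n_angles": 720,
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (stages keyed by name)."""

    stages: dict
    seed: int = 0
    output_dir: str = "rotorswitch_out"
    base_dir: Path = field(default_factory=Path)

    def resolve(self, p: str | Path) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    def to_dict(self) -> dict:
        """Manifest-schema dict: ``load_manifest(dump(cfg))`` round-trips."""
        return {"seed": self.seed, "output_dir": self.output_dir, **self.stages}


def load_manifest(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON manifest, filling defaults.

    All problems (unknown keys, missing files, out-of-range parameters)
    are collected and reported at once in a :class:`ManifestError`.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ManifestError(["manifest root must be a mapping"])
    base = path.parent
    problems: list[str] = []
    for key in raw:
        if key not in _TOP_KEYS:
            problems.append(f"unknown top-level key {key!r}")
    stages: dict = {}
    for stage, allowed in _STAGE_KEYS.items():
        if stage not in raw:
            continue
        block = dict(raw[stage]) if isinstance(raw[stage], dict) else None
        if block is None:
            problems.append(f"{stage}: must be a mapping")
            continue
        for key in block:
            if key not in allowed:
                problems.append(f"{stage}: unknown key {key!r}")
        cfg = dict(_DEFAULTS[stage])
        cfg.update({k: v for k, v in block.items() if k in allowed})
        for key in ("traces", "images"):
            for rel in cfg.get(key, []) or []:
                if not (base / rel if not Path(rel).is_absolute() else Path(rel)).exists():
                    problems.append(f"{stage}: missing file {rel!r}")
        if stage == "torque":
            for i, rec in enumerate(cfg.get("records", []) or []):
                if "trace" not in rec:
                    problems.append(f"torque: record {i} lacks 'trace'")
                elif not (base / rec["trace"]).exists():
                    problems.append(f"torque: missing file {rec['trace']!r}")
                if rec.get("bead_diameter_um", 1.0) <= 0:
                    problems.append(f"torque: record {i} bead_diameter_um must be > 0")
                if rec.get("viscosity_pa_s", 1.0) <= 0:
                    problems.append(f"torque: record {i} viscosity_pa_s must be > 0")
        if stage == "switching" and cfg["window_s"] <= 0:
            problems.append("switching: window_s must be > 0")
        if stage == "resurrection" and cfg["bin_width_hz"] <= 0:
            problems.append("resurrection: bin_width_hz must be > 0")
        stages[stage] = cfg
    if problems:
        raise ManifestError(problems)
    return RunConfig(
        stages=stages,
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "rotorswitch_out")),
        base_dir=base,
    )


# ---------------------------------------------------------------- pipeline

@dataclass
class RunReport:
    """Results of one pipeline run; every block is a plain-JSON mapping
    and carries the inputs and parameters that produced it."""

    config: dict
    provenance: dict
    switching: dict | None = None
    torque: dict | None = None
    resurrection: dict | None = None
    stability: dict | None = None
    ringsym: dict | None = None
    errors: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "config": self.config,
            "switching": self.switching,
            "torque": self.torque,
            "resurrection": self.resurrection,
            "stability": self.stability,
            "ringsym": self.ringsym,
            "errors": self.errors,
        }


def _load_any_speed(path: Path) -> SpeedTrace:
    """A trace file may hold a speed trace or a raw trajectory; raw
    trajectories are converted (circle fit + unwrap + differentiate)."""
    df = pd.read_csv(path, sep="\t", nrows=1)
    if "speed_hz" in df.columns:
        return read_speed_trace(path)
    speed, _ = trajectory_to_speed(read_trajectory(path))
    return speed


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every configured stage; a failing input is recorded in
    ``report.errors`` and does not abort the others.  Deterministic for
    a given config (the analysis stages draw no randomness; the seed is
    recorded for provenance of any upstream simulation)."""
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    report = RunReport(
        config=config.to_dict(),
        provenance={
            "package": "rotorswitch",
            "version": __version__,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.seed,
        },
    )

    if "switching" in config.stages:
        cfg = config.stages["switching"]
        per_motor, stats_list = [], []
        for rel in cfg["traces"]:
            try:
                trace = _load_any_speed(config.resolve(rel))
                stats = compute_switch_stats(
                    binarize(trace, cfg["hysteresis_hz"], cfg["min_dwell_s"]),
                    window_s=cfg["window_s"],
                )
                stats_list.append(stats)
                per_motor.append({
                    "trace": rel,
                    "cw_bias": stats.cw_bias,
                    "switching_frequency_per_s": stats.switching_frequency_per_s,
                    "rotation_class": stats.rotation_class,
                })
            except Exception as exc:  # noqa: BLE001 - isolate per input
                report.errors.append({"stage": "switching", "input": rel,
                                      "error": str(exc)})
        block = {"motors": per_motor}
        if stats_list:
            s = population_summary(stats_list)
            block["population"] = {
                "mean_cw_bias": s.mean_cw_bias,
                "sd_cw_bias": s.sd_cw_bias,
                "mean_switching_frequency_per_s": s.mean_switching_frequency_per_s,
                "sd_switching_frequency_per_s": s.sd_switching_frequency_per_s,
                "n": s.n,
                "class_counts": s.class_counts,
            }
        report.switching = block

    if "torque" in config.stages:
        cfg = config.stages["torque"]
        records = []
        for rec in cfg["records"]:
            try:
                trace = _load_any_speed(config.resolve(rec["trace"]))
                spec = BeadSpec(
                    bead_diameter_um=rec["bead_diameter_um"],
                    rotation_radius_um=rec.get("rotation_radius_um", 0.0),
                    viscosity_pa_s=rec.get("viscosity_pa_s", BeadSpec.viscosity_pa_s),
                )
                records.append((trace, spec))
            except Exception as exc:  # noqa: BLE001
                report.errors.append({"stage": "torque", "input": rec.get("trace"),
                                      "error": str(exc)})
        if records:
            try:
                curve = extrapolate_limits(build_curve(records),
                                           cfg["knee_speed_hz"])
                report.torque = {
                    "points": [
                        {"speed_hz": p.speed_hz, "torque_pn_nm": p.torque_pn_nm,
                         "bead_diameter_um": p.bead_diameter_um,
                         "n_motors": p.n_motors}
                        for p in curve.points
                    ],
                    "stall_torque_pn_nm": curve.stall_torque_pn_nm,
                    "zero_load_speed_hz": curve.zero_load_speed_hz,
                    "knee_speed_hz": curve.knee_speed_hz,
                }
            except Exception as exc:  # noqa: BLE001
                report.errors.append({"stage": "torque", "input": None,
                                      "error": str(exc)})

    if "resurrection" in config.stages:
        cfg = config.stages["resurrection"]
        out = []
        for rel in cfg["traces"]:
            try:
                trace = _load_any_speed(config.resolve(rel))
                hist = make_histogram(trace, cfg["bin_width_hz"])
                entry = {"trace": rel}
                try:
                    fit = fit_gaussian_comb(hist, cfg["max_components"])
                    mean_speed = float(np.mean(np.abs(trace.speed_hz)))
                    est = estimate_stator_number(mean_speed, fit.increment_hz)
                    entry.update({
                        "unit_increment_hz": fit.increment_hz,
                        "increment_stderr_hz": fit.increment_stderr_hz,
                        "offset_hz": fit.offset_hz,
                        "sigma_hz": fit.sigma_hz,
                        "n_components": fit.n_components,
                        "mean_speed_hz": est.mean_speed_hz,
                        "n_units": est.n_units,
                    })
                except CombFitError as exc:
                    entry["comb_fit_error"] = str(exc)
                out.append(entry)
            except Exception as exc:  # noqa: BLE001
                report.errors.append({"stage": "resurrection", "input": rel,
                                      "error": str(exc)})
        report.resurrection = {"motors": out}

    if "stability" in config.stages:
        cfg = config.stages["stability"]
        out = []
        for rel in cfg["traces"]:
            try:
                trace = _load_any_speed(config.resolve(rel))
                st = speed_stability(trace)
                out.append({"trace": rel, "omega_av_hz": st.omega_av_hz,
                            "sigma_omega_hz": st.sigma_omega_hz,
                            "ratio": st.ratio})
            except Exception as exc:  # noqa: BLE001
                report.errors.append({"stage": "stability", "input": rel,
                                      "error": str(exc)})
        report.stability = {"motors": out}

    if "ringsym" in config.stages:
        cfg = config.stages["ringsym"]
        out, pop = [], {}
        for rel in cfg["images"]:
            try:
                img = read_ring_image(config.resolve(rel),
                                      cfg["pixel_size_angstrom"])
                geo, spec = analyze_ring(
                    img, n_angles=cfg["n_angles"],
                    search_band=tuple(cfg["search_band"]),
                )
                out.append({
                    "image": rel,
                    "symmetry_n": geo.symmetry_n,
                    "diameter_angstrom": geo.diameter_angstrom,
                    "repeat_distance_angstrom": geo.repeat_distance_angstrom,
                    "confidence": spec.confidence,
                })
                pop[geo.symmetry_n] = pop.get(geo.symmetry_n, 0) + 1
            except Exception as exc:  # noqa: BLE001
                report.errors.append({"stage": "ringsym", "input": rel,
                                      "error": str(exc)})
        report.ringsym = {"images": out,
                          "population": {str(k): v for k, v in sorted(pop.items())}}

    return report


def write_report(report: RunReport, out_dir: str | Path) -> list[Path]:
    """Write report.json plus per-stage TSV tables; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    p = out_dir / "report.json"
    with open(p, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)
    if report.switching and report.switching.get("motors"):
        p = out_dir / "bias_vs_frequency.tsv"
        pd.DataFrame(report.switching["motors"]).to_csv(p, sep="\t", index=False)
        written.append(p)
    if report.torque and report.torque.get("points"):
        p = out_dir / "torque_speed.tsv"
        pd.DataFrame(report.torque["points"]).to_csv(p, sep="\t", index=False)
        written.append(p)
    if report.stability and report.stability.get("motors"):
        p = out_dir / "stability.tsv"
        pd.DataFrame(report.stability["motors"]).to_csv(p, sep="\t", index=False)
        written.append(p)
    if report.ringsym and report.ringsym.get("population"):
        p = out_dir / "symmetry_population.tsv"
        pd.DataFrame(
            [{"symmetry_n": k, "count": v}
             for k, v in report.ringsym["population"].items()]
        ).to_csv(p, sep="\t", index=False)
        written.append(p)
    return written
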