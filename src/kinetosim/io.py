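"""Volume and table I/O, experiment configuration and the seeded pipeline runner.

Volumes are stored as multichannel TIFF Z-stacks with the nm calibration
(voxel size, origin, channel names) embedded in the TIFF description, so a
written volume round-trips bit-identically.  Experiments are described by a
YAML-serializable config; every stochastic stage derives its seed
deterministically from the master seed, the stage name and the replicate
index, so re-running a config reproduces all outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import linescan, optics, scene, spotfit


class CalibrationError(ValueError):
    """A volume file lacks the nm calibration metadata."""


def write_volume(volume: optics.ImageVolume, path) -> None:
    """Write an :class:`~kinetosim.optics.ImageVolume` as a calibrated TIFF stack."""
    meta = {
        "axes": "CZYX",
        "voxel_size_nm": list(volume.voxel_size),
        "origin_nm": list(volume.origin),
        "channels": list(volume.channels),
        "extra": _jsonable(volume.metadata),
    }
    tifffile.imwrite(str(path), volume.data, metadata=meta)


def read_volume(path) -> optics.ImageVolume:
    """Read a volume written by :func:`write_volume`; errors on missing calibration."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        shaped = tf.shaped_metadata
        meta = dict(shaped[0]) if shaped else {}
    if "voxel_size_nm" not in meta or "channels" not in meta:
        raise CalibrationError(
            f"{path}: no nm calibration found in the TIFF metadata; volumes must be "
            "written with kinetosim.io.write_volume (or carry voxel_size_nm, "
            "origin_nm and channels in a JSON TIFF description)"
        )
    channels = tuple(meta["channels"])
    data = np.asarray(data).reshape((len(channels), -1) + data.shape[-2:])
    return optics.ImageVolume(
        data,
        channels,
        tuple(meta["voxel_size_nm"]),
        tuple(meta.get("origin_nm", (0.0, 0.0, 0.0))),
        dict(meta.get("extra", {})),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if _is_plain(v)}
    return obj


def _is_plain(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# seeding


def stage_seed(master_seed: int, stage: str, replicate: int = 0) -> np.random.SeedSequence:
    """Deterministic per-stage, per-replicate seed stream.

    The stage name is hashed (CRC-32) into the spawn key so that re-running a
    single stage reproduces exactly the stream it saw in the full pipeline.
    """
    return np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(zlib.crc32(stage.encode()), int(replicate))
    )


def stage_rng(master_seed: int, stage: str, replicate: int = 0) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage, replicate))


# ---------------------------------------------------------------------------
# experiment config


@dataclass
class ExperimentConfig:
    """Reproducible experiment description: scene, optics, grid, measurements."""

    name: str = "experiment"
    master_seed: int = 0
    replicates: int = 10
    scene: dict = field(
        default_factory=lambda: {
            "kind": "sister-pair",
            "plate_length": 1000.0,
            "plate_width": 250.0,
            "layer_thickness": 50.0,
            "layer_separation": 100.0,
            "ikd": 1000.0,
            "swivel_angles": [0.0, 0.0],
            "molecules_per_layer": 1000,
        }
    )
    psf: dict = field(default_factory=dict)  # lateral_fwhm / axial_fwhm overrides
    grid: dict = field(default_factory=lambda: {"voxel_xy": 43.0, "voxel_z": 200.0})
    measure: dict = field(
        default_factory=lambda: {"modes": ["linescan"], "angles": [0.0]}
    )
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))


def _build_pair_spec(cfg: dict) -> scene.SisterPairSpec:
    plate = scene.PlateSpec(
        shape=cfg.get("shape", scene.FLAT_PRISM),
        plate_length=cfg.get("plate_length", 1000.0),
        plate_width=cfg.get("plate_width", 250.0),
        layer_thickness=cfg.get("layer_thickness", 50.0),
        layer_separation=cfg.get("layer_separation", 100.0),
        curvature_radius=cfg.get("curvature_radius", float("inf")),
        curvature_mode=cfg.get("curvature_mode", "cap-3d"),
        molecules_per_layer=cfg.get("molecules_per_layer", 1000),
    )
    return scene.SisterPairSpec(
        plates=(plate, plate),
        inter_kinetochore_distance=cfg.get("ikd", 1000.0),
        swivel_angles=tuple(cfg.get("swivel_angles", (0.0, 0.0))),
    )


def _psf_from_config(cfg: dict) -> optics.PSFModel:
    return optics.psf_from_fwhm(cfg.get("lateral_fwhm"), cfg.get("axial_fwhm"))


def run_experiment(config: ExperimentConfig, output_dir=None) -> dict:
    """generate -> render -> measure -> summarize, fully seeded.

    Returns a dict of pandas DataFrames ("linescan" and/or "spots" plus
    "summary"); when an output directory is set the tables, a config
    snapshot and a log of per-stage seeds are written there.
    """
    out = Path(output_dir or config.output_dir) if (output_dir or config.output_dir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    psf = _psf_from_config(config.psf)
    vxy = config.grid.get("voxel_xy", 43.0)
    vz = config.grid.get("voxel_z", 200.0)
    if config.scene.get("kind", "sister-pair") != "sister-pair":
        raise ValueError(f"unknown scene kind {config.scene.get('kind')!r}")
    pair_spec = _build_pair_spec(config.scene)
    modes = config.measure.get("modes", ["linescan"])
    angles = config.measure.get("angles", [0.0])

    log_lines = [f"experiment {config.name}: master_seed={config.master_seed}"]
    line_rows = []
    spot_rows = []
    for rep in range(config.replicates):
        scene_rng = stage_rng(config.master_seed, "scene", rep)
        render_rng = stage_rng(config.master_seed, "render", rep)
        log_lines.append(f"replicate {rep}: stage seeds scene/render derived")
        cloud = scene.build_sister_pair(pair_spec, rng=scene_rng)
        volume = optics.render(
            cloud, psf, voxel_size=(vxy, vxy, vz), rng=render_rng
        )
        if out is not None and config.measure.get("save_volumes", False):
            write_volume(volume, out / f"volume_rep{rep:03d}.tiff")
        gt = cloud.ground_truth
        if "linescan" in modes:
            base = linescan.pair_scan_line(gt, psf)
            sweep = linescan.skew_sweep(volume, base, angles)
            for angle, m in sorted(sweep.measurements.items()):
                line_rows.append(
                    linescan.measurement_row(
                        m, scene_id=rep, angle_deg=angle,
                        true_separation=pair_spec.plates[0].layer_separation,
                    )
                )
        if "spotfit" in modes:
            spots = {
                ch: spotfit.fit_all_spots(volume, ch) for ch in volume.channels
            }
            reg = spotfit.register_channels(spots["green"], spots["red"])
            res = spotfit.kshrec_delta(spots["green"], spots["red"], reg)
            for (gi, ri), d in zip(res.pairs, res.deltas):
                spot_rows.append(
                    {
                        "scene_id": rep,
                        "green_label": spots["green"][gi].label,
                        "red_label": spots["red"][ri].label,
                        "delta_nm": d,
                        "registration_shift_nm": float(
                            np.linalg.norm(reg.translation)
                        ),
                        "true_separation": pair_spec.plates[0].layer_separation,
                    }
                )

    results: dict = {}
    if line_rows:
        df = pd.DataFrame(line_rows)
        results["linescan"] = df
        results["summary"] = (
            df[df.qc_pass]
            .groupby("angle_deg")["delta"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
    if spot_rows:
        results["spots"] = pd.DataFrame(spot_rows)
    if out is not None:
        config.to_yaml(out / "config.yaml")
        (out / "log.txt").write_text("\n".join(log_lines) + "\n")
        for name, df in results.items():
            df.to_csv(out / f"results_{name}.csv", index=False)
    return results
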