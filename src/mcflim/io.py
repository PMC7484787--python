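"""File formats, run configuration and the end-to-end pipeline driver.

Decay cubes are stored as multi-page TIFF (one 16-bit page per time
channel) with a JSON sidecar carrying the acquisition metadata (channel
width, power, IRF vector, pixel pitch, depth, seed), so cubes remain
inspectable with standard imaging tools.  Cohorts, fit maps and clouds go
to CSV; configs and reports to JSON.  Every pipeline artifact records the
config hash and seed; re-running with the same config reproduces the
outputs bit-exactly (the numerics are single-threaded).
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

from . import cellscan, classify, phasor, stats, synthetic
from .decay import CHANNEL_WIDTH_PS, DecayCube, FitConfig, FitMaps, IRF, fit_image

_SIDECAR_REQUIRED = ("channel_width_ps", "power_mw", "pixel_pitch_um",
                     "n_time_channels", "irf")


class FormatError(ValueError):
    pass


def write_cube(cube: DecayCube, path) -> Path:
    """Write a decay cube as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    counts = np.asarray(cube.counts)
    if np.issubdtype(counts.dtype, np.integer) and counts.max(initial=0) < 2**16:
        pages = counts.astype(np.uint16)
    else:
        pages = counts.astype(np.float32)
    # pages along the time axis
    tifffile.imwrite(path, np.moveaxis(pages, 2, 0))
    sidecar = {
        "channel_width_ps": cube.channel_width_ps,
        "power_mw": cube.power_mw,
        "pixel_pitch_um": cube.pixel_pitch_um,
        "n_time_channels": cube.n_channels,
        "depth_um": cube.depth_um,
        "seed": cube.seed,
        "irf": cube.irf.kernel.tolist(),
        "irf_form": cube.irf.form,
        "meta": cube.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def read_cube(path) -> DecayCube:
    """Read a cube written by :func:`write_cube`; validates the sidecar."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing metadata sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in sidecar:
            raise FormatError(f"metadata sidecar lacks required field {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    counts = np.moveaxis(pages, 0, 2)
    if counts.shape[2] != sidecar["n_time_channels"]:
        raise FormatError(
            f"page count {counts.shape[2]} does not match declared "
            f"n_time_channels {sidecar['n_time_channels']}")
    return DecayCube(
        counts=counts,
        channel_width_ps=sidecar["channel_width_ps"],
        power_mw=sidecar["power_mw"],
        pixel_pitch_um=sidecar["pixel_pitch_um"],
        irf=IRF(np.asarray(sidecar["irf"]), form=sidecar.get("irf_form")),
        depth_um=sidecar.get("depth_um", 0.0),
        seed=sidecar.get("seed"),
        meta=sidecar.get("meta", {}),
    )


def write_fit_maps(maps: FitMaps, outdir, stem: str = "fitmaps") -> Path:
    """One TIFF per parameter map plus a combined long-format CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = {}
    for name in ("tau1", "tau2", "a1", "a2", "tau_m", "ratio", "asym",
                 "chi2", "intensity"):
        arr = getattr(maps, name)
        tifffile.imwrite(outdir / f"{stem}_{name}.tif", arr.astype(np.float32))
        frames[name] = arr.ravel()
    frames["valid"] = maps.valid.ravel().astype(int)
    H, W = maps.valid.shape
    rows, cols = np.divmod(np.arange(H * W), W)
    df = pd.DataFrame({"row": rows, "col": cols, **frames})
    csv_path = outdir / f"{stem}.csv"
    df.to_csv(csv_path, index=False)
    return csv_path


# --------------------------------------------------------------------------
# run configuration


def _from_dict(cls, data: dict):
    """Strict dataclass construction: unknown keys are rejected."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    return cls(**data)


@dataclass
class CohortStage:
    counts: dict | None = None  # None -> study default composition
    scheme: str = "three_class"


@dataclass
class SceneStage:
    image_size: tuple = (24, 24)
    field_of_view_um: tuple = (7.03, 7.03)  # keeps ~0.29 um pixel pitch
    elastin_intensity: float = 450.0
    depth_um: float = 90.0
    power_mw: float = 50.0


@dataclass
class FitStage:
    binning: int = 3
    intensity_threshold: float = 200.0


@dataclass
class ClassifierStage:
    n_repeats: int = 200
    test_fraction: float = 0.4
    schemes: tuple = ("binary", "three_class")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    cohort: CohortStage = field(default_factory=CohortStage)
    scene: SceneStage = field(default_factory=SceneStage)
    fit: FitStage = field(default_factory=FitStage)
    classifier: ClassifierStage = field(default_factory=ClassifierStage)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, sub in (("cohort", CohortStage), ("scene", SceneStage),
                         ("fit", FitStage), ("classifier", ClassifierStage)):
            if key in data and isinstance(data[key], dict):
                data[key] = _from_dict(sub, data[key])
        return _from_dict(cls, data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute simulate -> fit -> phasor -> detect -> classify -> stats.

    Persists every intermediate artifact under ``outdir`` and returns the
    report bundle (also written to ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"config_hash": config.digest(), "seed": config.seed, "stages": {}}
    stage = "simulate"
    try:
        rng = np.random.default_rng(config.seed)
        cohort_spec = (synthetic.CohortSpec(counts=config.cohort.counts,
                                            label_scheme=config.cohort.scheme)
                       if config.cohort.counts is not None
                       else synthetic.CohortSpec(label_scheme=config.cohort.scheme))
        cohort = synthetic.generate_cohort(cohort_spec, rng)
        cohort.to_csv(outdir / "cohort.csv", index=False)
        report["stages"]["simulate"] = {"n_cells": int(len(cohort))}

        scene_cfg = synthetic.SceneConfig(
            image_size=tuple(config.scene.image_size),
            field_of_view_um=tuple(config.scene.field_of_view_um),
            depth_um=config.scene.depth_um,
            excitation_power_mw=config.scene.power_mw,
            elastin_intensity=config.scene.elastin_intensity,
        )
        cube, truth = synthetic.render_scene(scene_cfg, rng)
        cube.seed = config.seed
        write_cube(cube, outdir / "scene.tif")
        truth.table.to_csv(outdir / "scene_truth.csv", index=False)

        stage = "fit"
        fit_cfg = FitConfig(binning=config.fit.binning,
                            intensity_threshold=config.fit.intensity_threshold)
        maps = fit_image(cube, config=fit_cfg)
        write_fit_maps(maps, outdir)
        unmasked = maps.valid
        report["stages"]["fit"] = {
            "n_valid_pixels": int(unmasked.sum()),
            "tau_m_mean_ps": float(np.nanmean(maps.tau_m[unmasked]))
            if unmasked.any() else None,
        }

        stage = "phasor"
        cloud = phasor.phasor_image(cube)
        pd.DataFrame({
            "row": cloud.pixel_index[:, 0], "col": cloud.pixel_index[:, 1],
            "g": cloud.g, "s": cloud.s, "intensity": cloud.intensity,
        }).to_csv(outdir / "phasor.csv", index=False)
        report["stages"]["phasor"] = {"n_points": int(cloud.g.size)}

        stage = "detect"
        records = cellscan.scan_image(cube, maps)
        cellscan.records_to_frame(records).to_csv(outdir / "cells.csv", index=False)
        report["stages"]["detect"] = {
            "n_candidates": len(records),
            "labels": {lab: sum(r.search_label == lab for r in records)
                       for lab in set(r.search_label for r in records)},
        }

        stage = "classify"
        clf = {}
        for scheme in config.classifier.schemes:
            rep = classify.evaluate_cohort(
                cohort, scheme=scheme,
                n_repeats=config.classifier.n_repeats,
                test_fraction=config.classifier.test_fraction,
                base_seed=config.seed)
            clf[scheme] = rep.to_dict()
            for k, (fpr, tpr) in rep.roc.items():
                pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
                    outdir / f"roc_{scheme}_class{k}.csv", index=False)
        report["stages"]["classify"] = clf

        stage = "stats"
        mc = cohort[cohort["label3"] != synthetic.LABEL_OTHER]
        comparison = stats.population_compare(
            mc, "label3", synthetic.LABEL_RESTING, synthetic.LABEL_ACTIVATED)
        comparison.to_csv(outdir / "stats.csv", index=False)
        report["stages"]["stats"] = {
            "n_significant": int(comparison["significant"].sum()),
            "n_params": int(len(comparison)),
        }
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
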