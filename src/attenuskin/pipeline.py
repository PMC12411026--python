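"""End-to-end orchestration: simulate -> fit -> bin -> classify, plus the
Raman branch, with a reproducibility manifest.

A single global seed deterministically derives per-stage seeds (see
:func:`attenuskin.io.derive_seed`), so each stage can be rerun in
isolation and the full run is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .attenuation import fit_bscan, attenuation_map
from .binning import FEATURE_NAMES, bin_features, assemble_dataset
from .classify import CvConfig, cross_validate
from .io import (
    derive_seed,
    file_digest,
    fits_to_frame,
    write_bscan,
    write_spectrum,
)
from .raman import (
    ArplsConfig,
    arpls_baseline,
    difference_spectrum,
    group_statistics,
    normalize_fingerprint,
    remove_cosmic_rays,
    smooth,
)
from .synthetic import default_oct_config, default_raman_config, generate_bscan, generate_raman_spectrum

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "PipelineError"]

logger = logging.getLogger("attenuskin")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    out_dir: str = "attenuskin_run"
    seed: int = 0
    n_samples_per_class: int = 3
    n_ascans: int = 1000
    n_depth: int = 400
    fit_depth: int = 150
    bin_size: int = 5
    n_folds: int = 10
    regularization_C: float = 1.0
    feature_subset: str = "all"  # "all" or "atten"
    n_raman_per_group: int = 10
    despike_z: float = 8.0
    smooth_window: int = 11
    smooth_order: int = 3
    norm_lo: float = 800.0
    norm_hi: float = 1800.0
    arpls_lambda: float = 1e5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _json_dump(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def _raman_branch(cfg: RunConfig, out: Path, manifest: RunManifest) -> dict:
    arpls_cfg = ArplsConfig(lambda_smooth=cfg.arpls_lambda)
    groups: dict[str, list] = {"BN": [], "MM": []}
    corrected: dict[str, list] = {"BN": [], "MM": []}
    for group in ("BN", "MM"):
        for i in range(cfg.n_raman_per_group):
            seed = derive_seed(cfg.seed, f"raman/{group}/{i}")
            sim_cfg = default_raman_config(group, seed=seed)
            raw, _truth = generate_raman_spectrum(sim_cfg, group)
            sp = remove_cosmic_rays(raw, cfg.despike_z)
            sp = smooth(sp, cfg.smooth_window, cfg.smooth_order)
            sp = normalize_fingerprint(sp, cfg.norm_lo, cfg.norm_hi)
            groups[group].append(sp)
            _, corr = arpls_baseline(sp, arpls_cfg)
            corrected[group].append(corr)
            path = out / f"raman_{group.lower()}_{i:02d}.tsv"
            write_spectrum(sp, path)
            manifest.outputs[path.name] = file_digest(path)
    stats_raw = {g: group_statistics(groups[g], g) for g in groups}
    stats_corr = {g: group_statistics(corrected[g], g) for g in corrected}
    diff, diff_hw = difference_spectrum(stats_corr["BN"], stats_corr["MM"])
    report = {
        "n_per_group": cfg.n_raman_per_group,
        "groups": {
            g: {
                "mean_intensity": float(stats_raw[g].mean.mean()),
                "mean_ci_half_width": float(stats_raw[g].ci_half_width.mean()),
            }
            for g in stats_raw
        },
        "difference_bn_minus_mm": {
            "mean": float(diff.mean()),
            "max_abs": float(abs(diff).max()),
        },
        "processing": groups["BN"][0].processing_log,
    }
    diff_path = out / "raman_difference.tsv"
    np.savetxt(
        diff_path,
        np.column_stack([stats_corr["BN"].wavenumbers, diff, diff_hw]),
        header="wavenumber difference ci_half_width",
        comments="# ",
        fmt="%.17g",
    )
    manifest.outputs[diff_path.name] = file_digest(diff_path)
    return report


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the OCT and Raman branches and write all artifacts."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(cfg), version=__version__)
    manifest.started = time.strftime("%Y-%m-%dT%H:%M:%S")
    binned = []
    try:
        stage = "simulate/fit/bin"
        for label in ("BN", "MM"):
            for i in range(cfg.n_samples_per_class):
                sample_id = f"{i + 1:02d}_{'Nevus' if label == 'BN' else 'Melanoma'}"
                seed = derive_seed(cfg.seed, f"oct/{label}/{i}")
                sim = default_oct_config(
                    label, seed=seed, n_ascans=cfg.n_ascans, n_depth=cfg.n_depth
                )
                bscan = generate_bscan(sim, label, sample_id)
                bscan_path = out / f"bscan_{sample_id}.csv"
                write_bscan(bscan, bscan_path)
                fits = fit_bscan(bscan, fit_depth=cfg.fit_depth)
                frame = fits_to_frame(fits)
                fits_path = out / f"fits_{sample_id}.csv"
                frame.to_csv(fits_path, index=False)
                amap = attenuation_map(fits, sample_id)
                map_path = out / f"map_{sample_id}.csv"
                np.savetxt(map_path, amap.values, header="b", comments="# ")
                binned.append(
                    bin_features(fits, cfg.bin_size, label=label, sample_id=sample_id)
                )
                for p in (bscan_path, fits_path, map_path):
                    manifest.outputs[p.name] = file_digest(p)
        stage = "assemble"
        dataset = assemble_dataset(binned)
        features_path = out / "features.csv"
        dataset.to_csv(features_path, index=False)
        manifest.outputs[features_path.name] = file_digest(features_path)
        stage = "classify"
        subset = (
            ("mean_b", "sd_b") if cfg.feature_subset == "atten" else FEATURE_NAMES
        )
        cv_cfg = CvConfig(
            n_folds=cfg.n_folds,
            regularization_C=cfg.regularization_C,
            feature_subset=subset,
            seed=derive_seed(cfg.seed, "classify"),
        )
        report = cross_validate(dataset, cv_cfg)
        report_path = out / "report.json"
        _json_dump(report.to_dict(), report_path)
        manifest.outputs[report_path.name] = file_digest(report_path)
        stage = "raman"
        raman_report = _raman_branch(cfg, out, manifest)
        raman_path = out / "raman_report.json"
        _json_dump(raman_report, raman_path)
        manifest.outputs[raman_path.name] = file_digest(raman_path)
    except PipelineError:
        raise
    except Exception as exc:  # partial outputs stay on disk for inspection
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    return manifest
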