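"""End-to-end orchestration: frames -> masks -> volume -> mass -> aggregates.

Inputs are a directory of depth PNGs and a matching directory of masks,
with the filename convention ``<fish>_<frame>.png`` associating frames to
individuals (fish are photographed one at a time).  Every input frame
either contributes a volume row or an auditable QC rejection with a reason
code — nothing is silently dropped — and the run is deterministic for a
fixed configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mass as mass_mod
from . import volume as vol_mod
from .camera_model import CameraRig, Intrinsics, load_calibration, load_default_calibration
from .errors import EmptyMaskError, FishvolError, QCRejection, RingEmptyError
from .frames import read_depth_png
from .metrics import RegressionReport, regression_metrics
from .segmentation_io import clean_mask, read_mask

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "evaluate_against_truth"]


@dataclass
class PipelineConfig:
    """Everything a volume-estimation run needs."""

    depth_dir: str | Path = "depth"
    mask_dir: str | Path = "mask"
    out_dir: str | Path = "out"
    calibration: str | Path | None = None  # None -> shipped D455 calibration
    mode: str = "metric"                   # metric | paper
    y_ref: float | None = None             # required for paper mode, mm
    ring_width: int = 5
    min_mask_area: int = 32
    rho_g_cm3: float | None = None         # None -> density_file or default
    density_file: str | Path | None = None
    bottom_method: str = "mean"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("metric", "paper"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "paper" and self.y_ref is None:
            raise ValueError("mode='paper' requires y_ref")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class PipelineResult:
    per_frame: pd.DataFrame
    per_fish: pd.DataFrame
    qc: list[dict]
    per_frame_csv: Path
    per_fish_csv: Path
    qc_log: Path


def _density_model(cfg: PipelineConfig) -> mass_mod.DensityModel:
    if cfg.rho_g_cm3 is not None:
        return mass_mod.DensityModel(rho_g_cm3=cfg.rho_g_cm3)
    if cfg.density_file is not None:
        with open(cfg.density_file) as fh:
            doc = yaml.safe_load(fh)
        return mass_mod.DensityModel(rho_g_cm3=float(doc["rho_g_cm3"]))
    return mass_mod.DensityModel()


def _scaled_intrinsics(K: Intrinsics, shape: tuple[int, int]) -> Intrinsics:
    """Rescale calibrated intrinsics when frames were captured downscaled."""
    h, w = shape
    if K.width is None or K.width == w:
        return K
    factor = w / K.width
    if K.height is not None and int(round(K.height * factor)) != h:
        raise ValueError(
            f"frame shape {shape} is not an isotropic rescale of the "
            f"calibrated sensor ({K.height}, {K.width})"
        )
    return K.scaled(factor)


def run_pipeline(cfg: PipelineConfig, rig: CameraRig | None = None) -> PipelineResult:
    """Estimate per-frame volumes and per-fish masses for a whole directory.

    Writes ``per_frame.csv``, ``per_fish.csv`` and a JSON-lines QC log to
    ``cfg.out_dir`` and returns the loaded tables.  Conservation holds:
    every input frame appears exactly once, either as a volume row or as a
    QC rejection.
    """
    depth_dir = Path(cfg.depth_dir)
    mask_dir = Path(cfg.mask_dir)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if rig is None:
        rig = load_calibration(cfg.calibration) if cfg.calibration else load_default_calibration()
    density = _density_model(cfg)

    frame_paths = sorted(depth_dir.glob("*.png"))
    if not frame_paths:
        raise FileNotFoundError(f"no depth PNGs in {depth_dir}")

    rows: list[dict] = []
    qc: list[dict] = []
    for fp in frame_paths:
        stem = fp.stem
        fish_id, _, frame_id = stem.rpartition("_")
        fish_id = fish_id or stem
        try:
            frame = read_depth_png(fp)
            K = _scaled_intrinsics(rig.depth, frame.shape)
            mask = clean_mask(read_mask(mask_dir / fp.name, shape=frame.shape),
                              min_area=cfg.min_mask_area)
            est = vol_mod.estimate_frame_volume(
                frame, mask, K,
                ring_width=cfg.ring_width, mode=cfg.mode, y_ref=cfg.y_ref,
                bottom_method=cfg.bottom_method,
            )
        except EmptyMaskError as e:
            qc.append(dict(frame=stem, fish_id=fish_id, reason="empty-mask", detail=str(e)))
            continue
        except RingEmptyError as e:
            qc.append(dict(frame=stem, fish_id=fish_id, reason="ring-empty", detail=str(e)))
            continue
        except QCRejection as e:
            qc.append(dict(frame=stem, fish_id=fish_id, reason=e.reason, detail=e.detail))
            continue
        rows.append(dict(
            frame_id=stem,
            fish_id=fish_id,
            n_pixels=est.n_pixels,
            n_clamped=est.n_clamped,
            bottom_depth_mm=est.bottom_depth,
            mean_surface_depth_mm=est.mean_surface_depth,
            volume_mm3=est.volume_mm3,
            mass_g=mass_mod.volume_to_mass(est.volume_mm3, density),
            mode=est.mode,
        ))

    per_frame = pd.DataFrame(rows)
    fish_ids = sorted({r["fish_id"] for r in rows} | {q["fish_id"] for q in qc})
    agg_rows = []
    for fid in fish_ids:
        sub = per_frame[per_frame.fish_id == fid] if len(per_frame) else per_frame
        if len(sub) >= 2:
            est = mass_mod.aggregate_frames(sub.mass_g.to_numpy(), fish_id=fid)
            agg_rows.append(dict(
                fish_id=fid, n_frames=est.n_frames,
                mean_volume_mm3=float(sub.volume_mm3.mean()),
                mean_mass_g=est.mean_mass, sd_g=est.sd,
                ci95_lo=est.ci95[0], ci95_hi=est.ci95[1],
            ))
        else:
            # too few surviving frames: flag, never silently drop
            n = int(len(sub))
            agg_rows.append(dict(
                fish_id=fid, n_frames=n,
                mean_volume_mm3=float(sub.volume_mm3.mean()) if n else np.nan,
                mean_mass_g=float(sub.mass_g.mean()) if n else np.nan,
                sd_g=np.nan, ci95_lo=np.nan, ci95_hi=np.nan,
            ))
            qc.append(dict(frame="", fish_id=fid, reason="insufficient-frames",
                           detail=f"{n} surviving frame(s)"))
    per_fish = pd.DataFrame(agg_rows)

    per_frame_csv = out_dir / "per_frame.csv"
    per_fish_csv = out_dir / "per_fish.csv"
    qc_log = out_dir / "qc.jsonl"
    per_frame.to_csv(per_frame_csv, index=False, float_format="%.6f")
    per_fish.to_csv(per_fish_csv, index=False, float_format="%.6f")
    with open(qc_log, "w") as fh:
        for entry in qc:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    return PipelineResult(per_frame, per_fish, qc, per_frame_csv, per_fish_csv, qc_log)


def evaluate_against_truth(per_fish: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Compare per-fish estimates with a ground-truth table.

    ``truth`` needs columns fish_id, mass_g and (optionally) density and
    volume_mm3.  Returns the density model fitted from (estimated volume,
    true mass), the predicted-vs-true mass regression report using that
    fitted density, and per-fish relative errors.
    """
    merged = per_fish.merge(truth, on="fish_id", suffixes=("", "_true"))
    merged = merged[merged.n_frames >= 2].copy()
    if len(merged) < 2:
        raise ValueError("need at least two fish with surviving frames")
    model = mass_mod.fit_density(list(zip(merged.mean_volume_mm3, merged.mass_g)))
    merged["pred_mass_g"] = [mass_mod.volume_to_mass(v, model) for v in merged.mean_volume_mm3]
    report: RegressionReport = regression_metrics(merged.pred_mass_g, merged.mass_g)
    rel_err = np.abs(merged.pred_mass_g.to_numpy() / merged.mass_g.to_numpy() - 1.0)
    return dict(
        density=model,
        regression=report,
        per_fish=merged,
        rel_mass_errors=rel_err,
        frac_within_10pct=float(np.mean(rel_err <= 0.10)),
    )
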