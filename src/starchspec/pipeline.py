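"""Configuration-driven pipeline: cubes -> features -> selection -> models.

The driver chains every stage and emits a five-row comparison in the shape of
a chemometrics results table (columns data, NVs, LVs, Rc, RMSEC, Rp, RMSEP,
RPD), one row per predictor set:

    raw spectra (428) | SNV spectra (428) | texture (12)
    | low-level fusion (440) | mid-level fusion (CARS + correlation selection)

Each stage writes its output to the run directory and the next stage reads it
back, so stages are individually re-runnable from cached intermediates and a
rerun at a fixed seed is byte-identical. Variable selection (CARS and the
texture correlation screen) sees calibration samples only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemometrics import EvalReport, evaluate, pls_fit, rank_order_split, select_lv_cv
from .cube_io import Hypercube, read_cube, read_npz
from .pc_imagery import pca_score_images
from .selection import (
    CARSConfig,
    CARSResult,
    SelectionReport,
    cars_select,
    correlation_select,
    fuse_low,
    fuse_mid,
)
from .spectra import SpectrumTable, extract_roi, mean_spectrum, snv
from .synth import SimConfig, VarietySpec, iter_dataset
from .texture import TextureTable, texture_feature_names, texture_vector

__all__ = ["RunConfig", "run_pipeline", "extract_stage", "select_stage", "fit_stage", "report_stage"]

MODEL_ORDER = ["Raw spectra", "SNV preprocessed", "Texture", "Low-level fusion", "Mid-level fusion"]


@dataclass
class RunConfig:
    """Everything one run needs; serialised in full into the run log."""

    out_dir: str | Path = "run"
    mode: str = "simulate"            # "simulate" | "cubes"
    cube_dir: str | None = None       # cubes mode: directory of .hdr/.npz cubes
    reference_csv: str | None = None  # cubes mode: sample_id,variety,starch_g_per_100g
    roi_size: int = 100
    glcm_levels: int = 64
    glcm_distance: int = 1
    n_pc: int = 3
    corr_threshold: float = 0.3
    max_lv: int = 15
    cv_folds: int = 5
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    cars: CARSConfig = field(default_factory=CARSConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "cubes"):
            raise ValueError("mode must be 'simulate' or 'cubes'")
        if self.mode == "cubes" and (self.cube_dir is None or self.reference_csv is None):
            raise ValueError("cubes mode requires cube_dir and reference_csv")
        # one master seed drives generation, CARS and CV unless overridden
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.cars = dataclasses.replace(self.cars, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        sim_raw = raw.pop("sim", {})
        varieties = [VarietySpec(**v) for v in sim_raw.pop("varieties", [])] or None
        sim = SimConfig(**sim_raw) if varieties is None else SimConfig(varieties=varieties, **sim_raw)
        cars = CARSConfig(**raw.pop("cars", {}))
        return cls(sim=sim, cars=cars, **raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        return d


# ---------------------------------------------------------------------------
# Cube sources
# ---------------------------------------------------------------------------

def _iter_cubes(config: RunConfig) -> Iterator[tuple[str, str, float, Hypercube]]:
    if config.mode == "simulate":
        yield from iter_dataset(config.sim)
        return
    ref = pd.read_csv(config.reference_csv)
    for col in ("sample_id", "variety", "starch_g_per_100g"):
        if col not in ref.columns:
            raise ValueError(f"reference CSV missing column '{col}'")
    cube_dir = Path(config.cube_dir)
    for _, row in ref.iterrows():
        sid = str(row["sample_id"])
        hdr, npz = cube_dir / f"{sid}.hdr", cube_dir / f"{sid}.npz"
        if hdr.exists():
            cube = read_cube(hdr)
        elif npz.exists():
            cube = read_npz(npz)
        else:
            raise FileNotFoundError(f"no cube ({sid}.hdr or {sid}.npz) for sample {sid} in {cube_dir}")
        yield sid, str(row["variety"]), float(row["starch_g_per_100g"]), cube


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def extract_stage(config: RunConfig) -> Path:
    """Cubes -> reference.csv, spectra_raw.csv, spectra_snv.csv, texture.csv."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids: list[str] = []
    varieties: list[str] = []
    starch: list[float] = []
    spectra_rows: list[np.ndarray] = []
    texture_rows: list[np.ndarray] = []
    wavelengths = None
    for sid, variety, y, cube in _iter_cubes(config):
        try:
            roi = extract_roi(cube, size=config.roi_size)
            spectra_rows.append(mean_spectrum(roi))
            stack = pca_score_images(roi, n_components=config.n_pc, sample_id=sid)
            texture_rows.append(
                texture_vector(stack, levels=config.glcm_levels, distance=config.glcm_distance)
            )
        except Exception as err:  # noqa: BLE001 - annotate failing sample
            raise RuntimeError(f"feature extraction failed for sample {sid}: {err}") from err
        wavelengths = cube.wavelengths
        ids.append(sid)
        varieties.append(variety)
        starch.append(y)
    if not ids:
        raise ValueError("no samples found")

    pd.DataFrame(
        {"sample_id": ids, "variety": varieties, "starch_g_per_100g": starch}
    ).to_csv(out / "reference.csv", index=False)
    raw = SpectrumTable(np.vstack(spectra_rows), wavelengths, ids)
    raw.to_csv(out / "spectra_raw.csv")
    snv(raw).to_csv(out / "spectra_snv.csv")
    TextureTable(
        np.vstack(texture_rows), texture_feature_names(config.n_pc), ids
    ).to_csv(out / "texture.csv")
    return out


def _load_features(out: Path):
    ref = pd.read_csv(out / "reference.csv")
    raw = SpectrumTable.from_csv(out / "spectra_raw.csv")
    snv_t = SpectrumTable.from_csv(out / "spectra_snv.csv")
    tex = TextureTable.from_csv(out / "texture.csv")
    return ref, raw, snv_t, tex


def select_stage(config: RunConfig) -> Path:
    """Calibration-set CARS + texture correlation screen -> selection.json."""
    out = Path(config.out_dir)
    ref, _, snv_t, tex = _load_features(out)
    y = ref["starch_g_per_100g"].to_numpy()
    split = rank_order_split(y, ids=list(ref["sample_id"].astype(str)))
    cal = ref["sample_id"].astype(str).isin(split.calibration_ids).to_numpy()

    cars = cars_select(snv_t.X[cal], y[cal], config.cars, wavelengths=snv_t.wavelengths)
    tex_df = tex.to_frame().set_index("sample_id")
    sel = correlation_select(tex_df[cal], y[cal], threshold=config.corr_threshold)

    payload = {
        "seed": config.seed,
        "calibration_ids": split.calibration_ids,
        "prediction_ids": split.prediction_ids,
        "cars": {
            "selected_indices": cars.selected_indices.tolist(),
            "selected_wavelengths_nm": np.round(cars.selected_wavelengths, 2).tolist(),
            "best_run": cars.best_run,
            "rmsecv_by_run": cars.rmsecv_by_run.tolist(),
            "retained_count_by_run": cars.retained_count_by_run.tolist(),
            "eliminated_pct": 100.0 * cars.eliminated_fraction(snv_t.n_bands),
        },
        "texture": {
            "r": sel.texture_r.to_dict(),
            "selected": sel.texture_selected,
            "threshold": sel.threshold,
        },
    }
    (out / "selection.json").write_text(json.dumps(payload, indent=2))
    return out


def _model_matrices(config: RunConfig, out: Path):
    ref, raw, snv_t, tex = _load_features(out)
    sel_payload = json.loads((out / "selection.json").read_text())
    ids = list(ref["sample_id"].astype(str))
    wl_cols = [f"{w:.2f}" for w in snv_t.wavelengths]
    raw_df = pd.DataFrame(raw.X, index=ids, columns=wl_cols)
    snv_df = pd.DataFrame(snv_t.X, index=ids, columns=wl_cols)
    tex_df = pd.DataFrame(tex.T, index=ids, columns=tex.feature_names)

    cars_idx = np.array(sel_payload["cars"]["selected_indices"], dtype=int)
    cars = CARSResult(cars_idx, snv_t.wavelengths[cars_idx], np.array([]), np.array([]), 0)
    sel = SelectionReport(
        pd.Series(sel_payload["texture"]["r"]),
        sel_payload["texture"]["selected"],
        sel_payload["texture"]["threshold"],
    )
    matrices = {
        "Raw spectra": raw_df,
        "SNV preprocessed": snv_df,
        "Texture": tex_df,
        "Low-level fusion": fuse_low(snv_df, tex_df),
        "Mid-level fusion": fuse_mid(snv_df, cars, tex_df, sel),
    }
    y = ref["starch_g_per_100g"].to_numpy()
    cal_ids, pred_ids = sel_payload["calibration_ids"], sel_payload["prediction_ids"]
    return matrices, y, ids, cal_ids, pred_ids


def fit_stage(config: RunConfig) -> Path:
    """Fit and score the five PLSR models -> eval_reports.json."""
    out = Path(config.out_dir)
    matrices, y, ids, cal_ids, pred_ids = _model_matrices(config, out)
    cal = np.isin(ids, cal_ids)
    pred = np.isin(ids, pred_ids)
    reports: dict[str, dict] = {}
    for name in MODEL_ORDER:
        M = matrices[name].to_numpy(float)
        best_lv, _ = select_lv_cv(
            M[cal], y[cal], max_lv=config.max_lv, folds=config.cv_folds, seed=config.seed
        )
        model = pls_fit(M[cal], y[cal], best_lv)
        report = evaluate(model, M[cal], y[cal], M[pred], y[pred])
        reports[name] = report.to_dict()
    (out / "eval_reports.json").write_text(json.dumps(reports, indent=2))
    return out


def report_stage(config: RunConfig) -> pd.DataFrame:
    """Assemble the comparison table and the run log."""
    out = Path(config.out_dir)
    reports = json.loads((out / "eval_reports.json").read_text())
    rows = []
    for name in MODEL_ORDER:
        r = reports[name]
        rows.append(
            {
                "data": name,
                "NVs": r["n_vars"],
                "LVs": r["n_lv"],
                "Rc": round(r["Rc"], 4),
                "RMSEC": round(r["RMSEC"], 2),
                "Rp": round(r["Rp"], 4),
                "RMSEP": round(r["RMSEP"], 2),
                "RPD": round(r["RPD"], 2),
            }
        )
    comparison = pd.DataFrame(rows)
    comparison.to_csv(out / "comparison.csv", index=False)
    (out / "run_log.json").write_text(
        json.dumps({"starchspec_version": __version__, "config": self_config_jsonable(config)}, indent=2)
    )
    return comparison


def self_config_jsonable(config: RunConfig) -> dict:
    return config.to_jsonable()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the comparison table, reports and selection."""
    out = Path(config.out_dir)
    extract_stage(config)
    select_stage(config)
    fit_stage(config)
    comparison = report_stage(config)
    reports = {
        name: EvalReport(**{k: v for k, v in d.items()})
        for name, d in json.loads((out / "eval_reports.json").read_text()).items()
    }
    selection = json.loads((out / "selection.json").read_text())
    return {"comparison": comparison, "reports": reports, "selection": selection, "out_dir": out}
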