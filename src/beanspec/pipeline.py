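"""End-to-end orchestration: simulate -> segment -> calibrate -> select
bands -> classify -> map, as one reproducible, manifest-writing run.

One global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` so any stage can be rerun in isolation and
the whole run is bit-reproducible for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import band_selection, classification, synthetic
from .calibration import cross_validate
from .components import build_component_library, default_band_grid
from .hypercube import calibrate_reflectance, remove_spikes, to_absorbance, trim_spectral_range
from .mapping import predict_map, render_map
from .segmentation import SpectralTable, extract_mean_spectra, label_objects, threshold_mask

__all__ = ["RunConfig", "run_pipeline", "PipelineStageError", "metrics_table"]

_STAGES = ("simulate", "segment", "calibrate", "select_bands", "classify", "map")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name, partial outputs retained."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Fully serializable run description; config + seed fix all outputs."""

    out_dir: str = "results/run"
    seed: int = 0
    n_scenes: int = 3
    beans_per_scene: int = 20
    n_calibration_beans: int = 300
    n_per_class: int = 200
    scene: dict = field(default_factory=dict)  # SceneSpec overrides
    spectral_range: tuple[float, float] = (980.0, 2480.0)
    n_bands: int = 256
    chains: tuple[str, ...] = ("log1r", "mean_center", "savgol:1", "savgol:2", "snv")
    targets: tuple[str, ...] = ("moisture_pct", "fat_pct_dmb")
    max_lv: int = 12
    cv_segments: int = 10
    band_counts: tuple[int, ...] = (42, 22, 6)
    svm_c_grid: tuple[float, ...] = tuple(float(2.0 ** e) for e in range(-3, 12, 2))
    svm_gamma_grid: tuple[float, ...] = tuple(float(2.0 ** e) for e in range(-13, 2, 2))
    render_maps: bool = True

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("chains", "targets", "band_counts", "spectral_range",
                    "svm_c_grid", "svm_gamma_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.n_calibration_beans < self.cv_segments:
            raise ValueError("need at least cv_segments calibration beans")
        for t in self.targets:
            if t not in ("moisture_pct", "fat_pct_dmb", "fat_pct_asis"):
                raise ValueError(f"unknown target column {t!r}")

    def child_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(_STAGES))
        return {stage: int(c.generate_state(1)[0] % (2 ** 31))
                for stage, c in zip(_STAGES, children)}


def metrics_table(panel: dict[str, "ModelMetrics"]) -> pd.DataFrame:
    """Pre-treatment x metric table shaped like a calibration report."""
    rows = []
    for chain_name, metrics in panel.items():
        row = {"pre_treatment": chain_name}
        row.update(metrics.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def _trim_table(table: SpectralTable, lo: float, hi: float) -> SpectralTable:
    keep = np.nonzero((table.wavelengths >= lo) & (table.wavelengths <= hi))[0]
    return table.subset_bands(keep)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    seeds = config.child_seeds()
    lib = build_component_library(default_band_grid(config.n_bands))
    manifest: dict = {
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in dataclasses.asdict(config).items()},
        "seeds": seeds,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    lo, hi = config.spectral_range

    def _run(stage, fn):
        t0 = time.time()
        try:
            out = fn()
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(config, manifest)
            raise PipelineStageError(stage, exc) from exc
        entry = {"status": "ok", "elapsed_s": round(time.time() - t0, 2)}
        if out:
            entry.update(out)
        manifest["stages"][stage] = entry
        return entry

    state: dict = {}

    # -- simulate ------------------------------------------------------
    def simulate():
        scenes = []
        for i in range(config.n_scenes):
            spec = synthetic.SceneSpec(
                n_beans=config.beans_per_scene, seed=seeds["simulate"] + i,
                **config.scene,
            )
            scenes.append(synthetic.generate_scene(spec, lib))
        state["scenes"] = scenes
        return {"n_scenes": len(scenes)}

    _run("simulate", simulate)

    # -- segment -------------------------------------------------------
    def segment():
        recovered, truth_counts = [], []
        tables, maps = [], []
        for cube, white, dark, truth in state["scenes"]:
            refl = calibrate_reflectance(cube, white, dark)
            absorb = remove_spikes(to_absorbance(refl))
            mask = threshold_mask(absorb)
            omap = label_objects(mask)
            table = extract_mean_spectra(trim_spectral_range(absorb, lo, hi), omap)
            tables.append(table)
            maps.append((absorb, omap, truth))
            recovered.append(omap.n_objects)
            truth_counts.append(truth.n_beans)
        state["segmented"] = maps
        state["scene_tables"] = tables
        return {"objects_recovered": recovered, "objects_true": truth_counts}

    _run("segment", segment)

    # -- calibrate -----------------------------------------------------
    def calibrate():
        table = synthetic.generate_calibration_table(
            config.n_calibration_beans,
            spec=synthetic.SceneSpec(**config.scene),
            lib=lib, seed=seeds["calibrate"],
        )
        table = _trim_table(table, lo, hi)
        state["cal_table"] = table
        out = {}
        state["models"] = {}
        for target in config.targets:
            y = table.y(target)
            panel = {}
            best_name, best_model = None, None
            for chain_name in config.chains:
                _, model = cross_validate(
                    table.X, y, chain_name, max_lv=config.max_lv,
                    n_segments=config.cv_segments, seed=seeds["calibrate"],
                    wavelengths=table.wavelengths, target=target,
                )
                panel[chain_name] = model.metrics
                if best_model is None or model.metrics.rmsecv < best_model.metrics.rmsecv:
                    best_name, best_model = chain_name, model
            df = metrics_table(panel)
            path = os.path.join(config.out_dir, f"calibration_{target}.csv")
            df.to_csv(path, index=False)
            state["models"][target] = best_model
            out[target] = {
                "best_chain": best_name,
                "n_lv": best_model.n_lv,
                "r2_cv": round(best_model.metrics.r2_cv, 4),
                "rmsecv": round(best_model.metrics.rmsecv, 4),
                "rpd": round(best_model.metrics.rpd, 3),
                "table": path,
            }
        return out

    _run("calibrate", calibrate)

    # -- select bands --------------------------------------------------
    def select_bands():
        table = state["cal_table"]
        out = {}
        for target, model in state["models"].items():
            y = table.y(target)
            rows = []
            for n_bands in config.band_counts:
                subset = band_selection.select_by_beta(model, n_bands)
                _, metrics = band_selection.refit_reduced(
                    table, y, subset, method="mlr",
                    n_segments=config.cv_segments, seed=seeds["select_bands"],
                    target=target,
                )
                rows.append({"n_bands": n_bands, "method": "mlr",
                             "threshold": subset.threshold,
                             **metrics.as_row()})
            rows.append({"n_bands": table.wavelengths.size, "method": "pls",
                         "threshold": 0.0, **model.metrics.as_row()})
            df = pd.DataFrame(rows)
            path = os.path.join(config.out_dir, f"band_selection_{target}.csv")
            df.to_csv(path, index=False)
            out[target] = path
        return {"tables": out}

    _run("select_bands", select_bands)

    # -- classify ------------------------------------------------------
    def classify():
        table, labels = synthetic.generate_two_species_set(
            config.n_per_class, lib=lib, seed=seeds["classify"],
        )
        table = _trim_table(table, lo, hi)
        from .preprocessing import parse_chain

        chain = parse_chain("snv").fit(table.X)
        Xp = chain.transform(table.X)
        lda = classification.fit_lda(Xp, labels, function="linear")
        _, resub_cm, resub_correct, _ = classification.classify(lda, Xp, labels)
        lda_cv = classification.cv_accuracy(
            lambda Xtr, ytr: classification.fit_lda(Xtr, ytr, function="linear"),
            Xp, labels, n_segments=config.cv_segments, seed=seeds["classify"],
        )
        svm, (svm_train, svm_cv) = classification.fit_svm(
            Xp, labels, kernel="rbf",
            C_grid=config.svm_c_grid, gamma_grid=config.svm_gamma_grid,
            n_segments=config.cv_segments, seed=seeds["classify"],
        )
        state["classifiers"] = {"lda": lda, "svm": svm}
        return {
            "lda_resubstitution_pct": round(resub_correct, 2),
            "lda_cv_pct": round(100 * lda_cv, 2),
            "svm_train_pct": round(100 * svm_train, 2),
            "svm_cv_pct": round(100 * svm_cv, 2),
            "svm_params": {k: svm.params[k] for k in ("C", "gamma", "kernel")},
        }

    _run("classify", classify)

    # -- map -----------------------------------------------------------
    def chemical_map():
        absorb, omap, truth = state["segmented"][0]
        absorb = trim_spectral_range(absorb, lo, hi)
        out = {}
        for target, model in state["models"].items():
            pmap = predict_map(absorb, omap, model, constituent=target)
            csv_path = os.path.join(config.out_dir, f"map_{target}_means.csv")
            pmap.per_object.to_csv(csv_path, index=False)
            entry = {"per_bean_means": csv_path}
            if config.render_maps:
                png = os.path.join(config.out_dir, f"map_{target}.png")
                render_map(pmap, png, title=target)
                entry["png"] = png
            out[target] = entry
        return {"maps": out}

    _run("map", chemical_map)

    _write_manifest(config, manifest)
    return manifest


def _write_manifest(config: RunConfig, manifest: dict) -> str:
    path = os.path.join(config.out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
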