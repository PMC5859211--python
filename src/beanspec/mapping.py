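"""Per-pixel chemical maps from a fitted calibration.

Applying the regression coefficients to every foreground pixel's
spectrum turns a hypercube into an image of predicted constituent
concentration, with per-bean averages computed as the arithmetic mean of
each bean's pixel predictions. Pixels whose pre-treatment is undefined
(a perfectly constant spectrum under SNV, say) become missing values and
are counted, not propagated as errors — such pixels occur at bean edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import MLRModel, PLSModel
from .hypercube import Hypercube
from .segmentation import ObjectMap

__all__ = ["PredictionMap", "predict_map", "render_map"]


@dataclass
class PredictionMap:
    """Per-pixel predictions (NaN outside objects) + per-object summary."""

    values: np.ndarray
    object_map: ObjectMap
    per_object: pd.DataFrame  # object_id, mean_prediction, n_pixels, n_failed
    constituent: str = ""
    basis: str = ""
    model_id: str = ""

    @property
    def n_objects(self) -> int:
        return len(self.per_object)


def predict_map(cube: Hypercube, object_map: ObjectMap,
                model: PLSModel | MLRModel,
                constituent: str = "", basis: str = "") -> PredictionMap:
    """Apply the calibration at single-pixel level inside each object.

    The model's pre-treatment chain runs on each pixel spectrum
    independently (fitted statistics such as the MSC reference are
    reused, never refitted). Background pixels stay missing; an
    all-background map returns an empty summary without error.
    """
    labels = object_map.labels
    if labels.shape != cube.shape[:2]:
        raise ValueError("object map does not match cube spatial dimensions")
    if model.chain is not None and model.chain.has_step("msc") and not model.chain._fitted:
        raise ValueError("model chain requires fitted state that was never stored")
    K = object_map.n_objects
    values = np.full(labels.shape, np.nan)
    fg = labels > 0
    n_failed = np.zeros(K, dtype=int)
    if fg.any():
        pix = np.asarray(cube.cube, dtype=float)[fg]
        pix_labels = labels[fg]
        ok = np.ones(len(pix), dtype=bool)
        if model.chain is not None and model.chain.has_step("snv"):
            # tolerance, not == 0: an (almost) constant spectrum makes the
            # SNV scale numerically meaningless, not just exactly undefined
            ok &= pix.std(axis=1, ddof=1) > 1e-10 * (1 + np.abs(pix).max(axis=1))
        if model.chain is not None and model.chain.has_step("normalize"):
            ok &= np.linalg.norm(pix, axis=1) > 0
        preds = np.full(len(pix), np.nan)
        if ok.any():
            from .calibration import predict

            preds[ok] = predict(model, pix[ok])
        values[fg] = preds
        n_failed = np.bincount(pix_labels[~ok], minlength=K + 1)[1:]

    rows = []
    for k in range(1, K + 1):
        vals = values[labels == k]
        good = vals[np.isfinite(vals)]
        rows.append({
            "object_id": k,
            "mean_prediction": float(good.mean()) if good.size else np.nan,
            "n_pixels": int((labels == k).sum()),
            "n_failed": int(n_failed[k - 1]),
        })
    per_object = pd.DataFrame(rows, columns=["object_id", "mean_prediction",
                                             "n_pixels", "n_failed"])
    return PredictionMap(values, object_map, per_object,
                         constituent=constituent, basis=basis,
                         model_id=getattr(model, "target", ""))


def render_map(pmap: PredictionMap, out_path, value_range=None,
               annotate_means: bool = True, cmap: str = "viridis",
               title: str | None = None) -> str:
    """False-color PNG of the map with per-bean mean annotations.

    Values outside ``value_range`` are clamped to the endpoints.
    Deterministic for fixed inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = pmap.values
    if value_range is None:
        finite = vals[np.isfinite(vals)]
        value_range = (float(finite.min()), float(finite.max())) if finite.size else (0.0, 1.0)
    lo, hi = value_range
    shown = np.clip(vals, lo, hi)

    fig, ax = plt.subplots(figsize=(7, 7 * vals.shape[0] / max(vals.shape[1], 1)))
    im = ax.imshow(np.ma.masked_invalid(shown), cmap=cmap, vmin=lo, vmax=hi,
                   interpolation="nearest")
    ax.set_facecolor("black")
    ax.set_xticks([])
    ax.set_yticks([])
    label = pmap.constituent or "prediction"
    if pmap.basis:
        label += f" ({pmap.basis})"
    fig.colorbar(im, ax=ax, label=f"{label} %")
    if title:
        ax.set_title(title)
    if annotate_means and pmap.n_objects:
        cents = pmap.object_map.centroids()
        for (r, c), mean in zip(cents, pmap.per_object["mean_prediction"]):
            ax.text(c, r, f"{mean:.1f}", color="white", ha="center", va="center",
                    fontsize=9,
                    bbox=dict(facecolor="black", alpha=0.5, pad=1, edgecolor="none"))
    fig.savefig(out_path, dpi=120, bbox_inches="tight",
                metadata={"Software": "beanspec"})
    plt.close(fig)
    return str(out_path)
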