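"""Wavelength reduction by thresholding PLS regression coefficients.

Bands whose |beta| falls below a cut-off carry little weight in the full
model and are dropped; the survivors feed a reduced MLR (for emulating a
cheap filter-wheel multispectral sensor, where derivative pre-treatments
are impossible) or a reduced PLS model. The cut-off is parameterized by
the number of surviving bands — the presets 42 (moisture), 22 (fat) and
6 (minimal sensor) being the working points of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import MLRModel, PLSModel, cross_validate
from .preprocessing import PreprocessingChain, parse_chain
from .segmentation import SpectralTable

__all__ = ["BandSubset", "select_by_beta", "refit_reduced"]

PRESET_BAND_COUNTS = (42, 22, 6)


@dataclass(frozen=True)
class BandSubset:
    """Sorted, unique indices of retained bands and the |beta| cut-off."""

    indices: np.ndarray
    wavelengths: np.ndarray
    threshold: float
    parent_model: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        if idx.size == 0:
            raise ValueError("band subset is empty")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("indices must be sorted and unique")

    @property
    def n_bands(self) -> int:
        return self.indices.size


def select_by_beta(model: PLSModel | MLRModel, n_bands: int) -> BandSubset:
    """Keep the ``n_bands`` wavelengths with the largest |beta|.

    Equivalent to raising the |beta| threshold until exactly ``n_bands``
    survive; ties at the cut-off resolve toward larger |beta| first,
    then toward the lower wavelength.
    """
    beta = np.abs(np.asarray(model.beta, dtype=float))
    B = beta.size
    if not 1 <= n_bands <= B:
        raise ValueError(f"n_bands must lie in [1, {B}]")
    order = sorted(range(B), key=lambda i: (-beta[i], i))
    sel = np.array(sorted(order[:n_bands]))
    wl = model.wavelengths[sel] if model.wavelengths is not None else sel.astype(float)
    return BandSubset(
        indices=sel, wavelengths=np.asarray(wl, dtype=float),
        threshold=float(beta[order[n_bands - 1]]),
        parent_model=getattr(model, "target", ""),
    )


def refit_reduced(
    table: SpectralTable,
    y: np.ndarray,
    subset: BandSubset,
    method: str = "mlr",
    chain: PreprocessingChain | str | None = None,
    max_lv: int = 15,
    n_segments: int = 10,
    seed: int = 0,
    target: str = "",
):
    """Refit on the reduced band set; returns (model, ModelMetrics).

    For MLR the chain is forced to raw log(1/R): a filter instrument
    measuring a handful of discrete wavelengths cannot form derivatives.
    A chain containing a Savitzky-Golay step wider than the subset
    raises for PLS too.
    """
    if subset.indices.max() >= table.wavelengths.size:
        raise ValueError("band subset exceeds the table's wavelength axis")
    if isinstance(chain, str) or chain is None:
        chain = parse_chain(chain)
    if method == "mlr" and any(n != "none" for n in chain.names):
        chain = parse_chain("none")
    for name, params in chain.steps:
        if name == "savgol_derivative" and subset.n_bands < params.get("window", 9):
            raise ValueError(
                f"derivative window {params.get('window')} exceeds the "
                f"{subset.n_bands}-band subset"
            )
    sub_table = table.subset_bands(subset.indices)
    max_lv = min(max_lv, subset.n_bands)
    per_lv, model = cross_validate(
        sub_table.X, y, chain, max_lv=max_lv, n_segments=n_segments, seed=seed,
        method=method, wavelengths=sub_table.wavelengths, target=target,
    )
    return model, model.metrics
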