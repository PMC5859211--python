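"""Single-bean segmentation and per-object mean spectra.

Foreground detection follows the absorbance rule for seeds on a dark
stage: a pixel belongs to a bean when log10(1/R) at 1186 nm is below 1,
i.e. the pixel reflects more than 10 % of the incident light there.
Connected components are labelled, small residue dropped, and each bean
is summarized by the unweighted arithmetic mean of its pixel spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as _cc_label

from .hypercube import Hypercube

__all__ = ["ObjectMap", "SpectralTable", "threshold_mask", "label_objects",
           "extract_mean_spectra"]


@dataclass
class ObjectMap:
    """Integer label image: 0 = background, 1..K = individual beans."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def pixel_counts(self) -> np.ndarray:
        """Pixel count per object, index k-1 for label k."""
        return np.bincount(self.labels.ravel(), minlength=self.n_objects + 1)[1:]

    def centroids(self) -> np.ndarray:
        """(K, 2) array of (row, col) centroids in label order."""
        out = np.zeros((self.n_objects, 2))
        rr, cc = np.nonzero(self.labels)
        lab = self.labels[rr, cc]
        for k in range(1, self.n_objects + 1):
            sel = lab == k
            out[k - 1] = rr[sel].mean(), cc[sel].mean()
        return out


@dataclass
class SpectralTable:
    """Per-object mean spectra plus optional reference values.

    ``X`` is K objects x B bands; ``references`` holds per-object
    reference chemistry (moisture %, fat % ...) aligned with ``ids``;
    ``basis`` tags reference columns as "as is" or "dmb".
    """

    ids: np.ndarray
    wavelengths: np.ndarray
    X: np.ndarray
    references: pd.DataFrame | None = None
    basis: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.ids = np.asarray(self.ids)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.shape != (self.ids.size, self.wavelengths.size):
            raise ValueError("X must be (n objects) x (n wavelengths)")
        if not np.isfinite(self.X).all():
            raise ValueError("mean spectra contain non-finite values")
        if self.references is not None and len(self.references) != self.ids.size:
            raise ValueError("reference table length mismatch")

    @property
    def n_objects(self) -> int:
        return self.ids.size

    def y(self, column: str) -> np.ndarray:
        if self.references is None or column not in self.references:
            raise KeyError(f"no reference column {column!r}")
        return self.references[column].to_numpy(dtype=float)

    def subset_bands(self, indices: np.ndarray) -> "SpectralTable":
        indices = np.asarray(indices)
        return SpectralTable(self.ids, self.wavelengths[indices], self.X[:, indices],
                            self.references, dict(self.basis))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=[f"{w:.2f}" for w in self.wavelengths])
        df.insert(0, "bean_id", self.ids)
        if self.references is not None:
            for col in self.references.columns:
                df[col] = self.references[col].to_numpy()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectralTable":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c.replace(".", "", 1).isdigit()]
        ref_cols = [c for c in df.columns if c not in wl_cols and c != "bean_id"]
        refs = df[ref_cols].copy() if ref_cols else None
        return cls(
            ids=df["bean_id"].to_numpy(),
            wavelengths=np.array([float(c) for c in wl_cols]),
            X=df[wl_cols].to_numpy(dtype=float),
            references=refs,
        )


def threshold_mask(cube: Hypercube, wavelength_nm: float = 1186.0, cutoff: float = 1.0) -> np.ndarray:
    """Foreground mask: absorbance at the nearest band strictly below cutoff."""
    if cube.signal != "absorbance":
        raise ValueError("threshold_mask requires an absorbance cube")
    return cube.band(wavelength_nm) < cutoff


def label_objects(mask: np.ndarray, min_pixels: int = 50, connectivity: int = 8) -> ObjectMap:
    """Connected components of a binary mask, relabelled in raster order.

    Components smaller than ``min_pixels`` are dropped; surviving labels
    are renumbered 1..K by the raster position of each component's first
    pixel. An empty mask yields K = 0 without error.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    raw = _cc_label(mask, connectivity=1 if connectivity == 4 else 2)
    flat = raw.ravel()
    counts = np.bincount(flat)
    # first raster index of each label, for deterministic renumbering
    uniq, first = np.unique(flat, return_index=True)
    first_idx = np.full(counts.size, flat.size)
    first_idx[uniq] = first
    keep = [lab for lab in range(1, counts.size) if counts[lab] >= min_pixels]
    keep.sort(key=lambda lab: first_idx[lab])
    lut = np.zeros(counts.size, dtype=np.int32)
    for new, lab in enumerate(keep, start=1):
        lut[lab] = new
    return ObjectMap(lut[raw])


def extract_mean_spectra(cube: Hypercube, object_map: ObjectMap) -> SpectralTable:
    """Unweighted mean absorbance spectrum per labelled object."""
    labels = object_map.labels
    if labels.shape != cube.shape[:2]:
        raise ValueError("object map does not match cube spatial dimensions")
    K = object_map.n_objects
    counts = object_map.pixel_counts
    if K and counts.min() == 0:
        raise ValueError("object map contains an empty label")
    fg = labels > 0
    pix = np.asarray(cube.cube, dtype=float)[fg]  # (n_fg, B)
    sums = np.zeros((K, cube.n_bands))
    np.add.at(sums, labels[fg] - 1, pix)
    X = sums / counts[:, None] if K else sums
    return SpectralTable(ids=np.arange(1, K + 1), wavelengths=cube.wavelengths, X=X)
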