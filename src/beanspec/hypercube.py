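"""Hypercube container and radiometric operations.

A hypercube is a rows x cols x bands array with an ascending wavelength
axis. The ``signal`` tag records what the values mean: raw detector
``counts``, ``reflectance`` relative to a white reference, or
``absorbance`` log10(1/R).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Hypercube",
    "band_index",
    "calibrate_reflectance",
    "to_absorbance",
    "remove_spikes",
    "trim_spectral_range",
    "SIGNALS",
]

SIGNALS = ("counts", "reflectance", "absorbance")

#: floor on reflectance before taking log10, so absorbance caps at 6 AU
REFLECTANCE_EPS = 1e-6


@dataclass
class Hypercube:
    """3-D spectral image: two spatial axes by one spectral axis."""

    cube: np.ndarray
    wavelengths: np.ndarray
    signal: str = "counts"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.cube.ndim != 3:
            raise ValueError("cube must be rows x cols x bands")
        if self.wavelengths.ndim != 1 or np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.cube.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"cube has {self.cube.shape[2]} bands but wavelength axis has "
                f"{self.wavelengths.size}"
            )
        if self.signal not in SIGNALS:
            raise ValueError(f"unknown signal {self.signal!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cube.shape

    @property
    def n_bands(self) -> int:
        return self.cube.shape[2]

    def band(self, wavelength_nm: float) -> np.ndarray:
        """Single-band image at the grid wavelength nearest to the request."""
        return self.cube[:, :, band_index(self.wavelengths, wavelength_nm)]


def band_index(wavelengths: np.ndarray, wavelength_nm: float) -> int:
    """Index of the nearest grid wavelength; ties break to the lower one."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    if not (wavelengths[0] <= wavelength_nm <= wavelengths[-1]):
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside grid "
            f"[{wavelengths[0]}, {wavelengths[-1]}]"
        )
    # argmin returns the first minimum, i.e. the lower wavelength on a tie
    return int(np.argmin(np.abs(wavelengths - wavelength_nm)))


def _mean_frame(frame: np.ndarray, like: np.ndarray) -> np.ndarray:
    """Average a stack of reference frames; accept an already-averaged one."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == like.ndim + 1:  # stack of frames: average them
        frame = frame.mean(axis=0)
    return frame


def calibrate_reflectance(raw: Hypercube, white: np.ndarray, dark: np.ndarray) -> Hypercube:
    """Reflectance R = (raw - dark) / (white - dark), per pixel and band.

    ``white`` and ``dark`` may be single frames of the cube's shape (or a
    per-band vector) or stacks of repeated frames, which are averaged
    per band before use. Any band where the averaged white does not
    exceed the averaged dark raises, naming the first offending band.
    """
    cube = np.asarray(raw.cube, dtype=float)
    w = _mean_frame(white, cube)
    d = _mean_frame(dark, cube)
    denom = w - d
    bad = np.nonzero(~(np.min(denom.reshape(-1, denom.shape[-1]), axis=0) > 0))[0]
    if bad.size:
        lam = raw.wavelengths[bad[0]]
        raise ZeroDivisionError(
            f"white reference does not exceed dark at band {bad[0]} ({lam:.1f} nm)"
        )
    refl = (cube - d) / denom
    return Hypercube(refl, raw.wavelengths, signal="reflectance", metadata=dict(raw.metadata))


def to_absorbance(cube: Hypercube) -> Hypercube:
    """Absorbance A = log10(1 / max(R, 1e-6)); requires a reflectance cube."""
    if cube.signal != "reflectance":
        raise ValueError(f"to_absorbance requires a reflectance cube, got {cube.signal!r}")
    r = np.maximum(np.asarray(cube.cube, dtype=float), REFLECTANCE_EPS)
    a = -np.log10(r)
    return Hypercube(a, cube.wavelengths, signal="absorbance", metadata=dict(cube.metadata))


def remove_spikes(
    cube: Hypercube,
    window: int = 5,
    z_max: float = 5.0,
    min_scale: float = 0.01,
) -> Hypercube:
    """Hampel despiking along each pixel's spectral axis.

    A sample is replaced by the running median (window ``window``) when it
    deviates from it by more than ``z_max`` robust standard deviations.
    The robust SD is 1.4826 x the per-pixel median absolute deviation from
    the running median, floored at ``min_scale`` so that the curvature a
    genuine absorption band produces is never mistaken for a spike — with
    the defaults, only excursions beyond z_max * min_scale = 0.05 signal
    units can ever be touched.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    from scipy.ndimage import median_filter

    x = np.asarray(cube.cube, dtype=float)
    med = median_filter(x, size=(1, 1, window), mode="nearest")
    dev = x - med
    mad = np.median(np.abs(dev), axis=2, keepdims=True)
    scale = np.maximum(1.4826 * mad, min_scale)
    out = np.where(np.abs(dev) > z_max * scale, med, x)
    return Hypercube(out, cube.wavelengths, signal=cube.signal, metadata=dict(cube.metadata))


def trim_spectral_range(cube: Hypercube, lo_nm: float = 980.0, hi_nm: float = 2480.0) -> Hypercube:
    """Restrict the spectral axis to [lo_nm, hi_nm] (used before modelling)."""
    keep = (cube.wavelengths >= lo_nm) & (cube.wavelengths <= hi_nm)
    if not keep.any():
        raise ValueError("trim range excludes every band")
    return Hypercube(
        cube.cube[:, :, keep], cube.wavelengths[keep], signal=cube.signal,
        metadata=dict(cube.metadata),
    )
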