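"""Synthetic NIR component spectra for green coffee constituents.

Pure-component absorptivity spectra are modelled as sums of Gaussian
absorption bands placed at the wavelengths where the corresponding
chemical groups absorb in the 980-2500 nm short-wave infrared region:

* ``water``   — O-H combination/overtone bands at 1450 and 1940 nm, the
  1940 nm band being the strongest feature of a moist seed spectrum.
* ``lipid``   — C-H first/second overtone and combination bands at 1210,
  1725, 1760, 2310 and 2345 nm plus a weaker 1360 nm band.
* ``matrix``  — the broad, featureless carbohydrate/protein background of
  the dry bean matrix.
* ``marker``  — a caffeine/chlorogenic-acid-like component whose
  concentration differs strongly between coffee species.

Amplitudes are scaled so that a typical bean mixture (about 11 % water,
15 % fat on a wet basis, remainder matrix) yields absorbance in roughly
[0.1, 1.0] AU across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ComponentLibrary", "build_component_library", "default_band_grid"]

#: (center nm, width sigma nm, amplitude AU) triples per component.
_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "water": [
        (1450.0, 55.0, 2.2),
        (1940.0, 65.0, 3.0),
        (1150.0, 120.0, 0.30),
    ],
    "lipid": [
        (1210.0, 18.0, 0.90),
        (1360.0, 28.0, 0.45),
        (1725.0, 13.0, 1.50),
        (1760.0, 13.0, 1.25),
        (2310.0, 12.0, 1.70),
        (2345.0, 12.0, 1.45),
        (2080.0, 150.0, 0.20),
    ],
    "matrix": [
        (1200.0, 150.0, 0.25),
        (1580.0, 200.0, 0.35),
        (2100.0, 180.0, 0.45),
        (2350.0, 120.0, 0.30),
        (1700.0, 2000.0, 0.20),  # very broad: near-constant baseline
    ],
    "marker": [
        (1475.0, 20.0, 1.2),
        (1680.0, 22.0, 2.0),
        (2140.0, 26.0, 2.2),
    ],
}


def default_band_grid(n_bands: int = 256, lo: float = 980.0, hi: float = 2500.0) -> np.ndarray:
    """Evenly spaced wavelength grid emulating a 256-band SWIR spectrograph."""
    return np.linspace(lo, hi, n_bands)


@dataclass(frozen=True)
class ComponentLibrary:
    """Named unit-absorptivity spectra on a common wavelength grid.

    ``spectra[name]`` is absorbance per unit mass fraction, i.e. the
    absorbance contributed by a pixel whose composition is 100 % of that
    component.
    """

    band_grid: np.ndarray
    spectra: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        grid = np.asarray(self.band_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("band_grid must be a strictly increasing 1-D array")
        for name, s in self.spectra.items():
            if s.shape != grid.shape:
                raise ValueError(f"component {name!r} has wrong length")
            if np.any(s < 0):
                raise ValueError(f"component {name!r} has negative values")

    @property
    def names(self) -> list[str]:
        return list(self.spectra)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.spectra[name]

    def mixture(self, weights: dict[str, float | np.ndarray]) -> np.ndarray:
        """Beer-Lambert mixture: sum of weight * component spectra.

        Weights may be scalars (one spectrum) or arrays of shape (n,)
        (a batch of n spectra, returned as (n, B)).
        """
        out = None
        for name, w in weights.items():
            w = np.asarray(w, dtype=float)
            term = np.multiply.outer(w, self.spectra[name]) if w.ndim else w * self.spectra[name]
            out = term if out is None else out + term
        if out is None:
            raise ValueError("empty weight mapping")
        return out


def build_component_library(band_grid: np.ndarray) -> ComponentLibrary:
    """Evaluate the Gaussian band model on ``band_grid``.

    Raises ``ValueError`` for a non-ascending grid.
    """
    grid = np.asarray(band_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("band_grid must be a strictly increasing 1-D array")
    spectra = {}
    for name, bands in _BANDS.items():
        s = np.zeros_like(grid)
        for center, sigma, amp in bands:
            s += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
        spectra[name] = s
    return ComponentLibrary(band_grid=grid, spectra=spectra)
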