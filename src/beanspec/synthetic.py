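"""Synthetic single-bean hyperspectral scenes with known composition.

The generator emulates a push-broom SWIR imaging experiment on green
coffee beans: elliptical beans on a dark stage, each pixel's absorbance a
Beer-Lambert mixture of water, lipid, a species marker and the dry-bean
matrix, degraded by multiplicative/additive scatter and detector noise,
then folded back through the camera model (reflectance -> raw counts
between a dark and a white reference frame).

Default composition statistics reproduce the reference measurements of
the study population this package models: natural moisture 10.80 +/- 0.79 %
(oven basis), total fat 16.41 +/- 3.10 % on a dry-matter basis, and a
species-dependent fat split of 17.51 +/- 2.21 % (arabica) versus
12.63 +/- 1.85 % (robusta) with moisture shared between species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .components import ComponentLibrary, build_component_library, default_band_grid
from .hypercube import Hypercube

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "generate_scene",
    "generate_two_species_set",
    "generate_calibration_table",
    "write_scene",
    "SPECIES_FAT_DMB",
    "SPECIES_MARKER",
]

#: per-species fat % (dry-matter basis): mean, SD
SPECIES_FAT_DMB = {"arabica": (17.51, 2.21), "robusta": (12.63, 1.85)}

#: per-species caffeine/phenolic marker mass fraction: mean, SD.
#: Robusta carries roughly twice the caffeine + chlorogenic acids of
#: arabica; this is what makes whole-spectrum species discrimination far
#: sharper than the overlapping fat distributions alone would allow.
SPECIES_MARKER = {"arabica": (0.020, 0.004), "robusta": (0.040, 0.006)}


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Scatter follows the standard model MSC/SNV assume: per-pixel
    absorbance is scaled by N(1, scatter_slope_sd) and offset by
    N(0, scatter_offset_sd) before N(0, noise_sd) detector noise is
    added (all in AU).
    """

    rows: int = 180
    cols: int = 220
    n_beans: int = 12
    axis_range_px: tuple[float, float] = (10.0, 16.0)
    moisture_mean: float = 10.80
    moisture_sd: float = 0.79
    fat_dmb_mean: float = 16.41
    fat_dmb_sd: float = 3.10
    species: str | tuple[str, ...] = "arabica"
    species_fat: bool = False  # draw fat from the per-species distributions
    scatter_slope_sd: float = 0.07
    scatter_offset_sd: float = 0.03
    noise_sd: float = 0.005
    background_reflectance: float = 0.05
    gradient_amplitude: float = 0.08
    white_counts: float = 9000.0
    dark_counts: float = 120.0
    ref_frames: int = 100
    ref_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.background_reflectance < 0.1:
            raise ValueError("background reflectance must lie in (0, 0.1) so the "
                             "background fails the absorbance < 1 foreground test")
        if not (0 < self.moisture_mean < 100 and 0 < self.fat_dmb_mean < 100):
            raise ValueError("moisture and fat percentages must lie in (0, 100)")
        if self.n_beans < 1:
            raise ValueError("n_beans must be >= 1")

    def species_of(self, k: int) -> str:
        if isinstance(self.species, str):
            return self.species
        return self.species[k % len(self.species)]


@dataclass
class GroundTruth:
    """True object map and per-bean / per-pixel composition of a scene."""

    object_map: np.ndarray
    beans: pd.DataFrame  # bean_id, row_c, col_c, moisture_pct, fat_pct_dmb, species
    moisture_map: np.ndarray = field(repr=False, default=None)
    fat_dmb_map: np.ndarray = field(repr=False, default=None)

    @property
    def n_beans(self) -> int:
        return len(self.beans)


def _draw_compositions(rng: np.random.Generator, spec: SceneSpec) -> pd.DataFrame:
    """Per-bean moisture %, fat % dmb, marker fraction and species label."""
    n = spec.n_beans
    species = [spec.species_of(k) for k in range(n)]
    moisture = rng.normal(spec.moisture_mean, spec.moisture_sd, size=n)
    if spec.species_fat:
        fat = np.array([rng.normal(*SPECIES_FAT_DMB[s]) for s in species])
    else:
        fat = rng.normal(spec.fat_dmb_mean, spec.fat_dmb_sd, size=n)
    marker = np.array([rng.normal(*SPECIES_MARKER[s]) for s in species])
    moisture = np.clip(moisture, 0.5, 60.0)
    fat = np.clip(fat, 0.5, 40.0)
    marker = np.clip(marker, 0.002, 0.12)
    return pd.DataFrame(
        {"moisture_pct": moisture, "fat_pct_dmb": fat, "marker_frac": marker,
         "species": species}
    )


def _place_beans(rng: np.random.Generator, spec: SceneSpec, max_tries: int = 5000):
    """Non-overlapping axis-aligned ellipses; (row_c, col_c, a_row, b_col)."""
    lo, hi = spec.axis_range_px
    placed: list[tuple[float, float, float, float]] = []
    for _ in range(spec.n_beans):
        for attempt in range(max_tries):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            r0 = rng.uniform(a + 2, spec.rows - a - 2)
            c0 = rng.uniform(b + 2, spec.cols - b - 2)
            radius = max(a, b)
            ok = all(
                np.hypot(r0 - rr, c0 - cc) > radius + max(aa, bb) + 2
                for rr, cc, aa, bb in placed
            )
            if ok:
                placed.append((r0, c0, a, b))
                break
        else:
            raise RuntimeError(
                f"could not place bean {len(placed) + 1} of {spec.n_beans} "
                f"without overlap after {max_tries} tries; enlarge the scene"
            )
    return placed


def generate_scene(
    spec: SceneSpec,
    lib: ComponentLibrary | None = None,
) -> tuple[Hypercube, np.ndarray, np.ndarray, GroundTruth]:
    """Render one scene; returns (raw counts cube, white, dark, truth).

    Composition inside each bean follows a mild radial gradient (moisture
    highest at the core, fat highest toward the surface) so within-bean
    chemical maps are non-constant; the per-bean values recorded in the
    ground truth are the exact means over that bean's pixels. The raw
    cube is returned in float precision — quantization to 16-bit counts
    happens only when a scene is written to disk.
    """
    if lib is None:
        lib = build_component_library(default_band_grid())
    rng = np.random.default_rng(spec.seed)
    grid = lib.band_grid
    B = grid.size
    rows, cols = spec.rows, spec.cols

    comp = _draw_compositions(rng, spec)
    placed = _place_beans(rng, spec)

    object_map = np.zeros((rows, cols), dtype=np.int32)
    moisture_map = np.full((rows, cols), np.nan)
    fat_map = np.full((rows, cols), np.nan)
    marker_map = np.zeros((rows, cols))

    rr, cc = np.mgrid[0:rows, 0:cols]
    g = spec.gradient_amplitude
    for k, (r0, c0, a, b) in enumerate(placed):
        rho2 = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2
        inside = rho2 <= 1.0
        object_map[inside] = k + 1
        m_k = comp.loc[k, "moisture_pct"]
        f_k = comp.loc[k, "fat_pct_dmb"]
        # mean of rho2 over a filled ellipse is 1/2, so the bean-mean
        # composition stays close to the drawn value; truth records the
        # exact pixel mean below
        moisture_map[inside] = m_k * (1.0 + g * (0.5 - rho2[inside]))
        fat_map[inside] = f_k * (1.0 + g * (rho2[inside] - 0.5))
        marker_map[inside] = comp.loc[k, "marker_frac"]

    fg = object_map > 0
    m_frac = moisture_map[fg] / 100.0
    f_frac = fat_map[fg] / 100.0 * (1.0 - m_frac)  # dmb -> wet-mass fraction
    c_frac = marker_map[fg]
    weights = {
        "water": m_frac,
        "lipid": f_frac,
        "marker": c_frac,
        "matrix": 1.0 - m_frac - f_frac - c_frac,
    }
    absorb_fg = lib.mixture(weights)  # (n_fg, B)

    slope = rng.normal(1.0, spec.scatter_slope_sd, size=(absorb_fg.shape[0], 1))
    offset = rng.normal(0.0, spec.scatter_offset_sd, size=(absorb_fg.shape[0], 1))
    absorb_fg = slope * absorb_fg + offset
    absorb_fg = absorb_fg + rng.normal(0.0, spec.noise_sd, size=absorb_fg.shape)

    bg_absorb = -np.log10(spec.background_reflectance)
    absorbance = np.full((rows, cols, B), bg_absorb)
    if spec.noise_sd > 0:
        absorbance[~fg] += rng.normal(0.0, spec.noise_sd, size=(int((~fg).sum()), B))
    absorbance[fg] = absorb_fg

    reflectance = 10.0 ** (-absorbance)

    # camera model: smooth illumination profile between dark and white level
    illum = 1.0 - 0.15 * ((grid - grid.mean()) / (grid[-1] - grid[0])) ** 2 * 4
    white_level = spec.dark_counts + (spec.white_counts - spec.dark_counts) * illum
    if spec.ref_noise_sd > 0 and spec.ref_frames > 1:
        # reference frames are recorded ~ref_frames times and averaged
        white = white_level + rng.normal(
            0.0, spec.ref_noise_sd / np.sqrt(spec.ref_frames), size=(rows, cols, B)
        )
        dark = spec.dark_counts + rng.normal(
            0.0, spec.ref_noise_sd / np.sqrt(spec.ref_frames), size=(rows, cols, B)
        )
    else:
        white = np.broadcast_to(white_level, (rows, cols, B)).copy()
        dark = np.full((rows, cols, B), spec.dark_counts)

    raw = dark + reflectance * (white - dark)

    centroids = pd.DataFrame(placed, columns=["row_c", "col_c", "a_row", "b_col"])
    beans = pd.DataFrame(
        {
            "bean_id": np.arange(1, spec.n_beans + 1),
            "row_c": centroids["row_c"],
            "col_c": centroids["col_c"],
            "moisture_pct": [moisture_map[object_map == k + 1].mean() for k in range(spec.n_beans)],
            "fat_pct_dmb": [fat_map[object_map == k + 1].mean() for k in range(spec.n_beans)],
            "species": comp["species"],
        }
    )
    truth = GroundTruth(object_map, beans, moisture_map, fat_map)
    cube = Hypercube(raw, grid, signal="counts", metadata={"seed": spec.seed})
    return cube, white, dark, truth


def _mean_spectra_for(
    rng: np.random.Generator,
    lib: ComponentLibrary,
    moisture_pct: np.ndarray,
    fat_dmb_pct: np.ndarray,
    marker_frac: np.ndarray,
    scatter_slope_sd: float,
    scatter_offset_sd: float,
    noise_sd: float,
) -> np.ndarray:
    """Per-bean mean absorbance spectra with scatter and noise applied."""
    m = moisture_pct / 100.0
    f = fat_dmb_pct / 100.0 * (1.0 - m)
    X = lib.mixture(
        {"water": m, "lipid": f, "marker": marker_frac,
         "matrix": 1.0 - m - f - marker_frac}
    )
    n = X.shape[0]
    X = rng.normal(1.0, scatter_slope_sd, (n, 1)) * X
    X = X + rng.normal(0.0, scatter_offset_sd, (n, 1))
    return X + rng.normal(0.0, noise_sd, X.shape)


def generate_calibration_table(
    n_beans: int,
    spec: SceneSpec | None = None,
    lib: ComponentLibrary | None = None,
    seed: int | None = None,
):
    """Per-bean mean spectra + reference values, skipping the imaging step.

    Statistically equivalent to rendering scenes and extracting mean
    spectra, but at the bean level: each bean contributes one spectrum at
    its own composition with one scatter realization and independent
    band noise. Returns a :class:`~beanspec.segmentation.SpectralTable`
    whose reference frame has moisture_pct, fat_pct_dmb, fat_pct_asis and
    species columns.
    """
    from .segmentation import SpectralTable

    spec = spec if spec is not None else SceneSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    spec = replace(spec, n_beans=n_beans)
    if lib is None:
        lib = build_component_library(default_band_grid())
    rng = np.random.default_rng(spec.seed)
    comp = _draw_compositions(rng, spec)
    X = _mean_spectra_for(
        rng, lib,
        comp["moisture_pct"].to_numpy(), comp["fat_pct_dmb"].to_numpy(),
        comp["marker_frac"].to_numpy(),
        spec.scatter_slope_sd, spec.scatter_offset_sd, spec.noise_sd,
    )
    refs = comp.drop(columns="marker_frac").copy()
    refs["fat_pct_asis"] = refs["fat_pct_dmb"] * (1.0 - refs["moisture_pct"] / 100.0)
    return SpectralTable(
        ids=np.arange(1, n_beans + 1), wavelengths=lib.band_grid, X=X,
        references=refs, basis={"fat_pct_dmb": "dmb", "fat_pct_asis": "as is"},
    )


def generate_two_species_set(
    n_per_class: int,
    spec: SceneSpec | None = None,
    lib: ComponentLibrary | None = None,
    seed: int | None = None,
):
    """Balanced arabica/robusta spectral table for classification work.

    Fat (dmb) is drawn from the species-specific normals, moisture from
    one shared distribution, and the caffeine/phenolic marker from the
    species-specific levels. Returns (SpectralTable, labels array).
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 beans per class")
    spec = spec if spec is not None else SceneSpec()
    spec = replace(
        spec,
        n_beans=2 * n_per_class,
        species=tuple(["arabica"] * n_per_class + ["robusta"] * n_per_class),
        species_fat=True,
    )
    if seed is not None:
        spec = replace(spec, seed=seed)
    table = generate_calibration_table(spec.n_beans, spec=spec, lib=lib)
    labels = table.references["species"].to_numpy()
    return table, labels


def write_scene(out_dir, cube, white, dark, truth, stem: str = "scene"):
    """Persist one scene: ENVI cube + reference frames, truth CSV, label PNG."""
    import os

    from .envi import write_envi

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, arr in (("cube", cube.cube), ("white", white), ("dark", dark)):
        hc = Hypercube(arr, cube.wavelengths, signal="counts")
        hdr = os.path.join(out_dir, f"{stem}_{name}.hdr")
        write_envi(hc, hdr, interleave="bil")
        paths[name] = hdr
    truth_csv = os.path.join(out_dir, f"{stem}_truth.csv")
    truth.beans.to_csv(truth_csv, index=False)
    paths["truth"] = truth_csv
    try:
        from PIL import Image

        png = os.path.join(out_dir, f"{stem}_labels.png")
        Image.fromarray(truth.object_map.astype(np.uint16)).save(png)
        paths["labels"] = png
    except ImportError:  # pragma: no cover - pillow ships with matplotlib
        warnings.warn("Pillow unavailable; label image not written")
    return paths
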