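"""Segment the simulated scenes and extract per-bean mean spectra.

Reads the ENVI scenes written by 01_simulate_scenes.py, calibrates raw
counts to reflectance against the white/dark references, converts to
absorbance, despikes, masks the foreground with the log10(1/R_1186) < 1
rule, labels the beans and writes one mean-spectrum table per scene with
the ground-truth reference values joined on.
"""

import argparse
import glob
import os

import pandas as pd

from beanspec.envi import read_envi
from beanspec.hypercube import calibrate_reflectance, remove_spikes, to_absorbance, trim_spectral_range
from beanspec.segmentation import extract_mean_spectra, label_objects, threshold_mask


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scenes", default="results/scenes")
    parser.add_argument("--out", default="results/tables")
    args = parser.parse_args()

    os.makedirs(args.out, exist_ok=True)
    for cube_hdr in sorted(glob.glob(os.path.join(args.scenes, "*_cube.hdr"))):
        stem = os.path.basename(cube_hdr)[: -len("_cube.hdr")]
        raw = read_envi(cube_hdr)
        white = read_envi(cube_hdr.replace("_cube", "_white"))
        dark = read_envi(cube_hdr.replace("_cube", "_dark"))
        absorb = remove_spikes(to_absorbance(
            calibrate_reflectance(raw, white.cube, dark.cube)))
        absorb = trim_spectral_range(absorb)
        omap = label_objects(threshold_mask(absorb))
        table = extract_mean_spectra(absorb, omap)
        truth = pd.read_csv(os.path.join(args.scenes, f"{stem}_truth.csv"))
        # beans are labelled in raster order; match them to truth by centroid
        cents = omap.centroids()
        matched = []
        for r, c in cents:
            d2 = (truth["row_c"] - r) ** 2 + (truth["col_c"] - c) ** 2
            matched.append(truth.loc[d2.idxmin()])
        table.references = pd.DataFrame(matched).reset_index(drop=True)[
            ["moisture_pct", "fat_pct_dmb", "species"]
        ]
        out_csv = os.path.join(args.out, f"{stem}_spectra.csv")
        table.to_csv(out_csv)
        print(f"{stem}: {omap.n_objects}/{len(truth)} beans recovered -> {out_csv}")


if __name__ == "__main__":
    main()
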