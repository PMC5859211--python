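"""Render synthetic bean scenes and write them to disk as ENVI cubes.

Generates a small batch of push-broom SWIR scenes of green coffee beans
(12 beans each, composition drawn from the study population statistics),
writes raw counts + white/dark reference frames as ENVI header/raw pairs,
the ground-truth compositions as CSV and the label image as PNG.
"""

import argparse
import os

from beanspec.components import build_component_library, default_band_grid
from beanspec.synthetic import SceneSpec, generate_scene, write_scene


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-scenes", type=int, default=3)
    parser.add_argument("--out", default="results/scenes")
    args = parser.parse_args()

    lib = build_component_library(default_band_grid())
    os.makedirs(args.out, exist_ok=True)
    for i in range(args.n_scenes):
        spec = SceneSpec(seed=args.seed + i)
        cube, white, dark, truth = generate_scene(spec, lib)
        paths = write_scene(args.out, cube, white, dark, truth, stem=f"scene{i:02d}")
        print(f"scene {i}: {truth.n_beans} beans, "
              f"moisture {truth.beans['moisture_pct'].mean():.2f} % mean, "
              f"fat {truth.beans['fat_pct_dmb'].mean():.2f} % dmb mean "
              f"-> {paths['cube']}")


if __name__ == "__main__":
    main()
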