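#!/usr/bin/env python
"""Generate the synthetic bilateral soma-coordinate dataset.

Writes the coordinate table (all five structures, both hemispheres, at their
reported counts, with anterior–posterior gradients in CPu and NB) and the
CPu axonal-bundle exclusion mask, then prints the headline counts.
"""

import argparse
from pathlib import Path

import numpy as np

from somaspat.io import tubes_to_voxel_mask, write_coordinates, write_mask
from somaspat.synthetic import generate_bilateral_dataset, generate_bundles, make_region_fixture


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out-dir", default="results/data")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(args.seed)
    s_data, s_bundle = ss.spawn(2)
    data = generate_bilateral_dataset(s_data, with_bundles=True)
    write_coordinates(data, out / "coords.csv")

    region = make_region_fixture("CPu", "L")
    tubes = generate_bundles(region, seed=s_bundle.generate_state(1)[0] % 2**31)
    mask = tubes_to_voxel_mask(tubes, region, voxel_size_um=50.0)
    write_mask(mask, out / "cpu_left_bundles.csv")

    left = int((data.hemisphere == "L").sum())
    right = int((data.hemisphere == "R").sum())
    print(f"wrote {data.n} somata ({left} L / {right} R, "
          f"difference {abs(left - right)}) to {out/'coords.csv'}")
    print(f"wrote CPu-left bundle mask ({len(tubes)} tubes) "
          f"to {out/'cpu_left_bundles.csv'}")


if __name__ == "__main__":
    main()
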