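#!/usr/bin/env python
"""Run the calibration and power experiments and write their rates.

Covers: CSR-envelope pointwise coverage, rank-test and F-test type-I error,
the gradient-vs-clustering contrast, the bundle envelope shift, and the
nearest-neighbor direction checks.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from somaspat.calibration import (
    bundle_envelope_shift_experiment,
    envelope_coverage_experiment,
    f_test_type1_experiment,
    gradient_contrast_experiment,
    nn_direction_experiment,
    rank_test_type1_experiment,
    thomas_k_power_experiment,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out", default="results/calibration.json")
    args = ap.parse_args()

    ss = np.random.SeedSequence(args.seed)
    s1, s2, s3, s4, s5, s6, s7 = ss.spawn(7)
    report = dict(
        envelope_coverage=envelope_coverage_experiment(seed=s1),
        rank_test_type1=rank_test_type1_experiment(seed=s2),
        f_test_type1=f_test_type1_experiment(seed=s3),
        gradient_contrast=gradient_contrast_experiment(seed=s4),
        bundle_envelope_shift=bundle_envelope_shift_experiment(seed=s5),
        nn_directions=nn_direction_experiment(seed=s6),
        thomas_k_power=thomas_k_power_experiment(seed=s7),
    )
    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
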