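#!/usr/bin/env python
"""One-time calibration of the shipped 17-level screening-score thresholds.

Fits a zero-inflated truncated-geometric marginal over the score levels
0, 0.5, ..., 8 to the target moments (mean 0.76, sd 1.25) and converts the
cumulative probabilities to standard-normal cut points.  The resulting
constants are frozen in ``twinace.conditions.SYNAESTHESIA_THRESHOLDS``;
rerun this script only if the target moments change.
"""

import numpy as np

from twinace import conditions
from twinace.simulate import calibrate_thresholds, discretize_to_scale


def main() -> None:
    levels = conditions.SYNAESTHESIA_LEVELS
    th = calibrate_thresholds(levels, conditions.SYNAESTHESIA_MEAN,
                              conditions.SYNAESTHESIA_SD)
    print("thresholds:")
    print(np.array2string(th, precision=6, separator=", "))
    z = np.random.default_rng(0).standard_normal(10 ** 6)
    score = discretize_to_scale(z, th, levels)
    print(f"induced marginal: mean {score.mean():.4f} "
          f"sd {score.std(ddof=1):.4f}")
    drift = np.abs(th - conditions.SYNAESTHESIA_THRESHOLDS).max()
    print(f"max |difference| vs shipped constants: {drift:.2e}")


if __name__ == "__main__":
    main()
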