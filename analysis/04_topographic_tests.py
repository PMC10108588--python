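"""Topographic randomization tests: TCT within groups, TANOVA between.

The topographic consistency test marks the latencies at which each group
shares a stable scalp map (these feed the microstate clustering); the
TANOVA asks where the two facial-activity groups' map shapes differ. Both
use right-tailed randomization nulls and the 5% run-length rule.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common as C  # noqa: E402

from neopain.config import stage_seed  # noqa: E402
from neopain.io import load_epochs, randomization_to_frame  # noqa: E402
from neopain.topo import tanova, tct  # noqa: E402


def main() -> None:
    for cohort in C.COHORTS:
        groups = {g: load_epochs(C.DATA / f"{cohort}_{g}_clean")
                  for g in C.GROUPS}
        for gi, (g, es) in enumerate(groups.items()):
            res = tct(es, window_ms=C.TCT_MS, n_iter=C.N_ITER_RAND,
                      seed=(stage_seed(C.MASTER_SEED, "tct") + gi) % 2**31)
            randomization_to_frame(res).to_csv(
                C.OUT / f"{cohort}_{g}_tct.csv", index=False)
            frac = res.in_segment(res.times_ms).mean()
            print(f"{cohort}/{g}: {100 * frac:.1f}% of {C.TCT_MS} ms "
                  f"topographically consistent "
                  f"({len(res.segments)} segments, min run "
                  f"{res.min_run_ms:.0f} ms)")

        res = tanova(groups[C.GROUPS[0]], groups[C.GROUPS[1]],
                     window_ms=C.EPOCH_MS, n_iter=C.N_ITER_RAND,
                     seed=stage_seed(C.MASTER_SEED, "tanova"))
        randomization_to_frame(res).to_csv(
            C.OUT / f"{cohort}_tanova.csv", index=False)
        t = res.times_ms
        post = t >= 0
        frac_post = res.in_segment(t[post]).mean()
        frac_base = res.in_segment(t[~post]).mean()
        print(f"{cohort}: TANOVA {100 * frac_post:.1f}% of poststimulus / "
              f"{100 * frac_base:.1f}% of baseline significantly different")


if __name__ == "__main__":
    main()
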