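"""Identify microstates, select k by split-half CV, fit and extract events.

Pools grand-average maps at TCT-consistent latencies from both groups,
selects the number of states by subject-level 50/50 cross-validation,
clusters the pooled maps (AAHC), back-fits the templates to each group
average, gates activation against the baseline-topography null, and
extracts events (onset, duration, power).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common as C  # noqa: E402

from neopain.config import stage_seed  # noqa: E402
from neopain.io import events_to_frame, load_epochs  # noqa: E402
from neopain.microstates import (  # noqa: E402
    activation_significance,
    baseline_map_pool,
    cluster_microstates,
    explained_variance,
    extract_events_groups,
    fit_microstates,
    pool_consistent_maps,
    select_k,
    total_field_power,
)
from neopain.topo import tct  # noqa: E402


def main() -> None:
    seed0 = stage_seed(C.MASTER_SEED, "microstates")
    for cohort in C.COHORTS:
        groups = {g: load_epochs(C.DATA / f"{cohort}_{g}_clean")
                  for g in C.GROUPS}
        tct_res = {
            g: tct(es, window_ms=C.TCT_MS, n_iter=C.N_ITER_RAND,
                   seed=(stage_seed(C.MASTER_SEED, "tct") + i) % 2**31)
            for i, (g, es) in enumerate(groups.items())
        }
        pooled = pool_consistent_maps(groups, tct_res)
        k_star, curve = select_k(pooled, k_range=C.K_RANGE,
                                 n_iter=C.CV_ITER, seed=seed0)
        mset = cluster_microstates(pooled.maps, k_star,
                                   provenance={"cohort": cohort})
        pd.DataFrame(mset.templates, index=list(mset.ids),
                     columns=list(groups[C.GROUPS[0]].montage)).to_csv(
            C.OUT / f"{cohort}_microstates.csv")
        pd.DataFrame({"k": curve["k"], "mean_ev": curve["mean_ev"],
                      "mean_ev_corrected": curve["mean_ev_corrected"]}).to_csv(
            C.OUT / f"{cohort}_cv_curve.csv", index=False)
        print(f"{cohort}: k* = {k_star} "
              f"(corrected CV curve {np.round(curve['mean_ev_corrected'], 3)})")

        pool = baseline_map_pool(groups, (C.EPOCH_MS[0], 0.0))
        series = {}
        for i, (g, es) in enumerate(groups.items()):
            s = fit_microstates(es, mset)
            ev = explained_variance(s, C.POSTLANCE_MS)
            tfp = total_field_power(es, window_ms=C.POSTLANCE_MS)
            print(f"  {g}: {100 * ev:.2f}% of the postlance signal "
                  f"explained; mean GFP {tfp:.2f} µV")
            series[g] = activation_significance(
                s, pool, n_iter=C.N_ITER_ACT,
                window_ms=C.POSTLANCE_MS, seed=(seed0 + 17 + i) % 2**31)
        events = extract_events_groups(series)
        frames = [events_to_frame(v) for v in events.values()]
        edf = pd.concat(frames, ignore_index=True)
        edf.to_csv(C.OUT / f"{cohort}_events.csv", index=False)
        for g, evs in events.items():
            desc = ", ".join(
                f"{e.template_id}@{e.onset_ms:.0f}ms/{e.duration_ms:.0f}ms"
                for e in sorted(evs, key=lambda e: e.onset_ms))
            print(f"  {g} events: {desc}")


if __name__ == "__main__":
    main()
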