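"""Score NFCS constellations, apply the missing-data rules, and compare.

Reads the simulated facial coding table, resolves missingness (constancy
fill, proration, exclusion), scores NFCS-7/NFCS-3/NFCS-P-3 on the
reactivity epoch, compares the constellations (Friedman + pairwise
Wilcoxon, NFCS-7 rescaled to 0-30), and classifies each infant against
the 9/30 clinical threshold.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common as C  # noqa: E402

from neopain.facial import (  # noqa: E402
    classify_clinical,
    compare_constellations,
    scale_to_30,
    score_record,
)
from neopain.io import read_facial_records  # noqa: E402


def main() -> None:
    records = read_facial_records(C.DATA / "facial_coding.csv")
    rows = []
    for rec in records:
        if rec.epoch != "reactivity":
            continue
        row = {"subject": rec.subject_id, "group": rec.group}
        excluded = False
        for name in ("NFCS-7", "NFCS-3", "NFCS-P-3"):
            score = score_record(rec, name)
            row[name] = score.total
            row[f"{name}_prorated"] = score.flags.prorated
            excluded |= score.flags.excluded
        row["excluded"] = excluded
        if not excluded:
            row["clinical"] = classify_clinical(row["NFCS-P-3"]).label
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(C.OUT / "nfcs_scores.csv", index=False)

    kept = df[~df["excluded"]].copy()
    print(f"{len(kept)}/{len(df)} infants scoreable "
          f"({int(df['excluded'].sum())} excluded by the 60% rule)")

    scaled = kept[["NFCS-3", "NFCS-P-3"]].copy()
    scaled["NFCS-7(0-30)"] = kept["NFCS-7"].map(scale_to_30)
    report = compare_constellations(scaled, groups=kept["group"])
    f = report["friedman"]
    print(f"Friedman chi2({f['df']}) = {f['chi2']:.2f}, p = {f['p']:.4f}")
    for (a, b), res in report["wilcoxon"].items():
        print(f"  {a} vs {b}: Z = {res['z']:.2f}, p = {res['p']:.4f}")

    counts = kept.groupby(["group", "clinical"]).size()
    print("clinical split by simulated group:")
    print(counts.to_string())
    acc = np.mean(
        (kept["group"] == C.GROUPS[1])
        == (kept["clinical"] == "NFCS-clinical"))
    print(f"threshold recovers simulated group membership: {100 * acc:.1f}%")

    serializable = {
        "friedman": f,
        "wilcoxon": {f"{a}|{b}": v for (a, b), v in report["wilcoxon"].items()},
        "mannwhitney": report.get("mannwhitney", {}),
        "accuracy_vs_truth": float(acc),
    }
    (C.OUT / "nfcs_comparison.json").write_text(
        json.dumps(serializable, indent=1, default=str))


if __name__ == "__main__":
    main()
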