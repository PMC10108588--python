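"""Simulate the two ground-truthed cohorts (EEG epochs + facial coding).

Each cohort (late preterm, full term) gets two facial-activity groups
sharing a scripted 4-state poststimulus microstate sequence; in the
clinical group the third state is engaged 60 ms later. Facial coding
matrices use per-second action probabilities of 0.8 (clinical) vs 0.1
(subclinical), with obstruction-driven missingness, which reproduces the
bimodal clinical distribution of NFCS-P-3 totals.

Writes per-group epoch dumps, the facial coding table, and a cohort
manifest with the ground-truth scripts.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common as C  # noqa: E402

from neopain.config import stage_seed  # noqa: E402
from neopain.io import save_epochs, write_facial_records  # noqa: E402
from neopain.synthetic import (  # noqa: E402
    FacialSimSpec,
    SyntheticCohortSpec,
    four_state_script,
    generate_erp_cohort,
    generate_facial_cohort,
    make_templates,
)


def main() -> None:
    C.OUT.mkdir(parents=True, exist_ok=True)
    C.DATA.mkdir(parents=True, exist_ok=True)
    manifest = {"master_seed": C.MASTER_SEED, "cohorts": {}}

    for ci, cohort in enumerate(C.COHORTS):
        seed = (stage_seed(C.MASTER_SEED, "simulate_eeg") + ci) % 2**31
        templates = make_templates(C.N_CHANNELS, 4, seed=seed)
        shifted = sorted(templates)[2]
        scripts = {
            C.GROUPS[0]: four_state_script(templates, snr=C.SNR),
            C.GROUPS[1]: four_state_script(
                templates, snr=C.SNR,
                onset_shift_ms={shifted: C.ONSET_SHIFT_MS}),
        }
        spec = SyntheticCohortSpec(
            n_subjects_per_group=C.N_PER_GROUP, group_scripts=scripts,
            n_channels=C.N_CHANNELS, fs_hz=C.FS_HZ,
            epoch_window_ms=C.EPOCH_MS, seed=seed)
        groups, truth = generate_erp_cohort(spec)
        for g, es in groups.items():
            save_epochs(es, C.DATA / f"{cohort}_{g}_epochs")
        manifest["cohorts"][cohort] = {
            "seed": seed,
            "shifted_state": shifted,
            "scripts": {g: [list(e) for e in s.entries]
                        for g, s in scripts.items()},
        }
        print(f"{cohort}: {2 * C.N_PER_GROUP} subjects, "
              f"4-state script, state {shifted} +{C.ONSET_SHIFT_MS:.0f} ms "
              f"in the {C.GROUPS[1]} group")

    fspec = FacialSimSpec(
        n_subjects_per_group=2 * C.N_PER_GROUP,
        p_action={C.GROUPS[1]: 0.8, C.GROUPS[0]: 0.1},
        seed=stage_seed(C.MASTER_SEED, "simulate_facial"))
    records, _ = generate_facial_cohort(fspec)
    write_facial_records(records, C.DATA / "facial_coding.csv")
    n_missing = sum(r.n_missing for r in records)
    print(f"facial coding: {len(records)} records, "
          f"{n_missing} obstructed cells")

    (C.OUT / "manifest.json").write_text(json.dumps(manifest, indent=1))
    print(f"wrote {C.OUT}")


if __name__ == "__main__":
    main()
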