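"""Shared fixtures: small ground-truthed synthetic cohorts.

Everything is generated programmatically at test time with fixed seeds;
no data files are shipped.
"""

from __future__ import annotations

import numpy as np
import pytest

from neopain.synthetic import (
    MicrostateScript,
    SyntheticCohortSpec,
    four_state_script,
    generate_erp_cohort,
    make_templates,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def templates_18():
    return make_templates(18, 4, seed=1)


@pytest.fixture(scope="session")
def small_cohort(templates_18):
    """20 subjects/group, 500 Hz, shared 4-state script in both groups."""
    script = four_state_script(templates_18, snr=5.0)
    spec = SyntheticCohortSpec(
        n_subjects_per_group=20,
        group_scripts={"A": script, "B": script},
        seed=7,
    )
    groups, truth = generate_erp_cohort(spec)
    return groups, truth


@pytest.fixture(scope="session")
def shifted_cohort(templates_18):
    """Same 4-state script, but the third state starts 60 ms later in B."""
    shift_id = sorted(templates_18)[2]
    script_a = four_state_script(templates_18, snr=5.0)
    script_b = four_state_script(templates_18, snr=5.0,
                                 onset_shift_ms={shift_id: 60.0})
    spec = SyntheticCohortSpec(
        n_subjects_per_group=20,
        group_scripts={"A": script_a, "B": script_b},
        seed=3,
    )
    groups, truth = generate_erp_cohort(spec)
    return groups, truth, shift_id


def two_state_script(n_channels: int = 8, snr: float = 5.0,
                     seed: int = 5) -> MicrostateScript:
    """Tiny 2-state script on few channels for fast calibration studies."""
    tmpl = make_templates(n_channels, 2, seed=seed, smooth=False)
    ids = list(tmpl)
    return MicrostateScript(
        entries=[(ids[0], 60.0, 160.0, 4.0), (ids[1], 400.0, 200.0, 4.0)],
        templates=tmpl, jitter_sd_ms=8.0, snr=snr,
    )
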