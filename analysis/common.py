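"""Shared settings for the numbered analysis drivers.

One master seed drives every stage; problem sizes are desk-scale
(12 subjects per group at 250 Hz, randomization iterations in the
hundreds) so the whole analysis reruns in well under a minute while
keeping every statistic estimable.
"""

from pathlib import Path

MASTER_SEED = 20221027
_ROOT = Path(__file__).resolve().parent.parent
OUT = _ROOT / "results" / "analysis"  # small derived tables
DATA = _ROOT / "scratch" / "analysis"  # bulky generated inputs (not shipped)

COHORTS = ("preterm", "term")
GROUPS = ("subclinical", "clinical")  # NFCS facial-activity groups

N_PER_GROUP = 12
FS_HZ = 250.0
N_CHANNELS = 18
EPOCH_MS = (-500.0, 1000.0)
TCT_MS = (-200.0, 1000.0)
POSTLANCE_MS = (0.0, 1000.0)
SNR = 5.0
ONSET_SHIFT_MS = 60.0  # clinical group: third state engaged later

N_ITER_RAND = 600
N_ITER_ACT = 1000
N_ITER_SURR = 499
CV_ITER = 40
K_RANGE = (2, 8)
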