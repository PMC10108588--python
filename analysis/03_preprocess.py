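"""Signal conditioning: filter demonstration and common-average reference.

The band-pass (1-30 Hz) and notch (48-52 Hz) filters belong on the
*continuous* recording before epoching; applying a 1 Hz high-pass to an
already-epoched 1.5 s window would distort the slow scripted states and
ring their edges. The simulated epochs are generated stimulus-locked, so
this stage (a) demonstrates the filter chain on a constructed continuous
trace with known spectral content — a 10 Hz tone that must survive and a
50 Hz mains tone that must not — including the epoching arithmetic, and
(b) re-references the analysis epochs to the common average.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common as C  # noqa: E402

from neopain.io import load_epochs, save_epochs  # noqa: E402
from neopain.preprocess import (  # noqa: E402
    bandpass_notch,
    epoch,
    rereference_common_average,
)


def main() -> None:
    # filter demonstration on a continuous two-tone recording
    fs = C.FS_HZ
    t = np.arange(int(10 * fs)) / fs
    clean = np.sin(2 * np.pi * 10.0 * t)
    mains = 0.5 * np.sin(2 * np.pi * 50.0 * t)
    rec = np.tile(clean + mains, (4, 1))
    filt = bandpass_notch(rec, fs)
    core = slice(int(2 * fs), int(8 * fs))
    amp = lambda x, f: np.abs(np.fft.rfft(x[0, core]))[
        int(round(f * (core.stop - core.start) / fs))]
    print(f"continuous demo: 10 Hz tone kept at "
          f"{100 * amp(filt, 10) / amp(rec, 10):.1f}% amplitude, "
          f"50 Hz mains reduced to {100 * amp(filt, 50) / amp(rec, 50):.2f}%")
    es = epoch(filt, fs, int(5 * fs), C.EPOCH_MS)
    print(f"epoching: {es.n_times} samples, t=0 at index "
          f"{es.time_index(0.0)} (window {C.EPOCH_MS} ms at {fs:.0f} Hz)")

    # analysis epochs: common-average reference (idempotent on these data)
    for cohort in C.COHORTS:
        for g in C.GROUPS:
            es = load_epochs(C.DATA / f"{cohort}_{g}_epochs")
            out = rereference_common_average(es)
            save_epochs(out, C.DATA / f"{cohort}_{g}_clean")
            rel = (np.linalg.norm(out.data - es.data)
                   / np.linalg.norm(es.data))
            print(f"{cohort}/{g}: re-reference changed signal by "
                  f"{100 * rel:.2g}% (already average-referenced); "
                  f"channel means {np.abs(out.data.mean(axis=1)).max():.2e} µV")


if __name__ == "__main__":
    main()
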