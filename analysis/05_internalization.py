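#!/usr/bin/env python
"""Ring-ROI engulfment traces: actin peak before acidification.

Generates an ensemble of synthetic internalization events (transient
LifeAct ring brightening followed by a sigmoidal LysoTracker rise), runs
the normalized ring-intensity analysis, and measures the fraction of
acidified particles whose actin peak precedes the acidification onset.
Writes results/internalization_traces.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from padkin.internalization import (detect_peak_then_acidification,
                                    ring_intensity_trace)
from padkin.synth import render_internalization_event

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    rng = np.random.default_rng(50)
    rows = []
    for i in range(40):
        peak_t = rng.uniform(80, 160)
        onset_t = peak_t + rng.uniform(60, 140)
        ev = render_internalization_event(peak_t, peak_width=25.0,
                                          onset_time=onset_t, onset_rate=15.0,
                                          r_px=10, rng=rng)
        tr = ring_intensity_trace(ev["lifeact"], ev["lysotracker"],
                                  ev["centers"], r_nominal=10,
                                  times=ev["times"])
        res = detect_peak_then_acidification(tr, peak_threshold=1.2,
                                             onset_threshold=1.3)
        rows.append({"event": i, "true_peak_s": peak_t, "true_onset_s": onset_t,
                     "acidified": res["acidified"],
                     "peak_time_s": res["peak_time"],
                     "onset_time_s": res["onset_time"],
                     "peak_before_onset": res["peak_before_onset"]})
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "internalization_traces.csv", index=False)
    acid = df[df.acidified]
    frac = acid.peak_before_onset.mean() if len(acid) else float("nan")
    print(f"{len(acid)}/{len(df)} events acidified within the movie; "
          f"{100 * frac:.0f}% of those show the actin peak before the "
          "acidification onset.")


if __name__ == "__main__":
    main()
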