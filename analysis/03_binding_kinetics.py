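#!/usr/bin/env python
"""Binding/unbinding kinetics and shear adhesion for the synthetic bead panel.

Runs the full per-sample analysis (two-state simulation, event extraction,
occupancy-ratio rates, irreversible fractions, shear-phase remaining
fractions, internalization bookkeeping) over the six-type panel spanning
zeta potentials from -93 to -5 mV, three measurements each.  Writes
results/kinetics.csv.
"""

from pathlib import Path

import pandas as pd

from padkin import pipeline

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    records = pipeline.default_panel(n_particles=400, duration=600.0)
    report = pipeline.run_pipeline(records, n_measurements=3)
    df = pd.DataFrame(report["samples"])
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "kinetics.csv", index=False)
    cols = ["sample_id", "zeta_mv", "k_on_cell", "k_off_cell",
            "frac_irr_cell", "frac_remaining", "conditional", "absolute"]
    print(df[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print("\nMore negative zeta binds faster, releases slower, and survives "
          "the 50 pN shear more often, as configured in the panel truths.")


if __name__ == "__main__":
    main()
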