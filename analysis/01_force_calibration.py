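#!/usr/bin/env python
"""Calibrate the hydrodynamic drag force for the reference microchannel.

Computes the lid-sag correction C1, the effective channel height, the flow
rate and syringe-motor velocity needed to exert 50 pN on a 1.5 um-radius
bead, and the lattice-unit velocity conversions used to cross-check the
profile.  Writes results/force_calibration.json.
"""

import json
from pathlib import Path

from padkin import flow

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    # nominal assay channel (19 x 1 x 0.1 mm) for the force target ...
    chan = flow.ChannelGeometry(length=19e-3, width=1e-3, h0=1e-4)
    fluid = flow.FluidProperties(rho=993.36, eta=0.6922e-3, temperature_c=37.0)
    # ... and a typical imaging chamber (5 mm wide, 165 um center height,
    # sagging 10 um toward the side walls) for the C1 calibration
    w = 5e-3
    chamber = flow.ChannelGeometry(length=48e-3, width=w, h0=165e-6,
                                   beta=-10e-6 / (w / 2) ** 2)

    h_eff = flow.effective_height(chamber)
    c1 = flow.correction_c1(chamber)
    q_50pn = flow.flow_rate_for_force(50e-12, chan, fluid, r=1.5e-6,
                                      c1=c1, c2=flow.C2_DEFAULT)
    v_m = flow.motor_velocity(q_50pn, r_piston=6.135e-3)

    scaling = flow.SimUnitScaling(r_sim=16.0, nu_sim=1.0, r_si=1.5e-6,
                                  nu_si=6.968e-7)
    v_center = flow.velocity_profile_rect(0.0, chan.h0 / 2, 25e-9, chan, fluid)
    v_particle = flow.velocity_profile_rect(0.0, 1.5e-6, 25e-9, chan, fluid)

    out = {
        "chamber_h_eff_um": h_eff * 1e6,
        "chamber_c1": c1,
        "c2": flow.C2_DEFAULT,
        "q_for_50pN_uL_per_s": q_50pn * 1e9,
        "motor_velocity_um_per_s": v_m * 1e6,
        "lattice_velocity_center": flow.to_sim_units(v_center, scaling),
        "lattice_velocity_particle": flow.to_sim_units(v_particle, scaling),
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "force_calibration.json").write_text(json.dumps(out, indent=2))
    print("Force calibration for the reference channel:")
    for k, v in out.items():
        print(f"  {k}: {v:.6g}")
    print("The sagging lid raises the force by "
          f"{100 * (out['chamber_c1'] - 1):.0f}% at fixed flow rate.")


if __name__ == "__main__":
    main()
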