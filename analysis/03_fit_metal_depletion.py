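#!/usr/bin/env python
"""Fit the two-parameter metal-depletion model to the EDTA titration.

Each predicted point solves the coupled Mg·ATP/Mg·EDTA speciation
equilibria for free Mg²⁺, then evaluates the saturable transition-state
site plus metal-free floor; the fit is joint across the two enzyme
concentrations on log-activity.
"""

from pathlib import Path

import pandas as pd

from thermocycle import fit_depletion
from thermocycle.io import read_titration_csv
from thermocycle.synthetic import default_equilibrium_system

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    edta, act, conc = read_titration_csv(DATA / "edta_titration.csv")
    system = default_equilibrium_system()
    fit = fit_depletion(edta, act, system, conc)
    pd.DataFrame(
        {
            "parameter": ["f", "kd_ts_nM", "v_max"],
            "estimate": [fit.f, fit.kd_ts * 1e9, fit.v_max],
            "std_error": [fit.f_se, fit.kd_ts_se * 1e9, float("nan")],
        }
    ).to_csv(OUT / "depletion_fit.csv", index=False)
    print(f"metal-free rate fraction f = {fit.f:.2e} "
          f"(generating truth 1.1e-05)")
    print(f"transition-state K_D = {fit.kd_ts * 1e9:.0f} nM "
          f"(generating truth 120 nM)")
    print(f"plateau reached: {fit.plateau_reached}; "
          f"kd identifiable: {fit.kd_ts_identifiable}")


if __name__ == "__main__":
    main()
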