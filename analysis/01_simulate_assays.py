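#!/usr/bin/env python
"""Generate every synthetic assay the downstream analyses consume.

Writes, under results/data/: a replicated noisy 2^5 site×metal rate
table, a noiseless 2×2 modular (domain-presence) table, an EDTA
titration at two enzyme concentrations, a burst time course, and a
toy structure pair with its truth sidecar plus a mutation-suggestion
list for the packing filter.
"""

from pathlib import Path

import numpy as np

from thermocycle.synthetic import (
    D1_FACTORS,
    DEPLETION_TRUTH,
    FIVE_WAY_COUPLING,
    MODULAR_CYCLE_ENERGY,
    MODULAR_FACTORS,
    default_equilibrium_system,
    gen_burst_course,
    gen_edta_titration,
    gen_factorial_dataset,
    gen_toy_structures,
)

SEED = 20260921
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # 2^5 factorial at the study conditions: dominant five-way coupling,
    # modest main effects, σ = 0.3 kcal/mol on ΔG, three-fold replication
    coeffs = {
        tuple(D1_FACTORS): FIVE_WAY_COUPLING,
        ("I4",): 0.4,
        ("F26",): -0.3,
        ("Y33",): 0.2,
        ("F26", "Y33"): -0.25,
    }
    _, table = gen_factorial_dataset(
        D1_FACTORS, coeffs, intercept=-2.0, noise_sd_dg=0.3,
        replicates=3, seed=SEED,
    )
    table.drop(columns="response").to_csv(OUT / "d1_factorial_rates.csv", index=False)
    print(f"2^5 site×metal table: {len(table)} observations "
          f"({len(table) // 3} conditions × 3 replicates)")

    _, modular = gen_factorial_dataset(
        MODULAR_FACTORS, {MODULAR_FACTORS: MODULAR_CYCLE_ENERGY / 4},
        noise_sd_dg=0.0, replicates=1, seed=SEED,
    )
    modular.drop(columns="response").to_csv(OUT / "modular_cycle_rates.csv", index=False)
    print(f"modular 2×2 table: {len(modular)} corners")

    titration = gen_edta_titration(
        DEPLETION_TRUTH, default_equilibrium_system(), noise_sd_log=0.05, seed=SEED
    )
    titration.to_csv(OUT / "edta_titration.csv", index=False)
    print(f"EDTA titration: {len(titration)} points, "
          f"activity spans {titration.activity.min():.2e}–{titration.activity.max():.2e}")

    tc = gen_burst_course(noise_sd=5e-9, seed=SEED)
    np.savetxt(
        OUT / "burst_course.csv",
        np.column_stack([tc.times, tc.product]),
        delimiter=",", header="time,signal", comments="",
    )
    print(f"burst course: {tc.times.size} points over {tc.times[-1]:.1f} s")

    toy = gen_toy_structures(n_residues=20, displaced=(4, 8), out_dir=OUT, seed=SEED)
    (OUT / "suggestions.tsv").write_text(
        "# residue substitution\nA:4 I4V\nA:8 F26L\nA:15 Y33F\n"
    )
    print(f"toy structures: {toy['paths']}, displaced residues "
          f"{toy['truth']['displaced_residues']}")


if __name__ == "__main__":
    main()
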