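# thermocycle

Analysis machinery for measuring **energetic coupling networks in enzyme
catalysis** with thermodynamic cycles, built around the tryptophanyl-tRNA
synthetase (TrpRS) style of experiment: combinatorial perturbation of an
enzyme (point mutations, a Mg²⁺→Mn²⁺ metal swap, whole-domain
deletions), conversion of the measured rates to activation free
energies, and regression-based estimation of intrinsic and coupling
contributions to transition-state stabilization.

It is written for enzymologists and biophysicists running multi-mutant
or modular cycle experiments who want the full chain — raw rates to
coupling energies with significance statistics — as tested, scriptable
code rather than a statistics-GUI workflow.

## What it computes

**Thermodynamic-cycle algebra** (`thermocycle.energy_core`).
Rates become Gibbs activation energies via ΔG‡ = −RT ln k (RT = 0.592
kcal/mol). A 2^N factorial cycle's N-way non-additivity is the
parity-signed sum over its corners,

    ΔG_int = Σ_corners sign(corner) · (−RT ln k_corner),

with sign +1 for an even number of perturbed factors; for N = 2 this is
the textbook ΔG₁₁ − ΔG₁₀ − ΔG₀₁ + ΔG₀₀. Negative coupling means the
perturbed elements jointly stabilize the transition state.

**Effect-coded factorial regression** (`thermocycle.factorial`).
The observed energies are fitted by ordinary least squares to

    ΔG_obs = C + Σ β_i[i] + Σ β_ij[i][j] + … + β_1..N[1]…[N],

with [i] = ±1 (wild-type/reference = +1). On a balanced full factorial
the columns are orthogonal, every coefficient is a parity-weighted
corner average, and 2^k·β equals the k-way cycle non-additivity; both
scales are reported, along with t/p statistics and ranked contribution
histograms.

**Metal-depletion equilibria** (`thermocycle.metal`).
EDTA-titration activity data are modeled by solving the coupled
Mg·ATP / Mg·EDTA binding equilibria for free Mg²⁺ at every point and
fitting v = v_max·(f + (1−f)·m/(m+K_D‡)) on log-activity — two
parameters: the metal-free rate fraction f and the transition-state
Mg²⁺ dissociation constant K_D‡.

**Burst kinetics** (`thermocycle.kinetics`).
Active-site-titration time courses are fitted to
P(t) = A(1−e^(−k_chem·t)) + v_ss·t + C, separating the first-order
chemical step k_chem from steady-state turnover k_cat = v_ss/[E·active];
Michaelis–Menten fits cover the steady-state assays.

**Differential Delaunay tessellation** (`thermocycle.structure`).
Residue-packing simplices are computed per conformation from PDB
coordinates (side-chain centroids, 8 Å edge filter); simplices present
in every conformation are invariant (rigid-body packing), the rest are
dynamic, and dynamic residues are intersected with an external mutation
suggestion list to yield the candidate sites for cycle construction.

**Synthetic assays** (`thermocycle.synthetic`) generate all of the
above from their forward models with known truth, at the study's
conditions (2⁵ = 32 variant×metal combinations, three-fold replication,
lognormal rate noise, a −5 kcal/mol five-way coupling, f = 1.1×10⁻⁵,
K_D‡ = 120 nM, k_chem/k_cat = 625).

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on
synthetic assays and write tables under `results/`:

```bash
python analysis/01_simulate_assays.py
python analysis/02_fit_factorial_cycles.py
```

prints, among other lines:

```
2^5 fit: R² = 0.997, P(F) = 2.61e-70, residual df = 64
dominant term: I4:F26:Y33:F37:Metal at -4.99 kcal/mol (p = 1.1e-82) — the five-way site×metal coupling
modular 2×2: interdomain coupling -5.00 kcal/mol (coefficient -1.25) — matches the five-way cycle
```

i.e. from 96 noisy rate measurements the saturated regression recovers
the dominant five-way site×metal coupling (−4.99 vs the generating −5
kcal/mol), and the independent 2×2 domain-presence cycle returns the
same −5 kcal/mol interdomain coupling — the central cross-validation of
the approach. The remaining drivers fit the metal-depletion titration
(`f = 1.14e-05`, `K_D = 116 nM` from 5%-noise data), the burst course
(`k_chem = 3139 s⁻¹`, chemistry `628×` faster than turnover), and run
the dynamic-contact filter (displaced residues 4 and 8 recovered as
dynamic; 3 of 3 on-dynamic suggestions survive the intersection).

A minimal library-level session:

```python
from thermocycle import CycleTable, cycle_coupling
cyc = CycleTable(2, {(1, 1): 1.0, (-1, 1): 1e9, (1, -1): 5.0, (-1, -1): 1e14})
cycle_coupling(cyc).value   # -5.86 kcal/mol: enzyme–metal coupling
```

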