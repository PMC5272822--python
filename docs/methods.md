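# Methods

## Free energies and cycle algebra

All kinetic quantities (k_cat, K_M, k_cat/K_M, k_chem, fold
accelerations, specificity ratios) are converted to Gibbs energies with
ΔG‡ = −RT ln k. RT defaults to **0.592 kcal/mol** exactly — the value
used in the source analyses — rather than being recomputed from a
temperature, so energies are bit-compatible with published numbers; an
optional temperature override uses RT = 0.0019872·T. The sign
convention throughout: larger rate ⇒ more negative ΔG‡, so stabilizing
(rate-enhancing) couplings come out negative.

A 2^N cycle is stored as corner rates indexed by ±1 level vectors with
+1 the reference level (wild-type residue, Mg²⁺, domain present). The
N-way non-additivity is the parity-signed corner sum; for rates
generated from the effect-coded linear model it equals 2^N times the
N-way coefficient (proved by column orthogonality, checked by property
tests). The degenerate N = 1 "cycle" returns the single-edge ΔG
difference rather than erroring — useful when building cycles
incrementally. Closed circuits of edge energies must telescope to zero;
`cycle_closure` reports the deviation with a default tolerance of 1e−9
kcal/mol for noiseless tables (user-set otherwise).

## Factorial coupling regression

The design matrix uses effect coding with +1 = reference. Under the
opposite convention all odd-order coefficients flip sign; the choice is
therefore documented here and fixed in code. The model is homoscedastic
OLS on ΔG (statsmodels), matching how such data are conventionally
analyzed; replicate weighting is deliberately not applied by default.
Per-term p-values are raw t-tests on the residual degrees of freedom; a
Holm step-down adjustment is available behind a flag but off by
default. A saturated fit with one replicate per condition has zero
residual df: coefficients are exact corner averages, and standard
errors are reported as unavailable (NaN) rather than fabricated.

Published histograms of "contributions" can be read either as raw
coefficients or as 2^order-scaled non-additivities; since the intended
scale is ambiguous in that style of figure, **both** are always
emitted: `coefficient` and `cycle_energy = 2^order·coefficient`. The
five-way site×metal coupling is entered in the generator as a
coefficient of −5 kcal/mol; the modular (CP1×ABD) interdomain coupling
is entered on the cycle-energy scale (−5 kcal/mol ⇒ coefficient
−1.25), because that is how a two-way non-additivity is quoted from a
2×2 cycle.

Unbalanced or incomplete designs are fitted by generic OLS with a
warning; the orthogonal-averaging identity no longer holds there and no
shortcut is used.

## Metal-depletion model

Free Mg²⁺ under an EDTA titration is the unique root of

    Mg_total = m·(1 + Σ_j L_j,total/(K_dj + m))

for 1:1 complexes; ligand frees are closed-form in m. The root is
bracketed on log m (the lower bracket 80 log-units below Mg_total) and
solved by Brent's method, then polished by Newton steps to a relative
conservation residual ≤ 1e−10. Activity follows a single saturable
transition-state metal site over a metal-free floor:

    v(m) = v_max·(f + (1−f)·m/(m + K_D‡)),

which reproduces both limits of a depletion experiment (v → v_max at
saturating metal, v → f·v_max at full depletion). The fit is nonlinear
least squares **on log-activity** — the observable spans ~5 decades and
multiplicative assay error is the realistic structure — jointly across
enzyme concentrations with one v_max per series and shared (f, K_D‡).
f is parameterized through a logistic and K_D‡ through a log transform
to keep both in range. Because the (f, K_D‡, v_max) surface is strongly
nonconvex at these dynamic ranges, the local fit is started from a
deterministic coarse grid over (f, K_D‡) in which the optimal per-series
v_max is closed-form; the polish uses Levenberg–Marquardt.

Identifiability is flagged, not silently absorbed: a series that never
modulates the fitted curve (log-span < 0.05) marks K_D‡ unidentifiable;
a series whose most-depleted point still sits more than 2× above the
floor marks the fit weakly identified (f extrapolated, no plateau).

Mg·ATP and Mg·EDTA dissociation constants are configuration, not fitted
quantities. Defaults are conditional constants at assay pH on the
scales practitioners use: **K_d(Mg·ATP) = 10⁻⁴·⁵ M** and
**K_d(Mg·EDTA) = 10⁻⁹·⁵ M**. Generation and refitting of synthetic
titrations always share one set of constants, so parameter recovery is
insensitive to the particular defaults. Enzyme-bound metal is neglected
(enzyme ≪ ATP and EDTA totals); enzyme concentration enters only
through v_max scaling. The default simulated system — 5 µM residual
Mg²⁺, 1 mM ATP, EDTA from 0 to 30 mM in 12 points at two enzyme
concentrations — buffers free Mg²⁺ near K_D‡ at zero EDTA and reaches
the metal-free plateau at the top of the grid, the two features a real
titration needs for both parameters to be measurable.

## Burst kinetics

The fitted form is the standard burst equation
P(t) = A(1−e^(−k_chem·t)) + v_ss·t + C. (A published rendering of this
fit line with the exponential entering additively is typographically
inconsistent — product would decrease — and its own derived quantities,
a 5 s⁻¹ turnover and a 625-fold chemistry/turnover ratio, presuppose
the standard form implemented here.) Initialization is deterministic:
v_ss and A + C from a straight-line fit to the final third of the
course, k_chem from the log-slope of the first decaying residuals; no
random restarts, so identical inputs give bit-identical fits. k_cat =
v_ss/(enzyme_total·active_fraction) with active_fraction an explicit
input defaulting to 1 (it comes from the titration itself in real use).
When the initialized amplitude is indistinguishable from zero the
course is fitted as a straight line and the k_chem/k_cat ratio is
reported as undefined (None) rather than a meaningless number. Whether
C absorbs a quench artifact or true baseline is not resolvable from a
single course; it is simply a free offset.

Michaelis–Menten fits are initialized from the Hanes linearization
(S/v vs S) and refined by nonlinear least squares; all-saturating data
(rate spread < 5%, or fitted K_M far below the sampled range) flag K_M
unidentifiable.

## Differential Delaunay tessellation

Each residue is reduced to one point: the side-chain heavy-atom
centroid, Cα for glycine or side-chain-less residues (`point="ca"`
switches to Cα throughout; the representation used by the original
packing analyses is not documented, so it is configurable).
Highest-occupancy altlocs win; waters and hetero groups are excluded.
Tessellation is scipy's Qhull Delaunay; simplices with any edge longer
than **8 Å** (configurable) are discarded as solvent-spanning surface
artifacts — this edge filter, plus the Λ score bands, stands in for an
explicit core/surface classification. Cospherical degeneracies (exact
lattices) are broken by a deterministic ~10⁻⁶ Å jitter keyed to each
residue id, identical across runs and conformations, so tessellation
differences always reflect real coordinate changes; the brute-force
test oracle operates on the same jittered coordinates. No
superposition is performed — the tessellation is invariant to rigid
motion, which the property suite verifies explicitly.

Invariant simplices are those present in every conformation; dynamic
simplices appear in some but not all; dynamic residues are the union of
residues of dynamic simplices. Composition log-likelihood scores Λ are
computed against a pluggable table (the published statistical-potential
tables are not redistributable, so none ships); bands Λ > 0.6 and
Λ < 0 mark well-packed and unfavorable compositions. External mutation
suggestions (a 2-column TSV, e.g. from multi-state design — consumed,
never computed) are intersected with the dynamic residue set. PDB
numbering is preserved verbatim.

A minimum of 4 points is required (a single tetrahedron is the
degenerate minimal tessellation).

## Synthetic data: what it emulates, what it does not

Noise is Gaussian on the ΔG scale (σ default 0.3 kcal/mol), hence
lognormal on rates — the multiplicative error structure of kinetic
assays. Replication defaults to 3, the study's approximate level. The
toy structures are a compact serpentine pseudo-globule of alanines
(Cα + Cβ), with listed residues displaced radially in the second
conformation; the truth sidecar records exactly those residues. All
generators are bit-reproducible functions of their seed.

What passing tests therefore show: the estimators recover the
generating parameters under the assumed error model, the cycle algebra
and the regression are mutually consistent, and the geometric filter
finds planted rearrangements. What they do not show: robustness to
error structures the generators don't produce (systematic drift,
heteroscedasticity across variants, correlated replicates), real
side-chain packing geometry, or the behavior of the depletion model if
the true metal dependence involves more than one site.

## Problem sizes and runtime

Default analyses are desk-scale by construction: 96-observation
factorial fits, 24-point titrations with nested 1-D root finding,
25-point burst courses, ≤ 27-residue toy structures; Monte-Carlo suites
use 100–200 seeded replicates. The full test suite runs in well under a
minute on one CPU.
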