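# Methods

## Model

A chromosome is a linear bead-spring polymer, one bead per 50 kb of
chromatin, in reduced units: bead diameter σ = 1 is the length unit and
kT = 1 the energy unit. The potential energy is the sum of five terms.

**Connectivity.** Consecutive beads interact through FENE bonds,
U = −(k r₀²/2) ln(1 − (r/r₀)²), with k = 30, r₀ = 1.5 by default, plus
the steric core below. A harmonic variant (U = k_h r²/2, default
k_h = 3 so that ⟨r²⟩ = b² = 1) exists for Gaussian-chain limits and for
users who prefer phantom-chain topology.

**Steric core.** A purely repulsive WCA potential (12-6, shifted, cut at
2^{1/6}σ, ε = 1) that switches to a linear continuation below the radius
where it reaches E_cut = 4, so energy and force remain finite down to
r = 0. The cap serves two purposes: numerical stability under any
starting configuration, and — as in coarse-grained chromatin models
generally — it lets chains cross at a finite energy cost, mimicking
topoisomerase activity. Nearest-neighbor steric belongs to the bonded
term; all |i−j| ≥ 2 pairs get it through the type-to-type term.

**Confinement.** A half-harmonic spherical wall U = k_c (|r| − R)² for
|r| > R (k_c = 30) models the nuclear envelope. The helper
`confinement_radius_for(n, φ)` sets R for a bead volume fraction φ
(default 0.1, a standard interphase density choice).

**Ideal chromosome.** U = Σ γ(d) f(r) over pairs with genomic
separation d ∈ [d_min, d_max] (default [3, 500]), where
γ(d) = γ₁/log d + γ₂/d + γ₃/d². The term is translationally invariant —
it depends on d only, never on bead identity — and models the average
effect of motor activity along the fiber. d_min ≥ 3 because nearest and
next-nearest neighbors are governed by connectivity and sterics.

**Type-to-type.** U = Σ α(t_i, t_j) f(r) over |i−j| ≥ 2, with a
symmetric 7×7 coupling matrix over {A1, A2, B1, B2, B3, B4, NA}. The
neutral NA type (centromeres, unannotated loci) has zero couplings, so
such loci are excluded from compartment energetics. Negative α is
attractive; homotypic couplings slightly exceed heterotypic ones, which
is the structure that drives microphase separation and hence the plaid
Hi-C pattern.

**Loops.** U = χ f(r) for each listed anchor pair (default χ = −1.613).
Exact duplicate anchor pairs are collapsed to one entry with a warning.

**Contact function.** f(r) = (1 + tanh μ(r_c − r))/2 with μ = 3.22,
r_c = 1.78 — the field-standard reduced-unit values: ≈1 in contact,
exactly ½ at r_c, ≈0 beyond ~2.5σ.

### Parameter provenance

The published calibrated coefficient set for this model family (27
parameters, including the full type matrix and γ coefficients trained
against experimental Hi-C) lives in the original model's supplementary
data and is deliberately not re-derived here. The defaults above are a
generic profile with the right structure and magnitudes; every value can
be replaced via `MiChroMParameters` or its YAML config
(`MiChroMParameters.load/save`), after which the exported MD inputs and
the internal sampler both use the supplied values.

## Sampling

BAOAB splitting of underdamped Langevin dynamics, mass 1, default
timestep 0.01 τ and friction 0.1 τ⁻¹ — conventional coarse-grained
polymer settings; both exposed in `SamplerConfig`. Equilibration is a
fixed step count chosen by the user (no automatic detection, since no
robust universal criterion exists); the integrated autocorrelation time
of the radius of gyration is reported as a diagnostic so the choice can
be audited. Randomness comes from one numpy PCG64 generator; replica k
of a multi-replica run is seeded with the stream (seed, k), making every
replica independently reproducible. FENE overstretch or non-finite
forces abort the run with the step number.

The tested envelope is 100–2,000 beads (5–100 Mb) on one CPU;
whole-chromosome production sampling is intended to go through the
exported MD-engine inputs instead.

## MD-engine input export

The energy function is exported as tabulated potentials plus coordinate
and topology files, the scheme used to run this model family in a
standard MD package:

* `table_b0.xvg` (r, U): FENE + nearest-neighbor steric. The grid stops
  just short of r₀, where the FENE energy diverges.
* `table_b1.xvg` (d, U): confinement vs distance from the nuclear
  center, gridded to R + 3.
* `table_b2.xvg` (r, f): the contact basis for the ideal-chromosome
  term; γ(d) coefficients live in the .top.
* `table.xvg` (r, U_steric, f): type-to-type plus non-nearest steric.
  This table has three columns because the steric core does not scale
  with the type coupling: per-pair energies are
  U_steric(r) + α(t_i, t_j) f(r) with α from the .top type matrix.
* `tablep.xvg` (r, f): the loop basis; χ and the anchor list are in the
  .top.

Grids use 10⁻³ spacing (pairwise tables run to 3 r_c). Cubic
interpolation of any table reproduces the in-repo terms to ≤ 10⁻⁶;
linear interpolation is limited by curvature to ~10⁻⁵ at this spacing.

Initial conformations are confined random walks with unit bonds that
keep new beads off the steep part of the steric core (a "self-avoiding
enough" start), deterministic in the seed, with a density guard that
refuses chains that cannot plausibly fit the sphere.

## Analysis stack

In-silico Hi-C contact maps default to a hard distance cutoff at r_c
(the in-silico analogue of a ligation radius); a smooth kernel mode
(mean f(r)) is available since the right criterion is a modeling choice.
P(s) is the per-diagonal mean. Compartment profiles follow the standard
eigenvector methodology: observed/expected normalization by the
per-diagonal mean, Pearson correlation matrix of the columns, leading
eigenvector. All-zero (centromeric) loci are masked before the Pearson
step and re-inserted as NaN. Because an eigenvector's sign is arbitrary,
the orientation rule is explicit: A-class mean positive when annotations
are supplied, otherwise largest-magnitude entry positive; comparisons
between profiles sign-align first and report the sign used.
Distance-stratified map correlation computes Pearson r per diagonal
(NaN where a diagonal is constant), on raw, log1p or observed/expected
matrices, with optional truncation to a common size for the
cross-chromosome null comparison.

## Synthetic validation: what it shows and what it does not

Reproducing published chromosome-scale correlation figures requires
experimental Hi-C maps and ensembles of ~10⁵–10⁶ structures; neither
belongs in a desk-scale test suite. Validation here is therefore against
planted truth, with every generator deterministic in its seed:

* **Exact oracles.** Format round trips are identity on randomized valid
  ensembles; every energy term matches an independent scalar-loop
  brute-force sum to 10⁻¹⁰ relative; binning integrals match
  rational-arithmetic values exactly.
* **Closed-form statistical mechanics.** A tethered bead reproduces
  equipartition (the wall with R → 0 degenerates to U = k r², variance
  T/2k per coordinate); a FENE dimer's bond-length distribution matches
  the Boltzmann weight by quadrature (KS test); a harmonic chain obeys
  ⟨R²(s)⟩ = s b². Sampler test settings (friction 8 for the tether,
  4 for the dimer, 0.2 for the chain) are chosen for decorrelation speed
  of the observable in question, so run lengths of 3–4×10⁵ steps give
  standard errors of ~1–2% against 5% tolerances.
* **Mechanism recovery.** A 200-bead two-type block copolymer (25-bead
  blocks) is sampled for 10⁵ steps. The fixture uses a homotypic −0.4 /
  heterotypic −0.1 contrast with the ideal-chromosome term off: 0.3 kT
  per contact is the standard block-copolymer demixing setup and
  isolates the type term as the only sequence-dependent interaction, so
  demixing is resolvable in minutes on one CPU. Checks: homotypic
  contact frequency exceeds heterotypic; the contact map's leading
  Pearson eigenvector recovers the planted type sequence at ≥ 75%
  agreement (observed ≈ 100%); looped anchors sit closer on average
  than the matched control (all same-compartment pairs at the same
  genomic separation). Loop design notes: anchors are same-compartment
  pairs, so the loop term is not fighting compartment segregation, and
  the loop wells are deepened to 3 kT for this check — at the default
  1.6 kT the mean-distance shift is below the run-to-run noise of
  compartment-scale distances at these run lengths, i.e. it needs an
  order of magnitude more sampling to resolve, while a 3 kT well gives
  an unambiguous ~25% contraction. Within a replicate the control mean
  pools ~70 pairs to suppress its own noise.

What passing does **not** show: agreement with experimental Hi-C for a
real cell line, realistic A/B proportions or P(s) exponents (the
generic couplings are uncalibrated), loop-extrusion dynamics (loops are
static contacts), or annotation accuracy (the baseline predictor is a
deliberately transparent heuristic, not a trained model). The noise
model of the planted contact maps is i.i.d. multiplicative log-normal
(σ = 0.3 by default), which does not emulate the correlated noise of
real proximity-ligation data.

## Numerical choices and edge cases

* Text coordinates quantize to 10⁻³ σ; fixtures generate on that grid so
  text round trips are bit-exact. The binary container is float64.
* Degenerate contact maps (constant after observed/expected) raise
  rather than return a meaningless eigenvector; constant diagonals in
  map correlation are reported as NaN, detected by exact range (ptp)
  rather than floating-point variance.
* Duplicate loops deduplicate with a warning; intervals beyond the
  chromosome end clip with a warning; negative .bed scores are errors.
* `.bed` input is 0-based half-open; all internal genomic coordinates
  and .ndb fields 10–11 are 1-based inclusive; conversion happens once
  at ingest.
* The baseline annotation predictor maps zero-signal bins to B3 (the
  quiescent majority class), and otherwise compares summed active marks
  (H2AFZ, H3K27ac, H3K36me3, H3K4me1/2/3, H3K79me2, H3K9ac, H4K20me1)
  against repressive ones (H3K27me3, H3K9me3): A1 if active dominates,
  B1 otherwise. Feature matrices are passed to predictors raw
  (unnormalized); normalization policy belongs to the predictor.
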