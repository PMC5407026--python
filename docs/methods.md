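# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `allelicburst`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Generative model

For gene `g`, cell `c`, and allele `X in {A, B}`, the latent transcript
count follows a two-state (telegraph) promoter model in stationarity:

```
p^X_cg ~ Beta(k_on^X, k_off^X)
Y^X_cg ~ Poisson(phi_c * s^X * p^X_cg)
```

`p` is the fraction of time the promoter spends ON; `1/k_on` and `1/k_off`
are the mean OFF and ON dwell times. All rates are normalised by the mRNA
decay rate (only the stationary distribution is observed, so the decay
rate is not identifiable and is fixed at 1); estimated burst frequencies
are therefore activation rates per mRNA lifetime, and an apparent allelic
difference in burst frequency could in principle also reflect an allelic
difference in decay rate, which cancels in burst size `s/k_off` but not in
`k_on`. The two alleles are independent given `phi_c` unless the
simulator's copula coupling is switched on (below). Cell size `phi_c`
multiplies the transcription rate: burst size is proportional to cell
size, burst frequency is not. No cell-cycle adjustment is made (total
burst frequency is approximately conserved across the cycle; the package
assumes a reasonably homogeneous cell population).

Observation (technical) noise acts per entry, with batch-level parameters:

```
Q ~ Z * Poisson(alpha * Y^beta),   Z ~ Bernoulli(expit(kappa + tau*log Y)),
```

and `Q = 0` deterministically when `Y = 0` (the dropout logistic is
defined on log expression of expressed transcripts only). `alpha > 0` is
capture/sequencing efficiency, `beta > 0` amplification bias, and
`(kappa, tau)` the dropout curve; the model prints these per cell, but
estimation shares them across all cells of a batch, which is what the
spike-in design identifies.

## Simulator

`simulate_dataset` draws from exactly the hierarchy above, records all
latent state (`p`, `Y`, `Z`, `phi`, kinetic truth), and derives every
random stream from one root seed via `SeedSequence` spawning (same seed,
bit-identical output). Defaults encode the study conditions used
throughout the tests:

- cell sizes: `phi_c = exp(g_c)`, `g_c ~ Normal(0, sigma^2)` with
  `sigma = 0.1`. The log-scale reading keeps `phi` strictly positive, as a
  multiplier of a Poisson mean must be.
- technical noise (`MOUSE_LIKE_NOISE`): `alpha = 0.5`, `beta = 0.9`,
  `kappa = -1.5`, `tau = 0.7`. These are not fitted constants but a
  realistic Smart-seq-like regime chosen once: detection probability
  ~0.78 at Y = 50 and ~0.4 at Y = 5, i.e. substantial,
  expression-dependent dropout plus mild amplification compression.
- coordinated/repulsed alternatives: the two alleles' Beta draws are
  coupled through a Gaussian copula with user-set correlation `rho`. The
  marginals stay exactly Beta, so only the dependence structure changes —
  a clean alternative for power-testing the independence test.
- spike-ins: a fixed molecule level per spike-in in every cell, pushed
  through the same observation model. `simulate_spike_ins` sets molecule
  length equal to read length and back-computes the nominal concentration,
  so the read-to-molecule conversion returns the stated levels exactly.

What the simulator does **not** emulate: mapping/phasing errors and
reference bias at heterozygous sites, UMI structure, cell-cycle phase,
cell-type mixtures, gene-gene correlation, and per-cell variation of the
noise parameters. Tests passing on simulated data therefore validate the
estimators under the model's own assumptions; they do not certify
robustness to violations of those assumptions in real data.

## Library size, spike-in conversion, cell size

- `eta_c` is the median-of-ratios factor: median over genes of the cell's
  total allelic count divided by the gene's geometric mean across cells.
  Genes with a zero total in any cell are excluded (their geometric mean
  is undefined); if no gene survives — common for small bursty panels —
  the pipeline warns and proceeds with `eta = 1` rather than refusing.
- spike-in truth: `molecules = C * 1e-18 * N_Avogadro / dilution`, with
  `C` in attomoles/uL and the standard 1:40,000 dilution as default.
- observed spike-in molecules: `reads * read_length / molecule_length /
  eta_c`. The three adjustments (depth, read length, molecule length) are
  composed multiplicatively; this is one defensible arrangement of the
  named corrections.
- `phi_c` defaults to the endogenous-to-spike-in read-ratio proxy,
  median-normalised to 1 so kinetic parameters are on the
  per-typical-cell scale (the absolute scale of `phi` trades off against
  `s` and is not identifiable). Cells with zero spike-in or zero
  endogenous totals get `phi = 1` with a warning. The proxy needs
  genome-wide endogenous totals to be stable; with small simulated panels
  supply the true sizes via `cell_sizes`. User-supplied sizes bypass the
  proxy and are only median-normalised.

## Classification

Per gene, cell states {empty, A, B, AB} are mixed with weights
`(phi_1..phi_4)`. Reads from a silent allele arise through sequencing
error at rate `epsilon` (default 0.001, fixed; estimating it from sex
chromosomes needs annotation and is out of scope), giving the relative
likelihoods `f1 ~ eps^(nA+nB)`, `f2 ~ (1-eps)^nA eps^nB`, `f3`
symmetric, and for AB a Beta(a, a)-mixed binomial integral. All four share
the omitted combinatorial constant, so posteriors are exact. Numerics:

- `f4` has no closed form with the error mixing; it is evaluated by
  order-64 Gauss-Legendre quadrature on (0,1) in log space, validated in
  the tests against adaptive quadrature.
- `a = b` is selected from the grid {3, 4, 6, 10, 20} by observed-data
  log-likelihood (no closed-form M-step exists for the hyper-parameters;
  the grid keeps EM monotone and reproducible). `a >= 3` keeps the AB
  state distinguishable from A and B.
- EM starts at uniform mixing, stops at a log-likelihood gain < 1e-6 or
  500 iterations, and warns (returning the best iterate) on
  non-convergence. Ties in the max-posterior assignment break
  deterministically toward empty, then A, B, AB.
- a cell with **no reads at the locus** has identical likelihood under all
  four states (the densities model only the allelic split of observed
  reads). Left to the EM, such cells would be apportioned by the mixing
  weights and always fall below the 0.8 posterior cut-off, leaving
  `N_empty = 0` and biasing the downstream independence table. They are
  therefore pinned to the empty state — which is what "expressing neither
  allele" operationally means — and the EM runs on the informative cells.

Cells with max posterior <= 0.8 are excluded from the category tallies
(but not from kinetics input, which is gated per gene, not per cell).
Gene labels: silent; monoallelic A/B; otherwise biallelic, split into
bursty vs non-bursty by requiring both alleles' expressed fractions
`(N_X + N_AB)/N_total` to lie in [0.05, 0.95].

## Noise estimation

`(alpha, beta)` come from a Poisson GLM with log link on the pooled
non-zero spike-in observations (`log E[Q] = log alpha + beta log Y`),
exactly the truncation the estimator declares — no correction is applied
for the bias this induces at very low levels. Observations are pooled
across cells ("shared across the batch"); molecule-scale responses are
continuous, so the GLM acts as a quasi-likelihood fit. `(kappa, tau)`
maximise the mixture likelihood that attributes each zero either to
dropout or to Poisson sampling, via Nelder-Mead from nine starts
(`kappa in {-2,0,2} x tau in {0,0.5,1.5}`), box-constrained to
`kappa in [-20, 20]`, `tau in [-10, 10]`, objective tolerance 1e-8; the
best optimum is kept and dominates every start by construction. With no
zeros anywhere, dropout is indistinguishable from none and `kappa` is
reported at the upper bound + 10 with a warning. At least two distinct
spike-in levels are required; a single level is a collinear design and is
rejected.

## Kinetics

Repiling: for each distinct observed level `Q > 0` (after `eta`
normalisation), `Y = (Q/alpha)^(1/beta)` and
`n_hat(Y) = c(Q) / expit(kappa + (tau/beta) log(Q/alpha))` — the observed
multiplicity divided by the detection probability, since the observed
count at a level is Binomial(n(Y), detection). Residual weight sits at
`Y = 0`; if the repiled weight exceeds the number of cells the zero weight
is floored at 0 and the positive weights rescaled so the total is always
exactly the cell count (weight conservation keeps the moments
interpretable as per-cell averages). With identity noise the repiled
histogram equals the observed one bit-for-bit (the support uses a direct
power, not `exp(log(.)/beta)`, so `beta = 1` introduces no rounding).

Moments and inversion: `m1 = sum w*Y / sum phi_c`,
`m2 = sum w*Y(Y-1) / sum phi_c^2`, `m3 = sum w*Y(Y-1)(Y-2) / sum phi_c^3`,
with `Y` left continuous (rounding would break the moment identities
whenever `beta != 1`; how non-integer support should enter factorial
moments is otherwise unspecified, and continuity is the choice that
preserves the algebra). `phi` enters only the denominators, not the
repiling transform. The closed-form inversion of the three-moment system
was verified symbolically to be the exact inverse of the forward
equations. Estimates are declared non-estimable when any denominator falls
below 1e-12 in magnitude or any recovered parameter is non-positive or
non-finite — never truncated to a boundary, which would bias bootstrap
nulls. Non-identifiable regimes (large `k_on` with small `k_off`:
constitutive; Poisson-like data) are flagged, which is precisely why
kinetics are only attempted for biallelic bursty genes.

Uncertainty: paired-cell nonparametric bootstrap (cells resampled with
replacement, both alleles and `phi`/`eta` travelling together), percentile
95% intervals, default 200 replicates; an allele with more than half its
replicates non-estimable is flagged unstable.

## Hypothesis tests

- Differential kinetics: pool the `2n` depth-normalised counts, resample
  `2n` with replacement, assign the first `n` to pseudo-allele A and the
  rest to B — the resampled values land in the fixed cell-slot order, so
  cell sizes stay attached to slots, not to values. Both statistics
  (|difference in burst frequency|, |difference in burst size|) are
  evaluated on the same replicate stream. `p` is the exceedance fraction
  among replicates where both pseudo-alleles are estimable, floored at
  `1/n_valid` (never exactly 0); fewer than 100 valid replicates sets a
  low-confidence flag. The pool is sorted before resampling — statistically
  a no-op (draws are uniform over a multiset) that makes the test exactly
  invariant to swapping the allele labels. Default 1000 replicates.
- Allelic imbalance: exact two-sided binomial test of the summed A-count
  in the summed total at probability 0.5.
- Independence: Pearson chi-square (1 df, no continuity correction) on
  the 2x2 (A expressed) x (B expressed) table from the classification
  tallies, expected counts from the marginals; skipped for fewer than 20
  assignable cells or degenerate marginals. Direction: coordinated when
  `N_AB` exceeds its expectation, repulsed when below; annotated per gene
  but interpreted (reported in the results table) only where the test
  survives FDR.
- FDR: Benjamini-Hochberg within each of the four test families, each
  across all tested genes; skipped tests propagate as NaN and are never
  flagged.

## Pipeline behaviour

Stages run as normalise -> noise (identity fallback with a prominent
warning when neither spike-ins nor parameters are given) -> classify ->
kinetics (bursty genes only) -> tests -> FDR. Failures are isolated per
gene: an exception marks that gene non-estimable and the run continues.
Given a `random_state`, per-gene seeds are spawned from one root sequence
and the full results table is reproducible.

## Problem sizes used in the checks

The acceptance script and the heavier tests use: 100 random parameter
triples for the inversion check; 200 simulated replicates of 400 cells for
the adjustment-ordering comparison (the four estimator settings are run on
identical datasets, so the comparison is paired); 200 simulated genes of
100 cells with 500 bootstrap replicates for type-I calibration; 50
simulations for power; 1e5 draws for the simulator moment checks. These
sizes make the whole suite run in a few seconds while leaving the
Monte-Carlo bands quoted in the tests comfortably wide.

## Known limitations

- The moment estimator is noisy at realistic cell numbers; relative
  errors of ~30-50% for burst frequency at 400 cells under realistic noise
  are normal (the acceptance script reports the measured values). Burst
  size is more stable than `s` or `k_off` individually because their
  estimation errors cancel in the ratio.
- Repiling assumes the fitted noise parameters are exact; uncertainty in
  `(alpha, beta, kappa, tau)` is not propagated into the kinetic CIs.
- The spike-in-based cell-size proxy requires genome-scale endogenous
  totals; it is unreliable on small gene panels.
- Batch-level noise parameters ignore residual cell-to-cell efficiency
  variation; data with strong per-cell capture differences will show
  inflated kinetic dispersion.
- Upstream read alignment, SNP phasing, and cell QC are out of scope; the
  package starts from phased allelic count matrices.
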