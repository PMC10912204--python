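# Methods

This note documents the models, numerical choices and defaults behind
`fluxgrowth`, and what the synthetic study does and does not establish.

## Constraint-based simulation

A metabolic model is a stoichiometric matrix S (metabolites × reactions)
with flux bounds lb ≤ v ≤ ub (mmol/gDCW/h) and GPR boolean rules.  Bounds
meant as "unconstrained" are encoded as ±1000, which keeps every program
bounded.  Exchange status (exactly one participating metabolite) and
transport status (stoichiometry spanning ≥ 2 compartments) are always
derived from structure rather than trusted from annotations, because
annotation conventions vary across model sources; structural detection is
reproducible but may disagree with hand-curated exclusion lists at the
margins.

**FBA** maximizes the biomass flux over {S·v = 0, lb ≤ v ≤ ub}; the LP is
solved with HiGHS (scipy.optimize.linprog).  An infeasible polytope is
reported as status `infeasible` with growth 0 by convention.

**Wild-type reference.** FBA optima are typically degenerate.  The MOMA
reference must be unique and reproducible, so the optimum is refined by
minimizing ‖v‖₂ at the fixed optimal growth rate.  The squared norm is
strictly convex, so the refined point is unique; equivalent parallel routes
receive equal flux.  An L1 (parsimonious) refinement was considered but
cannot break ties among equal-total-flux routings, which is exactly the
degeneracy that matters here.

**MOMA** predicts a mutant's flux state as the minimizer of
Σ_j (v_j − v_j^wt)² over the mutant's polytope.  The distance runs over all
reactions, exchanges included, following the original formulation.  The
mutant's growth is read off the flux vector, never re-optimized.  The QP is
solved by a dense primal active-set method with exact KKT solves — chosen
because no dedicated QP library is part of the dependency stack and
general-purpose NLP solvers (SLSQP, trust-constr) deliver only ~1e-5
accuracy on these problems, while the active-set method terminates finitely
at machine precision.  Feasibility is established first by an LP; working
sets track active bounds; a bound constraint is released only when its
multiplier has the improving sign.  Solver hygiene: S·v = 0 is honored to
1e-6, bounds to 1e-9, and growth below 1e-9 is reported as exactly 0 (which
makes the <5% essentiality comparison robust to round-off).

**Deletion panels.** Gene deletions act through GPR truth values: a
reaction is bounded to [0, 0] when its rule evaluates false with the deleted
genes set false.  Panels accept a `replicates` parameter for interface
fidelity with triplicate-averaged workflows; with the deterministic solvers
used here replicates are identical and the mean equals a single run.

**Essentiality.** A reaction is essential on a medium when bounding it to
[0, 0] drops recomputed growth (FBA or MOMA) below 5% of wild type.

## Media

A medium opens one carbon exchange (uptake ≤ 10 mmol/gDCW/h by default),
optionally an oxygen exchange (≤ 20), and a set of freely exchanged salts;
all other exchange uptakes are closed and secretion is unconstrained.  The
medium type carries an explicit `oxygen_exchange` identifier since models
name their oxygen boundary differently (toy models may omit it entirely).

## Dataset assembly

Features are absolute simulated fluxes — magnitudes, so that reverse flux is
not mistaken for low activity.  Columns numerically zero (< 1e-9) in every
mutant are removed; constant non-zero columns (the ATP-maintenance analog)
are retained because the filter is variance thresholding at exactly zero,
not at a positive threshold (a configurable threshold exists but defaults to
0).  Output values are endpoint biomass normalized per condition by the
wild-type value and clipped at 0; mutants of listed essential genes are
zeroed regardless of measurement, mirroring screens where curated essential
calls override plate reads.  Multi-gene mutants are keyed by sorted,
"+"-joined gene identifiers.

## Elastic net

Per condition, y is regressed on standardized features with l1_ratio 0.01,
penalty strength chosen on a 50-point CV grid by minimum squared error
(the RMSE argmin), up to 1e4 iterations at tolerance 1e-6.  "300-fold"
cross-validation is interpreted as K-fold with K capped at the sample count
(leave-one-out on desk-scale data); fold assignment is seeded and echoed in
output metadata.  Standardization before fitting makes the penalty act
evenly across fluxes of very different magnitudes; coefficients are
reported on the standardized scale.  Group SDs in the selection rule are
population SDs over each sign group with zeros excluded — zero coefficients
have no sign, so they join neither group.  Negative-group thresholding
compares magnitudes (|β| > 0.1·SD); thresholding raw negatives would select
nothing.  The rule is scale-equivariant by construction.

## Multilayer perceptron and Shapley attribution

The regressor is a fully connected ReLU network with a single linear output
trained on mean-squared error with RMSprop (ρ = 0.9), inverted dropout on
hidden activations, and a per-unit max-norm clip of incoming weights after
every update.  It is implemented in numpy so every training control is
explicit, seeded and platform-independent.  The default configuration is
four 1000-unit layers, dropout 0.6, max-norm 4, ten seeded runs (seeds
0–9); training controls not fixed by that configuration default to 200
epochs, batch 32, learning rate 1e-3, validation split 0.1.  The
hyperparameter search that produced the default architecture is not re-run:
a search reproduces a configuration, not a result.  The `toy()` preset —
two 32-unit layers, dropout 0.2, 300 epochs, batch 16 — is the desk-scale
analog: small nets on tens of samples need far less regularization, and
heavier dropout there simply slows convergence without improving
generalization.

Attribution is permutation-sampling Shapley: for instance x and feature j,
φ_j averages f(x_{S∪{j}}, b_rest) − f(x_S, b_rest) over feature orderings,
with unrevealed features taking values from a background sample (default:
the training matrix).  Each sampled ordering is paired with one sampled
background row; when the requested sample count covers all p! orderings the
estimator enumerates them against the full background, making it exact —
this is how the small-p oracle comparisons are run.  Gradient-based deep
explainers were deliberately not used: the permutation estimator is defined
by the Shapley axioms themselves (additivity, dummy, symmetry, local
accuracy), is library-independent, and admits an exact enumeration oracle.
Per run, each reaction is summarized by its median attribution over
mutants; runs are averaged; the same sign + one-tenth-SD rule as the
elastic net produces the calls.  A constant target short-circuits to empty
prediction sets — a constant function has no attributable signal.

## Accuracy and enrichment

Critical genes map to reactions whose GPR turns false under the singleton
deletion of that gene; an isozyme-backed reaction is attributed to neither
isozyme alone.  The accuracy statistic P(B/A) = |A∩B| / |A| applies the
single-protein filter (non-empty GPR without OR nodes) to the predicted set
A only; B is used as mapped.  Accuracies are rounded to one decimal for
reporting, with the raw fraction preserved.  |A| = 0 yields NaN with a
warning rather than a silent zero.

Enrichment uses the hypergeometric upper tail P[X ≥ k] inclusive of the
observed overlap (the standard overrepresentation convention) together with
the cumulative probability P[X ≤ k]; a category is significant at P ≤ 0.01
and cumulative ≥ 0.95.  The two thresholds are near-redundant but both are
applied as stated.  The population is every annotated reaction; raw P
values are the default (a Benjamini–Hochberg option exists but is off).

## The synthetic study

The generator emulates the logic of a genome-wide deletion screen over
multiple carbon sources paired with a curated metabolic model, at a scale
where every quantity can be verified exhaustively.  Default study (seed 0):
3 carbons, each with an exchange, a gene-bearing transporter, a high-yield
catabolic step (1 carbon → 2 precursor) and a lower-yield bypass (→ 1
precursor); a 3-step linear core chain (first step an AND-complex of two
subunits) to a shared building block; an amino-acid branch and an energy
reaction carrying isozyme OR-pairs; a two-step nucleotide branch; a biomass
sink consuming three precursors; a spontaneous forced maintenance reaction
(constant non-zero flux column); and a forced wasteful drain (lower bound
1.0, own gene) burning precursor and energy — its deletion raises FBA
growth ~11%, the planted detrimental reaction, mirroring reported cases of
deletions in overflow-type pathways accelerating growth.

Ground truth comes from the model itself by exhaustive single-gene deletion
FBA per carbon: essential below 5% of wild-type growth, beneficial when the
reduction exceeds 10% (mapped to reactions via GPRs, exchanges/transports
excluded), detrimental when a reaction's own removal raises growth by more
than 1%.  Detrimental ground truth is restricted to gene-mediated
reactions: a gene-deletion screen cannot perturb spontaneous reactions, so
they sit outside the identifiable universe.  The planted essential list is
the genes essential on *every* carbon, plus a seeded 5% of other genes
force-zeroed in the screen — the analog of externally curated essential
lists that override plate measurements (and a small source of deliberate
label noise).  Screen noise is multiplicative lognormal with σ = 0.1:
endpoint biomass is positive with roughly proportional error.  All
randomness flows from the spec seed.

What passing on this study shows: the pipeline wiring is correct end to end
— GPR deletion logic, MOMA projection, feature assembly, both learners and
the selection rule recover planted signal through realistic collinearity
(parallel isozymes, chained reactions with identical flux) and mild label
noise.  What it does not show: performance under real screens' batch
effects, regulatory (non-metabolic) gene effects, media uncertainty, or
genome-scale degeneracy; the toy deliberately makes no attempt to mimic
genome-scale topology statistics.

## Problem sizes

The shipped tests and the acceptance script run the default study
(20 genes × 3 carbons, ≈ 26 reactions), 20 random stoichiometric toys
(≤ 15 reactions) for the LP/QP oracle comparisons, 6-feature networks for
exact Shapley enumeration, and an N ≤ 30 grid for exact hypergeometric
arithmetic — sizes chosen so every reference value is computable by brute
force or exact arithmetic.

## Known limitations

* The active-set QP uses dense linear algebra: right for toy and mid-size
  models, not tuned for genome-scale MOMA panels (thousands of reactions);
  a sparse factorizing solver would be the natural extension.
* Plain `fba` returns the solver's optimum; only `wildtype_reference` is
  guaranteed reproducible across solver versions.
* The growth screen normalizes per condition by wild type; per-plate or
  global normalizations are not implemented.
* No recall/F1 against critical sets (the precision-style P(B/A) is the
  statistic of record), and no statistical test on accuracy differences.
* GPR grammar: parenthesized infix with case-insensitive `and`/`or`
  keywords and gene tokens `[A-Za-z0-9_.:-]+` (full grammar in the
  `model_io` module docstring).
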