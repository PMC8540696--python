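# Methods

This note documents the models `gencore` implements, the defaults it ships
with and why, what the synthetic generator does and does not emulate, and the
numerical choices made where the method itself leaves them open.

## Node models

The package treats a genetic-and-epigenetic network (GEN) as the union of a
protein-protein interaction network (PPIN) and a gene regulatory network
(GRN) over five node kinds.  Receptors, proteins and TFs are *protein-like*:
they are PPIN members and act as TF/protein-class regulators; the finer kind
is kept for reporting only, because the models distinguish only
TF/protein vs lncRNA vs miRNA regressors.

Every model is a static cross-sample regression with an intercept (the
node's *basal level* β):

* **PPIN model** for a protein-like node *i* with candidate partners *m*:
  `p_i^n = Σ_m a_im φ_m^n + β_i + ε_i^n`.  Two regressor forms exist:
  `linear` (`φ_m = p_m`, the default) and `product` (`φ_m = p_i p_m`).
  The product form is the literal interaction notation, but it places the
  response inside every regressor column: any spurious partner column then
  explains `p_i` almost tautologically (on exogenous-driven rows the
  correlation between `p_i` and `p_i·p_m` is ~0.8+), and AIC pruning cannot
  remove false-positive interactions (measured decoy removal drops from
  ~76% to ~47%).  The linear form is also the one the estimation problem is
  actually written in; it is therefore the default, with `product` retained
  behind the `ppi_term` switch.
* **GRN model** for a gene *j*:
  `g_j^n = Σ_s b_js p_s^n + Σ_t c_jt x_t^n − Σ_u d_ju r_u^n + β_j + ε_j^n`
  with TF/protein terms `b`, lncRNA terms `c` and repressive miRNA terms
  `d ≥ 0`.  The miRNA constraint is implemented as a nonpositive coefficient
  on the raw miRNA expression column; the reported ability is the negated
  coefficient.
* **lncRNA / miRNA models** use the same additive form with TF/protein and
  miRNA regulator classes (repressive miRNA terms constrained as above).

A protein-like node with both PPI partners and incoming regulations gets two
separate fits (a PPIN row and a GRN row); they meet only in the network
matrix.

## Estimation

Each node model minimizes `‖Φθ − P‖₂²` subject to its sign constraints.
Unconstrained problems go through minimum-norm least squares
(`numpy.linalg.lstsq`); constrained ones through `scipy.optimize.lsq_linear`
(BVLS when the design has full column rank and N ≥ columns, trust-region
otherwise), with coefficients within 1e-12 of the bound snapped to it.  Rank
deficiency (more candidate regressors than samples) is tolerated with a
logged warning and minimum-norm behaviour — never silent regularization.
The test suite verifies the solver against an independent active-set
enumeration oracle to 1e-8 in objective.

## Order detection (AIC)

The real system order of a node is the regressor subset minimizing

    AIC(k) = log(SSE/N) + 2 (k + 1) / N     (natural log; +1 = intercept)

Because the penalty depends on the subset only through its size, a single
magnitude ranking of the full fit's |θ̂| serves all regulator classes
jointly: the nested prefixes {∅, top-1, top-2, …} are each refitted under
the constraints and the minimum-AIC prefix is selected, ties broken toward
the smaller order.  This costs a linear number of refits; an exhaustive mode
(≤ 12 regressors) enumerates every subset and doubles as the verification
oracle — the nested heuristic attains the exhaustive minimum on ~95% of
noisy test problems (rate measured and reported by the acceptance suite, not
asserted to be 1).  SSE is floored at 1e-300 before the log so noiseless
(zero-residual) fits stay finite; a perfect fit then always wins at its
order.

Pruning is per target: an undirected candidate PPI pair survives
independently in each endpoint's model, so the real GEN stores directed
(target, partner) ability entries.

## Principal network projection

Surviving abilities form the network matrix Δ: one row per fitted node model
(PPIN rows, gene rows, lncRNA rows, miRNA rows; order-0 models contribute
all-zero rows so every modeled node remains rankable), one column per
regulator in a single shared partition (TF/protein, lncRNA, miRNA blocks — a
protein that is both PPI partner and TF occupies one column).  Entries for
pruned or absent edges are exactly zero; miRNA-class entries are stored
negated (−d̂) so repression keeps its sign.  Basal levels are not part of Δ.

From the full SVD Δ = ΠΣΨᵀ, the eigen-expression fraction
`E_m = σ_m²/Σσ²` weights each component; the smallest M with
`Σ_{m≤M} E_m ≥ 0.85` (default threshold, configurable) defines the
principal subspace.  Node ω's projection value is
`D(ω) = (Σ_{m≤M} (δ_ω·ψ_m)²)^{1/2}`; a node owning two rows (PPIN + GRN
fits) combines them as the root-sum-square over its rows.  The top k nodes
by D (default k = 2000; ties toward the lexicographically smaller id; k
capped at the node count) induce the core GEN.  Ranking is joint across node
kinds.  Right singular vectors follow a deterministic sign convention (first
nonzero component positive); D is sign-invariant, so this affects only
exported projection coordinates.

## Epigenetic flagging

Epigenetic modification (methylation, acetylation, ubiquitination,
phosphorylation) is absorbed into the basal level; a node is flagged when
its basal level differs between the two stage fits by more than a threshold,
strictly.  The comparison is between-stage — the only reading consistent
with fitting the two stages independently.  No threshold value is dictated
by the method: the default is the 95th percentile of the |Δbasal|
distribution across shared nodes (scale-free and explicit in the report),
overridable by an absolute value.  Nodes fitted in several blocks use the
gene-level (regulatory) fit's basal level.

## Drug matching

A drug's score is the number of (target, effect) rows in a drug→target-effect
table that coincide with a biomarker's (node, desired action); drugs are
ranked by count (ties by name) and the top 3 (configurable) form the
candidate multiple-molecule drug.  Live perturbation-database queries are
out of scope; the bundled CSV fixtures transcribe published early- and
later-stage Alzheimer's screens and reproduce their printed counts
(8/7/6 and 8/7/7).

## Synthetic world

The generator emulates the statistical structure the identification assumes:

* **Layering.**  Exogenous nodes (all TFs, half the proteins, half the
  lncRNAs/miRNAs) are drawn i.i.d. lognormal(0, 0.5) per sample — positive,
  microarray-intensity-like, mean ≈ 1.13.  Modeled targets are computed in
  one pass from the exogenous draws; the models are static regressions, so
  no equilibrium solving is needed (under `product` the implicit PPIN model
  is solved in closed form with negative abilities keeping the denominator
  ≥ 1).
* **Abilities** are uniform in magnitude on [0.2, 1.0]; TF/protein and
  lncRNA signs random, miRNA abilities ≥ 0.
* **Noise** is additive Gaussian; the default `noise_sd = 0.05` is ~5% of
  the typical signal level.  Microarray noise is not characterized by the
  method — Gaussian additivity is this package's assumption.
* **Epigenetics**: 20% of modeled nodes (default) carry a later-group basal
  shift of magnitude `basal_shift` (default 1.0).
* **Decoys**: `round(decoy_rate × true edges)` kind-consistent false
  positives attached to modeled targets, default rate 0.5.
* **Cohorts**: two independent sample groups (default 120 each) with Braak
  scores cycling I–III / IV–VI in the written metadata.

Not emulated: probe effects, batch effects, missing values, feedback loops,
or realistic degree distributions.  A green recovery test therefore
establishes that the estimator and pruning behave correctly *when the data
follow the model*, not that the model fits any particular tissue.

Measured under the defaults (N = 200, 5% noise, decoy rate 0.5, pooled over
20 seeds): 100% true-edge retention and ~76% decoy removal.  Removal is
bounded near 0.84² ≈ 0.71 for PPI decoys because an undirected decoy pair
must be rejected independently by both endpoints' models, and AIC keeps a
pure-noise regressor with asymptotic probability P(χ²₁ > 2) ≈ 0.16.

## Degenerate inputs and determinism

Zero-regulator nodes become intercept-only fits (basal = group mean).
All-zero Δ is an error (fractions undefined).  Duplicate candidate edges are
deduplicated with a warning; PPI self-edges are rejected (GRN
self-regulation is allowed).  Every stochastic step is driven by an explicit
seed; identical configs give byte-identical exports (floats written as
%.17g and re-read round-trip).

## Known limitations

* The nested AIC search is a heuristic; optimality is verified only against
  the exhaustive oracle on small problems.
* Decoy removal for undirected PPI decoys is capped as described above.
* Expression is used unnormalized by default (optional per-node z-scoring);
  probe-to-gene summarization of real array data is the user's
  responsibility.
* Whether the top-2000 core should be counted jointly or per node kind is
  ambiguous; joint ranking is implemented.
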