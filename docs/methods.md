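# Methods

## Model

The package implements collective penalized matrix tri-factorization over
a data fusion graph. Object types i = 1..t carry n_i objects; each
relation edge (i, j) carries R_ij ∈ ℝ^{n_i×n_j} with a binary observation
mask M_ij; loops carry symmetric constraint matrices Θ_i^(l) (negative =
must-link, positive = cannot-link). The fitted model minimizes

    J(G, S) = Σ_ij ‖M_ij ∘ (R_ij − G_i S_ij G_jᵀ)‖²_F
            + Σ_i Σ_l tr(G_iᵀ Θ_i^(l) G_i),    G_i ≥ 0,

with one shared nonnegative recipe matrix G_i per type and one
unconstrained backbone matrix S_ij per relation. Constraint matrices only
regularize; they are never factorized and never traversed by chains.

Note that whenever some Θ has a negative part, J is unbounded below along
the scale direction (G_i ← tG_i, S ← S/t² leaves every reconstruction
fixed while the trace term grows like −t²). In practice constraint
magnitudes are small relative to the data (e.g. a −1-coded interaction
network against row-normalized relations) and the solver's bounded step
sizes keep trajectories finite; a run that does diverge is detected
(non-finite objective), aborted and reported, and the fit fails only if
every restart diverges. Test instances for the monotonicity property are
therefore drawn *well-posed*: constrained types also carry relation data
and constraint scales are mild.

## Solver

Alternating scheme, per iteration:

1. **Backbone solve (exact).** For each relation,
   S_ij ← (G_iᵀG_i)⁺ G_iᵀ R̃_ij G_j (G_jᵀG_j)⁺ — the least-squares
   minimizer for fixed G, with pseudo-inverses handling rank deficiency.
   R̃ is R with unobserved cells imputed by the current reconstruction
   (an EM-style majorization, so the observed-cell objective still
   decreases).
2. **Recipe update (multiplicative).** For each type, in sorted order,
   G_i ← G_i ∘ sqrt(N_i / (D_i + ε)) with

       N_i = Σ_{(i,j)} [R̃ G_j S_ijᵀ]⁺ + G_i [S_ij G_jᵀG_j S_ijᵀ]⁻
           + Σ_{(j,i)} [R̃ᵀ G_j S_ji]⁺ + G_i [S_jiᵀ G_jᵀG_j S_ji]⁻
           + Σ_l [Θ_i^(l)]⁻ G_i,

   and D_i the complementary parts ([X]⁺/[X]⁻ are element-wise
   positive/negative parts). The mixed-sign c×c kernel S GᵀG Sᵀ is split
   *before* multiplying by the nonnegative G_i: under this splitting the
   update is the standard semi-NMF auxiliary-function step and the
   objective is provably non-increasing per step; splitting the full
   product instead (an equivalent fixed point) empirically overshoots.
   Multiplicative updates preserve nonnegativity exactly and cannot revive
   an entry that has reached zero (zero-locking); the strictly positive
   initialization avoids spurious locks at iteration 1.

**Initialization.** G_i ~ U(0,1) scaled by the mean absolute observed
value of the data touching type i; S then set by step 1. Deterministic
given a seed; restart r uses seed + r.

**Stopping.** After each iteration the *total reconstruction error*
Σ_ij ‖M ∘ (R − G S Gᵀ)‖_F (norms, not squares; constraint term excluded)
is compared with the previous iteration; the run stops when the absolute
change falls below `tol` (default 0.01, 200 iterations maximum, 20
restarts — the defaults used in the original study) or `tol_mode=
"relative"` for scale-free stopping, useful because row normalization
makes the absolute scale data-dependent. The penalized objective J is
recorded per iteration in `objective_trace`.

**Restart combination.** Default: the restart with the lowest final J.
`run_combination="per_run_scores"` returns all restarts so downstream
scores can be aggregated across runs (how the original 20 restarts were
combined is not documented; both routes are provided).

**Ranks.** c_i = max(round(k·n_i), c_min) (round-half-to-even), capped at
n_i with a warning; c_min defaults to 5 as in the study. `rank_scan` fits
a grid of k, reports per-relation and total errors averaged over restarts,
and suggests the k with the maximum positive second difference of error
vs k (the "kink") — a suggestion, never an automatic choice.

## Chaining

Chains are the empty chain plus every directed simple path of relation
edges rooted at the target type, traversed only in stored edge direction
(reversed relations can be added explicitly as Rᵀ data if wanted);
parallel edges yield distinct chains; the simple-path rule (no repeated
node) guarantees termination on cyclic graphs. Enumeration order is
lexicographic by edge-label sequence. On the published 13-edge topology
this yields exactly 15 chains, the first being the bare recipe matrix.
No chain-length bound is imposed. The profile matrix of a chain is
G_target · S_e1 · ... · S_ek (objects × terminal latent components).

## Prioritization

Per candidate and chain, Spearman rank correlation (average ranks on
ties) against each seed's profile row fills a chains × seeds score
matrix. A constant profile row yields ρ = 0 by convention — a constant
latent profile carries no ranking signal. Internally correlations are
computed as dot products of centered, unit-norm rank-transformed profile
rows, which reproduces tie-corrected Spearman exactly and makes the
permutation analyses cheap.

Aggregation is a two-step median: across seeds within each chain, then
across chains (medians of even counts = mean of the central pair). The
order is a genuine free choice — the two orders differ on general
matrices — and is configurable (`order="chains_then_seeds"`); seeds-first
is the default because it first summarizes "how close is the candidate to
the seed set in this data view" and then asks for a consensus across
views.

Ranking is by descending score with competition (minimum) ranks on ties
and deterministic secondary order by object id. Empirical p-values are
(h+1)/(n+1) with h the number of n random seed sets (default n = 500, as
in the study) scoring at least the actual seed set; random sets are drawn
uniformly without replacement from all factorized target objects
excluding the scored candidate (the study does not state its pool; an
explicit `pool=` reproduces restricted-pool analyses such as scoring one
gene against randomized candidate sets). The floor is 1/(n+1); under
exchangeability the p-values are super-uniform by construction.

Leave-one-out evaluation holds out each seed in turn, ranks it among
negative controls using the remaining seeds, converts each fold's scores
to tie-averaged within-fold rank fractions (making folds comparable
despite different seed sets), pools folds, and computes ROC/AUC and
precision–recall/average precision with scikit-learn.

## Synthetic data

The generator emulates the model class the method assumes: per type a
planted nonnegative recipe with one dominant component per object
(dominant weight U(0.8, 1.2) against U(0, 0.1) background; the first c
objects seed one component each so none is empty), backbones U(0, 1),
R = G_i S_ij G_jᵀ plus N(0, σ²) noise (clipped at 0 for relations declared
nonnegative), i.i.d. missingness, and optionally a must-link constraint
(−1 within the module). One latent component of the target type is the
*module*; its members are ground-truth positives. `seed_split` samples
seeds from the module, leaving the remaining members as positives and all
off-module objects as negatives.

The default topology is a miniature 5-type, 6-edge graph (gene hub →
terms/pathways/articles, plus article→term, pathway→compound,
term→compound), 60 genes and planted ranks (5, 4, 3, 3, 3) — small enough
that a full fit takes well under a second, yet deep enough to produce
multi-step chains (8 chains).

What the generator does **not** emulate: realistic count distributions,
ontology DAG structure, correlated missingness, objects with mixed
membership, or data sets of heterogeneous quality. Passing the recovery
tests therefore shows the machinery is correct and calibrated under the
model's own assumptions, not that the method will rank well on any real
compendium.

## Experiment designs used in the behavioural tests

* **Monotonicity:** 100 random well-posed instances (2–3 types of 4–9
  objects, 1–3 relations, 30% masked with probability 0.3, mild
  constraints with probability 0.5), 30 iterations each; the objective
  trace must never rise beyond 1e−9 relative.
* **Exact recovery:** noiseless 3-relation graph (60/40/30 objects, ranks
  4/3/3), true ranks, 5 restarts × 1000 iterations; final total
  reconstruction error below 1% of the data's Frobenius norm.
* **Block recovery:** same graphs over 10 generator seeds; row-argmax of
  fitted recipes vs planted assignments under the best label permutation
  (Hungarian matching), pooled over seeds ≥ 95%. Pooling matters: at
  exact reconstruction the tri-factorization is not identifiable, so
  single seeds can dip to ~0.92 while the pooled fraction is ~0.97.
* **Planted-module AUC:** default topology, noise 0.05, true ranks,
  scaled-down fit (5 restarts × 100 iterations), 4 seeds; mean AUC of
  positives vs negatives over 5 generator seeds ≥ 0.9.
* **Degradation:** nested sub-compendia removing relations that carry
  direct gene information (6 edges → {gene–term, article–term,
  term–compound} → {gene–term}); mean AUC over the same 5 seeds must not
  increase as edges are removed. The nesting deliberately removes
  *informative* relations: in this generator every relation replicates
  the same planted signal, so removing only distant edges merely removes
  noisy chains and does not probe information loss.
* **Null calibration:** 500 candidates on i.i.d. profiles, 200
  randomizations each; the fraction of p ≤ α must not exceed α + 0.05 at
  α ∈ {0.05, 0.1}.

## Numerical choices and edge cases

* ε = 1e−12 guards every multiplicative denominator.
* Row normalization uses the Euclidean norm of the observed cells of each
  row (for a row vector the Frobenius norm *is* the Euclidean norm);
  all-zero rows are left unchanged.
* Constraint matrices are symmetrized on load by averaging with the
  transpose (the trace penalty only sees the symmetric part); a `scale`
  multiplier lets users sign-flip similarity networks into must-links.
* Sparse inputs choose explicitly whether absent cells are observed zeros
  (default, matching dense normalization) or unobserved.
* `max_iter=0` returns the initialized model untouched; a rank scan with
  fewer than three grid points reports no kink.
* Identifier matching is exact-string and case-sensitive throughout.

## Limitations

* Local optima: multiplicative updates converge to stationary points;
  restarts mitigate but do not eliminate the issue.
* The factorization is not identifiable at exact reconstruction, so
  component-level interpretations (argmax memberships) are only reliable
  when the data's block structure is strong.
* The loss is unbounded below in the presence of must-link constraints
  (see above); constraint scaling is the user's responsibility.
* Dense in-memory matrices only; the implementation targets compendia of
  the study's scale (~10⁴ objects in the largest type), not genome-scale
  sparse corpora.
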