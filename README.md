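# collage

Seed-based gene prioritization by collective penalized matrix
tri-factorization over a heterogeneous data fusion graph, latent matrix
chaining, and rank-correlation scoring with empirical permutation p-values.

## The problem

Finding new genes involved in a phenotype usually starts from a handful of
*seed genes* that are already known to matter, plus a heterogeneous pile of
data sets — expression compendia, pathway memberships, ontology
annotations, literature links — most of which describe objects *other*
than genes (articles, terms, pathways, compounds). Classical
guilt-by-association tools can only use data directly attached to genes.
This package fuses **all** dyadic data sets, however indirectly related to
the genes, and ranks candidates by their similarity to the seeds in the
fused latent space.

## The model

Data sets are organized in a **data fusion graph**: nodes are object types
(with n_i objects each), a directed edge (i, j) carries a relation matrix
R_ij ∈ ℝ^{n_i×n_j}, and loops carry symmetric constraint matrices Θ_i
(negative entries = must-link, positive = cannot-link; never factorized).
All relations are jointly decomposed as

    R_ij ≈ G_i S_ij G_jᵀ,

where the nonnegative *recipe matrix* G_i ∈ ℝ^{n_i×c_i} is **shared** by
every relation touching type i and the small unconstrained *backbone
matrix* S_ij ∈ ℝ^{c_i×c_j} is specific to one relation, minimizing

    Σ_ij ‖R_ij − G_i S_ij G_jᵀ‖²_F  +  Σ_i Σ_l tr(G_iᵀ Θ_i^(l) G_i),
    G_i ≥ 0.

Factorization ranks are set as c_i = max(round(k·n_i), c_min) from a
single compression fraction k (a rank scan with an automated “kink”
detector helps choose k). The solver alternates an exact least-squares
solve for every S_ij with a monotone multiplicative update of every G_i,
restarted from multiple random initializations.

**Chaining.** A *chain* is a directed simple path of relation edges rooted
at the target type (the empty chain included). Multiplying G_target by the
backbone matrices along the path yields a *profile matrix* that places
every target object in the latent space of the terminal type — including
types with no direct gene data.

**Prioritization.** For each candidate, the Spearman rank correlation
between its profile row and each seed's, in every chain, fills a
chains × seeds similarity score matrix, collapsed to one scalar by a
two-step median (median across seeds, then across chains). Candidates are
ranked by that score, and an empirical p-value (h+1)/(n+1) is attached by
re-scoring against n random seed sets.

## Worked example

Simulate a miniature 5-type fusion graph with a planted gene module, fit,
inspect the chains, and rank all genes against 4 seed genes drawn from the
module:

```sh
collage simulate --out sim --seed 1
collage fit --config sim/graph.yaml --k 0.1 --min-rank 3 \
        --runs 5 --max-iter 100 --tol 1e-6 --seed 1 --out model
collage chains --config sim/graph.yaml
collage rank --config sim/graph.yaml --model model \
        --seeds sim/seeds.txt --nperm 500 --seed 1 --out ranking.tsv
```

`chains` prints the 8 latent-matrix chains of this topology, e.g.

```
G_gene
G_gene · S_gene-term
G_gene · S_gene-term · S_term-compound
...
total   8
```

and `ranking.tsv` starts with

```
object_id   score                rank  p_value
gene0000    0.9999999999999998   1     0.16367265469061876
gene0005    0.9999999999999998   1     0.005988023952095809
gene0030    0.9999999999999998   1     0.001996007984031936
gene0032    0.9999999999999998   1     0.017964071856287425
gene0001    0.8749999999999998   5     0.3213572854291417
```

The four top-ranked genes are exactly the four unseen members of the
planted module (the other four members were the seeds): a score of 1 means
the gene's latent profile is rank-identical to the seeds' in every chain.
P-values are permutation-based, so with 500 randomizations the smallest
attainable value is 1/501 ≈ 0.002; ties in the tiny latent space keep some
p-values larger than the score alone would suggest.

## Input formats

* **Dense matrices** — tab-delimited text; first row = column ids, first
  column = row ids, `NA` = missing.
* **Sparse matrices** — MatrixMarket coordinate file plus `<stem>.rows.txt`
  / `<stem>.cols.txt` identifier sidecars (one id per line); absent cells
  are observed zeros or unobserved, per relation (`missing: zero|unobserved`).
* **Graph configuration** — YAML with keys `target`, `types`
  (`name`, `ids`/`ids_file`), `relations` (`label`, `source`, `target`,
  `path`, `format`, `normalize`, `missing`) and `constraints`
  (`type`, `path`, `scale`, `index`). Before analysis each relation can be
  row-normalized so the Frobenius norm of every row profile equals one.

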