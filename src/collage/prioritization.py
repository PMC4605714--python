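"""Seed-based prioritization over chained latent profiles.

Candidates are scored against a small seed set: for every chain, the
Spearman rank correlation between the candidate's profile row and each
seed's profile row is recorded in a chains x seeds similarity score
matrix, which is collapsed to a scalar by a two-step median (a
median-based L-estimator).  Candidates are ranked by that scalar, and an
empirical p-value (h+1)/(n+1) is attached by re-scoring against n random
seed sets.  Leave-one-out evaluation pools per-fold rankings of held-out
seeds against negative controls into ROC / precision-recall curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn import metrics as _skm

from .chaining import ProfileMatrix

__all__ = [
    "SimilarityScoreMatrix",
    "PrioritizationResult",
    "EvaluationResult",
    "spearman",
    "score_candidate",
    "aggregate",
    "prioritize",
    "empirical_pvalue",
    "loocv_evaluate",
]


def spearman(u: np.ndarray, v: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns 0 when either vector is constant: a constant latent profile
    carries no ranking signal, so the (undefined) correlation is taken as
    neutral.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.size} vs {v.size}")
    if u.size < 2:
        raise ValueError("vectors must have length >= 2")
    if np.all(u == u[0]) or np.all(v == v[0]):
        return 0.0
    rho = scipy.stats.spearmanr(u, v).statistic
    return float(rho) if np.isfinite(rho) else 0.0


@dataclass
class SimilarityScoreMatrix:
    """Chains x seeds table of Spearman correlations for one candidate."""

    candidate: str
    values: np.ndarray
    chains: tuple[str, ...] = ()
    seeds: tuple[str, ...] = ()


@dataclass
class PrioritizationResult:
    """Ranked candidates with aggregated scores (and optional p-values)."""

    table: pd.DataFrame
    seeds: tuple[str, ...] = ()
    n_randomizations: int | None = None
    seed: int | None = None


@dataclass
class EvaluationResult:
    roc: pd.DataFrame
    auc: float
    pr: pd.DataFrame
    auprc: float
    folds: list[PrioritizationResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# internal vectorized Spearman machinery
# ---------------------------------------------------------------------------

def _normalized_ranks(values: np.ndarray) -> np.ndarray:
    """Row-wise rank transform, centered and scaled to unit norm.

    Spearman correlation between two rows of the input equals the dot
    product of the corresponding output rows; constant rows map to zero
    vectors, realizing the rho=0 convention.
    """
    r = scipy.stats.rankdata(values, axis=1).astype(float)
    r -= r.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(r, axis=1, keepdims=True)
    return np.divide(r, norms, out=np.zeros_like(r), where=norms > 0)


def _profile_index(profiles: list[ProfileMatrix]) -> dict[str, int]:
    if not profiles:
        raise ValueError("at least one profile matrix is required")
    ids = profiles[0].ids
    if not ids:
        raise ValueError("profile matrices carry no object identifiers")
    for p in profiles[1:]:
        if p.ids != ids:
            raise ValueError("profile matrices disagree on object identifiers")
    return {obj: i for i, obj in enumerate(ids)}


def _lookup(index: dict[str, int], object_id: str) -> int:
    if object_id not in index:
        raise KeyError(f"unknown object id {object_id!r}")
    return index[object_id]


def score_candidate(profiles: list[ProfileMatrix], candidate: str,
                    seeds: list[str]) -> SimilarityScoreMatrix:
    """Build the chains x seeds Spearman similarity score matrix."""
    if not seeds:
        raise ValueError("seed set is empty")
    index = _profile_index(profiles)
    ci = _lookup(index, candidate)
    si = [_lookup(index, s) for s in seeds]
    values = np.empty((len(profiles), len(seeds)))
    for t, prof in enumerate(profiles):
        Z = _normalized_ranks(prof.values[[ci] + si, :])
        values[t, :] = Z[1:] @ Z[0]
    return SimilarityScoreMatrix(
        candidate=candidate, values=values,
        chains=tuple(p.chain.describe() for p in profiles),
        seeds=tuple(seeds))


def aggregate(scores: SimilarityScoreMatrix | np.ndarray,
              order: str = "seeds_then_chains") -> float:
    """Two-step median collapse of a chains x seeds score matrix.

    Default order takes the median across seeds within each chain, then the
    median of those values across chains; ``"chains_then_seeds"`` swaps the
    two steps.  Medians of even counts are the mean of the central pair.
    """
    values = scores.values if isinstance(scores, SimilarityScoreMatrix) else np.asarray(scores)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty score matrix")
    if order == "seeds_then_chains":
        return float(np.median(np.median(values, axis=1)))
    if order == "chains_then_seeds":
        return float(np.median(np.median(values, axis=0)))
    raise ValueError(f"unknown aggregation order {order!r}")


def _aggregate_stack(corr: np.ndarray, order: str) -> np.ndarray:
    """Aggregate a (chains, ..., seeds) correlation stack along axis 0/-1."""
    if order == "seeds_then_chains":
        return np.median(np.median(corr, axis=-1), axis=0)
    if order == "chains_then_seeds":
        return np.median(np.median(corr, axis=0), axis=-1)
    raise ValueError(f"unknown aggregation order {order!r}")


def _scores_for(profiles: list[ProfileMatrix], row_idx: np.ndarray,
                seed_idx: np.ndarray, order: str) -> np.ndarray:
    """Aggregated score of each row object against a fixed seed set."""
    corr = np.empty((len(profiles), len(row_idx), len(seed_idx)))
    for t, prof in enumerate(profiles):
        Z = _normalized_ranks(prof.values)
        corr[t] = Z[row_idx] @ Z[seed_idx].T
    return _aggregate_stack(corr, order)


def prioritize(profiles: list[ProfileMatrix], candidates: list[str] | None,
               seeds: list[str], order: str = "seeds_then_chains",
               n_randomizations: int | None = None,
               seed: int | None = None) -> PrioritizationResult:
    """Rank candidates by aggregated seed similarity.

    Candidates default to every profiled object not in the seed set (an
    explicit list mirrors e.g. a knockout-availability filter).  Ties get
    the minimum (competition) rank and are ordered secondarily by id.  When
    ``n_randomizations`` is given, an empirical p-value per candidate is
    computed by re-scoring against that many random seed sets (sampled from
    all profiled objects excluding the candidate) with base random ``seed``.
    """
    if not seeds:
        raise ValueError("seed set is empty")
    index = _profile_index(profiles)
    if candidates is None:
        candidates = [obj for obj in profiles[0].ids if obj not in set(seeds)]
    cand_idx = np.array([_lookup(index, c) for c in candidates], dtype=int)
    seed_idx = np.array([_lookup(index, s) for s in seeds], dtype=int)
    scores = _scores_for(profiles, cand_idx, seed_idx, order)

    frame = pd.DataFrame({"object_id": candidates, "score": scores})
    frame = frame.sort_values(["score", "object_id"],
                              ascending=[False, True], kind="mergesort")
    frame["rank"] = (frame["score"].rank(method="min", ascending=False)
                     .astype(int))
    frame = frame.reset_index(drop=True)

    if n_randomizations is not None:
        rng = np.random.default_rng(seed)
        pvals = [
            _empirical_pvalue_indexed(profiles, index, cand, list(seeds),
                                      n_randomizations, rng, order)
            for cand in frame["object_id"]
        ]
        frame["p_value"] = pvals
    return PrioritizationResult(table=frame, seeds=tuple(seeds),
                                n_randomizations=n_randomizations, seed=seed)


def _empirical_pvalue_indexed(profiles, index, candidate, seeds, n, rng,
                              order, pool=None) -> float:
    ci = _lookup(index, candidate)
    seed_idx = np.array([_lookup(index, s) for s in seeds], dtype=int)
    if pool is None:
        pool_idx = np.array([i for obj, i in index.items() if obj != candidate],
                            dtype=int)
    else:
        pool_idx = np.array([_lookup(index, p) for p in pool if p != candidate],
                            dtype=int)
    k = len(seed_idx)
    if len(pool_idx) < k:
        raise ValueError("population too small to sample seed sets")
    # correlation of the candidate with every pool object, per chain
    corr_pool = np.empty((len(profiles), len(pool_idx)))
    actual = np.empty((len(profiles), k))
    for t, prof in enumerate(profiles):
        Z = _normalized_ranks(prof.values)
        corr_pool[t] = Z[pool_idx] @ Z[ci]
        actual[t] = Z[seed_idx] @ Z[ci]
    actual_score = _aggregate_stack(actual[:, None, :], order)[0]
    draws = np.empty((n, k), dtype=int)
    for r in range(n):
        draws[r] = rng.choice(len(pool_idx), size=k, replace=False)
    rand = corr_pool[:, draws]                      # (chains, n, k)
    rand_scores = _aggregate_stack(rand, order)     # (n,)
    h = int(np.sum(rand_scores >= actual_score))
    return (h + 1) / (n + 1)


def empirical_pvalue(profiles: list[ProfileMatrix], candidate: str,
                     seeds: list[str], n: int, seed: int | None = None,
                     order: str = "seeds_then_chains",
                     pool: list[str] | None = None) -> float:
    """Permutation p-value (h+1)/(n+1) of a candidate's aggregated score.

    ``n`` random seed sets of size ``len(seeds)`` are drawn uniformly
    without replacement from all profiled objects excluding the candidate
    (or from an explicit ``pool``); h counts replicates whose aggregated
    score is >= the actual score.  Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if candidate in seeds:
        raise ValueError(f"candidate {candidate!r} is in the seed set")
    if not seeds:
        raise ValueError("seed set is empty")
    index = _profile_index(profiles)
    rng = np.random.default_rng(seed)
    return _empirical_pvalue_indexed(profiles, index, candidate, list(seeds),
                                     n, rng, order, pool=pool)


def loocv_evaluate(profiles: list[ProfileMatrix], seeds: list[str],
                   controls: list[str],
                   order: str = "seeds_then_chains") -> EvaluationResult:
    """Leave-one-out evaluation of seed recovery against negative controls.

    Each seed in turn is held out and ranked among the controls using the
    remaining seeds; per-fold tie-averaged rank fractions (higher = better)
    are pooled across folds into ROC and precision-recall curves.
    """
    if len(seeds) < 2:
        raise ValueError("need at least two seeds for leave-one-out")
    if not controls:
        raise ValueError("control set is empty")
    overlap = set(seeds) & set(controls)
    if overlap:
        raise ValueError(f"seeds and controls overlap: {sorted(overlap)}")
    y_true: list[int] = []
    y_score: list[float] = []
    folds = []
    for held_out in seeds:
        rest = [s for s in seeds if s != held_out]
        items = [held_out] + [c for c in controls if c != held_out]
        res = prioritize(profiles, items, rest, order=order)
        folds.append(res)
        tbl = res.table.set_index("object_id")
        frac = scipy.stats.rankdata(tbl["score"].to_numpy()) / len(tbl)
        for obj, f in zip(tbl.index, frac):
            y_true.append(1 if obj == held_out else 0)
            y_score.append(float(f))
    fpr, tpr, _ = _skm.roc_curve(y_true, y_score)
    auc = float(_skm.roc_auc_score(y_true, y_score))
    prec, rec, _ = _skm.precision_recall_curve(y_true, y_score)
    auprc = float(_skm.average_precision_score(y_true, y_score))
    return EvaluationResult(
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        auc=auc,
        pr=pd.DataFrame({"recall": rec, "precision": prec}),
        auprc=auprc,
        folds=folds,
    )
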