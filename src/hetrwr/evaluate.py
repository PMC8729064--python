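"""Cross-validation, ROC/PR metrics, restart-probability sweeps, and
novel-entity protocols for lncRNA-disease ranking.

Ten-fold cross-validation partitions the known lncRNA-disease pairs at
random; for each fold the held-out positives are masked out of LD, every
LD-derived quantity (lncRNA annotation sets, lncRNA/disease GIP kernels,
hence the integrated LL and DD similarities) is rebuilt from the training
positives only, the walk is run once per disease with held-out positives,
and scores are pooled into one global ROC/PR per fold.  Held-out pairs are
labelled positive, pairs unknown in the full data are the negatives, and
training positives are excluded from the pool.

``static_similarity`` in the config reproduces the literal protocol in
which similarities are computed once from the full LD matrix — useful for
comparison, but it leaks test labels through the similarity inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .network import initial_vector, laplacian_normalize
from .ontology import annotations_from_matrix
from .pipeline import HeteroDataset, SimilarityBuilder, seed_sets
from .registry import LayerLayout
from .rwr import walk

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "ScoredPairs",
    "CurvePoints",
    "make_folds",
    "run_fold",
    "confusion",
    "metrics",
    "curves_and_areas",
    "cross_validate",
    "lambda_sweep",
    "single_layer_cv",
    "novel_entity_protocol",
    "audit_no_leakage",
]


# ---------------------------------------------------------------------------
# fold plans


@dataclass(frozen=True)
class FoldPlan:
    """A k-way random partition of the positive (lncRNA, disease) pairs."""

    k: int
    seed: int
    pairs: np.ndarray  # (n, 2) index pairs
    folds: tuple[np.ndarray, ...]  # index arrays into `pairs`

    def fold_pairs(self, i: int) -> np.ndarray:
        return self.pairs[self.folds[i]]


def make_folds(positives: np.ndarray | Sequence, k: int, seed: int) -> FoldPlan:
    """Deterministic near-equal partition (fold sizes differ by at most 1)."""
    pairs = np.asarray(positives, dtype=int)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("positives must be an (n, 2) array of index pairs")
    if k < 2:
        raise ValueError("need at least 2 folds")
    if len(pairs) < k:
        raise ValueError(f"only {len(pairs)} positives for {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    return FoldPlan(k, seed, pairs, tuple(np.array_split(perm, k)))


# ---------------------------------------------------------------------------
# per-fold scoring


@dataclass(frozen=True)
class ScoredPairs:
    """Pooled candidate pairs of one fold: test positives vs unknowns."""

    lnc_idx: np.ndarray
    dis_idx: np.ndarray
    scores: np.ndarray
    labels: np.ndarray  # 1 = held-out positive, 0 = unknown pair

    def __len__(self) -> int:
        return len(self.scores)


def _mask_ld(data: HeteroDataset, held_out: np.ndarray) -> np.ndarray:
    ld_train = data.ld.copy()
    if len(held_out):
        ld_train[held_out[:, 0], held_out[:, 1]] = 0.0
    return ld_train


def run_fold(
    data: HeteroDataset,
    held_out: np.ndarray,
    config: RunConfig | None = None,
    builder: SimilarityBuilder | None = None,
    lambdas: Sequence[float] | None = None,
) -> dict[float, ScoredPairs]:
    """Score one fold, optionally for several restart probabilities at once.

    The transition matrix and similarity rebuild are shared across the
    lambda grid; only the walks differ.
    """
    config = config or RunConfig()
    builder = builder or SimilarityBuilder(data, config)
    lambdas = tuple(lambdas) if lambdas is not None else (config.lam,)
    held_out = np.asarray(held_out, dtype=int).reshape(-1, 2)

    ld_train = _mask_ld(data, held_out)
    sims, _ = builder.build(data.ld if config.static_similarity else ld_train)
    W, layout = builder.transition(ld_train, sims=sims)
    lnc_block = layout.block("lncRNA")

    test_by_disease: dict[int, set[int]] = {}
    for l, d in held_out:
        test_by_disease.setdefault(int(d), set()).add(int(l))

    collected: dict[float, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {
        lam: [] for lam in lambdas
    }
    for d, test_lncs in sorted(test_by_disease.items()):
        seeds = seed_sets(data, "disease", d, ld=ld_train)
        p0 = initial_vector(seeds, config.params, layout)
        train_lncs = np.flatnonzero(ld_train[:, d])
        pool = np.setdiff1d(np.arange(data.n("lncRNA")), train_lncs)
        labels = np.isin(pool, sorted(test_lncs)).astype(int)
        for lam in lambdas:
            result = walk(W, p0, lam=lam, tol=config.tol, max_iter=config.max_iter)
            scores = result.p_inf[lnc_block][pool]
            collected[lam].append((pool, np.full(pool.shape, d), labels, scores))

    out: dict[float, ScoredPairs] = {}
    for lam, chunks in collected.items():
        if chunks:
            ls, ds, ys, ss = (np.concatenate(x) for x in zip(*chunks))
        else:  # degenerate empty fold: nothing to score
            ls = ds = ys = ss = np.array([])
        out[lam] = ScoredPairs(ls, ds, ss, ys.astype(int))
    return out


# ---------------------------------------------------------------------------
# confusion counts and curves


def confusion(scored: ScoredPairs, threshold: float) -> tuple[int, int, int, int]:
    """(TP, FN, FP, TN) at a score threshold (strictly-greater rule)."""
    pos = scored.labels == 1
    above = scored.scores > threshold
    tp = int(np.sum(pos & above))
    fn = int(np.sum(pos & ~above))
    fp = int(np.sum(~pos & above))
    tn = int(np.sum(~pos & ~above))
    return tp, fn, fp, tn


@dataclass(frozen=True)
class Rates:
    tpr: float | None
    fpr: float | None
    precision: float | None


def metrics(tp: int, fn: int, fp: int, tn: int) -> Rates:
    """TPR/recall, FPR and precision; None marks an undefined (0/0) rate."""
    tpr = tp / (tp + fn) if (tp + fn) > 0 else None
    fpr = fp / (fp + tn) if (fp + tn) > 0 else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    return Rates(tpr, fpr, precision)


@dataclass(frozen=True)
class CurvePoints:
    """ROC and PR curves over the distinct-score threshold sweep."""

    fpr: np.ndarray
    tpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    auc: float
    aupr: float
    aupr_trapezoid: float


def curves_and_areas(scores: np.ndarray, labels: np.ndarray) -> CurvePoints:
    """Threshold sweep over distinct scores; trapezoidal AUC, step AUPR.

    Grouping tied scores at one threshold makes the trapezoidal ROC area
    equal to the tie-corrected Mann-Whitney statistic.  The step (average
    precision) AUPR sums precision times recall increments; a trapezoidal
    PR area is also reported.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative score")

    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # last index of each distinct-score group
    boundaries = np.r_[np.flatnonzero(np.diff(s) != 0), s.size - 1]
    tps = np.cumsum(y)[boundaries].astype(float)
    fps = boundaries + 1.0 - tps

    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))

    precision = tps / (tps + fps)
    recall = tps / n_pos
    aupr = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    aupr_trap = float(np.trapezoid(np.r_[precision[0], precision], np.r_[0.0, recall]))
    return CurvePoints(
        fpr=fpr,
        tpr=tpr,
        precision=precision,
        recall=recall,
        thresholds=s[boundaries],
        auc=auc,
        aupr=aupr,
        aupr_trapezoid=aupr_trap,
    )


# ---------------------------------------------------------------------------
# cross-validation drivers


@dataclass(frozen=True)
class CVResult:
    """Per-fold pooled AUC/AUPR plus their means."""

    lam: float
    fold_metrics: pd.DataFrame  # columns: fold, auc, aupr
    mean_auc: float
    mean_aupr: float


def cross_validate(
    data: HeteroDataset,
    config: RunConfig | None = None,
    k: int | None = None,
    seed: int | None = None,
    lambdas: Sequence[float] | None = None,
    builder: SimilarityBuilder | None = None,
    plan: FoldPlan | None = None,
) -> dict[float, CVResult]:
    """k-fold CV, sharing fold rebuilds across an optional lambda grid."""
    config = config or RunConfig()
    builder = builder or SimilarityBuilder(data, config)
    lambdas = tuple(lambdas) if lambdas is not None else (config.lam,)
    if plan is None:
        plan = make_folds(
            data.positive_pairs,
            k if k is not None else config.cv_folds,
            seed if seed is not None else config.seed,
        )

    rows: dict[float, list[dict]] = {lam: [] for lam in lambdas}
    for i in range(plan.k):
        scored_by_lam = run_fold(data, plan.fold_pairs(i), config, builder, lambdas)
        for lam, scored in scored_by_lam.items():
            cp = curves_and_areas(scored.scores, scored.labels)
            rows[lam].append({"fold": i, "auc": cp.auc, "aupr": cp.aupr})
        logger.info("fold %d done (%d scored pairs)", i, len(scored_by_lam[lambdas[0]]))

    out: dict[float, CVResult] = {}
    for lam in lambdas:
        df = pd.DataFrame(rows[lam])
        out[lam] = CVResult(lam, df, float(df["auc"].mean()), float(df["aupr"].mean()))
    return out


def lambda_sweep(
    data: HeteroDataset,
    grid: Iterable[float],
    config: RunConfig | None = None,
    k: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full CV at every restart probability in the grid; one row per value."""
    grid = [float(g) for g in grid]
    if not grid or not all(0.0 < g <= 1.0 for g in grid):
        raise ValueError("lambda grid values must lie in (0, 1]")
    results = cross_validate(data, config, k=k, seed=seed, lambdas=grid)
    return pd.DataFrame(
        {
            "lambda": grid,
            "auc": [results[g].mean_auc for g in grid],
            "aupr": [results[g].mean_aupr for g in grid],
        }
    )


def single_layer_cv(
    data: HeteroDataset,
    config: RunConfig | None = None,
    plan: FoldPlan | None = None,
    builder: SimilarityBuilder | None = None,
) -> CVResult:
    """Plain single-layer RWR baseline: walk on the lncRNA similarity
    network only, seeded by the disease's training lncRNAs (uniform restart
    over all lncRNAs when the disease has none).  Plumbing for comparison,
    not a re-implementation of any published competitor."""
    config = config or RunConfig()
    builder = builder or SimilarityBuilder(data, config)
    if plan is None:
        plan = make_folds(data.positive_pairs, config.cv_folds, config.seed)

    n_l = data.n("lncRNA")
    layout = LayerLayout((n_l, 0, 0, 0))
    rows = []
    for i in range(plan.k):
        held_out = plan.fold_pairs(i)
        ld_train = _mask_ld(data, held_out)
        sims, _ = builder.build(data.ld if config.static_similarity else ld_train)
        lap = laplacian_normalize(sims["lncRNA"])
        rs = lap.sum(axis=1, keepdims=True)
        W = np.where(rs > 0, lap / rs, 0.0)

        test_by_disease: dict[int, set[int]] = {}
        for l, d in held_out:
            test_by_disease.setdefault(int(d), set()).add(int(l))
        all_scores, all_labels = [], []
        for d, test_lncs in sorted(test_by_disease.items()):
            seeds = np.flatnonzero(ld_train[:, d])
            p0 = np.zeros(n_l)
            if seeds.size:
                p0[seeds] = 1.0 / seeds.size
            else:
                p0[:] = 1.0 / n_l
            result = walk(W, p0, lam=config.lam, tol=config.tol, max_iter=config.max_iter)
            pool = np.setdiff1d(np.arange(n_l), seeds if seeds.size else np.array([], int))
            all_scores.append(result.p_inf[pool])
            all_labels.append(np.isin(pool, sorted(test_lncs)).astype(int))
        cp = curves_and_areas(np.concatenate(all_scores), np.concatenate(all_labels))
        rows.append({"fold": i, "auc": cp.auc, "aupr": cp.aupr})
    df = pd.DataFrame(rows)
    return CVResult(config.lam, df, float(df["auc"].mean()), float(df["aupr"].mean()))


# ---------------------------------------------------------------------------
# novel-entity protocols and leakage audit


def novel_entity_protocol(
    data: HeteroDataset,
    entity: str,
    layer: str,
    config: RunConfig | None = None,
    builder: SimilarityBuilder | None = None,
) -> pd.DataFrame:
    """Treat a disease (or lncRNA) as novel: mask all its LD associations,
    rebuild, and rank the opposite layer.

    The returned frame carries a ``was_associated`` column taken from the
    unmasked data — the evaluation ground truth, never an input to the walk.
    """
    if layer not in ("disease", "lncRNA"):
        raise ValueError("novel-entity protocol applies to diseases and lncRNAs")
    config = config or RunConfig()
    builder = builder or SimilarityBuilder(data, config)
    idx = data.registry(layer).index(entity)

    ld_masked = data.ld.copy()
    if layer == "disease":
        ld_masked[:, idx] = 0.0
        target = "lncRNA"
        truth = np.flatnonzero(data.ld[:, idx])
    else:
        ld_masked[idx, :] = 0.0
        target = "disease"
        truth = np.flatnonzero(data.ld[idx, :])

    W, layout = builder.transition(ld_masked)
    seeds = seed_sets(data, layer, idx, ld=ld_masked)
    p0 = initial_vector(seeds, config.params, layout)
    result = walk(W, p0, lam=config.lam, tol=config.tol, max_iter=config.max_iter)

    reg = data.registry(target)
    scores = result.p_inf[layout.block(target)]
    order = sorted(range(len(reg)), key=lambda i: (-scores[i], i))
    truth_ids = {reg.ids[i] for i in truth}
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(reg) + 1),
            target: [reg.ids[i] for i in order],
            "score": [scores[i] for i in order],
            "was_associated": [reg.ids[i] in truth_ids for i in order],
        }
    )


def audit_no_leakage(data: HeteroDataset, plan: FoldPlan) -> bool:
    """Verify, fold by fold, that every held-out pair is absent from the
    training LD matrix, from the lncRNA annotation sets derived from it,
    and from the walk's seed sets.  Raises AssertionError on violation."""
    l_reg, d_reg = data.registry("lncRNA"), data.registry("disease")
    for i in range(plan.k):
        held_out = plan.fold_pairs(i)
        ld_train = _mask_ld(data, held_out)
        ann = annotations_from_matrix(ld_train, l_reg, d_reg)
        for l, d in held_out:
            l_id, d_id = l_reg.ids[l], d_reg.ids[d]
            assert ld_train[l, d] == 0, f"fold {i}: pair ({l_id},{d_id}) left in training LD"
            assert d_id not in ann.get(l_id, frozenset()), (
                f"fold {i}: held-out disease {d_id} leaked into {l_id}'s annotations"
            )
            seeds = seed_sets(data, "disease", int(d), ld=ld_train)
            assert l not in seeds["lncRNA"], (
                f"fold {i}: held-out lncRNA {l_id} leaked into {d_id}'s seed set"
            )
    return True
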