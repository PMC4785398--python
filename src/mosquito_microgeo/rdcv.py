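"""Repeated double cross-validated random-forest classification.

The procedure estimates how well sample provenance (village of capture)
can be predicted from microbiota composition while guarding against
overfitting at small n:

* an *outer* cross-validation loop holds out each sample exactly once per
  repetition and is used only for prediction;
* an *inner* loop, run on each outer-training portion, tunes the number
  of OTUs by backward elimination — at every step the 10% of OTUs with
  the worst average importance rank across the inner-segment forests are
  removed, and the OTU set with the fewest inner-validation
  misclassifications (ties toward fewer OTUs) is selected;
* one forest per outer fold is then refit on the full outer-training
  portion restricted to the selected OTUs and predicts class
  probabilities for the held-out samples;
* the whole double loop is repeated (default 200 times) with fresh fold
  splits, yielding a *population* of class probabilities per observation
  rather than a point estimate.  The consensus class is the argmax of the
  repetition-mean probability.

Every forest that predicts a sample was trained without that sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .table import OtuTable

__all__ = [
    "RdcvConfig",
    "RdcvResult",
    "make_folds",
    "rank_otus",
    "eliminate_step",
    "inner_tune",
    "run_rdcv",
    "importance_summary",
    "RdcvClassifier",
]

_SEED_MOD = 2**31 - 1


@dataclass
class RdcvConfig:
    """Tuning knobs of the repeated double cross-validation scheme.

    ``n_rep`` repetitions of the double loop (full-scale default 200);
    ``drop_fraction`` of OTUs removed per elimination step (default the
    10% least informative); ``n_outer``/``n_inner`` fold counts;
    ``forest_size`` trees per outer-model forest (``inner_forest_size``
    may be smaller for the tuning forests, which only need a stable
    importance ranking); ``min_otus`` floor of the elimination;
    ``importance`` is "impurity" (default) or "permutation" (out-of-bag
    permutation importance; markedly slower).
    """

    n_rep: int = 200
    n_outer: int = 6
    n_inner: int = 5
    drop_fraction: float = 0.10
    forest_size: int = 100
    inner_forest_size: int | None = None
    min_otus: int = 2
    stratified: bool = True
    importance: str = "impurity"
    seed: int = 0

    def validate(self, labels: np.ndarray | None = None) -> None:
        if self.n_rep < 1 or self.n_outer < 2 or self.n_inner < 2:
            raise ValueError("n_rep >= 1 and fold counts >= 2 required")
        if not 0.0 < self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must be in (0, 1)")
        if self.forest_size < 1 or self.min_otus < 2:
            raise ValueError("forest_size >= 1 and min_otus >= 2 required")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError(f"unknown importance {self.importance!r}")
        if labels is not None:
            classes, counts = np.unique(labels, return_counts=True)
            if classes.size < 2:
                raise ValueError("need at least two classes")
            if self.stratified and counts.min() < self.n_outer:
                raise ValueError(
                    f"smallest class ({counts.min()}) has fewer members than "
                    f"n_outer={self.n_outer} stratified folds"
                )

    @property
    def inner_trees(self) -> int:
        return self.inner_forest_size or self.forest_size


@dataclass
class RdcvResult:
    """Output of one repeated-double-CV run."""

    sample_ids: tuple[str, ...]
    classes: tuple
    otu_ids: tuple[str, ...]
    #: shape (n_obs, n_classes, n_rep); each (obs, rep) slice sums to 1
    prob: np.ndarray
    consensus_prob: np.ndarray
    consensus_class: np.ndarray
    n_misclassified: int
    #: shape (n_rep, n_outer): size of the selected OTU set per outer model
    selected_n_otus: np.ndarray
    #: per-OTU average importance rank over all outer models (1 = best)
    importance_rank: np.ndarray
    #: (repetition, fold, held_out_indices) audit log of outer folds
    fold_log: list = field(default_factory=list, repr=False)


def make_folds(labels, n_folds: int, stratified: bool = True,
               seed: int | None = 0) -> list[np.ndarray]:
    """Disjoint folds covering all observations, sizes differing by <= 1.

    Stratified folds preserve class proportions as closely as integer
    counts allow.  Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds {n} observations")
    if stratified:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros((n, 1)), labels)]


def rank_otus(importances: Sequence[np.ndarray]) -> np.ndarray:
    """Average rank (1 = most informative) of each OTU across models.

    Within each model OTUs are ranked by descending importance with ties
    averaged; the returned vector is the mean rank over models.
    """
    if len(importances) == 0:
        raise ValueError("need at least one model")
    mats = np.asarray(importances, dtype=float)
    if mats.ndim != 2:
        raise ValueError("models disagree on the OTU set")
    ranks = np.apply_along_axis(lambda v: rankdata(-v, method="average"), 1, mats)
    return ranks.mean(axis=0)


def eliminate_step(active_otus: Sequence, avg_rank: Sequence[float],
                   drop_fraction: float, min_otus: int) -> list:
    """Remove the worst-ranked ``ceil(drop_fraction * n)`` OTUs.

    Never reduces the set below ``min_otus``; ties at the cut are broken
    by the stable order of ``active_otus``.  Ceil guarantees progress even
    for very small sets.
    """
    active = list(active_otus)
    ranks = np.asarray(avg_rank, dtype=float)
    if ranks.size != len(active):
        raise ValueError("avg_rank length must match active_otus")
    n = len(active)
    if n <= min_otus:
        return active
    n_drop = min(math.ceil(drop_fraction * n), n - min_otus)
    # stable sort: worst average rank dropped first, position breaks ties
    order = np.lexsort((np.arange(n), ranks))
    keep = sorted(order[: n - n_drop])
    return [active[i] for i in keep]


def _forest(n_trees: int, rng: np.random.Generator) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        random_state=int(rng.integers(_SEED_MOD)),
        n_jobs=1,
    )


def _importance(forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray,
                kind: str, rng: np.random.Generator) -> np.ndarray:
    if kind == "impurity":
        return forest.feature_importances_
    # permutation importance: accuracy drop when one column is shuffled
    base = forest.score(X, y)
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        out[j] = base - forest.score(Xp, y)
    return out


def inner_tune(train_X: np.ndarray, train_y: np.ndarray, config: RdcvConfig,
               rng: np.random.Generator | None = None
               ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Backward OTU elimination tuned by inner-loop misclassifications.

    Runs ``n_inner``-fold CV inside the outer-training set; at each
    elimination step records total inner-validation misclassifications for
    the current OTU set, then removes the ``drop_fraction`` of OTUs with
    the worst average importance rank across the inner-segment forests.
    After reaching ``min_otus`` the OTU set minimising the inner
    misclassification count is selected, ties resolved toward fewer OTUs.

    Returns the selected feature indices (into the columns of
    ``train_X``) and the tuning curve as (n_otus, misclassifications)
    pairs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if np.unique(train_y).size < 2:
        raise ValueError("need >= 2 classes in the training labels")
    folds = make_folds(train_y, config.n_inner, config.stratified,
                       seed=int(rng.integers(_SEED_MOD)))
    all_idx = np.arange(train_y.size)
    active = list(range(train_X.shape[1]))
    curve: list[tuple[int, int]] = []
    candidates: list[list[int]] = []
    while True:
        cols = np.asarray(active)
        miss = 0
        imps = []
        for test in folds:
            train = np.setdiff1d(all_idx, test, assume_unique=True)
            f = _forest(config.inner_trees, rng)
            f.fit(train_X[np.ix_(train, cols)], train_y[train])
            pred = f.predict(train_X[np.ix_(test, cols)])
            miss += int((pred != train_y[test]).sum())
            imps.append(_importance(f, train_X[np.ix_(train, cols)],
                                    train_y[train], config.importance, rng))
        curve.append((len(active), miss))
        candidates.append(active.copy())
        if len(active) <= config.min_otus:
            break
        avg_rank = rank_otus(imps)
        active = eliminate_step(active, avg_rank, config.drop_fraction, config.min_otus)
    # argmin of misclassifications; ties toward fewer OTUs (later steps)
    best = 0
    for s in range(1, len(curve)):
        if curve[s][1] <= curve[best][1]:
            best = s
    return np.asarray(candidates[best]), curve


def _as_matrix(data: OtuTable | np.ndarray) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    if isinstance(data, OtuTable):
        counts = data.counts.astype(float)
        depths = counts.sum(axis=1)
        if (depths == 0).any():
            raise ValueError("zero-depth sample")
        return counts / depths[:, None], data.sample_ids, data.otu_ids
    X = np.asarray(data, dtype=float)
    return (X,
            tuple(f"S{i}" for i in range(X.shape[0])),
            tuple(f"F{j}" for j in range(X.shape[1])))


def run_rdcv(data: OtuTable | np.ndarray, labels, config: RdcvConfig | None = None
             ) -> RdcvResult:
    """Run the full repeated double cross-validation procedure.

    ``data`` is an OTU table (features are per-sample relative
    abundances) or a plain feature matrix.  Deterministic given
    ``config.seed``; repetition r draws its folds and forests from a
    child stream seeded by (seed, r), so repetitions are independent.
    """
    config = config or RdcvConfig()
    y = np.asarray(labels)
    X, sample_ids, otu_ids = _as_matrix(data)
    if y.size != X.shape[0]:
        raise ValueError("one label per sample required")
    config.validate(y)
    classes = np.unique(y)          # lexicographic order; argmax tie -> first
    n, p = X.shape
    K = classes.size
    class_pos = {c: i for i, c in enumerate(classes)}

    prob = np.full((n, K, config.n_rep), np.nan)
    selected_n = np.zeros((config.n_rep, config.n_outer), dtype=int)
    rank_sum = np.zeros(p)
    n_models = 0
    fold_log = []
    worst_tail = lambda m: (m + 1 + p) / 2.0   # tied rank of unselected OTUs

    for r in range(config.n_rep):
        rng = np.random.default_rng([config.seed % _SEED_MOD, r])
        folds = make_folds(y, config.n_outer, config.stratified,
                           seed=int(rng.integers(_SEED_MOD)))
        for f_idx, test in enumerate(folds):
            train = np.setdiff1d(np.arange(n), test, assume_unique=True)
            sel, _curve = inner_tune(X[train], y[train], config, rng)
            selected_n[r, f_idx] = sel.size
            forest = _forest(config.forest_size, rng)
            forest.fit(X[np.ix_(train, sel)], y[train])
            pp = forest.predict_proba(X[np.ix_(test, sel)])
            for local_c, c in enumerate(forest.classes_):
                prob[test, class_pos[c], r] = pp[:, local_c]
            for c in classes:
                if c not in forest.classes_:
                    prob[test, class_pos[c], r] = 0.0
            # aggregate importance ranks over the whole OTU set
            imp = _importance(forest, X[np.ix_(train, sel)], y[train],
                              config.importance, rng)
            local_rank = rankdata(-imp, method="average")
            model_rank = np.full(p, worst_tail(sel.size))
            model_rank[sel] = local_rank
            rank_sum += model_rank
            n_models += 1
            fold_log.append((r, f_idx, test.copy()))

    consensus_prob = prob.mean(axis=2)
    consensus_class = classes[np.argmax(consensus_prob, axis=1)]
    n_miss = int((consensus_class != y).sum())
    return RdcvResult(
        sample_ids=sample_ids,
        classes=tuple(classes.tolist()),
        otu_ids=otu_ids,
        prob=prob,
        consensus_prob=consensus_prob,
        consensus_class=consensus_class,
        n_misclassified=n_miss,
        selected_n_otus=selected_n,
        importance_rank=rank_sum / n_models,
        fold_log=fold_log,
    )


def importance_summary(result: RdcvResult, taxonomy=None) -> pd.DataFrame:
    """Aggregate per-OTU average ranks to genus level (best OTU per genus).

    Returns a DataFrame sorted by rank (most informative genus first)
    with columns genus, best_rank, best_otu, n_otus.
    """
    from .table import _parse_lineage

    genera = []
    for o in result.otu_ids:
        lin = (taxonomy or {}).get(o)
        genera.append(_parse_lineage(lin).get("genus", "unclassified") if lin else "unclassified")
    df = pd.DataFrame({
        "otu_id": list(result.otu_ids),
        "genus": genera,
        "avg_rank": result.importance_rank,
    })
    agg = (
        df.loc[df.groupby("genus")["avg_rank"].idxmin()]
        .rename(columns={"avg_rank": "best_rank", "otu_id": "best_otu"})
        .merge(df.groupby("genus").size().rename("n_otus"), on="genus")
        .sort_values(["best_rank", "genus"], kind="stable")
        .reset_index(drop=True)
    )
    return agg[["genus", "best_rank", "best_otu", "n_otus"]]


class RdcvClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style front end to the repeated double CV procedure.

    ``fit(X, y)`` runs the full scheme on the training data, exposing the
    per-observation probability population (``prob_``), the consensus
    classes and misclassification count, and the OTU importance ranking.
    For predicting *new* samples a deployment forest is refit on all
    training data restricted to the top-k OTUs, where k is the median
    selected OTU-set size across outer models.

    Parameters mirror :class:`RdcvConfig`.
    """

    def __init__(self, n_rep: int = 200, n_outer: int = 6, n_inner: int = 5,
                 drop_fraction: float = 0.10, forest_size: int = 100,
                 inner_forest_size: int | None = None, min_otus: int = 2,
                 stratified: bool = True, importance: str = "impurity",
                 random_state: int = 0):
        self.n_rep = n_rep
        self.n_outer = n_outer
        self.n_inner = n_inner
        self.drop_fraction = drop_fraction
        self.forest_size = forest_size
        self.inner_forest_size = inner_forest_size
        self.min_otus = min_otus
        self.stratified = stratified
        self.importance = importance
        self.random_state = random_state

    def _config(self) -> RdcvConfig:
        return RdcvConfig(
            n_rep=self.n_rep, n_outer=self.n_outer, n_inner=self.n_inner,
            drop_fraction=self.drop_fraction, forest_size=self.forest_size,
            inner_forest_size=self.inner_forest_size, min_otus=self.min_otus,
            stratified=self.stratified, importance=self.importance,
            seed=self.random_state,
        )

    def fit(self, X, y) -> "RdcvClassifier":
        config = self._config()
        res = run_rdcv(X, np.asarray(y), config)
        self.result_ = res
        self.classes_ = np.asarray(res.classes)
        self.prob_ = res.prob
        self.consensus_prob_ = res.consensus_prob
        self.consensus_class_ = res.consensus_class
        self.n_misclassified_ = res.n_misclassified
        self.importance_rank_ = res.importance_rank
        # deployment model on all data, top-k OTUs by aggregated rank
        k = max(int(np.median(res.selected_n_otus)), config.min_otus)
        order = np.lexsort((np.arange(res.importance_rank.size), res.importance_rank))
        self.selected_otus_ = np.sort(order[:k])
        Xm, _, _ = _as_matrix(X)
        rng = np.random.default_rng([config.seed % _SEED_MOD, config.n_rep])
        self.deployment_forest_ = _forest(config.forest_size, rng)
        self.deployment_forest_.fit(Xm[:, self.selected_otus_], np.asarray(y))
        return self

    def predict_proba(self, X) -> np.ndarray:
        Xm, _, _ = _as_matrix(X)
        return self.deployment_forest_.predict_proba(Xm[:, self.selected_otus_])

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
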