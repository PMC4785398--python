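"""Distance-based community analyses.

Implements the Morisita-Horn ("horn") dissimilarity, pairwise distance
matrices, hierarchical clustering, non-metric multidimensional scaling
(NMDS, Kruskal stress-1 minimised by alternating isotonic regression and
Guttman updates), one-factor permutational multivariate ANOVA
(PERMANOVA), and Pearson co-occurrence matrices.

Note on "horn": this is the abundance-based Morisita-Horn overlap index

    d(x, y) = 1 - 2 * sum_i x_i y_i /
              [ (sum_i x_i^2 / X^2 + sum_i y_i^2 / Y^2) * X * Y ]

with X = sum x_i, Y = sum y_i — the formula behind the "horn" method of
the standard community-ecology distance functions — not Horn's 1966
information-theoretic overlap.  It is symmetric, lies in [0, 1], and is
invariant to rescaling either sample's total depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .table import OtuTable

__all__ = [
    "DistanceMatrix",
    "NmdsResult",
    "horn_dissimilarity",
    "distance_matrix",
    "hierarchical_cluster",
    "NMDS",
    "nmds",
    "permanova",
    "cooccurrence",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal over sample ids."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if v.size and v.min() < -1e-12:
            raise ValueError("negative distances")
        v = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(v, 0.0)
        v.setflags(write=False)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def horn_dissimilarity(x, y) -> float:
    """Morisita-Horn dissimilarity between two count vectors, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative counts")
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        raise ValueError("zero-sum vector")
    lam = (x @ x) / X**2 + (y @ y) / Y**2
    d = 1.0 - 2.0 * (x @ y) / (lam * X * Y)
    return float(min(max(d, 0.0), 1.0))


def distance_matrix(table: OtuTable, metric: str = "horn") -> DistanceMatrix:
    """Pairwise dissimilarity matrix over the table's samples."""
    if metric != "horn":
        raise ValueError(f"unsupported metric {metric!r}")
    counts = table.counts.astype(float)
    depths = counts.sum(axis=1)
    zero = [s for s, d in zip(table.sample_ids, depths) if d == 0]
    if zero:
        raise ValueError(f"zero-depth samples: {zero}")
    p = counts / depths[:, None]
    lam = np.einsum("ij,ij->i", p, p)            # simpson-type concentration per sample
    cross = p @ p.T
    d = 1.0 - 2.0 * cross / (lam[:, None] + lam[None, :])
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.sample_ids, np.clip((d + d.T) / 2, 0.0, 1.0))


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "average") -> np.ndarray:
    """Agglomerative clustering; returns the scipy-format merge matrix Z.

    Each row of Z is (cluster_a, cluster_b, merge_height, new_size).
    """
    if d.n < 2:
        raise ValueError("need at least two samples to cluster")
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    return _scipy_linkage(d.condensed(), method=linkage)


@dataclass(frozen=True)
class NmdsResult:
    coordinates: np.ndarray
    stress: float
    n_starts_used: int
    converged: bool
    seed: int | None


def _kruskal_stress(delta_hat: np.ndarray, dist: np.ndarray) -> float:
    denom = float(dist @ dist)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((delta_hat - dist) ** 2) / denom))


def _config_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return squareform(np.sqrt((diff**2).sum(-1)), checks=False)


def _classical_mds(values: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric scaling used as the deterministic start."""
    n = values.shape[0]
    d2 = values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


class NMDS(BaseEstimator):
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    Alternates a monotone (isotonic, ties averaged) regression of the
    configuration distances on the input dissimilarities with a Guttman
    transform of the configuration toward the fitted disparities.  Runs
    one metric-scaling (Torgerson) start plus ``n_starts`` random starts
    and keeps the lowest-stress configuration; the result therefore never
    has higher stress than the metric start.  Non-convergence within
    ``max_iter`` is reported through ``converged_``, not raised.

    Attributes (after ``fit``)
    --------------------------
    embedding_ : (n, n_components) configuration.
    stress_ : Kruskal stress-1 of ``embedding_``.
    n_starts_used_ : number of starts actually run.
    converged_ : True if the best start met the tolerance.
    """

    def __init__(self, n_components: int = 2, n_starts: int = 8,
                 max_iter: int = 300, tol: float = 1e-7,
                 random_state: int | None = 0):
        self.n_components = n_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, d: DistanceMatrix | np.ndarray, y=None) -> "NMDS":
        values = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
        n = values.shape[0]
        k = self.n_components
        if n < k + 1:
            raise ValueError(f"need at least {k + 1} samples for {k}-D NMDS")
        delta = squareform(values, checks=False)
        order = np.argsort(delta, kind="stable")
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        rng = np.random.default_rng(self.random_state)

        def run(start: np.ndarray) -> tuple[np.ndarray, float, bool]:
            coords = start.copy()
            dist = _config_distances(coords)
            prev = np.inf
            converged = False
            best_coords, best_stress = coords, np.inf
            for _ in range(self.max_iter):
                if dist.max() == 0:
                    break
                dhat = np.empty_like(dist)
                dhat[order] = iso.fit_transform(delta[order], dist[order])
                stress = _kruskal_stress(dhat, dist)
                if stress < best_stress:
                    best_stress, best_coords = stress, coords.copy()
                if prev - stress < self.tol:
                    converged = True
                    break
                prev = stress
                # Guttman transform toward the disparities
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.where(dist > 0, dhat / dist, 0.0)
                b = -squareform(ratio, checks=False)
                np.fill_diagonal(b, -b.sum(axis=1))
                coords = b @ coords / n
                dist = _config_distances(coords)
            return best_coords, best_stress, converged

        starts = [_classical_mds(values, k)]
        scale = np.sqrt(np.mean(delta**2)) if delta.size else 1.0
        for _ in range(self.n_starts):
            starts.append(rng.normal(scale=scale, size=(n, k)))

        best: tuple[np.ndarray, float, bool] | None = None
        for start in starts:
            res = run(start)
            if best is None or res[1] < best[1]:
                best = res
        assert best is not None
        coords, stress, converged = best
        # center for a canonical gauge; stress is rotation/translation invariant
        self.embedding_ = coords - coords.mean(axis=0)
        self.stress_ = stress
        self.n_starts_used_ = len(starts)
        self.converged_ = converged
        return self

    def fit_transform(self, d: DistanceMatrix | np.ndarray, y=None) -> np.ndarray:
        return self.fit(d).embedding_


def nmds(d: DistanceMatrix, k: int = 2, n_starts: int = 8, max_iter: int = 300,
         tol: float = 1e-7, seed: int | None = 0) -> NmdsResult:
    """Functional wrapper over the :class:`NMDS` estimator."""
    est = NMDS(n_components=k, n_starts=n_starts, max_iter=max_iter,
               tol=tol, random_state=seed).fit(d)
    return NmdsResult(est.embedding_, est.stress_, est.n_starts_used_,
                      est.converged_, seed)


def _permanova_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = labels.size
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    k = groups.size
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(d: DistanceMatrix, groups, n_perm: int = 9999,
              seed: int | None = 0) -> tuple[float, float]:
    """One-factor PERMANOVA: pseudo-F and permutation p-value.

    The pseudo-F partitions the sum of squared distances into between-
    and within-group components; significance comes from shuffling the
    group labels, with ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    labels = np.asarray(groups)
    if labels.size != d.n:
        raise ValueError("one label per sample required")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    if np.max([np.sum(labels == g) for g in uniq]) == labels.size:
        raise ValueError("one group absorbs all samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d2 = d.values**2
    f_obs = _permanova_f(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = labels.copy()
    for _ in range(int(n_perm)):
        rng.shuffle(perm)
        if _permanova_f(d2, perm, uniq) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + int(n_perm))
    return float(f_obs), float(p)


def cooccurrence(table: OtuTable, level: str = "otu") -> "pd.DataFrame":
    """Pearson correlation of relative abundances across samples.

    ``level="genus"`` first aggregates OTU counts by genus (unannotated
    OTUs grouped under "unclassified").  Zero-variance features yield NaN
    rows/columns (undefined correlation) rather than an error.
    """
    import pandas as pd

    if table.n_samples < 3:
        raise ValueError("need at least three samples for correlation")
    depths = table.sample_depths().astype(float)
    if (depths == 0).any():
        raise ValueError("zero-depth sample")
    rel = table.counts / depths[:, None]
    if level == "otu":
        feats = pd.DataFrame(rel, columns=list(table.otu_ids))
    elif level == "genus":
        if table.taxonomy is None:
            raise ValueError("genus-level co-occurrence requires taxonomy")
        genera = [table.lineage_at(o, "genus") or "unclassified" for o in table.otu_ids]
        feats = pd.DataFrame(rel, columns=genera).T.groupby(level=0).sum().T
    else:
        raise ValueError(f"unknown level {level!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = feats.corr(method="pearson")
    zero_var = feats.std(axis=0) == 0
    corr.loc[zero_var, :] = np.nan
    corr.loc[:, zero_var] = np.nan
    np.fill_diagonal(corr.values, np.where(zero_var, np.nan, 1.0))
    return corr
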