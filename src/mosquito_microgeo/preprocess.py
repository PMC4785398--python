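"""Depth-based sample filtering and rarefaction.

Samples with too few reads are removed (default floor 7,500 reads,
the kind of threshold read off rarefaction curves), and the remaining samples are
rarefied — subsampled without replacement — to a common depth, by default
the smallest remaining sample depth.  Rarefaction uses multivariate
hypergeometric draws, the ecological convention, so per-OTU expectations
and variances are exactly hypergeometric and testable.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln

from .table import OtuTable

__all__ = ["DEFAULT_MIN_READS", "filter_low_depth", "rarefy", "rarefaction_curve"]

DEFAULT_MIN_READS = 7500


def filter_low_depth(table: OtuTable, min_reads: int = DEFAULT_MIN_READS
                     ) -> tuple[OtuTable, list[str]]:
    """Drop samples with fewer than `min_reads` total reads.

    Returns the filtered table and the removed sample ids sorted by depth
    ascending.  A sample with exactly `min_reads` reads is retained — the
    rule removes samples with *less than* the threshold.
    """
    if min_reads <= 0:
        raise ValueError("min_reads must be positive")
    depths = table.sample_depths()
    keep = [s for s, d in zip(table.sample_ids, depths) if d >= min_reads]
    removed = sorted(
        (s for s, d in zip(table.sample_ids, depths) if d < min_reads),
        key=lambda s: depths[table.sample_index(s)],
    )
    return table.select_samples(keep), removed


def rarefy(table: OtuTable, depth: int | Literal["min"] = "min",
           seed: int | np.random.Generator = 0) -> OtuTable:
    """Subsample every sample without replacement to a common depth.

    ``depth="min"`` resolves to the smallest sample depth.  Each row is a
    multivariate hypergeometric draw from that sample's counts, so
    ``rarefied[i, j] <= counts[i, j]`` always and every row sums exactly
    to ``depth``.  Deterministic given ``seed``.
    """
    depths = table.sample_depths()
    if depth == "min":
        depth = int(depths.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    too_shallow = [s for s, d in zip(table.sample_ids, depths) if d < depth]
    if too_shallow:
        raise ValueError(
            f"rarefaction depth {depth} exceeds the total reads of samples {too_shallow}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return replace(table, counts=out)


def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(k + 1) - gammaln(np.asarray(n) - k + 1)


def rarefaction_curve(sample_counts: Sequence[int], depths: Sequence[int],
                      mode: Literal["analytic", "montecarlo"] = "analytic",
                      reps: int = 100, seed: int = 0) -> np.ndarray:
    """Expected number of OTUs observed when subsampling to each depth.

    Analytic mode evaluates the hypergeometric expectation
    ``E[S(d)] = sum_i (1 - C(N - N_i, d) / C(N, d))`` in log space, where
    ``N`` is the sample total and ``N_i`` the count of OTU ``i``; Monte
    Carlo mode averages observed richness over ``reps`` hypergeometric
    subsamples.  The curve is non-decreasing in depth.
    """
    counts = np.asarray(sample_counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative counts")
    counts = counts[counts > 0]
    total = int(counts.sum())
    depths_arr = np.asarray(depths, dtype=np.int64)
    if (depths_arr > total).any():
        raise ValueError(f"depth exceeds sample total {total}")
    if (depths_arr < 0).any():
        raise ValueError("negative depth")
    out = np.empty(len(depths_arr), dtype=float)
    if mode == "analytic":
        for j, d in enumerate(depths_arr):
            # P(OTU i unseen) = C(N - N_i, d) / C(N, d); zero when d > N - N_i
            rem = total - counts
            seen = np.ones(len(counts))
            ok = rem >= d
            if ok.any():
                log_p_unseen = _log_comb(rem[ok], float(d)) - _log_comb(total, float(d))
                seen[ok] = 1.0 - np.exp(log_p_unseen)
            out[j] = seen.sum()
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        for j, d in enumerate(depths_arr):
            hits = np.zeros(reps)
            for r in range(reps):
                sub = rng.multivariate_hypergeometric(counts, int(d))
                hits[r] = np.count_nonzero(sub)
            out[j] = hits.mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out
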