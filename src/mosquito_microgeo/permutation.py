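"""Permutation-based model validity testing.

A classifier evaluated at small n can look good by overfitting alone, so
model validity is assessed against an explicit null: the labels are
permuted without replacement, the full repeated-double-CV procedure is
rerun, and the misclassification count recorded — many times over —
giving the "H0 population".  The observed model's misclassification
count is then located in a Student-t fit (location/scale by sample
moments, df = n_models - 1) of that population; its lower-tail
cumulative probability is the model p-value.

A closed form accompanies the simulation: when predictions carry no
label information, the expected misclassification count under label
permutation is ``n - sum_k n_k^2 / n`` (for K balanced classes,
``(1 - 1/K) * n``), which the estimated H0 mean should reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .rdcv import RdcvConfig, run_rdcv
from .table import OtuTable

__all__ = ["H0Population", "predicted_h0_mean", "build_h0", "pvalue"]


@dataclass(frozen=True)
class H0Population:
    """Misclassification counts from permuted-label models.

    ``skewness`` and ``excess_kurtosis`` are shape diagnostics for
    judging whether a t-distribution describes the population (the
    classical check is a histogram inspection).
    """

    counts: tuple[int, ...]
    n_models: int
    mean: float
    sd: float
    df: int
    skewness: float
    excess_kurtosis: float
    p_value: float | None = None

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "H0Population":
        arr = np.asarray(counts, dtype=float)
        if arr.size < 2:
            raise ValueError("need at least two null models")
        degenerate = arr.std() == 0
        return cls(
            counts=tuple(int(c) for c in counts),
            n_models=arr.size,
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)),
            df=arr.size - 1,
            skewness=float("nan") if degenerate else float(stats.skew(arr)),
            excess_kurtosis=float("nan") if degenerate else float(stats.kurtosis(arr)),
        )


def predicted_h0_mean(class_sizes: Sequence[int]) -> float:
    """Expected misclassifications under label permutation, no information.

    ``n - sum_k n_k^2 / n``: if predicted labels are drawn independently
    of the (permuted) truth with the class frequencies of the data, a
    sample of class k is matched with probability n_k/n.  For K balanced
    classes this is ``(1 - 1/K) * n`` — e.g. three balanced classes over
    29 observations give 2/3 * 29 = 19.33.
    """
    sizes = np.asarray(class_sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("class_sizes is empty")
    if (sizes <= 0).any():
        raise ValueError("class sizes must be positive")
    n = sizes.sum()
    return float(n - (sizes**2).sum() / n)


def build_h0(data: OtuTable | np.ndarray, labels, config: RdcvConfig | None = None,
             n_models: int = 400, seed: int = 0,
             null_reps: int = 10) -> H0Population:
    """Build the permuted-label H0 misclassification population.

    Each of the ``n_models`` null models permutes the labels uniformly
    without replacement and reruns the full double-CV procedure.  Null
    models run with ``null_reps`` repetitions instead of the observed
    model's ``config.n_rep`` (the null mean is insensitive to repetition
    count); pass ``null_reps=config.n_rep`` for fully faithful nulls.
    Deterministic given ``seed``.
    """
    if n_models < 2:
        raise ValueError("n_models must be >= 2")
    config = config or RdcvConfig()
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    counts = []
    for m in range(n_models):
        perm = rng.permutation(y)
        null_config = replace(config, n_rep=null_reps,
                              seed=int(rng.integers(2**31 - 1)))
        res = run_rdcv(data, perm, null_config)
        counts.append(res.n_misclassified)
    return H0Population.from_counts(counts)


def pvalue(observed_misclassifications: int, h0: H0Population) -> float:
    """Lower-tail t probability of the observed count in the H0 population.

    ``p = T_df((observed - mean) / sd)`` with df = n_models - 1: small
    p means the model misclassifies far fewer samples than permuted-label
    models do, i.e. the classification carries real information.
    Monotone increasing in the observed count.
    """
    if h0.sd <= 0:
        raise ValueError("degenerate null population (sd = 0)")
    t = (observed_misclassifications - h0.mean) / h0.sd
    return float(stats.t.cdf(t, df=h0.df))
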