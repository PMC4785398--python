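"""Tabular reports over taxa and classification results.

Covers the taxon-focused questions asked of the classifier's results:
how abundant is a marker taxon (e.g. the genus Wolbachia) per sample and
per location, and in what fraction of each location's samples does it
occur at all.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .table import OtuTable, SampleMetadata, relative_abundance, subset_by_taxon

__all__ = ["taxon_report"]


def taxon_report(table: OtuTable, metadata: Sequence[SampleMetadata],
                 taxa: Sequence[tuple[str, str]]) -> dict[str, pd.DataFrame]:
    """Per-sample and per-location abundance report for a list of taxa.

    Returns ``{"per_sample": ..., "per_location": ...}``.  The
    per-location frame carries min/max/mean relative abundance and
    prevalence (fraction of the location's samples with nonzero reads)
    for each (rank, name) pair.  A taxon absent from the taxonomy yields
    an all-zero row with a warning rather than an error.
    """
    loc = {m.sample_id: m.location for m in metadata}
    missing = [s for s in table.sample_ids if s not in loc]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")

    per_sample_rows = []
    for rank, name in taxa:
        sub = subset_by_taxon(table, rank, name)
        if sub.n_otus == 0:
            warnings.warn(f"taxon {rank}={name!r} not found; reporting zeros")
            fracs = dict.fromkeys(table.sample_ids, 0.0)
        else:
            fracs = relative_abundance(table, (rank, name))
        for s in table.sample_ids:
            per_sample_rows.append(
                {"sample_id": s, "location": loc[s], "rank": rank,
                 "taxon": name, "fraction": fracs[s]}
            )
    per_sample = pd.DataFrame(per_sample_rows)

    per_location = (
        per_sample.groupby(["rank", "taxon", "location"], sort=True)["fraction"]
        .agg(min="min", max="max", mean="mean",
             prevalence=lambda v: float(np.mean(np.asarray(v) > 0)))
        .reset_index()
    )
    return {"per_sample": per_sample, "per_location": per_location}
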