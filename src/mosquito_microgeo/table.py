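"""OTU count tables, taxonomy and sample metadata.

The entry point of the whole pipeline is an OTU (Operational Taxonomic
Unit) count table: an integer matrix of samples x OTUs, optionally
annotated with a ranked taxonomic lineage per OTU
(domain;phylum;class;order;family;genus) and per-sample metadata
(collection location, sex/diet class, whether the sample is a pool of
individuals).

Native on-disk format is TSV throughout: ``table.tsv`` (header row of OTU
ids, first column sample ids; an orientation flag handles transposed
exports), ``taxonomy.tsv`` (otu_id <tab> lineage) and ``metadata.tsv``
(sample_id, location, class_label, pooled).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "read_table",
    "write_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "subset_by_taxon",
    "relative_abundance",
    "pool_samples",
]


@dataclass(frozen=True)
class OtuTable:
    """Immutable samples x OTUs count matrix with ids and optional taxonomy.

    Parameters
    ----------
    sample_ids : ordered unique sample identifiers (rows).
    otu_ids : ordered unique OTU identifiers (columns).
    counts : non-negative integer matrix, shape (n_samples, n_otus).
    taxonomy : optional mapping otu_id -> ";"-separated lineage string.
    """

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    counts: np.ndarray
    taxonomy: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if self.taxonomy is not None:
            object.__setattr__(self, "taxonomy", dict(self.taxonomy))

    # -- convenience ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_depths(self) -> np.ndarray:
        """Total read count per sample (row sums)."""
        return self.counts.sum(axis=1)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.sample_ids), columns=list(self.otu_ids))

    def select_samples(self, which: Sequence[int] | Sequence[str]) -> "OtuTable":
        idx = [self.sample_index(s) if isinstance(s, str) else int(s) for s in which]
        return replace(
            self,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            counts=self.counts[idx, :],
        )

    def select_otus(self, which: Sequence[str]) -> "OtuTable":
        pos = {o: j for j, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in which]
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in which if o in self.taxonomy}
        return OtuTable(self.sample_ids, tuple(which), self.counts[:, idx], tax)

    def lineage_at(self, otu_id: str, rank: str) -> str | None:
        """Taxon name of `otu_id` at `rank`, or None if unannotated."""
        if self.taxonomy is None or otu_id not in self.taxonomy:
            return None
        return _parse_lineage(self.taxonomy[otu_id]).get(rank)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
            and (self.taxonomy or None) == (other.taxonomy or None)
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample location and sex/diet class.

    ``location`` is the capture site label (e.g. VK3/VK5/VK7);
    ``class_label`` the sex/diet class (M = male, FBF = female blood-fed,
    FNBF = female non-blood-fed); ``pooled`` marks samples that are pools
    of several individuals (males pooled for DNA yield).
    """

    sample_id: str
    location: str
    class_label: str = ""
    pooled: bool = False


def validate_metadata(metadata: Sequence[SampleMetadata], table: OtuTable) -> None:
    """Every metadata sample id must appear in the companion table."""
    known = set(table.sample_ids)
    missing = [m.sample_id for m in metadata if m.sample_id not in known]
    if missing:
        raise ValueError(f"metadata sample ids not in table: {missing}")


def _parse_lineage(lineage: str) -> dict[str, str]:
    """Parse ``d;p;c;o;f;g`` with optional ``g__``-style rank prefixes."""
    names = {}
    for rank, part in zip(RANKS, lineage.split(";")):
        part = part.strip()
        if "__" in part:
            part = part.split("__", 1)[1]
        if part:
            names[rank] = part
    return names


# -- TSV IO -------------------------------------------------------------

def read_table(path: str | Path, *, samples_as_rows: bool = True,
               taxonomy_path: str | Path | None = None) -> OtuTable:
    """Read an OTU table from TSV.

    The file has a header row of OTU ids and a first column of sample ids;
    ``samples_as_rows=False`` reads the transposed layout (OTUs as rows).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if not samples_as_rows:
        df = df.T
    try:
        counts = df.to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-integer cell in {path}: {exc}") from None
    if (counts < 0).any():
        raise ValueError(f"negative count in {path}")
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else None
    return OtuTable(tuple(df.index), tuple(df.columns), counts, taxonomy)


def write_table(table: OtuTable, path: str | Path, *, samples_as_rows: bool = True) -> None:
    df = table.to_frame()
    if not samples_as_rows:
        df = df.T
    df.index.name = "sample_id" if samples_as_rows else "otu_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read ``otu_id <tab> lineage`` pairs."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        otu_id, _, lineage = line.partition("\t")
        out[otu_id.strip()] = lineage.strip()
    return out


def write_taxonomy(taxonomy: Mapping[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{otu}\t{lin}\n" for otu, lin in taxonomy.items())
    )


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        SampleMetadata(
            sample_id=row["sample_id"],
            location=row["location"],
            class_label=row.get("class_label", ""),
            pooled=str(row.get("pooled", "")).strip().lower() in ("1", "true", "yes"),
        )
        for _, row in df.iterrows()
    ]


def write_metadata(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "location": m.location,
                "class_label": m.class_label,
                "pooled": str(m.pooled).lower(),
            }
            for m in metadata
        ]
    ).to_csv(path, sep="\t", index=False)


# -- table operations ---------------------------------------------------

def subset_by_taxon(table: OtuTable, rank: str, name: str) -> OtuTable:
    """Keep only OTUs whose lineage at `rank` equals `name` (case-insensitive).

    All samples are retained, even if their row becomes all-zero; a name
    that matches nothing yields a valid 0-OTU table.
    """
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    keep = [
        o for o in table.otu_ids
        if (table.lineage_at(o, rank) or "").lower() == name.lower()
    ]
    return table.select_otus(keep)


def relative_abundance(table: OtuTable, taxon: tuple[str, str]) -> dict[str, float]:
    """Per-sample fraction of reads assigned to a taxon (rank, name)."""
    depths = table.sample_depths()
    if (depths == 0).any():
        bad = [s for s, d in zip(table.sample_ids, depths) if d == 0]
        raise ValueError(f"zero-depth samples: {bad}")
    sub = subset_by_taxon(table, *taxon)
    taxon_reads = sub.counts.sum(axis=1) if sub.n_otus else np.zeros(table.n_samples, dtype=np.int64)
    return dict(zip(table.sample_ids, (taxon_reads / depths).tolist()))


def pool_samples(table: OtuTable, groups: Sequence[Sequence[str]],
                 new_ids: Sequence[str]) -> OtuTable:
    """Element-wise-sum groups of samples into pooled samples.

    Groups must be disjoint; samples not mentioned in any group are kept
    unchanged, in their original order, after the pooled samples.
    """
    if len(groups) != len(new_ids):
        raise ValueError("groups and new_ids must have equal length")
    seen: set[str] = set()
    for g in groups:
        for s in g:
            if s in seen:
                raise ValueError(f"sample {s!r} appears in more than one group")
            if s not in table.sample_ids:
                raise KeyError(f"unknown sample id {s!r}")
            seen.add(s)
    rows = [table.counts[[table.sample_index(s) for s in g], :].sum(axis=0) for g in groups]
    rest = [s for s in table.sample_ids if s not in seen]
    rows += [table.counts[table.sample_index(s), :] for s in rest]
    return OtuTable(
        tuple(new_ids) + tuple(rest),
        table.otu_ids,
        np.vstack(rows) if rows else np.zeros((0, table.n_otus), dtype=np.int64),
        table.taxonomy,
    )
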