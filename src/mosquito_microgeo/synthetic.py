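"""Synthetic OTU tables with village-specific community structure.

Generates count tables that emulate whole-body 16S profiles of mosquitoes
captured in a small number of villages: a long tail of rare background
OTUs, a few dominant location-specific marker OTUs (village markers
of the kind reported for wild mosquitoes: Massilia, Wolbachia,
Shewanella and Acinetobacter, all abundant taxa), wide log-normal per-sample read
depths, and optional "migrant" samples whose expected profile is a convex
mixture of two villages' profiles.

The model: each class (village) has an expected relative-abundance
profile over all OTUs.  Background OTU baseline weights are i.i.d.
log-normal; each class additionally owns ``n_signature_otus_per_class``
signature OTUs whose weight is multiplied by ``signature_fold_change`` in
the home class.  Signature baseline weights are shared across classes
(position-matched), so every class profile has the same normalising
constant and the ratio of a signature OTU's expected *relative* abundance
between home and away classes is exactly the fold change.  Counts are
multinomial draws given a log-normal per-sample depth (optionally
Dirichlet-overdispersed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .table import OtuTable, SampleMetadata

__all__ = [
    "MARKER_GENERA",
    "SyntheticConfig",
    "class_profiles",
    "generate_migrant_profile",
    "generate_dataset",
]

MARKER_GENERA = ("Massilia-like", "Wolbachia-like", "Shewanella-like", "Acinetobacter-like")

#: village labels used for up to three classes
_LOCATIONS = ("VK3", "VK5", "VK7")
_CLASS_LABELS = ("M", "FBF", "FNBF")

# log-normal depth parameters: method-of-moments fit to mean 17300,
# SD 13161.83 reads per sample on the natural scale
_DEPTH_LOG_MEAN = 9.5297
_DEPTH_LOG_SD = 0.6758


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic community generator.

    Defaults emulate a three-village field survey: 29 samples
    (10/10/9), 4 signature OTUs per village at 5-fold relative-abundance
    enrichment, 200 background OTUs with a heavy-tailed (log-normal)
    abundance distribution, and per-sample depths log-normal with natural
    mean ~17,300 and SD ~13,162 reads.
    """

    class_sizes: list[int] = field(default_factory=lambda: [10, 10, 9])
    n_signature_otus_per_class: int = 4
    signature_fold_change: float = 5.0
    n_background_otus: int = 200
    background_log_abundance_sd: float = 2.0
    #: log-scale mean weight of signature OTUs; exp(3.4) ~ 30 vs the
    #: background mean weight exp(sd^2/2) ~ 7.4, so each marker OTU sits at
    #: a few percent relative abundance before home-class enrichment —
    #: marker taxa in real data are dominant community members
    signature_log_abundance_mean: float = 3.4
    signature_log_abundance_sd: float = 0.5
    depth_log_mean: float = _DEPTH_LOG_MEAN
    depth_log_sd: float = _DEPTH_LOG_SD
    #: (sample_index, source_class, mixing_weight) triples; the sample's
    #: expected profile becomes weight*source + (1-weight)*home
    migrant_specs: list[tuple[int, int, float]] = field(default_factory=list)
    #: None = pure multinomial counts; a positive value adds
    #: Dirichlet-multinomial overdispersion with total concentration
    #: overdispersion * profile
    overdispersion: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if len(self.class_sizes) < 2 or sum(self.class_sizes) < 2:
            raise ValueError("need >= 2 classes and >= 2 samples total")
        if any(n <= 0 for n in self.class_sizes):
            raise ValueError("empty class in class_sizes")
        if self.signature_fold_change < 1:
            raise ValueError("signature_fold_change must be >= 1")
        if self.n_signature_otus_per_class < 0 or self.n_background_otus <= 0:
            raise ValueError("invalid OTU counts")
        if self.background_log_abundance_sd <= 0:
            raise ValueError("background_log_abundance_sd must be > 0")
        n = sum(self.class_sizes)
        for idx, src, w in self.migrant_specs:
            if not 0 <= idx < n:
                raise ValueError(f"migrant sample_index {idx} out of range")
            if not 0 <= src < len(self.class_sizes):
                raise ValueError(f"migrant source_class {src} out of range")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"mixing_weight {w} outside [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.class_sizes)

    @property
    def n_otus(self) -> int:
        return self.n_background_otus + self.n_classes * self.n_signature_otus_per_class


def generate_migrant_profile(home_profile: np.ndarray, source_profile: np.ndarray,
                             weight: float) -> np.ndarray:
    """Convex mixture ``weight*source + (1-weight)*home`` of two profiles.

    Migrants are modelled at the expected-profile level: an individual
    that spent part of its life in another village carries a mixture of
    the two villages' expected communities.
    """
    home = np.asarray(home_profile, dtype=float)
    source = np.asarray(source_profile, dtype=float)
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"weight {weight} outside [0, 1]")
    for name, p in (("home", home), ("source", source)):
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"{name}_profile is not a probability vector")
    return weight * source + (1.0 - weight) * home


def _baseline_weights(config: SyntheticConfig, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Background weights and (position-shared) signature baseline weights."""
    bg = rng.lognormal(mean=0.0, sigma=config.background_log_abundance_sd,
                       size=config.n_background_otus)
    sig = rng.lognormal(mean=config.signature_log_abundance_mean,
                        sigma=config.signature_log_abundance_sd,
                        size=config.n_signature_otus_per_class)
    return bg, sig


def class_profiles(config: SyntheticConfig) -> np.ndarray:
    """Expected relative-abundance profile of each class, shape (K, n_otus).

    OTU order: class-0 signature OTUs, class-1 signature OTUs, ...,
    then background OTUs.  Sharing signature baselines across classes makes
    every row's normaliser identical, so the home/away relative-abundance
    ratio of each signature OTU equals ``signature_fold_change`` exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bg, sig = _baseline_weights(config, rng)
    K, J = config.n_classes, config.n_signature_otus_per_class
    profiles = np.empty((K, config.n_otus))
    for k in range(K):
        w = np.concatenate([np.tile(sig, K), bg])
        w[k * J:(k + 1) * J] *= config.signature_fold_change
        profiles[k] = w / w.sum()
    return profiles


def _otu_ids_and_taxonomy(config: SyntheticConfig) -> tuple[list[str], dict[str, str]]:
    otu_ids: list[str] = []
    taxonomy: dict[str, str] = {}
    K, J = config.n_classes, config.n_signature_otus_per_class
    for k in range(K):
        genus = MARKER_GENERA[k % len(MARKER_GENERA)]
        for j in range(J):
            oid = f"OTU_sig_c{k}_{j}"
            otu_ids.append(oid)
            taxonomy[oid] = (
                f"Bacteria;Proteobacteria;MarkerClass;MarkerOrder;MarkerFamily;{genus}"
            )
    for j in range(config.n_background_otus):
        oid = f"OTU_bg_{j:04d}"
        otu_ids.append(oid)
        taxonomy[oid] = (
            f"Bacteria;BackgroundPhylum;BackgroundClass;BackgroundOrder;"
            f"BackgroundFamily;Genus{j:04d}"
        )
    return otu_ids, taxonomy


def generate_dataset(config: SyntheticConfig) -> tuple[OtuTable, list[SampleMetadata]]:
    """Draw one synthetic dataset: counts, taxonomy and sample metadata.

    Deterministic given ``config.seed``: identical configs yield bitwise
    identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    # consume the same stream as class_profiles so profiles are reproducible
    bg, sig = _baseline_weights(config, rng)
    K, J = config.n_classes, config.n_signature_otus_per_class
    profiles = np.empty((K, config.n_otus))
    for k in range(K):
        w = np.concatenate([np.tile(sig, K), bg])
        w[k * J:(k + 1) * J] *= config.signature_fold_change
        profiles[k] = w / w.sum()

    labels = np.repeat(np.arange(K), config.class_sizes)
    n = labels.size
    migrants = {idx: (src, w) for idx, src, w in config.migrant_specs}

    depths = np.maximum(
        1, np.round(rng.lognormal(config.depth_log_mean, config.depth_log_sd, size=n))
    ).astype(np.int64)

    counts = np.empty((n, config.n_otus), dtype=np.int64)
    for i in range(n):
        p = profiles[labels[i]]
        if i in migrants:
            src, w = migrants[i]
            p = generate_migrant_profile(p, profiles[src], w)
        if config.overdispersion is not None:
            p = rng.dirichlet(config.overdispersion * p)
        counts[i] = rng.multinomial(depths[i], p)

    otu_ids, taxonomy = _otu_ids_and_taxonomy(config)
    locations = [
        _LOCATIONS[k] if k < len(_LOCATIONS) else f"Loc{k}" for k in range(K)
    ]
    sample_ids, metadata = [], []
    counters = dict.fromkeys(range(K), 0)
    for i in range(n):
        k = labels[i]
        counters[k] += 1
        sid = f"{locations[k]}_{counters[k]:02d}"
        sample_ids.append(sid)
        cls = _CLASS_LABELS[counters[k] % len(_CLASS_LABELS)]
        metadata.append(
            SampleMetadata(sample_id=sid, location=locations[k],
                           class_label=cls, pooled=(cls == "M"))
        )
    table = OtuTable(tuple(sample_ids), tuple(otu_ids), counts, taxonomy)
    return table, metadata
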