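import numpy as np
import pytest

from mosquito_microgeo import OtuTable, SyntheticConfig, generate_dataset
from mosquito_microgeo.rdcv import RdcvConfig


@pytest.fixture
def toy_table() -> OtuTable:
    """4 samples x 3 OTUs with taxonomy, tiny enough to check by hand."""
    counts = np.array([
        [36, 60, 4],
        [0, 90, 10],
        [50, 50, 0],
        [10, 10, 80],
    ])
    taxonomy = {
        "otu1": "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Moraxellaceae;Acinetobacter",
        "otu2": "Bacteria;Proteobacteria;Alphaproteobacteria;Rickettsiales;Anaplasmataceae;Wolbachia",
        "otu3": "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus",
    }
    return OtuTable(("s1", "s2", "s3", "s4"), ("otu1", "otu2", "otu3"), counts, taxonomy)


@pytest.fixture(scope="session")
def strong_signal_small():
    """Fast strong-signal dataset: 18 samples, 2 villages, clear markers."""
    cfg = SyntheticConfig(
        class_sizes=[9, 9],
        n_signature_otus_per_class=2,
        signature_fold_change=6.0,
        n_background_otus=20,
        seed=11,
    )
    table, metadata = generate_dataset(cfg)
    labels = np.asarray([m.location for m in metadata])
    return table, labels, cfg


def tiny_rdcv_config(**overrides) -> RdcvConfig:
    """Desk-scale rdCV settings used across the statistical tests."""
    base = dict(n_rep=2, n_outer=3, n_inner=2, forest_size=15,
                inner_forest_size=15, min_otus=2, seed=0)
    base.update(overrides)
    return RdcvConfig(**base)
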