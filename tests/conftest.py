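import numpy as np
import pandas as pd
import pytest

from bidirmr.harmonize import HarmonizedInstrumentSet
from bidirmr.simulate import (collinear_egger_set, constant_ratio_set,
                              harmonization_quirk_tables, outlier_presso_set)
from bidirmr.summary_io import TraitMetadata, dataset_from_frame


@pytest.fixture
def collinear_set() -> HarmonizedInstrumentSet:
    """Instruments exactly on Gamma = 0.05 + 2*gamma."""
    return collinear_egger_set()


@pytest.fixture
def constant_set() -> HarmonizedInstrumentSet:
    """All per-SNP ratios identical (theta = 1.5)."""
    return constant_ratio_set()


@pytest.fixture
def outlier_set():
    """Clean theta=1 set with one outcome effect shifted by +10 SE."""
    return outlier_presso_set()


@pytest.fixture
def quirk_tables():
    """Exposure/outcome frames covering every harmonization path."""
    return harmonization_quirk_tables()


def make_dataset(rows, trait_id="trait", **meta_kw):
    """Build a SummaryDataset from a list of row dicts, filling defaults."""
    defaults = dict(chromosome="1", position=1000, effect_allele="A",
                    other_allele="G", eaf=0.3, beta=0.1, se=0.01,
                    p_value=1e-9, n=10_000)
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults, variant_id=f"rs{i + 1}", position=1000 + i * 1_000_000)
        r.update(row)
        full.append(r)
    return dataset_from_frame(pd.DataFrame(full), TraitMetadata(trait_id, **meta_kw))


@pytest.fixture
def dataset_factory():
    return make_dataset
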