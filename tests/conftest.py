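import numpy as np
import pandas as pd
import pytest

from culturocall import culturability as cb
from culturocall.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A quick fixture: 60 species, 12 conditions, two planted clades."""
    cfg = SimulationConfig(
        n_species=60,
        n_inocula=3,
        n_conditions=12,
        depth=20_000,
        frac_unculturable=0.2,
        n_unculturable_clades=2,
        clade_sizes=(5, 6),
        chimera_rate=0.5,
        n_chimera_queries=20,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def recovery_dataset():
    """The parameter-recovery fixture: 300 species, 6 inocula, 40
    conditions, deep sequencing, three planted clades of 11/11/32."""
    cfg = SimulationConfig(
        n_species=300,
        n_inocula=6,
        n_conditions=40,
        depth=1_000_000,
        frac_unculturable=0.18,
        n_unculturable_clades=3,
        clade_sizes=(11, 11, 32),
        n_chimera_queries=0,
        seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def recovery_calls(recovery_dataset):
    ds = recovery_dataset
    ra = cb.relative_abundance(ds.table)
    selected = cb.select_common_otus(ra, ds.metadata)
    calls = cb.call_growth(ra, ds.metadata, selected)
    return ra, selected, calls


def make_table(counts, otus=None, samples=None):
    """Build a raw counts frame for AbundanceTable construction."""
    counts = np.asarray(counts)
    otus = otus or [f"OTU{i + 1}" for i in range(counts.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(counts.shape[1])]
    return pd.DataFrame(counts, index=otus, columns=samples)


def make_metadata(rows):
    """rows: iterable of (sample_id, role, experiment_id, condition, category)."""
    df = pd.DataFrame(
        rows, columns=["sample_id", "role", "experiment_id", "condition", "category"]
    )
    return df.set_index("sample_id")
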