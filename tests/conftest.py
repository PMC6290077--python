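import numpy as np
import pandas as pd
import pytest

from resistex import DatasetMeta, IntegratedTable
from resistex.simulate import SimulationConfig, simulate_integrated


@pytest.fixture(scope="session")
def toy_meta():
    def make(i, **kw):
        base = dict(
            dataset_id=f"DS{i:02d}",
            country="Burkina Faso",
            species="coluzzii",
            latitude=11.2 + i,
            longitude=-4.3 + i,
            resistance_class="high",
            mortality_pct=10.0 + i,
            exposure="pyrethroid",
            kdr_frequency=0.8,
            year=2012,
            comparator="N'Gousso",
        )
        base.update(kw)
        return DatasetMeta(**base)

    return [
        make(1),
        make(2, species="gambiae", exposure="none", country="Kenya"),
        make(3, species="coluzzii", exposure="DDT"),
    ]


@pytest.fixture(scope="session")
def toy_table():
    """4 transcripts x 3 datasets with a clean up, a clean down, a direction
    conflict, and an absence."""
    transcripts = ["AGAP000001-RA", "AGAP000001-RB", "AGAP000002-RA", "AGAP000003-RA"]
    datasets = ["DS01", "DS02", "DS03"]
    fc = pd.DataFrame(
        [
            [1.5, 2.0, 1.2],
            [0.5, 0.4, 0.8],
            [1.5, 0.8, 2.0],
            [2.0, np.nan, 3.0],
        ],
        index=pd.Index(transcripts, name="transcript"),
        columns=datasets,
    )
    q = pd.DataFrame(
        [
            [0.01, 0.04, 0.03],
            [0.02, 0.01, 0.04],
            [0.01, 0.02, 0.01],
            [0.03, np.nan, 0.2],
        ],
        index=fc.index,
        columns=datasets,
    )
    return IntegratedTable(fc=fc, q=q)


@pytest.fixture(scope="session")
def sim_small():
    """Small synthetic study reused across unit tests (8 datasets)."""
    cfg = SimulationConfig(
        seed=11,
        n_datasets=8,
        n_transcripts=150,
        n_planted_up=10,
        n_planted_down=6,
        module_specs=[(5, 1.0, 0.1)],
    )
    table, meta, truth = simulate_integrated(cfg)
    return cfg, table, meta, truth


@pytest.fixture(scope="session")
def sim_study():
    """Default-condition synthetic study: 31 datasets, planted signature and
    one co-expression module."""
    cfg = SimulationConfig(seed=5)
    table, meta, truth = simulate_integrated(cfg)
    return cfg, table, meta, truth
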