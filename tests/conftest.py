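import numpy as np
import pandas as pd
import pytest

from enterocag.abundance_io import CohortMetadata, GenusAbundanceTable, to_relative
from enterocag.synthetic import default_config, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_table():
    """3 samples x 4 genera count table with simple values."""
    df = pd.DataFrame(
        [[2, 3, 5, 0], [1, 0, 0, 9], [4, 4, 4, 4]],
        index=["s1", "s2", "s3"],
        columns=["Bacteroides", "Prevotella", "Escherichia", "Faecalibacterium"],
    )
    return GenusAbundanceTable(df, "counts")


@pytest.fixture
def tiny_metadata():
    frame = pd.DataFrame(
        {"stage6": ["normal", "advanced_adenoma", "crc_early"]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return CohortMetadata(frame)


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort, 90 samples, seed 42 (shared, read-only)."""
    table, meta, truth = generate_cohort(default_config(), seed=42)
    return table, meta, truth


@pytest.fixture(scope="session")
def medium_cohort():
    """180-sample default cohort (60/group), seed 7, with relative table."""
    cfg = default_config()
    cfg.n_per_cell = 20
    table, meta, truth = generate_cohort(cfg, seed=7)
    return table, to_relative(table), meta, truth


def random_count_table(rng, n_samples=8, n_genera=12, prefix="g"):
    counts = rng.integers(0, 50, size=(n_samples, n_genera))
    counts[:, 0] += 1  # no all-zero rows
    df = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"{prefix}{j}" for j in range(n_genera)],
    )
    return GenusAbundanceTable(df, "counts")
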