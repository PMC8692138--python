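import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tumorcross import GenomeModel, make_genome

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    """One 300 kb chromosome, 20 genes, 1 kb windows."""
    return make_genome(
        n_chromosomes=1,
        chromosome_length_bp=300_000,
        n_genes=20,
        min_gene_len=600,
        max_gene_len=5_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def two_chrom_genome() -> GenomeModel:
    return make_genome(
        n_chromosomes=2,
        chromosome_length_bp=200_000,
        n_genes=40,
        min_gene_len=600,
        max_gene_len=4_000,
        seed=7,
    )


def make_track(counts, gc=0.45, chrom="chr1", window=1000) -> pd.DataFrame:
    """Hand-build a window track from a count vector."""
    counts = np.asarray(counts)
    n = len(counts)
    gc = np.full(n, gc, dtype=float) if np.isscalar(gc) else np.asarray(gc, dtype=float)
    starts = np.arange(n) * window
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window,
            "gc_fraction": gc,
            "count": counts,
        }
    )
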