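import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from prsoverlap.dataio import GenotypeMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_genotypes(dosage, positions=None, chrom="1", sample_prefix="S") -> GenotypeMatrix:
    """Small GenotypeMatrix from an (n_samples, n_snps) array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if positions is None:
        positions = 1 + np.arange(m) * 1000
    snps = pd.DataFrame(
        {
            "id": [f"snp{i + 1}" for i in range(m)],
            "chrom": chrom,
            "pos": positions,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{j + 1}" for j in range(n)],
        snps=snps,
        dosage=dosage,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
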