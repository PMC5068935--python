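import numpy as np
import pandas as pd
import pytest

from germxqtl import GeneticMap, default_map


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    """Two 10-Mbp chromosomes, 100 SNPs each."""
    return default_map(n_chromosomes=2, length_bp=10_000_000, n_snps=200)


@pytest.fixture(scope="session")
def desk_map() -> GeneticMap:
    """The default desk-scale panel (5 x 30 Mbp, 3000 SNPs)."""
    return default_map()


def single_chrom_map(n_snps: int, spacing_bp: int = 100_000) -> GeneticMap:
    """One chromosome with evenly spaced SNPs, for window-level tests."""
    pos = np.arange(1, n_snps + 1) * spacing_bp
    length = int(pos[-1] + spacing_bp)
    snps = pd.DataFrame(
        {
            "chrom": "Chr1",
            "pos_bp": pos,
            "pos_cM": pos / 1e6 * 4.0,
            "id": [f"s{i:03d}" for i in range(n_snps)],
        }
    )
    return GeneticMap(chromosomes=[("Chr1", length, length / 1e6 * 4.0)], snps=snps)
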