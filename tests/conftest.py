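import numpy as np
import pytest

from promotif import PFM, SimulationConfig, consensus_pfm
from promotif.promoters import Promoter


@pytest.fixture
def small_config() -> SimulationConfig:
    """Compact simulation that runs in well under a second."""
    return SimulationConfig(
        n_chromosomes=2, chrom_length=120_000, n_genes=60, gene_length=200,
        gene_spacing=100, promoter_window=(300, 100), enriched_set_size=6,
        rate_enriched=3.0, rate_background=0.3, n_samples_per_group=4,
        de_fraction=0.2, planted_lfc_magnitude=2.0, nb_dispersion=0.1, seed=11)


@pytest.fixture
def sharp_pfm() -> PFM:
    """Near-deterministic PFM: >=0.99 column mass on the consensus."""
    return consensus_pfm("ACGTTGCA", motif_id="sharp", concentration=0.99)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def make_promoter(seq: str, gene_id: str = "gX", chrom: str = "chr1",
                  start: int = 0, strand: str = "+") -> Promoter:
    return Promoter(gene_id=gene_id, chrom=chrom, start=start,
                    end=start + len(seq), strand=strand, sequence=seq)


def random_pfm(rng: np.random.Generator, length: int, total: int = 40) -> PFM:
    """Random PFM with strictly positive column totals."""
    counts = rng.integers(0, total, size=(4, length)).astype(float)
    counts[rng.integers(0, 4), :] += 1  # no all-zero column
    return PFM(motif_id=f"rand{length}", counts=counts)
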