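import numpy as np
import pytest

from mcalite import (
    NoiseModel,
    TruthEvent,
    simulate_phased_sample,
    spike_event,
    toy_genome,
)


@pytest.fixture(scope="session")
def genome():
    return toy_genome()


@pytest.fixture(scope="session")
def null_sample():
    """Event-free single-chromosome sample with default noise."""
    sample, hap = simulate_phased_sample(chroms=["3"], seed=11)
    return sample, hap


@pytest.fixture(scope="session")
def gain_sample():
    """Sample with a 5 Mb mosaic gain at cell fraction 0.3 on chromosome 3."""
    sample, hap = simulate_phased_sample(chroms=["3"], seed=21)
    truth = TruthEvent(
        individual="sim", chrom="3", start=20_000_000, end=25_000_000,
        type="gain", origin="mitotic", cell_fraction={"saliva": 0.3},
    )
    spiked = spike_event(sample, truth, NoiseModel(), hap, seed=22)
    return spiked, truth, hap


def brute_force_mixture_baf(f: float, n_cells: int, b_aff: int, n_aff: int,
                            b_norm: int = 1, n_norm: int = 2) -> float:
    """Independent oracle: average allele counts over an explicit cell pool.

    Builds ``n_cells`` cells of which ``round(f * n_cells)`` carry the
    event, sums B-allele and total copies cell by cell, and returns the
    pooled B fraction.  Deliberately avoids the closed forms it checks.
    """
    k = round(f * n_cells)
    cells_b = np.concatenate([np.full(k, b_aff), np.full(n_cells - k, b_norm)])
    cells_n = np.concatenate([np.full(k, n_aff), np.full(n_cells - k, n_norm)])
    return float(cells_b.sum() / cells_n.sum())
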