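import numpy as np
import pytest

from pmdlnet import (
    ExpressionMatrix,
    QuantizedMatrix,
    SimConfig,
    generate_network,
    simulate_timeseries,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def chain_data():
    """Three genes where each deterministically copies the previous one
    with unit lag: g1 -> g2 -> g3."""
    rng = np.random.default_rng(7)
    m = 100
    x1 = rng.integers(2, size=m)
    x2 = np.empty(m, dtype=np.int64)
    x3 = np.empty(m, dtype=np.int64)
    x2[0] = x3[0] = 0
    x2[1:] = x1[:-1]
    x3[1:] = x2[:-1]
    return QuantizedMatrix(np.vstack([x1, x2, x3]), q=2, gene_ids=["g1", "g2", "g3"])


@pytest.fixture
def random_quantized(rng):
    """Small random binary dataset for oracle comparisons."""
    values = rng.integers(2, size=(4, 10))
    return QuantizedMatrix(values, q=2, gene_ids=[f"g{i}" for i in range(4)])


@pytest.fixture
def five_gene_files(tmp_path):
    """Simulated 5-gene network written to disk: (data path, truth path, net)."""
    from pmdlnet import io

    cfg = SimConfig(n=5, m=30, seed=11)
    net = generate_network(cfg)
    data = simulate_timeseries(net, 30, seed=12)
    data_path = tmp_path / "five.data.tsv"
    truth_path = tmp_path / "five.truth.sif"
    io.write_quantized_matrix(data, data_path)
    io.write_network(net.connectivity(), net.gene_ids, truth_path)
    return data_path, truth_path, net
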