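import numpy as np
import pytest

from scopesim import MarkerMap, Population, QTLModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_map():
    """Six loci on two chromosomes."""
    return MarkerMap(
        locus_id=np.array([f"m{i}" for i in range(6)], dtype=object),
        chromosome=np.array([1, 1, 1, 2, 2, 2]),
        position_cM=np.array([0.0, 50.0, 100.0, 0.0, 25.0, 50.0]),
    )


@pytest.fixture
def inbred_pop(tiny_map):
    """Four fully homozygous lines over the tiny map."""
    codes = np.array(
        [
            [1, 1, 1, 1, 1, 1],
            [-1, -1, -1, -1, -1, -1],
            [1, -1, 1, -1, 1, -1],
            [-1, 1, -1, 1, -1, 1],
        ]
    )
    allele = ((codes + 1) // 2).astype(np.uint8)
    haps = np.repeat(allele[:, None, :], 2, axis=1)
    return Population([f"L{i}" for i in range(4)], haps, tiny_map)


def make_qtl(indices, effects, signs, n_loci):
    markers = np.setdiff1d(np.arange(n_loci), np.asarray(indices))
    return QTLModel(
        np.asarray(indices),
        np.asarray(effects, dtype=float),
        np.asarray(signs, dtype=np.int8),
        markers,
    )


@pytest.fixture
def pop_from_codes(tiny_map):
    def _make(codes, marker_map=None):
        codes = np.asarray(codes)
        m = marker_map if marker_map is not None else tiny_map
        h1 = (codes >= 0).astype(np.uint8)  # het -> (1, 0)
        h2 = (codes > 0).astype(np.uint8)
        haps = np.stack([h1, h2], axis=1)
        return Population([f"I{i}" for i in range(codes.shape[0])], haps, m)

    return _make
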