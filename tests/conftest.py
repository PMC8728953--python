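import numpy as np
import pytest

from m2pp.netio import (
    AssociationMatrix,
    EntityRegistry,
    HeterogeneousNetwork,
    SimilarityMatrix,
)


def random_similarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """A valid random similarity matrix (symmetric, [0,1], unit diagonal)."""
    v = rng.random((n, n))
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 1.0)
    return v


def random_instance(rng: np.random.Generator, nT=6, nD=6, nM=5, p=0.4):
    """Small random heterogeneous instance as raw arrays."""
    TDA = (rng.random((nT, nD)) < p).astype(np.int8)
    TDI = (rng.random((nT, nM)) < p).astype(np.int8)
    DDA = (rng.random((nD, nM)) < p).astype(np.int8)
    TTS = random_similarity(rng, nT)
    DDS = random_similarity(rng, nD)
    MMS_T = random_similarity(rng, nM)
    MMS_D = random_similarity(rng, nM)
    return TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D


def registry(kind: str, n: int) -> EntityRegistry:
    return EntityRegistry(kind, tuple(f"{kind[0]}{k}" for k in range(n)))


def make_network(TDA, TDI, DDA) -> HeterogeneousNetwork:
    nT, nD = TDA.shape
    nM = TDI.shape[1]
    t, d, m = registry("target", nT), registry("disease", nD), registry("drug", nM)
    return HeterogeneousNetwork(
        targets=t, diseases=d, drugs=m,
        tda=AssociationMatrix(t, d, TDA),
        tdi=AssociationMatrix(t, m, TDI),
        dda=AssociationMatrix(d, m, DDA),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_network(rng):
    """6-target / 6-disease / 5-drug random network with similarity layers."""
    TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D = random_instance(rng)
    net = make_network(TDA, TDI, DDA)
    return net, (
        SimilarityMatrix(net.targets, TTS),
        SimilarityMatrix(net.diseases, DDS),
        SimilarityMatrix(net.drugs, MMS_T),
        SimilarityMatrix(net.drugs, MMS_D),
    )
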