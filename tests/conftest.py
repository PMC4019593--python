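import numpy as np
import pytest

from alnseg import SegmentationModel, simulate as sim
from alnseg.encoding import CONS2, EncodedSequence, PAIR8


#: three well-separated pair8 class frequency vectors (pairwise total
#: variation distance >= 0.45): conserved/AT-rich, conserved/GC-rich,
#: divergent/intermediate
THREE_CLASSES = np.array(
    [
        [0.75, 0.010, 0.020, 0.010, 0.010, 0.150, 0.010, 0.040],
        [0.15, 0.010, 0.020, 0.010, 0.010, 0.750, 0.010, 0.040],
        [0.30, 0.060, 0.090, 0.060, 0.060, 0.250, 0.060, 0.120],
    ]
)
THREE_CLASSES = THREE_CLASSES / THREE_CLASSES.sum(axis=1, keepdims=True)


@pytest.fixture(scope="session")
def three_class_freqs():
    return THREE_CLASSES


@pytest.fixture(scope="session")
def tiny_binary_seq():
    """12-symbol binary sequence with one fixed boundary (small enough
    for exhaustive posterior enumeration)."""
    rng = np.random.default_rng(42)
    sym = rng.integers(0, 2, size=12).astype(np.uint8)
    return EncodedSequence(sym, CONS2, fixed_boundaries=[6])


@pytest.fixture(scope="session")
def planted3():
    """Planted 3-class pair8 sequence (30 kb) with its truth."""
    seq, truth = sim.multiclass(THREE_CLASSES, boundary_rate=0.01, length=30_000, seed=11)
    return seq, truth


@pytest.fixture(scope="session")
def planted3_fit(planted3):
    """One converged K=3 fit of the planted sequence, relabelled."""
    seq, _ = planted3
    res = SegmentationModel(seq, n_classes=3).fit(iterations=1200, seed=21)
    return res.relabel()


@pytest.fixture(scope="session")
def control_seq_small():
    """20 kb single-class control with fixed boundaries every ~300."""
    bounds = sim.evenly_spaced_boundaries(20_000, 300.0, seed=5)
    return sim.single_class_control(
        sim.DROSOPHILA_UTR_PAIR8_FREQS, 20_000, bounds, concentration=100.0, seed=6
    )
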