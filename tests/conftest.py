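import numpy as np
import pytest

from graphdpm import (
    FitConfig,
    Hyperparameters,
    IsingHyper,
    ModalityKind,
    ModalitySpec,
    MultiModalDataset,
)
from graphdpm.simulate import SimulationDesign, simulate

#: hyperparameters matched to the n=300/p=200 planted-simulation conditions:
#: sparsity between the noise-feature evidence mass (~1 nat/subject) and the
#: signal evidence mass (~3-4 nats/subject for Normal, ~0.2 for Bernoulli)
STUDY_HYPER = dict(
    alpha0=10.0,
    H=10,
    ising=IsingHyper(eta=(150.0, 8.0), nu=(0.0, 0.0)),
)

#: tiny two-group instances for oracle comparisons: denser signal so the
#: handful of features still carries the group structure
TINY_DESIGN = dict(
    n=60, p=20, K=2, signal_frac=0.3, normal_means=(-2.0, 2.0), bern_probs=(0.2, 0.8)
)
TINY_HYPER = dict(alpha0=1.0, H=5, ising=IsingHyper(eta=(25.0, 2.0), nu=(0.0, 0.0)))


@pytest.fixture(scope="session")
def study_fit():
    """One fit under the planted-simulation study conditions (seed 0)."""
    import graphdpm

    data, truth = simulate(SimulationDesign(seed=0))
    hyper = Hyperparameters(**STUDY_HYPER)
    result = graphdpm.fit(data, None, hyper, FitConfig(seed=0))
    return data, truth, result


@pytest.fixture
def toy_dataset():
    """Deterministic 4-sample, 2-modality dataset for structural tests."""
    spec1 = ModalitySpec("expr", ModalityKind.NORMAL, ("g1", "g2", "g3"))
    spec2 = ModalitySpec("alt", ModalityKind.BERNOULLI, ("a1", "a2"))
    X1 = np.array([[0.1, -0.2, 1.0], [0.0, 0.3, -1.0], [2.0, 0.1, 0.4], [-0.5, 1.2, 0.0]])
    X2 = np.array([[0.0, 1.0], [1.0, 1.0], [0.0, 0.0], [1.0, 0.0]])
    return MultiModalDataset(
        sample_ids=("s1", "s2", "s3", "s4"), modalities=[(spec1, X1), (spec2, X2)]
    )
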