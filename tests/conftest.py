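import numpy as np
import pytest

from soc.simulate import ARSpec, NetworkSpec, PairSpec


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def standard_pair_spec():
    """The canonical simulation condition: AR(1) 0.8 regressor, AR(1) 0.2 noise."""
    return PairSpec(
        regressor=ARSpec((0.8,)), noise=ARSpec((0.2,)), alpha=0.5, n_samples=2000
    )


@pytest.fixture
def five_node_spec():
    """5-node sparse SEM with strong edges and distinct per-node AR spectra."""
    return NetworkSpec(
        n_nodes=5,
        dag_edges=((0, 1), (1, 2), (0, 3), (3, 4)),
        edge_weights=0.8,
        node_ar=tuple(ARSpec((c,)) for c in (0.9, 0.3, 0.7, 0.2, 0.5)),
        n_samples=5000,
    )


@pytest.fixture
def cohort_spec():
    """Weak-coupling cohort condition: similar (but unequal) node spectra."""
    return NetworkSpec(
        n_nodes=8,
        dag_edges=((0, 1), (1, 2), (3, 4), (5, 6), (0, 7)),
        edge_weights=0.5,
        node_ar=tuple(
            ARSpec((c,)) for c in (0.60, 0.40, 0.55, 0.35, 0.50, 0.65, 0.45, 0.58)
        ),
        n_samples=800,
    )
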