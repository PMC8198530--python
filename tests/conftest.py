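import numpy as np
import pytest

from trimertrace.synthetic import TrimerGeometrySpec, generate_trimer_ensemble


@pytest.fixture(scope="session")
def symmetric_ensemble():
    """Noise-free C3-symmetric trimer, one frame."""
    spec = TrimerGeometrySpec(n_frames=1, seed=1)
    ensemble, truth = generate_trimer_ensemble(spec)
    return ensemble, truth


@pytest.fixture(scope="session")
def planted_ensemble():
    """Pair (A,C) approaching by 6 A, mild noise, 10 frames."""
    spec = TrimerGeometrySpec(
        n_frames=10, approach_delta=-6.0, noise_sigma=0.3, planted_pair=("A", "C"), seed=2
    )
    ensemble, truth = generate_trimer_ensemble(spec)
    return ensemble, truth


def make_network(adjacency):
    """Wrap a plain adjacency matrix as a single-chain ContactNetwork."""
    from trimertrace.contact_network import ContactNetwork

    n = len(adjacency)
    return ContactNetwork(
        adjacency=np.asarray(adjacency, dtype=np.int8),
        chain_ids=np.array(["A"] * n, dtype="U4"),
        res_ids=np.arange(1, n + 1),
    )


def brute_force_ratio_cuts(adjacency):
    """All distinct ratio-cut objective values of a graph, ascending."""
    import itertools

    a = np.asarray(adjacency, dtype=float)
    n = len(a)
    vals = []
    for bits in itertools.product([1, -1], repeat=n - 1):
        labels = np.array((1,) + bits)
        s = labels == 1
        if s.all() or (~s).all():
            continue
        cut = a[np.ix_(s, ~s)].sum()
        vals.append(cut * (1.0 / s.sum() + 1.0 / (~s).sum()))
    return sorted(set(np.round(vals, 10)))


def ratio_cut_value(adjacency, labels):
    a = np.asarray(adjacency, dtype=float)
    s = np.asarray(labels) == 1
    cut = a[np.ix_(s, ~s)].sum()
    return cut * (1.0 / s.sum() + 1.0 / (~s).sum())
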