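import numpy as np
import pytest

from metastate import msm, synthetic


@pytest.fixture(scope="session")
def helix():
    return synthetic.build_structure_fixtures("helix")


@pytest.fixture(scope="session")
def hairpin():
    return synthetic.build_structure_fixtures("hairpin")


@pytest.fixture(scope="session")
def extended():
    return synthetic.build_structure_fixtures("extended")


@pytest.fixture(scope="session")
def chain78():
    return synthetic.build_structure_fixtures("chain78")


@pytest.fixture(scope="session")
def fast_chain():
    """Six-state ground-truth chain with 10x faster exchange, for short tests."""
    edges = {e: 10.0 * a for e, a in synthetic.DEFAULT_EDGE_RATES.items()}
    return synthetic.build_ground_truth_chain(topology=edges)


@pytest.fixture(scope="session")
def generator_run(fast_chain):
    """Moderate-size sampled dataset plus fitted micro/macro models.

    8 trajectories x 50k steps of the fast test chain: all six states are
    visited thousands of times, so parameter-recovery checks are sharp while
    the whole fixture builds in seconds.
    """
    emissions = synthetic.default_emission_model()
    mats, hidden = synthetic.sample_feature_trajectories(
        fast_chain, emissions, n_traj=8, n_steps=50_000, seed=123)
    disc = msm.cluster_kmeans(mats, k=60, seed=7)
    counts = msm.count_transitions(disc.dtrajs, lag_frames=20,
                                   frame_interval_ns=fast_chain.step_ns)
    micro = msm.estimate_reversible(counts)
    macro = msm.coarse_grain(disc.dtrajs, micro, n_macro=6, lag_frames=20)
    return {
        "chain": fast_chain,
        "emissions": emissions,
        "features": mats,
        "hidden": hidden,
        "disc": disc,
        "counts": counts,
        "micro": micro,
        "macro": macro,
        "lag_frames": 20,
    }


@pytest.fixture(scope="session")
def macro_truth_map(generator_run):
    """Permutation mapping estimated macrostates -> generator states."""
    from scipy.optimize import linear_sum_assignment

    run = generator_run
    centers = run["disc"].centers[run["counts"].active_set]
    mean_feat = run["macro"].emission @ centers
    cost = np.linalg.norm(mean_feat[:, None, :]
                          - run["emissions"].means[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return {int(c): int(r) for r, c in zip(rows, cols)}  # truth -> estimated
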