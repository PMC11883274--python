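import numpy as np
import pytest

from chromopws import (OpticsConfig, PackingScalingEstimator, ScenarioSpec,
                       make_scene, paper_like_scenarios)


@pytest.fixture(scope="session")
def cfg():
    return OpticsConfig()


@pytest.fixture(scope="session")
def packing_estimator(cfg):
    """Session-wide self-calibrated Σ→D estimator (the expensive fit)."""
    return PackingScalingEstimator(cfg=cfg, random_state=1234).fit()


@pytest.fixture(scope="session")
def control_spec():
    return paper_like_scenarios()["control"]


@pytest.fixture()
def small_spec():
    """Scaled-down scenario for fast per-test generation."""
    return ScenarioSpec(shape=(32, 32), nucleus_axes=(11.0, 8.0),
                        bleb_radius_px=4.0, neck_width_px=2.0,
                        n_frames=150, domain_count_body=40,
                        domain_count_bleb=12, background_events=40)


@pytest.fixture()
def small_scene(small_spec):
    return make_scene(small_spec, rng_seed=7)


def brute_force_dbscan(xy: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Independent O(n^2) DBSCAN reference (classic semantics).

    Core points have >= min_pts neighbors (self-inclusive) within eps;
    clusters grow by breadth-first expansion from unvisited core points in
    ascending index order; border points join the first cluster that
    reaches them. Noise is -1.
    """
    n = xy.shape[0]
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    neigh = d2 <= eps * eps
    core = neigh.sum(axis=1) >= min_pts
    labels = np.full(n, -1)
    visited = np.zeros(n, dtype=bool)
    current = -1
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        current += 1
        queue = [i]
        visited[i] = True
        labels[i] = current
        while queue:
            j = queue.pop(0)
            if not core[j]:
                continue
            for k in np.flatnonzero(neigh[j]):
                if labels[k] == -1:
                    labels[k] = current
                if not visited[k]:
                    visited[k] = True
                    queue.append(k)
    return labels
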