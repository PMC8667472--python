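import numpy as np
import pytest

from rowlai import HeightCloud, PointCloud


def make_height_cloud(heights, xy=None, seed=0, threshold=0.1):
    """HeightCloud over flat zero terrain: z doubles as the height."""
    h = np.asarray(heights, dtype=float)
    if xy is None:
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0.0, 2.0, (h.size, 2))
    xy = np.asarray(xy, dtype=float)
    cloud = PointCloud(xy[:, 0], xy[:, 1], h)
    return HeightCloud(cloud, h, h < threshold, threshold)


def canonical_partition(labels):
    """Order-independent representation of a clustering: the set of
    frozensets of member indices."""
    labels = np.asarray(labels)
    return frozenset(
        frozenset(np.flatnonzero(labels == c).tolist()) for c in np.unique(labels)
    )


def bruteforce_radius_components(pts, radius):
    """Union-find over all point pairs within the radius: the independent
    oracle for region-growing with a vacuous k-NN constraint."""
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] <= radius**2:
                parent[find(i)] = find(j)
    return np.array([find(i) for i in range(n)])


@pytest.fixture(scope="session")
def small_bundle():
    """A 12-variety study at reduced pulse density, shared across tests."""
    from rowlai import generate_study

    return generate_study(n_varieties=12, pulse_density=120.0, seed=11)
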