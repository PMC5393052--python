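import numpy as np
import pytest

from telostorm import simulate


@pytest.fixture(scope="session")
def small_fov():
    """One modest simulated FOV shared by read-only tests."""
    spec = simulate.FovSpec(
        n_clusters=12,
        field_size_nm=(20_000.0, 20_000.0),
        n_fiducials=2,
        ddr_fraction=0.25,
    )
    spec.blink.frames_total = 1_500
    return simulate.simulate_fov(spec, 42)


def dbscan_oracle(xy: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """O(n^2) brute-force DBSCAN by explicit density-connectivity expansion.

    Closed-ball neighborhoods counting the point itself; border points join the
    first cluster that reaches them (points visited in index order).
    """
    n = len(xy)
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    neigh = d2 <= eps**2
    core = neigh.sum(axis=1) >= min_samples
    labels = np.full(n, -1, dtype=np.int64)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cid
        frontier = [i]
        while frontier:
            j = frontier.pop()
            for k in np.flatnonzero(neigh[j]):
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        frontier.append(int(k))
        cid += 1
    return labels


def core_points(xy: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    return (d2 <= eps**2).sum(axis=1) >= min_samples


def same_clustering(labels_a: np.ndarray, labels_b: np.ndarray, xy: np.ndarray,
                    eps: float, min_samples: int) -> bool:
    """Partition equality up to label permutation and border-point ties.

    Core points must partition identically; each border point must sit in a
    cluster that has a core point within eps of it; noise sets must agree.
    """
    core = core_points(xy, eps, min_samples)
    # noise sets identical
    if not np.array_equal(labels_a == -1, labels_b == -1):
        return False
    # bijection between core-point labels
    for la, lb in ((labels_a, labels_b), (labels_b, labels_a)):
        mapping = {}
        for i in np.flatnonzero(core):
            a, b = la[i], lb[i]
            if mapping.setdefault(a, b) != b:
                return False
    # border points: assigned cluster must contain an eps-close core point
    for labels in (labels_a, labels_b):
        for i in np.flatnonzero(~core & (labels_a != -1)):
            members = np.flatnonzero((labels == labels[i]) & core)
            if len(members) == 0:
                return False
            d2 = np.sum((xy[members] - xy[i]) ** 2, axis=1)
            if d2.min() > eps**2:
                return False
    return True
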