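import numpy as np
import pytest

from edgecrit import roi, synth


@pytest.fixture(scope="session")
def hex_montage() -> roi.Montage:
    """Regular hexagonal grid mapped onto a spherical cap.

    Interior points of a hexagonal lattice have exactly six Delaunay
    neighbors, which makes cluster construction predictable.
    """
    pts = []
    rows = 9
    for r in range(rows):
        for c in range(rows):
            x = (c + 0.5 * (r % 2)) * 0.18 - 0.8
            y = r * 0.156 - 0.62
            if x * x + y * y < 0.9:
                pts.append((x, y))
    pts = np.array(pts)
    z = np.sqrt(np.clip(1.0 - pts[:, 0] ** 2 - pts[:, 1] ** 2, 0.01, 1.0))
    pos = np.column_stack([pts, z])
    ids = [f"H{i}" for i in range(len(pos))]
    return roi.Montage(ids=tuple(ids), positions=pos)


@pytest.fixture(scope="session")
def dense_montage() -> roi.Montage:
    return synth.synthetic_montage(256)


@pytest.fixture(scope="session")
def cluster_map(dense_montage) -> roi.ClusterMap:
    return roi.build_clusters(dense_montage)
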