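"""Shared fixtures: simple band ROIs and independent flood/BFS oracles."""

from collections import deque

import numpy as np
import pytest

from ejpnet import EpitheliumROI


def make_band_roi(rows: int = 60, cols: int = 80, top: int = 0, bottom: int | None = None):
    """Flat rectangular epithelium: apical row ``top``, basal row ``bottom``."""
    if bottom is None:
        bottom = rows - 1
    r = np.arange(rows)[:, None]
    interior = np.zeros((rows, cols), dtype=bool)
    apical = np.zeros_like(interior)
    basal = np.zeros_like(interior)
    apical[top, :] = True
    basal[bottom, :] = True
    interior[((r > top) & (r < bottom)).ravel(), :] = True
    return EpitheliumROI(interior, apical, basal)


@pytest.fixture
def band_roi():
    return make_band_roi


def bfs_flood(free: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Brute-force 4-connected breadth-first flood, independent of scipy."""
    rows, cols = free.shape
    visited = np.zeros_like(free, dtype=bool)
    queue = deque()
    for r, c in zip(*np.nonzero(seeds & free)):
        visited[r, c] = True
        queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for rr, cc in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
            if 0 <= rr < rows and 0 <= cc < cols and free[rr, cc] and not visited[rr, cc]:
                visited[rr, cc] = True
                queue.append((rr, cc))
    return visited


@pytest.fixture
def bfs_oracle():
    return bfs_flood
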