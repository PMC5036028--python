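"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pearloct import PhantomSpec, generate_phantom, run_pipeline, sinusoid_profile

# ---------------------------------------------------------------- oracles


def brute_force_min_cost(graph) -> float:
    """Exhaustive minimum-weight simple path start -> end.

    Depth-first enumeration of simple paths with exact branch-and-bound
    pruning (a partial path already at or above the best complete cost
    cannot improve, since all weights are positive). Independent of any
    shortest-path library.
    """
    mat = graph.matrix.tocoo()
    adj: dict[int, list[tuple[int, float]]] = {}
    for u, v, w in zip(mat.row, mat.col, mat.data):
        adj.setdefault(int(u), []).append((int(v), float(w)))
        adj.setdefault(int(v), []).append((int(u), float(w)))
    for k in adj:
        adj[k].sort(key=lambda t: t[1])
    best = [np.inf]
    start, end = graph.start, graph.end
    visited = {start}

    def dfs(node: int, cost: float) -> None:
        if cost >= best[0]:
            return
        if node == end:
            best[0] = cost
            return
        for nxt, w in adj.get(node, ()):
            if nxt not in visited:
                visited.add(nxt)
                dfs(nxt, cost + w)
                visited.remove(nxt)

    dfs(start, 0.0)
    return best[0]


def sliding_median(pixels: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Direct sliding-window median with edge-replicated borders.

    The window centre follows the size // 2 convention; for even window
    sizes the upper middle order statistic (sorted[n // 2]) is taken.
    """
    wy, wx = window
    top, left = wy // 2, wx // 2
    bot, right = wy - 1 - top, wx - 1 - left
    padded = np.pad(pixels, ((top, bot), (left, right)), mode="edge")
    out = np.empty_like(pixels, dtype=np.float64)
    n = wy * wx
    for i in range(pixels.shape[0]):
        for j in range(pixels.shape[1]):
            win = padded[i : i + wy, j : j + wx]
            out[i, j] = np.sort(win, axis=None)[n // 2]
    return out


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def noiseless_defect_phantom():
    """1024x1024 defect phantom with zero speckle and background noise."""
    width = 1024
    spec = PhantomSpec(
        has_defect=True,
        defect_top_profile=sinusoid_profile(width, depth=120.0, amplitude=20.0, tilt=0.02),
        defect_thickness_profile=np.full(width, 40.0),
        speckle_level=0.0,
        background_noise_sigma=0.0,
        seed=1,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_normal_phantom():
    spec = PhantomSpec(speckle_level=0.0, background_noise_sigma=0.0, seed=2)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def defect_pipeline_result(noiseless_defect_phantom):
    img, _ = noiseless_defect_phantom
    return run_pipeline(img)


@pytest.fixture(scope="session")
def normal_pipeline_result(noiseless_normal_phantom):
    img, _ = noiseless_normal_phantom
    return run_pipeline(img)
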