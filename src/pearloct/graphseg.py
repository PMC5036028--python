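"""Minimum-weight-path segmentation of defect sub-layer boundaries.

The flattened B-scan is viewed as an 8-connected pixel graph. Vertical
intensity gradients mark layer boundaries: the up boundary is a
dark-to-light transition (positive gradient), the down boundary
light-to-dark (negative gradient). For each polarity the rectified
gradient is min-max normalised to g in [0, 1] and every edge between
nodes a and b is weighted

    w_ab = 2 - (g_a + g_b) + w_min,        w_min = 0.01

so strong boundaries become cheap corridors: the weight reaches its
minimum w_min = 0.01 when both incident gradients saturate at 1 and its
maximum 2 + w_min on flat regions. Two extra columns of nodes are
appended at the left and right; all their incident edges carry the
negligible weight 1e-5, so the minimum-weight path from the middle of
the left appended column to the middle of the right one is free to enter
and leave the image at any row and traces the boundary laterally across
the whole image. Dijkstra's algorithm finds the path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra

from .image import BScanImage

W_MIN = 0.01
ENDPOINT_WEIGHT = 1e-5

# undirected 8-neighbour offsets, emitted once per edge, row-major
_OFFSETS = ((0, 1), (1, -1), (1, 0), (1, 1))


@dataclass
class GradientField:
    """Signed vertical gradient plus its polarity-selected normalised form."""

    raw: np.ndarray  # signed, gray-level units per pixel
    polarity: str  # "up" | "down"
    g: np.ndarray  # rectified + min-max normalised, in [0, 1]


@dataclass
class LayerGraph:
    """Pixel-node grid graph with two appended endpoint columns.

    Nodes are (row, col) over a rows x (cols + 2) grid where col 0 and
    col cols+1 are the appended endpoint columns; node index is
    row-major. ``matrix`` holds each undirected edge once.
    """

    g: np.ndarray  # normalised gradient over the original columns
    polarity: str
    matrix: csr_matrix
    n_rows: int
    n_cols: int  # original (un-appended) columns
    start: int
    end: int
    w_min: float = W_MIN
    endpoint_weight: float = ENDPOINT_WEIGHT

    def edge_list(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(u, v, weight) arrays, one entry per undirected edge."""
        coo = self.matrix.tocoo()
        return coo.row, coo.col, coo.data

    def interior_mask(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """True for edges whose both endpoints are original-image nodes."""
        total = self.n_cols + 2
        cu, cv = u % total, v % total
        appended = (cu == 0) | (cu == total - 1) | (cv == 0) | (cv == total - 1)
        return ~appended


@dataclass
class Boundary:
    """Per-column boundary rows over the original image columns."""

    rows: np.ndarray
    polarity: str
    path_cost: float


def vertical_gradient(img: BScanImage | np.ndarray) -> np.ndarray:
    """Signed central-difference gradient along the depth (row) axis.

    Positive where intensity increases downward (dark above, light
    below). Border rows use one-sided differences over the same 2-pixel
    denominator as the interior, so the crop's top junction row is not
    double-weighted relative to interior layer edges.
    """
    pixels = img.pixels if isinstance(img, BScanImage) else np.asarray(img, dtype=np.float64)
    if pixels.shape[0] < 3:
        raise ValueError("need at least 3 rows for a vertical gradient")
    grad = np.gradient(pixels, axis=0)
    grad[0] /= 2.0
    grad[-1] /= 2.0
    return grad


def normalize_polarity(raw: np.ndarray, polarity: str) -> GradientField:
    """Rectify by polarity and min-max rescale to [0, 1] over the image.

    polarity="up" keeps positive raw gradients, "down" the absolute
    values of negative ones. A constant rectified field (nothing to
    normalise against) maps to all-zero g, i.e. uniform maximal weights.
    """
    if polarity not in ("up", "down"):
        raise ValueError(f"polarity must be 'up' or 'down', got {polarity!r}")
    rect = np.maximum(raw, 0.0) if polarity == "up" else np.maximum(-raw, 0.0)
    lo, hi = float(rect.min()), float(rect.max())
    if hi > lo:
        g = (rect - lo) / (hi - lo)
    else:
        g = np.zeros_like(rect)
    return GradientField(raw=np.asarray(raw, dtype=np.float64), polarity=polarity, g=g)


def build_graph(
    field: GradientField,
    w_min: float = W_MIN,
    endpoint_weight: float = ENDPOINT_WEIGHT,
) -> LayerGraph:
    """Assemble the weighted 8-neighbour grid graph with endpoint columns.

    Interior edges (both ends in the original image) get
    w = 2 - (g_a + g_b) + w_min; every edge touching an appended column
    gets exactly ``endpoint_weight``. Start and end are the middle rows
    of the two appended columns.
    """
    g = field.g
    R, C = g.shape
    total = C + 2
    # appended columns get g = 0; their edge weights are overridden below
    g_ext = np.zeros((R, total), dtype=np.float64)
    g_ext[:, 1 : C + 1] = g
    idx = np.arange(R * total).reshape(R, total)

    us, vs, ws = [], [], []
    for dr, dc in _OFFSETS:
        r0 = slice(max(0, -dr), R - max(0, dr))
        c0 = slice(max(0, -dc), total - max(0, dc))
        r1 = slice(max(0, dr), R - max(0, -dr))
        c1 = slice(max(0, dc), total - max(0, -dc))
        u = idx[r0, c0].ravel()
        v = idx[r1, c1].ravel()
        w = 2.0 - (g_ext[r0, c0].ravel() + g_ext[r1, c1].ravel()) + w_min
        cu, cv = u % total, v % total
        touches_end = (cu == 0) | (cu == total - 1) | (cv == 0) | (cv == total - 1)
        w = np.where(touches_end, endpoint_weight, w)
        us.append(u)
        vs.append(v)
        ws.append(w)
    u = np.concatenate(us)
    v = np.concatenate(vs)
    w = np.concatenate(ws)
    matrix = csr_matrix((w, (u, v)), shape=(R * total, R * total))
    return LayerGraph(
        g=g,
        polarity=field.polarity,
        matrix=matrix,
        n_rows=R,
        n_cols=C,
        start=int(idx[R // 2, 0]),
        end=int(idx[R // 2, total - 1]),
        w_min=w_min,
        endpoint_weight=endpoint_weight,
    )


def shortest_path(graph: LayerGraph) -> Boundary:
    """Dijkstra minimum-weight path start -> end, reduced to one row per column.

    The appended endpoint columns are stripped from the path. If the
    path visits a column more than once, the row with the largest
    normalised gradient is kept (the strongest transition). Because the
    column index changes by at most 1 per 8-connected step, the path
    necessarily covers every original column.
    """
    dist, pred = _sp_dijkstra(
        graph.matrix,
        directed=False,
        indices=graph.start,
        return_predecessors=True,
    )
    if not np.isfinite(dist[graph.end]):
        raise RuntimeError("end node unreachable; grid graph should be connected")

    path = []
    node = graph.end
    while node != graph.start:
        path.append(node)
        node = pred[node]
    path.append(graph.start)
    path.reverse()

    total = graph.n_cols + 2
    rows = np.full(graph.n_cols, -1, dtype=np.int64)
    best_g = np.full(graph.n_cols, -np.inf)
    for node in path:
        r, c = divmod(int(node), total)
        if 1 <= c <= graph.n_cols:
            oc = c - 1
            if graph.g[r, oc] > best_g[oc]:
                best_g[oc] = graph.g[r, oc]
                rows[oc] = r
    assert (rows >= 0).all(), "path skipped a column"
    return Boundary(rows=rows, polarity=graph.polarity, path_cost=float(dist[graph.end]))


def segment_layer(
    img: BScanImage,
    w_min: float = W_MIN,
    endpoint_weight: float = ENDPOINT_WEIGHT,
) -> tuple[Boundary, Boundary]:
    """Estimate the up and down boundaries of the brightest sub-layer.

    Runs the gradient -> rectify/normalise -> graph -> Dijkstra chain
    once per polarity on a preprocessed (flattened, cropped, downscaled,
    power-law transformed) image. Two boundaries are always returned —
    on a defect-free pearl they snap to ring-line transitions, and no
    ordering between up and down is enforced.
    """
    raw = vertical_gradient(img)
    boundaries = []
    for polarity in ("up", "down"):
        field = normalize_polarity(raw, polarity)
        graph = build_graph(field, w_min=w_min, endpoint_weight=endpoint_weight)
        boundaries.append(shortest_path(graph))
    return boundaries[0], boundaries[1]
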