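"""Unsupervised structure discovery on pixel feature vectors.

Bisecting K-Means repeatedly splits the leaf cluster with the largest
within-cluster sum of squares into two with a restarted 2-means, producing a
binary cluster tree whose leaves partition the pixels.  PCA with optional
per-feature unit-variance scaling provides the low-dimensional score view.
Cluster assignments and single-feature intensities can be rendered as
molecular maps (one pixel per grid cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA as _PCA

from .errors import DataError, ParameterError, ShapeError
from .preprocess import FeatureMatrix

__all__ = [
    "ClusterNode",
    "SegmentationResult",
    "PCAResult",
    "bisecting_kmeans",
    "pca",
    "render_map",
]


@dataclass
class ClusterNode:
    node_id: int
    parent: int | None
    pixel_count: int
    wcss: float
    children: tuple[int, int] | None = None


@dataclass
class SegmentationResult:
    assignment: np.ndarray                 # leaf node id per pixel
    tree: dict[int, ClusterNode]
    k: int
    seed: int
    pixel_index: list[tuple[int, int]] = field(default_factory=list)

    @property
    def leaves(self) -> list[int]:
        return [n.node_id for n in self.tree.values() if n.children is None]

    def leaf_pixels(self, node_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == node_id)

    def total_inertia(self) -> float:
        return float(
            sum(self.tree[leaf].wcss for leaf in self.leaves)
        )

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "tree": [
                {
                    "node_id": n.node_id,
                    "parent": n.parent,
                    "pixel_count": n.pixel_count,
                    "wcss": n.wcss,
                    "children": list(n.children) if n.children else None,
                }
                for n in sorted(self.tree.values(), key=lambda n: n.node_id)
            ],
        }


@dataclass
class PCAResult:
    scores: np.ndarray               # pixels x components
    explained_fraction: np.ndarray   # non-increasing, sums to <= 1
    components: np.ndarray           # components x features (loadings)
    kept_features: np.ndarray        # indices of non-constant features used


def _wcss(x: np.ndarray) -> float:
    if len(x) == 0:
        return 0.0
    centred = x - x.mean(axis=0)
    return float(np.sum(centred * centred))


def bisecting_kmeans(
    fm: FeatureMatrix,
    k: int,
    seed: int = 0,
    metric: str = "euclidean",
    n_init: int = 10,
) -> SegmentationResult:
    """Divisive 2-means clustering until ``k`` leaves exist.

    At each step the leaf with the largest within-cluster sum of squares is
    bisected by a restarted 2-means (best of ``n_init`` inits).  With
    ``metric="correlation"`` pixel vectors are row-standardised first, so
    euclidean 2-means groups spectra of similar *shape* regardless of
    overall intensity.  Deterministic for a fixed seed.
    """
    n_pixels = len(fm.pixel_index)
    if k < 1 or k > n_pixels:
        raise ParameterError(f"k must be in [1, {n_pixels}], got {k}")
    if metric not in ("euclidean", "correlation"):
        raise ParameterError(f"unknown metric {metric!r}")
    x = fm.values
    if metric == "correlation":
        centred = x - x.mean(axis=1, keepdims=True)
        scale = np.linalg.norm(centred, axis=1, keepdims=True)
        scale[scale == 0] = 1.0
        x = centred / scale

    tree: dict[int, ClusterNode] = {
        0: ClusterNode(0, None, n_pixels, _wcss(x))
    }
    assignment = np.zeros(n_pixels, dtype=int)
    next_id = 1
    rng = np.random.default_rng(seed)
    while len([n for n in tree.values() if n.children is None]) < k:
        leaves = [n for n in tree.values() if n.children is None]
        # split the leaf with the largest WCSS that is still divisible
        leaves = [n for n in leaves if n.pixel_count >= 2]
        if not leaves:
            raise DataError("no divisible leaf left before reaching k leaves")
        target = max(leaves, key=lambda n: (n.wcss, n.pixel_count))
        rows = np.flatnonzero(assignment == target.node_id)
        km = KMeans(
            n_clusters=2,
            n_init=n_init,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(x[rows])
        left_id, right_id = next_id, next_id + 1
        next_id += 2
        for child_id, side in ((left_id, 0), (right_id, 1)):
            members = rows[km.labels_ == side]
            assignment[members] = child_id
            tree[child_id] = ClusterNode(
                child_id, target.node_id, len(members), _wcss(x[members])
            )
        tree[target.node_id].children = (left_id, right_id)
    return SegmentationResult(
        assignment=assignment,
        tree=tree,
        k=k,
        seed=seed,
        pixel_index=list(fm.pixel_index),
    )


def pca(
    fm: FeatureMatrix,
    n_components: int | None = None,
    scale: str = "unit_variance",
) -> PCAResult:
    """PCA of the (centred, optionally unit-variance scaled) feature matrix.

    Zero-variance features carry no information and break unit-variance
    scaling; they are dropped before the decomposition.
    """
    if scale not in ("unit_variance", "none"):
        raise ParameterError(f"unknown scale {scale!r}")
    x = fm.values
    std = x.std(axis=0)
    kept = np.flatnonzero(std > 0)
    if kept.size == 0:
        raise DataError("all features have zero variance")
    x = x[:, kept] - x[:, kept].mean(axis=0)
    if scale == "unit_variance":
        x = x / std[kept]
    max_rank = min(x.shape)
    if n_components is None:
        n_components = max_rank
    if n_components > max_rank:
        raise ParameterError(
            f"n_components {n_components} exceeds min(pixels, features) = {max_rank}"
        )
    model = _PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    return PCAResult(
        scores=scores,
        explained_fraction=model.explained_variance_ratio_,
        components=model.components_,
        kept_features=kept,
    )


# ---------------------------------------------------------------------------
# molecular maps
# ---------------------------------------------------------------------------

#: deterministic categorical palette, indexed by cluster rank
_PALETTE = np.array(
    [
        (214, 39, 40),    # red
        (31, 119, 180),   # blue
        (44, 160, 44),    # green
        (255, 127, 14),   # orange
        (148, 103, 189),  # purple
        (140, 86, 75),    # brown
        (227, 119, 194),  # pink
        (127, 127, 127),  # grey
        (188, 189, 34),   # olive
        (23, 190, 207),   # cyan
    ],
    dtype=np.uint8,
)


def render_map(
    data: np.ndarray,
    pixel_index: list[tuple[int, int]],
    grid_shape: tuple[int, int] | None = None,
    kind: str = "cluster",
    path: str | None = None,
) -> np.ndarray:
    """Render per-pixel values as an RGB image (h, w, 3, uint8).

    ``kind="cluster"`` colour-codes integer labels with a deterministic
    palette; ``kind="intensity"`` grey-scales a continuous feature column
    (min-max over observed pixels).  Missing grid cells are black.  If
    ``path`` is given the image is also written as PNG.
    """
    data = np.asarray(data)
    if len(data) != len(pixel_index):
        raise ShapeError(
            f"{len(data)} values for {len(pixel_index)} pixels"
        )
    xs = np.array([p[0] for p in pixel_index])
    ys = np.array([p[1] for p in pixel_index])
    if grid_shape is None:
        grid_shape = (ys.max() + 1, xs.max() + 1)
    h, w = grid_shape
    if np.any(xs >= w) or np.any(ys >= h):
        raise ShapeError(f"pixel coordinates exceed grid {h}x{w}")
    img = np.zeros((h, w, 3), dtype=np.uint8)
    if kind == "cluster":
        labels = np.unique(data)
        for rank, lab in enumerate(sorted(labels)):
            colour = _PALETTE[rank % len(_PALETTE)]
            sel = data == lab
            img[ys[sel], xs[sel]] = colour
    elif kind == "intensity":
        values = data.astype(float)
        lo, hi = float(values.min()), float(values.max())
        scaled = np.zeros_like(values) if hi == lo else (values - lo) / (hi - lo)
        grey = (scaled * 255).astype(np.uint8)
        img[ys, xs] = grey[:, None]
    else:
        raise ParameterError(f"unknown kind {kind!r}")
    if path is not None:
        from PIL import Image

        Image.fromarray(img).save(path, format="PNG")
    return img
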