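"""Shared fixtures: small synthetic scenes, random thin skeletons, and
the brute-force geodesic oracle used to cross-check branch measurement."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest
from skimage.draw import line as draw_line

from tubulequant.skeleton import SQRT2, skeletonize
from tubulequant.synth import SceneParams

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def brute_force_branch_length(path) -> float:
    """Independent geodesic length: Dijkstra over the branch's own pixels.

    Edges connect 8-adjacent pixels with weight 1 (axial) or sqrt(2)
    (diagonal). For a simple chain this is the unique path length.
    """
    pixels = set(path)
    if len(path) == 2:
        (r0, c0), (r1, c1) = path
        return SQRT2 if r0 != r1 and c0 != c1 else 1.0
    g = nx.Graph()
    for r, c in pixels:
        g.add_node((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in pixels:
                    w = SQRT2 if dr != 0 and dc != 0 else 1.0
                    g.add_edge((r, c), q, weight=w)
    return nx.dijkstra_path_length(g, path[0], path[-1], weight="weight")


def random_thin_skeletons(n: int, size: int = 32, seed: int = 0):
    """Yield n random thin skeletons built from stroke unions.

    Strokes (random polylines, optionally dilated) are thinned with
    skeletonize, giving realistic mixtures of lines, junctions and loops.
    """
    rng = np.random.default_rng(seed)
    made = 0
    while made < n:
        img = np.zeros((size, size), dtype=bool)
        for _ in range(rng.integers(1, 5)):
            n_pts = rng.integers(2, 5)
            pts = rng.integers(1, size - 1, size=(n_pts, 2))
            for (r0, c0), (r1, c1) in zip(pts, pts[1:]):
                rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
                img[rr, cc] = True
        if rng.random() < 0.5:
            from scipy import ndimage

            img = ndimage.binary_dilation(img)
        # enclosed 1-px holes block thinning (kept as rings), which can
        # leave locally solid patches; fill them as the pipeline does
        from tubulequant.preprocess import fill_small_holes

        skel = skeletonize(fill_small_holes(img, max_px=4))
        from tubulequant.skeleton import _neighbor_counts

        if skel.any() and not (_neighbor_counts(skel) == 8).any():
            made += 1
            yield skel


@pytest.fixture
def small_scene_params():
    """Scene parameters scaled down for fast unit tests (256x256)."""
    return SceneParams(
        image_size=(256, 256),
        cell_radius_px=90.0,
        n_puncta=25,
        n_tubules=2,
        tubule_length_um_range=(2.5, 5.0),
        seed=42,
    )
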