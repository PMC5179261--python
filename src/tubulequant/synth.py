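"""Synthetic two-channel widefield-like scenes with ground truth.

Every pipeline stage is testable without real data: a scene is a bright
cell silhouette on a dark background (cell channel) plus a marker
channel containing Gaussian puncta, curvilinear tubules of controlled
arc length and curvature, an optional dense MTOC cluster, a linear
background gradient, optical (Gaussian PSF) blur and camera noise.
Ground truth records the cell silhouette, every tubule centreline with
its arc length, punctum positions and the MTOC disk.

Tubule centrelines are unit-step random walks whose per-step heading
change is bounded by a curvature parameter, giving one interpretable
knob spanning straight to strongly curved ("linear or curvilinear")
morphologies. The walk length is chosen so the arc length lands in the
requested range exactly (unit steps, so arc length = step count).

Default intensities, counts and noise approximate a 63x widefield
acquisition of a single HeLa-sized cell at 0.1 um/px: a ~30 um radius
cell, ~120 SNX1-like puncta, shot noise plus Gaussian read noise.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import line as _draw_line

from .io_formats import MultiChannelImage, write_two_channel_tiff
from .skeleton import SkeletonGraph

__all__ = [
    "SceneParams",
    "TubuleTruth",
    "GroundTruth",
    "TubulePlacementError",
    "generate_scene",
    "generate_cohort",
    "scene_preset",
    "cohort_preset",
    "tubule_recovery",
    "SCENE_PRESETS",
    "COHORT_PRESETS",
]


class TubulePlacementError(RuntimeError):
    """A tubule could not be placed inside the cell after bounded retries."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene.

    ``n_tubules`` is an exact count in ``fixed`` mode and a Poisson mean
    in ``poisson`` mode (used by cohort presets, where tubule counts
    vary image to image).
    """

    image_size: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.1
    cell_radius_px: float = 300.0
    cell_intensity: float = 180.0
    n_puncta: int = 120
    punctum_sigma_px: float = 1.5
    punctum_intensity: float = 150.0
    n_tubules: float = 2
    tubule_count_mode: Literal["fixed", "poisson"] = "fixed"
    tubule_length_um_range: tuple[float, float] = (2.0, 6.0)
    tubule_curvature: float = 0.25
    tubule_intensity: float = 120.0
    mtoc: bool = False
    mtoc_radius_px: float = 35.0
    mtoc_n_puncta: int = 150
    psf_sigma_px: float = 1.0
    noise_model: Literal["gaussian", "poisson_gaussian"] = "poisson_gaussian"
    noise_sd: float = 2.0
    background_gradient: float = 5.0
    puncta_avoid_tubules: bool = False
    avoid_margin_px: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tubule_length_um_range
        if not (0 < lo <= hi):
            raise ValueError("tubule_length_um_range must be positive and ordered")
        if self.n_puncta < 0 or self.n_tubules < 0 or self.mtoc_n_puncta < 0:
            raise ValueError("counts must be >= 0")
        if self.tubule_curvature < 0:
            raise ValueError("tubule_curvature must be >= 0")
        h, w = self.image_size
        if 2 * self.cell_radius_px >= min(h, w):
            raise ValueError("image too small to contain the cell disk")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclass(frozen=True)
class TubuleTruth:
    """One ground-truth tubule: ordered centreline points and arc length."""

    points: np.ndarray  # (N, 2) float (row, col)
    arc_length_um: float


@dataclass(frozen=True)
class GroundTruth:
    cell_mask: np.ndarray
    tubules: tuple[TubuleTruth, ...]
    puncta_centres: tuple[tuple[float, float], ...]
    mtoc_disk: tuple[tuple[float, float], float] | None

    @property
    def tubule_arc_lengths_um(self) -> list[float]:
        return [t.arc_length_um for t in self.tubules]


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _uniform_in_disk(rng, center, radius) -> np.ndarray:
    r = radius * math.sqrt(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([center[0] + r * math.sin(theta), center[1] + r * math.cos(theta)])


def _walk_tubule(
    rng: np.random.Generator,
    center: tuple[float, float],
    interior_radius: float,
    n_steps: int,
    curvature: float,
    max_attempts: int = 200,
) -> np.ndarray:
    """Unit-step bounded-heading random walk kept inside the cell interior."""
    for _ in range(max_attempts):
        pts = np.empty((n_steps + 1, 2), dtype=np.float64)
        pts[0] = _uniform_in_disk(rng, center, interior_radius)
        heading = rng.uniform(0.0, 2.0 * math.pi)
        ok = True
        for i in range(1, n_steps + 1):
            heading += rng.uniform(-curvature, curvature)
            pts[i, 0] = pts[i - 1, 0] + math.sin(heading)
            pts[i, 1] = pts[i - 1, 1] + math.cos(heading)
            dr = pts[i, 0] - center[0]
            dc = pts[i, 1] - center[1]
            if dr * dr + dc * dc > interior_radius**2:
                ok = False
                break
        if ok:
            return pts
    raise TubulePlacementError(
        f"could not place a {n_steps}-step tubule inside the cell "
        f"(interior radius {interior_radius:.0f} px) after {max_attempts} attempts"
    )


def _render_polyline(canvas: np.ndarray, points: np.ndarray) -> None:
    ipts = np.rint(points).astype(int)
    for (r0, c0), (r1, c1) in zip(ipts, ipts[1:]):
        rr, cc = _draw_line(r0, c0, r1, c1)
        canvas[rr, cc] = True


def generate_scene(params: SceneParams) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one synthetic scene; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    cell_mask = _disk_mask((h, w), center, params.cell_radius_px)

    # --- tubules -----------------------------------------------------
    if params.tubule_count_mode == "poisson":
        n_tubules = int(rng.poisson(params.n_tubules))
    else:
        n_tubules = int(round(params.n_tubules))
    lo_um, hi_um = params.tubule_length_um_range
    step_um = params.pixel_size_um  # unit pixel steps
    n_min = max(1, math.ceil(lo_um / step_um))
    n_max = max(n_min, math.floor(hi_um / step_um))
    interior_radius = params.cell_radius_px - 5.0

    tubule_canvas = np.zeros((h, w), dtype=bool)
    tubules: list[TubuleTruth] = []
    for _ in range(n_tubules):
        target_um = rng.uniform(lo_um, hi_um)
        n_steps = int(np.clip(round(target_um / step_um), n_min, n_max))
        pts = _walk_tubule(
            rng, center, interior_radius, n_steps, params.tubule_curvature
        )
        _render_polyline(tubule_canvas, pts)
        arc = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()) * params.pixel_size_um
        tubules.append(TubuleTruth(points=pts, arc_length_um=arc))
    if tubules:
        # widen centrelines to 2-3 px before blur
        tubule_canvas = ndimage.binary_dilation(
            tubule_canvas, structure=np.ones((3, 3), dtype=bool)
        )

    # --- puncta (including the MTOC cluster) -------------------------
    delta_layer = np.zeros((h, w), dtype=np.float64)
    sigma_p = params.punctum_sigma_px
    # delta amplitude chosen so the blurred punctum peak ~ punctum_intensity
    amp = params.punctum_intensity * 2.0 * math.pi * sigma_p**2

    tubule_tree = None
    if params.puncta_avoid_tubules and tubules:
        tubule_tree = cKDTree(np.vstack([t.points for t in tubules]))

    puncta: list[tuple[float, float]] = []
    attempts = 0
    while len(puncta) < params.n_puncta and attempts < 50 * max(params.n_puncta, 1):
        attempts += 1
        p = _uniform_in_disk(rng, center, params.cell_radius_px - 2.0)
        if tubule_tree is not None:
            if tubule_tree.query(p)[0] < params.avoid_margin_px:
                continue
        puncta.append((float(p[0]), float(p[1])))
    for p in puncta:
        delta_layer[int(round(p[0])), int(round(p[1]))] += amp

    mtoc_disk = None
    if params.mtoc:
        # perinuclear placement: offset from the cell centre
        ang = rng.uniform(0.0, 2.0 * math.pi)
        off = 0.35 * params.cell_radius_px
        mc = (center[0] + off * math.sin(ang), center[1] + off * math.cos(ang))
        for _ in range(params.mtoc_n_puncta):
            q = _uniform_in_disk(rng, mc, params.mtoc_radius_px)
            delta_layer[int(round(q[0])), int(round(q[1]))] += amp
        mtoc_disk = ((float(mc[0]), float(mc[1])), float(params.mtoc_radius_px))

    marker = ndimage.gaussian_filter(delta_layer, sigma=sigma_p)
    marker += params.tubule_intensity * tubule_canvas

    if params.background_gradient > 0:
        ramp = np.linspace(0.0, params.background_gradient, w)[None, :]
        marker = marker + ramp

    if params.psf_sigma_px > 0:
        marker = ndimage.gaussian_filter(marker, sigma=params.psf_sigma_px)

    # --- cell channel ------------------------------------------------
    cell = params.cell_intensity * ndimage.gaussian_filter(
        cell_mask.astype(np.float64), sigma=3.0
    )

    marker = _apply_noise(rng, marker, params.noise_model, params.noise_sd)
    cell = _apply_noise(rng, cell, params.noise_model, params.noise_sd)

    image = MultiChannelImage(
        cell_channel=cell.astype(np.float32),
        marker_channel=marker.astype(np.float32),
        pixel_size_um=params.pixel_size_um,
        source_id=f"synthetic_seed{params.seed}",
    )
    truth = GroundTruth(
        cell_mask=cell_mask,
        tubules=tuple(tubules),
        puncta_centres=tuple(puncta),
        mtoc_disk=mtoc_disk,
    )
    return image, truth


def _apply_noise(rng, signal, model, sd) -> np.ndarray:
    if model == "poisson_gaussian":
        noisy = rng.poisson(np.clip(signal, 0.0, None)).astype(np.float64)
        if sd > 0:
            noisy = noisy + rng.normal(0.0, sd, size=signal.shape)
    elif model == "gaussian":
        noisy = signal + (rng.normal(0.0, sd, size=signal.shape) if sd > 0 else 0.0)
    else:
        raise ValueError("noise_model must be 'gaussian' or 'poisson_gaussian'")
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# presets

SCENE_PRESETS: dict[str, SceneParams] = {
    # sparse, short tubules: untreated control morphology
    "control-like": SceneParams(
        n_tubules=0.5,
        tubule_count_mode="poisson",
        tubule_length_um_range=(1.0, 2.5),
        tubule_curvature=0.3,
    ),
    # frequent, long tubules: fission-factor (e.g. spastin) depletion
    "depleted-like": SceneParams(
        n_tubules=3.0,
        tubule_count_mode="poisson",
        tubule_length_um_range=(2.5, 8.0),
        tubule_curvature=0.3,
    ),
    # straighter and longer: IST1-depletion-like morphology
    "straighter-longer": SceneParams(
        n_tubules=3.0,
        tubule_count_mode="poisson",
        tubule_length_um_range=(4.0, 10.0),
        tubule_curvature=0.08,
    ),
    # dense MTOC cluster, no true tubules: the false-positive confound
    "mtoc-confound": SceneParams(
        n_tubules=0,
        mtoc=True,
    ),
}

COHORT_PRESETS: dict[str, tuple[str, str]] = {
    # negative vs positive control pair mirroring a depletion experiment
    "fig3-like": ("control-like", "depleted-like"),
    "straight-tubule": ("control-like", "straighter-longer"),
}


def scene_preset(name: str, **overrides) -> SceneParams:
    if name not in SCENE_PRESETS:
        raise KeyError(
            f"unknown scene preset {name!r}; available: {sorted(SCENE_PRESETS)}"
        )
    return replace(SCENE_PRESETS[name], **overrides)


def cohort_preset(name: str) -> tuple[SceneParams, SceneParams]:
    if name not in COHORT_PRESETS:
        raise KeyError(
            f"unknown cohort preset {name!r}; available: {sorted(COHORT_PRESETS)}"
        )
    a, b = COHORT_PRESETS[name]
    return SCENE_PRESETS[a], SCENE_PRESETS[b]


# ---------------------------------------------------------------------------
# cohort generation

def stable_seed(base_seed: int, *parts) -> int:
    """Deterministic, insertion-order-independent per-image seed (< 2^31)."""
    key = "|".join(str(p) for p in (base_seed, *parts)).encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (2**31)


def generate_cohort(
    control: SceneParams,
    treated: SceneParams,
    n_images_per_condition: int,
    n_repeats: int,
    base_seed: int,
    out_dir: str | Path,
    condition_names: tuple[str, str] = ("control", "treated"),
) -> pd.DataFrame:
    """Write a two-condition synthetic experiment to disk.

    Produces ``images/<id>.tif`` (2-plane float32), per-image ground
    truth tables under ``truth/`` and a ``manifest.tsv`` with one row
    per image (image_id, condition, repeat, index, seed, path). Seeds
    derive deterministically from ``base_seed``; two runs with the same
    arguments produce identical files.
    """
    if n_images_per_condition < 1 or n_repeats < 1:
        raise ValueError("n_images_per_condition and n_repeats must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "truth").mkdir(parents=True, exist_ok=True)

    rows = []
    truth_rows = []
    centre_rows = []
    for cond_name, params in zip(condition_names, (control, treated)):
        for r in range(n_repeats):
            for k in range(n_images_per_condition):
                seed = stable_seed(base_seed, cond_name, r, k)
                image_id = f"{cond_name}_r{r}_i{k:03d}"
                image, truth = generate_scene(replace(params, seed=seed))
                path = out_dir / "images" / f"{image_id}.tif"
                write_two_channel_tiff(image, path)
                rows.append(
                    {
                        "image_id": image_id,
                        "condition": cond_name,
                        "repeat": r,
                        "index": k,
                        "seed": seed,
                        "path": str(path.relative_to(out_dir)),
                    }
                )
                for t_id, t in enumerate(truth.tubules):
                    truth_rows.append(
                        {
                            "image_id": image_id,
                            "tubule_id": t_id,
                            "arc_length_um": round(t.arc_length_um, 6),
                        }
                    )
                    for p_idx, (pr, pc) in enumerate(t.points):
                        centre_rows.append(
                            {
                                "image_id": image_id,
                                "tubule_id": t_id,
                                "point_idx": p_idx,
                                "row": round(float(pr), 3),
                                "col": round(float(pc), 3),
                            }
                        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth_rows, columns=["image_id", "tubule_id", "arc_length_um"]
    ).to_csv(out_dir / "truth" / "tubules.csv", index=False)
    pd.DataFrame(
        centre_rows, columns=["image_id", "tubule_id", "point_idx", "row", "col"]
    ).to_csv(out_dir / "truth" / "centrelines.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# ground-truth matching

@dataclass(frozen=True)
class RecoveryResult:
    n_truth: int
    n_recovered: int
    matched: tuple[bool, ...]

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else float("nan")


def tubule_recovery(
    truth: GroundTruth,
    graph: SkeletonGraph,
    min_length_px: float = 20.0,
    match_dist_px: float = 4.0,
    min_arc_length_um: float | None = None,
    min_overlap_fraction: float = 0.5,
) -> RecoveryResult:
    """Match detected tubules (qualifying branches) to ground truth.

    A ground-truth tubule counts as recovered when some branch longer
    than ``min_length_px`` has at least ``min_overlap_fraction`` of its
    pixels within ``match_dist_px`` of the tubule's centreline.
    """
    gt = [
        t
        for t in truth.tubules
        if min_arc_length_um is None or t.arc_length_um >= min_arc_length_um
    ]
    qualifying = [b for b in graph.branches if b.length_px > min_length_px]
    matched = []
    for t in gt:
        tree = cKDTree(t.points)
        hit = False
        for b in qualifying:
            pix = np.asarray(b.path, dtype=float)
            dists, _ = tree.query(pix)
            if (dists <= match_dist_px).mean() >= min_overlap_fraction:
                hit = True
                break
        matched.append(hit)
    return RecoveryResult(
        n_truth=len(gt), n_recovered=int(sum(matched)), matched=tuple(matched)
    )
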