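"""End-to-end per-image pipeline and cohort-level reporting.

Per image: cell mask -> marker enhancement -> MTOC detection ->
binarisation -> MTOC removal -> skeletonisation -> branch measurement ->
tubule classification. Cohort level: the three metrics per condition,
Z' between designated positive/negative conditions for each metric
(computed on per-repeat means), and paired/unpaired t-tests across
repeats.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import BranchRecord, MultiChannelImage
from .metrics import (
    CohortSummary,
    DegenerateTestError,
    ImageResult,
    TTestResult,
    UndefinedZPrimeError,
    classify_tubules,
    condition_stats,
    interpret_zprime,
    summarize_cohort,
    zprime,
)
from .mtoc import MTOCConfig, MTOCRegion, detect_mtoc, remove_region
from .preprocess import (
    CellMask,
    EnhanceConfig,
    binarize,
    enhance_marker,
    fill_small_holes,
    make_cell_mask,
)
from .skeleton import SkeletonGraph, analyze_skeleton, skeletonize

__all__ = [
    "PipelineConfig",
    "ImageAnalysis",
    "analyze_image",
    "summarize_experiment",
    "load_config",
    "default_config_toml",
]

METRIC_NAMES = (
    "mean_tubules_per_image",
    "pct_images_with_tubule",
    "mean_longest_excess_um",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Full run configuration (all stages)."""

    enhancement: EnhanceConfig = field(default_factory=EnhanceConfig)
    mtoc: MTOCConfig = field(default_factory=MTOCConfig)
    min_tubule_length_px: float = 20.0
    strict_threshold: bool = True
    pixel_size_um: float = 0.1
    tubule_unit: Literal["branch", "component_max_path"] = "branch"
    excess_metric_empty_images: Literal["zero", "exclude"] = "zero"
    zprime_denominator: Literal["difference", "as_printed_sum"] = "difference"
    cell_mask_sigma_px: float = 5.0
    cell_mask_min_region_px: int = 500
    prune_px: float = 2.0

    def __post_init__(self) -> None:
        if self.min_tubule_length_px <= 0:
            raise ValueError("min_tubule_length_px must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.tubule_unit not in ("branch", "component_max_path"):
            raise ValueError("tubule_unit must be 'branch' or 'component_max_path'")


@dataclass(frozen=True)
class ImageAnalysis:
    """Everything the pipeline produced for one image."""

    result: ImageResult
    records: list[BranchRecord]
    graph: SkeletonGraph
    cell_mask: CellMask
    mtoc_region: MTOCRegion
    binary: np.ndarray


def analyze_image(
    image: MultiChannelImage, config: PipelineConfig | None = None
) -> ImageAnalysis:
    """Run the full detection pipeline on one two-channel image."""
    config = config or PipelineConfig()
    mask = make_cell_mask(
        image.cell_channel,
        blur_sigma_px=config.cell_mask_sigma_px,
        min_region_px=config.cell_mask_min_region_px,
    )
    enhanced = enhance_marker(image.marker_channel, config.enhancement)
    region = detect_mtoc(enhanced, mask, config.mtoc)
    binary = binarize(enhanced, mask, config.enhancement)
    binary = remove_region(binary, region)
    binary = fill_small_holes(binary, max_px=4) & mask.mask
    skel = skeletonize(binary)
    graph = analyze_skeleton(skel, prune_px=config.prune_px)
    records = graph.to_branch_records(image.source_id)
    if config.tubule_unit == "component_max_path":
        lengths: Sequence[float] = graph.component_max_path_lengths()
        result = classify_tubules(
            lengths,
            min_length_px=config.min_tubule_length_px,
            image_id=image.source_id,
            strict=config.strict_threshold,
        )
    else:
        result = classify_tubules(
            records,
            min_length_px=config.min_tubule_length_px,
            image_id=image.source_id,
            strict=config.strict_threshold,
        )
    return ImageAnalysis(
        result=result,
        records=records,
        graph=graph,
        cell_mask=mask,
        mtoc_region=region,
        binary=binary,
    )


def _per_image_metrics(result: ImageResult, pixel_size_um: float) -> dict[str, float]:
    return {
        "mean_tubules_per_image": float(result.n_tubules),
        "pct_images_with_tubule": 100.0 * float(result.has_tubule),
        "mean_longest_excess_um": result.longest_excess_px * pixel_size_um,
    }


def summarize_experiment(
    results: Sequence[ImageResult],
    manifest: pd.DataFrame,
    config: PipelineConfig | None = None,
    positive: str | None = None,
    negative: str | None = None,
    paired: bool = True,
) -> dict:
    """Cohort-level report from per-image results plus a manifest.

    The manifest must carry ``image_id``, ``condition`` and ``repeat``
    columns. Per condition: the three metrics (plus per-repeat values).
    When positive and negative conditions are designated: Z' per metric
    computed on per-repeat means, and t-tests across repeats (paired by
    repeat index by default).
    """
    config = config or PipelineConfig()
    by_id = {r.image_id: r for r in results}
    missing = [i for i in manifest["image_id"] if i not in by_id]
    if missing:
        raise ValueError(f"manifest rows without results: {missing[:5]}")

    report: dict = {"conditions": {}, "config": dataclasses.asdict(config)}
    per_repeat: dict[str, dict[str, list[float]]] = {}
    for cond, cond_rows in manifest.groupby("condition", sort=True):
        cond_results = [by_id[i] for i in cond_rows["image_id"]]
        summary = summarize_cohort(
            cond_results,
            pixel_size_um=config.pixel_size_um,
            condition=str(cond),
            empty_images=config.excess_metric_empty_images,
        )
        repeats: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
        for rep, rep_rows in cond_rows.groupby("repeat", sort=True):
            rep_summary = summarize_cohort(
                [by_id[i] for i in rep_rows["image_id"]],
                pixel_size_um=config.pixel_size_um,
                condition=str(cond),
                empty_images=config.excess_metric_empty_images,
            )
            for m in METRIC_NAMES:
                repeats[m].append(getattr(rep_summary, m))
        per_repeat[str(cond)] = repeats
        report["conditions"][str(cond)] = {
            **dataclasses.asdict(summary),
            "per_repeat": repeats,
        }

    if positive is not None and negative is not None:
        for name, cond in (("positive", positive), ("negative", negative)):
            if cond not in per_repeat:
                raise ValueError(f"unknown {name} condition {cond!r}")
        zp: dict[str, dict] = {}
        tests: dict[str, dict] = {}
        for m in METRIC_NAMES:
            pos_vals = per_repeat[positive][m]
            neg_vals = per_repeat[negative][m]
            pos_stats = condition_stats(pos_vals)
            neg_stats = condition_stats(neg_vals)
            entry: dict = {}
            for mode in ("difference", "as_printed_sum"):
                try:
                    z = zprime(pos_stats, neg_stats, denominator_mode=mode)
                    entry[mode] = {"z": z, "interpretation": interpret_zprime(z)}
                except UndefinedZPrimeError as exc:
                    entry[mode] = {"z": None, "error": str(exc)}
            entry["selected_mode"] = config.zprime_denominator
            zp[m] = entry
            try:
                from .metrics import compare_conditions

                t = compare_conditions(pos_vals, neg_vals, paired=paired)
                tests[m] = dataclasses.asdict(t)
            except DegenerateTestError as exc:
                tests[m] = {"error": str(exc)}
        report["zprime"] = zp
        report["t_tests"] = tests
        report["positive"] = positive
        report["negative"] = negative
    return report


# ---------------------------------------------------------------------------
# TOML configuration

def default_config_toml() -> str:
    """Render the full default configuration as a TOML document."""
    cfg = PipelineConfig()

    def fmt(v) -> str:
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, str):
            return f'"{v}"'
        return repr(v)

    lines = ["[pipeline]"]
    for f in dataclasses.fields(PipelineConfig):
        if f.name in ("enhancement", "mtoc"):
            continue
        lines.append(f"{f.name} = {fmt(getattr(cfg, f.name))}")
    lines.append("")
    lines.append("[enhancement]")
    for f in dataclasses.fields(EnhanceConfig):
        v = getattr(cfg.enhancement, f.name)
        if v is None:
            lines.append(f"# {f.name} = <unset>")
        else:
            lines.append(f"{f.name} = {fmt(v)}")
    lines.append("")
    lines.append("[mtoc]")
    for f in dataclasses.fields(MTOCConfig):
        lines.append(f"{f.name} = {fmt(getattr(cfg.mtoc, f.name))}")
    return "\n".join(lines) + "\n"


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a TOML run configuration; missing sections keep defaults."""
    if path is None:
        return PipelineConfig()
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    enh = EnhanceConfig(**data.get("enhancement", {}))
    mt = MTOCConfig(**data.get("mtoc", {}))
    pipe = dict(data.get("pipeline", {}))
    return PipelineConfig(enhancement=enh, mtoc=mt, **pipe)
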