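"""Batch pipeline: generate prey, score every camouflage metric, emit a CSV.

Produces one analysis-ready row per generated prey — the per-presentation
table a detection experiment would join its behavioural data onto.  Columns
cover GabRat at six scales, the Canny ratios and densities, the
edge-intersecting cluster count (missing for background-matching prey, which
have none by construction), SIFT correspondence counts, HMAX match summaries
with and without rotation, bandpass spectra differences and descriptives,
Euclidean Pattern Distances (z-scored over the batch), and the luminance
metrics, for both the local and global comparison regions.  Failures of an
individual metric are logged and recorded as missing values, never as 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .edgemetrics import (
    UndefinedRatioError,
    canny_edges,
    disruption_ratios,
    edge_densities,
    edge_intersecting_cluster_count,
)
from .gabrat import DEFAULT_SIGMAS, gabrat_profile
from .hmax import prey_template, s1_c1, template_match
from .imnorm import LuminanceImage
from .patternmetrics import (
    energy_spectrum,
    euclidean_pattern_distance,
    luminance_metrics,
    pattern_diff,
    spectrum_descriptives,
)
from .regions import make_region_set
from .siftmatch import SiftSettings, composite_on_white, sift_correspondences
from .stimgen import GenerationConfig, generate_prey, place_prey
from .stimgen import full_mask as _full_mask

__all__ = ["BatchConfig", "run_batch", "METRIC_GROUPS"]

logger = logging.getLogger("camometrics.harness")

METRIC_GROUPS = frozenset(
    {"gabrat", "canny", "cluster", "sift", "hmax", "pattern", "luminance"}
)

_DESC_FIELDS = (
    "max_energy",
    "dominant_scale",
    "proportion_power",
    "mean_energy",
    "energy_sd",
)


@dataclass
class BatchConfig:
    """Every knob of a batch run in one place (serialized to the manifest)."""

    generation: GenerationConfig = field(default_factory=GenerationConfig)
    sift: SiftSettings = field(default_factory=SiftSettings)
    gabrat_sigmas: tuple = DEFAULT_SIGMAS
    canny_sigma: float = 3.0
    canny_low: float = 0.2
    canny_high: float = 0.5
    body_length: int = 126
    hmax_stride: int = 2
    metrics: frozenset = METRIC_GROUPS

    def __post_init__(self) -> None:
        unknown = set(self.metrics) - METRIC_GROUPS
        if unknown:
            raise ValueError(f"unknown metric groups: {sorted(unknown)}")


def _gabrat_columns(record, slide, mask, cfg):
    prof = gabrat_profile(slide.pixels, mask, cfg.gabrat_sigmas)
    for s, res in prof.items():
        record[f"gabrat_s{s:g}"] = res.gabrat


def _canny_columns(record, slide, regions, cfg):
    edges = canny_edges(slide.pixels, cfg.canny_sigma, cfg.canny_low, cfg.canny_high)
    dens = edge_densities(edges, regions)
    record["moth_edge"] = dens.moth_edge
    record["cont_edge"] = dens.cont_edge
    record["local_bg_edge"] = dens.local_bg_edge
    record["global_bg_edge"] = dens.global_bg_edge
    record["mean_edge_region_canny"] = dens.cont_edge
    try:
        ratios = disruption_ratios(dens)
    except UndefinedRatioError:
        logger.warning("outline band has no edges; ratios recorded as missing")
        return
    record["visrat_local"] = ratios.visrat_local
    record["visrat_global"] = ratios.visrat_global
    record["disrat"] = ratios.disrat
    record["log_visrat_local"] = ratios.log_visrat_local
    record["log_visrat_global"] = ratios.log_visrat_global
    record["log_disrat"] = ratios.log_disrat


def _pattern_columns(record, slide, regions, spectra_out):
    local_bg = regions.local & ~regions.prey
    global_bg = ~regions.prey
    specs = {
        "prey": energy_spectrum(slide.pixels, regions.prey, region_label="prey"),
        "local": energy_spectrum(slide.pixels, local_bg, region_label="local"),
        "global": energy_spectrum(slide.pixels, global_bg, region_label="global"),
    }
    record["patterndiff_local"] = pattern_diff(specs["prey"], specs["local"])
    record["patterndiff_global"] = pattern_diff(specs["prey"], specs["global"])
    for label, spec in specs.items():
        desc = spectrum_descriptives(spec)
        spectra_out[label] = desc
        for f in _DESC_FIELDS:
            record[f"{label}_{f}"] = getattr(desc, f)
    record["mean_local_bandpass_energy"] = record["local_mean_energy"]


def _luminance_columns(record, slide, regions):
    prey_px = slide.pixels[regions.prey]
    local_px = slide.pixels[regions.local & ~regions.prey]
    global_px = slide.pixels[~regions.prey]
    for label, px in (("local", local_px), ("global", global_px)):
        m = luminance_metrics(prey_px, px)
        record[f"luminance_diff_{label}"] = m.luminance_diff
        record[f"mean_lum_diff_{label}"] = m.mean_lum_diff
        record[f"contrast_diff_{label}"] = m.contrast_diff
    record["mean_local_luminance"] = float(local_px.mean())


def _sift_columns(record, slide, prey, regions, cfg):
    fill = cfg.sift.background_fill
    prey_img = composite_on_white(prey.pixels, prey.mask, fill)
    local_img = composite_on_white(
        slide.pixels, regions.local & ~regions.prey, fill
    )
    global_img = composite_on_white(slide.pixels, ~regions.prey, fill)
    record["sift_local"] = sift_correspondences(prey_img, local_img, cfg.sift)
    record["sift_global"] = sift_correspondences(prey_img, global_img, cfg.sift)


def _hmax_columns(record, slide, regions, cfg):
    c1 = s1_c1(slide.pixels)
    template = prey_template(c1, regions.prey)
    masks = {"local": regions.local & ~regions.prey, "global": ~regions.prey}
    for label, mask in masks.items():
        for rot, tag in ((True, "rot"), (False, "norot")):
            m = template_match(template, c1, mask, rot, cfg.hmax_stride)
            record[f"hmax_mean_{tag}_{label}"] = m.mean_match
            record[f"hmax_best_{tag}_{label}"] = m.best_match
            record[f"hmax_sd_{tag}_{label}"] = m.sd_match


def run_batch(
    backgrounds: list[LuminanceImage],
    n_prey_per_bg: int,
    treatments=("background_matching", "disruptive"),
    polarity: str = "dark_on_light",
    seed: int = 0,
    config: BatchConfig | None = None,
    out_csv=None,
    manifest=None,
) -> pd.DataFrame:
    """Generate and score ``n_prey_per_bg x len(treatments)`` prey per
    background; deterministic for a fixed seed.  Optionally writes the CSV
    (comma, UTF-8, header, missing = empty) and a JSON run manifest."""
    if config is None:
        config = BatchConfig()
    rows: list[dict] = []
    spectra: list[dict] = []
    ss = np.random.SeedSequence(seed)
    slide_id = 0
    for bg_id, bg in enumerate(backgrounds):
        for treatment in treatments:
            for _ in range(n_prey_per_bg):
                rng = np.random.default_rng(ss.spawn(1)[0])
                record: dict = {
                    "slide_id": slide_id,
                    "background_id": bg_id,
                    "treatment": treatment,
                    "polarity": polarity,
                }
                prey = generate_prey(bg, treatment, polarity, config.generation, rng)
                slide, placed = place_prey(bg, prey, rng=rng,
                                           margin=config.body_length)
                record["x"], record["y"] = placed.placement
                record["patch_x"], record["patch_y"] = placed.source_patch_origin
                record["pattern_fraction"] = placed.pattern_fraction
                mask = _full_mask(placed, slide.pixels.shape)
                regions = make_region_set(mask, config.body_length)
                desc: dict = {}
                steps = []
                if "gabrat" in config.metrics:
                    steps.append(lambda: _gabrat_columns(record, slide, mask, config))
                if "canny" in config.metrics:
                    steps.append(lambda: _canny_columns(record, slide, regions, config))
                if "cluster" in config.metrics and treatment == "disruptive":
                    steps.append(
                        lambda: record.__setitem__(
                            "cluster_count",
                            edge_intersecting_cluster_count(placed),
                        )
                    )
                if "pattern" in config.metrics:
                    steps.append(
                        lambda: _pattern_columns(record, slide, regions, desc)
                    )
                if "luminance" in config.metrics:
                    steps.append(lambda: _luminance_columns(record, slide, regions))
                if "sift" in config.metrics:
                    steps.append(
                        lambda: _sift_columns(record, slide, placed, regions, config)
                    )
                if "hmax" in config.metrics:
                    steps.append(lambda: _hmax_columns(record, slide, regions, config))
                for step in steps:
                    try:
                        step()
                    except Exception:
                        logger.exception(
                            "metric failed on slide %d; recording missing", slide_id
                        )
                rows.append(record)
                spectra.append(desc)
                slide_id += 1
    df = pd.DataFrame(rows)
    if "pattern" in config.metrics:
        _add_pattern_distances(df, spectra)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    if manifest is not None:
        payload = {
            "version": __version__,
            "seed": seed,
            "n_backgrounds": len(backgrounds),
            "n_prey_per_bg": n_prey_per_bg,
            "treatments": list(treatments),
            "polarity": polarity,
            "config": repr(config),
        }
        with open(manifest, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
    return df


def _add_pattern_distances(df: pd.DataFrame, spectra: list[dict]) -> None:
    """Second pass: Euclidean Pattern Distances z-scored over the batch."""
    population = [d for row in spectra for d in row.values()]
    finite = [
        d for d in population if np.all(np.isfinite(d.as_vector()))
    ]
    for label in ("local", "global"):
        col = []
        for row in spectra:
            if "prey" in row and label in row and len(finite) >= 2:
                try:
                    col.append(
                        euclidean_pattern_distance(row["prey"], row[label], finite)
                    )
                    continue
                except ValueError:
                    pass
            col.append(np.nan)
        df[f"epd_{label}"] = col
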