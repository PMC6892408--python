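"""End-to-end convenience wrappers: image -> masks -> cells -> region metrics.

These functions chain the stain separation, segmentation and morphometry
modules with sensible defaults so that an analysis of a cohort is a few
lines; every knob of the underlying modules remains reachable through the
keyword arguments.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .morphometry import RegionMorphometry, summarize_region
from .segment import SegmentationResult, assign_processes, detect_nuclei
from .stains import (
    DEFAULT_STAIN_VECTORS,
    CalibratedImage,
    rgb_to_od,
    threshold_channel,
    unmix_stains,
)
from .synth import AnimalSample

_METRIC_COLUMNS = [
    "n_nuclei",
    "cells_per_mm2",
    "iba1_area_per_nucleus_um2",
    "process_area_per_nucleus_um2",
    "process_perimeter_per_nucleus_um",
]


def segment_image(
    image: CalibratedImage,
    stain_vectors: Optional[np.ndarray] = None,
    threshold_method: str = "otsu",
    iba1_threshold: Optional[float] = None,
    pu1_threshold: Optional[float] = None,
    radius_um: float = 2.0,
    min_nucleus_area_um2: float = 10.0,
    max_nucleus_area_um2: float = 400.0,
) -> SegmentationResult:
    """Unmix, threshold and segment one calibrated dual-stain image."""
    vectors = DEFAULT_STAIN_VECTORS if stain_vectors is None else stain_vectors
    maps = unmix_stains(rgb_to_od(image), vectors, image.microns_per_pixel)
    iba1 = threshold_channel(
        maps.iba1_od, threshold_method, iba1_threshold, image.microns_per_pixel
    )
    pu1 = threshold_channel(
        maps.pu1_od, threshold_method, pu1_threshold, image.microns_per_pixel
    )
    nuclei = detect_nuclei(pu1, min_nucleus_area_um2, max_nucleus_area_um2)
    return assign_processes(iba1, nuclei, radius_um=radius_um)


def analyze_image(
    image: CalibratedImage, **segment_kwargs
) -> tuple[SegmentationResult, RegionMorphometry]:
    """Segment one image and summarise it into per-region morphometrics."""
    seg = segment_image(image, **segment_kwargs)
    return seg, summarize_region(seg, image)


def cohort_morphometry(
    animals: Iterable[AnimalSample], **segment_kwargs
) -> pd.DataFrame:
    """Run the full image pipeline over a cohort.

    Returns one row per animal x region with the factor columns and the
    four region metrics; this is the table the ANOVA consumes.
    """
    rows = []
    for animal in animals:
        for region, image in animal.images.items():
            if image is None:
                raise ValueError(
                    "cohort was generated without rendering; use "
                    "cohort_truth_morphometry for ground-truth tables"
                )
            _, summary = analyze_image(image, **segment_kwargs)
            rows.append(_row(animal, region, summary))
    return pd.DataFrame(rows)


def cohort_truth_morphometry(animals: Iterable[AnimalSample]) -> pd.DataFrame:
    """Animal x region table of ground-truth morphometrics (no imaging step).

    ``process_area_per_nucleus_um2`` here is the mean per-cell *total*
    Iba1 area (soma + processes), i.e. the quantity the 2-um contiguity
    pipeline measures; ``true_process_area_um2`` is the soma-exclusive
    mean that factor-level multipliers on process geometry scale directly.
    """
    rows = []
    for animal in animals:
        for region, truth in animal.truths.items():
            mpp = truth.params.microns_per_pixel
            h, w = truth.iba1_mask.shape
            area_mm2 = h * w * mpp**2 / 1e6
            n = truth.n_cells
            rows.append(
                {
                    "animal_id": animal.animal_id,
                    "genotype": animal.genotype,
                    "age": animal.age,
                    "gender": animal.gender,
                    "region": region,
                    "n_nuclei": n,
                    "cells_per_mm2": n / area_mm2,
                    "iba1_area_per_nucleus_um2": (
                        truth.total_iba1_area_um2 / n if n else np.nan
                    ),
                    "process_area_per_nucleus_um2": (
                        float(np.mean([c.total_iba1_area_um2 for c in truth.cells]))
                        if n else np.nan
                    ),
                    "process_perimeter_per_nucleus_um": (
                        float(np.mean([c.process_perimeter_um for c in truth.cells]))
                        if n else np.nan
                    ),
                    "true_process_area_um2": (
                        float(np.mean([c.process_area_um2 for c in truth.cells]))
                        if n else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def _row(animal: AnimalSample, region: str, summary: RegionMorphometry) -> dict:
    return {
        "animal_id": animal.animal_id,
        "genotype": animal.genotype,
        "age": animal.age,
        "gender": animal.gender,
        "region": region,
        "n_nuclei": summary.n_nuclei,
        "cells_per_mm2": summary.cells_per_mm2,
        "iba1_area_per_nucleus_um2": summary.total_iba1_area_per_nucleus_um2,
        "process_area_per_nucleus_um2": summary.process_area_per_nucleus_um2,
        "process_perimeter_per_nucleus_um": summary.process_perimeter_per_nucleus_um,
    }
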