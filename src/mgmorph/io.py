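"""Reading and writing the pipeline's file formats.

Images and masks travel as 8-bit RGB / single-channel TIFF; tables as
CSV; ground truth as a JSON record plus label-mask TIFFs; gene sets as
one-id-per-line text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .stains import BinaryMask, CalibratedImage
from .synth import AnimalSample, GroundTruth


def write_image(path: str | Path, image: CalibratedImage) -> None:
    tifffile.imwrite(path, image.pixels, photometric="rgb")


def read_image(
    path: str | Path, microns_per_pixel: float, region: str = "other"
) -> CalibratedImage:
    pixels = tifffile.imread(path)
    return CalibratedImage(pixels=pixels, microns_per_pixel=microns_per_pixel,
                           region=region)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    tifffile.imwrite(path, mask.mask.astype(np.uint8))


def read_mask(path: str | Path, microns_per_pixel: float) -> BinaryMask:
    return BinaryMask(tifffile.imread(path) > 0, microns_per_pixel)


def write_ground_truth(directory: str | Path, truth: GroundTruth, stem: str) -> None:
    """Per-cell records as JSON plus nucleus/Iba1 label masks as TIFF."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cells = [
        {
            "cell_id": c.cell_id,
            "center_px": list(c.center_px),
            "nucleus_area_um2": c.nucleus_area_um2,
            "total_iba1_area_um2": c.total_iba1_area_um2,
            "process_area_um2": c.process_area_um2,
            "process_perimeter_um": c.process_perimeter_um,
        }
        for c in truth.cells
    ]
    meta = {
        "n_cells": truth.n_cells,
        "total_iba1_area_um2": truth.total_iba1_area_um2,
        "microns_per_pixel": truth.params.microns_per_pixel,
        "seed": truth.params.seed,
        "cells": cells,
    }
    (directory / f"{stem}_truth.json").write_text(json.dumps(meta, indent=1))
    tifffile.imwrite(directory / f"{stem}_nuclei.tif", truth.nucleus_labels)
    iba1_labels = np.zeros(truth.iba1_mask.shape, dtype=np.int32)
    for c in truth.cells:
        iba1_labels[c.iba1_mask] = c.cell_id
    tifffile.imwrite(directory / f"{stem}_iba1.tif", iba1_labels)


def write_cohort(directory: str | Path, animals: Iterable[AnimalSample]) -> pd.DataFrame:
    """Write cohort images plus a manifest CSV; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for animal in animals:
        for region, image in animal.images.items():
            stem = f"{animal.animal_id}_{region}"
            if image is not None:
                write_image(directory / f"{stem}.tif", image)
            write_ground_truth(directory, animal.truths[region], stem)
            rows.append(
                {
                    "animal_id": animal.animal_id,
                    "genotype": animal.genotype,
                    "age": animal.age,
                    "gender": animal.gender,
                    "region": region,
                    "image_path": f"{stem}.tif" if image is not None else "",
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def write_gene_set(path: str | Path, genes: Iterable[str]) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gene_set(path: str | Path) -> list[str]:
    return [line for line in Path(path).read_text().splitlines() if line.strip()]
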