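"""Per-cell and per-region microglial morphometrics.

Four metrics summarise each imaged region: Pu.1+ nuclei per mm^2, total
Iba1-immunoreactive area per nucleus, nucleus-attached process area per
nucleus, and nucleus-attached process perimeter per nucleus.  Areas are
pixel counts scaled by the squared pixel pitch; perimeters come from a
multi-directional Crofton line-intercept estimator.

The Crofton estimate follows the Cauchy-Crofton identity
``L = 1/2 * integral over line orientations and offsets of the crossing
count``: for each sampled direction the number of foreground runs along
every digital line is counted (one run contributes two boundary
crossings), weighted by the line spacing and the angular sector the
direction represents.  With the classical four directions {0, 45, 90,
135 degrees} the estimator carries an intrinsic ~-5% bias on axis-aligned
rectangles (pi times the mean projection width of a square over those
directions is 3.79a, not 4a); the default therefore adds the four
knight-move directions, which brings rectangles to ~-4% and digital discs
to ~-1%.  A naive boundary-edge count is available for sensitivity
analysis (exact on axis-aligned shapes, +27% on discs).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .segment import CellRecord, SegmentationResult
    from .stains import CalibratedImage

logger = logging.getLogger(__name__)


def _direction_table(directions: int) -> list[tuple[int, int, float, float]]:
    """(dr, dc, line spacing, angular weight) per sampled orientation."""
    if directions == 4:
        steps = [(0, 1), (1, 0), (1, 1), (1, -1)]
    elif directions == 8:
        steps = [(0, 1), (1, 0), (1, 1), (1, -1), (1, 2), (2, 1), (2, -1), (1, -2)]
    else:
        raise ValueError("directions must be 4 or 8")
    angles = [math.atan2(dr, dc) % math.pi for dr, dc in steps]
    order = np.argsort(angles)
    sorted_angles = [angles[i] for i in order]
    n = len(steps)
    weights = [0.0] * n
    for rank, i in enumerate(order):
        nxt = (sorted_angles[(rank + 1) % n] - sorted_angles[rank]) % math.pi
        prv = (sorted_angles[rank] - sorted_angles[rank - 1]) % math.pi
        weights[i] = 0.5 * (nxt + prv)
    return [
        (dr, dc, 1.0 / math.hypot(dr, dc), weights[i])
        for i, (dr, dc) in enumerate(steps)
    ]

_TABLES = {4: _direction_table(4), 8: _direction_table(8)}


def _shifted(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """mask translated by (dr, dc), zero-filled at the borders."""
    out = np.zeros_like(mask)
    r0, r1 = max(0, dr), mask.shape[0] + min(0, dr)
    c0, c1 = max(0, dc), mask.shape[1] + min(0, dc)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = mask[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    return out


def estimate_perimeter(
    mask: np.ndarray,
    mpp: float,
    method: str = "crofton",
    directions: int = 8,
) -> float:
    """Perimeter of a binary pixel set, in micrometres.

    ``method="crofton"`` (default) is the multi-directional line-intercept
    estimator described in the module docstring; ``method="edge"`` counts
    exposed pixel faces.  An empty mask returns 0 with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("empty mask has no perimeter; returning 0", stacklevel=2)
        return 0.0
    if method == "edge":
        length_px = sum(
            int(np.count_nonzero(mask & ~_shifted(mask, dr, dc)))
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0))
        )
    elif method == "crofton":
        length_px = 0.0
        for dr, dc, spacing, weight in _TABLES[directions]:
            runs = int(np.count_nonzero(mask & ~_shifted(mask, dr, dc)))
            length_px += weight * runs * spacing
    else:
        raise ValueError(f"unknown perimeter method {method!r}")
    logger.debug("estimate_perimeter: method=%s directions=%s", method, directions)
    return float(length_px) * mpp


@dataclass
class RegionMorphometry:
    """Aggregate morphometrics for one imaged region of one animal.

    Per-nucleus quantities are NaN when the region contains no nuclei.
    """

    region: str
    imaged_area_mm2: float
    n_nuclei: int
    cells_per_mm2: float
    total_iba1_area_per_nucleus_um2: float
    process_area_per_nucleus_um2: float
    process_perimeter_per_nucleus_um: float
    non_process_iba1_area_um2: float


def measure_cells(
    seg: "SegmentationResult",
    perimeter_method: str = "crofton",
) -> list["CellRecord"]:
    """Fill per-cell morphometrics on a segmentation result, in place.

    Only nucleus-attached Iba1 (each cell's assigned component pixels,
    soma-overlapping signal included) contributes to the per-cell process
    metrics; ``process_area = |process_mask| * mpp^2``.
    """
    mpp = seg.microns_per_pixel
    for cell in seg.cells:
        n_px = int(cell.process_mask.sum())
        cell.process_area_um2 = n_px * mpp**2
        cell.total_iba1_area_um2 = cell.process_area_um2
        if n_px:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cell.process_perimeter_um = estimate_perimeter(
                    cell.process_mask, mpp, method=perimeter_method
                )
        else:
            cell.process_perimeter_um = 0.0
    return seg.cells


def summarize_region(
    seg: "SegmentationResult",
    image: "CalibratedImage",
    perimeter_method: str = "crofton",
) -> RegionMorphometry:
    """Aggregate a segmented field into the four per-region metrics.

    ``total_iba1_area_per_nucleus`` divides the region's entire Iba1 area
    (non-process signal included) by the nucleus count; the process metrics
    are means over cells of the nucleus-attached values.
    """
    h, w = image.shape
    mpp = seg.microns_per_pixel
    imaged_area_mm2 = h * w * mpp**2 / 1e6
    if imaged_area_mm2 <= 0:
        raise ValueError("imaged area is zero")
    cells = measure_cells(seg, perimeter_method=perimeter_method)
    n = len(cells)
    non_process_area = float(seg.non_process_mask.sum()) * mpp**2
    total_iba1 = sum(c.process_area_um2 for c in cells) + non_process_area
    return RegionMorphometry(
        region=image.region,
        imaged_area_mm2=imaged_area_mm2,
        n_nuclei=n,
        cells_per_mm2=n / imaged_area_mm2,
        total_iba1_area_per_nucleus_um2=total_iba1 / n if n else float("nan"),
        process_area_per_nucleus_um2=(
            float(np.mean([c.process_area_um2 for c in cells])) if n else float("nan")
        ),
        process_perimeter_per_nucleus_um=(
            float(np.mean([c.process_perimeter_um for c in cells]))
            if n else float("nan")
        ),
        non_process_iba1_area_um2=non_process_area,
    )
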