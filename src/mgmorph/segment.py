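"""Pu.1+ nucleus detection and Iba1 process assignment.

The assignment rule mirrors the morphometry algorithm used on the real
slides: all contiguous Iba1 immunoreactivity whose minimum Euclidean
distance to a Pu.1-positive nucleus is at most 2 um belongs to that
nucleus's cell ("its microglial processes"); Iba1 signal not attributable
to any nucleus is "non-process Iba1".  Contiguity uses 8-connectivity so
that 1-px-wide diagonal processes stay connected.

When one Iba1 connected component lies within the radius of two or more
nuclei, the component is partitioned between those nuclei by geodesic
(within-component, 8-neighbour hop count) distance to the nearest
qualifying nucleus, ties going to the lower nucleus id.  The cell process
masks plus the non-process mask always tile the Iba1 mask exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import graph

from .stains import BinaryMask

#: 3x3 structuring element: 8-connectivity for both stains.
_EIGHT = np.ones((3, 3), dtype=bool)


class ScaleMismatchError(ValueError):
    """Input masks do not share shape or physical scale."""


@dataclass
class NucleusRecord:
    """One Pu.1+ nucleus: id, pixel mask, centroid and physical area."""

    id: int
    mask: np.ndarray
    centroid: tuple[float, float]
    area_um2: float


@dataclass
class CellRecord:
    """A nucleus with its assigned Iba1 pixels and (filled later) metrics.

    ``process_mask`` holds every Iba1 pixel attributed to this nucleus,
    soma-overlapping signal included.  Metric fields are populated by
    :func:`mgmorph.morphometry.measure_cells`.
    """

    nucleus: NucleusRecord
    process_mask: np.ndarray
    total_iba1_area_um2: Optional[float] = None
    process_area_um2: Optional[float] = None
    process_perimeter_um: Optional[float] = None


@dataclass
class SegmentationResult:
    """Partition of the Iba1 mask into per-cell masks and non-process signal."""

    cells: list[CellRecord]
    non_process_mask: np.ndarray
    microns_per_pixel: float
    radius_um: float = 2.0
    parameters: dict = field(default_factory=dict)


def detect_nuclei(
    pu1_mask: BinaryMask,
    min_area_um2: float = 10.0,
    max_area_um2: float = 400.0,
) -> list[NucleusRecord]:
    """Connected components of the Pu.1 mask, size-filtered to plausible nuclei.

    Components (8-connectivity) with area in ``[min_area_um2,
    max_area_um2]`` are kept; ids are assigned in raster order of each
    component's first pixel.  An empty mask yields an empty list.
    """
    if not (0 <= min_area_um2 < max_area_um2):
        raise ValueError("need 0 <= min_area_um2 < max_area_um2")
    mpp = pu1_mask.microns_per_pixel
    labels, n = ndimage.label(pu1_mask.mask, structure=_EIGHT)
    records: list[NucleusRecord] = []
    if n == 0:
        return records
    # scipy assigns labels in raster order of first pixels already
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    centroids = ndimage.center_of_mass(pu1_mask.mask, labels, index=range(1, n + 1))
    next_id = 1
    for lab, n_px, centroid in zip(range(1, n + 1), areas, centroids):
        area = float(n_px) * mpp**2
        if min_area_um2 <= area <= max_area_um2:
            records.append(
                NucleusRecord(
                    id=next_id,
                    mask=labels == lab,
                    centroid=(float(centroid[0]), float(centroid[1])),
                    area_um2=area,
                )
            )
            next_id += 1
    return records


def _near_nucleus_mask(
    nucleus_mask: np.ndarray, radius_px: float
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Pixels within Euclidean distance ``radius_px`` (inclusive) of the nucleus.

    Computed by an exact Euclidean distance transform on a padded bounding
    box; returns the boolean box and its slices into the full image.
    """
    rows, cols = np.nonzero(nucleus_mask)
    pad = int(math.ceil(radius_px)) + 1
    h, w = nucleus_mask.shape
    r0, r1 = max(rows.min() - pad, 0), min(rows.max() + pad + 1, h)
    c0, c1 = max(cols.min() - pad, 0), min(cols.max() + pad + 1, w)
    box = nucleus_mask[r0:r1, c0:c1]
    dist = ndimage.distance_transform_edt(~box)
    return dist <= radius_px, (slice(r0, r1), slice(c0, c1))


def _geodesic_hops(component_box: np.ndarray, seeds_box: np.ndarray) -> np.ndarray:
    """8-neighbour hop-count distance within a component from seed pixels."""
    costs = np.where(component_box, 1.0, np.inf)
    mcp = graph.MCP(costs, fully_connected=True)
    starts = list(zip(*np.nonzero(seeds_box)))
    cum, _ = mcp.find_costs(starts)
    return cum  # hop count + 1 at reachable pixels; +1 cancels in argmin


def assign_processes(
    iba1_mask: BinaryMask,
    nuclei: list[NucleusRecord],
    radius_um: float = 2.0,
) -> SegmentationResult:
    """Attribute Iba1 connected components to nuclei by the contiguity rule.

    A component is cell-associated iff its minimum Euclidean distance to
    some nucleus pixel is <= ``radius_um`` (inclusive).  Components near
    exactly one nucleus are assigned wholly to it; components near several
    are partitioned by within-component hop distance to the nearest
    qualifying nucleus (ties to the lower id); everything else is
    non-process Iba1.
    """
    if radius_um < 0:
        raise ValueError("radius_um must be >= 0")
    mpp = iba1_mask.microns_per_pixel
    for nuc in nuclei:
        if nuc.mask.shape != iba1_mask.shape:
            raise ScaleMismatchError("nucleus and Iba1 masks differ in shape")
    radius_px = radius_um / mpp

    comp_labels, n_comp = ndimage.label(iba1_mask.mask, structure=_EIGHT)
    # nearby[j] = (component ids, per-nucleus halo and its window)
    candidates: dict[int, list[tuple[NucleusRecord, np.ndarray, tuple[slice, slice]]]] = {}
    for nuc in nuclei:
        if not nuc.mask.any():
            continue
        halo, window = _near_nucleus_mask(nuc.mask, radius_px)
        touched = np.unique(comp_labels[window][halo])
        for comp in touched[touched > 0]:
            candidates.setdefault(int(comp), []).append((nuc, halo, window))

    assigned: dict[int, np.ndarray] = {
        nuc.id: np.zeros(iba1_mask.shape, dtype=bool) for nuc in nuclei
    }
    non_process = np.zeros(iba1_mask.shape, dtype=bool)
    comp_slices = ndimage.find_objects(comp_labels)
    for comp in range(1, n_comp + 1):
        owners = candidates.get(comp, [])
        if not owners:
            non_process |= comp_labels == comp
            continue
        if len(owners) == 1:
            assigned[owners[0][0].id] |= comp_labels == comp
            continue
        # shared component: geodesic nearest-qualifying-nucleus partition
        sl = comp_slices[comp - 1]
        comp_mask_box = comp_labels[sl] == comp
        hop_maps = []
        ids = []
        for nuc, halo, window in sorted(owners, key=lambda o: o[0].id):
            seeds = np.zeros(iba1_mask.shape, dtype=bool)
            seeds[window] = halo
            seeds_box = seeds[sl] & comp_mask_box
            hop_maps.append(_geodesic_hops(comp_mask_box, seeds_box))
            ids.append(nuc.id)
        stack = np.stack(hop_maps)  # argmin picks the lowest id on ties
        winner = np.take(ids, np.argmin(stack, axis=0))
        for nuc_id in ids:
            full = np.zeros(iba1_mask.shape, dtype=bool)
            full[sl] = comp_mask_box & (winner == nuc_id)
            assigned[nuc_id] |= full

    cells = [
        CellRecord(nucleus=nuc, process_mask=assigned[nuc.id]) for nuc in nuclei
    ]
    return SegmentationResult(
        cells=cells,
        non_process_mask=non_process,
        microns_per_pixel=mpp,
        radius_um=radius_um,
        parameters={"radius_um": radius_um, "connectivity": 8},
    )
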