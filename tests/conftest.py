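import numpy as np
import pytest

import mgmorph as mg


@pytest.fixture(scope="session")
def noise_free_params() -> mg.SynthParams:
    return mg.SynthParams(seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_field(noise_free_params):
    """One rendered noise-free field with its ground truth."""
    return mg.generate_microglia_image(noise_free_params)


@pytest.fixture(scope="session")
def segmented_field(noise_free_field):
    image, truth = noise_free_field
    seg = mg.segment_image(image)
    return image, truth, seg


def match_truth_cell(cell: mg.CellRecord, truth: mg.GroundTruth) -> mg.CellGroundTruth:
    """Pair a segmented cell with its ground-truth cell via the nucleus centroid."""
    r, c = cell.nucleus.centroid
    return min(
        truth.cells,
        key=lambda t: (t.center_px[0] - r) ** 2 + (t.center_px[1] - c) ** 2,
    )


def bfs_flood_fill(mask: np.ndarray, start: tuple[int, int], connectivity: int):
    """Brute-force flood fill, oracle for connected-component membership."""
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if dr or dc]
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for r, c in frontier:
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and (rr, cc) not in seen:
                    seen.add((rr, cc))
                    nxt.append((rr, cc))
        frontier = nxt
    return seen
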