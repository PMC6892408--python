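"""Synthetic dual-stain microglia histology with exact ground truth.

Real slides for this assay are whole-brain sections immunoreacted with
anti-Iba1 (purple chromogen, cytosol and processes) and anti-Pu.1 (brown
chromogen, nucleus), scanned in brightfield.  This module draws simplified
but structurally faithful versions of such fields: each microglial cell is
a soma disc containing a Pu.1+ nucleus, with thin branching Iba1+ processes
radiating outward (ramified class) or a compact blobby soma with short
stubs (amoeboid class, as seen in cerebellum).  Concentrations are rendered
to RGB through the Beer-Lambert model using the same stain vectors the
unmixing step assumes, with optional Gaussian noise added in OD space.

Every generated image carries a :class:`GroundTruth` whose per-cell masks
and morphometrics are exact (areas are literal pixel counts times the
squared pixel pitch), so the downstream segmentation and statistics can be
validated against a known answer.  The module also generates per-gene and
per-peak statistics tables with known true-positive labels for exercising
the genomics threshold filters.

All outputs are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .morphometry import estimate_perimeter
from .stains import DEFAULT_STAIN_VECTORS, CalibratedImage, od_to_rgb

#: Neutral gray absorbance direction used for tissue background.
_BACKGROUND_VECTOR = np.ones(3) / np.sqrt(3.0)

#: Placement attempts per cell before it is dropped.
_MAX_PLACEMENT_TRIES = 200

#: Approximate arc length of one random-walk segment, in micrometres.
_SEGMENT_LENGTH_UM = 4.0

#: Std dev of the per-segment heading change, radians.
_TURN_SD = 0.3

#: Probability that a process spawns one side branch.
_BRANCH_PROB = 0.5


@dataclass(frozen=True)
class SynthParams:
    """Generation parameters for one synthetic field.

    Lengths are micrometres.  ``process_length_um`` is a ``(low, high)``
    uniform range for the arc length of each primary process.  Identical
    parameters and seed give bit-identical output.
    """

    n_cells: int = 4
    soma_radius_um: float = 5.0
    nucleus_radius_um: float = 3.5
    n_processes_per_cell: int = 4
    process_length_um: tuple[float, float] = (10.0, 22.0)
    process_thickness_um: float = 2.0
    morphology_class: str = "ramified"
    stain_vectors: np.ndarray = field(default_factory=lambda: DEFAULT_STAIN_VECTORS)
    iba1_peak_od: float = 0.8
    pu1_peak_od: float = 0.9
    background_od: float = 0.05
    noise_sd: float = 0.02
    microns_per_pixel: float = 0.5
    image_size_px: tuple[int, int] = (256, 256)
    min_separation_um: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("soma_radius_um", "nucleus_radius_um", "process_thickness_um",
                     "microns_per_pixel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.process_length_um
        if not (0 < lo <= hi):
            raise ValueError("process_length_um must be 0 < low <= high")
        if self.nucleus_radius_um > self.soma_radius_um:
            raise ValueError("nucleus must fit inside the soma")
        if self.morphology_class not in ("ramified", "amoeboid"):
            raise ValueError("morphology_class must be 'ramified' or 'amoeboid'")
        if self.background_od < 0 or self.noise_sd < 0:
            raise ValueError("background_od and noise_sd must be >= 0")
        vectors = np.asarray(self.stain_vectors, dtype=float)
        if vectors.shape != (2, 3):
            raise ValueError("stain_vectors must be 2 x 3")
        if not np.allclose(np.linalg.norm(vectors, axis=1), 1.0, atol=1e-6):
            raise ValueError("stain vectors must have unit norm")
        if np.linalg.matrix_rank(vectors) < 2:
            raise ValueError("stain vectors must be linearly independent")


@dataclass
class CellGroundTruth:
    """Exact per-cell masks and morphometrics for one generated cell."""

    cell_id: int
    center_px: tuple[float, float]
    nucleus_mask: np.ndarray
    soma_mask: np.ndarray
    iba1_mask: np.ndarray  # soma plus processes
    nucleus_area_um2: float = 0.0
    total_iba1_area_um2: float = 0.0  # area the 2-um contiguity rule attributes
    process_area_um2: float = 0.0  # soma-exclusive: scales with process geometry
    process_perimeter_um: float = 0.0

    @property
    def process_mask(self) -> np.ndarray:
        return self.iba1_mask & ~self.soma_mask


@dataclass
class GroundTruth:
    """Region-level ground truth: per-cell records plus combined masks."""

    cells: list[CellGroundTruth]
    iba1_mask: np.ndarray
    pu1_mask: np.ndarray
    nucleus_labels: np.ndarray
    params: SynthParams

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total_iba1_area_um2(self) -> float:
        return float(self.iba1_mask.sum()) * self.params.microns_per_pixel**2


# ---------------------------------------------------------------------------
# rasterisation helpers (continuous geometry -> pixel-centre membership)

def _fill_disc(mask: np.ndarray, center: tuple[float, float], radius: float) -> None:
    h, w = mask.shape
    r0 = max(int(math.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(math.ceil(center[0] + radius)) + 2, h)
    c0 = max(int(math.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(math.ceil(center[1] + radius)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _fill_stroke(mask: np.ndarray, p: np.ndarray, q: np.ndarray, radius: float) -> None:
    """Mark pixel centres within ``radius`` of segment p-q."""
    h, w = mask.shape
    r0 = max(int(math.floor(min(p[0], q[0]) - radius)) - 1, 0)
    r1 = min(int(math.ceil(max(p[0], q[0]) + radius)) + 2, h)
    c0 = max(int(math.floor(min(p[1], q[1]) - radius)) - 1, 0)
    c1 = min(int(math.ceil(max(p[1], q[1]) + radius)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    v = q - p
    vv = float(v @ v)
    if vv == 0.0:
        d2 = (rr - p[0]) ** 2 + (cc - p[1]) ** 2
    else:
        t = ((rr - p[0]) * v[0] + (cc - p[1]) * v[1]) / vv
        t = np.clip(t, 0.0, 1.0)
        d2 = (rr - (p[0] + t * v[0])) ** 2 + (cc - (p[1] + t * v[1])) ** 2
    mask[r0:r1, c0:c1] |= d2 <= radius**2


def _reflect(value: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by mirror reflection."""
    while value < lo or value > hi:
        if value < lo:
            value = 2 * lo - value
        else:
            value = 2 * hi - value
    return value


def _sample_polyline(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    length_px: float,
    seg_len_px: float,
    bounds: tuple[int, int],
) -> np.ndarray:
    """Random-walk polyline of roughly ``length_px`` total arc length.

    Vertices reflect off the image border so a process never leaves the
    field: a clipped path would render as a disconnected fragment that the
    contiguity rule could not attribute to its cell.
    """
    h, w = bounds
    n_seg = max(2, int(round(length_px / seg_len_px)))
    step = length_px / n_seg
    vertices = [start]
    pos = start.astype(float).copy()
    for _ in range(n_seg):
        heading += rng.normal(0.0, _TURN_SD)
        pos = pos + step * np.array([math.sin(heading), math.cos(heading)])
        pos = np.array(
            [_reflect(pos[0], 1.0, h - 2.0), _reflect(pos[1], 1.0, w - 2.0)]
        )
        vertices.append(pos)
    return np.array(vertices)


def _cell_geometry(rng: np.random.Generator, center: np.ndarray, p: SynthParams):
    """Sample soma discs and process polylines for one cell, in pixel units.

    Returns (soma_discs, polylines) where soma_discs is a list of
    (center, radius) and polylines a list of (vertices, stroke_radius).
    """
    mpp = p.microns_per_pixel
    soma_r = p.soma_radius_um / mpp
    stroke_r = p.process_thickness_um / 2.0 / mpp
    lo, hi = p.process_length_um
    n_proc = p.n_processes_per_cell
    amoeboid = p.morphology_class == "amoeboid"
    if amoeboid:
        # compact reactive morphology: enlarged irregular soma, short stubs
        discs = [(center, soma_r)]
        for _ in range(2):
            offset = rng.normal(0.0, 0.3 * soma_r, size=2)
            discs.append((center + offset, soma_r * rng.uniform(0.75, 1.0)))
        n_proc = max(1, n_proc // 2)
        lo, hi = 0.3 * lo, 0.3 * hi
        stroke_r *= 1.5
    else:
        discs = [(center, soma_r)]
    seg_len = _SEGMENT_LENGTH_UM / mpp
    bounds = p.image_size_px
    polylines = []
    for k in range(n_proc):
        phi = 2.0 * math.pi * k / max(n_proc, 1) + rng.normal(0.0, 0.3)
        length = rng.uniform(lo, hi) / mpp
        # root slightly inside the soma so the process is always contiguous
        root = center + 0.8 * soma_r * np.array([math.sin(phi), math.cos(phi)])
        line = _sample_polyline(rng, root, phi, length, seg_len, bounds)
        polylines.append((line, stroke_r))
        if not amoeboid and rng.random() < _BRANCH_PROB and len(line) > 2:
            j = int(rng.integers(1, len(line) - 1))
            used = length * j / (len(line) - 1)
            branch_len = 0.5 * (length - used)
            if branch_len > seg_len:
                delta = line[j] - line[j - 1]
                base_heading = math.atan2(delta[0], delta[1])
                turn = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)
                branch = _sample_polyline(
                    rng, line[j], base_heading + turn, branch_len, seg_len, bounds
                )
                polylines.append((branch, stroke_r))
    return discs, polylines


# ---------------------------------------------------------------------------
# image generation

def generate_microglia_image(params: SynthParams) -> tuple[CalibratedImage, GroundTruth]:
    """Render one calibrated dual-stain field and its exact ground truth.

    Somas are placed by rejection sampling with a minimum centre-to-centre
    separation; cells that cannot be placed after a bounded number of tries
    are dropped, and the ground truth reflects actual placements.  Raises
    ``ValueError`` if the image is too small to hold even one soma.
    """
    _, noise_rng = _spawn_rngs(params.seed)
    truth = generate_ground_truth(params)
    image = _render(truth.iba1_mask, truth.pu1_mask, params, noise_rng)
    return image, truth


def generate_ground_truth(params: SynthParams) -> GroundTruth:
    """Sample cell geometry and masks without rendering an RGB image.

    Uses the same geometry random stream as :func:`generate_microglia_image`,
    so the returned truth is identical to the one that call would produce.
    """
    geometry, _ = _spawn_rngs(params.seed)
    h, w = params.image_size_px
    mpp = params.microns_per_pixel
    soma_r_px = params.soma_radius_um / mpp
    margin = soma_r_px + 1.0
    if params.n_cells > 0 and (h - 2 * margin <= 0 or w - 2 * margin <= 0):
        raise ValueError(
            f"image {h}x{w} px too small to place a soma of radius "
            f"{soma_r_px:.1f} px"
        )
    min_sep_px = params.min_separation_um / mpp

    centers: list[np.ndarray] = []
    for _ in range(params.n_cells):
        for _ in range(_MAX_PLACEMENT_TRIES):
            cand = geometry.uniform([margin, margin], [h - margin, w - margin])
            if all(np.hypot(*(cand - c)) >= min_sep_px for c in centers):
                centers.append(cand)
                break
        # else: drop the cell; the count reflects placements

    cells: list[CellGroundTruth] = []
    iba1 = np.zeros((h, w), dtype=bool)
    pu1 = np.zeros((h, w), dtype=bool)
    labels = np.zeros((h, w), dtype=np.int32)
    for i, center in enumerate(centers):
        discs, polylines = _cell_geometry(geometry, center, params)
        soma = np.zeros((h, w), dtype=bool)
        for c, r in discs:
            _fill_disc(soma, tuple(c), r)
        cell_iba1 = soma.copy()
        for line, stroke_r in polylines:
            for a, b in zip(line[:-1], line[1:]):
                _fill_stroke(cell_iba1, a, b, stroke_r)
        nucleus = np.zeros((h, w), dtype=bool)
        _fill_disc(nucleus, tuple(center), params.nucleus_radius_um / mpp)
        process = cell_iba1 & ~soma
        cell = CellGroundTruth(
            cell_id=i + 1,
            center_px=(float(center[0]), float(center[1])),
            nucleus_mask=nucleus,
            soma_mask=soma,
            iba1_mask=cell_iba1,
            nucleus_area_um2=float(nucleus.sum()) * mpp**2,
            total_iba1_area_um2=float(cell_iba1.sum()) * mpp**2,
            process_area_um2=float(process.sum()) * mpp**2,
            process_perimeter_um=(
                estimate_perimeter(process, mpp) if process.any() else 0.0
            ),
        )
        cells.append(cell)
        iba1 |= cell_iba1
        pu1 |= nucleus
        labels[nucleus] = cell.cell_id

    return GroundTruth(
        cells=cells, iba1_mask=iba1, pu1_mask=pu1, nucleus_labels=labels, params=params
    )


def _spawn_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def _render(
    iba1_mask: np.ndarray,
    pu1_mask: np.ndarray,
    params: SynthParams,
    noise_rng: np.random.Generator,
    region: str = "other",
) -> CalibratedImage:
    vectors = np.asarray(params.stain_vectors, dtype=float)
    od = (
        iba1_mask[..., None] * params.iba1_peak_od * vectors[0]
        + pu1_mask[..., None] * params.pu1_peak_od * vectors[1]
        + params.background_od * _BACKGROUND_VECTOR
    )
    if params.noise_sd > 0:
        od = od + noise_rng.normal(0.0, params.noise_sd, size=od.shape)
    od = np.maximum(od, 0.0)
    return CalibratedImage(
        pixels=od_to_rgb(od),
        microns_per_pixel=params.microns_per_pixel,
        region=region,
    )


# ---------------------------------------------------------------------------
# cohorts

#: SynthParams fields that factor-level effect multipliers may scale.
_SCALABLE_FIELDS = (
    "process_thickness_um",
    "process_length_um",
    "n_cells",
    "soma_radius_um",
)


@dataclass(frozen=True)
class CohortDesign:
    """Factorial animal cohort: genotype x age cells with genders rotated within.

    ``effects`` maps factor name -> level -> {param field: multiplier}, e.g.
    ``{"genotype": {"KO": {"process_thickness_um": 0.7}}}`` thins KO
    processes to 70%.  ``n_per_cell`` animals are generated per genotype x
    age cell (about five per gender subgroup mirrors a typical cohort).
    """

    genotypes: tuple[str, ...] = ("WT", "KO")
    ages: tuple[str, ...] = ("2mo", "18-24mo")
    genders: tuple[str, ...] = ("M", "F")
    n_per_cell: int = 9
    regions: tuple[str, ...] = ("cortex",)
    effects: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genotypes", "ages", "genders", "regions"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2 for downstream ANOVA")
        for factor, levels in self.effects.items():
            if factor not in ("genotype", "age", "gender"):
                raise ValueError(f"unknown effect factor {factor!r}")
            for level, mults in levels.items():
                for fname, m in mults.items():
                    if fname not in _SCALABLE_FIELDS:
                        raise ValueError(f"cannot scale SynthParams field {fname!r}")
                    if not m > 0:
                        raise ValueError("effect multipliers must be > 0")


@dataclass
class AnimalSample:
    """One animal: factor levels plus per-region images and ground truths.

    ``images[region]`` is ``None`` when the cohort was generated with
    ``render=False`` (ground truth only).
    """

    animal_id: str
    genotype: str
    age: str
    gender: str
    images: dict[str, Optional[CalibratedImage]]
    truths: dict[str, GroundTruth]


def _apply_effects(base: SynthParams, design: CohortDesign,
                   levels: Mapping[str, str]) -> SynthParams:
    mult: dict[str, float] = {}
    for factor, level in levels.items():
        for fname, m in design.effects.get(factor, {}).get(level, {}).items():
            mult[fname] = mult.get(fname, 1.0) * m
    changes: dict = {}
    for fname, m in mult.items():
        value = getattr(base, fname)
        if fname == "n_cells":
            changes[fname] = max(0, int(round(value * m)))
        elif fname == "process_length_um":
            changes[fname] = (value[0] * m, value[1] * m)
        else:
            changes[fname] = value * m
    return replace(base, **changes) if changes else base


def generate_cohort(
    design: CohortDesign,
    base_params: Optional[SynthParams] = None,
    render: bool = True,
) -> list[AnimalSample]:
    """Generate one image (or ground truth) set per animal per region.

    Animal-level seeds derive deterministically from ``design.seed``.
    Cerebellar fields use the amoeboid morphology class; all other regions
    inherit ``base_params.morphology_class``.
    """
    base = base_params if base_params is not None else SynthParams()
    seed_rng = np.random.default_rng(np.random.SeedSequence((design.seed, 0x9E37)))
    animals: list[AnimalSample] = []
    idx = 0
    for genotype in design.genotypes:
        for age in design.ages:
            for i in range(design.n_per_cell):
                gender = design.genders[i % len(design.genders)]
                idx += 1
                params_a = _apply_effects(
                    base, design, {"genotype": genotype, "age": age, "gender": gender}
                )
                images: dict[str, Optional[CalibratedImage]] = {}
                truths: dict[str, GroundTruth] = {}
                for region in design.regions:
                    seed = int(seed_rng.integers(0, 2**31 - 1))
                    morphology = (
                        "amoeboid" if region == "cerebellum"
                        else params_a.morphology_class
                    )
                    params_r = replace(
                        params_a, seed=seed, morphology_class=morphology
                    )
                    if render:
                        image, truth = generate_microglia_image(params_r)
                        image.region = region
                        image.metadata.update(
                            animal_id=f"A{idx:03d}", genotype=genotype,
                            age=age, gender=gender,
                        )
                        images[region] = image
                    else:
                        truth = generate_ground_truth(params_r)
                        images[region] = None
                    truths[region] = truth
                animals.append(
                    AnimalSample(
                        animal_id=f"A{idx:03d}", genotype=genotype, age=age,
                        gender=gender, images=images, truths=truths,
                    )
                )
    return animals


# ---------------------------------------------------------------------------
# synthetic statistics tables

def generate_gene_stat_table(
    n_genes: int = 5000,
    n_true_de: int = 100,
    fc_range: tuple[float, float] = (1.5, 4.0),
    tpm_meanlog: float = 2.0,
    tpm_sdlog: float = 1.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene statistics with known differential-expression labels.

    Non-DE genes receive Uniform(0, 1) p-values and fold changes near 1;
    true-DE genes receive fold-change magnitudes drawn from ``fc_range``
    (random direction, reciprocal for down) and very small p-values.  Mean
    TPM is log-normal.  The ``fdr`` column is left missing: it is computed
    downstream by the Benjamini-Hochberg step.  Columns: ``gene_id,
    mean_tpm, fold_change, p, fdr, true_de``.
    """
    if n_true_de > n_genes:
        raise ValueError("n_true_de must be <= n_genes")
    if not (1.0 <= fc_range[0] <= fc_range[1]):
        raise ValueError("fc_range must satisfy 1 <= low <= high")
    rng = np.random.default_rng(seed)
    gene_id = np.array([f"g{i:05d}" for i in range(n_genes)])
    true_de = np.zeros(n_genes, dtype=bool)
    true_de[rng.choice(n_genes, size=n_true_de, replace=False)] = True

    p = rng.uniform(0.0, 1.0, size=n_genes)
    p[true_de] = 10.0 ** rng.uniform(-12.0, -6.0, size=n_true_de)

    fold_change = 2.0 ** rng.normal(0.0, 0.05, size=n_genes)
    magnitude = rng.uniform(fc_range[0], fc_range[1], size=n_true_de)
    direction = rng.random(n_true_de) < 0.5
    fold_change[true_de] = np.where(direction, magnitude, 1.0 / magnitude)

    mean_tpm = rng.lognormal(tpm_meanlog, tpm_sdlog, size=n_genes)
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "mean_tpm": mean_tpm,
            "fold_change": fold_change,
            "p": p,
            "fdr": np.nan,
            "true_de": true_de,
        }
    )


def generate_peak_table(
    n_peaks: int = 2000,
    n_true: int = 40,
    read_columns: Sequence[str] = ("reads_WT", "reads_KO"),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-peak ChIP statistics with known differentially-bound labels.

    Signed TSS distances span +-3 kb (negative = upstream); read counts are
    Poisson; true positives get >= 2-fold changes and small IDR.  Columns:
    ``peak_id, tss_distance``, one column per entry of ``read_columns``,
    ``fold_change, idr, true_diff``.
    """
    if n_true > n_peaks:
        raise ValueError("n_true must be <= n_peaks")
    rng = np.random.default_rng(seed)
    true_diff = np.zeros(n_peaks, dtype=bool)
    true_diff[rng.choice(n_peaks, size=n_true, replace=False)] = True
    table = pd.DataFrame({
        "peak_id": [f"peak{i:05d}" for i in range(n_peaks)],
        "tss_distance": rng.integers(-3000, 3001, size=n_peaks),
    })
    for col in read_columns:
        table[col] = rng.poisson(12.0, size=n_peaks)
    fold_change = 2.0 ** rng.normal(0.0, 0.2, size=n_peaks)
    magnitude = rng.uniform(2.0, 6.0, size=n_true)
    direction = rng.random(n_true) < 0.5
    fold_change[true_diff] = np.where(direction, magnitude, 1.0 / magnitude)
    idr = rng.uniform(0.0, 1.0, size=n_peaks)
    idr[true_diff] = rng.uniform(0.0, 0.04, size=n_true)
    table["fold_change"] = fold_change
    table["idr"] = idr
    table["true_diff"] = true_diff
    return table
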