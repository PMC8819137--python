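"""Synthetic cohorts, survival records, and H&E-like mini-slides.

Every downstream stage of the pipeline is testable without controlled-access
data: this module plants known ground truth and hands it back alongside the
generated artifact.

* Expression cohorts: Gaussian log-scale expression where a chosen subset of
  genes (always containing the markers CDH1, VIM, CDH2, FN1) separates an
  epithelial (Epi) from a mesenchymal (Mes) group by a configurable effect
  size, so signature selection and subtype clustering have a known answer.
* Survival: exponential event times with a mesenchymal hazard ratio and
  independent censoring, emulating the worse overall survival of Mes tumors.
* Mini-slides: grids of 256x256 tiles of four tissue classes (near-white
  background, necrosis, stroma, tumor) rendered through a Beer–Lambert
  stain model (concentrations x stain matrix -> optical density -> RGB), so
  Macenko stain estimation has an exact forward-model oracle.  Mesenchymal
  tumor tiles carry denser nuclei than epithelial ones — density is the
  morphological signal the tile classifier is meant to learn.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .signature import EPI, MES, ExpressionMatrix

__all__ = [
    "CohortSpec",
    "LabeledExpressionCohort",
    "SlideSpec",
    "SyntheticSlide",
    "DEFAULT_STAIN_MATRIX",
    "generate_expression_cohort",
    "generate_survival",
    "render_tile",
    "render_tile_with_meta",
    "generate_slide",
    "beer_lambert_render",
    "write_slide",
    "write_gmt",
]

TILE = 256
TISSUE_CLASSES = ("background", "necrosis", "stroma", "tumor")

# Column-unit H&E optical-density vectors (hematoxylin, eosin) used for
# rendering.  The eosin vector carries enough red/blue absorbance that
# tissue pixels clear a per-channel OD floor, which keeps both stain
# directions observable to downstream estimation.
DEFAULT_STAIN_MATRIX = np.array(
    [[0.650, 0.250],
     [0.704, 0.950],
     [0.286, 0.190]]
)
DEFAULT_STAIN_MATRIX /= np.linalg.norm(DEFAULT_STAIN_MATRIX, axis=0, keepdims=True)


def _rng(seed: int, *tags) -> np.random.Generator:
    """Counter-based stream split: a root seed plus hashed context tags."""
    words = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        words.append(zlib.crc32(str(t).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))


# ---------------------------------------------------------------------------
# expression cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-group synthetic expression cohort.

    ``effect_size`` is the Mes-minus-Epi group-mean shift of each planted
    signature gene, in units of ``noise_sd``.
    """

    n_samples: int = 200
    n_genes: int = 500
    n_signature_genes: int = 63
    mes_fraction: float = 0.5
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_signature_genes < 4:
            raise ValueError("n_signature_genes must be >= 4 (markers included)")
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes must be <= n_genes")
        if not 0.0 <= self.mes_fraction <= 1.0:
            raise ValueError("mes_fraction must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class LabeledExpressionCohort:
    expression: ExpressionMatrix
    true_labels: dict[str, str]              # sample id -> Epi | Mes
    planted_signature: dict[str, str]        # gene id -> epithelial-up | mesenchymal-up

    @property
    def labels_series(self) -> pd.Series:
        return pd.Series(self.true_labels, name="subtype")


MARKER_DIRECTIONS = {"CDH1": "epithelial-up", "VIM": "mesenchymal-up",
                     "CDH2": "mesenchymal-up", "FN1": "mesenchymal-up"}


def generate_expression_cohort(spec: CohortSpec) -> LabeledExpressionCohort:
    """Two-group Gaussian cohort with a planted EMT-associated gene subset.

    Mesenchymal-up genes shift by +effect_size * noise_sd in the Mes group
    relative to Epi (epithelial-up genes by the negative); the remaining
    genes are i.i.d. noise.  CDH1 is planted epithelial-up, VIM/CDH2/FN1
    mesenchymal-up.
    """
    markers = list(MARKER_DIRECTIONS)
    sig_genes = markers + [f"SIG{i:04d}" for i in range(spec.n_signature_genes - 4)]
    noise_genes = [f"GENE{i:04d}" for i in range(spec.n_genes - spec.n_signature_genes)]
    gene_ids = sig_genes + noise_genes

    planted = dict(MARKER_DIRECTIONS)
    for i, g in enumerate(sig_genes[4:]):
        planted[g] = "mesenchymal-up" if i % 2 == 0 else "epithelial-up"

    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    n_mes = int(round(spec.mes_fraction * spec.n_samples))
    labels_arr = np.array([MES] * n_mes + [EPI] * (spec.n_samples - n_mes))
    _rng(spec.seed, "labels").shuffle(labels_arr)
    is_mes = labels_arr == MES

    rng = _rng(spec.seed, "expression")
    baseline = rng.uniform(4.0, 12.0, size=(spec.n_genes, 1))
    values = baseline + rng.normal(0.0, spec.noise_sd,
                                   size=(spec.n_genes, spec.n_samples))
    half = 0.5 * spec.effect_size * spec.noise_sd
    for i, g in enumerate(sig_genes):
        sign = 1.0 if planted[g] == "mesenchymal-up" else -1.0
        values[i] += np.where(is_mes, sign * half, -sign * half)

    expr = ExpressionMatrix(values, gene_ids, sample_ids)
    true_labels = dict(zip(sample_ids, labels_arr))
    return LabeledExpressionCohort(expression=expr, true_labels=true_labels,
                                   planted_signature=planted)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def generate_survival(labels: dict[str, str], hazard_ratio: float,
                      baseline_median: float = 60.0, censor_rate: float = 0.3,
                      seed: int = 0) -> pd.DataFrame:
    """Exponential survival with Mes hazard = hazard_ratio x Epi hazard.

    Censoring is independent exponential, calibrated per group so the
    expected censored fraction equals ``censor_rate``.  Returns a table with
    columns sample, time, event, group.
    """
    if not labels:
        raise ValueError("labels must be nonempty")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if baseline_median <= 0:
        raise ValueError("baseline_median must be > 0")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")

    rng = _rng(seed, "survival")
    samples = list(labels)
    lam_epi = np.log(2.0) / baseline_median
    lam = np.array([lam_epi * (hazard_ratio if labels[s] == MES else 1.0)
                    for s in samples])
    event_t = rng.exponential(1.0 / lam)
    if censor_rate > 0:
        # exp censoring at rate lam_c gives P(censor) = lam_c / (lam + lam_c)
        lam_c = lam * censor_rate / (1.0 - censor_rate)
        censor_t = rng.exponential(1.0 / lam_c)
    else:
        censor_t = np.full(len(samples), np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return pd.DataFrame({"sample": samples, "time": time, "event": event,
                         "group": [labels[s] for s in samples]})


# ---------------------------------------------------------------------------
# tile / slide rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlideSpec:
    """Parameters of a rendered mini-slide.

    Nucleus densities are mean nuclei per tumor tile; the mesenchymal
    default exceeds the epithelial one (dense packing vs loose arrangement
    with large cell gaps).  The realistic per-slide tile-count range seen on
    real whole-slide images is 170–9500; grids outside it are permitted (for
    compact tests) with a warning.
    """

    subtype: str = MES
    grid_shape: tuple[int, int] = (14, 14)
    composition: dict = field(default_factory=lambda: {
        "background": 0.20, "necrosis": 0.10, "stroma": 0.15, "tumor": 0.55})
    nucleus_density_epi: float = 25.0
    nucleus_density_mes: float = 70.0
    nucleus_radius_range: tuple[float, float] = (4.0, 9.0)
    stain_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_STAIN_MATRIX.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subtype not in (EPI, MES):
            raise ValueError(f"subtype must be {EPI!r} or {MES!r}")
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValueError("grid_shape must be positive")
        comp = self.composition
        if set(comp) - set(TISSUE_CLASSES):
            raise ValueError(f"unknown tissue classes: {set(comp) - set(TISSUE_CLASSES)}")
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"composition must sum to 1, got {total}")
        if any(v < 0 for v in comp.values()):
            raise ValueError("composition proportions must be nonnegative")
        if self.nucleus_density_epi <= 0 or self.nucleus_density_mes <= 0:
            raise ValueError("nucleus densities must be > 0")
        lo, hi = self.nucleus_radius_range
        if not 0 < lo <= hi:
            raise ValueError("nucleus_radius_range must satisfy 0 < lo <= hi")
        s = np.asarray(self.stain_matrix, dtype=float)
        if s.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        n_tiles = rows * cols
        if not 170 <= n_tiles <= 9500:
            warnings.warn(
                f"{n_tiles} tiles is outside the realistic per-slide range "
                "[170, 9500]", stacklevel=2)


@dataclass
class SyntheticSlide:
    image: np.ndarray                       # H x W x 3 uint8
    tile_truth: dict[tuple[int, int], str]  # (row, col) -> tissue class
    subtype: str
    slide_id: str = "slide"


def beer_lambert_render(c_h: np.ndarray, c_e: np.ndarray,
                        stain_matrix: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Render stain concentration fields to 8-bit RGB.

    OD = stains x concentrations per pixel; intensity I = I0 * 10^-OD - 1,
    the exact inverse of OD = -log10((I + 1) / I0).
    """
    conc = np.stack([c_h, c_e], axis=-1)
    od = conc @ np.asarray(stain_matrix, dtype=float).T
    img = i0 * np.power(10.0, -od) - 1.0
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _smooth_noise(rng, shape, sigma, upscale: int = 4):
    # filtered at 1/upscale resolution, then block-upsampled: 16x cheaper and
    # visually equivalent for the blotchy fields it drives
    small = (shape[0] // upscale, shape[1] // upscale)
    x = gaussian_filter(rng.standard_normal(small), sigma / upscale)
    sd = x.std()
    if sd > 0:
        x /= sd
    return np.repeat(np.repeat(x, upscale, axis=0), upscale, axis=1)


def render_tile_with_meta(tissue_class: str, subtype: str | None,
                          spec: SlideSpec, cell_seed: int):
    """Render one 256x256 tile; returns (rgb, meta) with planted ground truth."""
    if tissue_class not in TISSUE_CLASSES:
        raise ValueError(f"unknown tissue class {tissue_class!r}")
    if tissue_class == "tumor" and subtype not in (EPI, MES):
        raise ValueError("tumor tiles require subtype Epi or Mes")
    rng = _rng(spec.seed, "tile", tissue_class, subtype, cell_seed)
    meta = {"class": tissue_class, "subtype": subtype, "nucleus_count": 0}

    if tissue_class == "background":
        # near-white glass: every channel >= 240 by construction
        img = 248 + rng.integers(-3, 4, size=(TILE, TILE, 3))
        return np.clip(img, 244, 252).astype(np.uint8), meta

    if tissue_class == "necrosis":
        # dull, mottled eosinophilic debris: both stains, low contrast
        c_h = np.clip(0.28 + 0.08 * _smooth_noise(rng, (TILE, TILE), 6), 0.12, None)
        c_e = np.clip(0.45 + 0.12 * _smooth_noise(rng, (TILE, TILE), 6), 0.2, None)
    elif tissue_class == "stroma":
        # wavy eosin-rich collagen fibres, scant hematoxylin
        yy, xx = np.mgrid[0:TILE, 0:TILE].astype(float)
        theta = rng.uniform(0, np.pi)
        wavelength = rng.uniform(18, 34)
        phase = rng.uniform(0, 2 * np.pi)
        fibres = np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta))
                        / wavelength + phase)
        c_e = np.clip(0.95 + 0.35 * fibres
                      + 0.10 * _smooth_noise(rng, (TILE, TILE), 3), 0.35, None)
        c_h = np.clip(0.16 + 0.04 * _smooth_noise(rng, (TILE, TILE), 4), 0.08, None)
    else:  # tumor
        density = (spec.nucleus_density_mes if subtype == MES
                   else spec.nucleus_density_epi)
        c_e = np.clip(0.95 + 0.20 * _smooth_noise(rng, (TILE, TILE), 8), 0.4, None)
        c_h = np.clip(0.06 + 0.02 * _smooth_noise(rng, (TILE, TILE), 8), 0.03, None)
        n_nuclei = int(rng.poisson(density))
        meta["nucleus_count"] = n_nuclei
        lo, hi = spec.nucleus_radius_range
        for _ in range(n_nuclei):
            cy, cx = rng.uniform(0, TILE, size=2)
            a, b = rng.uniform(lo, hi, size=2)
            angle = rng.uniform(0, np.pi)
            r = int(np.ceil(max(a, b))) + 1
            y0, y1 = int(max(0, cy - r)), int(min(TILE, cy + r + 1))
            x0, x1 = int(max(0, cx - r)), int(min(TILE, cx + r + 1))
            if y0 >= y1 or x0 >= x1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
            dy, dx = yy - cy, xx - cx
            ca, sa = np.cos(angle), np.sin(angle)
            u = (dx * ca + dy * sa) / a
            v = (-dx * sa + dy * ca) / b
            mask = u**2 + v**2 <= 1.0
            c_h[y0:y1, x0:x1][mask] = rng.uniform(0.85, 1.15)
            c_e[y0:y1, x0:x1][mask] *= 0.03

    return beer_lambert_render(c_h, c_e, spec.stain_matrix), meta


def render_tile(tissue_class: str, subtype: str | None, spec: SlideSpec,
                cell_seed: int) -> np.ndarray:
    img, _ = render_tile_with_meta(tissue_class, subtype, spec, cell_seed)
    return img


def generate_slide(spec: SlideSpec, slide_id: str = "slide") -> SyntheticSlide:
    """Assemble a mini-slide from per-cell tissue classes drawn i.i.d. from
    the composition; ground-truth class per grid cell is recorded."""
    rows, cols = spec.grid_shape
    active = [c for c in TISSUE_CLASSES if spec.composition.get(c, 0.0) > 0]
    if rows * cols < len(active):
        raise ValueError(
            f"grid of {rows * cols} cells cannot honor a composition with "
            f"{len(active)} tissue classes")
    probs = np.array([spec.composition.get(c, 0.0) for c in TISSUE_CLASSES])
    rng = _rng(spec.seed, "slide", slide_id)
    draws = rng.choice(len(TISSUE_CLASSES), size=rows * cols, p=probs)

    image = np.empty((rows * TILE, cols * TILE, 3), dtype=np.uint8)
    tile_truth = {}
    for idx, cls_idx in enumerate(draws):
        r, c = divmod(idx, cols)
        cls = TISSUE_CLASSES[cls_idx]
        tile_truth[(r, c)] = cls
        subtype = spec.subtype if cls == "tumor" else None
        cell_seed = int(rng.integers(0, 2**31 - 1))
        image[r * TILE:(r + 1) * TILE, c * TILE:(c + 1) * TILE] = render_tile(
            cls, subtype, spec, cell_seed)
    return SyntheticSlide(image=image, tile_truth=tile_truth,
                          subtype=spec.subtype, slide_id=slide_id)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_slide(slide: SyntheticSlide, out_dir, fmt: str = "png") -> pd.DataFrame:
    """Write per-tile PNGs (or one TIFF) plus a manifest CSV; returns the
    manifest (slide_id, row, col, x, y, truth_class, subtype)."""
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for (r, c), cls in sorted(slide.tile_truth.items()):
        rows.append({"slide_id": slide.slide_id, "row": r, "col": c,
                     "x": c * TILE, "y": r * TILE, "truth_class": cls,
                     "subtype": slide.subtype if cls == "tumor" else ""})
    manifest = pd.DataFrame(rows)
    if fmt == "png":
        for rec in rows:
            r, c = rec["row"], rec["col"]
            tile = slide.image[r * TILE:(r + 1) * TILE, c * TILE:(c + 1) * TILE]
            iio.imwrite(out / f"{slide.slide_id}_r{r:03d}_c{c:03d}.png", tile)
    elif fmt == "tiff":
        import tifffile

        tifffile.imwrite(out / f"{slide.slide_id}.tiff", slide.image, tile=(TILE, TILE))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    manifest.to_csv(out / f"{slide.slide_id}_manifest.csv", index=False)
    return manifest


def write_gmt(gene_sets: dict[str, list[str]], path,
              description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets
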