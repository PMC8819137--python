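"""Tiling, background filtering, and Macenko stain normalization.

Histology images are cut into non-overlapping 256x256 windows; windows that
are mostly blank glass are dropped; the colors of the rest are standardized
by estimating each slide's hematoxylin/eosin stain matrix from pixel optical
densities (Macenko's eigenvector/robust-angle construction) and re-rendering
tile concentrations through a reference stain matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Tile",
    "BackgroundFilterConfig",
    "StainProfile",
    "tile_image",
    "background_fraction",
    "filter_tiles",
    "estimate_stain_profile",
    "normalize_tile",
    "default_reference_profile",
]

TILE_SIZE = 256


@dataclass
class Tile:
    """One 256x256 RGB window.

    ``origin`` is (x, y) in pixels, 0-based from the top-left corner of the
    source image: x is the column of the left edge, y the row of the top
    edge; both are multiples of the tile size.  ``grid`` is (row, col).
    """

    pixels: np.ndarray
    slide_id: str
    origin: tuple[int, int]
    grid: tuple[int, int]

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("tile pixels must be HxWx3")
        if self.pixels.dtype != np.uint8:
            raise ValueError("tile pixels must be 8-bit")


@dataclass(frozen=True)
class BackgroundFilterConfig:
    """Background rule: a pixel is background when ALL three channels are at
    or above ``intensity_threshold`` (near-white glass).  Tiles whose
    background fraction exceeds ``max_background_fraction`` are dropped; a
    fraction of exactly 0.5 is kept.  ``background_is_bright=False`` flips
    the inequality for non-standard imagery.
    """

    intensity_threshold: int = 220
    max_background_fraction: float = 0.5
    background_is_bright: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.intensity_threshold < 255:
            raise ValueError("intensity_threshold must be in (0, 255)")
        if not 0 < self.max_background_fraction <= 1:
            raise ValueError("max_background_fraction must be in (0, 1]")


@dataclass
class StainProfile:
    """Macenko stain parameters for one slide.

    ``stain_matrix`` has unit-norm OD columns (hematoxylin, eosin);
    ``max_concentrations`` holds the per-stain 99th-percentile concentration
    used to match dynamic range between slides.
    """

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray
    i0: float = 255.0
    od_threshold: float = 0.15
    angle_percentile: float = 1.0

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain_matrix columns must be unit norm")
        if (self.max_concentrations <= 0).any():
            raise ValueError("max_concentrations must be > 0")

    def to_json(self, path) -> None:
        payload = {"stain_matrix": self.stain_matrix.tolist(),
                   "max_concentrations": self.max_concentrations.tolist(),
                   "i0": self.i0, "od_threshold": self.od_threshold,
                   "angle_percentile": self.angle_percentile}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "StainProfile":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["stain_matrix"]), np.array(d["max_concentrations"]),
                   i0=d.get("i0", 255.0), od_threshold=d.get("od_threshold", 0.15),
                   angle_percentile=d.get("angle_percentile", 1.0))


def default_reference_profile() -> StainProfile:
    """Reference H&E stain space shipped with the package."""
    with resources.files("emtpath").joinpath(
            "data/reference_stain_profile.json").open() as fh:
        d = json.load(fh)
    return StainProfile(np.array(d["stain_matrix"]),
                        np.array(d["max_concentrations"]),
                        i0=d.get("i0", 255.0), od_threshold=d.get("od_threshold", 0.15),
                        angle_percentile=d.get("angle_percentile", 1.0))


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def tile_image(image: np.ndarray, tile_size: int = TILE_SIZE,
               slide_id: str = "slide") -> list[Tile]:
    """Cut an RGB image into non-overlapping tiles, row-major order.

    Partial windows at the right/bottom edges are dropped.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be HxWx3 RGB")
    h, w = image.shape[:2]
    if h < tile_size or w < tile_size:
        raise ValueError(f"image {w}x{h} smaller than one {tile_size}px tile")
    if image.dtype != np.uint8:
        image = np.clip(image, 0, 255).astype(np.uint8)
    tiles = []
    for r in range(h // tile_size):
        for c in range(w // tile_size):
            y, x = r * tile_size, c * tile_size
            tiles.append(Tile(pixels=image[y:y + tile_size, x:x + tile_size],
                              slide_id=slide_id, origin=(x, y), grid=(r, c)))
    return tiles


def background_fraction(tile, config: BackgroundFilterConfig | None = None) -> float:
    """Fraction of near-white background pixels in a tile."""
    config = config or BackgroundFilterConfig()
    pixels = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    if config.background_is_bright:
        bg = (pixels >= config.intensity_threshold).all(axis=-1)
    else:
        bg = (pixels < config.intensity_threshold).all(axis=-1)
    return float(bg.mean())


def filter_tiles(tiles, config: BackgroundFilterConfig | None = None):
    """Split tiles into (kept, manifest); a tile is kept iff its background
    fraction is at most the configured maximum (exactly 0.5 is kept)."""
    config = config or BackgroundFilterConfig()
    kept, rows = [], []
    for t in tiles:
        frac = background_fraction(t, config)
        keep = frac <= config.max_background_fraction
        if keep:
            kept.append(t)
        rows.append({"slide_id": t.slide_id, "row": t.grid[0], "col": t.grid[1],
                     "x": t.origin[0], "y": t.origin[1],
                     "background_fraction": frac, "kept": keep})
    return kept, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Macenko stain estimation / normalization
# ---------------------------------------------------------------------------

def _to_od(pixels: np.ndarray, i0: float) -> np.ndarray:
    return -np.log10((pixels.reshape(-1, 3).astype(float) + 1.0) / i0)


def _nnls_2stain(stain_matrix: np.ndarray, od: np.ndarray) -> np.ndarray:
    """Vectorized nonnegative least squares for the 2-stain case.

    Solves min ||S c - od|| with c >= 0 per pixel: take the unconstrained
    solution; when a coefficient goes negative, clamp it to zero and project
    onto the remaining stain (clipped at zero).
    """
    s = stain_matrix
    gram = s.T @ s
    rhs = od @ s
    c = rhs @ np.linalg.inv(gram).T
    s_sq = (s**2).sum(axis=0)
    for j, other in ((0, 1), (1, 0)):
        neg = c[:, j] < 0
        if neg.any():
            c[neg, j] = 0.0
            c[neg, other] = np.maximum(0.0, rhs[neg, other] / s_sq[other])
    return c


def estimate_stain_profile(pixels, i0: float = 255.0, od_threshold: float = 0.15,
                           angle_percentile: float = 1.0,
                           min_tissue_pixels: int = 1000) -> StainProfile:
    """Macenko stain-matrix estimation from an RGB pixel pool.

    Pixels are mapped to optical density OD = -log10((I+1)/I0); pixels with
    any channel below ``od_threshold`` are discarded as non-tissue.  The
    surviving OD cloud is projected onto its top-2 covariance eigenvectors;
    the robust extreme directions at the (alpha, 100-alpha) angle
    percentiles, back-projected and normalized, are the stain vectors.  The
    column with the larger blue-channel OD component is labeled hematoxylin.
    Per-stain 99th-percentile concentrations (nonnegative least squares)
    complete the profile.
    """
    pixels = np.asarray(pixels)
    od = _to_od(pixels, i0)
    tissue = od[(od >= od_threshold).all(axis=1)]
    if tissue.shape[0] < min_tissue_pixels:
        raise ValueError(
            f"insufficient tissue: {tissue.shape[0]} pixels above the OD "
            f"threshold (need >= {min_tissue_pixels})")

    cov = np.cov(tissue, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[-2] <= 1e-10 * max(eigval[-1], 1e-30):
        raise ValueError("degenerate stain geometry: OD cloud is effectively 1-D")
    basis = eigvec[:, [-1, -2]]  # 3x2, descending eigenvalue order
    proj = tissue @ basis
    # orient the plane so the bulk projects positively on the first axis
    if proj[:, 0].mean() < 0:
        basis[:, 0] *= -1
        proj[:, 0] *= -1
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(angles, angle_percentile)
    hi = np.percentile(angles, 100.0 - angle_percentile)
    vecs = []
    for phi in (lo, hi):
        v = basis @ np.array([np.cos(phi), np.sin(phi)])
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        vecs.append(v / np.linalg.norm(v))
    v1, v2 = vecs
    # hematoxylin absorbs more in the blue channel
    if v1[2] >= v2[2]:
        stain_matrix = np.column_stack([v1, v2])
    else:
        stain_matrix = np.column_stack([v2, v1])

    conc = _nnls_2stain(stain_matrix, tissue)
    max_conc = np.percentile(conc, 99, axis=0)
    max_conc = np.maximum(max_conc, 1e-6)
    return StainProfile(stain_matrix=stain_matrix, max_concentrations=max_conc,
                        i0=i0, od_threshold=od_threshold,
                        angle_percentile=angle_percentile)


def pool_tile_pixels(tiles, max_tiles: int = 50, pixels_per_tile: int = 2000,
                     seed: int = 0) -> np.ndarray:
    """Pool a random pixel sample from up to ``max_tiles`` tiles, for a
    per-slide stain estimate."""
    rng = np.random.default_rng(seed)
    if len(tiles) > max_tiles:
        idx = rng.choice(len(tiles), size=max_tiles, replace=False)
        tiles = [tiles[i] for i in idx]
    pools = []
    for t in tiles:
        px = (t.pixels if isinstance(t, Tile) else np.asarray(t)).reshape(-1, 3)
        take = rng.choice(px.shape[0], size=min(pixels_per_tile, px.shape[0]),
                          replace=False)
        pools.append(px[take])
    return np.concatenate(pools, axis=0)


def normalize_tile(tile, source: StainProfile, reference: StainProfile):
    """Re-render a tile in the reference stain space.

    Concentrations under the source profile are scaled per stain by
    reference.max / source.max and reconstructed through the reference stain
    matrix; output is clipped to 0..255.  Background pixels carry near-zero
    concentrations and stay near white.
    """
    if (source.max_concentrations <= 1e-6).any():
        raise ValueError("source profile has a zero maximum concentration")
    pixels = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    shape = pixels.shape
    od = _to_od(pixels, source.i0)
    conc = _nnls_2stain(source.stain_matrix, od)
    conc *= reference.max_concentrations / source.max_concentrations
    od_new = conc @ reference.stain_matrix.T
    out = reference.i0 * np.power(10.0, -od_new) - 1.0
    out = np.clip(np.round(out), 0, 255).astype(np.uint8).reshape(shape)
    if isinstance(tile, Tile):
        return Tile(pixels=out, slide_id=tile.slide_id, origin=tile.origin,
                    grid=tile.grid)
    return out


def stain_vector_angles_deg(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Angular error (degrees) between matched columns of two stain matrices."""
    est = estimated / np.linalg.norm(estimated, axis=0, keepdims=True)
    tru = truth / np.linalg.norm(truth, axis=0, keepdims=True)
    cosines = np.clip(np.abs((est * tru).sum(axis=0)), -1.0, 1.0)
    return np.degrees(np.arccos(cosines))
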