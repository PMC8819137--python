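"""Slide-level aggregation, prediction heatmaps, and class activation maps.

A slide's call is the plain mean of its tumor tiles' mesenchymal
probabilities (the "AI score"): above 0.5 the slide is called Mes, below
0.5 Epi; exactly 0.5 is called Mes and flagged as a boundary case.  Tile
scores are also laid back onto the tiling grid as a heatmap, and class
activation maps localize the morphology each class responds to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize

from .classify import TileClassifier
from .signature import EPI, MES

__all__ = [
    "SlidePrediction",
    "Heatmap",
    "CAMap",
    "aggregate_slide",
    "render_heatmap",
    "compute_cam",
]


@dataclass
class SlidePrediction:
    slide_id: str
    tiles: pd.DataFrame          # row, col, x, y, p_mes
    ai_score: float
    call: str
    boundary: bool = False

    def summary_row(self) -> dict:
        return {"slide_id": self.slide_id, "n_tumor_tiles": len(self.tiles),
                "ai_score": self.ai_score, "call": self.call,
                "boundary": self.boundary}


@dataclass
class Heatmap:
    grid: np.ndarray             # rows x cols of scores
    mask: np.ndarray             # True where no tile score exists
    cmap: str = "coolwarm"


@dataclass
class CAMap:
    tile_id: str
    target_class: str
    raw: np.ndarray              # 256 x 256, unnormalized evidence (upsampled)
    display: np.ndarray          # min-max scaled to [0, 1]
    raw_small: np.ndarray = None  # feature-map-resolution CAM, pre-upsampling


def aggregate_slide(tile_probs, slide_id: str = "slide",
                    coords=None) -> SlidePrediction:
    """Mean tumor-tile Mes probability -> slide AI score and Epi/Mes call.

    ``tile_probs`` is a sequence of per-tile mesenchymal probabilities;
    ``coords`` optionally carries aligned (row, col) grid positions.
    """
    probs = np.asarray(list(tile_probs), dtype=float)
    if probs.size == 0:
        raise ValueError(f"no tumor detected on slide {slide_id!r}")
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("tile probabilities must lie in [0, 1]")
    if coords is None:
        coords = [(0, i) for i in range(probs.size)]
    coords = list(coords)
    if len(coords) != probs.size:
        raise ValueError("coords must align with tile_probs")
    tiles = pd.DataFrame({
        "row": [rc[0] for rc in coords],
        "col": [rc[1] for rc in coords],
        "x": [rc[1] * 256 for rc in coords],
        "y": [rc[0] * 256 for rc in coords],
        "p_mes": probs,
    })
    ai_score = float(probs.mean())
    boundary = ai_score == 0.5
    call = MES if ai_score >= 0.5 else EPI
    return SlidePrediction(slide_id=slide_id, tiles=tiles, ai_score=ai_score,
                           call=call, boundary=boundary)


def render_heatmap(prediction: SlidePrediction, grid_shape: tuple[int, int],
                   path=None, cmap: str = "coolwarm") -> Heatmap:
    """Lay tile scores back onto the tiling grid; cells without a score
    (dropped, stroma, necrosis) are masked.  Optionally renders a PNG."""
    rows, cols = grid_shape
    grid = np.full((rows, cols), np.nan)
    for rec in prediction.tiles.itertuples():
        r, c = int(rec.row), int(rec.col)
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"tile at grid ({r}, {c}) outside {grid_shape}")
        if not np.isnan(grid[r, c]):
            raise ValueError(f"coordinate collision at grid ({r}, {c})")
        grid[r, c] = rec.p_mes
    mask = np.isnan(grid)
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(3, cols / 3), max(3, rows / 3)))
        im = ax.imshow(np.ma.masked_array(grid, mask), cmap=cmap, vmin=0, vmax=1)
        fig.colorbar(im, ax=ax, label="P(Mes)")
        ax.set_title(f"{prediction.slide_id}  AI score {prediction.ai_score:.2f} "
                     f"({prediction.call})")
        ax.set_xlabel("tile column")
        ax.set_ylabel("tile row")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return Heatmap(grid=grid, mask=mask, cmap=cmap)


def compute_cam(classifier: TileClassifier, tile: np.ndarray, target_class,
                tile_id: str = "tile") -> CAMap:
    """Class activation map of one tile for one class.

    CAM_c(u, v) = sum_k w_k^c f_k(u, v) over the backbone's final conv
    feature maps, using the softmax-head weights — valid because the head is
    linear over globally average-pooled features.  The raw map is bilinearly
    upsampled to the tile size; a min-max scaled copy is provided for
    display.
    """
    if not hasattr(classifier.backbone, "feature_maps"):
        raise ValueError("classifier backbone does not expose conv feature maps; "
                         "CAM requires a GAP-headed architecture")
    maps = classifier.backbone.feature_maps(np.asarray(tile)[None])[0]  # h, w, K
    j = classifier.class_index(target_class)
    cam_small = maps @ classifier.weights[:, j]
    side = tile.shape[0]
    raw = resize(cam_small, (side, side), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    lo, hi = float(raw.min()), float(raw.max())
    display = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
    return CAMap(tile_id=tile_id, target_class=str(target_class), raw=raw,
                 display=display, raw_small=cam_small)
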