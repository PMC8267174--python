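"""Malignant-probability heatmaps: assembly from patch predictions,
dark-blue-to-crimson rendering, and overlay on the slide."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

DARK_BLUE = np.array([0.0, 0.0, 139.0])
CRIMSON = np.array([220.0, 20.0, 60.0])


@dataclass
class ProbabilityHeatmap:
    """Per-patch (p_normal, p_tumor) grid over one slide.

    grid has shape (rows, cols, 2); background flags mark near-white cells
    that carry no tissue signal.
    """

    slide_id: str
    grid: np.ndarray
    patch_size: int
    stride: int
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3 or self.grid.shape[2] != 2:
            raise ValueError("grid must be rows x cols x 2")
        if self.background is None:
            self.background = np.zeros(self.grid.shape[:2], dtype=bool)
        self.background = np.asarray(self.background, dtype=bool)
        if self.background.shape != self.grid.shape[:2]:
            raise ValueError("background flags must match grid shape")
        if not np.allclose(self.grid.sum(axis=2), 1.0, atol=1e-6):
            raise ValueError("cell probabilities must sum to 1")

    @property
    def p_tumor(self) -> np.ndarray:
        return self.grid[:, :, 1]


def grid_shape(slide_shape: tuple[int, int], patch_size: int,
               stride: int) -> tuple[int, int]:
    """(rows, cols) of the non-overlapping-coverage tiling grid."""
    h, w = slide_shape
    if h < patch_size or w < patch_size:
        raise ValueError("slide smaller than one patch")
    return ((h - patch_size) // stride + 1, (w - patch_size) // stride + 1)


def assemble_heatmap(predictions, slide_shape: tuple[int, int],
                     patch_size: int, stride: int,
                     background_flags: dict[tuple[int, int], bool] | None = None,
                     slide_id: str | None = None) -> ProbabilityHeatmap:
    """Place patch predictions on the slide grid.

    Cell (r, c) holds the prediction for the patch at pixel
    (c*stride, r*stride). Every grid cell must be covered exactly once;
    missing or duplicate cells are reported with their coordinates.
    """
    rows, cols = grid_shape(slide_shape, patch_size, stride)
    grid = np.full((rows, cols, 2), np.nan)
    seen = np.zeros((rows, cols), dtype=int)
    for p in predictions:
        if p.x % stride or p.y % stride:
            raise ValueError(f"prediction at ({p.x},{p.y}) off the stride grid")
        c, r = p.x // stride, p.y // stride
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"prediction at ({p.x},{p.y}) outside the grid")
        seen[r, c] += 1
        grid[r, c] = (p.p_normal, p.p_tumor)
        if slide_id is None:
            slide_id = p.slide_id
    dup = [(int(r), int(c)) for r, c in zip(*np.nonzero(seen > 1))]
    missing = [(int(r), int(c)) for r, c in zip(*np.nonzero(seen == 0))]
    if dup or missing:
        raise ValueError(f"grid coverage error: duplicates at {dup}, "
                         f"missing at {missing}")
    background = np.zeros((rows, cols), dtype=bool)
    if background_flags:
        for (x, y), flag in background_flags.items():
            background[y // stride, x // stride] = flag
    return ProbabilityHeatmap(slide_id=slide_id or "slide", grid=grid,
                              patch_size=patch_size, stride=stride,
                              background=background)


def probability_ramp(p: np.ndarray) -> np.ndarray:
    """Map probabilities in [0,1] to the dark-blue -> crimson ramp, linear
    per channel, rounded to uint8."""
    p = np.asarray(p, dtype=float)
    rgb = DARK_BLUE + p[..., None] * (CRIMSON - DARK_BLUE)
    return np.rint(rgb).astype(np.uint8)


def colorize(heatmap: ProbabilityHeatmap, block: int | None = None) -> np.ndarray:
    """Render p_tumor on the dark-blue (0,0,139) to crimson (220,20,60)
    ramp, linear per channel; each cell becomes a patch_size block.
    Background cells render at p_tumor = 0."""
    p = np.where(heatmap.background, 0.0, heatmap.p_tumor)
    rgb = probability_ramp(p)
    block = block or heatmap.patch_size
    return rgb.repeat(block, axis=0).repeat(block, axis=1)


def overlay(slide_image: np.ndarray, colorized: np.ndarray,
            alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend the rendered heatmap onto the slide:
    out = (1 - alpha) * slide + alpha * heatmap."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if slide_image.shape != colorized.shape:
        raise ValueError(f"size mismatch: slide {slide_image.shape} vs "
                         f"heatmap {colorized.shape}")
    out = (1.0 - alpha) * slide_image.astype(float) + alpha * colorized.astype(float)
    return np.rint(out).astype(np.uint8)


def save_heatmap(heatmap: ProbabilityHeatmap, path: str | Path) -> None:
    """Two-plane float TIFF plus a JSON sidecar with the geometry."""
    path = Path(path)
    tifffile.imwrite(path.with_suffix(".tif"),
                     heatmap.grid.transpose(2, 0, 1).astype(np.float32),
                     photometric="minisblack")
    path.with_suffix(".json").write_text(json.dumps({
        "slide_id": heatmap.slide_id,
        "patch_size": heatmap.patch_size,
        "stride": heatmap.stride,
        "rows": heatmap.grid.shape[0],
        "cols": heatmap.grid.shape[1],
    }))


def load_heatmap(path: str | Path) -> ProbabilityHeatmap:
    path = Path(path)
    planes = tifffile.imread(path.with_suffix(".tif"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return ProbabilityHeatmap(slide_id=meta["slide_id"],
                              grid=planes.transpose(1, 2, 0).astype(float),
                              patch_size=meta["patch_size"],
                              stride=meta["stride"])


def save_overlay_png(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(image).save(str(path))
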