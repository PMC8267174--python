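"""Synthetic annotated pseudo-whole-slide images.

Real gigapixel H&E slides are not shippable, so this module emulates the
two tissue appearances the pipeline has to tell apart: tumor regions are
dense fields of dark, irregular "nuclei" blobs on a darker background,
normal tissue is sparse pale texture. Tumor regions are random simple
polygons (perturbed star-shaped hulls), which stand in for a pathologist's
free-hand lesion annotations, and double as the segmentation ground truth.

All randomness flows from a single integer seed through one
``numpy.random.Generator``, so a (parameters, seed) pair reproduces a slide
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from shapely.geometry import Polygon
from skimage.draw import disk

NORMAL, CANCEROUS = "normal", "cancerous"


@dataclass(frozen=True)
class TextureParams:
    """Appearance of one tissue class.

    nucleus_density is the expected blob count per 10^4 px^2;
    nucleus_radius_range is a (lo, hi) pixel interval; colors are RGB in
    [0, 255]; jitter_sd is the per-channel Gaussian intensity noise SD.
    """

    nucleus_density: float
    nucleus_radius_range: tuple[float, float]
    nucleus_color: tuple[int, int, int]
    background_color: tuple[int, int, int]
    jitter_sd: float = 6.0

    def __post_init__(self) -> None:
        lo, hi = self.nucleus_radius_range
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be >= 0")
        if not (0 < lo <= hi):
            raise ValueError("nucleus_radius_range must be a positive, nonempty interval")
        for color in (self.nucleus_color, self.background_color):
            if len(color) != 3 or any(c < 0 or c > 255 for c in color):
                raise ValueError(f"colors must be RGB triples in [0,255], got {color}")


#: Dense dark irregular blobs on a mauve background — the "carcinoma" look.
TUMOR_TEXTURE = TextureParams(
    nucleus_density=25.0,
    nucleus_radius_range=(3.0, 7.0),
    nucleus_color=(70, 40, 110),
    background_color=(205, 170, 205),
    jitter_sd=8.0,
)

#: Sparse pale blobs on a light pink background — the "normal tissue" look.
NORMAL_TEXTURE = TextureParams(
    nucleus_density=6.0,
    nucleus_radius_range=(2.0, 5.0),
    nucleus_color=(180, 120, 160),
    background_color=(236, 214, 226),
    jitter_sd=6.0,
)


@dataclass
class SyntheticSlide:
    """An RGB pseudo-slide plus its tumor polygon annotations.

    slide_label is CANCEROUS iff tumor_polygons is nonempty. Polygons are
    (k, 2) float arrays of (x, y) vertices, 0-based, y-down, open rings.
    """

    slide_id: str
    image: np.ndarray
    tumor_polygons: list[np.ndarray] = field(default_factory=list)
    seed: int = 0

    @property
    def slide_label(self) -> str:
        return CANCEROUS if self.tumor_polygons else NORMAL

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width)."""
        return self.image.shape[:2]


def _random_polygon(rng: np.random.Generator, width: int, height: int,
                    radius_frac: tuple[float, float] = (0.15, 0.25),
                    n_vertices: int = 14) -> np.ndarray:
    """A star-shaped simple polygon: sorted angles, radii perturbed around a
    base radius, clipped to the canvas."""
    base = rng.uniform(*radius_frac) * min(width, height)
    cx = rng.uniform(base * 0.6, width - base * 0.6)
    cy = rng.uniform(base * 0.6, height - base * 0.6)
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = base * rng.uniform(0.65, 1.3, n_vertices)
    xs = np.clip(cx + radii * np.cos(angles), 0, width - 1)
    ys = np.clip(cy + radii * np.sin(angles), 0, height - 1)
    return np.column_stack([xs, ys])


def _polygon_mask(polygons: list[np.ndarray], x0: int, y0: int,
                  w: int, h: int) -> np.ndarray:
    """Binary mask over window [x0, x0+w) x [y0, y0+h): pixel = 1 iff the
    pixel center lies strictly inside any polygon."""
    mask = np.zeros((h, w), dtype=np.uint8)
    for poly in polygons:
        shp = Polygon(poly)
        minx, miny, maxx, maxy = shp.bounds
        c_lo = max(int(np.floor(minx - x0 - 0.5)), 0)
        c_hi = min(int(np.ceil(maxx - x0 + 0.5)), w)
        r_lo = max(int(np.floor(miny - y0 - 0.5)), 0)
        r_hi = min(int(np.ceil(maxy - y0 + 0.5)), h)
        if c_lo >= c_hi or r_lo >= r_hi:
            continue
        cols = np.arange(c_lo, c_hi)
        rows = np.arange(r_lo, r_hi)
        cc, rr = np.meshgrid(cols, rows)
        shapely.prepare(shp)
        inside = shapely.contains_xy(shp, x0 + cc + 0.5, y0 + rr + 0.5)
        mask[r_lo:r_hi, c_lo:c_hi] |= inside.astype(np.uint8)
    return mask


def rasterize_mask(slide_or_polygons, window: tuple[int, int, int, int]) -> np.ndarray:
    """Rasterize tumor polygons over a rectangular window.

    window is (x, y, width, height) in slide pixel coordinates. A mask pixel
    is 1 iff its center (x+0.5, y+0.5 convention) falls inside any tumor
    polygon. Raises ValueError if the window leaves the slide bounds (when a
    slide with bounds is supplied).
    """
    x0, y0, w, h = window
    if w <= 0 or h <= 0:
        raise ValueError("window must have positive extent")
    if isinstance(slide_or_polygons, SyntheticSlide):
        sh, sw = slide_or_polygons.shape
        if x0 < 0 or y0 < 0 or x0 + w > sw or y0 + h > sh:
            raise ValueError(f"window {window} outside slide bounds {sw}x{sh}")
        polygons = slide_or_polygons.tumor_polygons
    else:
        polygons = list(slide_or_polygons)
    return _polygon_mask(polygons, x0, y0, w, h)


def _draw_texture(canvas: np.ndarray, params: TextureParams,
                  region_mask: np.ndarray | None,
                  rng: np.random.Generator) -> None:
    """Fill (part of) the canvas with one texture class, in place.

    region_mask restricts both the background fill and the blob pixels;
    None means the whole canvas.
    """
    h, w, _ = canvas.shape
    if region_mask is None:
        area = h * w
        canvas[:] = params.background_color
    else:
        area = int(region_mask.sum())
        canvas[region_mask.astype(bool)] = params.background_color
    n_blobs = rng.poisson(params.nucleus_density * area / 1e4)
    lo, hi = params.nucleus_radius_range
    color = np.array(params.nucleus_color, dtype=np.uint8)
    for _ in range(n_blobs):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        r = rng.uniform(lo, hi)
        rr, cc = disk((cy, cx), r, shape=(h, w))
        if region_mask is not None:
            keep = region_mask[rr, cc].astype(bool)
            rr, cc = rr[keep], cc[keep]
        canvas[rr, cc] = color


def generate_slide(width: int, height: int, n_tumor_regions: int,
                   tumor_params: TextureParams = TUMOR_TEXTURE,
                   normal_params: TextureParams = NORMAL_TEXTURE,
                   seed: int = 0, slide_id: str | None = None,
                   min_size: int = 256,
                   region_radius_frac: tuple[float, float] = (0.15, 0.25),
                   ) -> SyntheticSlide:
    """Generate one annotated pseudo-slide.

    The canvas is filled with normal texture; each of n_tumor_regions random
    simple polygons is then refilled with tumor texture (blobs clipped to
    the polygon), so the polygons exactly delimit the tumor-textured area.
    Deterministic given (arguments, seed).

    min_size guards against slides smaller than one patch.
    """
    if width < min_size or height < min_size:
        raise ValueError(f"slide {width}x{height} smaller than minimum {min_size}")
    if n_tumor_regions < 0:
        raise ValueError("n_tumor_regions must be >= 0")
    rng = np.random.Generator(np.random.PCG64(seed))
    canvas = np.empty((height, width, 3), dtype=np.uint8)
    _draw_texture(canvas, normal_params, None, rng)
    polygons = [_random_polygon(rng, width, height, region_radius_frac)
                for _ in range(n_tumor_regions)]
    if polygons:
        mask = _polygon_mask(polygons, 0, 0, width, height)
        _draw_texture(canvas, tumor_params, mask, rng)
    # per-channel intensity jitter over the whole slide
    sd = max(tumor_params.jitter_sd, normal_params.jitter_sd)
    if sd > 0:
        noise = rng.normal(0.0, sd, canvas.shape)
        canvas = np.clip(canvas.astype(np.int16) + noise.astype(np.int16),
                         0, 255).astype(np.uint8)
    if slide_id is None:
        slide_id = f"synthetic_{seed:06d}"
    return SyntheticSlide(slide_id=slide_id, image=canvas,
                          tumor_polygons=polygons, seed=seed)


# -- persistence ------------------------------------------------------------

def write_slide_png(slide: SyntheticSlide, path: str | Path) -> None:
    Image.fromarray(slide.image).save(str(path))


def polygons_to_geojson(slide: SyntheticSlide) -> dict:
    """Annotations as a GeoJSON FeatureCollection of Polygons, pixel
    coordinates, 0-based, y-down."""
    features = []
    for i, poly in enumerate(slide.tumor_polygons):
        ring = poly.tolist() + [poly[0].tolist()]
        features.append({
            "type": "Feature",
            "properties": {"slide_id": slide.slide_id, "region": i,
                           "label": "tumor"},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    return {"type": "FeatureCollection", "features": features}


def geojson_to_polygons(doc: dict) -> list[np.ndarray]:
    polys = []
    for feature in doc.get("features", []):
        ring = feature["geometry"]["coordinates"][0]
        arr = np.asarray(ring, dtype=float)
        if len(arr) > 1 and np.array_equal(arr[0], arr[-1]):
            arr = arr[:-1]
        polys.append(arr)
    return polys


def write_annotations(slide: SyntheticSlide, path: str | Path) -> None:
    Path(path).write_text(json.dumps(polygons_to_geojson(slide)))


def write_slide_manifest(slides: list[SyntheticSlide], paths: list[str],
                         out_csv: str | Path) -> pd.DataFrame:
    rows = [{"slide_id": s.slide_id, "path": p, "label": s.slide_label,
             "seed": s.seed} for s, p in zip(slides, paths, strict=True)]
    df = pd.DataFrame(rows)
    df.to_csv(out_csv, index=False)
    return df
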