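"""Slide tiling, half-overlap subsampling and class-balancing augmentation.

Coordinates are 0-based, y-down; a patch occupies the half-open window
[x, x+size) x [y, y+size). Classification patches default to 1,024 px and
are enumerated row-major; segmentation tiles are 256 px cut at half-overlap
stride so each 1,024 patch yields an 8x8 grid of 64 tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthetic import SyntheticSlide, rasterize_mask

NORMAL, CARCINOMA, UNLABELED = "normal", "carcinoma", "unlabeled"
SPLITS = ("training", "validation", "testing")
AUG_OPS = ("rot90", "rot180", "rot270", "fliph", "flipv")

#: a patch is flagged background when more than this fraction of its pixels
#: are near-white (all channels > 220)
BACKGROUND_FRACTION = 0.8
WHITE_LEVEL = 220

#: tumor-mask fraction thresholds: >= hi -> carcinoma, <= lo -> normal,
#: in between -> unlabeled (excluded from training)
LABEL_THRESHOLDS = (0.05, 0.5)


@dataclass
class PatchRecord:
    """One image tile plus its provenance and label."""

    slide_id: str
    x: int
    y: int
    size: int
    image: np.ndarray
    label: str = UNLABELED
    split: str | None = None
    augmentation_tag: str = "identity"
    background_flag: bool = False
    tumor_fraction: float | None = None

    @property
    def parent_id(self) -> str:
        """Identity of the un-augmented parent patch; augmentation never
        changes it, which is what the split-leakage check keys on."""
        return f"{self.slide_id}:{self.x}:{self.y}:{self.size}"


def is_background(image: np.ndarray) -> bool:
    white = (image > WHITE_LEVEL).all(axis=-1)
    return float(white.mean()) > BACKGROUND_FRACTION


def _offsets(extent: int, patch: int, stride: int, edge_policy: str) -> list[int]:
    if extent >= patch:
        last = extent - patch
        offs = list(range(0, last + 1, stride))
        if edge_policy == "pad" and offs[-1] != last:
            offs.append(offs[-1] + stride)
        return offs
    return [0] if edge_policy == "pad" else []


def _crop_padded(image: np.ndarray, x: int, y: int, size: int) -> np.ndarray:
    """Crop [y:y+size, x:x+size], mirror-padding any overhang (symmetric
    reflection, which stays valid even when the overhang equals the crop)."""
    h, w = image.shape[:2]
    px = max(0, x + size - w)
    py = max(0, y + size - h)
    crop = image[y:min(y + size, h), x:min(x + size, w)]
    if px or py:
        pad = [(0, py), (0, px)] + [(0, 0)] * (image.ndim - 2)
        crop = np.pad(crop, pad, mode="symmetric")
    return crop


def tile_slide(slide, patch_size: int = 1024, stride: int = 1024,
               edge_policy: str = "drop",
               label_thresholds: tuple[float, float] = LABEL_THRESHOLDS,
               ) -> list[PatchRecord]:
    """Cut a slide into labelled patches, row-major.

    ``slide`` may be a SyntheticSlide (patches are labelled from the tumor
    polygon mask and flagged for background) or a bare RGB array (patches
    come back unlabeled). With edge_policy="drop" partial edge tiles are
    discarded; with "pad" they are reflection-padded to full size.
    """
    if patch_size < 1 or stride < 1:
        raise ValueError("patch_size and stride must be >= 1")
    if edge_policy not in ("drop", "pad"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    if isinstance(slide, SyntheticSlide):
        image, slide_id = slide.image, slide.slide_id
        mask = (rasterize_mask(slide, (0, 0, image.shape[1], image.shape[0]))
                if slide.tumor_polygons else None)
        labelled = True
    else:
        image, slide_id, mask, labelled = np.asarray(slide), "slide", None, False

    h, w = image.shape[:2]
    lo, hi = label_thresholds
    records = []
    for y in _offsets(h, patch_size, stride, edge_policy):
        for x in _offsets(w, patch_size, stride, edge_policy):
            img = _crop_padded(image, x, y, patch_size)
            if labelled:
                if mask is None:
                    frac = 0.0
                else:
                    frac = float(_crop_padded(mask, x, y, patch_size).mean())
                label = CARCINOMA if frac >= hi else NORMAL if frac <= lo else UNLABELED
            else:
                frac, label = None, UNLABELED
            records.append(PatchRecord(
                slide_id=slide_id, x=x, y=y, size=patch_size, image=img,
                label=label, background_flag=is_background(img),
                tumor_fraction=frac))
    return records


def subsample_half_overlap(image: np.ndarray, tile: int = 256):
    """Cut a square patch into half-overlap tiles.

    Offsets run over {0, tile/2, ..., side - tile/2} on both axes, so a
    1,024 patch yields an 8x8 grid of 64 tiles of 256 px. Tiles at the last
    offset overhang the patch by tile/2 and are completed by reflection
    padding. Works on image or mask arrays alike (geometry is identical).

    Returns (tiles, offsets) with offsets as (x, y) pairs, row-major.
    """
    h, w = image.shape[:2]
    stride = tile // 2
    if h != w:
        raise ValueError(f"patch must be square, got {w}x{h}")
    if h % stride:
        raise ValueError(f"side {h} not divisible by stride {stride}")
    offs = list(range(0, h, stride))
    tiles, coords = [], []
    for y in offs:
        for x in offs:
            tiles.append(_crop_padded(image, x, y, tile))
            coords.append((x, y))
    return tiles, coords


_AUG_FUNCS = {
    "rot90": lambda a: np.rot90(a, 1, axes=(0, 1)),
    "rot180": lambda a: np.rot90(a, 2, axes=(0, 1)),
    "rot270": lambda a: np.rot90(a, 3, axes=(0, 1)),
    "fliph": lambda a: a[:, ::-1],
    "flipv": lambda a: a[::-1, :],
}


def augment(patch: PatchRecord, ops=AUG_OPS) -> list[PatchRecord]:
    """One new record per op; labels and coordinates inherited, tag set."""
    out = []
    for op in ops:
        if op not in _AUG_FUNCS:
            raise ValueError(f"unknown augmentation op {op!r}")
        if op.startswith("rot") and patch.image.shape[0] != patch.image.shape[1]:
            raise ValueError("rotation augmentation requires a square patch")
        out.append(replace(patch, image=np.ascontiguousarray(_AUG_FUNCS[op](patch.image)),
                           augmentation_tag=op))
    return out


@dataclass
class SplitManifest:
    """Balanced, split patch collection; splits are disjoint at the
    parent-patch level and augmented descendants stay with their parent."""

    records: list[PatchRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "slide_id": r.slide_id, "x": r.x, "y": r.y, "size": r.size,
            "label": r.label, "split": r.split,
            "augmentation_tag": r.augmentation_tag,
            "background_flag": r.background_flag,
        } for r in self.records])

    def counts(self) -> pd.DataFrame:
        df = self.to_frame()
        return df.pivot_table(index="label", columns="split", values="x",
                              aggfunc="count", fill_value=0)

    def subset(self, split: str) -> list[PatchRecord]:
        return [r for r in self.records if r.split == split]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Parent counts per split for one class: round the training and
    validation fractions, clamp, and give the remainder to testing."""
    n_train = min(int(round(fractions[0] * n)), n)
    n_val = min(int(round(fractions[1] * n)), n - n_train)
    return n_train, n_val, n - n_train - n_val


def build_balanced_manifest(patches: list[PatchRecord],
                            targets: dict[str, int],
                            seed: int,
                            split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                            ops=AUG_OPS) -> SplitManifest:
    """Assign parent patches to splits, then augment each class up to the
    per-class-per-split target.

    Parents are partitioned before any augmentation (no leakage across
    splits); background-flagged and unlabeled patches are excluded. The
    target for a (class, split) cell must not exceed parents x (1 + #ops);
    otherwise the deficit is reported.
    """
    usable = [p for p in patches
              if p.label in (NORMAL, CARCINOMA) and not p.background_flag]
    rng = np.random.Generator(np.random.PCG64(seed))
    by_class: dict[str, list[PatchRecord]] = {NORMAL: [], CARCINOMA: []}
    for p in usable:
        by_class[p.label].append(p)

    records: list[PatchRecord] = []
    for label, parents in by_class.items():
        parents = sorted(parents, key=lambda p: p.parent_id)
        order = rng.permutation(len(parents))
        parents = [parents[i] for i in order]
        # partition parents by split fractions
        n_train, n_val, _ = split_sizes(len(parents), split_fractions)
        parts = {"training": parents[:n_train],
                 "validation": parents[n_train:n_train + n_val],
                 "testing": parents[n_train + n_val:]}
        for split, target in targets.items():
            if split not in parts:
                raise ValueError(f"unknown split {split!r}")
            pool = parts[split]
            capacity = len(pool) * (1 + len(ops))
            if target > capacity:
                raise ValueError(
                    f"cannot reach {target} {label!r} patches in split "
                    f"{split!r}: {len(pool)} parents x {1 + len(ops)} "
                    f"variants = {capacity} (deficit {target - capacity})")
            chosen: list[PatchRecord] = []
            for p in pool:
                if len(chosen) >= target:
                    break
                chosen.append(replace(p, split=split))
            for op in ops:
                if len(chosen) >= target:
                    break
                for p in pool:
                    if len(chosen) >= target:
                        break
                    chosen.append(replace(augment(p, [op])[0], split=split))
            records.extend(chosen)
    return SplitManifest(records=records)
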