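"""Annotation conversion and the five-operation augmentation pipeline.

Polygon annotations (Labelme JSON) are rasterized to binary masks with an
even-odd fill evaluated at pixel centers: pixel (r, c) is covered iff the
point (r + 0.5, c + 0.5) lies inside the polygon.

Augmentation covers exactly five operations — cropping (tiling), rotation
(right angles), mirroring, raising the gray value (gamma correction with
gamma < 1) and additive zero-mean Gaussian noise.  Geometric operations
transform image and mask identically; photometric operations never touch
the mask.  An :class:`AugmentationPlan` expands to an exact number of
outputs per operation under a single seed, so a whole augmented dataset is
reproducible from (source data, plan).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .synthetic import ImageMaskPair

logger = logging.getLogger(__name__)

AUGMENTATION_KINDS = ("crop", "rotate", "mirror", "raise_gray", "gaussian_noise")


# ---------------------------------------------------------------------------
# Labelme polygons -> masks
# ---------------------------------------------------------------------------

@dataclass
class PolygonAnnotation:
    """Polygon outlines in (row, col) coordinates for one image."""

    image_size: tuple[int, int]
    polygons: list[np.ndarray]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        h, w = self.image_size
        clipped = []
        for poly in self.polygons:
            arr = np.asarray(poly, dtype=float)
            if np.any(arr[:, 0] < 0) or np.any(arr[:, 0] > h) or \
               np.any(arr[:, 1] < 0) or np.any(arr[:, 1] > w):
                warnings.warn("polygon points outside image bounds; clipping",
                              RuntimeWarning, stacklevel=3)
                arr = np.clip(arr, [0, 0], [h, w])
            clipped.append(arr)
        self.polygons = clipped
        if not self.labels:
            self.labels = ["cell"] * len(self.polygons)


def load_labelme(source) -> PolygonAnnotation:
    """Read a Labelme JSON file (or already-parsed dict).

    Labelme stores points as [x, y] = (col, row); they are transposed to
    the package's (row, col) convention.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = json.load(fh)
    else:
        data = source
    h, w = int(data["imageHeight"]), int(data["imageWidth"])
    polygons, labels = [], []
    for shape in data.get("shapes", []):
        pts = np.asarray(shape["points"], dtype=float)[:, ::-1]  # (x,y) -> (r,c)
        polygons.append(pts)
        labels.append(shape.get("label", "cell"))
    return PolygonAnnotation(image_size=(h, w), polygons=polygons, labels=labels)


def _points_in_polygon(rows: np.ndarray, cols: np.ndarray,
                       poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (ray casting) point-in-polygon test."""
    inside = np.zeros(rows.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        r1, c1 = poly[i]
        r2, c2 = poly[(i + 1) % n]
        if r1 == r2:
            continue
        crosses = (r1 > rows) != (r2 > rows)
        c_inter = (rows - r1) * (c2 - c1) / (r2 - r1) + c1
        inside ^= crosses & (cols < c_inter)
    return inside


def labelme_to_mask(ann: PolygonAnnotation) -> np.ndarray:
    """Union of filled polygons; degenerate polygons (< 3 points) are skipped."""
    h, w = ann.image_size
    mask = np.zeros((h, w), dtype=np.uint8)
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    rows += 0.5
    cols += 0.5
    for k, poly in enumerate(ann.polygons):
        if len(poly) < 3:
            logger.warning("skipping degenerate polygon %d (%d points)", k, len(poly))
            continue
        mask |= _points_in_polygon(rows, cols, poly).astype(np.uint8)
    return mask


# ---------------------------------------------------------------------------
# individual augmentation operations
# ---------------------------------------------------------------------------

def _derive(pair: ImageMaskPair, image: np.ndarray, mask: np.ndarray,
            instances, op: dict) -> ImageMaskPair:
    meta = dict(pair.meta)
    meta["history"] = list(meta.get("history", [])) + [op]
    return ImageMaskPair(image=image, mask=mask, instances=instances, meta=meta)


def crop_tiles(pair: ImageMaskPair, tile: tuple[int, int],
               stride: tuple[int, int] | None = None) -> list[ImageMaskPair]:
    """Cut a raster grid of tiles; the final row/column is anchored flush to
    the bottom/right edge so the whole image is covered without padding."""
    th, tw = tile
    h, w = pair.mask.shape
    if th > h or tw > w:
        raise ValueError(f"tile {tile} larger than image {(h, w)}")
    sh, sw = stride or tile

    def anchors(size, t, s):
        pos = list(range(0, size - t + 1, s))
        if pos[-1] != size - t:
            pos.append(size - t)
        return pos

    out = []
    for r in anchors(h, th, sh):
        for c in anchors(w, tw, sw):
            out.append(_derive(
                pair, pair.image[r:r + th, c:c + tw].copy(),
                pair.mask[r:r + th, c:c + tw].copy(),
                None if pair.instances is None
                else pair.instances[r:r + th, c:c + tw].copy(),
                {"op": "crop", "origin": (r, c), "tile": (th, tw)}))
    return out


def rotate(pair: ImageMaskPair, angle: int) -> ImageMaskPair:
    """Lossless right-angle rotation (counter-clockwise, degrees in
    {90, 180, 270}); image and mask rotate identically."""
    if angle % 360 == 0:
        k = 0
    elif angle in (90, 180, 270):
        k = angle // 90
    else:
        raise ValueError(f"only right-angle rotations are supported, got {angle}")
    return _derive(pair,
                   np.rot90(pair.image, k, axes=(0, 1)).copy(),
                   np.rot90(pair.mask, k).copy(),
                   None if pair.instances is None else np.rot90(pair.instances, k).copy(),
                   {"op": "rotate", "angle": angle})


def mirror(pair: ImageMaskPair, axis: str = "horizontal") -> ImageMaskPair:
    """Flip image and mask: 'horizontal' reverses columns (left-right),
    'vertical' reverses rows (up-down)."""
    if axis == "horizontal":
        flip_axis = 1
    elif axis == "vertical":
        flip_axis = 0
    else:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    return _derive(pair,
                   np.flip(pair.image, axis=flip_axis).copy(),
                   np.flip(pair.mask, axis=flip_axis).copy(),
                   None if pair.instances is None
                   else np.flip(pair.instances, axis=flip_axis).copy(),
                   {"op": "mirror", "axis": axis})


def raise_gray(pair: ImageMaskPair, gamma: float = 0.7) -> ImageMaskPair:
    """Gamma correction ``image ** gamma`` with gamma in (0, 1].

    For gamma < 1 every non-extreme intensity strictly increases, which
    brightens dim structure and stretches the dynamic range; the mask is
    untouched.
    """
    if not (0 < gamma <= 1):
        raise ValueError(f"gamma must lie in (0, 1], got {gamma}")
    image = np.power(np.clip(pair.image, 0.0, 1.0), gamma).astype(pair.image.dtype)
    return _derive(pair, image, pair.mask.copy(),
                   None if pair.instances is None else pair.instances.copy(),
                   {"op": "raise_gray", "gamma": gamma})


def add_gaussian_noise(pair: ImageMaskPair, sigma: float = 0.03,
                       seed: int = 0) -> ImageMaskPair:
    """Add zero-mean Gaussian noise to the image only; clip to [0, 1]."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        image = pair.image.copy()
    else:
        rng = np.random.default_rng(seed)
        image = np.clip(pair.image + rng.normal(0.0, sigma, pair.image.shape),
                        0.0, 1.0).astype(pair.image.dtype)
    return _derive(pair, image, pair.mask.copy(),
                   None if pair.instances is None else pair.instances.copy(),
                   {"op": "gaussian_noise", "sigma": sigma, "seed": seed})


# ---------------------------------------------------------------------------
# plan-driven dataset expansion
# ---------------------------------------------------------------------------

@dataclass
class AugmentationOp:
    kind: str
    count: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in AUGMENTATION_KINDS:
            raise ValueError(f"unknown augmentation kind {self.kind!r}; "
                             f"expected one of {AUGMENTATION_KINDS}")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass
class AugmentationPlan:
    ops: list[AugmentationOp]
    seed: int = 0

    @property
    def total(self) -> int:
        return sum(op.count for op in self.ops)


def paper_plan(seed: int = 0, tile: tuple[int, int] = (256, 256)) -> AugmentationPlan:
    """The five-operation plan with per-op counts 371/199/199/769/769
    (crop, vertical mirror, horizontal mirror, raise-gray, noise), totalling
    2307 outputs."""
    return AugmentationPlan(ops=[
        AugmentationOp("crop", 371, {"tile": tile}),
        AugmentationOp("mirror", 199, {"axis": "vertical"}),
        AugmentationOp("mirror", 199, {"axis": "horizontal"}),
        AugmentationOp("raise_gray", 769, {}),
        AugmentationOp("gaussian_noise", 769, {}),
    ], seed=seed)


def _apply_random_op(pair: ImageMaskPair, op: AugmentationOp,
                     rng: np.random.Generator) -> ImageMaskPair:
    if op.kind == "crop":
        th, tw = op.params.get("tile", (256, 256))
        h, w = pair.mask.shape
        th, tw = min(th, h), min(tw, w)
        r = int(rng.integers(0, h - th + 1))
        c = int(rng.integers(0, w - tw + 1))
        return _derive(pair, pair.image[r:r + th, c:c + tw].copy(),
                       pair.mask[r:r + th, c:c + tw].copy(),
                       None if pair.instances is None
                       else pair.instances[r:r + th, c:c + tw].copy(),
                       {"op": "crop", "origin": (r, c), "tile": (th, tw)})
    if op.kind == "rotate":
        angle = op.params.get("angle") or int(rng.choice([90, 180, 270]))
        return rotate(pair, angle)
    if op.kind == "mirror":
        axis = op.params.get("axis") or str(rng.choice(["horizontal", "vertical"]))
        return mirror(pair, axis)
    if op.kind == "raise_gray":
        gamma = op.params.get("gamma") or float(rng.uniform(0.5, 0.9))
        return raise_gray(pair, gamma)
    if op.kind == "gaussian_noise":
        sigma = op.params.get("sigma", 0.03)
        return add_gaussian_noise(pair, sigma, seed=int(rng.integers(2 ** 31)))
    raise ValueError(op.kind)  # unreachable; kinds validated at construction


def build_augmented_dataset(pairs: list[ImageMaskPair], plan: AugmentationPlan
                            ) -> tuple[list[ImageMaskPair], list[dict]]:
    """Expand a source set to exactly ``plan.total`` augmented pairs.

    For every requested output a source image and the operation parameters
    are drawn from one generator seeded with ``plan.seed``, so the same
    (sources, plan) always produces the same dataset.  Returns the outputs
    and a manifest recording each output's lineage.
    """
    if not pairs and plan.total > 0:
        raise ValueError("cannot augment an empty source set")
    rng = np.random.default_rng(plan.seed)
    out: list[ImageMaskPair] = []
    manifest: list[dict] = []
    for op in plan.ops:
        for _ in range(op.count):
            src = int(rng.integers(len(pairs)))
            aug = _apply_random_op(pairs[src], op, rng)
            record = {"index": len(out), "kind": op.kind, "source": src,
                      "applied": aug.meta["history"][-1]}
            aug.meta["name"] = f"aug{len(out):05d}"
            out.append(aug)
            manifest.append(record)
    assert len(out) == plan.total
    return out, manifest


def plan_to_dict(plan: AugmentationPlan) -> dict:
    return {"seed": plan.seed, "ops": [asdict(op) for op in plan.ops]}


def plan_from_dict(d: dict) -> AugmentationPlan:
    return AugmentationPlan(ops=[AugmentationOp(**op) for op in d["ops"]],
                            seed=d.get("seed", 0))
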