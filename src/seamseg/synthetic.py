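"""Synthetic FISH-like images of adherent cell clusters with exact ground truth.

Real FISH photographs show bright, roughly elliptical cells on a dark
background; cells cluster and adhere, so their contours touch or overlap —
the failure mode boundary-segmentation models are built for.  This module
emulates those features parametrically: each cell is an ellipse with a
smooth radial intensity falloff, placement is controlled by an adhesion
level in [0, 1] (the probability that a new cell is deliberately planted
against an existing one), and the rendered image receives Gaussian blur and
sensor noise.  The geometry is known exactly, so the binary mask and
per-cell instance labels are exact by construction rather than annotated.

Everything is deterministic: a (config, seed) pair fixes the sampled scene,
and a scene fixes every rendered byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage


class PackingError(RuntimeError):
    """Raised when cells cannot be placed without violating the constraints."""


@dataclass
class CellInstance:
    """One elliptical cell: center (row, col), semi-axes a >= b, orientation
    in radians, peak intensity in (0, 1] and a radial decay exponent."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float
    peak_intensity: float
    intensity_profile: float = 0.35

    def __post_init__(self):
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError(f"semi-axes must satisfy a >= b > 0, got {self.semi_axes}")
        if not (0 < self.peak_intensity <= 1):
            raise ValueError("peak_intensity must lie in (0, 1]")

    def elliptic_distance_sq(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Squared normalized elliptic radius; <= 1 marks the interior."""
        dr = rows - self.center[0]
        dc = cols - self.center[1]
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = dr * c + dc * s
        v = -dr * s + dc * c
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2

    def contains(self, row: float, col: float) -> bool:
        return bool(self.elliptic_distance_sq(np.asarray(row), np.asarray(col)) <= 1.0)


@dataclass
class SceneSpec:
    """Full parametric description of one synthetic field of cells."""

    canvas: tuple[int, int]
    cells: list[CellInstance]
    adhesion_level: float = 0.5
    background_level: float = 0.06
    noise_sigma: float = 0.02
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.canvas
        if h < 64 or w < 64:
            raise ValueError("canvas dimensions must be >= 64")
        if not (0 <= self.adhesion_level <= 1):
            raise ValueError("adhesion_level must lie in [0, 1]")
        if not (0 <= self.background_level < 1):
            raise ValueError("background_level must lie in [0, 1)")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sigma and blur_sigma must be >= 0")
        for cell in self.cells:
            r, c = cell.center
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"cell center {cell.center} outside canvas {self.canvas}")

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ImageMaskPair:
    """An RGB image in [0, 1], its binary mask, optional instance labels and
    provenance metadata (seed, spec hash, augmentation history)."""

    image: np.ndarray
    mask: np.ndarray
    instances: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be (H, W, 3)")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask/image shape mismatch")
        if not np.isfinite(self.image).all():
            raise ValueError("image contains non-finite values")
        if self.instances is not None:
            if not np.array_equal(self.mask.astype(bool), self.instances > 0):
                raise ValueError("mask and instance map disagree")


@dataclass
class GeneratorConfig:
    """Tunable knobs of the scene sampler.

    Defaults describe a moderately crowded field: 6-14 cells of semi-major
    axis 10-22 px on a 256x256 canvas, adhesion 0.5 (about half the cells
    planted against a neighbour), dim background, mild blur and noise.
    """

    canvas: tuple[int, int] = (256, 256)
    n_cells: tuple[int, int] = (6, 14)
    semi_major: tuple[float, float] = (10.0, 22.0)
    aspect: tuple[float, float] = (0.55, 0.95)
    peak_intensity: tuple[float, float] = (0.55, 1.0)
    intensity_profile: float = 0.35
    adhesion_level: float = 0.5
    background_level: float = 0.06
    noise_sigma: float = 0.02
    blur_sigma: float = 1.0
    max_retries: int = 200

    def scaled_to(self, canvas: tuple[int, int]) -> "GeneratorConfig":
        """Rescale cell size/count for a different canvas, keeping density.

        Linear dimensions scale with min(canvas)/min(default); cell count
        scales with the area ratio (at least one cell).
        """
        import dataclasses as _dc

        s = min(canvas) / min(self.canvas)
        area = (canvas[0] * canvas[1]) / (self.canvas[0] * self.canvas[1])
        n_lo = max(1, round(self.n_cells[0] * area))
        n_hi = max(n_lo, round(self.n_cells[1] * area))
        return _dc.replace(
            self, canvas=tuple(canvas), n_cells=(n_lo, n_hi),
            semi_major=(self.semi_major[0] * s, self.semi_major[1] * s))


# cells render with this RGB tint (FISH-like cyan/blue stain)
TINT = (0.55, 0.85, 1.0)


def _random_cell(rng: np.random.Generator, config: GeneratorConfig,
                 center: tuple[float, float]) -> CellInstance:
    a = rng.uniform(*config.semi_major)
    b = a * rng.uniform(*config.aspect)
    return CellInstance(center=center, semi_axes=(a, b),
                        orientation=rng.uniform(0, np.pi),
                        peak_intensity=rng.uniform(*config.peak_intensity),
                        intensity_profile=config.intensity_profile)


def sample_scene(config: GeneratorConfig, seed: int) -> SceneSpec:
    """Sample a cell layout whose contact frequency rises with adhesion_level.

    Cells are placed sequentially.  With probability ``adhesion_level`` a
    new cell is planted next to a randomly chosen existing cell at a
    center distance below the sum of semi-major axes (guaranteeing likely
    contact); otherwise a position is rejection-sampled so the new ellipse
    cannot intersect any placed cell (center distance > a_i + a_j + 1).
    A cell that cannot be placed within ``max_retries`` attempts raises
    :class:`PackingError`.
    """
    rng = np.random.default_rng(seed)
    h, w = config.canvas
    n = int(rng.integers(config.n_cells[0], config.n_cells[1] + 1))
    cells: list[CellInstance] = []
    for k in range(n):
        placed = False
        adhere = k > 0 and rng.random() < config.adhesion_level
        for _ in range(config.max_retries):
            if adhere:
                anchor = cells[int(rng.integers(len(cells)))]
                a_new = rng.uniform(*config.semi_major)
                dist = (anchor.semi_axes[0] + a_new) * rng.uniform(0.45, 0.9)
                theta = rng.uniform(0, 2 * np.pi)
                r = anchor.center[0] + dist * np.sin(theta)
                c = anchor.center[1] + dist * np.cos(theta)
                if not (0 <= r < h and 0 <= c < w):
                    continue
                cand = CellInstance(
                    (r, c), (a_new, a_new * rng.uniform(*config.aspect)),
                    rng.uniform(0, np.pi), rng.uniform(*config.peak_intensity),
                    config.intensity_profile)
                cells.append(cand)
                placed = True
                break
            else:
                margin = config.semi_major[0]
                r = rng.uniform(margin, h - margin)
                c = rng.uniform(margin, w - margin)
                cand = _random_cell(rng, config, (r, c))
                ok = all(np.hypot(r - other.center[0], c - other.center[1])
                         > cand.semi_axes[0] + other.semi_axes[0] + 1.0
                         for other in cells)
                if ok:
                    cells.append(cand)
                    placed = True
                    break
        if not placed:
            raise PackingError(
                f"could not place cell {k + 1}/{n} after {config.max_retries} "
                f"attempts; reduce n_cells or cell size for canvas {config.canvas}")
    return SceneSpec(canvas=config.canvas, cells=cells,
                     adhesion_level=config.adhesion_level,
                     background_level=config.background_level,
                     noise_sigma=config.noise_sigma,
                     blur_sigma=config.blur_sigma, seed=seed)


def cell_masks(spec: SceneSpec) -> np.ndarray:
    """Boolean stack (n_cells, H, W): pixel (r, c) covered by each ellipse."""
    h, w = spec.canvas
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    if not spec.cells:
        return np.zeros((0, h, w), dtype=bool)
    return np.stack([c.elliptic_distance_sq(rows, cols) <= 1.0 for c in spec.cells])


def touching_fraction(spec: SceneSpec) -> float:
    """Fraction of cells whose rasterized ellipse touches (shares or borders
    a pixel with) at least one other cell's ellipse."""
    masks = cell_masks(spec)
    n = len(masks)
    if n == 0:
        return 0.0
    grown = [ndimage.binary_dilation(m) for m in masks]
    touching = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if np.any(grown[i] & masks[j]):
                touching[i] = touching[j] = True
    return float(touching.mean())


def mean_pairwise_overlap(spec: SceneSpec) -> float:
    """Mean over cell pairs of the shared pixel count (0 when < 2 cells)."""
    masks = cell_masks(spec)
    n = len(masks)
    if n < 2:
        return 0.0
    overlaps = [np.count_nonzero(masks[i] & masks[j])
                for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(overlaps))


def render_pair(spec: SceneSpec) -> ImageMaskPair:
    """Render a scene to an image, binary mask and instance-label map.

    Overlapping intensities compose by pixelwise maximum; the mask is the
    union of ellipse interiors; each covered pixel is owned by the cell
    with the nearest center (ties to the lower id).  Gaussian blur, then
    zero-mean Gaussian noise, apply to the image only; the image is clipped
    to [0, 1] and quantized to 8-bit levels so PNG round-trips are exact.
    """
    h, w = spec.canvas
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    intensity = np.full((h, w), spec.background_level, dtype=np.float64)
    mask = np.zeros((h, w), dtype=bool)
    instances = np.zeros((h, w), dtype=np.int32)
    best_dist = np.full((h, w), np.inf)
    for idx, cell in enumerate(spec.cells, start=1):
        d2 = cell.elliptic_distance_sq(rows, cols)
        inside = d2 <= 1.0
        profile = np.zeros_like(d2)
        profile[inside] = cell.peak_intensity * np.power(
            np.clip(1.0 - d2[inside], 0.0, 1.0), cell.intensity_profile)
        intensity = np.maximum(intensity, profile)
        mask |= inside
        euclid = (rows - cell.center[0]) ** 2 + (cols - cell.center[1]) ** 2
        take = inside & (euclid < best_dist)  # strict: ties keep the lower id
        instances[take] = idx
        best_dist[take] = euclid[take]

    tint = np.asarray(TINT)
    image = intensity[:, :, None] * tint[None, None, :]
    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=(spec.blur_sigma,
                                                      spec.blur_sigma, 0))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    image = np.round(image * 255.0) / 255.0  # 8-bit grid -> exact PNG round-trip
    pair = ImageMaskPair(image=image.astype(np.float32),
                         mask=mask.astype(np.uint8),
                         instances=instances,
                         meta={"seed": spec.seed, "spec_hash": spec.spec_hash(),
                               "history": []})
    pair.validate()
    return pair


def generate_dataset(config: GeneratorConfig, n_images: int,
                     seed: int) -> list[ImageMaskPair]:
    """Generate ``n_images`` independent scenes; scene k uses a sub-seed
    derived deterministically from (seed, k)."""
    seq = np.random.SeedSequence(seed)
    sub = seq.generate_state(n_images) % (2 ** 31)
    pairs = []
    for k in range(n_images):
        spec = sample_scene(config, int(sub[k]))
        pair = render_pair(spec)
        pair.meta["name"] = f"scene{k:04d}"
        pairs.append(pair)
    return pairs


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def write_dataset(pairs: list[ImageMaskPair], root) -> dict:
    """Write PNG images/masks (+ 16-bit instance maps) and a JSON manifest.

    Mask PNGs contain exactly {0, 255}.  Reading the directory back with
    :func:`read_dataset` reproduces every array bit-exactly.
    """
    from PIL import Image

    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(exist_ok=True)
    (root / "instances").mkdir(exist_ok=True)
    entries = []
    for i, pair in enumerate(pairs):
        pair.validate()
        name = pair.meta.get("name", f"pair{i:04d}")
        img8 = np.round(np.clip(pair.image, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(img8).save(root / "images" / f"{name}.png")
        Image.fromarray((pair.mask.astype(np.uint8) * 255)).save(
            root / "masks" / f"{name}.png")
        entry = {"name": name, "image": f"images/{name}.png",
                 "mask": f"masks/{name}.png", "meta": pair.meta}
        if pair.instances is not None:
            inst = pair.instances.astype(np.uint16)
            Image.fromarray(inst).save(root / "instances" / f"{name}.png")
            entry["instances"] = f"instances/{name}.png"
        entries.append(entry)
    manifest = {"n_pairs": len(pairs), "pairs": entries}
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def read_dataset(root) -> list[ImageMaskPair]:
    """Load a dataset written by :func:`write_dataset`."""
    from PIL import Image

    root = Path(root)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    pairs = []
    for entry in manifest["pairs"]:
        image = np.asarray(Image.open(root / entry["image"]), dtype=np.float32) / 255.0
        mask_png = np.asarray(Image.open(root / entry["mask"]))
        if not np.isin(np.unique(mask_png), (0, 255)).all():
            raise ValueError(f"mask {entry['mask']} is not binary {{0, 255}}")
        mask = (mask_png > 0).astype(np.uint8)
        instances = None
        if "instances" in entry:
            instances = np.asarray(Image.open(root / entry["instances"])).astype(np.int32)
        pairs.append(ImageMaskPair(image=image, mask=mask, instances=instances,
                                   meta=entry.get("meta", {})))
    return pairs
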