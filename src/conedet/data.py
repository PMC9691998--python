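"""Dataset plumbing and the synthetic forest-scene generator.

The real acquisition regime this emulates: forest photographs in two
scene types (cones on the ground, cones on the tree) with multiple
scattered, roughly circular brown targets per image.  Target bounding
boxes span about 0.01%-1.4% of the image area with a mode near 0.57%
(a 300x300 box in a 5312x2988 frame), so targets are small relative to
the frame.  Annotations use the Pascal VOC XML dialect written by
LabelImg (1-based closed pixel coordinates); internally boxes are
0-based half-open (xmin, ymin, xmax, ymax).

Offline augmentation doubles a dataset by appending, for every image,
one copy transformed by a uniformly chosen member of {contrast
transform, random colour, Gaussian noise, salt-and-pepper noise}; all
four are geometry-preserving so boxes carry over unchanged.  Mosaic
augmentation composes four images onto one canvas at train time.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .head import iou

DEFAULT_CLASS = "pinecone"

# the published acquisition regime (camera frame and box-size extremes)
SOURCE_RESOLUTION = (5312, 2988)
SOURCE_BOX_RANGE = (25, 600)
SOURCE_BOX_MODE = 300


def modal_area_fraction() -> float:
    """Area fraction of the modal 300x300 target in a 5312x2988 frame."""
    w, h = SOURCE_RESOLUTION
    return SOURCE_BOX_MODE ** 2 / (w * h)


@dataclass
class ImageSample:
    """An RGB image with its ground-truth boxes and scene metadata."""

    pixels: np.ndarray                      # (H, W, 3) uint8
    boxes: list                             # [(x1, y1, x2, y2, class_id)]
    scene_type: str = "ground"              # ground | tree
    provenance: str = "original"            # original | augmented:<kind> | mosaic | synthetic
    name: str = "sample"
    source_id: str | None = None            # groups augmented copies with sources

    def __post_init__(self):
        h, w = self.pixels.shape[:2]
        for b in self.boxes:
            x1, y1, x2, y2 = b[:4]
            if not (0 <= x1 < x2 <= w and 0 <= y1 < y2 <= h):
                raise ValueError(f"box {b} outside image {w}x{h}")
            if x2 - x1 < 2 or y2 - y1 < 2:
                raise ValueError(f"box {b} smaller than 2 px")

    @property
    def size(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[0]


# -- Pascal VOC XML (LabelImg dialect) ---------------------------------

def write_voc_xml(sample: ImageSample, xml_path, image_filename: str | None = None,
                  class_names=(DEFAULT_CLASS,)):
    w, h = sample.size
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = "images"
    ET.SubElement(root, "filename").text = image_filename or f"{sample.name}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(w)
    ET.SubElement(size, "height").text = str(h)
    ET.SubElement(size, "depth").text = "3"
    for x1, y1, x2, y2, cid in sample.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = class_names[cid]
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        # internal 0-based half-open -> VOC 1-based closed
        ET.SubElement(bb, "xmin").text = str(int(round(x1)) + 1)
        ET.SubElement(bb, "ymin").text = str(int(round(y1)) + 1)
        ET.SubElement(bb, "xmax").text = str(int(round(x2)))
        ET.SubElement(bb, "ymax").text = str(int(round(y2)))
    ET.ElementTree(root).write(xml_path)


def read_voc_xml(path, class_names=(DEFAULT_CLASS,)):
    """Parse a VOC XML file; returns (filename, (width, height), boxes)
    with boxes converted to internal 0-based half-open coordinates."""
    root = ET.parse(path).getroot()
    size = root.find("size")
    if size is None:
        raise ValueError(f"{path}: missing <size> element")
    w, h = int(size.findtext("width")), int(size.findtext("height"))
    filename = root.findtext("filename", default="")
    boxes = []
    names = list(class_names)
    for idx, obj in enumerate(root.iter("object")):
        bb = obj.find("bndbox")
        if bb is None:
            raise ValueError(f"{path}: object {idx} has no <bndbox>")
        vals = {}
        for key in ("xmin", "ymin", "xmax", "ymax"):
            text = bb.findtext(key)
            if text is None:
                raise ValueError(f"{path}: object {idx} missing <{key}>")
            vals[key] = float(text)
        x1, y1 = vals["xmin"] - 1, vals["ymin"] - 1  # VOC closed -> half-open
        x2, y2 = vals["xmax"], vals["ymax"]
        if not (0 <= x1 < x2 <= w and 0 <= y1 < y2 <= h):
            raise ValueError(f"{path}: object {idx} box outside declared size")
        name = obj.findtext("name", default=DEFAULT_CLASS)
        if name not in names:
            names.append(name)
        boxes.append((x1, y1, x2, y2, names.index(name)))
    return filename, (w, h), boxes


# -- offline augmentations (all geometry-preserving) -------------------

def _clip8(arr: np.ndarray) -> np.ndarray:
    return np.clip(arr, 0, 255).astype(np.uint8)


def augment_contrast(s: ImageSample, factor: float) -> ImageSample:
    """Rescale pixel deviations about the per-image mean by `factor`."""
    if factor <= 0:
        raise ValueError("contrast factor must be positive")
    mean = s.pixels.astype(np.float64).mean()
    out = _clip8(mean + factor * (s.pixels.astype(np.float64) - mean))
    return replace(s, pixels=out, provenance="augmented:contrast")


def augment_random_color(s: ImageSample, seed: int = 0) -> ImageSample:
    """Independent channel gains drawn uniformly from [0.7, 1.3]."""
    rng = np.random.default_rng(seed)
    gains = rng.uniform(0.7, 1.3, size=3)
    out = _clip8(s.pixels.astype(np.float64) * gains[None, None, :])
    return replace(s, pixels=out, provenance="augmented:color")


def augment_gaussian_noise(s: ImageSample, sigma: float, seed: int = 0) -> ImageSample:
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=s.pixels.shape)
    out = _clip8(s.pixels.astype(np.float64) + noise)
    return replace(s, pixels=out, provenance="augmented:gaussian")


def augment_salt_pepper(s: ImageSample, amount: float, seed: int = 0) -> ImageSample:
    """Each pixel independently becomes salt or pepper with probability
    `amount` (half white, half black in expectation)."""
    if not (0.0 <= amount <= 1.0):
        raise ValueError("amount must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = s.pixels.shape[:2]
    u = rng.random((h, w))
    out = s.pixels.copy()
    out[u < amount / 2] = 0
    out[(u >= amount / 2) & (u < amount)] = 255
    return replace(s, pixels=out, provenance="augmented:saltpepper")


_AUGMENT_KINDS = ("contrast", "color", "gaussian", "saltpepper")


def apply_augment(s: ImageSample, kind: str, rng: np.random.Generator) -> ImageSample:
    sub = int(rng.integers(0, 2 ** 31 - 1))
    if kind == "contrast":
        return augment_contrast(s, float(rng.uniform(0.6, 1.5)))
    if kind == "color":
        return augment_random_color(s, sub)
    if kind == "gaussian":
        return augment_gaussian_noise(s, float(rng.uniform(5.0, 15.0)), sub)
    if kind == "saltpepper":
        return augment_salt_pepper(s, float(rng.uniform(0.02, 0.08)), sub)
    raise ValueError(f"unknown augmentation kind {kind!r}")


def expand_dataset(samples: list[ImageSample], seed: int = 0) -> list[ImageSample]:
    """Append one augmented copy per sample (uniformly chosen transform):
    the output has exactly twice the input cardinality."""
    rng = np.random.default_rng(seed)
    out = list(samples)
    for s in samples:
        kind = _AUGMENT_KINDS[int(rng.integers(0, 4))]
        aug = apply_augment(s, kind, rng)
        aug = replace(aug, name=f"{s.name}_aug",
                      source_id=s.source_id or s.name)
        out.append(aug)
    return out


# -- mosaic ------------------------------------------------------------

def _resize_sample(pixels: np.ndarray, boxes, new_w: int, new_h: int):
    h, w = pixels.shape[:2]
    img = Image.fromarray(pixels).resize((new_w, new_h), Image.BILINEAR)
    sx, sy = new_w / w, new_h / h
    new_boxes = [(x1 * sx, y1 * sy, x2 * sx, y2 * sy, c)
                 for x1, y1, x2, y2, c in boxes]
    return np.asarray(img), new_boxes


def mosaic(samples: list[ImageSample], out_side: int = 416, seed: int = 0,
           min_box_keep: float = 0.25) -> ImageSample:
    """Compose exactly four samples onto one canvas split at a random
    point; boxes are rescaled into their region and dropped when the
    surviving area falls below `min_box_keep` of the rescaled box."""
    if len(samples) != 4:
        raise ValueError("mosaic needs exactly four samples")
    rng = np.random.default_rng(seed)
    sx = int(rng.uniform(0.3, 0.7) * out_side)
    sy = int(rng.uniform(0.3, 0.7) * out_side)
    regions = [(0, 0, sx, sy), (sx, 0, out_side, sy),
               (0, sy, sx, out_side), (sx, sy, out_side, out_side)]
    canvas = np.zeros((out_side, out_side, 3), dtype=np.uint8)
    boxes = []
    for s, (rx1, ry1, rx2, ry2) in zip(samples, regions):
        rw, rh = rx2 - rx1, ry2 - ry1
        pix, bxs = _resize_sample(s.pixels, s.boxes, rw, rh)
        canvas[ry1:ry2, rx1:rx2] = pix
        for x1, y1, x2, y2, c in bxs:
            full = (x2 - x1) * (y2 - y1)
            cx1, cy1 = max(x1, 0) + rx1, max(y1, 0) + ry1
            cx2, cy2 = min(x2, rw) + rx1, min(y2, rh) + ry1
            kept = max(0.0, cx2 - cx1) * max(0.0, cy2 - cy1)
            if full > 0 and kept / full >= min_box_keep \
                    and cx2 - cx1 >= 2 and cy2 - cy1 >= 2:
                boxes.append((cx1, cy1, cx2, cy2, c))
    return ImageSample(canvas, boxes, scene_type=samples[0].scene_type,
                       provenance="mosaic", name="mosaic")


# -- synthetic forest scenes -------------------------------------------

@dataclass
class SceneSpec:
    """Parameters of one generated scene; the seed fully determines the
    output."""

    image_side: int = 416
    n_targets: int | None = None            # None -> 1..15 drawn per scene
    area_fraction_range: tuple[float, float] = (0.0001, 0.014)
    area_fraction_median: float = 0.0057
    scene_type: str = "ground"              # ground | tree
    illumination: float = 1.0               # multiplicative brightness
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.area_fraction_range
        if not (0 < lo < hi <= 1):
            raise ValueError("area fraction range must satisfy 0 < lo < hi <= 1")
        if not (lo <= self.area_fraction_median <= hi):
            raise ValueError("median area fraction outside configured range")
        if self.scene_type not in ("ground", "tree"):
            raise ValueError("scene_type must be 'ground' or 'tree'")


def _smooth_noise(rng, side, scale, lo, hi):
    # correlated noise field: filter at a coarse grid, then zoom up
    red = max(1, int(scale // 2))
    small = max(8, side // red)
    coarse = ndimage.gaussian_filter(rng.random((small, small)),
                                     sigma=max(scale / red, 0.5))
    sm = ndimage.zoom(coarse, side / small, order=1)[:side, :side]
    if sm.shape != (side, side):
        sm = np.pad(sm, ((0, side - sm.shape[0]), (0, side - sm.shape[1])),
                    mode="edge")
    sm = (sm - sm.min()) / max(np.ptp(sm), 1e-9)
    return lo + sm * (hi - lo)


def _ground_background(rng, side):
    base = np.empty((side, side, 3))
    # leaf-litter browns mixed with patchy greens
    brown = np.array([118.0, 86.0, 52.0])
    green = np.array([74.0, 102.0, 48.0])
    mix = _smooth_noise(rng, side, side / 24, 0.0, 1.0)[..., None]
    base = brown * (1 - mix) + green * mix
    texture = _smooth_noise(rng, side, 1.5, -28.0, 28.0)[..., None]
    return base + texture


def _tree_background(rng, side):
    # bright sky gradient with canopy patches and dark branch strokes
    sky_top = np.array([168.0, 196.0, 226.0])
    sky_bot = np.array([196.0, 214.0, 232.0])
    t = np.linspace(0, 1, side)[:, None, None]
    base = sky_top * (1 - t) + sky_bot * t
    canopy = _smooth_noise(rng, side, side / 16, 0.0, 1.0)
    mask = (canopy > 0.62)[..., None]
    green = np.array([66.0, 96.0, 44.0]) + \
        _smooth_noise(rng, side, 2.0, -18.0, 18.0)[..., None]
    base = np.where(mask, green, base)
    for _ in range(rng.integers(4, 9)):
        x0, y0 = rng.uniform(0, side, 2)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(side * 0.4, side * 1.2)
        thick = int(rng.integers(1, 4))
        n = int(length)
        xs = (x0 + np.cos(ang) * np.arange(n)).astype(int)
        ys = (y0 + np.sin(ang) * np.arange(n)).astype(int)
        ok = (xs >= 0) & (xs < side) & (ys >= 0) & (ys < side)
        for dx in range(-thick, thick + 1):
            xs2 = np.clip(xs[ok] + dx, 0, side - 1)
            base[ys[ok], xs2] = np.array([72.0, 52.0, 34.0])
    return base


def _draw_cone(rng, img, mask, cx, cy, bw, bh, side):
    """Paint one ellipsoidal cone with a scale-lattice texture; returns
    its exact bounding box."""
    a, b = bw / 2.0, bh / 2.0
    x1, x2 = int(np.floor(cx - a)), int(np.ceil(cx + a))
    y1, y2 = int(np.floor(cy - b)), int(np.ceil(cy + b))
    yy, xx = np.mgrid[y1:y2, x1:x2]
    ell = ((xx + 0.5 - cx) / a) ** 2 + ((yy + 0.5 - cy) / b) ** 2 <= 1.0
    if not ell.any():
        return None
    base = np.array([142.0, 96.0, 50.0]) + rng.uniform(-18, 18, 3)
    # criss-cross scale lattice: two oblique sinusoid families
    freq = 2 * np.pi / max(2.5, bw / 4.0)
    lat = (np.sin(freq * (xx + yy * 0.6)) * np.sin(freq * (xx - yy * 0.6)))
    shade = 1.0 + 0.25 * lat + 0.18 * ((yy - cy) / max(b, 1)) * -1.0
    patch = base[None, None, :] * shade[..., None]
    region = img[y1:y2, x1:x2]
    region[ell] = patch[ell]
    mask[y1:y2, x1:x2][ell] = True
    ys, xs = np.nonzero(ell)
    return (x1 + xs.min(), y1 + ys.min(), x1 + xs.max() + 1, y1 + ys.max() + 1)


def generate_scene(spec: SceneSpec):
    """Generate one synthetic scene.

    Returns an ImageSample; the generator's own target mask is attached
    as `sample.target_mask` for pixel/box agreement checks.
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side
    img = (_ground_background(rng, side) if spec.scene_type == "ground"
           else _tree_background(rng, side))
    mask = np.zeros((side, side), dtype=bool)
    n = spec.n_targets if spec.n_targets is not None else int(rng.integers(1, 16))
    lo, hi = spec.area_fraction_range
    boxes = []
    for _ in range(n):
        # log-normal about the configured median, clipped to the range
        frac = float(np.exp(rng.normal(np.log(spec.area_fraction_median), 0.75)))
        frac = min(max(frac, lo), hi)
        area = frac * side * side
        aspect = float(rng.uniform(0.75, 1.3))
        bw = np.sqrt(area * aspect)
        bh = area / bw
        bw, bh = max(bw, 3.0), max(bh, 3.0)
        placed = False
        for _try in range(50):
            cx = rng.uniform(bw / 2 + 1, side - bw / 2 - 1)
            cy = rng.uniform(bh / 2 + 1, side - bh / 2 - 1)
            cand = (cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2)
            if all(iou(cand, b[:4]) < 0.2 for b in boxes):
                bb = _draw_cone(rng, img, mask, cx, cy, bw, bh, side)
                if bb is not None:
                    x1, y1, x2, y2 = bb
                    x1, y1 = max(0, x1), max(0, y1)
                    x2, y2 = min(side, x2), min(side, y2)
                    if x2 - x1 >= 2 and y2 - y1 >= 2:
                        boxes.append((float(x1), float(y1),
                                      float(x2), float(y2), 0))
                        placed = True
                break
        if not placed and _try == 49:
            warnings.warn("target placement failed after bounded retries; "
                          "scene has fewer targets than requested")
    img = _clip8(img * spec.illumination)
    sample = ImageSample(img, boxes, scene_type=spec.scene_type,
                         provenance="synthetic",
                         name=f"scene_{spec.scene_type}_{spec.seed}")
    sample.target_mask = mask
    return sample


def make_synthetic_dataset(n_images: int, side: int = 416, seed: int = 0,
                           **spec_overrides) -> list[ImageSample]:
    """Generate `n_images` scenes alternating ground/tree scene types,
    with per-image seeds derived from `seed`."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_images):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        stype = "ground" if i % 2 == 0 else "tree"
        illum = float(rng.uniform(0.7, 1.15))
        spec = SceneSpec(image_side=side, scene_type=stype, seed=sub,
                         illumination=illum, **spec_overrides)
        s = generate_scene(spec)
        mask = s.target_mask
        s = replace(s, name=f"synthetic_{i:05d}", source_id=f"synthetic_{i:05d}")
        s.target_mask = mask
        samples.append(s)
    return samples


# -- splits and on-disk layout -----------------------------------------

def split_dataset(samples: list[ImageSample], train_fraction: float = 0.8,
                  seed: int = 0):
    """Deterministic 8:2-style split at the source level: augmented
    copies always land in the same split as their source image."""
    groups: dict[str, list[ImageSample]] = {}
    for s in samples:
        groups.setdefault(s.source_id or s.name, []).append(s)
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n_train = int(round(train_fraction * len(keys)))
    train_keys = set(keys[:n_train])
    train = [s for k in sorted(groups) if k in train_keys for s in groups[k]]
    test = [s for k in sorted(groups) if k not in train_keys for s in groups[k]]
    return train, test


def save_dataset(samples: list[ImageSample], out_dir, splits=None):
    """Write images (PNG), VOC XML annotations and split manifests."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    for s in samples:
        img_path = out / "images" / f"{s.name}.png"
        Image.fromarray(s.pixels).save(img_path)
        write_voc_xml(s, out / "annotations" / f"{s.name}.xml",
                      image_filename=img_path.name)
    if splits is None:
        splits = {"all": samples}
    for split_name, split_samples in splits.items():
        with open(out / f"{split_name}.txt", "w") as fh:
            for s in split_samples:
                fh.write(f"images/{s.name}.png\n")
    return out


def load_manifest(root, manifest_name: str) -> list[ImageSample]:
    """Load the samples listed by a split manifest file."""
    root = Path(root)
    samples = []
    with open(root / manifest_name) as fh:
        for line in fh:
            rel = line.strip()
            if not rel:
                continue
            img_path = root / rel
            if not img_path.exists():
                raise FileNotFoundError(f"listed image missing: {img_path}")
            pixels = np.asarray(Image.open(img_path).convert("RGB"))
            xml_path = root / "annotations" / (Path(rel).stem + ".xml")
            _, _, boxes = read_voc_xml(xml_path)
            samples.append(ImageSample(pixels, boxes, name=Path(rel).stem))
    return samples
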