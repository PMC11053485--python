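"""Seeded synthetic canopy scenes with ground-truth biomass labels.

Real biomass plot imagery consists of green vegetation (foliage, stems) and —
for fruiting crops — red fruit over a brown soil background, with heavy
occlusion, photographed top-down, and one positive continuous mass label per
plot.  The generator emulates exactly that statistical structure at minimal
visual fidelity: each scene scatters a few "plants" made of overlapping green
elliptical foliage blobs, paints red fruit ellipses on top, and defines the
label as a linear function of the *visible* vegetation and fruit pixel
counts plus Gaussian noise:

    biomass = a_veg · (#foliage px) + a_fruit · (#fruit px) + N(0, σ²),

floored at ``label_floor``.  Coverage fractions are drawn from a right-skewed
Beta distribution, so the label distribution is continuous and imbalanced —
the regime the contrastive regression loss is designed for.  Defaults put
labels in roughly 500–4000 g, the scale of fruit-plus-stem masses of field
plots whose reported errors are a few hundred grams.

The on-disk layout is the one the loaders expect for real data too:
PNG images + a CSV manifest (filename, biomass, split) + a JSON params
sidecar.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .scdr import RegressionSample

logger = logging.getLogger("bioumixer")

SOIL, FOLIAGE, FRUIT = 0, 1, 2


@dataclass
class SceneParams:
    image_size: int = 64
    n_plants: tuple = (2, 6)                 # inclusive integer range
    foliage_coverage: tuple = (0.05, 0.65)   # fraction of the frame
    coverage_beta: tuple = (1.8, 3.5)        # right-skew of the coverage draw
    fruit_count: tuple = (0, 5)              # per plant
    a_veg: float = 1.3                       # grams per visible foliage pixel
    a_fruit: float = 2.5                     # grams per visible fruit pixel
    noise_sigma: float = 60.0                # grams
    background: tuple = (0.45, 0.33, 0.22)   # soil RGB
    label_floor: float = 1.0                 # grams

    def __post_init__(self):
        if self.image_size < 8:
            raise ValueError("degenerate image size")
        if self.a_veg < 0 or self.a_fruit < 0:
            raise ValueError("pixel-mass coefficients must be >= 0")
        if self.label_floor <= 0:
            raise ValueError("label_floor must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class DatasetManifest:
    frame: pd.DataFrame            # columns: filename, biomass, split
    params: SceneParams
    seed: int

    def rows(self, split: str | None = None) -> pd.DataFrame:
        if split is None:
            return self.frame
        return self.frame[self.frame["split"] == split].reset_index(drop=True)


def _ellipse_mask(size: int, cy, cx, ry, rx, rng) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def render_scene(params: SceneParams, rng_seed: int, return_layers: bool = False):
    """Render one canopy scene; returns ``(image H×W×3 in [0,1], biomass)``.

    With ``return_layers=True`` also returns the per-pixel class map
    (soil / foliage / fruit) the label was computed from.
    """
    rng = np.random.default_rng(rng_seed)
    size = params.image_size
    # soil background with mild texture
    img = np.empty((size, size, 3))
    base = np.asarray(params.background)
    img[:] = base
    img += rng.normal(0, 0.02, size=(size, size, 1))
    classes = np.full((size, size), SOIL, dtype=np.int8)

    target_cov = rng.beta(*params.coverage_beta) \
        * (params.foliage_coverage[1] - params.foliage_coverage[0]) + params.foliage_coverage[0]
    n_plants = int(rng.integers(params.n_plants[0], params.n_plants[1] + 1))
    # blob radius chosen so n_plants * blobs roughly meets the target coverage
    blob_area = target_cov * size * size / max(n_plants * 3, 1)
    r0 = max(2.0, np.sqrt(blob_area / np.pi))
    fruit_centers = []
    for _ in range(n_plants):
        cy, cx = rng.uniform(0, size, 2)
        for _ in range(3):  # overlapping foliage blobs per plant
            dy, dx = rng.normal(0, r0, 2)
            ry = r0 * rng.uniform(0.6, 1.5)
            rx = r0 * rng.uniform(0.6, 1.5)
            mask = _ellipse_mask(size, cy + dy, cx + dx, ry, rx, rng)
            classes[mask] = FOLIAGE
            shade = np.array([0.12, 0.45, 0.10]) * rng.uniform(0.7, 1.3)
            img[mask] = np.clip(shade + rng.normal(0, 0.02, 3), 0, 1)
        n_fruit = int(rng.integers(params.fruit_count[0], params.fruit_count[1] + 1))
        for _ in range(n_fruit):
            fruit_centers.append((cy + rng.normal(0, r0), cx + rng.normal(0, r0), rng))
    for fy, fx, _ in fruit_centers:
        rr = max(1.5, r0 * 0.35)
        mask = _ellipse_mask(size, fy, fx, rr * rng.uniform(0.7, 1.2), rr * rng.uniform(0.7, 1.2), rng)
        classes[mask] = FRUIT
        img[mask] = np.clip(np.array([0.75, 0.12, 0.10]) * rng.uniform(0.8, 1.2), 0, 1)

    img = np.clip(img, 0.0, 1.0)
    n_fol = int((classes == FOLIAGE).sum())
    n_fru = int((classes == FRUIT).sum())
    biomass = params.a_veg * n_fol + params.a_fruit * n_fru
    biomass += rng.normal(0, params.noise_sigma) if params.noise_sigma > 0 else 0.0
    biomass = max(float(biomass), params.label_floor)
    if return_layers:
        return img, biomass, classes
    return img, biomass


def generate_dataset(n_images: int, params: SceneParams, seed: int, out_dir) -> DatasetManifest:
    """Write ``n_images`` PNG scenes, a CSV manifest and a params sidecar.

    The train/test split is 80/20, stratified by label quartile, and the
    whole dataset is reproducible from ``seed``.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31, size=n_images)
    names, labels = [], []
    for i, s in enumerate(scene_seeds):
        img, biomass = render_scene(params, int(s))
        name = f"scene_{i:05d}.png"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(os.path.join(out_dir, name))
        names.append(name)
        labels.append(biomass)
    labels = np.asarray(labels)
    # stratified 80/20 split by label quartile
    split = np.empty(n_images, dtype=object)
    quart = np.searchsorted(np.quantile(labels, [0.25, 0.5, 0.75]), labels, side="left")
    for q in range(4):
        idx = np.flatnonzero(quart == q)
        idx = rng.permutation(idx)
        n_test = int(round(0.2 * len(idx)))
        split[idx[:n_test]] = "test"
        split[idx[n_test:]] = "train"
    frame = pd.DataFrame({"filename": names, "biomass": labels, "split": split})
    frame.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    with open(os.path.join(out_dir, "params.json"), "w") as fh:
        json.dump({"seed": seed, "n_images": n_images, "params": asdict(params)}, fh, indent=2)
    return DatasetManifest(frame=frame, params=params, seed=seed)


def load_dataset(manifest_path, images_dir=None, split: str | None = None,
                 filename_column: str = "filename", label_column: str = "biomass",
                 split_column: str = "split", strict: bool = False):
    """Read a manifest CSV + image folder into :class:`RegressionSample` rows.

    Column names are configurable so user-supplied folders with different
    manifests load too.  Unreadable images are skipped with a warning
    (``strict=True`` raises instead); non-numeric labels always raise.
    """
    frame = pd.read_csv(manifest_path)
    if frame.empty:
        raise ValueError(f"empty manifest: {manifest_path}")
    for col in (filename_column, label_column):
        if col not in frame.columns:
            raise ValueError(f"manifest lacks required column {col!r}")
    if split is not None and split_column in frame.columns:
        frame = frame[frame[split_column] == split]
        if frame.empty:
            raise ValueError(f"no rows with split {split!r}")
    if images_dir is None:
        images_dir = os.path.dirname(os.fspath(manifest_path))
    samples = []
    for _, row in frame.iterrows():
        label = float(row[label_column])  # raises on non-numeric labels
        path = os.path.join(images_dir, str(row[filename_column]))
        try:
            with Image.open(path) as im:
                img = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
        except (OSError, FileNotFoundError) as exc:
            if strict:
                raise
            logger.warning("skipping unreadable image %s (%s)", path, exc)
            continue
        samples.append(RegressionSample(image=img, label=label, name=str(row[filename_column])))
    if not samples:
        raise ValueError("no readable samples in manifest")
    return samples
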