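"""Blur degradation, corpus splitting and synthetic face fixtures.

The evaluation protocol degrades clean photographs with a 5x5 Gaussian
blur and trains/tests on a 70/30 split.  Because the clinical face
datasets are external, a deterministic fixture generator produces
face-like test images — a skin-tone ellipse with darker contour strokes
(jaw, eyes, nose, mouth) and small high-contrast "acne" blobs — along
with ground-truth contour and acne masks, so every stage of the
framework is trainable and testable offline.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .cat import CatParams, GaussianKernelSpec, make_gaussian_kernel, run_cat
from .exceptions import CatDeblurError, PlacementError, SizeError


@dataclass(frozen=True)
class BlurSpec:
    """Gaussian degradation: 5x5 kernel by default, sigma in pixels."""

    kernel_size: int = 5
    sigma: float = 1.0

    def __post_init__(self):
        GaussianKernelSpec(self.kernel_size, self.sigma)  # validates


@dataclass(frozen=True)
class DatasetSplit:
    train_paths: tuple
    test_paths: tuple
    train_fraction: float
    seed: int


@dataclass(frozen=True)
class FaceFixtureSpec:
    image_size: int = 64
    n_acne: int = 6
    skin_tone: tuple = (224, 172, 140)
    acne_contrast: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise CatDeblurError("image_size must be >= 32")
        if self.n_acne < 0:
            raise CatDeblurError("n_acne must be >= 0")


def gaussian_blur(img: np.ndarray, spec: BlurSpec | None = None) -> np.ndarray:
    """Blur each channel with the shared normalized Gaussian kernel."""
    spec = spec or BlurSpec()
    img = np.asarray(img, dtype=np.float64)
    if spec.kernel_size > min(img.shape[:2]):
        raise SizeError(f"kernel side {spec.kernel_size} exceeds image extent {img.shape[:2]}")
    kernel = make_gaussian_kernel(GaussianKernelSpec(spec.kernel_size, spec.sigma))
    if img.ndim == 2:
        return ndimage.correlate(img, kernel, mode="mirror")
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[:, :, c] = ndimage.correlate(img[:, :, c], kernel, mode="mirror")
    return out


def split_dataset(paths, train_fraction: float, seed: int) -> DatasetSplit:
    """Seeded shuffle then partition with |train| = round(f * N), half-up."""
    paths = list(paths)
    if not paths:
        raise CatDeblurError("cannot split an empty corpus")
    if not 0 < train_fraction < 1:
        raise CatDeblurError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(paths))
    n_train = int(np.floor(train_fraction * len(paths) + 0.5))
    train = tuple(paths[i] for i in order[:n_train])
    test = tuple(paths[i] for i in order[n_train:])
    return DatasetSplit(train, test, train_fraction, seed)


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.ellipse(center[0], center[1], radii[0], radii[1], shape=shape)
    mask[rr, cc] = True
    return mask


def generate_face_fixture(spec: FaceFixtureSpec):
    """Deterministic face-like image plus ground-truth contour/acne masks.

    Returns ``(clean, contour_mask, acne_mask)`` where ``clean`` is an
    HxWx3 float array in [0, 255] and the masks are boolean HxW arrays.
    """
    rng = np.random.default_rng(spec.seed)
    S = spec.image_size
    img = np.zeros((S, S, 3), dtype=np.float64)

    bg = np.array([72.0, 80.0, 96.0]) + rng.uniform(-8, 8, size=3)
    img[:] = bg

    cy = S / 2 + rng.uniform(-0.02, 0.02) * S
    cx = S / 2 + rng.uniform(-0.02, 0.02) * S
    ry = (0.40 + rng.uniform(-0.02, 0.02)) * S
    rx = (0.31 + rng.uniform(-0.02, 0.02)) * S
    face = _ellipse_mask((S, S), (cy, cx), (ry, rx))

    skin = np.clip(np.asarray(spec.skin_tone, dtype=np.float64) + rng.uniform(-8, 8, size=3), 0, 255)
    img[face] = skin
    # mild vertical shading so the face is not perfectly flat
    shade = np.broadcast_to(1.0 + 0.06 * (np.linspace(-1, 1, S)[:, None] - 0.1), (S, S))
    img[face] = np.clip(img[face] * shade[face][:, None], 0, 255)

    contour = np.zeros((S, S), dtype=bool)

    def _perimeter(c0, c1, r0, r1):
        rr, cc = skdraw.ellipse_perimeter(int(round(c0)), int(round(c1)),
                                          int(round(r0)), int(round(r1)), shape=(S, S))
        contour[rr, cc] = True

    _perimeter(cy, cx, ry, rx)                                  # jaw / face outline
    eye_dy, eye_dx = 0.16 * S, 0.14 * S
    for sgn in (-1, 1):
        _perimeter(cy - eye_dy, cx + sgn * eye_dx, 0.035 * S, 0.06 * S)
    rr, cc = skdraw.line(int(cy - 0.06 * S), int(cx), int(cy + 0.10 * S), int(cx))
    contour[rr, cc] = True                                      # nose
    rr, cc = skdraw.ellipse_perimeter(int(cy + 0.20 * S), int(cx),
                                      int(0.045 * S), int(0.13 * S), shape=(S, S))
    mouth = (rr >= int(cy + 0.20 * S))
    contour[rr[mouth], cc[mouth]] = True                        # lower lip arc
    contour = ndimage.binary_dilation(contour, iterations=1)
    stroke = np.clip(skin * 0.45, 0, 255)
    img[contour] = stroke

    acne_mask = np.zeros((S, S), dtype=bool)
    inner = _ellipse_mask((S, S), (cy, cx), (0.78 * ry, 0.78 * rx)) & ~contour
    r_max = max(1, S // 28)
    for _ in range(spec.n_acne):
        placed = False
        for _attempt in range(60):
            ay = rng.uniform(cy - 0.8 * ry, cy + 0.8 * ry)
            ax = rng.uniform(cx - 0.8 * rx, cx + 0.8 * rx)
            ar = rng.integers(1, r_max + 1)
            rr, cc = skdraw.disk((ay, ax), ar + 0.5, shape=(S, S))
            cand = np.zeros((S, S), dtype=bool)
            cand[rr, cc] = True
            # keep blobs inside the inner face region and separated, so the
            # acne mask's connected components equal n_acne exactly
            grown = ndimage.binary_dilation(cand, iterations=2)
            if cand.any() and not (cand & ~inner).any() and not (grown & acne_mask).any():
                acne_mask |= cand
                shift = np.array([spec.acne_contrast, -0.5 * spec.acne_contrast,
                                  -0.5 * spec.acne_contrast])
                img[cand] = np.clip(img[cand] + shift, 0, 255)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {spec.n_acne} acne blobs inside the face ellipse")
    return img, contour, acne_mask


@dataclass(frozen=True)
class PairedSample:
    blurred: np.ndarray
    clean: np.ndarray
    sketch: np.ndarray      # CAT sketch of the clean image (deblurrer target)


def build_paired_corpus(spec: FaceFixtureSpec, n_images: int,
                        blur: BlurSpec | None = None,
                        cat_params: CatParams | None = None):
    """Generate ``n_images`` (blurred, clean, clean-CAT-sketch) triples.

    Fixture ``i`` uses seed ``spec.seed + i`` so the corpus is fully
    reproducible and any slice of it is stable.
    """
    if n_images < 1:
        raise CatDeblurError("n_images must be >= 1")
    blur = blur or BlurSpec()
    cat_params = cat_params or CatParams()
    out = []
    for i in range(n_images):
        clean, _, _ = generate_face_fixture(replace(spec, seed=spec.seed + i))
        out.append(PairedSample(
            blurred=gaussian_blur(clean, blur),
            clean=clean,
            sketch=run_cat(clean, cat_params),
        ))
    return out


def save_corpus(samples, root) -> None:
    """Write a paired corpus as ``{root}/{clean,blurred,sketch}/NNN.png``."""
    from .imageio import save_image

    root = Path(root)
    for sub in ("clean", "blurred", "sketch"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    stems = []
    for i, s in enumerate(samples):
        stem = f"{i:04d}"
        stems.append(stem)
        save_image(root / "clean" / f"{stem}.png", s.clean)
        save_image(root / "blurred" / f"{stem}.png", s.blurred)
        save_image(root / "sketch" / f"{stem}.png", s.sketch)
    (root / "manifest.json").write_text(json.dumps({"stems": stems}, indent=2))


def load_corpus(root):
    from .imageio import load_image

    root = Path(root)
    stems = json.loads((root / "manifest.json").read_text())["stems"]
    return [PairedSample(
        blurred=load_image(root / "blurred" / f"{stem}.png").astype(np.float64),
        clean=load_image(root / "clean" / f"{stem}.png").astype(np.float64),
        sketch=load_image(root / "sketch" / f"{stem}.png").astype(np.float64),
    ) for stem in stems]
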