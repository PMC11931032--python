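"""Image-quality metric battery.

Referential metrics (SSIM, PSNR, AE) compare a candidate image to its
clean reference; distributional/no-reference metrics (FID, IS, BRISQUE,
NIQE) need either a feature extractor or a fitted natural-statistics
model.  Because the canonical Inception backbone and the released
BRISQUE/NIQE models are trained artifacts that cannot be shipped here,
the defaults are deterministic, self-contained stand-ins:

* FID/IS use a seeded random-projection feature extractor over intensity
  and Laplacian (sharpness) channels — scores are therefore comparable
  only between corpora evaluated with the same extractor configuration;
* BRISQUE/NIQE use the standard MSCN/AGGD feature constructions their
  names denote, scored against Gaussian models fitted on a clean corpus
  via :func:`fit_brisque_model` / :func:`fit_niqe_model`.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, ndimage, special
from skimage import metrics as skmetrics
from skimage import transform as sktransform

from .cat import to_grayscale
from .exceptions import CatDeblurError, ShapeError, SizeError

TABLE_METRICS = ("niqe", "brisque", "diqa_srcc", "diqa_plcc",
                 "ssim", "psnr", "ae", "fid", "is")


# ---------------------------------------------------------------------
# referential metrics
# ---------------------------------------------------------------------

def _check_same_shape(x, y):
    if np.shape(x) != np.shape(y):
        raise ShapeError(f"shape mismatch: {np.shape(x)} vs {np.shape(y)}")


def ssim(x: np.ndarray, y: np.ndarray) -> float:
    """Windowed SSIM (11x11 Gaussian, sigma 1.5, K1=0.01, K2=0.03, L=255).

    Color images are scored as the mean of per-channel SSIM.
    """
    _check_same_shape(x, y)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    kwargs = dict(data_range=255.0, gaussian_weights=True, sigma=1.5,
                  use_sample_covariance=False, K1=0.01, K2=0.03)
    if x.ndim == 3:
        kwargs["channel_axis"] = -1
    return float(skmetrics.structural_similarity(x, y, **kwargs))


def psnr(x: np.ndarray, y: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB w.r.t. the 255 peak; inf if identical."""
    _check_same_shape(x, y)
    mse = float(np.mean((np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)) ** 2))
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(255.0 ** 2 / mse)


def ae(x: np.ndarray, y: np.ndarray) -> float:
    """Average absolute pixel error on the [0, 255] scale."""
    _check_same_shape(x, y)
    return float(np.mean(np.abs(np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64))))


# ---------------------------------------------------------------------
# feature extractor for FID / IS
# ---------------------------------------------------------------------

@dataclass
class RandomProjectionExtractor:
    """Deterministic feature embedding: seeded Gaussian projection of
    per-image-standardized intensity + Laplacian channels.

    The classifier head for the Inception-score analogue is a second
    fixed projection followed by a temperature softmax, so blurrier
    images (weaker Laplacian responses) yield flatter, less diverse
    label distributions.
    """

    name: str = "random-projection"
    dim: int = 48
    image_size: int = 32
    n_classes: int = 10
    temperature: float = 3.0
    seed: int = 20240101
    deterministic: bool = True
    source: str = "builtin-projection"

    def __post_init__(self):
        if self.dim < 2:
            raise CatDeblurError("feature dimension must be >= 2")
        rng = np.random.default_rng(self.seed)
        n_in = 2 * self.image_size ** 2
        self._proj = rng.standard_normal((self.dim, n_in)) / np.sqrt(n_in)
        self._head = rng.standard_normal((self.n_classes, self.dim)) / np.sqrt(self.dim)

    def _vector(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=np.float64)
        gray = to_grayscale(img) if img.ndim == 3 else img
        g = sktransform.resize(gray / 255.0, (self.image_size, self.image_size),
                               anti_aliasing=True)
        lap = ndimage.laplace(g)
        v = np.concatenate([g.ravel(), 4.0 * lap.ravel()])
        return (v - v.mean()) / (v.std() + 1e-8)

    def features(self, img: np.ndarray) -> np.ndarray:
        return self._proj @ self._vector(img)

    def predict_proba(self, img: np.ndarray) -> np.ndarray:
        z = self.temperature * (self._head @ self.features(img))
        z -= z.max()
        p = np.exp(z)
        return p / p.sum()


def _feature_matrix(images, fx) -> np.ndarray:
    feats = np.stack([fx.features(im) for im in images])
    return feats


def fid_from_features(f1: np.ndarray, f2: np.ndarray, eps: float = 1e-6) -> float:
    """Frechet distance between Gaussian fits of two feature clouds."""
    f1 = np.atleast_2d(np.asarray(f1, dtype=np.float64))
    f2 = np.atleast_2d(np.asarray(f2, dtype=np.float64))
    mu1, mu2 = f1.mean(0), f2.mean(0)
    s1 = np.cov(f1, rowvar=False) + eps * np.eye(f1.shape[1])
    s2 = np.cov(f2, rowvar=False) + eps * np.eye(f2.shape[1])
    covmean = linalg.sqrtm(s1 @ s2)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    d2 = float(np.sum((mu1 - mu2) ** 2) + np.trace(s1 + s2 - 2.0 * covmean))
    return max(d2, 0.0)


def fid(real_images, fake_images, fx: RandomProjectionExtractor | None = None) -> float:
    if not len(real_images) or not len(fake_images):
        raise CatDeblurError("FID needs non-empty corpora")
    fx = fx or RandomProjectionExtractor()
    return fid_from_features(_feature_matrix(real_images, fx),
                             _feature_matrix(fake_images, fx))


@dataclass(frozen=True)
class InceptionScoreResult:
    mean: float
    sd: float

    def __float__(self):
        return self.mean


def inception_score(images, classifier=None, n_splits: int = 10) -> InceptionScoreResult:
    """exp(mean KL(p(y|x) || p(y))) computed over sequential splits."""
    classifier = classifier or RandomProjectionExtractor()
    probs = np.stack([classifier.predict_proba(im) for im in images])
    if np.any(probs < 0) or not np.allclose(probs.sum(1), 1.0, atol=1e-6):
        raise CatDeblurError("classifier must emit probability vectors")
    n = probs.shape[0]
    n_splits = max(1, min(n_splits, n))
    scores = []
    for chunk in np.array_split(probs, n_splits):
        marginal = chunk.mean(0)
        logs = np.log(chunk, out=np.zeros_like(chunk), where=chunk > 0)
        kl = np.where(chunk > 0, chunk * (logs - np.log(marginal)), 0.0).sum(1)
        scores.append(float(np.exp(kl.mean())))
    return InceptionScoreResult(float(np.mean(scores)), float(np.std(scores)))


# ---------------------------------------------------------------------
# MSCN / AGGD machinery shared by BRISQUE and NIQE
# ---------------------------------------------------------------------

def _gauss_window(size: int = 7, sigma: float = 7.0 / 6.0) -> np.ndarray:
    r = size // 2
    ax = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    k /= k.sum()
    return np.outer(k, k)


def mscn_coefficients(gray: np.ndarray, window: int = 7, c: float = 1.0) -> np.ndarray:
    """Mean-subtracted contrast-normalized coefficients (I - mu)/(sigma + C)."""
    gray = np.asarray(gray, dtype=np.float64)
    if min(gray.shape) < window:
        raise SizeError(f"image {gray.shape} smaller than the {window}x{window} window")
    w = _gauss_window(window)
    mu = ndimage.correlate(gray, w, mode="mirror")
    sigma = np.sqrt(np.clip(ndimage.correlate(gray * gray, w, mode="mirror") - mu * mu, 0, None))
    return (gray - mu) / (sigma + c)


_ALPHAS = np.arange(0.2, 10.001, 0.001)
_RHO = (special.gamma(2.0 / _ALPHAS) ** 2 /
        (special.gamma(1.0 / _ALPHAS) * special.gamma(3.0 / _ALPHAS)))


def _fit_ggd(x: np.ndarray):
    """Moment-matched generalized Gaussian: returns (alpha, sigma^2)."""
    x = x.ravel()
    var = float(np.mean(x * x)) + 1e-12
    rho = float(np.mean(np.abs(x))) ** 2 / var
    alpha = float(_ALPHAS[np.argmin((_RHO - rho) ** 2)])
    return alpha, var


def _fit_aggd(x: np.ndarray):
    """Asymmetric GGD moment fit: returns (alpha, eta, sigma_l^2, sigma_r^2)."""
    x = x.ravel()
    left = x[x < 0]
    right = x[x >= 0]
    sl2 = float(np.mean(left ** 2)) if left.size else 1e-12
    sr2 = float(np.mean(right ** 2)) if right.size else 1e-12
    gamma_hat = math.sqrt(sl2 / (sr2 + 1e-12) + 1e-12)
    r_hat = float(np.mean(np.abs(x))) ** 2 / (float(np.mean(x * x)) + 1e-12)
    R_hat = r_hat * (gamma_hat ** 3 + 1) * (gamma_hat + 1) / (gamma_hat ** 2 + 1) ** 2
    alpha = float(_ALPHAS[np.argmin((_RHO - R_hat) ** 2)])
    g1, g2, g3 = special.gamma(1.0 / alpha), special.gamma(2.0 / alpha), special.gamma(3.0 / alpha)
    eta = (math.sqrt(sr2) - math.sqrt(sl2)) * (g2 / g1) * math.sqrt(g1 / g3)
    return alpha, eta, sl2, sr2


_SHIFTS = ((0, 1), (1, 0), (1, 1), (1, -1))   # H, V, D1, D2 neighbor products


def _natural_scene_features(gray: np.ndarray) -> np.ndarray:
    """18 features per scale: GGD of MSCN + AGGD of 4 neighbor products."""
    mscn = mscn_coefficients(gray)
    feats = list(_fit_ggd(mscn))
    for dy, dx in _SHIFTS:
        prod = mscn * np.roll(np.roll(mscn, dy, axis=0), dx, axis=1)
        feats.extend(_fit_aggd(prod))
    return np.asarray(feats, dtype=np.float64)


def brisque_features(gray: np.ndarray) -> np.ndarray:
    """36-dim BRISQUE feature vector (18 features at two scales)."""
    gray = np.asarray(gray, dtype=np.float64)
    half = sktransform.rescale(gray, 0.5, anti_aliasing=True)
    return np.concatenate([_natural_scene_features(gray),
                           _natural_scene_features(half)])


@dataclass
class GaussianIQAModel:
    """Multivariate Gaussian of natural-scene features; the score of an
    observation is its Mahalanobis distance to the model."""

    mean: np.ndarray
    cov: np.ndarray
    kind: str = "brisque"

    def score_features(self, f: np.ndarray, cov2: np.ndarray | None = None) -> float:
        cov = self.cov if cov2 is None else (self.cov + cov2) / 2.0
        cov = cov + 1e-6 * np.eye(cov.shape[0])
        d = f - self.mean
        return float(math.sqrt(max(float(d @ np.linalg.pinv(cov) @ d), 0.0)))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"kind": self.kind, "mean": self.mean.tolist(), "cov": self.cov.tolist()}))

    @classmethod
    def from_json(cls, path) -> "GaussianIQAModel":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["mean"]), np.asarray(d["cov"]), d["kind"])


def fit_brisque_model(grays) -> GaussianIQAModel:
    feats = np.stack([brisque_features(g) for g in grays])
    return GaussianIQAModel(feats.mean(0), np.cov(feats, rowvar=False), "brisque")


def brisque_score(gray: np.ndarray, model: GaussianIQAModel) -> float:
    if model is None:
        raise CatDeblurError("a BRISQUE score model is required")
    return model.score_features(brisque_features(gray))


def _niqe_patches(gray: np.ndarray, patch: int) -> np.ndarray:
    """Per-patch 36-dim features (18 per scale) on aligned patch grids."""
    gray = np.asarray(gray, dtype=np.float64)
    if min(gray.shape) < 2 * patch:
        raise SizeError("image too small for NIQE patch analysis")
    half = sktransform.rescale(gray, 0.5, anti_aliasing=True)
    mscn1 = mscn_coefficients(gray)
    mscn2 = mscn_coefficients(half)
    ny, nx = gray.shape[0] // patch, gray.shape[1] // patch
    rows = []
    for iy in range(ny):
        for ix in range(nx):
            p1 = mscn1[iy * patch:(iy + 1) * patch, ix * patch:(ix + 1) * patch]
            h = patch // 2
            p2 = mscn2[iy * h:(iy + 1) * h, ix * h:(ix + 1) * h]
            f1 = [*_fit_ggd(p1)]
            for dy, dx in _SHIFTS:
                f1.extend(_fit_aggd(p1 * np.roll(np.roll(p1, dy, axis=0), dx, axis=1)))
            f2 = [*_fit_ggd(p2)]
            for dy, dx in _SHIFTS:
                f2.extend(_fit_aggd(p2 * np.roll(np.roll(p2, dy, axis=0), dx, axis=1)))
            rows.append(np.asarray(f1 + f2))
    return np.stack(rows)


def fit_niqe_model(grays, patch: int = 16) -> GaussianIQAModel:
    feats = np.concatenate([_niqe_patches(g, patch) for g in grays])
    model = GaussianIQAModel(feats.mean(0), np.cov(feats, rowvar=False), "niqe")
    model.patch = patch
    return model


def niqe_score(gray: np.ndarray, model: GaussianIQAModel) -> float:
    """Distance between the image's patch-feature Gaussian and the reference."""
    if model is None:
        raise CatDeblurError("a NIQE reference model is required")
    patch = getattr(model, "patch", 16)
    feats = _niqe_patches(gray, patch)
    mu = feats.mean(0)
    cov = np.cov(feats, rowvar=False) if feats.shape[0] > 1 else np.zeros_like(model.cov)
    d = mu - model.mean
    sigma = (model.cov + cov) / 2.0 + 1e-6 * np.eye(model.cov.shape[0])
    return float(math.sqrt(max(float(d @ np.linalg.pinv(sigma) @ d), 0.0)))


# ---------------------------------------------------------------------
# corpus-level evaluation
# ---------------------------------------------------------------------

@dataclass
class MetricReport:
    per_image: pd.DataFrame
    corpus_level: dict
    config: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """One value per Table-style metric row (None when not computed)."""
        out = {m: None for m in TABLE_METRICS}
        for m in ("ssim", "psnr", "ae", "brisque", "niqe"):
            if m in self.per_image:
                col = self.per_image[m].astype(float)
                out[m] = float(col.mean())
        out["fid"] = self.corpus_level.get("fid")
        out["is"] = self.corpus_level.get("inception_score")
        return out

    def to_json(self, path) -> None:
        payload = {"per_image": self.per_image.to_dict(orient="records"),
                   "corpus_level": self.corpus_level, "config": self.config,
                   "summary": self.summary()}
        Path(path).write_text(json.dumps(payload, indent=2, default=float))

    def to_csv(self, path) -> None:
        self.per_image.to_csv(path, index=False)


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    return to_grayscale(img) if img.ndim == 3 else img


def evaluate_corpus(candidates, references=None, ids=None,
                    extractor: RandomProjectionExtractor | None = None,
                    brisque_model: GaussianIQAModel | None = None,
                    niqe_model: GaussianIQAModel | None = None,
                    n_is_splits: int = 4, config: dict | None = None) -> MetricReport:
    """Compute all applicable metrics for a corpus of candidate images.

    Referential metrics need ``references`` (paired, same order); FID
    compares the candidate corpus against the reference corpus; BRISQUE
    and NIQE are computed only when their fitted models are supplied.
    Per-metric failures are recorded in the report, never fatal.
    """
    candidates = list(candidates)
    ids = list(ids) if ids is not None else [f"{i:04d}" for i in range(len(candidates))]
    extractor = extractor or RandomProjectionExtractor()
    rows, errors = [], {}
    for i, cand in enumerate(candidates):
        row = {"id": ids[i]}
        if references is not None:
            ref = references[i]
            for name, fn in (("ssim", ssim), ("psnr", psnr), ("ae", ae)):
                try:
                    row[name] = fn(cand, ref)
                except CatDeblurError as exc:   # pragma: no cover - defensive
                    errors[f"{name}:{ids[i]}"] = str(exc)
        gray = _as_gray(cand)
        if brisque_model is not None:
            try:
                row["brisque"] = brisque_score(gray, brisque_model)
            except CatDeblurError as exc:
                errors[f"brisque:{ids[i]}"] = str(exc)
        if niqe_model is not None:
            try:
                row["niqe"] = niqe_score(gray, niqe_model)
            except CatDeblurError as exc:
                errors[f"niqe:{ids[i]}"] = str(exc)
        rows.append(row)

    corpus = {}
    if references is not None:
        try:
            corpus["fid"] = fid(list(references), candidates, extractor)
        except CatDeblurError as exc:
            errors["fid"] = str(exc)
    try:
        is_res = inception_score(candidates, extractor, n_splits=n_is_splits)
        corpus["inception_score"] = is_res.mean
        corpus["inception_score_sd"] = is_res.sd
    except CatDeblurError as exc:
        errors["inception_score"] = str(exc)
    if errors:
        corpus["errors"] = errors
    return MetricReport(pd.DataFrame(rows), corpus, dict(config or {}))
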