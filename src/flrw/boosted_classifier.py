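"""AdaBoost ensemble of RBF-SVM weak learners and per-pixel liver probability.

Training protocol
-----------------
Samples are drawn from three regions of each training slice — inside the
liver (eroded by the edge band), outside it (background eroded by the same
band), and the symmetric band around the boundary — with labels +1 / -1
taken from the mask.  Raw window features are fused by PCA, then boosted:

- weights start uniform, w_n = 1/N;
- each cycle trains an RBF-SVM on a weight-proportional bootstrap resample
  (how sample weights enter the weak learner is a free choice; resampling
  works with any SVM trainer and is seed-controlled);
- the kernel width sigma decreases geometrically across cycles,
  sigma_t = sigma_0 * rho^(t-1), with sigma_0 defaulting to the median
  pairwise training distance;
- the weighted error e_t = sum of weights of misclassified samples gives
  alpha_t = 0.5 ln((1 - e_t)/e_t); weights update
  w <- w * exp(-alpha_t * l_n * h_t(y_n)) and renormalize to sum 1;
- e_t >= 1/2 clamps alpha_t to 0 and resets the weights to uniform;
  e_t = 0 clamps alpha_t to a large finite constant (ALPHA_MAX).

The ensemble margin C(y) = sum_t alpha_t h_t(y) (h_t the hard +-1 vote) is
mapped to a probability through the logistic p = e^C / (1 + e^C); applying
this to every pixel of a slice yields the probability image.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.special import expit
from sklearn.svm import SVC

from . import texture_features as tf
from .errors import ConfigError, FormatError, IOError_
from .feature_fusion import FusionModel, fit_pca, project
from .image_io import ImageGrid, LabelMask

__all__ = [
    "TrainingSet",
    "PixelSample",
    "EnsembleModel",
    "ProbabilityMap",
    "sample_training_pixels",
    "collect_training_features",
    "train_adaboost_svm",
    "train_flrw_model",
    "ensemble_score",
    "class_probability",
    "probability_image",
    "save_model",
    "load_model",
    "ALPHA_MAX",
]

ALPHA_MAX = 10.0
_MODEL_MAGIC = "flrw-model"
_MODEL_VERSION = 1

REGION_INSIDE = "inside"
REGION_OUTSIDE = "outside"
REGION_EDGE = "edge"


@dataclass
class PixelSample:
    """Pixel coordinates with labels and region provenance for one slice."""

    coords: np.ndarray  # (n, 2) row/col indices
    labels: np.ndarray  # (n,) in {-1, +1}
    regions: np.ndarray  # (n,) strings from {inside, outside, edge}


@dataclass
class TrainingSet:
    """Feature table with labels and per-sample region provenance."""

    X: np.ndarray  # (n, D)
    labels: np.ndarray  # (n,) in {-1, +1}
    regions: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if not np.all(np.isin(lab, (-1, 1))):
            raise ConfigError("labels must be in {-1, +1}")
        if len(np.unique(lab)) < 2:
            raise ConfigError("both classes must be present")


@dataclass
class WeakLearner:
    svc: SVC
    alpha: float
    sigma: float

    def decide(self, Y: np.ndarray) -> np.ndarray:
        """Hard +-1 vote, identical to ``svc.predict`` but BLAS-batched."""
        return _svc_hard_vote(self.svc, Y)


@dataclass
class EnsembleModel:
    learners: list
    fusion: FusionModel | None
    feature_spec: tf.FeatureWindowSpec | None
    training_history: dict = field(default_factory=dict)

    @property
    def alphas(self):
        return np.array([wl.alpha for wl in self.learners])

    @property
    def sigmas(self):
        return np.array([wl.sigma for wl in self.learners])


@dataclass
class ProbabilityMap:
    """Per-pixel liver likelihood p(l=1|x) on an image's grid."""

    values: np.ndarray
    spacing: tuple = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ConfigError("probabilities must lie in [0, 1]")
        if self.spacing is None:
            self.spacing = (1.0,) * self.values.ndim
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.values.shape


# ---------------------------------------------------------------------------
# Training-sample selection
# ---------------------------------------------------------------------------

def _disk(radius: int, ndim: int = 2) -> np.ndarray:
    if radius <= 0:
        out = np.zeros((1,) * ndim, dtype=bool)
        out[(0,) * ndim] = True
        return out
    grids = np.ogrid[tuple(slice(-radius, radius + 1) for _ in range(ndim))]
    return sum(g**2 for g in grids) <= radius**2


def sample_training_pixels(
    image: ImageGrid | np.ndarray,
    mask: LabelMask | np.ndarray,
    n_per_region: int = 7000,
    edge_band: int = 3,
    rng_seed: int | np.random.Generator = 0,
) -> PixelSample:
    """Draw training pixels from the interior, exterior, and boundary band.

    ``n_per_region`` pixels are drawn uniformly without replacement from
    (a) the mask interior eroded by ``edge_band``, (b) the background eroded
    by the same band, and (c) the symmetric band within ``edge_band`` of the
    boundary.  Regions smaller than the request are used whole, with a
    warning.  Deterministic for a fixed seed.
    """
    from scipy import ndimage
    import warnings

    m = mask.as_bool() if isinstance(mask, LabelMask) else np.asarray(mask, dtype=bool)
    img = image.values if isinstance(image, ImageGrid) else np.asarray(image)
    if img.shape != m.shape:
        raise ConfigError("image and mask shapes differ")
    if not m.any() or m.all():
        raise ConfigError("mask must be nonempty and not cover the whole image")
    if edge_band < 1:
        raise ConfigError("edge_band must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    selem = _disk(edge_band, m.ndim)
    # border_value=1: beyond-grid voxels count as belonging to the region,
    # so the image frame is not mistaken for the boundary band
    interior = ndimage.binary_erosion(m, structure=selem, border_value=1)
    exterior = ndimage.binary_erosion(~m, structure=selem, border_value=1)
    band = ~interior & ~exterior

    coords, labels, regions = [], [], []
    for name, region in (
        (REGION_INSIDE, interior),
        (REGION_OUTSIDE, exterior),
        (REGION_EDGE, band),
    ):
        idx = np.argwhere(region)
        n = min(n_per_region, idx.shape[0])
        if n < n_per_region:
            warnings.warn(
                f"region {name!r} has only {idx.shape[0]} pixels; capping at that",
                stacklevel=2,
            )
        if n == 0:
            continue
        pick = rng.choice(idx.shape[0], size=n, replace=False)
        chosen = idx[np.sort(pick)]
        coords.append(chosen)
        labels.append(np.where(m[tuple(chosen.T)], 1, -1))
        regions.append(np.full(n, name))
    return PixelSample(
        coords=np.concatenate(coords),
        labels=np.concatenate(labels).astype(np.int64),
        regions=np.concatenate(regions),
    )


def collect_training_features(
    images,
    masks,
    spec: tf.FeatureWindowSpec,
    n_per_region: int = 7000,
    edge_band: int = 3,
    seed: int = 0,
    dtype=np.float32,
):
    """Raw feature table over sampled pixels of several training slices.

    Returns (F, labels, regions) with F of shape (n_total, n_features).
    """
    rng = np.random.default_rng(seed)
    tables, labs, regs = [], [], []
    for image, mask in zip(images, masks):
        img = image.values if isinstance(image, ImageGrid) else np.asarray(image)
        if img.ndim != 2:
            raise ConfigError("training slices must be 2-D")
        sample = sample_training_pixels(img, mask, n_per_region, edge_band, rng)
        maps = tf.feature_maps(img, spec)
        flat = maps.reshape(maps.shape[0], -1)
        lin = sample.coords[:, 0] * img.shape[1] + sample.coords[:, 1]
        tables.append(flat[:, lin].T.astype(dtype))
        labs.append(sample.labels)
        regs.append(sample.regions)
    return np.concatenate(tables), np.concatenate(labs), np.concatenate(regs)


# ---------------------------------------------------------------------------
# AdaBoost of RBF-SVMs
# ---------------------------------------------------------------------------

def _svc_hard_vote(svc: SVC, Y: np.ndarray, chunk: int = 8192) -> np.ndarray:
    """+-1 decision of a fitted binary SVC, computed with batched kernels.

    Equivalent to ``svc.predict`` (classes are -1/+1) but evaluates the RBF
    kernel against the support vectors with dense BLAS products, chunked to
    bound memory.
    """
    Y = np.asarray(Y, dtype=np.float64)
    sv = svc.support_vectors_
    dual = svc.dual_coef_[0]
    b = svc.intercept_[0]
    gamma = svc.gamma if isinstance(svc.gamma, (int, float)) else svc._gamma
    sv_sq = (sv**2).sum(axis=1)
    out = np.empty(Y.shape[0], dtype=np.float64)
    for lo in range(0, Y.shape[0], chunk):
        block = Y[lo : lo + chunk]
        d2 = (block**2).sum(axis=1)[:, None] + sv_sq[None, :] - 2.0 * block @ sv.T
        np.maximum(d2, 0.0, out=d2)
        K = np.exp(-gamma * d2)
        out[lo : lo + chunk] = K @ dual + b
    # sign convention: positive decision value votes for classes_[1]
    pos, neg = svc.classes_[1], svc.classes_[0]
    return np.where(out > 0, pos, neg).astype(np.float64)


def _median_pairwise_distance(X: np.ndarray, rng: np.random.Generator, cap: int = 400) -> float:
    n = X.shape[0]
    sub = X if n <= cap else X[rng.choice(n, size=cap, replace=False)]
    d = pdist(sub)
    med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return med if med > 0 else 1.0


def train_adaboost_svm(
    training_set: TrainingSet,
    T: int = 10,
    sigma_schedule=None,
    svm_C: float = 1.0,
    rho: float = 0.8,
    resample_size: int = 2000,
    rng_seed: int | np.random.Generator = 0,
) -> EnsembleModel:
    """Boost T RBF-SVM weak learners on a fused training set.

    ``sigma_schedule`` may be an explicit decreasing sequence of kernel
    widths; by default sigma_t = sigma_0 * rho^(t-1) with sigma_0 the median
    pairwise distance of the training features.
    """
    if T < 1:
        raise ConfigError("T must be >= 1")
    X = np.asarray(training_set.X, dtype=np.float64)
    y = np.asarray(training_set.labels, dtype=np.float64)
    N = X.shape[0]
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if sigma_schedule is None:
        sigma0 = _median_pairwise_distance(X, rng)
        sigma_schedule = [sigma0 * rho ** t for t in range(T)]
    sigma_schedule = list(sigma_schedule)
    if len(sigma_schedule) < T:
        raise ConfigError("sigma_schedule shorter than T")

    w = np.full(N, 1.0 / N)
    learners = []
    errors, alphas_hist, weight_sums = [], [], []
    n_sub = min(N, resample_size)
    for t in range(T):
        sigma = float(sigma_schedule[t])
        idx = rng.choice(N, size=n_sub, replace=True, p=w)
        # the resample must contain both classes for the SVM to train
        for cls in (-1.0, 1.0):
            if not np.any(y[idx] == cls):
                pool = np.flatnonzero(y == cls)
                idx[: min(5, pool.size)] = pool[np.argsort(-w[pool])[:5]]
        svc = SVC(kernel="rbf", C=svm_C, gamma=1.0 / (2.0 * sigma**2))
        svc.fit(X[idx], y[idx])
        h = _svc_hard_vote(svc, X)
        e = float(w[h != y].sum())
        if e >= 0.5:
            alpha = 0.0
            w = np.full(N, 1.0 / N)  # reset and move on
        elif e <= 0.0:
            alpha = ALPHA_MAX
        else:
            alpha = 0.5 * np.log((1.0 - e) / e)
        if e < 0.5:
            w = w * np.exp(-alpha * y * h)
            w /= w.sum()
        learners.append(WeakLearner(svc=svc, alpha=alpha, sigma=sigma))
        errors.append(e)
        alphas_hist.append(alpha)
        weight_sums.append(float(w.sum()))
    return EnsembleModel(
        learners=learners,
        fusion=None,
        feature_spec=None,
        training_history={
            "errors": errors,
            "alphas": alphas_hist,
            "weight_sums": weight_sums,
        },
    )


def adaboost_alpha(e: float) -> float:
    """Weak-learner weight alpha = 0.5 ln((1-e)/e), with the edge clamps."""
    if e >= 0.5:
        return 0.0
    if e <= 0.0:
        return ALPHA_MAX
    return 0.5 * float(np.log((1.0 - e) / e))


def ensemble_score(model: EnsembleModel, fused_vector: np.ndarray) -> np.ndarray | float:
    """Unsigned ensemble margin C(y) = sum_t alpha_t h_t(y).

    The sign of the score is the hard two-class decision; the magnitude
    feeds the logistic probability.  Accepts a single vector or a batch.
    """
    Y = np.asarray(fused_vector, dtype=np.float64)
    single = Y.ndim == 1
    if single:
        Y = Y[None, :]
    score = np.zeros(Y.shape[0])
    for wl in model.learners:
        if wl.alpha != 0.0:
            score += wl.alpha * wl.decide(Y)
    return float(score[0]) if single else score


def class_probability(score) -> np.ndarray | float:
    """Logistic map of the ensemble margin: p = e^C / (1 + e^C)."""
    p = expit(np.asarray(score, dtype=np.float64))
    return float(p) if np.isscalar(score) else p


def probability_image(model: EnsembleModel, image: ImageGrid) -> ProbabilityMap:
    """Liver-probability map of an image (3-D volumes slice by slice)."""
    if model.fusion is None or model.feature_spec is None:
        raise ConfigError("model has no fusion/feature spec attached")

    def _slice_prob(sl: np.ndarray) -> np.ndarray:
        maps = tf.feature_maps(sl, model.feature_spec)
        flat = maps.reshape(maps.shape[0], -1).T
        fused = project(model.fusion, flat)
        score = ensemble_score(model, fused)
        return class_probability(score).reshape(sl.shape)

    if image.ndim == 2:
        values = _slice_prob(image.values)
    else:
        values = np.stack([_slice_prob(sl) for sl in image.values])
    return ProbabilityMap(values=values, spacing=image.spacing)


def train_flrw_model(
    images,
    masks,
    spec: tf.FeatureWindowSpec | None = None,
    n_per_region: int = 7000,
    edge_band: int = 3,
    variance_fraction: float = 0.95,
    n_components: int | None = None,
    T: int = 10,
    rho: float = 0.8,
    sigma_schedule=None,
    svm_C: float = 1.0,
    resample_size: int = 2000,
    seed: int = 0,
) -> EnsembleModel:
    """End-to-end training: sample pixels, extract + fuse features, boost."""
    spec = spec or tf.FeatureWindowSpec()
    rng = np.random.default_rng(seed)
    F, labels, regions = collect_training_features(
        images, masks, spec, n_per_region, edge_band, seed=int(rng.integers(2**31))
    )
    fusion = fit_pca(F, variance_fraction=variance_fraction, D=n_components)
    Y = project(fusion, F)
    ts = TrainingSet(X=Y, labels=labels, regions=regions)
    model = train_adaboost_svm(
        ts,
        T=T,
        sigma_schedule=sigma_schedule,
        svm_C=svm_C,
        rho=rho,
        resample_size=resample_size,
        rng_seed=np.random.default_rng(int(rng.integers(2**31))),
    )
    model.fusion = fusion
    model.feature_spec = spec
    return model


# ---------------------------------------------------------------------------
# Model bundle I/O
# ---------------------------------------------------------------------------

def save_model(model: EnsembleModel, path: str) -> None:
    payload = {"magic": _MODEL_MAGIC, "version": _MODEL_VERSION, "model": model}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str) -> EnsembleModel:
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except FileNotFoundError as exc:
        raise IOError_(f"no such model file: {path!r}") from exc
    except Exception as exc:  # corrupted pickle
        raise FormatError(f"unreadable model file {path!r}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("magic") != _MODEL_MAGIC:
        raise FormatError(f"{path!r} is not a flrw model bundle")
    if payload.get("version") != _MODEL_VERSION:
        raise FormatError(
            f"model format version {payload.get('version')} unsupported"
        )
    return payload["model"]
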