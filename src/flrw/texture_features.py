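"""Per-pixel windowed texture descriptors: LBP, GLCM statistics, Haar, HOG.

Each pixel x of an image is described by the concatenation

    f(x) = [ f_LBP(x) ; f_GLCM(x) ; f_Haar(x) ; f_HOG(x) ]

computed over an h x w feature window centred on x.  ``extract_features``
is the per-pixel reference path; ``feature_maps`` computes the identical
vectors for every pixel of an image at once via integral images and is the
path used for training-sample collection and probability images.  The two
paths share all conventions (edge-replication padding, global-range GLCM
quantization, central-difference gradients) and are cross-checked in tests.

Descriptor conventions
----------------------
LBP   : N samples on a radius-r circle, starting at angle 0 (east) and
        proceeding counter-clockwise; bilinear interpolation at non-integer
        sample points; bit n set iff sample >= centre (ties count as 1);
        code = sum s(n) 2^n, n = 0..N-1.
GLCM  : gray levels quantized by equal-width binning of the *global* image
        range; co-occurrence counts at displacement (d, theta) symmetrized
        (both directions) and normalized to sum 1; summarized by 12
        statistics in the fixed order energy, contrast, correlation,
        homogeneity, entropy, autocorrelation, dissimilarity, cluster shade,
        cluster tendency, maximum probability, variance, sum mean
        (Haralick / Soh conventions, stated per-statistic below).
Haar  : 15 rectangle filters = 5 shapes (edge-h, edge-v, line-h, line-v,
        center-surround) at 3 centred scales (1, 1/2, 1/4 of the window);
        each feature is the area-normalized white mean minus black mean,
        evaluated with an integral image.
HOG   : gradient magnitude-weighted orientation histogram with K equal bins
        on [0, 180) degrees; gradients by central differences; normalized to
        sum 1 (zero vector when the window has no gradient mass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = [
    "FeatureWindowSpec",
    "FeatureVector",
    "lbp_code",
    "lbp_feature",
    "glcm_matrix",
    "glcm_statistics",
    "haar_features",
    "hog_feature",
    "extract_features",
    "feature_maps",
    "GLCM_STAT_NAMES",
]

GLCM_STAT_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "homogeneity",
    "entropy",
    "autocorrelation",
    "dissimilarity",
    "cluster_shade",
    "cluster_tendency",
    "maximum_probability",
    "variance",
    "sum_mean",
)

N_HAAR = 15
_HAAR_SCALES = (1.0, 0.5, 0.25)
_HAAR_SHAPES = ("edge_h", "edge_v", "line_h", "line_v", "center_surround")


@dataclass(frozen=True)
class FeatureWindowSpec:
    """Geometry and sampling parameters of the feature window.

    Defaults follow common literature choices: an 11x11 window, 8-neighbour
    radius-1 LBP, 16 GLCM levels with a single (d=1, theta=0) offset, and 9
    HOG orientation bins on [0, 180).
    """

    h: int = 11
    w: int = 11
    lbp_radius: float = 1.0
    lbp_neighbors: int = 8
    glcm_levels: int = 16
    glcm_offsets: tuple = ((1, 0.0),)  # (distance px, angle degrees)
    hog_bins: int = 9

    def __post_init__(self):
        if self.h < 3 or self.w < 3 or self.h % 2 == 0 or self.w % 2 == 0:
            raise ConfigError("window h, w must be odd and >= 3")
        if self.lbp_neighbors < 4:
            raise ConfigError("lbp_neighbors must be >= 4")
        if self.lbp_radius <= 0:
            raise ConfigError("lbp_radius must be > 0")
        if self.glcm_levels < 2:
            raise ConfigError("glcm_levels must be >= 2")
        if self.hog_bins < 2:
            raise ConfigError("hog_bins must be >= 2")
        if not self.glcm_offsets:
            raise ConfigError("at least one GLCM offset required")

    @property
    def lbp_margin(self) -> int:
        return int(math.ceil(self.lbp_radius))

    @property
    def n_features(self) -> int:
        return self.h * self.w + 12 * len(self.glcm_offsets) + N_HAAR + self.hog_bins

    def layout(self) -> dict:
        """Named spans (offset, length) of the concatenated vector."""
        n_lbp = self.h * self.w
        n_glcm = 12 * len(self.glcm_offsets)
        return {
            "lbp": (0, n_lbp),
            "glcm": (n_lbp, n_glcm),
            "haar": (n_lbp + n_glcm, N_HAAR),
            "hog": (n_lbp + n_glcm + N_HAAR, self.hog_bins),
        }


@dataclass
class FeatureVector:
    values: np.ndarray
    layout: dict

    def span(self, name: str) -> np.ndarray:
        off, length = self.layout[name]
        return self.values[off : off + length]


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

def _neighbor_offsets(r: float, N: int):
    """Sample offsets (dy, dx), counter-clockwise from angle 0 (east).

    Rows grow downward, so counter-clockwise on screen means dy = -r sin.
    Offsets within 1e-9 of an integer are snapped to avoid interpolation
    noise at the axis-aligned samples.
    """
    offs = []
    for n in range(N):
        ang = 2.0 * math.pi * n / N
        dy, dx = -r * math.sin(ang), r * math.cos(ang)
        if abs(dy - round(dy)) < 1e-9:
            dy = float(round(dy))
        if abs(dx - round(dx)) < 1e-9:
            dx = float(round(dx))
        offs.append((dy, dx))
    return offs


def lbp_code(window: np.ndarray, center_index: tuple, r: float, N: int) -> int:
    """Decimal LBP code of the pixel at ``center_index`` inside ``window``.

    Raises if the radius-r circle leaves the window (callers pad first).
    """
    window = np.asarray(window, dtype=np.float64)
    ci, cj = center_index
    H, W = window.shape
    m = math.ceil(r)
    if ci - m < 0 or cj - m < 0 or ci + m > H - 1 or cj + m > W - 1:
        raise ValueError("LBP circle exits the window; pad the image first")
    center = window[ci, cj]
    code = 0
    for n, (dy, dx) in enumerate(_neighbor_offsets(r, N)):
        # split the offset into integer cell and fraction *before* adding the
        # centre index, so interpolation weights are bit-identical to the
        # vectorized whole-image path
        y0, x0 = int(math.floor(dy)), int(math.floor(dx))
        fy, fx = dy - y0, dx - x0
        ys = (ci + y0, ci + y0 + 1 if fy > 0 else ci + y0)
        xs = (cj + x0, cj + x0 + 1 if fx > 0 else cj + x0)
        sample = (
            (1 - fy) * (1 - fx) * window[ys[0], xs[0]]
            + (1 - fy) * fx * window[ys[0], xs[1]]
            + fy * (1 - fx) * window[ys[1], xs[0]]
            + fy * fx * window[ys[1], xs[1]]
        )
        if sample >= center:
            code |= 1 << n
    return code


def lbp_feature(image_window: np.ndarray, spec: FeatureWindowSpec) -> np.ndarray:
    """LBP codes of every pixel of the inner h x w window, row-major.

    ``image_window`` must include the LBP margin: shape
    (h + 2*ceil(r)) x (w + 2*ceil(r)).
    """
    m = spec.lbp_margin
    win = np.asarray(image_window, dtype=np.float64)
    exp = (spec.h + 2 * m, spec.w + 2 * m)
    if win.shape != exp:
        raise ValueError(f"lbp_feature expects window shape {exp}, got {win.shape}")
    out = np.empty(spec.h * spec.w, dtype=np.float64)
    k = 0
    for i in range(spec.h):
        for j in range(spec.w):
            out[k] = lbp_code(win, (i + m, j + m), spec.lbp_radius, spec.lbp_neighbors)
            k += 1
    return out


def _lbp_map(image: np.ndarray, r: float, N: int) -> np.ndarray:
    """LBP code of every pixel, neighbours beyond the border edge-replicated."""
    image = np.asarray(image, dtype=np.float64)
    m = int(math.ceil(r)) + 1
    pad = np.pad(image, m, mode="edge")
    H, W = image.shape
    codes = np.zeros((H, W), dtype=np.float64)
    for n, (dy, dx) in enumerate(_neighbor_offsets(r, N)):
        y0, x0 = int(math.floor(dy)), int(math.floor(dx))
        fy, fx = dy - y0, dx - x0

        def sh(a, b):
            return pad[m + a : m + a + H, m + b : m + b + W]

        s = (
            (1 - fy) * (1 - fx) * sh(y0, x0)
            + (1 - fy) * fx * sh(y0, x0 + 1 if fx > 0 else x0)
            + fy * (1 - fx) * sh(y0 + 1 if fy > 0 else y0, x0)
            + fy * fx * sh((y0 + 1 if fy > 0 else y0), (x0 + 1 if fx > 0 else x0))
        )
        codes += (s >= image) * float(1 << n)
    return codes


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_displacement(d: int, theta_deg: float) -> tuple:
    t = round(theta_deg) % 180
    if t == 0:
        return (0, d)
    if t == 45:
        return (-d, d)
    if t == 90:
        return (-d, 0)
    if t == 135:
        return (-d, -d)
    raise ConfigError(f"GLCM angle must be one of 0/45/90/135 degrees, got {theta_deg}")


def quantize_levels(values: np.ndarray, levels: int, vmin=None, vmax=None) -> np.ndarray:
    """Equal-width quantization of intensities to integer levels [0, levels)."""
    values = np.asarray(values, dtype=np.float64)
    vmin = float(values.min()) if vmin is None else float(vmin)
    vmax = float(values.max()) if vmax is None else float(vmax)
    if vmax == vmin:
        return np.zeros(values.shape, dtype=np.int64)
    q = np.floor((values - vmin) / (vmax - vmin) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcm_matrix(window: np.ndarray, d: int, theta_deg: float, levels: int) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix of a window.

    ``window`` holds integer levels in [0, levels).  Every pair at
    displacement (d, theta) is counted in both directions; the matrix is
    normalized to sum to 1.
    """
    win = np.asarray(window)
    dy, dx = _glcm_displacement(d, theta_deg)
    H, W = win.shape
    if H - abs(dy) <= 0 or W - abs(dx) <= 0:
        raise ValueError("window smaller than the GLCM displacement")
    a0, b0 = max(0, -dy), max(0, -dx)
    a = win[a0 : a0 + H - abs(dy), b0 : b0 + W - abs(dx)]
    b = win[a0 + dy : a0 + dy + H - abs(dy), b0 + dx : b0 + dx + W - abs(dx)]
    glcm = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(glcm, (a.ravel(), b.ravel()), 1.0)
    glcm = glcm + glcm.T  # count each pair in both directions
    total = glcm.sum()
    if total > 0:
        glcm /= total
    return glcm


def glcm_statistics(glcm: np.ndarray) -> np.ndarray:
    """The 12 texture statistics of a normalized GLCM, in the fixed order of
    ``GLCM_STAT_NAMES``.

    With p(a,b) the normalized co-occurrence probabilities and marginal mean
    mu = sum_a a p_a (marginals coincide for a symmetric matrix):

    - energy          = sum p^2
    - contrast        = sum (a-b)^2 p
    - correlation     = sum (a-mu)(b-mu) p / sigma^2  (0 when sigma = 0)
    - homogeneity     = sum p / (1 + (a-b)^2)   (inverse difference moment)
    - entropy         = -sum p ln p  over p > 0
    - autocorrelation = sum a b p
    - dissimilarity   = sum |a-b| p
    - cluster shade   = sum (a + b - 2 mu)^3 p
    - cluster tendency= sum (a + b - 2 mu)^2 p
    - max probability = max p
    - variance        = sum (a-mu)^2 p  (marginal sum of squares)
    - sum mean        = 0.5 sum (a+b) p
    """
    p = np.asarray(glcm, dtype=np.float64)
    L = p.shape[0]
    a = np.arange(L, dtype=np.float64)[:, None]
    b = np.arange(L, dtype=np.float64)[None, :]
    mu_a = float((a * p).sum())
    mu_b = float((b * p).sum())
    var_a = float(((a - mu_a) ** 2 * p).sum())
    var_b = float(((b - mu_b) ** 2 * p).sum())
    diff2 = (a - b) ** 2
    energy = float((p**2).sum())
    contrast = float((diff2 * p).sum())
    if var_a <= 0 or var_b <= 0:
        correlation = 0.0
    else:
        correlation = float((((a - mu_a) * (b - mu_b) * p).sum()) / math.sqrt(var_a * var_b))
    homogeneity = float((p / (1.0 + diff2)).sum())
    pos = p[p > 0]
    entropy = float(-(pos * np.log(pos)).sum())
    autocorr = float((a * b * p).sum())
    dissim = float((np.abs(a - b) * p).sum())
    dev = a + b - mu_a - mu_b
    shade = float((dev**3 * p).sum())
    tendency = float((dev**2 * p).sum())
    maxprob = float(p.max())
    variance = var_a
    sum_mean = float(0.5 * ((a + b) * p).sum())
    return np.array(
        [
            energy,
            contrast,
            correlation,
            homogeneity,
            entropy,
            autocorr,
            dissim,
            shade,
            tendency,
            maxprob,
            variance,
            sum_mean,
        ]
    )


# ---------------------------------------------------------------------------
# Haar
# ---------------------------------------------------------------------------

def haar_bank(h: int, w: int):
    """The frozen 15-filter rectangle bank for an h x w window.

    Each filter is a list of (r0, c0, hh, ww, sign) rectangles; the feature
    value is  sum_white(mean) - sum_black(mean), i.e. each rectangle
    contributes sign * (rect sum) / (rect area).  Five shapes at three
    centred scales.  Degenerate sub-rectangles (too small at a scale) yield
    an empty rectangle list and a feature value of 0.
    """
    bank = []
    for scale in _HAAR_SCALES:
        hh = max(2, int(h * scale))
        ww = max(2, int(w * scale))
        top, left = (h - hh) // 2, (w - ww) // 2
        for shape in _HAAR_SHAPES:
            rects = []
            if shape == "edge_v":
                half = ww // 2
                rects = [
                    (top, left, hh, half, +1.0),
                    (top, left + ww - half, hh, half, -1.0),
                ]
            elif shape == "edge_h":
                half = hh // 2
                rects = [
                    (top, left, half, ww, +1.0),
                    (top + hh - half, left, half, ww, -1.0),
                ]
            elif shape == "line_v":
                t = ww // 3
                if t >= 1:
                    rects = [
                        (top, left + t, hh, ww - 2 * t, +1.0),
                        (top, left, hh, t, -0.5),
                        (top, left + ww - t, hh, t, -0.5),
                    ]
            elif shape == "line_h":
                t = hh // 3
                if t >= 1:
                    rects = [
                        (top + t, left, hh - 2 * t, ww, +1.0),
                        (top, left, t, ww, -0.5),
                        (top + hh - t, left, t, ww, -0.5),
                    ]
            elif shape == "center_surround":
                ch, cw = max(1, hh // 2), max(1, ww // 2)
                ct, cl = top + (hh - ch) // 2, left + (ww - cw) // 2
                # surround mean = (window sum - centre sum) / (area diff)
                area_s = hh * ww - ch * cw
                if area_s > 0:
                    rects = [
                        (ct, cl, ch, cw, +1.0),
                        ("surround", (top, left, hh, ww), (ct, cl, ch, cw), area_s),
                    ]
            bank.append((shape, scale, rects))
    return bank


def _integral(arr: np.ndarray) -> np.ndarray:
    ii = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.float64)
    ii[1:, 1:] = np.cumsum(np.cumsum(arr, axis=0), axis=1)
    return ii


def _rect_sum(ii: np.ndarray, r0: int, c0: int, hh: int, ww: int) -> float:
    return ii[r0 + hh, c0 + ww] - ii[r0, c0 + ww] - ii[r0 + hh, c0] + ii[r0, c0]


def haar_features(window: np.ndarray) -> np.ndarray:
    """The 15 Haar-like rectangle features of a window (integral image)."""
    win = np.asarray(window, dtype=np.float64)
    h, w = win.shape
    if h < 2 or w < 2:
        raise ValueError("Haar window must be at least 2x2")
    ii = _integral(win)
    out = np.zeros(N_HAAR, dtype=np.float64)
    for k, (_, _, rects) in enumerate(haar_bank(h, w)):
        val = 0.0
        for rect in rects:
            if rect[0] == "surround":
                _, (ot, ol, oh, ow), (ct, cl, ch, cw), area_s = rect
                s = _rect_sum(ii, ot, ol, oh, ow) - _rect_sum(ii, ct, cl, ch, cw)
                val -= s / area_s
            else:
                r0, c0, hh, ww, sign = rect
                val += sign * _rect_sum(ii, r0, c0, hh, ww) / (hh * ww)
        out[k] = val
    return out


# ---------------------------------------------------------------------------
# HOG
# ---------------------------------------------------------------------------

def _fold_angle_deg(gy: np.ndarray, gx: np.ndarray) -> np.ndarray:
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0
    # guard against 180.0 from rounding
    ang[ang >= 180.0] = 0.0
    return ang


def hog_feature(window: np.ndarray, K: int) -> np.ndarray:
    """Gradient-orientation histogram of the inner region of a window.

    ``window`` must include a one-pixel margin, shape (h+2) x (w+2);
    gradients of the inner h x w region are central differences using the
    margin.  Bins partition [0, 180) degrees equally; bin mass is gradient
    magnitude, normalized to sum 1 (zero vector when there is no gradient).
    """
    win = np.asarray(window, dtype=np.float64)
    gx = (win[1:-1, 2:] - win[1:-1, :-2]) / 2.0
    gy = (win[2:, 1:-1] - win[:-2, 1:-1]) / 2.0
    mag = np.hypot(gx, gy)
    total = mag.sum()
    out = np.zeros(K, dtype=np.float64)
    if total <= 0:
        return out
    ang = _fold_angle_deg(gy, gx)
    bins = np.minimum((ang / (180.0 / K)).astype(np.int64), K - 1)
    np.add.at(out, bins.ravel(), mag.ravel())
    return out / total


# ---------------------------------------------------------------------------
# Concatenated per-pixel features
# ---------------------------------------------------------------------------

def _pad_width(spec: FeatureWindowSpec) -> int:
    # half window + LBP margin + one ring so central-difference gradients
    # exist for every window pixel in both extraction paths
    return spec.h // 2 + max(spec.lbp_margin, 1) + 1


def extract_features(image: np.ndarray, pixel_index: tuple, spec: FeatureWindowSpec) -> FeatureVector:
    """Concatenated feature vector f(x) at one pixel (reference path).

    The image is edge-replicated so windows exist at every border pixel;
    layout is LBP | GLCM (12 per offset) | Haar (15) | HOG (K).
    """
    image = np.asarray(image, dtype=np.float64)
    i, j = pixel_index
    P = _pad_width(spec)
    padded = np.pad(image, P, mode="edge")
    half_h, half_w = spec.h // 2, spec.w // 2
    ci, cj = i + P, j + P

    m = spec.lbp_margin
    lbp_win = padded[
        ci - half_h - m : ci + half_h + m + 1, cj - half_w - m : cj + half_w + m + 1
    ]
    f_lbp = lbp_feature(lbp_win, spec)

    q = quantize_levels(image, spec.glcm_levels)
    q_padded = np.pad(q, P, mode="edge")
    q_win = q_padded[ci - half_h : ci + half_h + 1, cj - half_w : cj + half_w + 1]
    f_glcm = np.concatenate(
        [
            glcm_statistics(glcm_matrix(q_win, d, theta, spec.glcm_levels))
            for d, theta in spec.glcm_offsets
        ]
    )

    win = padded[ci - half_h : ci + half_h + 1, cj - half_w : cj + half_w + 1]
    f_haar = haar_features(win)

    hog_win = padded[ci - half_h - 1 : ci + half_h + 2, cj - half_w - 1 : cj + half_w + 2]
    f_hog = hog_feature(hog_win, spec.hog_bins)

    values = np.concatenate([f_lbp, f_glcm, f_haar, f_hog])
    return FeatureVector(values=values, layout=spec.layout())


def _window_sum_map(padded: np.ndarray, P: int, H: int, W: int, top: int, left: int, hh: int, ww: int) -> np.ndarray:
    """Sliding sums of ``padded`` over rectangles anchored at window-relative
    (top, left) of size hh x ww, for windows centred at every image pixel.

    ``top``/``left`` are offsets from the window's top-left corner, which for
    the pixel (i, j) sits at padded position (i + P - h//2, j + P - w//2);
    the caller folds the window half-size into ``top``/``left``.
    """
    ii = _integral(padded)
    r0 = P + top
    c0 = P + left
    return (
        ii[r0 + hh : r0 + hh + H, c0 + ww : c0 + ww + W]
        - ii[r0 : r0 + H, c0 + ww : c0 + ww + W]
        - ii[r0 + hh : r0 + hh + H, c0 : c0 + W]
        + ii[r0 : r0 + H, c0 : c0 + W]
    )


def feature_maps(image: np.ndarray, spec: FeatureWindowSpec) -> np.ndarray:
    """Feature vectors for every pixel: array (n_features, H, W).

    Exactly matches ``extract_features`` at each pixel; computed with
    integral images so whole slices are practical.
    """
    image = np.asarray(image, dtype=np.float64)
    H, W = image.shape
    P = _pad_width(spec)
    padded = np.pad(image, P, mode="edge")
    half_h, half_w = spec.h // 2, spec.w // 2
    out = np.empty((spec.n_features, H, W), dtype=np.float64)
    layout = spec.layout()

    # --- LBP: codes once per pixel, then gathered over window offsets ------
    lbp_codes = _lbp_map(padded, spec.lbp_radius, spec.lbp_neighbors)
    off0, _ = layout["lbp"]
    k = 0
    for di in range(-half_h, half_h + 1):
        for dj in range(-half_w, half_w + 1):
            out[off0 + k] = lbp_codes[P + di : P + di + H, P + dj : P + dj + W]
            k += 1

    # --- GLCM: per-code window counts via integral images ------------------
    q = quantize_levels(image, spec.glcm_levels)
    q_padded = np.pad(q, P, mode="edge")
    off0, _ = layout["glcm"]
    L = spec.glcm_levels
    for oi, (d, theta) in enumerate(spec.glcm_offsets):
        dy, dx = _glcm_displacement(d, theta)
        if spec.h - abs(dy) <= 0 or spec.w - abs(dx) <= 0:
            raise ValueError("window smaller than the GLCM displacement")
        a0, b0 = max(0, -dy), max(0, -dx)
        # pair code at padded position p = level(p) * L + level(p + (dy,dx))
        Hp, Wp = q_padded.shape
        pa = q_padded[: Hp - abs(dy) if dy else Hp, : Wp - abs(dx) if dx else Wp]
        # build aligned first/second members of each pair on a common grid
        ya, xa = max(0, -dy), max(0, -dx)
        yb, xb = max(0, dy), max(0, dx)
        hh_pair, ww_pair = Hp - abs(dy), Wp - abs(dx)
        first = q_padded[ya : ya + hh_pair, xa : xa + ww_pair]
        second = q_padded[yb : yb + hh_pair, xb : xb + ww_pair]
        pair_code = first * L + second
        # counts of each pair code over the valid sub-rectangle of the window
        rect_h, rect_w = spec.h - abs(dy), spec.w - abs(dx)
        counts = np.zeros((L * L, H, W), dtype=np.float64)
        # pair at padded coordinate (ya + r, xa + c) corresponds to offset
        # (r, c) in pair_code; the valid anchor inside a window at image
        # pixel (i, j) is (i + P - half_h + a0 - ya, ...) relative to pair_code.
        for code in range(L * L):
            ind = (pair_code == code).astype(np.float64)
            ii = _integral(ind)
            r0 = P - half_h + a0 - ya
            c0 = P - half_w + b0 - xa
            counts[code] = (
                ii[r0 + rect_h : r0 + rect_h + H, c0 + rect_w : c0 + rect_w + W]
                - ii[r0 : r0 + H, c0 + rect_w : c0 + rect_w + W]
                - ii[r0 + rect_h : r0 + rect_h + H, c0 : c0 + W]
                + ii[r0 : r0 + H, c0 : c0 + W]
            )
        counts = counts.reshape(L, L, H * W)
        counts = counts + counts.transpose(1, 0, 2)  # symmetrize
        total = counts.sum(axis=(0, 1))
        total[total == 0] = 1.0
        p = counts / total
        out[off0 + 12 * oi : off0 + 12 * (oi + 1)] = _glcm_stats_batch(p).reshape(12, H, W)

    # --- Haar ---------------------------------------------------------------
    off0, _ = layout["haar"]
    ii_pad = _integral(padded)
    for fk, (_, _, rects) in enumerate(haar_bank(spec.h, spec.w)):
        fmap = np.zeros((H, W), dtype=np.float64)
        for rect in rects:
            if rect[0] == "surround":
                _, (ot, ol, oh, ow), (ct, cl, ch, cw), area_s = rect
                s = _sliding_rect(ii_pad, P, H, W, ot - half_h, ol - half_w, oh, ow) - _sliding_rect(
                    ii_pad, P, H, W, ct - half_h, cl - half_w, ch, cw
                )
                fmap -= s / area_s
            else:
                r0, c0, hh, ww, sign = rect
                fmap += sign * _sliding_rect(ii_pad, P, H, W, r0 - half_h, c0 - half_w, hh, ww) / (hh * ww)
        out[off0 + fk] = fmap

    # --- HOG ----------------------------------------------------------------
    off0, _ = layout["hog"]
    K = spec.hog_bins
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    mag = np.hypot(gx, gy)
    ang = _fold_angle_deg(gy, gx)
    bins = np.minimum((ang / (180.0 / K)).astype(np.int64), K - 1)
    Pg = P - 1  # gradient arrays lose the outermost padded ring
    denom = None
    bin_maps = np.empty((K, H, W), dtype=np.float64)
    for kbin in range(K):
        wmap = np.where(bins == kbin, mag, 0.0)
        bin_maps[kbin] = _window_sum_map(wmap, Pg, H, W, -half_h, -half_w, spec.h, spec.w)
    denom = bin_maps.sum(axis=0)
    safe = denom.copy()
    safe[safe <= 0] = 1.0
    bin_maps /= safe
    bin_maps[:, denom <= 0] = 0.0
    out[off0 : off0 + K] = bin_maps

    return out


def _sliding_rect(ii_pad: np.ndarray, P: int, H: int, W: int, top: int, left: int, hh: int, ww: int) -> np.ndarray:
    """Sliding rectangle sums from a precomputed padded integral image.

    (top, left) are offsets from the window *centre* pixel.
    """
    r0, c0 = P + top, P + left
    return (
        ii_pad[r0 + hh : r0 + hh + H, c0 + ww : c0 + ww + W]
        - ii_pad[r0 : r0 + H, c0 + ww : c0 + ww + W]
        - ii_pad[r0 + hh : r0 + hh + H, c0 : c0 + W]
        + ii_pad[r0 : r0 + H, c0 : c0 + W]
    )


def _glcm_stats_batch(p: np.ndarray) -> np.ndarray:
    """Vectorized ``glcm_statistics`` over a batch: p has shape (L, L, M)."""
    L, _, M = p.shape
    a = np.arange(L, dtype=np.float64)[:, None, None]
    b = np.arange(L, dtype=np.float64)[None, :, None]
    mu_a = (a * p).sum(axis=(0, 1))
    mu_b = (b * p).sum(axis=(0, 1))
    var_a = (((a - mu_a) ** 2) * p).sum(axis=(0, 1))
    var_b = (((b - mu_b) ** 2) * p).sum(axis=(0, 1))
    diff2 = (a - b) ** 2
    energy = (p**2).sum(axis=(0, 1))
    contrast = (diff2 * p).sum(axis=(0, 1))
    cov = (((a - mu_a) * (b - mu_b)) * p).sum(axis=(0, 1))
    denom = np.sqrt(var_a * var_b)
    correlation = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    homogeneity = (p / (1.0 + diff2)).sum(axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    entropy = -(p * logs).sum(axis=(0, 1))
    autocorr = (a * b * p).sum(axis=(0, 1))
    dissim = (np.abs(a - b) * p).sum(axis=(0, 1))
    dev = a + b - mu_a - mu_b
    shade = (dev**3 * p).sum(axis=(0, 1))
    tendency = (dev**2 * p).sum(axis=(0, 1))
    maxprob = p.max(axis=(0, 1))
    variance = var_a
    sum_mean = 0.5 * ((a + b) * p).sum(axis=(0, 1))
    return np.stack(
        [
            energy,
            contrast,
            correlation,
            homogeneity,
            entropy,
            autocorr,
            dissim,
            shade,
            tendency,
            maxprob,
            variance,
            sum_mean,
        ]
    )
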