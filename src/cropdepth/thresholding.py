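"""Pseudo crop-mask generation from depth maps by histogram thresholding.

Three algorithms share a common contract (depth map in, binary mask out,
crop = high-depth class):

* **Otsu** — the split maximizing between-class variance
  ``sigma_B^2(T) = w0(T) w1(T) (u0(T) - u1(T))^2``.
* **GHT** — generalized histogram thresholding: a Bayesian split objective
  with conjugate-prior-regularized per-side Gaussian log-likelihoods,
  controlled by hyperparameters ``(nu, tau, kappa, omega)``. Limits of the
  hyperparameters recover Otsu's method, minimum-error thresholding and
  weighted percentile thresholding.
* **GGT** (gradient-guided histogram thresholding) — the depth-informed
  pipeline: separable row/column depth normalization, Sobel gradient and
  Canny edge maps, an edge-gated gradient-level-weighted depth histogram,
  cumulative normalization to a monotone sequence ``S``, a bounded sigmoid
  fit to ``S``, and binarization of the ``S``-transformed depth at the
  sigmoid's inflection point.

Crops photographed top-down sit on a distinct depth plane above the ground,
so they read brighter in a relative (monocular) depth map; all three methods
label the high-intensity class as crop. GGT exists because in-field and UAV
backgrounds often show a strong depth drop-off across the frame, which
bimodal-histogram splitters mistake for foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import curve_fit
from skimage import feature, morphology

from .errors import (
    DegenerateHistogramError,
    NoEdgesError,
    NoGradientError,
    FitFailureError,
    ParameterError,
)
from .imgio import validate_depth

__all__ = [
    "GHTParams",
    "GGTConfig",
    "SigmoidFit",
    "GGTDiagnostics",
    "histogram",
    "otsu_threshold",
    "ght_threshold",
    "ght_objective",
    "apply_threshold",
    "normalize_depth",
    "compute_gradient",
    "compute_edges",
    "build_target_mask",
    "gradient_levels",
    "level_weights",
    "weighted_histogram",
    "fit_sigmoid",
    "threshold_from_fit",
    "generate_pseudo_mask",
]


# ---------------------------------------------------------------------------
# Histogram and classic thresholds
# ---------------------------------------------------------------------------

def histogram(depth: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram with round-half-away-from-zero binning."""
    depth = validate_depth(depth)
    idx = np.floor(depth + 0.5).astype(int).clip(0, 255)
    return np.bincount(idx.ravel(), minlength=256).astype(float)


def _check_histogram(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (256,) or (counts < 0).any():
        raise ParameterError("histogram must be 256 nonnegative bin counts")
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError(
            "histogram has fewer than two populated intensities; no split exists"
        )
    return counts


def otsu_threshold(counts: np.ndarray) -> int:
    """Threshold maximizing between-class variance; classes {<=T} vs {>T}.

    Ties are broken toward the smallest maximizing T for reproducibility.
    """
    n = _check_histogram(counts)
    x = np.arange(256, dtype=float)
    w0 = np.cumsum(n)[:-1]
    w1 = np.cumsum(n[::-1])[::-1][1:]
    s0 = np.cumsum(n * x)[:-1]
    s1 = np.cumsum((n * x)[::-1])[::-1][1:]
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.full(255, -np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = s0 / w0 - s1 / w1
        sigma_b[valid] = (w0 * w1 * diff**2)[valid]
    return int(np.argmax(sigma_b))


@dataclass(frozen=True)
class GHTParams:
    """Prior hyperparameters of generalized histogram thresholding.

    ``nu`` is the strength and ``tau`` the scale of the inverse-chi-squared
    variance prior; ``kappa`` the strength and ``omega`` the mean of the
    Beta prior on the mixture weight. The shipped defaults are the reference
    implementation's released defaults (the minimum-error-thresholding
    corner of the family).
    """

    nu: float = 0.0
    tau: float = 0.0
    kappa: float = 0.0
    omega: float = 0.5

    def validate(self) -> "GHTParams":
        if not all(np.isfinite([self.nu, self.tau, self.kappa, self.omega])):
            raise ParameterError("GHT hyperparameters must be finite")
        if self.nu < 0 or self.tau < 0 or self.kappa < 0:
            raise ParameterError("nu, tau, kappa must be nonnegative")
        if not 0.0 <= self.omega <= 1.0:
            raise ParameterError("omega must be in [0, 1]")
        return self

    @classmethod
    def otsu_limit(cls) -> "GHTParams":
        """Hyperparameter limit (nu -> inf, tau -> 0) recovering Otsu."""
        return cls(nu=1e15, tau=1e-2, kappa=0.0, omega=0.5)


_EPS = 1e-30


def ght_objective(counts: np.ndarray, params: GHTParams) -> np.ndarray:
    """GHT split objective f0(T) + f1(T) for every split T in 0..254.

    Each side of the split is scored by the log-likelihood of a Gaussian
    whose variance is shrunk toward ``tau**2`` with strength ``nu`` and
    whose mass is tilted by a Beta(kappa*omega, kappa*(1-omega)) prior.
    """
    n = np.asarray(counts, dtype=float)
    p = params.validate()
    x = np.arange(256, dtype=float)
    csum = lambda z: np.cumsum(z)[:-1]
    dsum = lambda z: np.cumsum(z[::-1])[::-1][1:]
    w0 = np.maximum(csum(n), _EPS)
    w1 = np.maximum(dsum(n), _EPS)
    p0 = w0 / (w0 + w1)
    p1 = w1 / (w0 + w1)
    mu0 = csum(n * x) / w0
    mu1 = dsum(n * x) / w1
    d0 = np.maximum(csum(n * x**2) - w0 * mu0**2, 0.0)
    d1 = np.maximum(dsum(n * x**2) - w1 * mu1**2, 0.0)
    v0 = np.maximum((p.nu * p0 * p.tau**2 + d0) / (p.nu * p0 + w0), _EPS)
    v1 = np.maximum((p.nu * p1 * p.tau**2 + d1) / (p.nu * p1 + w1), _EPS)
    f0 = -d0 / v0 - w0 * np.log(v0) + 2.0 * (w0 + p.kappa * p.omega) * np.log(w0)
    f1 = -d1 / v1 - w1 * np.log(v1) + 2.0 * (w1 + p.kappa * (1.0 - p.omega)) * np.log(w1)
    return f0 + f1


def ght_threshold(counts: np.ndarray, params: GHTParams | None = None) -> int:
    """GHT threshold: smallest T maximizing the split objective."""
    n = _check_histogram(counts)
    params = params or GHTParams()
    return int(np.argmax(ght_objective(n, params)))


def apply_threshold(depth: np.ndarray, threshold: int) -> np.ndarray:
    """Binarize: crop (1) where depth is strictly greater than the threshold."""
    depth = validate_depth(depth)
    if not 0 <= threshold <= 255:
        raise ParameterError(f"threshold must be in [0, 255], got {threshold}")
    return (depth > threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# Gradient-guided thresholding stages
# ---------------------------------------------------------------------------

def normalize_depth(depth: np.ndarray) -> np.ndarray:
    """Remove a separable background bias by sequential row/column min subtraction.

    Subtracts from every row its minimum, then from every column of the
    intermediate its minimum. Any additive bias of the form f(row) + g(col)
    on a crop-free plane is removed exactly; the operation is idempotent.
    """
    depth = validate_depth(depth)
    out = depth - depth.min(axis=1, keepdims=True)
    out -= out.min(axis=0, keepdims=True)
    return out


def _sobel_kernels(ksize: int) -> tuple[np.ndarray, np.ndarray]:
    # classic (unnormalized) Sobel: derivative [-1, 0, 1] composed with
    # (ksize - 2) smoothing passes of [1, 2, 1]
    smooth = np.array([1.0, 2.0, 1.0])
    deriv = np.array([-1.0, 0.0, 1.0])
    avg = np.array([1.0, 2.0, 1.0])
    for _ in range((ksize - 3) // 2):
        deriv = np.convolve(deriv, smooth)
        avg = np.convolve(avg, smooth)
    return deriv, avg


def compute_gradient(depth: np.ndarray, ksize: int = 3) -> np.ndarray:
    """Sobel gradient magnitude sqrt(Sx^2 + Sy^2) with reflective borders."""
    if ksize < 3 or ksize % 2 == 0:
        raise ParameterError(f"Sobel kernel size must be odd and >= 3, got {ksize}")
    depth = validate_depth(depth)
    deriv, avg = _sobel_kernels(ksize)
    gx = ndi.convolve1d(depth, deriv, axis=1, mode="reflect")
    gx = ndi.convolve1d(gx, avg, axis=0, mode="reflect")
    gy = ndi.convolve1d(depth, deriv, axis=0, mode="reflect")
    gy = ndi.convolve1d(gy, avg, axis=1, mode="reflect")
    return np.hypot(gx, gy)


def compute_edges(depth: np.ndarray, low: float = 50.0, high: float = 125.0) -> np.ndarray:
    """Canny edge map (binary {0, 1}) of a [0, 255] depth map.

    ``low``/``high`` are hysteresis thresholds on the classic unnormalized
    Sobel magnitude scale (a step of height h has magnitude 4h); they are
    divided by 4 internally to match the normalized kernels of the Canny
    implementation used.
    """
    if not 0 <= low < high <= 255:
        raise ParameterError(f"need 0 <= low < high <= 255, got ({low}, {high})")
    depth = validate_depth(depth)
    edges = feature.canny(
        depth, sigma=1.0, low_threshold=low / 4.0, high_threshold=high / 4.0
    )
    return edges.astype(np.uint8)


def build_target_mask(edges: np.ndarray, dilation: int = 30) -> np.ndarray:
    """Coarse target region: dilate edges, close contours, fill interiors.

    A single dilation with a ``dilation`` x ``dilation`` square structuring
    element bridges broken edge chains; interior holes of the resulting
    contours are then filled. The output is a superset of the dilated edges.
    """
    if dilation < 1:
        raise ParameterError(f"dilation size must be >= 1, got {dilation}")
    edges = np.asarray(edges).astype(bool)
    dilated = morphology.dilation(edges, morphology.footprint_rectangle((dilation, dilation)))
    return ndi.binary_fill_holes(dilated).astype(np.uint8)


def gradient_levels(grad: np.ndarray, p: int = 3) -> np.ndarray:
    """Quantize gradient magnitudes into p levels: floor(p*g/max g), clamped.

    Pixels at the global maximum land in the top level p - 1.
    """
    if p < 2:
        raise ParameterError(f"number of gradient levels must be >= 2, got {p}")
    grad = np.asarray(grad, dtype=float)
    gmax = grad.max()
    if gmax <= 0:
        raise NoGradientError("gradient map is identically zero")
    return np.minimum(np.floor(p * grad / gmax), p - 1).astype(int)


def level_weights(levels: np.ndarray, edges: np.ndarray, p: int = 3) -> np.ndarray:
    """Per-level weights: the fraction of edge pixels at each gradient level."""
    edges = np.asarray(edges).astype(bool)
    total = edges.sum()
    if total == 0:
        raise NoEdgesError("edge map is empty; level weights undefined")
    gamma = np.bincount(np.asarray(levels)[edges].ravel(), minlength=p).astype(float)
    return gamma / total


def weighted_histogram(
    depth_n: np.ndarray, levels: np.ndarray, edges: np.ndarray, gamma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Edge-weighted depth histogram R and its normalized cumulative S.

    ``R[T]`` sums the level weight ``gamma[l_ij]`` of every edge pixel whose
    rounded normalized-depth intensity is T; ``S`` is the running sum of R
    rescaled so that ``S[255] == 255`` (monotone nondecreasing by
    construction).
    """
    depth_n = validate_depth(depth_n)
    edges = np.asarray(edges).astype(bool)
    idx = np.floor(depth_n + 0.5).astype(int).clip(0, 255)
    w = np.asarray(gamma, dtype=float)[np.asarray(levels)] * edges
    r = np.bincount(idx.ravel(), weights=w.ravel(), minlength=256)
    total = r.sum()
    if total <= 0:
        raise NoEdgesError("weighted histogram is identically zero")
    s = 255.0 * np.cumsum(r) / total
    return r, s


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted parameters of s(T) = c / (1 + exp(-a (T - b))), c = 255."""

    a: float
    b: float
    c: float = 255.0
    residual: float = 0.0


def _sigmoid(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return 255.0 / (1.0 + np.exp(-np.clip(a * (t - b), -500, 500)))


def fit_sigmoid(s: np.ndarray) -> SigmoidFit:
    """Bounded least-squares sigmoid fit to the normalized sequence S.

    The slope a is constrained to (0, 5] and the midpoint b to [0, 255].
    Restarts from three spread initial midpoints guard against poor local
    minima; the first initial b is the smallest T whose S value crosses the
    half-range 127.5.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (256,):
        raise ParameterError("S must be a length-256 sequence")
    t = np.arange(256, dtype=float)
    crossing = np.nonzero(s >= 127.5)[0]
    b_first = float(crossing[0]) if crossing.size else 128.0
    best: SigmoidFit | None = None
    for a0, b0 in [(0.1, b_first), (0.1, 64.0), (0.5, 192.0)]:
        try:
            (a_hat, b_hat), _ = curve_fit(
                _sigmoid, t, s, p0=(a0, b0),
                bounds=([1e-6, 0.0], [5.0, 255.0]), maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = float(np.sum((s - _sigmoid(t, a_hat, b_hat)) ** 2))
        if best is None or resid < best.residual:
            best = SigmoidFit(a=float(a_hat), b=float(b_hat), residual=resid)
    if best is None:
        raise FitFailureError("sigmoid fit failed after all restarts")
    return best


def threshold_from_fit(fit: SigmoidFit) -> int:
    """Threshold at the sigmoid's maximum slope, which is its midpoint b."""
    return int(np.clip(np.floor(fit.b + 0.5), 0, 255))


# ---------------------------------------------------------------------------
# Full pipelines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GGTConfig:
    """Stage parameters of gradient-guided thresholding.

    Defaults: Sobel kernel 3, Canny hysteresis 50/125, p = 3 gradient
    levels, one dilation with a 30x30 square element, and depth
    normalization applied (intended for in-field and UAV scenes; disable
    for lab scenes with flat backgrounds).
    """

    sobel_ksize: int = 3
    canny_low: float = 50.0
    canny_high: float = 125.0
    p: int = 3
    dilation: int = 30
    apply_normalization: bool = True

    def validate(self) -> "GGTConfig":
        if self.sobel_ksize < 3 or self.sobel_ksize % 2 == 0:
            raise ParameterError("sobel_ksize must be odd and >= 3")
        if not 0 <= self.canny_low < self.canny_high <= 255:
            raise ParameterError("need 0 <= canny_low < canny_high <= 255")
        if self.p < 2:
            raise ParameterError("p must be >= 2")
        if self.dilation < 1:
            raise ParameterError("dilation must be >= 1")
        return self


@dataclass
class GGTDiagnostics:
    """Intermediate products of one pseudo-mask generation call."""

    method: str
    threshold: int | None = None
    fallback: str | None = None
    depth_n: np.ndarray | None = None
    gradient: np.ndarray | None = None
    edges: np.ndarray | None = None
    target_mask: np.ndarray | None = None
    r: np.ndarray | None = None
    s: np.ndarray | None = None
    fit: SigmoidFit | None = None
    depth_t: np.ndarray | None = None


def generate_pseudo_mask(
    depth: np.ndarray,
    method: str = "ggt",
    cfg: GGTConfig | None = None,
    ght_params: GHTParams | None = None,
) -> tuple[np.ndarray, GGTDiagnostics]:
    """Generate a pseudo crop mask with the selected thresholding method.

    ``method`` is one of ``otsu``, ``ght``, ``ggt``. The GGT pipeline falls
    back to Otsu — with the failed stage named in the diagnostics — when a
    stage degenerates (no gradient, no edges, empty weighted histogram, or
    sigmoid fit failure). A depth map that is degenerate for Otsu itself
    (single intensity) raises ``DegenerateHistogramError``.
    """
    depth = validate_depth(depth)
    cfg = (cfg or GGTConfig()).validate()
    if method == "otsu":
        t = otsu_threshold(histogram(depth))
        return apply_threshold(depth, t), GGTDiagnostics(method="otsu", threshold=t)
    if method == "ght":
        t = ght_threshold(histogram(depth), ght_params)
        return apply_threshold(depth, t), GGTDiagnostics(method="ght", threshold=t)
    if method != "ggt":
        raise ParameterError(f"unknown method {method!r}; expected otsu|ght|ggt")

    diag = GGTDiagnostics(method="ggt")
    depth_n = normalize_depth(depth) if cfg.apply_normalization else depth
    diag.depth_n = depth_n
    try:
        grad = compute_gradient(depth_n, cfg.sobel_ksize)
        diag.gradient = grad
        edges = compute_edges(depth_n, cfg.canny_low, cfg.canny_high)
        diag.edges = edges
        if edges.sum() == 0:
            raise NoEdgesError("edge map is empty")
        target = build_target_mask(edges, cfg.dilation)
        diag.target_mask = target
        levels = gradient_levels(grad, cfg.p)
        gamma = level_weights(levels, edges, cfg.p)
        r, s = weighted_histogram(depth_n, levels, edges, gamma)
        diag.r, diag.s = r, s
        fit = fit_sigmoid(s)
        diag.fit = fit
        t = threshold_from_fit(fit)
    except (NoGradientError, NoEdgesError, FitFailureError) as exc:
        diag.fallback = type(exc).__name__
        t = otsu_threshold(histogram(depth))
        diag.threshold = t
        return apply_threshold(depth, t), diag
    diag.threshold = t
    # transformed depth: monotone remap through S, gated to the target region
    idx = np.floor(depth_n + 0.5).astype(int).clip(0, 255)
    depth_t = s[idx] * (target > 0)
    diag.depth_t = depth_t
    return (depth_t > t).astype(np.uint8), diag
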