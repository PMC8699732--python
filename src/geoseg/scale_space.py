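"""Gaussian scale-space kernels and the differential-geometric filter bank.

Pixel ("injective") features: every operation maps an H×W image to one or
more H×W response planes.  Smoothing and differentiation are performed in a
single step by convolving with analytically sampled Gaussian derivative
kernels, which realizes weak (distributional) differentiation of the
sampled image: the response of the order-(dx, dy) kernel is the (dx, dy)
partial derivative of the Gaussian-smoothed image.

Conventions
-----------
* ``x`` is the column coordinate (axis 1), ``y`` the row coordinate
  (axis 0); both increase with index.
* The scale parameter is ``s = sigma**2``; the user-facing parameter is
  ``sigma`` in pixels.
* Boundaries are handled by reflect padding; analytic identities are exact
  only at interior pixels at distance >= kernel radius from the border.
* Gradient sign convention: ``gradient_features`` reports dI_sigma/dx of
  the smoothed image I_sigma (the distributional minus sign is absorbed
  into the kernel sampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from numpy.polynomial import hermite_e
from scipy import ndimage

__all__ = [
    "GaussianKernelSpec",
    "ScaleSpec",
    "FeatureStack",
    "FILTER_REGISTRY",
    "make_kernel",
    "gaussian_smooth",
    "gaussian_derivative",
    "gradient_features",
    "laplacian_features",
    "alog_features",
    "hessian_features",
    "structure_tensor_features",
    "curvature2d_features",
    "curvature3d_features",
    "power_laplacian",
    "gaussian_jet",
    "build_feature_stack",
]

# relative tolerance (of plane max) below which a gradient is degenerate
DEGENERATE_RTOL = 1e-12


def default_radius(sigma: float, radius_factor: float = 3.0) -> int:
    return int(math.ceil(radius_factor * sigma))


@dataclass(frozen=True)
class GaussianKernelSpec:
    """Sampled Gaussian derivative kernel of scale ``s = sigma**2``.

    The window is the odd square of side ``2*radius + 1``; ``dx`` and
    ``dy`` are the derivative orders along the column and row axes.
    """

    sigma: float
    dx: int = 0
    dy: int = 0
    radius: int | None = None

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.dx < 0 or self.dy < 0:
            raise ValueError("derivative orders must be non-negative")
        if self.dx + self.dy > 6:
            raise ValueError("total derivative order dx+dy must be <= 6")
        if self.radius is None:
            object.__setattr__(self, "radius", default_radius(self.sigma))
        if self.radius < math.ceil(3 * self.sigma):
            raise ValueError(
                f"radius {self.radius} too small for sigma {self.sigma}: "
                f"need >= ceil(3*sigma) = {math.ceil(3 * self.sigma)}"
            )

    @property
    def s(self) -> float:
        """Scale parameter s = sigma**2."""
        return self.sigma**2


@dataclass(frozen=True)
class ScaleSpec:
    """The set of smoothing scales of the filter bank."""

    sigmas: Tuple[float, ...] = (2.0, 4.0, 8.0)
    radius_factor: float = 3.0

    def __post_init__(self) -> None:
        sig = tuple(float(s) for s in self.sigmas)
        if len(sig) == 0:
            raise ValueError("sigmas must be non-empty")
        if any(s <= 0 for s in sig):
            raise ValueError("sigmas must be positive")
        if any(b <= a for a, b in zip(sig, sig[1:])):
            raise ValueError("sigmas must be strictly increasing")
        if self.radius_factor <= 0:
            raise ValueError("radius_factor must be positive")
        object.__setattr__(self, "sigmas", sig)


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"image too small: {img.shape}, need >= 3x3")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains NaN or Inf")
    return img


def _kernel1d(sigma: float, order: int, radius: int) -> np.ndarray:
    """Sampled 1-D Gaussian derivative with exact discrete moments.

    d^n/dx^n G(x) = (-1)^n sigma^-n He_n(x/sigma) G(x) with He_n the
    probabilists' Hermite polynomial.  The samples are then corrected so
    that the discrete moments match the continuous ones exactly:
    sum x^j k(x) = 0 for j < order and (-1)^order * order! for j = order
    (so a monomial x^order is differentiated exactly, and polynomials of
    lower degree give a zero response).  For order 0 the kernel sums to 1.
    """
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2)) / (sigma * math.sqrt(2.0 * math.pi))
    if order == 0:
        return g / g.sum()
    herm = hermite_e.hermeval(x / sigma, [0.0] * order + [1.0])
    k = ((-1.0) ** order) * sigma ** (-order) * herm * g
    # constrained least-squares moment correction: V @ (k + delta) = target
    V = np.vander(x, N=order + 1, increasing=True).T  # rows: x^0 .. x^order
    target = np.zeros(order + 1)
    target[order] = ((-1.0) ** order) * math.factorial(order)
    resid = target - V @ k
    delta, *_ = np.linalg.lstsq(V, resid, rcond=None)
    return k + delta


def make_kernel(spec: GaussianKernelSpec) -> np.ndarray:
    """Sample the (dx, dy)-order Gaussian derivative on the odd window.

    The smoothing kernel (dx = dy = 0) is renormalized to sum exactly 1;
    derivative kernels are moment-corrected so they sum exactly 0 and
    differentiate monomials up to their order exactly.
    """
    kx = _kernel1d(spec.sigma, spec.dx, spec.radius)
    ky = _kernel1d(spec.sigma, spec.dy, spec.radius)
    return np.outer(ky, kx)


def _convolve_sep(img: np.ndarray, spec: GaussianKernelSpec) -> np.ndarray:
    """Separable convolution (true convolution, reflect boundary)."""
    kx = _kernel1d(spec.sigma, spec.dx, spec.radius)
    ky = _kernel1d(spec.sigma, spec.dy, spec.radius)
    out = ndimage.convolve1d(img, kx, axis=1, mode="reflect")
    return ndimage.convolve1d(out, ky, axis=0, mode="reflect")


def gaussian_derivative(
    img: np.ndarray, sigma: float, dx: int, dy: int, radius: int | None = None
) -> np.ndarray:
    """(dx, dy) partial derivative of the Gaussian-smoothed image."""
    img = _validate_image(img)
    spec = GaussianKernelSpec(sigma=sigma, dx=dx, dy=dy, radius=radius)
    return _convolve_sep(img, spec)


def gaussian_smooth(img: np.ndarray, sigma: float, radius: int | None = None) -> np.ndarray:
    """Pure Gaussian smoothing (order-0 member of the scale space)."""
    return gaussian_derivative(img, sigma, 0, 0, radius=radius)


def _degenerate_mask(amplitude_sq: np.ndarray) -> np.ndarray:
    tol = DEGENERATE_RTOL * max(float(amplitude_sq.max()), 1.0)
    return amplitude_sq <= tol


def gradient_features(img: np.ndarray, sigma: float) -> Dict[str, np.ndarray]:
    """Gradient amplitude A = sqrt(Gx^2 + Gy^2) and orientation (sin, cos).

    At degenerate pixels (A below tolerance) sin and cos are set to 0.
    """
    gx = gaussian_derivative(img, sigma, 1, 0)
    gy = gaussian_derivative(img, sigma, 0, 1)
    a2 = gx**2 + gy**2
    amp = np.sqrt(a2)
    degen = _degenerate_mask(a2)
    safe = np.where(degen, 1.0, amp)
    sin_phi = np.where(degen, 0.0, gy / safe)
    cos_phi = np.where(degen, 0.0, gx / safe)
    return {"amplitude": amp, "sin": sin_phi, "cos": cos_phi, "gx": gx, "gy": gy}


def laplacian_features(img: np.ndarray, sigma: float) -> Dict[str, np.ndarray]:
    """Laplacian of Gaussian: trace of the smoothed Hessian, Gxx + Gyy."""
    gxx = gaussian_derivative(img, sigma, 2, 0)
    gyy = gaussian_derivative(img, sigma, 0, 2)
    return {"log": gxx + gyy}


def _second_order(img: np.ndarray, sigma: float):
    gxx = gaussian_derivative(img, sigma, 2, 0)
    gyy = gaussian_derivative(img, sigma, 0, 2)
    gxy = gaussian_derivative(img, sigma, 1, 1)
    return gxx, gyy, gxy


def alog_features(img: np.ndarray, sigma: float) -> Dict[str, np.ndarray]:
    """Anisotropic (gauge) decomposition of the Laplacian of Gaussian.

    The LoG splits into the second directional derivative along the
    gradient (normal component, ``perp``) and along the isophote
    (tangential component, ``par``)::

        perp = (Gx^2 Gxx + 2 Gx Gy Gxy + Gy^2 Gyy) / (Gx^2 + Gy^2)
        par  = (Gy^2 Gxx - 2 Gx Gy Gxy + Gx^2 Gyy) / (Gx^2 + Gy^2)

    so perp + par == LoG identically.  Where the gradient is degenerate
    the split is undefined and the convention perp = LoG, par = 0 is used.
    """
    grad = gradient_features(img, sigma)
    gx, gy = grad["gx"], grad["gy"]
    gxx, gyy, gxy = _second_order(img, sigma)
    a2 = gx**2 + gy**2
    lap = gxx + gyy
    degen = _degenerate_mask(a2)
    safe = np.where(degen, 1.0, a2)
    perp = (gx**2 * gxx + 2 * gx * gy * gxy + gy**2 * gyy) / safe
    par = (gy**2 * gxx - 2 * gx * gy * gxy + gx**2 * gyy) / safe
    perp = np.where(degen, lap, perp)
    par = np.where(degen, 0.0, par)
    return {
        "perp": perp,
        "par": par,
        "amplitude": grad["amplitude"],
        "sin": grad["sin"],
        "cos": grad["cos"],
    }


def hessian_features(img: np.ndarray, sigma: float) -> Dict[str, np.ndarray]:
    """Eigenvalues (descending, signed) and determinant of the smoothed Hessian.

    lambda1 + lambda2 equals the LoG and lambda1 * lambda2 the determinant
    pixelwise.  Both eigenvalues positive flags a dark blob, both negative
    a bright blob, opposite signs a saddle.
    """
    gxx, gyy, gxy = _second_order(img, sigma)
    half_tr = 0.5 * (gxx + gyy)
    disc = np.sqrt(np.maximum(0.25 * (gxx - gyy) ** 2 + gxy**2, 0.0))
    return {
        "lambda1": half_tr + disc,
        "lambda2": half_tr - disc,
        "det": gxx * gyy - gxy**2,
    }


def structure_tensor_features(
    img: np.ndarray, sigma_grad: float, sigma_window: float
) -> Dict[str, np.ndarray]:
    """Structure tensor: window-smoothed outer product of the smoothed gradient.

    Returns the (descending, non-negative) eigenvalues, the coherence
    ``c = ((l1 - l2) / (l1 + l2))**2`` (1 for a totally aligned gradient
    field, 0 for no preferred direction; 0 by convention where the trace
    is degenerate), and sin/cos of the principal orientation.
    """
    if sigma_grad <= 0 or sigma_window <= 0:
        raise ValueError("both sigmas must be positive")
    gx = gaussian_derivative(img, sigma_grad, 1, 0)
    gy = gaussian_derivative(img, sigma_grad, 0, 1)
    jxx = gaussian_smooth(gx * gx, sigma_window)
    jxy = gaussian_smooth(gx * gy, sigma_window)
    jyy = gaussian_smooth(gy * gy, sigma_window)
    half_tr = 0.5 * (jxx + jyy)
    disc = np.sqrt(np.maximum(0.25 * (jxx - jyy) ** 2 + jxy**2, 0.0))
    l1 = half_tr + disc
    l2 = np.maximum(half_tr - disc, 0.0)  # PSD up to fp round-off
    tr = l1 + l2
    degen = _degenerate_mask(tr)
    safe = np.where(degen, 1.0, tr)
    coherence = np.where(degen, 0.0, ((l1 - l2) / safe) ** 2)
    theta = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    sin_t = np.where(degen, 0.0, np.sin(theta))
    cos_t = np.where(degen, 0.0, np.cos(theta))
    return {"lambda1": l1, "lambda2": l2, "coherence": np.clip(coherence, 0.0, 1.0),
            "sin": sin_t, "cos": cos_t}


def curvature2d_features(img: np.ndarray, sigma: float) -> Dict[str, np.ndarray]:
    """Isophote (line) curvature and the Hessian determinant.

    line curvature = (Gxx Gy^2 - 2 Gx Gy Gxy + Gx^2 Gyy) / (Gx^2+Gy^2)^(3/2),
    0 at degenerate-gradient pixels.
    """
    gx = gaussian_derivative(img, sigma, 1, 0)
    gy = gaussian_derivative(img, sigma, 0, 1)
    gxx, gyy, gxy = _second_order(img, sigma)
    a2 = gx**2 + gy**2
    degen = _degenerate_mask(a2)
    safe = np.where(degen, 1.0, a2)
    num = gxx * gy**2 - 2 * gx * gy * gxy + gx**2 * gyy
    kappa = np.where(degen, 0.0, num / safe**1.5)
    return {"line_curvature": kappa, "det": gxx * gyy - gxy**2}


def curvature3d_features(img: np.ndarray, sigma: float) -> Dict[str, np.ndarray]:
    """Mean and Gaussian curvature of the intensity surface z = I(x, y).

    Monge-patch forms; the intensity is taken as elevation with no
    rescaling (callers may pre-normalize to [0, 1]).
    """
    gx = gaussian_derivative(img, sigma, 1, 0)
    gy = gaussian_derivative(img, sigma, 0, 1)
    gxx, gyy, gxy = _second_order(img, sigma)
    w = 1.0 + gx**2 + gy**2
    mean_c = 0.5 * ((1 + gx**2) * gyy - 2 * gx * gy * gxy + (1 + gy**2) * gxx) / w**1.5
    gauss_c = (gxx * gyy - gxy**2) / w**2
    return {"mean_curvature": mean_c, "gaussian_curvature": gauss_c}


def power_laplacian(img: np.ndarray, sigma: float, n: int = 2) -> Dict[str, np.ndarray]:
    """n-th iterate of the Laplacian of Gaussian at a single scale.

    n = 1 is the LoG, n = 2 the bi-Laplacian (BoG).  Implemented by
    iterated application of the LoG operator; the response to polynomials
    of degree < 2n vanishes at interior pixels.
    """
    if not (1 <= n <= 4):
        raise ValueError("power_laplacian order n must be in 1..4")
    out = _validate_image(img)
    for _ in range(n):
        feat = laplacian_features(out, sigma)
        out = feat["log"]
    return {f"log{n}": out}


def gaussian_jet(img: np.ndarray, sigma: float, order: int = 2) -> Dict[str, np.ndarray]:
    """All partial derivatives d^(i+j) I / dx^i dy^j with i + j <= order."""
    if not (1 <= order <= 6):
        raise ValueError("jet order must be in 1..6")
    planes: Dict[str, np.ndarray] = {}
    for total in range(order + 1):
        for i in range(total, -1, -1):
            j = total - i
            planes[f"d{i}{j}"] = gaussian_derivative(img, sigma, i, j)
    return planes


# ---------------------------------------------------------------------------
# Filter registry and FeatureStack

def _f_gauss(img, sigma):
    return {"smooth": gaussian_smooth(img, sigma)}


def _f_gradient(img, sigma):
    return gradient_features(img, sigma)


def _f_structure(img, sigma):
    return structure_tensor_features(img, sigma, sigma)


def _f_log(img, sigma):
    return laplacian_features(img, sigma)


def _f_bog(img, sigma):
    return power_laplacian(img, sigma, 2)


def _f_jet(img, sigma):
    return gaussian_jet(img, sigma, 2)


#: Registry of the filter bank: name -> (callable(img, sigma) -> planes,
#: component names in canonical order).
FILTER_REGISTRY: Dict[str, Tuple[object, Tuple[str, ...]]] = {
    "Gauss2D": (_f_gauss, ("smooth",)),
    "Gradient": (_f_gradient, ("amplitude", "sin", "cos", "gx", "gy")),
    "GaussianStructure": (_f_structure, ("lambda1", "lambda2", "coherence", "sin", "cos")),
    "LoG": (_f_log, ("log",)),
    "ALoG": (alog_features, ("perp", "par", "amplitude", "sin", "cos")),
    "Hessian": (hessian_features, ("lambda1", "lambda2", "det")),
    "Curvature2D": (curvature2d_features, ("line_curvature", "det")),
    "Curvature3D": (curvature3d_features, ("mean_curvature", "gaussian_curvature")),
    "BoG": (_f_bog, ("log2",)),
    "GaussianJet": (_f_jet, ("d00", "d10", "d01", "d20", "d11", "d02")),
}


@dataclass
class FeatureStack:
    """Named per-pixel feature planes over one source image.

    Plane names follow ``<filter>.<component>@s<sigma>``; ordering is
    deterministic (registry order x component order x ascending sigma).
    """

    source: np.ndarray
    planes: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.source.shape

    @property
    def names(self) -> List[str]:
        return list(self.planes.keys())

    def add(self, name: str, plane: np.ndarray) -> None:
        if name in self.planes:
            raise ValueError(f"duplicate plane name {name!r}")
        if plane.shape != self.source.shape:
            raise ValueError(
                f"plane {name!r} shape {plane.shape} != image {self.source.shape}"
            )
        if not np.all(np.isfinite(plane)):
            raise ValueError(f"plane {name!r} contains non-finite values")
        self.planes[name] = plane

    def as_matrix(self) -> np.ndarray:
        """(H*W) x n_planes feature matrix in row-major pixel order."""
        return np.stack([p.ravel() for p in self.planes.values()], axis=1)


def _format_sigma(sigma: float) -> str:
    return f"{sigma:g}"


def build_feature_stack(
    img: np.ndarray,
    scale_spec: ScaleSpec | None = None,
    filter_names: Sequence[str] = ("Gradient", "LoG", "Hessian", "GaussianStructure"),
) -> FeatureStack:
    """Run the selected filters of the bank at every scale.

    Unknown filter names are rejected with the registry listing.  Plane
    count is sum over filters of n_components * n_sigmas.
    """
    img = _validate_image(img)
    scale_spec = scale_spec or ScaleSpec()
    unknown = [f for f in filter_names if f not in FILTER_REGISTRY]
    if unknown:
        raise ValueError(
            f"unknown filter(s) {unknown}; available: {sorted(FILTER_REGISTRY)}"
        )
    stack = FeatureStack(source=img)
    for fname in FILTER_REGISTRY:  # registry order, not request order
        if fname not in filter_names:
            continue
        func, components = FILTER_REGISTRY[fname]
        per_sigma = {sigma: func(img, sigma) for sigma in scale_spec.sigmas}
        for comp in components:
            for sigma in scale_spec.sigmas:
                stack.add(f"{fname}.{comp}@s{_format_sigma(sigma)}", per_sigma[sigma][comp])
    return stack
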