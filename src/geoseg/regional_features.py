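"""Regional ("surjective") features: orthogonal image moments, GLCM
textures, and ROI statistics.

A regional feature maps a whole region of interest to a single number.
Four families are provided:

* Legendre moments — projection of the region (bounding box mapped to
  [-1, 1]^2) onto products of Legendre polynomials; computed by the
  two-term recurrence so all orders come out of one pass.
* Zernike moments — projection onto the Zernike basis of the unit disk
  (the circumscribing circle of the bounding box); magnitudes are
  reported, which makes them rotation invariant.
* Haralick textures — 13 classic statistics of the symmetric, normalized
  gray-level co-occurrence matrix per (distance, angle).
* Region statistics — the usual intensity-histogram and shape
  descriptors of a ROI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats
from skimage import measure

from .scale_space import FeatureStack

__all__ = [
    "MomentSpec",
    "GLCMSpec",
    "RegionMask",
    "legendre_polynomials",
    "legendre_moments",
    "zernike_radial",
    "zernike_radial_direct",
    "zernike_moments",
    "haralick_features",
    "region_statistics",
    "compute_regional_vector",
]


@dataclass(frozen=True)
class MomentSpec:
    family: str = "legendre"  # or "zernike"
    max_order: int = 6

    def __post_init__(self) -> None:
        if self.family not in ("legendre", "zernike"):
            raise ValueError(f"unknown moment family {self.family!r}")
        if not (0 <= self.max_order <= 20):
            raise ValueError("max_order must be in 0..20")


@dataclass(frozen=True)
class GLCMSpec:
    distances: Tuple[int, ...] = (1, 2, 3)
    angles: Tuple[int, ...] = (0, 45, 90, 135)
    levels: int = 32

    def __post_init__(self) -> None:
        if len(self.distances) == 0 or len(self.angles) == 0:
            raise ValueError("distances and angles must be non-empty")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be positive integers")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


@dataclass(frozen=True)
class RegionMask:
    """Boolean mask inside a half-open bounding box (row0, col0, row1, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int
    mask: np.ndarray  # (row1-row0, col1-col0) boolean

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (self.row1 - self.row0, self.col1 - self.col0):
            raise ValueError("mask shape does not match bounding box")
        if not mask.any():
            raise ValueError("region mask has no true pixel")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_full_mask(cls, full: np.ndarray) -> "RegionMask":
        full = np.asarray(full, dtype=bool)
        rows = np.any(full, axis=1).nonzero()[0]
        cols = np.any(full, axis=0).nonzero()[0]
        if rows.size == 0:
            raise ValueError("empty mask")
        r0, r1 = int(rows[0]), int(rows[-1]) + 1
        c0, c1 = int(cols[0]), int(cols[-1]) + 1
        return cls(r0, c0, r1, c1, full[r0:r1, c0:c1])

    def crop(self, img: np.ndarray) -> np.ndarray:
        if self.row1 > img.shape[0] or self.col1 > img.shape[1]:
            raise ValueError("region bounding box outside image")
        return np.asarray(img, dtype=np.float64)[self.row0:self.row1, self.col0:self.col1]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.mask.shape


def _masked_crop(img: np.ndarray, region: RegionMask) -> np.ndarray:
    """Crop to the bounding box with outside-mask pixels zeroed."""
    crop = region.crop(img)
    return np.where(region.mask, crop, 0.0)


# ---------------------------------------------------------------------------
# Legendre moments

def legendre_polynomials(x, max_order: int) -> np.ndarray:
    """L_0(x)..L_n(x) by the two-term recurrence, simultaneously.

    (n+1) L_{n+1} = (2n+1) x L_n - n L_{n-1};  L_0 = 1, L_1 = x.
    Returns array of shape (max_order+1,) + shape(x).
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("Legendre argument must lie in [-1, 1]")
    out = np.empty((max_order + 1,) + x.shape, dtype=np.float64)
    out[0] = 1.0
    if max_order >= 1:
        out[1] = x
    for n in range(1, max_order):
        out[n + 1] = ((2 * n + 1) * x * out[n] - n * out[n - 1]) / (n + 1)
    return out


def legendre_moments(
    img: np.ndarray, region: RegionMask, spec: MomentSpec | None = None
) -> Dict[str, float]:
    """Legendre moment grid M_mn, 0 <= m, n <= max_order.

    The bounding box is affinely mapped to [-1, 1]^2 (pixel centers);
    M_mn = (2m+1)(2n+1)/4 * sum f(x,y) L_m(x) L_n(y) dx dy with midpoint
    quadrature.  Pixels outside the mask contribute 0.  m indexes x
    (columns), n indexes y (rows).
    """
    spec = spec or MomentSpec("legendre")
    h, w = region.shape
    if h < 2 or w < 2:
        raise ValueError("degenerate region: need at least 2x2 bounding box")
    f = _masked_crop(img, region)
    nmax = spec.max_order
    xs = -1.0 + (np.arange(w) + 0.5) * 2.0 / w
    ys = -1.0 + (np.arange(h) + 0.5) * 2.0 / h
    lx = legendre_polynomials(xs, nmax)  # (n+1, W)
    ly = legendre_polynomials(ys, nmax)  # (n+1, H)
    # S[m, n] = sum_ij f_ij L_m(x_j) L_n(y_i)
    s = np.einsum("mw,hw,nh->mn", lx, f, ly)
    dxdy = (2.0 / w) * (2.0 / h)
    out: Dict[str, float] = {}
    for m in range(nmax + 1):
        for n in range(nmax + 1):
            norm = (2 * m + 1) * (2 * n + 1) / 4.0
            out[f"legendre.M{m}{n}"] = float(norm * s[m, n] * dxdy)
    return out


# ---------------------------------------------------------------------------
# Zernike moments

def zernike_radial_direct(r, n: int, m: int) -> np.ndarray:
    """Radial Zernike polynomial by the direct factorial sum (oracle form)."""
    _check_nm(n, m)
    r = np.asarray(r, dtype=np.float64)
    out = np.zeros_like(r)
    for l in range((n - m) // 2 + 1):
        coef = (
            (-1.0) ** l
            * math.factorial(n - l)
            / (
                math.factorial(l)
                * math.factorial((n + m) // 2 - l)
                * math.factorial((n - m) // 2 - l)
            )
        )
        out = out + coef * r ** (n - 2 * l)
    return out


def _check_nm(n: int, m: int) -> None:
    if not (0 <= m <= n):
        raise ValueError(f"need 0 <= m <= n, got (n, m) = ({n}, {m})")
    if (n - m) % 2 != 0:
        raise ValueError(f"n - m must be even, got (n, m) = ({n}, {m})")


def _radial_all(r: np.ndarray, max_order: int) -> Dict[Tuple[int, int], np.ndarray]:
    """All valid R_n^m for n <= max_order via the three-term recursion.

    R_n^m = r * (R_{n-1}^{|m-1|} + R_{n-1}^{m+1}) - R_{n-2}^m, R_0^0 = 1,
    with out-of-range terms (m > n, or n - m odd, or negative index)
    taken as 0.
    """
    table: Dict[Tuple[int, int], np.ndarray] = {(0, 0): np.ones_like(r)}

    def get(n: int, m: int) -> np.ndarray:
        if n < 0 or m > n or (n - m) % 2 != 0:
            return np.zeros_like(r)
        return table[(n, m)]

    for n in range(1, max_order + 1):
        for m in range(n % 2, n + 1, 2):
            table[(n, m)] = r * (get(n - 1, abs(m - 1)) + get(n - 1, m + 1)) - get(n - 2, m)
    return table


def zernike_radial(r, n: int, m: int) -> np.ndarray:
    """Radial Zernike polynomial by the recursive scheme."""
    _check_nm(n, m)
    r = np.asarray(r, dtype=np.float64)
    return _radial_all(r, n)[(n, m)]


def zernike_moments(
    img: np.ndarray, region: RegionMask, spec: MomentSpec | None = None
) -> Dict[str, float]:
    """Rotation-invariant Zernike moment magnitudes |Z_nm|.

    The unit disk is centered on the bounding-box center with radius half
    the larger box side, so a disk-shaped region fills it exactly; pixels
    with r > 1 (box corners) are ignored.  The masked crop is normalized
    to unit range before projection.  All (n, m) with n <= max_order,
    m >= 0, n - m even are reported.
    """
    spec = spec or MomentSpec("zernike")
    h, w = region.shape
    if h < 2 or w < 2:
        raise ValueError("degenerate region: need at least 2x2 bounding box")
    f = _masked_crop(img, region)
    fmin, fmax = float(f.min()), float(f.max())
    if fmax > fmin:
        f = (f - fmin) / (fmax - fmin)
    radius = 0.5 * max(w, h)
    ys = (np.arange(h) - (h - 1) / 2.0) / radius
    xs = (np.arange(w) - (w - 1) / 2.0) / radius
    xg, yg = np.meshgrid(xs, ys)
    r = np.hypot(xg, yg)
    theta = np.arctan2(yg, xg)
    inside = r <= 1.0
    rr = np.where(inside, r, 0.0)
    table = _radial_all(rr, spec.max_order)
    darea = 1.0 / radius**2  # pixel area in unit-disk coordinates
    out: Dict[str, float] = {}
    for n in range(spec.max_order + 1):
        for m in range(n % 2, n + 1, 2):
            basis = table[(n, m)] * np.exp(-1j * m * theta)
            z = (n + 1) / math.pi * np.sum(f * np.conj(basis) * inside) * darea
            out[f"zernike.Z{n}{m}"] = float(abs(z))
    return out


# ---------------------------------------------------------------------------
# Haralick textures

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def _glcm(q: np.ndarray, mask: np.ndarray, levels: int, d: int, angle: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix over in-mask pixel pairs."""
    dr, dc = _OFFSETS[angle]
    dr, dc = dr * d, dc * d
    h, w = q.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    if r0s >= r0e or c0s >= c0e:
        return np.full((levels, levels), 0.0)
    a = q[r0s:r0e, c0s:c0e]
    b = q[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    if not valid.any():
        return np.full((levels, levels), 0.0)
    pairs = np.ravel_multi_index((a[valid], b[valid]), (levels, levels))
    p = np.bincount(pairs, minlength=levels * levels).reshape(levels, levels).astype(float)
    p = p + p.T  # symmetric
    return p / p.sum()


def _haralick_stats(p: np.ndarray) -> Dict[str, float]:
    """The 13 classic co-occurrence statistics of a normalized GLCM."""
    levels = p.shape[0]
    idx = np.arange(levels, dtype=np.float64)
    i, j = np.meshgrid(idx, idx, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(idx * px))
    mu_y = float(np.sum(idx * py))
    sd_x = math.sqrt(max(float(np.sum((idx - mu_x) ** 2 * px)), 0.0))
    sd_y = math.sqrt(max(float(np.sum((idx - mu_y) ** 2 * py)), 0.0))

    def ent(q):
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q))) if q.size else 0.0

    asm = float(np.sum(p**2))
    contrast = float(np.sum((i - j) ** 2 * p))
    if sd_x > 0 and sd_y > 0:
        correlation = float(np.sum((i - mu_x) * (j - mu_y) * p) / (sd_x * sd_y))
    else:
        correlation = 0.0  # constant region convention
    variance = float(np.sum((i - mu_x) ** 2 * p))
    idm = float(np.sum(p / (1.0 + (i - j) ** 2)))
    # sum (i+j) and difference |i-j| distributions
    ksum = np.arange(2 * levels - 1, dtype=np.float64)
    p_sum = np.bincount((i + j).astype(int).ravel(), weights=p.ravel(),
                        minlength=2 * levels - 1)
    kdiff = np.arange(levels, dtype=np.float64)
    p_diff = np.bincount(np.abs(i - j).astype(int).ravel(), weights=p.ravel(),
                         minlength=levels)
    sum_avg = float(np.sum(ksum * p_sum))
    sum_var = float(np.sum((ksum - sum_avg) ** 2 * p_sum))
    sum_ent = ent(p_sum)
    entropy = ent(p.ravel())
    diff_avg = float(np.sum(kdiff * p_diff))
    diff_var = float(np.sum((kdiff - diff_avg) ** 2 * p_diff))
    diff_ent = ent(p_diff)
    hx, hy = ent(px), ent(py)
    pxy = np.outer(px, py)
    nz = (p > 0)
    hxy1 = float(-np.sum(p[nz & (pxy > 0)] * np.log2(pxy[nz & (pxy > 0)])))
    hxy2 = ent(pxy.ravel())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    arg = -2.0 * (hxy2 - entropy)
    imc2 = math.sqrt(max(1.0 - math.exp(arg), 0.0)) if entropy <= hxy2 else 0.0
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "idm": idm,
        "sum_average": sum_avg,
        "sum_variance": sum_var,
        "sum_entropy": sum_ent,
        "entropy": entropy,
        "difference_variance": diff_var,
        "difference_entropy": diff_ent,
        "imc1": imc1,
        "imc2": imc2,
    }


def haralick_features(
    img: np.ndarray, region: RegionMask, spec: GLCMSpec | None = None
) -> Dict[str, float]:
    """13 Haralick statistics per (distance, angle) co-occurrence matrix.

    The region is quantized to ``levels`` gray bins over its own min-max
    range; a constant region maps to a single level (correlation is then
    defined as 0).
    """
    spec = spec or GLCMSpec()
    crop = region.crop(img)
    vals = crop[region.mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax > vmin:
        q = np.clip(((crop - vmin) / (vmax - vmin) * spec.levels).astype(int),
                    0, spec.levels - 1)
    else:
        q = np.zeros_like(crop, dtype=int)
    out: Dict[str, float] = {}
    for d in spec.distances:
        for angle in spec.angles:
            p = _glcm(q, region.mask, spec.levels, d, angle)
            if p.sum() == 0:
                raise ValueError(
                    f"region too small for distance {d} at angle {angle}"
                )
            stats13 = _haralick_stats(p)
            for name, v in stats13.items():
                out[f"haralick.{name}@d{d}a{angle}"] = float(v)
    return out


# ---------------------------------------------------------------------------
# Region statistics

def region_statistics(img: np.ndarray, region: RegionMask) -> Dict[str, float]:
    """Histogram and shape descriptors of a ROI.

    Statistical: mean, std, mode, min, max, center of mass, integrated
    density, median, skewness, kurtosis, area fraction.  Geometric: area,
    bounding-box width/height, centroid, perimeter, fitted-ellipse
    axes/angle, Feret diameter, form factor 4*pi*A/P^2, roundness, aspect
    ratio, solidity.
    """
    crop = region.crop(img)
    vals = crop[region.mask]
    mask_u8 = region.mask.astype(np.uint8)
    props = measure.regionprops(mask_u8, intensity_image=crop)[0]
    area = float(region.mask.sum())
    perimeter = float(measure.perimeter(region.mask))
    hist_mode = float(sstats.mode(vals, keepdims=False).mode)
    total = float(vals.sum())
    if total != 0.0:
        rr, cc = np.nonzero(region.mask)
        com_r = float(np.sum(rr * crop[rr, cc]) / total) + region.row0
        com_c = float(np.sum(cc * crop[rr, cc]) / total) + region.col0
    else:
        com_r, com_c = props.centroid[0] + region.row0, props.centroid[1] + region.col0
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    form_factor = 4.0 * math.pi * area / perimeter**2 if perimeter > 0 else 0.0
    roundness = 4.0 * area / (math.pi * major**2) if major > 0 else 0.0
    aspect = major / minor if minor > 0 else 0.0
    h, w = region.shape
    return {
        "stats.mean": float(vals.mean()),
        "stats.std": float(vals.std()),
        "stats.mode": hist_mode,
        "stats.min": float(vals.min()),
        "stats.max": float(vals.max()),
        "stats.com_row": com_r,
        "stats.com_col": com_c,
        "stats.integrated_density": total,
        "stats.median": float(np.median(vals)),
        "stats.skewness": float(sstats.skew(vals)) if vals.std() > 0 else 0.0,
        "stats.kurtosis": float(sstats.kurtosis(vals)) if vals.std() > 0 else 0.0,
        "stats.area_fraction": area / (h * w),
        "geom.area": area,
        "geom.bbox_width": float(w),
        "geom.bbox_height": float(h),
        "geom.centroid_row": float(props.centroid[0] + region.row0),
        "geom.centroid_col": float(props.centroid[1] + region.col0),
        "geom.perimeter": perimeter,
        "geom.ellipse_major": major,
        "geom.ellipse_minor": minor,
        "geom.ellipse_angle": float(props.orientation),
        "geom.feret_diameter": float(props.feret_diameter_max),
        "geom.form_factor": form_factor,
        "geom.roundness": roundness,
        "geom.aspect_ratio": aspect,
        "geom.solidity": float(props.solidity),
    }


# ---------------------------------------------------------------------------
# Compound vector

def compute_regional_vector(
    img: np.ndarray,
    region: RegionMask,
    moment_specs: Sequence[MomentSpec] = (MomentSpec("legendre"), MomentSpec("zernike")),
    glcm_spec: Optional[GLCMSpec] = GLCMSpec(),
    stack: Optional[FeatureStack] = None,
    include_statistics: bool = True,
) -> Dict[str, float]:
    """Concatenated regional features on the raw image and, optionally,
    on every plane of a feature stack (names prefixed by plane name)."""

    def block(plane: np.ndarray) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for mspec in moment_specs:
            fn = legendre_moments if mspec.family == "legendre" else zernike_moments
            out.update(fn(plane, region, mspec))
        if glcm_spec is not None:
            out.update(haralick_features(plane, region, glcm_spec))
        if include_statistics:
            out.update(region_statistics(plane, region))
        return out

    vector = {f"raw.{k}": v for k, v in block(np.asarray(img, dtype=np.float64)).items()}
    if stack is not None:
        for name, plane in stack.planes.items():
            vector.update({f"{name}.{k}": v for k, v in block(plane).items()})
    bad = [k for k, v in vector.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite regional features: {bad[:5]}")
    return vector
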