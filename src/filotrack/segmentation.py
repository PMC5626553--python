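"""Per-frame segmentation of a cell body and its filopodial protrusions.

The mapping-channel frame is enhanced with a Laplacian-of-Gaussian (LoG)
filter, binarised with an auto-threshold method, and the largest connected
object is taken to be the cell / growth-cone. Applying ``n`` binary erosions
followed by ``n`` dilations (a morphological opening) removes thin
protrusions from the mask; subtracting the opened mask from the original
leaves the protrusions, each of which receives a base point (where it meets
the body boundary) and a tip point (the pixel farthest from the base).

Coordinates are 0-based ``(row, col)`` pixel indices throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import draw as skdraw
from skimage import filters as skfilters
from skimage import measure as skmeasure

from .errors import NoObjectError, OverErosionError, ParameterError

# 3x3 square structuring element (8-connected), the common binary
# erode/dilate default.
SQUARE_3 = np.ones((3, 3), bool)

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ~2.3548


# --------------------------------------------------------------------------
# parameters and result containers
# --------------------------------------------------------------------------

@dataclass
class SegmentationParams:
    """Parameters controlling per-frame segmentation.

    ``sigma_log`` is the LoG scale in pixels and should match the expected
    filopodium half-width: the corresponding full width at half maximum is
    ``w = 2 sqrt(2 ln 2) * sigma_log`` pixels. ``ed_iterations`` is the
    number of erode/dilate steps; it must be large enough to delete the
    widest filopodium from the cell mask. ``base_back_frames`` is how many
    frames before a filopodium forms its future base position is projected
    backwards for fluorescence readout.
    """

    sigma_log: float = 2.6
    threshold_method: str = "RenyiEntropy"
    adaptive: bool = False
    ed_iterations: int = 4
    join_fragments: bool = False
    fit_tip: bool = False
    base_back_frames: int = 20
    structuring_element: str = "square"  # "square" (3x3) or "disk" (r=1)

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise ParameterError("sigma_log must be > 0")
        if self.ed_iterations < 1:
            raise ParameterError("ed_iterations must be >= 1")
        if self.base_back_frames < 0:
            raise ParameterError("base_back_frames must be >= 0")
        if self.structuring_element not in ("square", "disk"):
            raise ParameterError("structuring_element must be 'square' or 'disk'")

    @property
    def width_px(self) -> float:
        """Estimated filopodium width (FWHM of the LoG scale), in pixels."""
        return FWHM_FACTOR * self.sigma_log

    @property
    def selem(self) -> np.ndarray:
        if self.structuring_element == "square":
            return SQUARE_3
        return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)


@dataclass
class ProtrusionGeometry:
    """Geometry of one protrusion in one frame."""

    label: int
    area_px: int
    perimeter_px: float
    base_rc: np.ndarray  # (row, col), float
    tip_rc: np.ndarray   # (row, col), float
    tip_radius_px: float
    euclidean_d_px: float
    width_px: float
    pixels: np.ndarray   # (N, 2) int array of (row, col) protrusion pixels

    @property
    def base_xy(self) -> tuple[float, float]:
        return float(self.base_rc[1]), float(self.base_rc[0])

    @property
    def tip_xy(self) -> tuple[float, float]:
        return float(self.tip_rc[1]), float(self.tip_rc[0])


@dataclass
class FrameSegmentation:
    """Body/protrusion partition of one frame.

    ``body_mask`` and the protrusion labels are disjoint; their union is a
    subset of the original thresholded mask. Labels listed in ``fragments``
    do not touch the body boundary (disconnected pieces, e.g. out-of-focus
    filopodium parts) and carry no geometry unless joined.
    """

    body_mask: np.ndarray                      # bool (Y, X)
    protrusion_labels: np.ndarray              # int (Y, X), 0 = background
    boundary: np.ndarray                       # (N, 2) float, closed loop (row, col)
    fragments: set[int] = field(default_factory=set)
    geometries: Dict[int, ProtrusionGeometry] = field(default_factory=dict)

    @property
    def labels(self) -> list[int]:
        out = np.unique(self.protrusion_labels)
        return [int(v) for v in out if v != 0]


# --------------------------------------------------------------------------
# LoG filtering
# --------------------------------------------------------------------------

def log_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Sample the Laplacian-of-Gaussian kernel

    ``f(x, y) = -1/(pi sigma^4) (1 - (x^2+y^2)/(2 sigma^2)) exp(-(x^2+y^2)/(2 sigma^2))``

    on an integer grid of radius ``ceil(truncate * sigma)``. At the origin
    the kernel equals ``-1/(pi sigma^4)``; a uniform bright region therefore
    produces a response near zero while bright ridges of width comparable to
    the FWHM produce a strong *negative* response.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    radius = max(int(math.ceil(truncate * sigma)), 1)
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx ** 2 + yy ** 2
    s2 = sigma ** 2
    return (-1.0 / (math.pi * s2 ** 2)
            * (1.0 - r2 / (2.0 * s2))
            * np.exp(-r2 / (2.0 * s2)))


def log_filter(image: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Convolve ``image`` with the LoG kernel of scale ``sigma`` (pixels).

    Sign convention: bright features on a dark background give a *negative*
    response (the kernel is applied as written, centre value < 0);
    downstream thresholding negates the response so that the cell interior
    is high.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("log_filter expects a 2D image")
    kernel = log_kernel(sigma, truncate=truncate)
    if min(image.shape) < 3 * sigma:
        raise ParameterError("image must be at least 3*sigma wide")
    return ndimage.convolve(image, kernel, mode="reflect")


def directional_log_kernels(sigma: float, truncate: float = 4.0) -> list[np.ndarray]:
    """Eight one-sided LoG kernels for the principal directions.

    Each kernel is the full LoG kernel with the half-plane opposite the
    direction zeroed (the centre row/column along the dividing line is
    kept), giving an edge detector sensitive to intensity structure on one
    side only.
    """
    base = log_kernel(sigma, truncate=truncate)
    radius = base.shape[0] // 2
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    kernels = []
    for k in range(8):
        theta = k * math.pi / 4.0
        d = (math.cos(theta), math.sin(theta))
        keep = (xx * d[0] + yy * d[1]) >= 0
        kernels.append(np.where(keep, base, 0.0))
    return kernels


# --------------------------------------------------------------------------
# auto-threshold registry
# --------------------------------------------------------------------------

def _histogram_256(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram with bin centres, over the image's value range."""
    lo, hi = float(np.min(image)), float(np.max(image))
    if hi <= lo:
        hi = lo + 1.0
    counts, edges = np.histogram(image.ravel(), bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def threshold_huang(image: np.ndarray) -> float:
    """Huang & Wang fuzzy-entropy threshold on a 256-bin histogram."""
    counts, centers = _histogram_256(image)
    nz = np.nonzero(counts)[0]
    first, last = nz[0], nz[-1]
    if first == last:
        return centers[first]
    c = centers[last] - centers[first]  # fuzziness normaliser
    w = counts * centers
    cum_n = np.cumsum(counts)
    cum_w = np.cumsum(w)
    total_n, total_w = cum_n[-1], cum_w[-1]
    best_t, best_s = first, np.inf
    for t in range(first, last):
        n0 = cum_n[t]
        n1 = total_n - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = cum_w[t] / n0
        mu1 = (total_w - cum_w[t]) / n1
        mu = np.where(np.arange(256) <= t, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(centers - mu) / c)  # in [0.5, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            hf = -(u * np.log(u) + (1.0 - u) * np.log(1.0 - u))
        hf = np.nan_to_num(hf)
        s = float(np.sum(counts * hf))
        if s < best_s:
            best_s, best_t = s, t
    return float(centers[best_t])


def threshold_renyi_entropy(image: np.ndarray, alpha: float = 2.0) -> float:
    """Maximum Renyi-entropy-sum threshold (order ``alpha``) on 256 bins.

    Splits the histogram at the level maximising the sum of the Renyi
    entropies of the background and foreground class distributions; the
    ``alpha -> 1`` limit is the classic maximum-(Shannon)-entropy method.
    """
    if alpha <= 0:
        raise ParameterError("alpha must be > 0")
    counts, centers = _histogram_256(image)
    p = counts / counts.sum()
    cdf = np.cumsum(p)
    best_t, best_h = 0, -np.inf
    for t in range(255):
        p0, p1 = cdf[t], 1.0 - cdf[t]
        if p0 <= 0 or p1 <= 0:
            continue
        q0 = p[: t + 1] / p0
        q1 = p[t + 1:] / p1
        if abs(alpha - 1.0) < 1e-9:
            with np.errstate(divide="ignore", invalid="ignore"):
                h0 = -np.sum(np.where(q0 > 0, q0 * np.log(q0), 0.0))
                h1 = -np.sum(np.where(q1 > 0, q1 * np.log(q1), 0.0))
        else:
            h0 = np.log(np.sum(q0 ** alpha)) / (1.0 - alpha)
            h1 = np.log(np.sum(q1 ** alpha)) / (1.0 - alpha)
        h = h0 + h1
        if h > best_h:
            best_h, best_t = h, t
    return float(centers[best_t])


THRESHOLD_REGISTRY: Dict[str, Callable[[np.ndarray], float]] = {
    "RenyiEntropy": threshold_renyi_entropy,
    "MaxEntropy": lambda im: threshold_renyi_entropy(im, alpha=1.0),
    "Huang": threshold_huang,
    "Otsu": skfilters.threshold_otsu,
    "Triangle": skfilters.threshold_triangle,
    "Li": skfilters.threshold_li,
    "Yen": skfilters.threshold_yen,
    "Mean": skfilters.threshold_mean,
    "IsoData": skfilters.threshold_isodata,
}


def compute_threshold(image: np.ndarray, method: str) -> float:
    if method not in THRESHOLD_REGISTRY:
        raise ParameterError(
            f"unknown threshold method {method!r}; "
            f"available: {sorted(THRESHOLD_REGISTRY)}"
        )
    return float(THRESHOLD_REGISTRY[method](np.asarray(image, dtype=float)))


def threshold_mask(
    filtered: np.ndarray,
    method: str = "RenyiEntropy",
    adaptive: bool = False,
    *,
    image: Optional[np.ndarray] = None,
    sigma: Optional[float] = None,
    fill_holes: bool = True,
) -> np.ndarray:
    """Binarise a LoG-filtered frame into a foreground mask.

    The LoG response of bright structures is negative, so thresholding is
    applied to the *negated* response (cell interior high). With
    ``adaptive=True`` the raw ``image`` and ``sigma`` must be supplied: the
    image is convolved with eight one-sided LoG kernels, each response is
    thresholded separately, the per-direction masks are OR-combined and a
    3x3 median filter removes speckle.

    A membrane marker outlines the cell, so interior holes in the
    thresholded ring are filled by default.
    """
    if adaptive:
        if image is None or sigma is None:
            raise ParameterError("adaptive thresholding needs image= and sigma=")
        combined = np.zeros(np.asarray(image).shape, dtype=bool)
        for kernel in directional_log_kernels(sigma):
            resp = -ndimage.convolve(np.asarray(image, float), kernel, mode="reflect")
            combined |= resp > compute_threshold(resp, method)
        mask = ndimage.median_filter(combined.astype(np.uint8), size=3).astype(bool)
    else:
        resp = -np.asarray(filtered, dtype=float)
        mask = resp > compute_threshold(resp, method)
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask


# --------------------------------------------------------------------------
# mask partitioning
# --------------------------------------------------------------------------

def extract_cell_mask(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component (assumed cell body).

    Ties are broken deterministically in favour of the lowest component
    label (first encountered in scan order).
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=SQUARE_3)
    if n == 0:
        raise NoObjectError("mask contains no object")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1  # argmax -> lowest index on ties
    return labels == keep


def body_boundary(body_mask: np.ndarray) -> np.ndarray:
    """Ordered closed boundary polygon of the body mask (sub-pixel, (row, col))."""
    contours = skmeasure.find_contours(body_mask.astype(float), 0.5)
    if not contours:
        raise NoObjectError("body mask has no boundary")
    return max(contours, key=len)


def split_body_protrusions(
    mask: np.ndarray,
    ed_iterations: int,
    selem: np.ndarray = SQUARE_3,
) -> FrameSegmentation:
    """Partition a cell mask into body and protrusions by n-fold erode/dilate.

    ``body = dilate^n(erode^n(mask & largest))``; protrusion candidates are
    the connected components of ``mask & ~body``. Components that do not
    touch the body (8-connectivity) are flagged as fragments.
    """
    mask = np.asarray(mask, dtype=bool)
    if ed_iterations < 1:
        raise ParameterError("ed_iterations must be >= 1")
    cell = extract_cell_mask(mask)
    eroded = ndimage.binary_erosion(cell, structure=selem,
                                    iterations=ed_iterations, border_value=0)
    if not eroded.any():
        raise OverErosionError(
            f"erosion with n={ed_iterations} removed the entire mask; "
            "reduce ed_iterations"
        )
    body = ndimage.binary_dilation(eroded, structure=selem,
                                   iterations=ed_iterations, border_value=0)
    body &= cell  # opening is a subset of cell; guard against border effects
    protr = mask & ~body
    labels, n = ndimage.label(protr, structure=SQUARE_3)
    body_halo = ndimage.binary_dilation(body, structure=SQUARE_3)
    fragments = set()
    for lab in range(1, n + 1):
        if not (body_halo & (labels == lab)).any():
            fragments.add(lab)
    return FrameSegmentation(
        body_mask=body,
        protrusion_labels=labels,
        boundary=body_boundary(body),
        fragments=fragments,
    )


def join_fragments(seg: FrameSegmentation, max_iterations: int = 10) -> FrameSegmentation:
    """Connect disconnected protrusion fragments to the cell structure.

    Repeatedly draws the shortest 1-px line between the two closest
    disconnected components (fragments join each other first when they are
    mutually closest, then the merged piece joins the cell), for at most
    ``max_iterations`` rounds. Fragments still disconnected afterwards stay
    flagged and carry no geometry.
    """
    if not seg.fragments:
        return seg
    full = seg.body_mask | (seg.protrusion_labels > 0)
    for _ in range(max_iterations):
        labels, n = ndimage.label(full, structure=SQUARE_3)
        if n <= 1:
            break
        comp_pixels = {lab: np.argwhere(labels == lab) for lab in range(1, n + 1)}
        # closest pair of distinct components
        best = None
        for a in range(1, n + 1):
            tree = cKDTree(comp_pixels[a])
            for b in range(a + 1, n + 1):
                dists, idx = tree.query(comp_pixels[b])
                j = int(np.argmin(dists))
                if best is None or dists[j] < best[0]:
                    best = (float(dists[j]), comp_pixels[a][idx[j]], comp_pixels[b][j])
        if best is None:
            break
        _, p, q = best
        rr, cc = skdraw.line(int(p[0]), int(p[1]), int(q[0]), int(q[1]))
        full[rr, cc] = True
    protr = full & ~seg.body_mask
    labels, n = ndimage.label(protr, structure=SQUARE_3)
    body_halo = ndimage.binary_dilation(seg.body_mask, structure=SQUARE_3)
    fragments = set()
    for lab in range(1, n + 1):
        if not (body_halo & (labels == lab)).any():
            fragments.add(lab)
    return FrameSegmentation(
        body_mask=seg.body_mask,
        protrusion_labels=labels,
        boundary=seg.boundary,
        fragments=fragments,
        geometries={},
    )


# --------------------------------------------------------------------------
# base/tip assignment and tip fitting
# --------------------------------------------------------------------------

def assign_base_tip(
    seg: FrameSegmentation,
    label: int,
    params: SegmentationParams,
    perimeter_method: str = "crofton",
) -> ProtrusionGeometry:
    """Assign base and tip points and measure one protrusion.

    The base is the centroid of the pixels where the protrusion touches the
    body, snapped to the nearest body-boundary point; the tip is the
    protrusion pixel with maximum Euclidean distance from the base. Note
    that for strongly bent (looping/buckling) protrusions the farthest pixel
    need not be the morphological tip.
    """
    pmask = seg.protrusion_labels == label
    if not pmask.any():
        raise ParameterError(f"label {label} not present in segmentation")
    if label in seg.fragments:
        raise NoObjectError(
            f"protrusion {label} does not touch the body (fragment); "
            "enable fragment joining or exclude it"
        )
    contact = pmask & ndimage.binary_dilation(seg.body_mask, structure=SQUARE_3)
    if not contact.any():
        raise NoObjectError(f"protrusion {label} has no body contact pixels")
    centroid = np.argwhere(contact).mean(axis=0)
    # snap to the nearest point on the body boundary polygon
    d2 = np.sum((seg.boundary - centroid) ** 2, axis=1)
    base = seg.boundary[int(np.argmin(d2))].astype(float)

    pixels = np.argwhere(pmask)
    dist2 = np.sum((pixels - base) ** 2, axis=1)
    tip = pixels[int(np.argmax(dist2))].astype(float)

    if perimeter_method == "crofton":
        perimeter = float(skmeasure.perimeter_crofton(pmask, directions=4))
    else:
        perimeter = float(skmeasure.perimeter(pmask))
    width = params.width_px
    return ProtrusionGeometry(
        label=int(label),
        area_px=int(pmask.sum()),
        perimeter_px=perimeter,
        base_rc=base,
        tip_rc=tip,
        tip_radius_px=width / 2.0,
        euclidean_d_px=float(np.sqrt(np.max(dist2))),
        width_px=width,
        pixels=pixels,
    )


def fit_tip(geom: ProtrusionGeometry, measurement_image: np.ndarray) -> ProtrusionGeometry:
    """Refine the tip position against the measurement channel.

    Searches a radius ``r = clamp(sqrt((area/2)/pi), 3, 20)`` pixels around
    the mapped tip for local intensity maxima; the tip is moved to their
    intensity-weighted mean position and the tip radius is set to half the
    mean squared error of the maxima about the new tip (floored at 1 px). If
    no strict local maximum exists inside the search disk (e.g. a uniform
    channel), the geometry is returned unchanged.
    """
    img = np.asarray(measurement_image, dtype=float)
    r = float(np.clip(math.sqrt((geom.area_px / 2.0) / math.pi), 3.0, 20.0))
    rr, cc = np.ogrid[: img.shape[0], : img.shape[1]]
    within = (rr - geom.tip_rc[0]) ** 2 + (cc - geom.tip_rc[1]) ** 2 <= r ** 2
    maxfilt = ndimage.maximum_filter(img, size=3, mode="nearest")
    minfilt = ndimage.minimum_filter(img, size=3, mode="nearest")
    maxima = (img == maxfilt) & (maxfilt > minfilt) & within
    coords = np.argwhere(maxima)
    if coords.size == 0:
        return geom
    weights = img[maxima]
    if weights.sum() <= 0:
        return geom
    new_tip = (coords * weights[:, None]).sum(axis=0) / weights.sum()
    mse = float(np.mean(np.sum((coords - new_tip) ** 2, axis=1)))
    new_radius = max(mse / 2.0, 1.0)
    d = float(np.linalg.norm(new_tip - geom.base_rc))
    return replace(geom, tip_rc=new_tip, tip_radius_px=new_radius, euclidean_d_px=d)


def geometry_from_mask(
    mask: np.ndarray,
    base_rc: Sequence[float],
    params: SegmentationParams,
    label: int = 1,
) -> ProtrusionGeometry:
    """Measure a free-standing protrusion mask with a known base point.

    Convenience for validation against rasterised shapes: the tip is the
    mask pixel farthest from the given base, and area/perimeter/D are
    computed as in :func:`assign_base_tip`.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoObjectError("empty mask")
    base = np.asarray(base_rc, dtype=float)
    pixels = np.argwhere(mask)
    dist2 = np.sum((pixels - base) ** 2, axis=1)
    tip = pixels[int(np.argmax(dist2))].astype(float)
    width = params.width_px
    return ProtrusionGeometry(
        label=label,
        area_px=int(mask.sum()),
        perimeter_px=float(skmeasure.perimeter_crofton(mask, directions=4)),
        base_rc=base,
        tip_rc=tip,
        tip_radius_px=width / 2.0,
        euclidean_d_px=float(np.sqrt(np.max(dist2))),
        width_px=width,
        pixels=pixels,
    )


# --------------------------------------------------------------------------
# per-frame driver
# --------------------------------------------------------------------------

def segment_frame(
    image: np.ndarray,
    params: SegmentationParams,
    measurement_image: Optional[np.ndarray] = None,
) -> FrameSegmentation:
    """Run the full segmentation chain on one mapping-channel frame."""
    if params.adaptive:
        mask = threshold_mask(None, params.threshold_method, adaptive=True,
                              image=image, sigma=params.sigma_log)
    else:
        filtered = log_filter(image, params.sigma_log)
        mask = threshold_mask(filtered, params.threshold_method)
    if not params.join_fragments:
        mask = extract_cell_mask(mask)
    seg = split_body_protrusions(mask, params.ed_iterations, selem=params.selem)
    if params.join_fragments:
        seg = join_fragments(seg)
    for label in seg.labels:
        if label in seg.fragments:
            continue
        geom = assign_base_tip(seg, label, params)
        if params.fit_tip and measurement_image is not None:
            geom = fit_tip(geom, measurement_image)
        seg.geometries[label] = geom
    return seg
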