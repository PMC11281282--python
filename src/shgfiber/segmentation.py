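"""Fiber segmentation by intensity-based fuzzy c-means (FCM) clustering.

Collagen fibers appear as bright curvilinear structures on a dark, noisy
background.  Segmentation proceeds in two steps: a light preprocessing pass
(median filter plus background-percentile subtraction) and soft clustering of
the voxel intensities into ``c`` classes with fuzzy c-means.  The cluster with
the highest centroid is taken as the fiber class and defuzzified by argmax
membership.  Spatial regularity is not enforced here; non-fibrillar structures
that share the fiber intensity range are removed downstream by the shape
filter (:mod:`shgfiber.morphometry`).

The FCM objective being minimised is

    J(U, V) = sum_i sum_k u_ik^m * (x_i - v_k)^2,

subject to ``sum_k u_ik = 1`` for every voxel ``i``, with fuzziness exponent
``m > 1``.  Alternating optimisation updates are the classical ones:

    v_k  = sum_i u_ik^m x_i / sum_i u_ik^m
    u_ik = 1 / sum_j (d_ik / d_ij)^(2/(m-1)),   d_ik = |x_i - v_k|

with the convention that a voxel sitting exactly on a centroid gets full
membership in that cluster.  Each full sweep can only decrease J.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .images import FiberMask, ShgImage


class DegenerateInputError(ValueError):
    """Raised when the input cannot support the requested number of clusters."""


@dataclass
class FcmConfig:
    """Settings for fuzzy c-means intensity clustering.

    Parameters
    ----------
    n_clusters
        Number of intensity classes ``c``; 2 separates background from fiber,
        3 adds a diffuse intermediate class (top cluster is always the fiber).
    fuzziness
        Exponent ``m > 1``; 2.0 is the conventional choice.  As ``m -> 1`` the
        partition hardens toward k-means.
    tol
        Convergence tolerance on the maximum centroid movement, expressed as a
        fraction of the intensity range of the data.
    max_iter
        Iteration cap for the alternating updates.
    init
        ``"quantile"`` places initial centroids at evenly spaced intensity
        quantiles (deterministic); ``"random"`` samples distinct data values
        using ``seed``.
    """

    n_clusters: int = 2
    fuzziness: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    init: str = "quantile"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.fuzziness <= 1:
            raise ValueError("fuzziness m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.init not in ("quantile", "random"):
            raise ValueError("init must be 'quantile' or 'random'")


@dataclass
class FcmResult:
    """Output of a fuzzy c-means run.

    ``centroids`` are sorted ascending and ``membership`` columns follow the
    same order; ``objective_history`` holds J after every full sweep and is
    non-increasing.
    """

    centroids: np.ndarray
    membership: np.ndarray
    n_iter: int
    objective: float
    objective_history: np.ndarray = field(repr=False, default=None)


def _init_centroids(x: np.ndarray, config: FcmConfig) -> np.ndarray:
    c = config.n_clusters
    if config.init == "random":
        rng = np.random.default_rng(config.seed)
        v = rng.choice(np.unique(x), size=c, replace=False).astype(float)
    else:
        q = (np.arange(c) + 0.5) / c
        v = np.quantile(x, q)
        if np.unique(v).size < c:
            # heavily skewed data can collapse quantiles; spread over the
            # unique values instead
            uniq = np.unique(x)
            idx = np.linspace(0, uniq.size - 1, c).round().astype(int)
            v = uniq[idx].astype(float)
    return np.sort(v)


def _memberships(d: np.ndarray, m: float) -> np.ndarray:
    """Membership matrix from a (n, c) distance matrix."""
    with np.errstate(divide="ignore", invalid="ignore"):
        w = d ** (-2.0 / (m - 1.0))
        u = w / w.sum(axis=1, keepdims=True)
    hit = ~np.isfinite(w).all(axis=1)  # voxel exactly on >=1 centroid
    if np.any(hit):
        onehot = (d[hit] == 0).astype(float)
        u[hit] = onehot / onehot.sum(axis=1, keepdims=True)
    return u


def fuzzy_c_means(values, config: FcmConfig | None = None) -> FcmResult:
    """Cluster scalar intensities with fuzzy c-means.

    Parameters
    ----------
    values
        Flat (or flattenable) array of intensities.
    config
        Clustering settings; defaults to ``FcmConfig()``.

    Returns
    -------
    FcmResult
        Centroids sorted ascending, the (n, c) membership matrix in matching
        column order, the iteration count, and the final objective J.

    Raises
    ------
    DegenerateInputError
        If the data holds fewer distinct values than requested clusters.
    """
    config = config or FcmConfig()
    x = np.asarray(values, dtype=float).ravel()
    if np.unique(x).size < config.n_clusters:
        raise DegenerateInputError(
            f"need at least {config.n_clusters} distinct values, "
            f"got {np.unique(x).size}"
        )
    span = float(x.max() - x.min())
    tol_abs = config.tol * (span if span > 0 else 1.0)
    m = config.fuzziness

    v = _init_centroids(x, config)
    history = []
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        d = np.abs(x[:, None] - v[None, :])
        u = _memberships(d, m)
        um = u**m
        denom = um.sum(axis=0)
        v_new = (um * x[:, None]).sum(axis=0) / denom
        history.append(float((um * (x[:, None] - v_new[None, :]) ** 2).sum()))
        shift = float(np.max(np.abs(v_new - v)))
        v = v_new
        if shift < tol_abs:
            break

    # final half-step so the returned memberships match the returned centroids
    d = np.abs(x[:, None] - v[None, :])
    u = _memberships(d, m)
    history.append(float((u**m * d**2).sum()))

    order = np.argsort(v)
    return FcmResult(
        centroids=v[order],
        membership=u[:, order],
        n_iter=n_iter,
        objective=history[-1],
        objective_history=np.asarray(history),
    )


def preprocess(
    image: ShgImage,
    median_radius_px: int = 1,
    background_percentile: float = 25.0,
) -> ShgImage:
    """Denoise an SHG image before clustering.

    Applies a median filter with a disk footprint of the given radius (0 skips
    filtering), then subtracts the given intensity percentile of the whole
    image and clips at zero.  For z-stacks the median filter runs per plane.
    """
    if median_radius_px < 0:
        raise ValueError("median_radius_px must be >= 0")
    if not 0 <= background_percentile < 100:
        raise ValueError("background_percentile must be in [0, 100)")
    data = image.intensities
    if median_radius_px > 0:
        footprint = disk(median_radius_px)
        if image.is_stack:
            data = np.stack([ndimage.median_filter(p, footprint=footprint) for p in data])
        else:
            data = ndimage.median_filter(data, footprint=footprint)
    if background_percentile > 0:
        data = np.clip(data - np.percentile(data, background_percentile), 0, None)
    return ShgImage(data, pixel_size_um=image.pixel_size_um, z_step_um=image.z_step_um)


def segment_fibers(
    image: ShgImage,
    config: FcmConfig | None = None,
    per_slice: bool = False,
) -> FiberMask:
    """Extract a candidate fiber mask from an SHG image.

    Voxel intensities are clustered with :func:`fuzzy_c_means`; the cluster
    with the highest centroid is the fiber class, and a voxel enters the mask
    iff its membership in that cluster is strictly the largest (ties are
    background).  3D stacks are maximum-intensity projected by default;
    ``per_slice=True`` instead segments every plane independently and returns
    a 3D mask.

    A constant image cannot be clustered; it yields an empty mask with a
    warning rather than an error.
    """
    config = config or FcmConfig()
    if image.is_stack and not per_slice:
        image = image.max_project()
    if image.is_stack and per_slice:
        planes = [
            segment_fibers(
                ShgImage(p, pixel_size_um=image.pixel_size_um), config=config
            ).mask
            for p in image.intensities
        ]
        return FiberMask(np.stack(planes), pixel_size_um=image.pixel_size_um)

    x = image.intensities.ravel()
    try:
        result = fuzzy_c_means(x, config)
    except DegenerateInputError:
        warnings.warn("image has too few distinct intensities; returning empty mask")
        return FiberMask(np.zeros(image.shape, dtype=bool), pixel_size_um=image.pixel_size_um)

    u = result.membership
    fiber = u.shape[1] - 1  # centroids sorted ascending -> last is brightest
    others = np.delete(u, fiber, axis=1).max(axis=1)
    flat = u[:, fiber] > others  # strict: ties are not fiber
    return FiberMask(flat.reshape(image.shape), pixel_size_um=image.pixel_size_um)
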