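"""Canopy segmentation in the visible image.

Plant pixels are identified by colour alone: the RGB image is converted to
CIELAB, and only the chromatic channels a* (green-red) and b* (blue-yellow)
are clustered with mean shift, which makes the result robust to lightness
differences across a scene (shadows, sun angle). Clusters whose mode lies on
the green side of the a* axis are taken as plant material; the resulting
binary mask is then eroded so that mixed plant/background border pixels never
enter the temperature statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial.distance import pdist
from skimage import color as _skcolor
from sklearn.cluster import MeanShift
from sklearn.metrics import pairwise_distances_argmin

__all__ = [
    "LabelImage",
    "rgb_to_lab",
    "mean_shift_ab",
    "select_plant_mask",
    "erode_mask",
    "estimate_bandwidth_ab",
]

logger = logging.getLogger(__name__)


@dataclass
class LabelImage:
    """Mean-shift clustering result: one integer label per pixel.

    ``labels`` is H x W with contiguous labels starting at 0; ``mode_centers``
    holds the converged (a*, b*) mode of each label, indexed by label. Labels
    are ordered by ascending a* of their mode, so greener clusters come first.
    """

    labels: np.ndarray
    mode_centers: np.ndarray = field(repr=False)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        centers = np.asarray(self.mode_centers, dtype=float)
        if labels.min() != 0 or labels.max() != len(centers) - 1:
            raise ValueError("labels must be contiguous from 0 and index mode_centers")
        self.labels = labels
        self.mode_centers = centers

    @property
    def n_clusters(self) -> int:
        return len(self.mode_centers)


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("RGB image must be H x W x 3")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("RGB values must lie in [0, 255]")
    return img


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB image to CIELAB (D65).

    The standard chain is applied pixel-wise: sRGB gamma decoding, linear
    RGB -> XYZ under D65, XYZ -> L*a*b*. L* spans [0, 100]; a* and b* are in
    the usual roughly [-128, 127] range.
    """
    img = _validate_rgb(img)
    return _skcolor.rgb2lab(np.ascontiguousarray(img, dtype=np.uint8))


def estimate_bandwidth_ab(
    ab: np.ndarray, quantile: float = 0.2, subsample: int = 1000, seed: int = 0
) -> float:
    """Bandwidth heuristic: a quantile of pairwise a*b* distances on a subsample."""
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if len(ab) > subsample:
        ab = ab[rng.choice(len(ab), size=subsample, replace=False)]
    d = pdist(ab)
    d = d[d > 0]
    if len(d) == 0:  # constant-colour image: any positive bandwidth works
        return 1.0
    return float(np.quantile(d, quantile))


def mean_shift_ab(
    lab: np.ndarray,
    bandwidth: float | str = "auto",
    subsample: int = 1000,
    seed: int = 0,
    quantile: float = 0.2,
    min_seed_fraction: float = 0.01,
) -> LabelImage:
    """Cluster pixels by mean shift in the 2-D (a*, b*) chroma plane.

    L* is deliberately ignored. Mode seeking runs on a seeded random pixel
    subsample for speed; every pixel of the full image is then assigned to the
    nearest converged mode.

    Parameters
    ----------
    bandwidth : float or "auto"
        Flat-kernel radius in a*b* units. "auto" estimates it as the
        ``quantile`` quantile of pairwise distances on the subsample.
    min_seed_fraction : float
        Mode seeking starts only from bandwidth-sized bins holding at least
        this fraction of the fitted points. Isolated noise-tail pixels midway
        between colour populations otherwise converge to their own spurious
        modes under the flat kernel.
    """
    lab = np.asarray(lab, dtype=float)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError("Lab image must be H x W x 3")
    h, w = lab.shape[:2]
    ab = lab[..., 1:].reshape(-1, 2)

    if bandwidth == "auto":
        bw = estimate_bandwidth_ab(ab, quantile=quantile, subsample=subsample, seed=seed)
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be > 0")

    rng = np.random.default_rng(seed)
    if len(ab) > subsample:
        fit_pts = ab[rng.choice(len(ab), size=subsample, replace=False)]
    else:
        fit_pts = ab
    min_bin_freq = max(1, int(min_seed_fraction * len(fit_pts)))
    # bin_seeding fails if the bandwidth bin grid collapses (tiny bandwidth);
    # fall back to seeding on the points themselves.
    try:
        ms = MeanShift(bandwidth=bw, bin_seeding=True, min_bin_freq=min_bin_freq).fit(fit_pts)
    except ValueError:
        ms = MeanShift(bandwidth=bw, bin_seeding=False).fit(fit_pts)
    centers = ms.cluster_centers_

    order = np.lexsort((centers[:, 1], centers[:, 0]))  # ascending a*, then b*
    centers = centers[order]
    labels = pairwise_distances_argmin(ab, centers).reshape(h, w)

    # Drop modes that end up owning no pixel after full-image assignment.
    present = np.unique(labels)
    if len(present) < len(centers):
        remap = -np.ones(len(centers), dtype=int)
        remap[present] = np.arange(len(present))
        labels = remap[labels]
        centers = centers[present]

    if len(centers) == 1:
        logger.info("mean shift produced a single cluster (bandwidth=%.3g)", bw)
    return LabelImage(labels=labels, mode_centers=centers)


def select_plant_mask(
    label_img: LabelImage,
    a_threshold: float = 0.0,
    override_labels: list[int] | None = None,
) -> np.ndarray:
    """Designate plant clusters and return their union as a boolean mask.

    Default rule: clusters whose mode a* falls below ``a_threshold`` (green
    side of the axis) are plant. An explicit ``override_labels`` list replaces
    the rule, mirroring a manual annotation workflow. If nothing qualifies an
    empty mask is returned with a warning rather than an error.
    """
    if override_labels is not None:
        chosen = np.asarray(sorted(set(int(v) for v in override_labels)))
        if (chosen < 0).any() or (chosen >= label_img.n_clusters).any():
            raise ValueError(f"override labels {chosen.tolist()} out of range")
    else:
        chosen = np.nonzero(label_img.mode_centers[:, 0] < a_threshold)[0]
    if len(chosen) == 0:
        warnings.warn(
            "no cluster satisfies the plant rule; returning an empty mask",
            stacklevel=2,
        )
        return np.zeros(label_img.labels.shape, dtype=bool)
    return np.isin(label_img.labels, chosen)


def erode_mask(mask: np.ndarray, selem_radius: int = 1, iterations: int = 1) -> np.ndarray:
    """Morphologically erode a binary mask with a square structuring element.

    A square of side ``2 * selem_radius + 1`` is applied ``iterations`` times,
    removing border pixels that could mix plant and background temperatures.
    Pixels beyond the image frame count as background, so a mask touching the
    frame erodes there too. The result is always a subset of the input.
    """
    if selem_radius < 1:
        raise ValueError("selem_radius must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    footprint = np.ones((2 * selem_radius + 1, 2 * selem_radius + 1), dtype=bool)
    return binary_erosion(mask, structure=footprint, iterations=iterations, border_value=0)
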