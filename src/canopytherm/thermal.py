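"""Radiometry and canopy temperature statistics.

A thermal camera reports *apparent* temperature: the temperature a blackbody
would need to produce the observed radiance. A real leaf is modelled as a
greybody with emissivity close to but below one (0.98 is the standard canopy
value), so the observed radiance mixes emission from the leaf with reflected
radiance from the surroundings:

    sigma * T_app**4 = eps * sigma * T_obj**4 + (1 - eps) * sigma * T_refl**4

with all temperatures absolute (Kelvin) under the Stefan-Boltzmann fourth
power law and atmospheric transmission taken as one over short ranges. The
correction inverts this for T_obj. Canopy temperature (CT) is then the
arithmetic mean of leaf-pixel temperatures under the aligned canopy mask, and
drought response is quantified as deltaCT: mean CT of stressed plants minus
mean CT of the well-watered controls of the same genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ThermalMeta",
    "ThermalImage",
    "CTSummary",
    "CanopySample",
    "ThermalHistogram",
    "greybody_correct",
    "greybody_forward",
    "extract_canopy_pixels",
    "histogram",
    "canopy_temperature",
    "delta_ct",
    "ground_sampling_distance",
]

_ZERO_C_IN_K = 273.15


@dataclass(frozen=True)
class ThermalMeta:
    """Acquisition metadata carried with a thermogram."""

    emissivity_setting: float = 1.0
    reflected_temp_c: float = 20.0
    height_m: float | None = None
    timestamp: str | None = None


@dataclass(frozen=True)
class ThermalImage:
    """Single-channel apparent-temperature raster in degrees Celsius."""

    temps_c: np.ndarray
    meta: ThermalMeta = field(default_factory=ThermalMeta)
    plausible_range_c: tuple[float, float] = (-20.0, 80.0)

    def __post_init__(self):
        arr = np.asarray(self.temps_c, dtype=float)
        if arr.ndim != 2:
            raise ValueError("thermal image must be a 2-D array")
        if not np.isfinite(arr).all():
            raise ValueError("thermal image contains non-finite values")
        lo, hi = self.plausible_range_c
        if arr.min() < lo or arr.max() > hi:
            warnings.warn(
                f"thermal values outside plausible range [{lo}, {hi}] degC "
                f"(observed [{arr.min():.1f}, {arr.max():.1f}])",
                stacklevel=2,
            )
        object.__setattr__(self, "temps_c", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.temps_c.shape


def greybody_correct(
    apparent: ThermalImage | np.ndarray,
    emissivity: float,
    reflected_temp_c: float,
) -> ThermalImage | np.ndarray:
    """Recover object temperature from apparent temperature.

    Solves ``T_app^4 = eps*T_obj^4 + (1-eps)*T_refl^4`` (Kelvin) for T_obj and
    converts back to Celsius. ``emissivity`` must lie in (0, 1]; at 1 the
    correction is the identity. An array input returns an array; a
    ``ThermalImage`` returns a new ``ThermalImage`` with updated metadata.
    """
    if not 0.0 < emissivity <= 1.0:
        raise ValueError(f"emissivity must be in (0, 1], got {emissivity}")
    arr = apparent.temps_c if isinstance(apparent, ThermalImage) else np.asarray(apparent, float)
    t_app = arr + _ZERO_C_IN_K
    t_refl = reflected_temp_c + _ZERO_C_IN_K
    obj4 = (t_app**4 - (1.0 - emissivity) * t_refl**4) / emissivity
    if (obj4 <= 0).any():
        raise ValueError(
            "greybody correction yields non-positive absolute temperature; "
            "check emissivity and reflected temperature"
        )
    corrected = obj4**0.25 - _ZERO_C_IN_K
    if isinstance(apparent, ThermalImage):
        meta = replace(
            apparent.meta, emissivity_setting=emissivity, reflected_temp_c=reflected_temp_c
        )
        return ThermalImage(temps_c=corrected, meta=meta,
                            plausible_range_c=apparent.plausible_range_c)
    return corrected


def greybody_forward(
    object_temp_c: np.ndarray, emissivity: float, reflected_temp_c: float
) -> np.ndarray:
    """Forward model: apparent temperature a camera would report for a greybody."""
    if not 0.0 < emissivity <= 1.0:
        raise ValueError(f"emissivity must be in (0, 1], got {emissivity}")
    t_obj = np.asarray(object_temp_c, float) + _ZERO_C_IN_K
    t_refl = reflected_temp_c + _ZERO_C_IN_K
    app4 = emissivity * t_obj**4 + (1.0 - emissivity) * t_refl**4
    return app4**0.25 - _ZERO_C_IN_K


def extract_canopy_pixels(img: ThermalImage | np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Temperatures at True mask positions, row-major order."""
    arr = img.temps_c if isinstance(img, ThermalImage) else np.asarray(img, float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {arr.shape}")
    if not mask.any():
        raise ValueError("no canopy pixels: mask is empty")
    return arr[mask]


@dataclass(frozen=True)
class ThermalHistogram:
    """Uniform-bin frequency histogram of canopy pixel temperatures."""

    bin_edges_c: np.ndarray
    counts: np.ndarray
    bin_width_c: float

    def __post_init__(self):
        edges = np.asarray(self.bin_edges_c, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        if len(edges) != len(counts) + 1:
            raise ValueError("need len(edges) == len(counts) + 1")
        if not (np.diff(edges) > 0).all():
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "bin_edges_c", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_centers_c(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_c[:-1] + self.bin_edges_c[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_c": self.bin_edges_c[:-1],
                "bin_right_c": self.bin_edges_c[1:],
                "count": self.counts,
            }
        )


def histogram(pixels: np.ndarray, bin_width_c: float = 0.5) -> ThermalHistogram:
    """Histogram pixel temperatures on uniform bins.

    Bins step by ``bin_width_c`` from floor(min) up to at least ceil(max), so
    every pixel is counted exactly once.
    """
    if bin_width_c <= 0:
        raise ValueError("bin_width_c must be > 0")
    pixels = np.asarray(pixels, dtype=float).ravel()
    if len(pixels) == 0:
        raise ValueError("empty pixel vector")
    lo = np.floor(pixels.min())
    hi = np.ceil(pixels.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width_c)))
    edges = lo + bin_width_c * np.arange(n_bins + 1)
    counts, _ = np.histogram(pixels, bins=edges)
    return ThermalHistogram(bin_edges_c=edges, counts=counts, bin_width_c=bin_width_c)


@dataclass(frozen=True)
class CTSummary:
    """Summary statistics of one canopy's pixel temperatures (degC)."""

    mean_c: float
    median_c: float
    p5_c: float
    p95_c: float
    n_pixels: int


def canopy_temperature(pixels: np.ndarray) -> CTSummary:
    """Summarize canopy pixel temperatures.

    The arithmetic mean is the CT statistic used downstream; the median and
    the 5th/95th percentiles (linear interpolation) are reported so outliers
    remain auditable without being removed.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    if len(pixels) == 0:
        raise ValueError("empty pixel vector")
    p5, med, p95 = np.percentile(pixels, [5, 50, 95])
    return CTSummary(
        mean_c=float(pixels.mean()),
        median_c=float(med),
        p5_c=float(p5),
        p95_c=float(p95),
        n_pixels=len(pixels),
    )


@dataclass(frozen=True)
class CanopySample:
    """One plant x date: extracted pixels and their CT summary."""

    genotype: str
    treatment: str
    replicate: int
    day_of_stress: int | None
    pixel_temps_c: np.ndarray
    summary: CTSummary

    @classmethod
    def from_pixels(cls, genotype, treatment, replicate, pixels, day_of_stress=None):
        return cls(
            genotype=genotype,
            treatment=treatment,
            replicate=int(replicate),
            day_of_stress=day_of_stress,
            pixel_temps_c=np.asarray(pixels, dtype=float),
            summary=canopy_temperature(pixels),
        )

    @property
    def ct_mean_c(self) -> float:
        return self.summary.mean_c


def delta_ct(
    ct_drought: np.ndarray, ct_control: np.ndarray
) -> tuple[float, pd.DataFrame]:
    """Drought-induced canopy temperature increase.

    deltaCT = mean(CT drought) - mean(CT control). The per-replicate table
    (each drought replicate's CT minus the control mean) supports variance
    estimation and genotype comparisons of the increase itself.
    """
    ct_drought = np.asarray(ct_drought, dtype=float).ravel()
    ct_control = np.asarray(ct_control, dtype=float).ravel()
    if len(ct_drought) == 0 or len(ct_control) == 0:
        raise ValueError("replicate CT lists must be nonempty")
    control_mean = ct_control.mean()
    table = pd.DataFrame(
        {
            "replicate": np.arange(1, len(ct_drought) + 1),
            "ct_drought_c": ct_drought,
            "control_mean_c": control_mean,
            "delta_ct_c": ct_drought - control_mean,
        }
    )
    return float(ct_drought.mean() - control_mean), table


def ground_sampling_distance(fov_deg: float, n_pixels_across: int, height_m: float) -> float:
    """Ground extent of one pixel (m) for a lens of given field of view.

    GSD = 2 * height * tan(fov / 2) / n_pixels_across. For a 25 degree lens
    with 320 pixels across flown at 20 m this is about 0.028 m, i.e. a 2.8 cm
    pixel -- below the width of an adult maize leaf.
    """
    if not 0 < fov_deg < 180:
        raise ValueError("fov_deg must be in (0, 180)")
    if n_pixels_across < 1:
        raise ValueError("n_pixels_across must be >= 1")
    if height_m <= 0:
        raise ValueError("height_m must be > 0")
    return 2.0 * height_m * np.tan(np.deg2rad(fov_deg) / 2.0) / n_pixels_across
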