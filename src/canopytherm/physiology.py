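"""Physiological formulas and the per-plant record schema.

Pure arithmetic on directly measured quantities:

* leaf relative water content, LRWC = 100 * (FW - DW) / (TW - DW), hydration
  of a leaf piece relative to full turgor;
* maximum photosystem II quantum yield from dark-adapted fluorescence,
  Fv/Fm = (Fm - Fo) / Fm;
* water-use efficiency as the ratio of net CO2 assimilation to transpiration,
  iWUE = A / E (note: much of the literature reserves "intrinsic" for A/gs;
  the A/E ratio is kept here because it is the definition this pipeline's
  record schema carries, and the discrepancy is documented);
* gravimetric soil water content, (wet - oven_dry) / oven_dry;
* daily water consumption from pot-weight bookkeeping under daily refill.

Units are carried by the record schema and are never converted implicitly; a
validation pass flags unit-implausible magnitudes instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "lrwc",
    "fv_fm",
    "iwue",
    "swc_gravimetric",
    "daily_water_consumption",
    "PLANT_RECORD_COLUMNS",
    "validate_records",
]


def lrwc(FW: float, TW: float, DW: float) -> float:
    """Leaf relative water content in percent.

    ``FW``: fresh weight at sampling; ``TW``: turgid weight after rehydration;
    ``DW``: oven-dry weight (all grams). FW slightly outside [DW, TW] is a
    common weighing anomaly: it warns and returns the raw (possibly >100 or
    <0) value so tables can cap it without losing the measurement.
    """
    if min(FW, TW, DW) <= 0:
        raise ValueError("weights must be positive")
    if TW <= DW:
        raise ValueError(f"turgid weight ({TW}) must exceed dry weight ({DW})")
    if not DW <= FW <= TW:
        warnings.warn(
            f"FW={FW} outside [DW={DW}, TW={TW}]: measurement anomaly, "
            "raw LRWC returned",
            stacklevel=2,
        )
    return 100.0 * (FW - DW) / (TW - DW)


def fv_fm(Fo: float, Fm: float) -> float:
    """Maximum PSII quantum yield (Fm - Fo) / Fm from dark-adapted fluorescence."""
    if Fm <= 0:
        raise ValueError("Fm must be > 0")
    if Fo < 0:
        raise ValueError("Fo must be >= 0")
    if Fo > Fm:
        raise ValueError(f"Fo ({Fo}) cannot exceed Fm ({Fm})")
    return (Fm - Fo) / Fm


def iwue(A: float, E: float) -> float:
    """Water-use efficiency as assimilation over transpiration, A / E."""
    if E == 0:
        raise ValueError("transpiration E is zero (stomata closed); iWUE undefined")
    return A / E


def swc_gravimetric(wet_g: float, oven_dry_g: float) -> float:
    """Gravimetric soil water content on a dry-mass basis, (wet - dry) / dry."""
    if oven_dry_g <= 0:
        raise ValueError("oven-dry weight must be > 0")
    if wet_g < oven_dry_g:
        raise ValueError("wet weight below dry weight")
    return (wet_g - oven_dry_g) / oven_dry_g


def daily_water_consumption(
    pot_weight_before_g: "pd.Series | np.ndarray",
    pot_weight_after_refill_g: "pd.Series | np.ndarray",
) -> pd.Series:
    """Daily evapotranspiration from pot weights under daily refill.

    ``DWC(t) = after_refill(t-1) - before(t)`` in grams (equivalently mL of
    water). The series are day-indexed and paired: element t of ``before`` is
    the morning weight of day t, element t of ``after_refill`` the weight
    after that day's refill. The first day has no preceding refill, so the
    output has one fewer entry.
    """
    before = pd.Series(np.asarray(pot_weight_before_g, dtype=float))
    after = pd.Series(np.asarray(pot_weight_after_refill_g, dtype=float))
    if len(before) != len(after):
        raise ValueError("before and after-refill series must have equal length")
    if len(before) < 2:
        raise ValueError("need at least two days of weights")
    dwc = after.values[:-1] - before.values[1:]
    neg = np.nonzero(dwc < 0)[0]
    if len(neg):
        raise ValueError(
            f"negative water consumption on day {neg[0] + 1}: pot gained mass"
        )
    return pd.Series(dwc, index=np.arange(1, len(before)), name="dwc_g")


#: Canonical per-plant record columns and units.
PLANT_RECORD_COLUMNS = {
    "genotype": "label",
    "treatment": "control|drought",
    "replicate": "int",
    "day_of_stress": "d",
    "A": "umol CO2 m-2 s-1",
    "gs": "mol H2O m-2 s-1",
    "E": "mmol H2O m-2 s-1",
    "Ci": "umol mol-1",
    "iWUE": "A/E",
    "FW": "g",
    "TW": "g",
    "DW": "g",
    "LRWC": "%",
    "SWC": "fraction",
    "DWC": "L d-1",
    "Fo": "rel. fluorescence",
    "Fm": "rel. fluorescence",
    "FvFm": "ratio",
    "CCI": "index",
    "leaves_total": "count",
    "leaves_wilted": "count",
    "leaves_dead": "count",
    "AGB": "g dry",
    "GY": "g dry",
    "CT": "degC",
}

# (column, check description, row-wise boolean predicate); NaNs pass.
_CHECKS = [
    ("LRWC", "LRWC in [0, 100]", lambda d: d["LRWC"].between(0, 100)),
    ("FvFm", "FvFm in [0, 1)", lambda d: (d["FvFm"] >= 0) & (d["FvFm"] < 1)),
    ("Fo/Fm", "Fo <= Fm", lambda d: d["Fo"] <= d["Fm"]),
    ("FW/TW/DW", "DW <= FW <= TW", lambda d: (d["DW"] <= d["FW"]) & (d["FW"] <= d["TW"])),
    (
        "leaves",
        "wilted + dead <= total",
        lambda d: d["leaves_wilted"] + d["leaves_dead"] <= d["leaves_total"],
    ),
    ("masses", "nonnegative masses", lambda d: (d[["AGB", "GY"]] >= 0).all(axis=1)),
    ("SWC", "SWC plausibly < 2 g/g", lambda d: d["SWC"].between(0, 2)),
]


def validate_records(records: pd.DataFrame) -> list[str]:
    """Schema and plausibility report for a plant-record table.

    Returns a list of human-readable problem descriptions (empty if clean).
    Checks are warnings-level: the caller decides whether to proceed.
    """
    problems: list[str] = []
    for col in ("genotype", "treatment", "replicate"):
        if col not in records.columns:
            problems.append(f"missing required column '{col}'")
    if problems:
        return problems
    bad_treat = set(records["treatment"].unique()) - {"control", "drought"}
    if bad_treat:
        problems.append(f"unknown treatment levels {sorted(bad_treat)}")
    for name, desc, pred in _CHECKS:
        try:
            ok = pred(records)
        except KeyError:
            continue  # variable not measured in this table
        ok = ok | records.isna().any(axis=1)  # NaN rows are not flagged here
        if not ok.all():
            problems.append(f"{name}: {desc} violated in {(~ok).sum()} row(s)")
    return problems
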