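"""Validity checks for semi-static exposure experiments (OECD-305 style).

The bioconcentration guideline commits the exposure concentration to stay
within 20% variation; controls must stay free of the test item; body burdens
below the analytical limits are censored rather than used numerically.  QC
failures annotate the study report — they never abort the analysis, since a
slightly out-of-spec water profile is common at low nominal levels and the
kinetic fit remains informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientDataError, InvalidConfigError, InvalidInputError
from .series import (
    CENSOR_BELOW_LOD,
    CENSOR_BELOW_LOQ,
    CENSOR_NONE,
    ConcentrationSeries,
)

__all__ = [
    "WaterVariationResult",
    "water_variation_check",
    "ControlCheckResult",
    "control_check",
    "censor_series",
    "nominal_from_lc50",
    "QCReport",
]


@dataclass
class WaterVariationResult:
    analyte: str
    mean: float                 # ug/L
    sd: float
    relative_variation: float   # sd/mean (or max deviation, see mode)
    passed: bool
    mode: str
    limit: float


def water_variation_check(water: ConcentrationSeries, limit: float = 0.20,
                          mode: str = "sd_over_mean") -> WaterVariationResult:
    """Exposure-concentration stability check.

    ``mode="sd_over_mean"`` (default, matching the mean +/- sd reporting
    convention) passes iff sd/mean <= limit over all uncensored measurements;
    ``mode="max_deviation"`` uses max |value - mean| / mean instead.
    """
    values = water.usable(include_below_loq=False)["value"].to_numpy()
    if len(values) < 2:
        raise InsufficientDataError(
            f"{water.analyte}: need >= 2 uncensored water measurements, have {len(values)}"
        )
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if mode == "sd_over_mean":
        rel = sd / mean if mean > 0 else math.inf
    elif mode == "max_deviation":
        rel = float(np.max(np.abs(values - mean)) / mean) if mean > 0 else math.inf
    else:
        raise InvalidConfigError(f"unknown variation mode {mode!r}")
    return WaterVariationResult(analyte=water.analyte, mean=mean, sd=sd,
                                relative_variation=rel, passed=rel <= limit,
                                mode=mode, limit=limit)


@dataclass
class ControlCheckResult:
    analyte: str
    n_controls: int
    n_detects: int
    passed: bool
    offending: list[dict] = field(default_factory=list)


def control_check(controls: ConcentrationSeries, lod: float) -> ControlCheckResult:
    """Unexposed controls must show no detectable test item.

    Passes iff every control measurement is censored or below ``lod``;
    offending records are listed in the result.
    """
    if len(controls) == 0:
        raise InsufficientDataError(f"{controls.analyte}: control series is empty")
    if not (lod > 0):
        raise InvalidInputError(f"LOD must be positive, got {lod}")
    df = controls.data
    detected = df[(df["censoring"] == CENSOR_NONE) & (df["value"] >= lod)]
    offending = detected[["time_h", "replicate", "value"]].to_dict("records")
    return ControlCheckResult(analyte=controls.analyte, n_controls=len(df),
                              n_detects=len(detected), passed=len(detected) == 0,
                              offending=offending)


def censor_series(series: ConcentrationSeries, lod: float, loq: float) -> ConcentrationSeries:
    """Apply LOD/LOQ censoring flags: value < lod -> ``below_lod``,
    lod <= value < loq -> ``below_loq``, else uncensored.  Idempotent; the
    measured value is retained alongside the flag.
    """
    if not (0 < lod <= loq):
        raise InvalidConfigError(f"need 0 < LOD <= LOQ, got lod={lod}, loq={loq}")
    df = series.data.copy()
    df["censoring"] = np.select(
        [df["value"] < lod, df["value"] < loq],
        [CENSOR_BELOW_LOD, CENSOR_BELOW_LOQ],
        default=CENSOR_NONE,
    )
    return ConcentrationSeries(analyte=series.analyte, medium=series.medium, data=df)


def nominal_from_lc50(lc50: float, fraction: float) -> float:
    """Nominal exposure concentration as a fraction of the LC50 (ug/L).

    The guideline prescribes test levels at 1% and 0.1% of the LC50;
    ``fraction`` must lie strictly in (0, 1).
    """
    if not (math.isfinite(lc50) and lc50 > 0):
        raise InvalidInputError(f"LC50 must be positive and finite, got {lc50}")
    if not (0.0 < fraction < 1.0):
        raise InvalidInputError(f"fraction must be in (0, 1), got {fraction}")
    return lc50 * fraction


@dataclass
class QCReport:
    """Aggregated compliance outcome for one experiment."""

    water_variation: dict[str, WaterVariationResult] = field(default_factory=dict)
    control_check: ControlCheckResult | None = None
    steady_state: dict[str, object] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        ok = all(r.passed for r in self.water_variation.values())
        if self.control_check is not None:
            ok = ok and self.control_check.passed
        return ok
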