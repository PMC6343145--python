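"""Calibration, concentration inversion, LOD/LOQ and content conversion.

Calibration lines are ordinary least squares of peak area (mAU·min, y)
on standard concentration (µg/mL, x), reported with the Pearson
correlation coefficient r.  LOD and LOQ are the concentrations giving
signal-to-noise 3 and 10, interpolated linearly in a measured
(concentration, S/N) dilution series.  Contents are expressed per gram
of dried material through the sample preparation (mass m extracted into
volume V, optionally diluted d-fold):

    content (µg/g) = concentration (µg/mL) x V x d / m
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    ANALYTES,
    CALIBRATION,
    EXTRACT_VOLUME_ML,
    SAMPLE_MASS_G,
)
from .signal import PeakTable

#: S/N thresholds defining detection and quantification.
SNR_LOD = 3.0
SNR_LOQ = 10.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted calibration line and sensitivity limits for one analyte."""

    analyte: str
    slope: float
    intercept: float
    r: float
    linear_range: tuple[float, float]
    lod: float | None = None
    loq: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        low, high = self.linear_range
        if low >= high:
            raise ValueError("linear range must be increasing")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation coefficient out of [-1, 1]")
        if self.lod is not None and self.loq is not None and self.lod >= self.loq:
            raise ValueError("LOD must be below LOQ")

    def area(self, concentration: float) -> float:
        """Forward-predict a peak area from a concentration."""
        return self.slope * concentration + self.intercept


def default_curves() -> dict[str, CalibrationCurve]:
    """The published calibration lines as ready-made curves."""
    return {
        a: CalibrationCurve(
            analyte=a,
            slope=c.slope,
            intercept=c.intercept,
            r=1.0,
            linear_range=c.linear_range,
            lod=c.lod,
            loq=c.loq,
        )
        for a, c in CALIBRATION.items()
    }


def fit_calibration(points: list[tuple[float, float]], analyte: str) -> CalibrationCurve:
    """Ordinary least squares of area on concentration.

    ``points`` are (concentration µg/mL, area mAU·min) pairs; at least
    three points over at least two distinct concentrations are required.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 calibration points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("all concentrations equal; calibration fit is singular")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        linear_range=(float(x.min()), float(x.max())),
    )


class RangeViolation(ValueError):
    """An inverted concentration fell outside the linear range."""


def invert_calibration(
    curve: CalibrationCurve, area: float, allow_extrapolation: bool = False
) -> float:
    """Concentration (µg/mL) implied by a peak area: x = (y - b) / a.

    Outside the linear range the value is either rejected
    (:class:`RangeViolation`) or, with ``allow_extrapolation``, returned
    with a warning.  Sub-blank areas (negative x) clamp to 0.
    """
    x = (area - curve.intercept) / curve.slope
    if x < 0:
        warnings.warn(
            f"{curve.analyte}: area {area} below blank; concentration clamped to 0",
            stacklevel=2,
        )
        return 0.0
    low, high = curve.linear_range
    if not low <= x <= high:
        if not allow_extrapolation:
            raise RangeViolation(
                f"{curve.analyte}: concentration {x:.4g} µg/mL outside linear "
                f"range ({low}, {high})"
            )
        warnings.warn(
            f"{curve.analyte}: extrapolating outside linear range ({x:.4g} µg/mL)",
            stacklevel=2,
        )
    return float(x)


@dataclass(frozen=True)
class SamplePrep:
    """Extraction parameters linking extract concentration to content."""

    mass: float = SAMPLE_MASS_G
    volume: float = EXTRACT_VOLUME_ML
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.volume <= 0:
            raise ValueError("mass and volume must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


def concentration_to_content(conc: float, prep: SamplePrep) -> float:
    """Convert an injected concentration to dry-weight content (µg/g)."""
    return conc * prep.volume * prep.dilution_factor / prep.mass


def estimate_lod_loq(series: list[tuple[float, float]]) -> tuple[float, float]:
    """LOD and LOQ from a dilution series of (concentration, S/N) points.

    S/N must increase with concentration; the concentrations at S/N 3
    and 10 are obtained by linear interpolation, extrapolating through
    the origin below the lowest measured point.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 (concentration, snr) points")
    pts = sorted(series)
    conc = np.asarray([p[0] for p in pts], dtype=float)
    snr = np.asarray([p[1] for p in pts], dtype=float)
    if np.any(np.diff(snr) <= 0):
        raise ValueError("snr series must increase with concentration")
    if snr[-1] < SNR_LOQ:
        raise ValueError("series does not reach S/N 10; cannot bracket the LOQ")
    # Assume S/N -> 0 with concentration for sub-series extrapolation.
    conc = np.concatenate([[0.0], conc])
    snr = np.concatenate([[0.0], snr])
    lod = float(np.interp(SNR_LOD, snr, conc))
    loq = float(np.interp(SNR_LOQ, snr, conc))
    return lod, loq


#: Content-table flags.
FLAG_OK = "ok"
FLAG_BELOW_LOQ = "below_loq"
FLAG_ND = "nd"


def quantify_batch(
    table: PeakTable,
    curves: dict[str, CalibrationCurve] | None = None,
    prep: SamplePrep | None = None,
    dilutions: dict[str, float] | None = None,
    allow_extrapolation: bool = False,
) -> pd.DataFrame:
    """Per-analyte dry-weight contents of one analyte-assigned peak table.

    An analyte with no assigned peak, or whose peak has S/N below 3, is
    reported as not detected (content NaN, flag ``nd``); S/N in [3, 10)
    reports the value flagged ``below_loq``; otherwise the calibration is
    inverted and converted to µg/g, applying the analyte's dilution
    factor (``dilutions`` overrides ``prep.dilution_factor``).
    """
    curves = curves if curves is not None else default_curves()
    prep = prep or SamplePrep()
    assigned = table.by_analyte()
    for analyte in assigned:
        if analyte not in curves:
            raise ValueError(f"no calibration curve for detected analyte {analyte!r}")
    rows = []
    for analyte in ANALYTES:
        peak = assigned.get(analyte)
        content = np.nan
        flag = FLAG_ND
        if peak is not None and peak.snr >= SNR_LOD:
            d = dilutions.get(analyte, prep.dilution_factor) if dilutions else prep.dilution_factor
            conc = invert_calibration(
                curves[analyte], peak.area, allow_extrapolation=allow_extrapolation
            )
            batch_prep = SamplePrep(mass=prep.mass, volume=prep.volume, dilution_factor=d)
            content = concentration_to_content(conc, batch_prep)
            flag = FLAG_OK if peak.snr >= SNR_LOQ else FLAG_BELOW_LOQ
        rows.append(
            {
                "batch_id": table.batch_id,
                "analyte": analyte,
                "content_ug_per_g": content,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def calibration_table(curves: dict[str, CalibrationCurve]) -> pd.DataFrame:
    """Calibration summary (one row per analyte, mirrors the assay report)."""
    return pd.DataFrame(
        [
            {
                "analyte": c.analyte,
                "slope": c.slope,
                "intercept": c.intercept,
                "r": c.r,
                "range_low": c.linear_range[0],
                "range_high": c.linear_range[1],
                "lod": c.lod,
                "loq": c.loq,
            }
            for c in curves.values()
        ]
    )
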