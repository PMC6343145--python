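"""Single-wavelength chromatogram processing.

Baseline correction, peak detection and integration, signal-to-noise
estimation and retention-time-based analyte assignment for LC-DAD traces
recorded at one wavelength.  The processing chain assumed by the rest of
the package is::

    correct_baseline -> detect_peaks -> assign_analytes

Intensities are in milli-absorbance units (mAU), times in minutes and
peak areas in mAU·min (trapezoidal integration on the time grid).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, grey_opening, uniform_filter1d
from scipy.signal import find_peaks

from .constants import WAVELENGTH_NM

_GRID_TOL = 1e-9


@dataclass
class Chromatogram:
    """A detector trace on a uniform time grid.

    Parameters
    ----------
    time
        Strictly increasing, uniformly spaced time grid in minutes.
    intensity
        Detector response in mAU, same length as ``time``.
    batch_id
        Sample label carried through the pipeline.
    wavelength
        Monitored wavelength in nm (260 for the nucleoside assay).
    """

    time: np.ndarray
    intensity: np.ndarray
    batch_id: str = ""
    wavelength: float = WAVELENGTH_NM

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("chromatogram needs at least 2 time points")
        if self.intensity.shape != self.time.shape:
            raise ValueError("time and intensity lengths differ")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.ptp(steps) > _GRID_TOL:
            raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def step(self) -> float:
        """Grid spacing in minutes."""
        return float(self.time[1] - self.time[0])

    def with_intensity(self, intensity: np.ndarray) -> "Chromatogram":
        return dataclasses.replace(self, intensity=np.asarray(intensity, dtype=float))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.time, "intensity_mau": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, batch_id: str = "", wavelength: float = WAVELENGTH_NM):
        df = pd.read_csv(path)
        return cls(
            time=df["time_min"].to_numpy(),
            intensity=df["intensity_mau"].to_numpy(),
            batch_id=batch_id,
            wavelength=wavelength,
        )


@dataclass
class Peak:
    """One detected chromatographic peak (baseline-corrected scale)."""

    apex_rt: float
    height: float
    area: float
    left_bound: float
    right_bound: float
    snr: float
    analyte: str | None = None

    def __post_init__(self) -> None:
        if not (self.left_bound < self.apex_rt < self.right_bound):
            raise ValueError("peak bounds must bracket the apex")
        if self.area <= 0 or self.height <= 0:
            raise ValueError("peak height and area must be positive")


@dataclass
class PeakTable:
    """Detected peaks of one chromatogram, ordered by apex retention time."""

    batch_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        rts = [p.apex_rt for p in self.peaks]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("peak apexes must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_analyte(self) -> dict[str, Peak]:
        return {p.analyte: p for p in self.peaks if p.analyte is not None}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "batch_id": self.batch_id,
                    "analyte": p.analyte,
                    "apex_rt_min": p.apex_rt,
                    "height_mau": p.height,
                    "area_mau_min": p.area,
                    "left_min": p.left_bound,
                    "right_min": p.right_bound,
                    "snr": p.snr,
                }
                for p in self.peaks
            ],
            columns=[
                "batch_id",
                "analyte",
                "apex_rt_min",
                "height_mau",
                "area_mau_min",
                "left_min",
                "right_min",
                "snr",
            ],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PeakTable":
        batch_ids = df["batch_id"].unique()
        if len(batch_ids) != 1:
            raise ValueError("one PeakTable per batch; got " + repr(list(batch_ids)))
        peaks = [
            Peak(
                apex_rt=row.apex_rt_min,
                height=row.height_mau,
                area=row.area_mau_min,
                left_bound=row.left_min,
                right_bound=row.right_min,
                snr=row.snr,
                analyte=None if pd.isna(row.analyte) else row.analyte,
            )
            for row in df.itertuples()
        ]
        return cls(batch_id=str(batch_ids[0]), peaks=peaks)


def resample(chrom: Chromatogram, time: np.ndarray) -> Chromatogram:
    """Linearly interpolate a trace onto a new uniform grid."""
    time = np.asarray(time, dtype=float)
    intensity = np.interp(time, chrom.time, chrom.intensity)
    return Chromatogram(time, intensity, chrom.batch_id, chrom.wavelength)


def estimate_noise_sd(intensity: np.ndarray) -> float:
    """Robust white-noise standard deviation from first differences.

    Uses the median absolute first difference, which ignores the small
    fraction of grid points occupied by peaks; exact zero on noiseless
    traces whose flat baseline dominates.
    """
    d = np.abs(np.diff(np.asarray(intensity, dtype=float)))
    return float(1.4826 * np.median(d) / np.sqrt(2.0))


def correct_baseline(chrom: Chromatogram, window: float = 1.0) -> Chromatogram:
    """Subtract a morphological-opening baseline estimate.

    The baseline is a grey-scale opening (rolling minimum followed by
    rolling maximum) of a lightly smoothed copy of the trace, followed by
    a rolling-mean polish.  Opening with a structuring window wider than
    any peak removes the peaks but follows offsets, ramps and slow drift
    essentially exactly, so a constant-offset trace corrects to zero and
    a peak on a linear ramp keeps its area.

    Parameters
    ----------
    window
        Structuring-element width in minutes; must exceed the grid step
        (and the widest peak base for unbiased areas) but be smaller than
        the trace span.
    """
    step = chrom.step
    span = chrom.time[-1] - chrom.time[0]
    if window <= step:
        raise ValueError(f"baseline window {window} min must exceed the grid step {step}")
    if window > span:
        raise ValueError(f"baseline window {window} min exceeds the trace span {span}")
    size = max(3, int(round(window / step)) | 1)
    # Light pre-smoothing keeps the opening from tracking noise minima.
    smoothed = gaussian_filter1d(chrom.intensity, sigma=2.0, mode="nearest")
    baseline = grey_opening(smoothed, size=size, mode="nearest")
    baseline = uniform_filter1d(baseline, size=max(3, size // 3), mode="nearest")
    return chrom.with_intensity(chrom.intensity - baseline)


def _bounds(y: np.ndarray, apex: int, left_limit: int, right_limit: int, height: float):
    """Integration bounds: flanking valley or 1%-of-height crossing."""
    floor = 0.01 * height
    lo = apex
    while lo > left_limit and y[lo - 1] > floor:
        lo -= 1
    hi = apex
    while hi < right_limit and y[hi + 1] > floor:
        hi += 1
    return lo, hi


def detect_peaks(
    chrom: Chromatogram,
    min_snr: float = 3.0,
    min_height: float | None = None,
    smooth_sigma: float = 0.02,
) -> PeakTable:
    """Detect, bound and integrate peaks on a baseline-corrected trace.

    Apex candidates are local maxima of a Gaussian-smoothed copy of the
    trace (``smooth_sigma`` in minutes) exceeding the height threshold;
    smoothing suppresses single-sample noise spikes without moving real
    apexes.  Heights are read from the unsmoothed trace at the apex,
    bounds are placed at the flanking valley or where the signal falls
    below 1% of the height, areas are trapezoidal between the bounds and
    S/N is height over the robust baseline-noise estimate.

    ``min_height`` defaults to 3x the estimated noise floor.  Flat or
    empty traces yield an empty table.
    """
    y = chrom.intensity
    step = chrom.step
    noise_sd = estimate_noise_sd(y)
    if min_height is None:
        min_height = 3.0 * noise_sd
    sigma_pts = smooth_sigma / step
    smooth = gaussian_filter1d(y, sigma=sigma_pts, mode="nearest") if sigma_pts > 0 else y
    # Threshold on the smoothed trace; prominence guards shoulder points.
    threshold = max(min_height, 3.0 * noise_sd)
    idx, _ = find_peaks(smooth, height=threshold if threshold > 0 else None, prominence=threshold / 2 if threshold > 0 else None)
    if idx.size == 0:
        return PeakTable(batch_id=chrom.batch_id)

    # Refine each apex to the raw-trace maximum near the smoothed apex.
    refine = max(1, int(round(2 * sigma_pts)))
    apexes = []
    for i in idx:
        lo = max(0, i - refine)
        hi = min(y.size, i + refine + 1)
        apexes.append(lo + int(np.argmax(y[lo:hi])))
    apexes = sorted(set(apexes))

    peaks: list[Peak] = []
    for k, apex in enumerate(apexes):
        height = float(y[apex])
        if height < min_height or height <= 0:
            continue
        left_limit = 0 if k == 0 else apexes[k - 1] + int(np.argmin(y[apexes[k - 1] : apex]))
        right_limit = (
            y.size - 1
            if k == len(apexes) - 1
            else apex + int(np.argmin(y[apex : apexes[k + 1]]))
        )
        lo, hi = _bounds(y, apex, left_limit, right_limit, height)
        if hi - lo < 2:
            continue
        area = float(np.trapezoid(y[lo : hi + 1], chrom.time[lo : hi + 1]))
        if area <= 0:
            continue
        snr = height / noise_sd if noise_sd > 0 else np.inf
        if snr < min_snr:
            continue
        peaks.append(
            Peak(
                apex_rt=float(chrom.time[apex]),
                height=height,
                area=area,
                left_bound=float(chrom.time[lo]),
                right_bound=float(chrom.time[hi]),
                snr=float(snr),
            )
        )
    return PeakTable(batch_id=chrom.batch_id, peaks=peaks)


def estimate_snr(
    chrom: Chromatogram, peak: Peak, quiet_window: tuple[float, float]
) -> float:
    """Peak S/N: height over the sample SD of a peak-free window.

    The quiet window (min, min) must not overlap the peak's integration
    bounds.  A zero-noise window yields ``inf``.
    """
    lo, hi = quiet_window
    if hi <= lo:
        raise ValueError("quiet_window must be an increasing (start, stop) pair")
    if lo < peak.right_bound and hi > peak.left_bound:
        raise ValueError("quiet_window overlaps the peak")
    mask = (chrom.time >= lo) & (chrom.time <= hi)
    if mask.sum() < 2:
        raise ValueError("quiet_window contains fewer than 2 samples")
    sd = float(np.std(chrom.intensity[mask], ddof=1))
    if sd == 0:
        return float("inf")
    return peak.height / sd


def assign_analytes(
    table: PeakTable, analyte_rts: dict[str, float], rt_tolerance: float = 0.10
) -> PeakTable:
    """Label peaks with the analyte of nearest reference retention time.

    Each analyte claims at most one peak (the nearest apex within
    ``rt_tolerance``); peaks without a reference RT within tolerance stay
    unlabelled.  Reference RTs closer together than twice the tolerance
    are ambiguous and rejected.
    """
    if rt_tolerance <= 0:
        raise ValueError("rt_tolerance must be positive")
    rts = sorted(analyte_rts.values())
    for a, b in zip(rts, rts[1:]):
        if b - a < 2 * rt_tolerance:
            raise ValueError(
                f"analyte reference RTs {a} and {b} are closer than 2x tolerance"
            )
    peaks = [dataclasses.replace(p, analyte=None) for p in table.peaks]
    for analyte, ref_rt in analyte_rts.items():
        dists = [abs(p.apex_rt - ref_rt) for p in peaks]
        if not dists:
            continue
        best = int(np.argmin(dists))
        if dists[best] <= rt_tolerance:
            peaks[best] = dataclasses.replace(peaks[best], analyte=analyte)
    return PeakTable(batch_id=table.batch_id, peaks=peaks)
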