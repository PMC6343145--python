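"""Seeded simulation of UHPLC-DAD chromatograms and study designs.

The generator emulates the 260 nm nucleoside assay: each analyte elutes
as a symmetric Gaussian whose area follows the instrument's calibration
line (area in mAU·min = slope x concentration in µg/mL + intercept), on
a flat baseline perturbed by white detector noise, one slow sinusoidal
drift cycle, and small per-injection retention-time jitter.  Batch-level
study simulation draws species-typical dry-weight contents log-uniformly
within the observed per-species ranges, converts them to extract
concentrations through the 1.0 g / 20 mL preparation, and applies the
smallest integer dilution whenever an analyte would exceed its linear
range.

All outputs are pure functions of their inputs and an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import (
    ANALYTES,
    AUTHENTIC_SPECIES,
    CALIBRATION,
    DEFAULT_RTS,
    EXTRACT_VOLUME_ML,
    SAMPLE_MASS_G,
    SPECIES_PROFILES,
    SpeciesProfile,
)
from .signal import Chromatogram

SeedLike = int | np.random.SeedSequence

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _seed_sequence(seed: SeedLike) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _default_response() -> dict[str, tuple[float, float]]:
    return {a: (c.slope, c.intercept) for a, c in CALIBRATION.items()}


@dataclass(frozen=True)
class GeneratorParams:
    """Instrument model for the chromatogram simulator.

    Attributes
    ----------
    analyte_rts
        Nominal retention time per analyte (min), strictly increasing in
        elution order and inside the grid.
    peak_sigma
        Gaussian peak standard deviation (min).
    response
        Per-analyte (slope, intercept): peak area (mAU·min) produced by a
        concentration (µg/mL); defaults to the published calibration
        lines so quantitation round-trips exactly.
    noise_sd
        White baseline noise SD (mAU).
    drift_amplitude
        Amplitude (mAU) of one slow sinusoidal baseline-drift cycle with
        a random phase.
    rt_jitter_sd
        Per-injection, per-analyte retention-time jitter SD (min).
    grid
        (t_start, t_end, step) in minutes.
    """

    analyte_rts: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RTS))
    peak_sigma: float = 0.05
    response: dict[str, tuple[float, float]] = field(default_factory=_default_response)
    noise_sd: float = 0.05
    drift_amplitude: float = 0.2
    rt_jitter_sd: float = 0.01
    grid: tuple[float, float, float] = (0.0, 16.0, 0.01)

    def __post_init__(self) -> None:
        t0, t1, step = self.grid
        if step <= 0:
            raise ValueError("grid step must be positive")
        if t0 >= t1:
            raise ValueError("grid start must precede grid end")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be positive")
        rts = list(self.analyte_rts.values())
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("analyte_rts must be strictly increasing in elution order")
        if rts and (rts[0] < t0 or rts[-1] > t1):
            raise ValueError("analyte_rts must lie inside the grid")
        for analyte in self.analyte_rts:
            if analyte not in self.response:
                raise ValueError(f"no response line for analyte {analyte!r}")

    def time_grid(self) -> np.ndarray:
        t0, t1, step = self.grid
        n = int(round((t1 - t0) / step)) + 1
        return t0 + step * np.arange(n)


def peak_area(analyte: str, concentration: float, params: GeneratorParams) -> float:
    """True peak area (mAU·min) the instrument model produces.

    Zero concentration emits no peak; positive concentrations follow the
    response line, clipped at zero.
    """
    if concentration <= 0:
        return 0.0
    slope, intercept = params.response[analyte]
    return max(slope * concentration + intercept, 0.0)


def generate_chromatogram(
    concentrations: dict[str, float],
    params: GeneratorParams | None = None,
    seed: SeedLike = 0,
    batch_id: str = "",
) -> Chromatogram:
    """Simulate one injection at the given extract concentrations (µg/mL).

    The trace is drift + sum of Gaussian analyte peaks + white noise.
    Identical inputs and seed give a bit-identical trace.
    """
    params = params or GeneratorParams()
    for analyte, conc in concentrations.items():
        if analyte not in params.analyte_rts:
            raise ValueError(f"unknown analyte {analyte!r}")
        if conc < 0:
            raise ValueError(f"negative concentration for {analyte}: {conc}")
    rng = np.random.default_rng(seed)
    t = params.time_grid()
    span = t[-1] - t[0]

    phase = rng.uniform(0.0, 2.0 * math.pi)
    y = params.drift_amplitude * np.sin(2.0 * math.pi * (t - t[0]) / span + phase)

    for analyte in params.analyte_rts:
        jitter = rng.normal(0.0, params.rt_jitter_sd) if params.rt_jitter_sd > 0 else 0.0
        conc = concentrations.get(analyte, 0.0)
        area = peak_area(analyte, conc, params)
        if area <= 0:
            continue
        rt = params.analyte_rts[analyte] + jitter
        height = area / (params.peak_sigma * _SQRT_2PI)
        y = y + height * np.exp(-0.5 * ((t - rt) / params.peak_sigma) ** 2)

    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, t.size)
    return Chromatogram(time=t, intensity=y, batch_id=batch_id)


@dataclass(frozen=True)
class StudyDesign:
    """Batch roster for a multi-species authentication study."""

    batches: tuple[tuple[str, str], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [b for b, _ in self.batches]
        if len(set(ids)) != len(ids):
            raise ValueError("batch_ids must be unique")

    @property
    def n_authentic(self) -> int:
        return sum(1 for _, sp in self.batches if sp == AUTHENTIC_SPECIES)

    @property
    def n_adulterant(self) -> int:
        return len(self.batches) - self.n_authentic


def default_design(seed: int = 0) -> StudyDesign:
    """The surveyed-market roster: batches 1-22 authentic *P. aspergillum*,
    23-31 *A. obscuritoporus*, 32-42 *M. magna*."""
    batches = []
    for i in range(1, 43):
        if i <= 22:
            sp = "P. aspergillum"
        elif i <= 31:
            sp = "A. obscuritoporus"
        else:
            sp = "M. magna"
        batches.append((str(i), sp))
    return StudyDesign(batches=tuple(batches), seed=seed)


def dilution_factor(concentration: float, linear_high: float) -> int:
    """Smallest integer dilution bringing a concentration into range."""
    if concentration <= linear_high:
        return 1
    return int(math.ceil(concentration / linear_high))


def generate_study(
    design: StudyDesign,
    profiles: dict[str, SpeciesProfile] | None = None,
    params: GeneratorParams | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[Chromatogram], pd.DataFrame, pd.DataFrame]:
    """Simulate every batch of a study design.

    Per batch, true contents (µg/g) are drawn log-uniformly within the
    species profile ranges (exactly zero for absent analytes), converted
    to extract concentrations via the 1.0 g / 20 mL preparation, diluted
    into the linear range where needed, and rendered as one chromatogram.

    Returns ``(chromatograms, ground_truth, manifest)``.  Ground truth is
    a long table (batch_id, species, analyte, content_ug_per_g,
    concentration_ug_per_ml, dilution_factor) where the concentration is
    the injected (post-dilution) one.  If ``out_dir`` is given, each
    trace is written as CSV and the manifest's ``file`` column filled.
    """
    profiles = profiles if profiles is not None else SPECIES_PROFILES
    params = params or GeneratorParams()
    for batch_id, species in design.batches:
        if species not in profiles:
            raise ValueError(f"batch {batch_id}: no profile for species {species!r}")

    root = np.random.SeedSequence(design.seed)
    children = root.spawn(len(design.batches))
    chroms: list[Chromatogram] = []
    truth_rows = []
    manifest_rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for (batch_id, species), child in zip(design.batches, children):
        profile = profiles[species]
        content_ss, trace_ss = child.spawn(2)
        rng = np.random.default_rng(content_ss)
        concentrations: dict[str, float] = {}
        max_dilution = 1
        for analyte in ANALYTES:
            low, high = profile.analyte_content_ranges[analyte]
            if high <= 0:
                content = 0.0
            elif low == high:
                content = low
            else:
                content = float(np.exp(rng.uniform(np.log(low), np.log(high))))
            conc = content * SAMPLE_MASS_G / EXTRACT_VOLUME_ML
            d = dilution_factor(conc, CALIBRATION[analyte].linear_range[1])
            injected = conc / d
            max_dilution = max(max_dilution, d)
            concentrations[analyte] = injected
            truth_rows.append(
                {
                    "batch_id": batch_id,
                    "species": species,
                    "analyte": analyte,
                    "content_ug_per_g": content,
                    "concentration_ug_per_ml": injected,
                    "dilution_factor": d,
                }
            )
        chrom = generate_chromatogram(concentrations, params, seed=trace_ss, batch_id=batch_id)
        chroms.append(chrom)
        file_name = ""
        if out_path is not None:
            file_name = str(out_path / f"batch_{batch_id}.csv")
            chrom.to_csv(file_name)
        manifest_rows.append(
            {
                "batch_id": batch_id,
                "species": species,
                "role": "authentic" if species == AUTHENTIC_SPECIES else "adulterant",
                "file": file_name,
                "dilution_factor": max_dilution,
            }
        )
    ground_truth = pd.DataFrame(truth_rows)
    manifest = pd.DataFrame(manifest_rows)
    return chroms, ground_truth, manifest


def geometric_levels(low: float, high: float, n_levels: int) -> np.ndarray:
    """Geometric dilution series from ``low`` to ``high`` inclusive."""
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    if low <= 0 or low >= high:
        raise ValueError("need 0 < low < high")
    return np.geomspace(low, high, n_levels)


def generate_standards(
    ranges: dict[str, tuple[float, float]] | None = None,
    n_levels: int = 6,
    params: GeneratorParams | None = None,
    seed: SeedLike = 0,
) -> tuple[list[Chromatogram], pd.DataFrame]:
    """Simulate a mixed-standard geometric dilution series.

    Level ``j`` injects every analyte at its level-``j`` concentration;
    level 0 is the low end of each range and the last level the high end.
    Returns the traces and a levels x analytes concentration table.
    """
    if ranges is None:
        ranges = {a: c.linear_range for a, c in CALIBRATION.items()}
    params = params or GeneratorParams()
    levels = {a: geometric_levels(low, high, n_levels) for a, (low, high) in ranges.items()}
    table = pd.DataFrame(levels, index=pd.RangeIndex(n_levels, name="level"))
    children = _seed_sequence(seed).spawn(n_levels)
    chroms = []
    for j in range(n_levels):
        conc = {a: float(levels[a][j]) for a in levels}
        chroms.append(generate_chromatogram(conc, params, seed=children[j], batch_id=f"std_{j}"))
    return chroms, table


def generate_spike_experiment(
    base_concentrations: dict[str, float],
    spike_amounts: dict[str, float],
    n_replicates: int = 3,
    params: GeneratorParams | None = None,
    seed: SeedLike = 0,
) -> tuple[Chromatogram, list[Chromatogram], pd.DataFrame]:
    """Simulate a standard-addition (recovery) experiment.

    One unspiked injection plus ``n_replicates`` spiked injections whose
    concentrations are base + spike per analyte; spiked injections that
    leave an analyte's linear range get the smallest integer dilution,
    recorded in the truth table.

    Returns ``(unspiked, spiked_list, truth)`` with truth columns
    analyte, original_ug_ml, spiked_ug_ml, total_ug_ml,
    dilution_unspiked, dilution_spiked.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    for analyte, amount in spike_amounts.items():
        if amount <= 0:
            raise ValueError(f"spike amount for {analyte} must be positive")
    params = params or GeneratorParams()

    base_inj: dict[str, float] = {}
    spike_inj: dict[str, float] = {}
    rows = []
    for analyte in params.analyte_rts:
        base = base_concentrations.get(analyte, 0.0)
        spike = spike_amounts.get(analyte, 0.0)
        high = CALIBRATION[analyte].linear_range[1] if analyte in CALIBRATION else math.inf
        d0 = dilution_factor(base, high)
        d1 = dilution_factor(base + spike, high)
        base_inj[analyte] = base / d0
        spike_inj[analyte] = (base + spike) / d1
        rows.append(
            {
                "analyte": analyte,
                "original_ug_ml": base,
                "spiked_ug_ml": spike,
                "total_ug_ml": base + spike,
                "dilution_unspiked": d0,
                "dilution_spiked": d1,
            }
        )
    children = _seed_sequence(seed).spawn(n_replicates + 1)
    unspiked = generate_chromatogram(base_inj, params, seed=children[0], batch_id="unspiked")
    spiked = [
        generate_chromatogram(spike_inj, params, seed=children[i + 1], batch_id=f"spiked_{i}")
        for i in range(n_replicates)
    ]
    return unspiked, spiked, pd.DataFrame(rows)
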