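"""Analytical validation: precision, repeatability, stability, recovery.

Simulates the standard single-lab validation experiments end to end
(generate replicate injections, detect and quantify the peaks) and
aggregates per-analyte statistics:

- intra-day precision: RSD of peak areas over replicate injections in
  one day;
- inter-day precision: RSD of the day-mean areas over consecutive days;
- repeatability: RSD of contents over independently prepared solutions
  of the same sample;
- stability: RSD of contents of one solution re-injected over several
  hours;
- recovery: (amount found - original amount) / amount spiked x 100%,
  from a standard-addition experiment.

RSDs use the sample (n-1) standard deviation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import quant, signal, synthdata
from .constants import (
    ANALYTES,
    CALIBRATION,
    EXTRACT_VOLUME_ML,
    SAMPLE_MASS_G,
    VALIDATION_SAMPLE_CONTENTS,
)


def rsd(values) -> float:
    """Relative standard deviation, % (sample SD over mean)."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for an RSD")
    mean = x.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


def recovery(found_total: float, original: float, spiked: float) -> float:
    """Standard-addition recovery, %: (found - original) / spiked x 100."""
    if spiked <= 0:
        raise ValueError("spiked amount must be positive")
    return 100.0 * (found_total - original) / spiked


@dataclass(frozen=True)
class ValidationProtocol:
    """Replicate design of the validation experiments."""

    intra_day_n: int = 6
    inter_days: int = 3
    repeatability_n: int = 6
    stability_timepoints: int = 5
    recovery_n: int = 3

    def __post_init__(self) -> None:
        for name in (
            "intra_day_n",
            "inter_days",
            "repeatability_n",
            "stability_timepoints",
            "recovery_n",
        ):
            if getattr(self, name) < 2 and name != "recovery_n":
                raise ValueError(f"{name} must be at least 2")
        if self.recovery_n < 1:
            raise ValueError("recovery_n must be at least 1")


def _measure(
    concentrations: dict[str, float],
    params: synthdata.GeneratorParams,
    seed,
    min_snr: float = 3.0,
) -> dict[str, float]:
    """Simulate one injection and return per-analyte peak areas."""
    chrom = synthdata.generate_chromatogram(concentrations, params, seed=seed)
    corrected = signal.correct_baseline(chrom)
    table = signal.detect_peaks(corrected, min_snr=min_snr)
    table = signal.assign_analytes(table, params.analyte_rts)
    return {a: p.area for a, p in table.by_analyte().items()}


def _contents_from_areas(areas: dict[str, float], dilutions: dict[str, float]) -> dict[str, float]:
    curves = quant.default_curves()
    out = {}
    for a, area in areas.items():
        conc = quant.invert_calibration(curves[a], area, allow_extrapolation=True)
        prep = quant.SamplePrep(dilution_factor=dilutions.get(a, 1.0))
        out[a] = quant.concentration_to_content(conc, prep)
    return out


def run_validation(
    protocol: ValidationProtocol | None = None,
    params: synthdata.GeneratorParams | None = None,
    sample_contents: dict[str, float] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Simulate the full validation battery for one test sample.

    ``sample_contents`` (µg/g) defaults to the survey's repeatability
    sample.  Returns one row per analyte with columns intra_day_rsd,
    inter_day_rsd, repeatability_rsd, stability_rsd, recovery_mean,
    recovery_rsd and the replicate counts used.
    """
    protocol = protocol or ValidationProtocol()
    params = params or synthdata.GeneratorParams()
    contents = sample_contents or dict(VALIDATION_SAMPLE_CONTENTS)

    base_conc = {
        a: c * SAMPLE_MASS_G / EXTRACT_VOLUME_ML for a, c in contents.items()
    }
    for a, conc in base_conc.items():
        d = synthdata.dilution_factor(conc, CALIBRATION[a].linear_range[1])
        if d != 1:
            raise ValueError(
                f"validation sample {a} concentration {conc} µg/mL exceeds the "
                "linear range; choose an in-range sample"
            )

    root = synthdata._seed_sequence(seed)
    ss_intra, ss_inter, ss_rep, ss_stab, ss_rec = root.spawn(5)

    # Intra-day precision: replicate injections of one solution.
    intra_areas = [
        _measure(base_conc, params, s) for s in ss_intra.spawn(protocol.intra_day_n)
    ]
    # Inter-day precision: same experiment on consecutive days; RSD of day means.
    day_means: list[dict[str, float]] = []
    for day_ss in ss_inter.spawn(protocol.inter_days):
        reps = [_measure(base_conc, params, s) for s in day_ss.spawn(protocol.intra_day_n)]
        day_means.append({a: float(np.mean([r[a] for r in reps])) for a in ANALYTES})
    # Repeatability: independently prepared solutions of the same sample.
    rep_areas = [
        _measure(base_conc, params, s) for s in ss_rep.spawn(protocol.repeatability_n)
    ]
    # Stability: one solution re-injected over several hours.
    stab_areas = [
        _measure(base_conc, params, s) for s in ss_stab.spawn(protocol.stability_timepoints)
    ]

    # Recovery: spike approximately the sample's own amount of each analyte.
    spike = dict(base_conc)
    unspiked, spiked, truth = synthdata.generate_spike_experiment(
        base_conc, spike, n_replicates=protocol.recovery_n, params=params, seed=ss_rec
    )
    truth = truth.set_index("analyte")

    def quantify(chrom, dilution_col):
        corrected = signal.correct_baseline(chrom)
        table = signal.assign_analytes(signal.detect_peaks(corrected), params.analyte_rts)
        areas = {a: p.area for a, p in table.by_analyte().items()}
        dil = {a: float(truth.loc[a, dilution_col]) for a in areas}
        return _contents_from_areas(areas, dil)

    found_original = quantify(unspiked, "dilution_unspiked")
    found_totals = [quantify(c, "dilution_spiked") for c in spiked]

    rows = []
    for a in ANALYTES:
        spike_content = quant.concentration_to_content(
            float(truth.loc[a, "spiked_ug_ml"]), quant.SamplePrep()
        )
        recs = [
            recovery(found[a], found_original[a], spike_content) for found in found_totals
        ]
        rows.append(
            {
                "analyte": a,
                "intra_day_rsd": rsd([m[a] for m in intra_areas]),
                "inter_day_rsd": rsd([m[a] for m in day_means]),
                "repeatability_rsd": rsd(
                    [_contents_from_areas(m, {})[a] for m in rep_areas]
                ),
                "stability_rsd": rsd(
                    [_contents_from_areas(m, {})[a] for m in stab_areas]
                ),
                "recovery_mean": float(np.mean(recs)),
                "recovery_rsd": rsd(recs) if len(recs) > 1 else 0.0,
                "n_intra": protocol.intra_day_n,
                "n_days": protocol.inter_days,
                "n_repeatability": protocol.repeatability_n,
                "n_stability": protocol.stability_timepoints,
                "n_recovery": protocol.recovery_n,
            }
        )
    return pd.DataFrame(rows)
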