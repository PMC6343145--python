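"""Shared instrument and study constants.

All numeric constants here describe the published UHPLC-DAD assay for
Guang Dilong (dried *Pheretima aspergillum*): the six nucleoside analytes
monitored at 260 nm, their calibration lines (peak area in mAU·min versus
concentration in µg/mL), linear ranges, LOD/LOQ, the sample preparation
(1.0 g powder extracted into 20 mL), and per-species dry-weight content
ranges (µg/g) for the authentic species and its two common adulterants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Elution order of the six monitored nucleosides / nucleobases.
ANALYTES: tuple[str, ...] = (
    "hypoxanthine",
    "xanthine",
    "uridine",
    "inosine",
    "guanosine",
    "adenosine",
)

#: Reference retention times (min) at the default gradient.  Inosine's
#: 9.35 min is the assay's reference peak; the others are nominal values
#: inside the 0-15 min window preserving the observed elution order.
DEFAULT_RTS: dict[str, float] = {
    "hypoxanthine": 3.20,
    "xanthine": 4.60,
    "uridine": 6.10,
    "inosine": 9.35,
    "guanosine": 11.20,
    "adenosine": 13.40,
}

#: Detection wavelength (nm).
WAVELENGTH_NM: float = 260.0


@dataclass(frozen=True)
class CalibrationConstants:
    """Published calibration line and sensitivity limits for one analyte.

    ``slope`` is in mAU·min per µg/mL, ``intercept`` in mAU·min,
    ``linear_range``, ``lod`` and ``loq`` in µg/mL.
    """

    slope: float
    intercept: float
    linear_range: tuple[float, float]
    lod: float
    loq: float


#: Calibration lines y = slope·x + intercept with linear range, LOD (S/N 3)
#: and LOQ (S/N 10) for each analyte.
CALIBRATION: dict[str, CalibrationConstants] = {
    "hypoxanthine": CalibrationConstants(33.148, -0.7255, (0.682, 33.5), 0.102, 0.341),
    "xanthine": CalibrationConstants(34.489, -2.5796, (0.606, 29.8), 0.0918, 0.303),
    "uridine": CalibrationConstants(22.413, 0.3431, (1.08, 54.5), 0.164, 0.542),
    "inosine": CalibrationConstants(17.695, 0.5263, (1.66, 83.2), 0.250, 0.831),
    "guanosine": CalibrationConstants(21.392, -0.9505, (1.14, 56.8), 0.172, 0.572),
    "adenosine": CalibrationConstants(31.131, -0.5006, (0.824, 41.3), 0.125, 0.412),
}

#: Sample preparation: 1.0 g of 24-mesh powder extracted into 20 mL of 5%
#: methanol; extract concentration (µg/mL) = content (µg/g) × mass / volume.
SAMPLE_MASS_G: float = 1.0
EXTRACT_VOLUME_ML: float = 20.0


@dataclass(frozen=True)
class SpeciesProfile:
    """Per-species dry-weight content ranges used by the study simulator.

    ``analyte_content_ranges`` maps analyte name to an inclusive
    (low, high) content range in µg per g of dried material.  The
    adenosine range is (0, 0) exactly when ``adenosine_present`` is
    False: absence of adenosine is the marker separating authentic
    *P. aspergillum* from its adulterants.
    """

    species_name: str
    analyte_content_ranges: dict[str, tuple[float, float]] = field(repr=False)
    adenosine_present: bool = True

    def __post_init__(self) -> None:
        missing = [a for a in ANALYTES if a not in self.analyte_content_ranges]
        if missing:
            raise ValueError(f"profile {self.species_name!r} missing ranges for {missing}")
        for analyte, (low, high) in self.analyte_content_ranges.items():
            if low < 0 or high < low:
                raise ValueError(
                    f"profile {self.species_name!r}: invalid range {(low, high)} for {analyte}"
                )
        aden = self.analyte_content_ranges["adenosine"]
        if (aden == (0.0, 0.0)) == self.adenosine_present:
            raise ValueError(
                f"profile {self.species_name!r}: adenosine range {aden} inconsistent "
                f"with adenosine_present={self.adenosine_present}"
            )


def _profile(name: str, present: bool, *ranges: tuple[float, float]) -> SpeciesProfile:
    return SpeciesProfile(
        species_name=name,
        analyte_content_ranges=dict(zip(ANALYTES, ranges)),
        adenosine_present=present,
    )


#: Observed per-species content ranges (µg/g, min-max over surveyed batches).
SPECIES_PROFILES: dict[str, SpeciesProfile] = {
    "P. aspergillum": _profile(
        "P. aspergillum",
        False,
        (131.05, 982.11),
        (31.51, 420.25),
        (49.08, 430.44),
        (794.49, 2692.14),
        (50.27, 410.54),
        (0.0, 0.0),
    ),
    "A. obscuritoporus": _profile(
        "A. obscuritoporus",
        True,
        (40.71, 823.42),
        (20.03, 183.93),
        (53.53, 282.30),
        (128.67, 1332.21),
        (48.73, 154.79),
        (303.92, 1357.74),
    ),
    "M. magna": _profile(
        "M. magna",
        True,
        (110.27, 1050.56),
        (18.61, 876.82),
        (97.10, 248.04),
        (191.79, 2385.55),
        (87.35, 860.87),
        (128.88, 398.14),
    ),
}

#: The authentic species name.
AUTHENTIC_SPECIES: str = "P. aspergillum"

#: Contents (µg/g) of the repeatability/stability/recovery test sample
#: (an adulterant batch whose extract falls inside every linear range).
VALIDATION_SAMPLE_CONTENTS: dict[str, float] = {
    "hypoxanthine": 503.07,
    "xanthine": 82.11,
    "uridine": 143.20,
    "inosine": 991.91,
    "guanosine": 84.55,
    "adenosine": 819.37,
}
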