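"""Published reference figures for the León (NW Spain) case study.

Bundled so the synthetic pathway can mirror the real study design: the six
dominant forest strata with their areas and national-forest-inventory plot
counts (province-wide and within the ten most-surveyed municipalities), and
the published power-law calibration parameter sets per stratum, used here as
known generator truths for simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "StratumReference",
    "STRATA",
    "COMBINED",
    "CALIBRATIONS",
    "CalibrationReference",
]


@dataclass(frozen=True)
class StratumReference:
    code: int
    species: str
    area_ha_province: float
    area_ha_districts: float
    plots_province: int
    plots_districts: int


#: Six dominant forest strata: province-wide and 10-district areas/plot counts.
STRATA: tuple[StratumReference, ...] = (
    StratumReference(102, "Pinus sylvestris", 64_012.82, 8_794.10, 167, 40),
    StratumReference(103, "Pinus pinaster", 23_413.33, 7_998.96, 58, 20),
    StratumReference(106, "Quercus pyrenaica", 212_017.32, 32_680.84, 322, 66),
    StratumReference(118, "Pinus nigra", 28_631.40, 7_840.99, 95, 26),
    StratumReference(119, "Fagus sylvatica", 21_894.53, 9_229.60, 87, 42),
    StratumReference(121, "Quercus spp.", 15_010.45, 4_629.24, 47, 14),
)

#: The printed combined row (all six strata).
COMBINED = StratumReference(
    0, "combined", 364_979.85, 71_173.73, 725, 208
)


@dataclass(frozen=True)
class CalibrationReference:
    """Published AGBD = a * h1^b * h2^c calibration for one stratum."""

    code: int
    h1: str
    h2: str | None
    a: float
    b: float
    c: float | None
    rmse: float
    rmse_pct: float
    bias_pct: float
    adj_r2: float
    n_plots: int


#: Published per-stratum calibrations (two-predictor power models; stratum 121
#: uses a single height predictor).
CALIBRATIONS: dict[int, CalibrationReference] = {
    102: CalibrationReference(102, "h50", "fc", 0.0096, 1.0555, 1.5165, 21.07, 27.50, -0.47, 0.88, 167),
    103: CalibrationReference(103, "h20", "fc", 0.1002, 1.1347, 1.0145, 22.39, 33.65, -0.98, 0.88, 58),
    106: CalibrationReference(106, "h30", "fc", 0.0164, 1.7494, 1.1383, 33.30, 51.60, -2.05, 0.76, 325),
    118: CalibrationReference(118, "h25", "fc", 2.3993, 1.1252, 0.3476, 32.00, 27.42, -0.65, 0.87, 68),
    119: CalibrationReference(119, "h40", "fc", 0.0069, 0.5667, 1.9600, 70.90, 37.30, 0.84, 0.84, 87),
    121: CalibrationReference(121, "h50", None, 2.6310, 1.7440, None, 72.39, 45.03, 0.69, 0.70, 47),
}
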