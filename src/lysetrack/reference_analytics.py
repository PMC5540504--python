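"""Reductions for the orthogonal cell-disruption assays.

The chromatographic recovery statistic is benchmarked against four
reference methods, each reduced here to one number per homogenization
cycle:

* Bradford total protein (mg/mL) — used as-is;
* colony-forming units — serial-dilution plate counts converted to CFU/mL,
  picking the countable plate (30-300 colonies) per cycle;
* flow cytometry — viable events = membrane-stained total (RH414) minus
  depolarized dead cells (DiBAC4(3));
* dielectric spectroscopy — mean delta capacitance, i.e. low-frequency
  (viable-cell polarization) minus high-frequency (background) capacitance
  averaged over the measurement window.

:func:`build_comparison` assembles the five-method table: protein-type
signals are end-anchored (final cycle = 100% released protein), viability
signals start-anchored (untreated sample = 100% intact cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import normalize_end_anchored, normalize_start_anchored

__all__ = [
    "CfuPlate",
    "FcCounts",
    "DsTrace",
    "cfu_per_ml",
    "select_countable_plate",
    "fc_viable",
    "ds_signal",
    "build_comparison",
    "PROTEIN_METHODS",
    "VIABILITY_METHODS",
]

PROTEIN_METHODS = ("Bradford", "HPLC")
VIABILITY_METHODS = ("DS", "CfUs", "FC")

#: Standard microbiological countable range for a plate.
COUNTABLE_RANGE = (30, 300)


@dataclass(frozen=True)
class CfuPlate:
    """One plated dilution of one cycle's sample.

    ``dilution_exp`` is log10 of the dilution factor (e.g. -6 for a
    1:10^6 dilution); 100 uL plated by default.
    """

    cycle: int
    dilution_exp: int
    colonies: int
    plated_volume_ml: float = 0.1

    def __post_init__(self) -> None:
        if self.dilution_exp > 0:
            raise ValueError("dilution_exp is log10 of a dilution, must be <= 0")
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")
        if self.plated_volume_ml <= 0:
            raise ValueError("plated_volume_ml must be > 0")


@dataclass(frozen=True)
class FcCounts:
    """Flow-cytometry event counts of one cycle (total vs dead dye)."""

    cycle: int
    total_rh414: int
    dead_dibac: int

    def __post_init__(self) -> None:
        if self.total_rh414 < 0 or self.dead_dibac < 0:
            raise ValueError("counts must be >= 0")
        if self.dead_dibac > self.total_rh414:
            raise ValueError("dead count exceeds total count")


@dataclass
class DsTrace:
    """Dual-frequency capacitance logging of one cycle's suspension."""

    cycle: int
    cap_low_freq: np.ndarray
    cap_high_freq: np.ndarray
    duration_s: float = 180.0

    def __post_init__(self) -> None:
        self.cap_low_freq = np.asarray(self.cap_low_freq, dtype=float)
        self.cap_high_freq = np.asarray(self.cap_high_freq, dtype=float)
        if self.cap_low_freq.size != self.cap_high_freq.size:
            raise ValueError("the two frequency traces must have equal length")
        if self.cap_low_freq.size == 0:
            raise ValueError("empty capacitance trace")
        if self.duration_s < 180.0:
            raise ValueError("capacitance must be logged for at least 3 min")


def cfu_per_ml(plate: CfuPlate) -> float:
    """Colony-forming units per mL of the undiluted sample."""
    return plate.colonies / plate.plated_volume_ml * 10.0 ** (-plate.dilution_exp)


def _range_distance(colonies: int) -> int:
    lo, hi = COUNTABLE_RANGE
    if colonies < lo:
        return lo - colonies
    if colonies > hi:
        return colonies - hi
    return 0


def select_countable_plate(plates: Sequence[CfuPlate]) -> CfuPlate:
    """Pick the plate to count from a dilution series of one cycle.

    Preference: a plate inside the countable range (30-300 colonies) with
    count closest to 100; if no plate is in range, the plate nearest the
    range. Ties go to the higher dilution (more negative exponent).
    """
    if not plates:
        raise ValueError("no plates to select from")
    in_range = [p for p in plates if _range_distance(p.colonies) == 0]
    if in_range:
        return min(in_range, key=lambda p: (abs(p.colonies - 100), p.dilution_exp))
    return min(plates, key=lambda p: (_range_distance(p.colonies), p.dilution_exp))


def fc_viable(counts: FcCounts) -> int:
    """Viable cells: total membrane-stained events minus dead-dye events."""
    return counts.total_rh414 - counts.dead_dibac


def ds_signal(trace: DsTrace) -> float:
    """Mean delta capacitance (low-frequency minus high-frequency)."""
    return float(np.mean(trace.cap_low_freq - trace.cap_high_freq))


def build_comparison(
    protein: Mapping[str, Sequence[float]],
    viability: Mapping[str, Sequence[float]],
    cycles: Sequence[int],
) -> pd.DataFrame:
    """Five-method percent table, rows = cycles, columns = methods.

    ``protein`` series (e.g. Bradford mg/mL, chromatographic total AUC) are
    end-anchored; ``viability`` series (delta capacitance, CFU/mL, viable
    events) are start-anchored. Every series must cover ``cycles`` exactly.
    """
    cycles = list(cycles)
    n = len(cycles)
    data: dict[str, np.ndarray] = {}
    for name, series in protein.items():
        if len(series) != n:
            raise ValueError(f"method {name!r} does not cover the cycle set")
        data[name] = normalize_end_anchored(np.asarray(series, dtype=float))
    for name, series in viability.items():
        if len(series) != n:
            raise ValueError(f"method {name!r} does not cover the cycle set")
        data[name] = normalize_start_anchored(np.asarray(series, dtype=float))
    df = pd.DataFrame(data, index=pd.Index(cycles, name="cycle"))
    return df
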