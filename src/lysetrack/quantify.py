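"""Peak integration and protein-recovery statistics.

After alignment, the flowthrough (FT) and elution (EL) peaks of each run
are integrated by the composite trapezoid rule over half-open regions of
interest ``[start_s, end_s)``; the summed area tracks total soluble
protein. Two normalization conventions turn per-cycle areas into percent
recoveries:

* start-anchored relative recovery,
  ``(AUC_i - AUC_start) / (AUC_end - AUC_start) * 100`` — 0% before
  homogenization, 100% after the final cycle;
* end-anchored, ``AUC_i / AUC_end * 100`` — the final cycle is declared
  100% total protein, so the untreated sample reports its free-protein
  share directly.

Viability-type signals (plate counts, cytometry, capacitance) use the
mirror start-anchored form ``value_i / value_0 * 100`` instead; see
:mod:`lysetrack.reference_analytics`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import Chromatogram, ChromatogramSet, SampleMeta

__all__ = [
    "RegionOfInterest",
    "PeakAreas",
    "RecoverySeries",
    "integrate_roi",
    "peak_areas",
    "propose_roi_boundaries",
    "relative_recovery_eq2",
    "normalize_end_anchored",
    "normalize_start_anchored",
    "normalize_per_biomass",
    "od_to_dcw",
    "dcw_to_od",
    "tabulate_recovery",
]

#: Slope of the linear OD600 -> dry-cell-weight correlation, g DCW/L per OD unit.
OD600_DCW_SLOPE = 0.451


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open integration window ``[start_s, end_s)`` in seconds."""

    name: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"ROI {self.name!r}: start_s must be < end_s")

    def overlaps(self, other: "RegionOfInterest") -> bool:
        return self.start_s < other.end_s and other.start_s < self.end_s


@dataclass(frozen=True)
class PeakAreas:
    """Integrated FT and EL areas (mAU·s) of one sample."""

    sample: SampleMeta
    auc_ft: float
    auc_el: float

    @property
    def auc_total(self) -> float:
        return self.auc_ft + self.auc_el


@dataclass
class RecoverySeries:
    """Cycle-indexed total areas of one disruption experiment."""

    cycles: np.ndarray
    auc_total: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.auc_total = np.asarray(self.auc_total, dtype=float)
        if self.cycles.size != self.auc_total.size:
            raise ValueError("cycles and auc_total must have equal length")
        if self.cycles.size and np.any(np.diff(self.cycles) <= 0):
            raise ValueError("cycles must be strictly increasing")


def integrate_roi(chrom: Chromatogram, roi: RegionOfInterest) -> float:
    """Trapezoid-rule area (mAU·s) of the trace over ``[start_s, end_s)``.

    Partial sampling intervals at the window boundaries are handled by
    linear interpolation of the trace at the boundary times, so the result
    is the exact integral of the piecewise-linear interpolant.
    """
    t, y = chrom.time_s, chrom.absorbance_mau
    eps = 1e-9 * max(1.0, abs(t[-1]))
    # half-open windows may end one spacing past the last sample
    if roi.start_s < t[0] - eps or roi.end_s > t[-1] + chrom.spacing_s + eps:
        raise ValueError(
            f"ROI {roi.name!r} [{roi.start_s}, {roi.end_s}) outside the trace "
            f"span [{t[0]}, {t[-1]}]"
        )
    start = max(roi.start_s, t[0])
    end = min(roi.end_s, t[-1])
    inner = (t > start) & (t < end)
    ts = np.concatenate(([start], t[inner], [end]))
    ys = np.concatenate(([np.interp(start, t, y)], y[inner], [np.interp(end, t, y)]))
    return float(np.trapezoid(ys, ts))


def _baseline_corrected(chrom: Chromatogram, roi: RegionOfInterest) -> Chromatogram:
    """Subtract the line through the trace values at the ROI endpoints."""
    t, y = chrom.time_s, chrom.absorbance_mau
    y0 = np.interp(roi.start_s, t, y)
    y1 = np.interp(min(roi.end_s, t[-1]), t, y)
    x1 = min(roi.end_s, t[-1])
    slope = (y1 - y0) / (x1 - roi.start_s)
    line = y0 + slope * (t - roi.start_s)
    return chrom.with_absorbance(y - line)


def peak_areas(
    chrom: Chromatogram,
    ft: RegionOfInterest,
    el: RegionOfInterest,
    baseline: bool = False,
) -> PeakAreas:
    """Integrate the FT and EL windows of one trace.

    With ``baseline=True`` a straight line through the trace values at each
    window's endpoints is subtracted before integrating that window.
    Negative areas (noise below baseline) are clipped to zero with a
    warning, since a negative protein amount is non-physical.
    """
    if ft.overlaps(el):
        raise ValueError("FT and EL regions of interest must be disjoint")
    areas = {}
    for roi in (ft, el):
        source = _baseline_corrected(chrom, roi) if baseline else chrom
        a = integrate_roi(source, roi)
        if a < 0:
            warnings.warn(
                f"negative area {a:.3g} in ROI {roi.name!r} clipped to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            a = 0.0
        areas[roi.name] = a
    return PeakAreas(sample=chrom.meta, auc_ft=areas[ft.name], auc_el=areas[el.name])


def propose_roi_boundaries(
    reference: Chromatogram, names: tuple[str, str] = ("FT", "EL")
) -> tuple[RegionOfInterest, RegionOfInterest]:
    """Split the run at the deepest valley between the two largest peaks.

    Convenience for configuring FT/EL windows from a mean reference trace:
    the first window runs from injection to the valley, the second from the
    valley to the end of the run.
    """
    t, y = reference.time_s, reference.absorbance_mau
    peaks, props = find_peaks(y, prominence=(y.max() - y.min()) * 0.05)
    if peaks.size < 2:
        raise ValueError("reference trace does not show two separated peaks")
    order = np.argsort(props["prominences"])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    valley = p1 + int(np.argmin(y[p1:p2]))
    return (
        RegionOfInterest(names[0], float(t[0]), float(t[valley])),
        RegionOfInterest(names[1], float(t[valley]), float(t[-1]) + reference.spacing_s),
    )


def _as_values(series) -> np.ndarray:
    if isinstance(series, RecoverySeries):
        return series.auc_total
    return np.asarray(series, dtype=float)


def relative_recovery_eq2(series) -> np.ndarray:
    """Start-anchored relative protein recovery, percent per cycle.

    ``(AUC_i - AUC_start) / (AUC_end - AUC_start) * 100`` where start and
    end are the first and last cycles of the series. By construction the
    first cycle maps to 0% and the last to 100%; the statistic is invariant
    under positive affine transforms of the area series.
    """
    v = _as_values(series)
    if v.size < 2:
        raise ValueError("relative recovery needs at least two cycles")
    span = v[-1] - v[0]
    if span == 0:
        raise ZeroDivisionError(
            "relative recovery undefined: first and last AUC are equal"
        )
    return (v - v[0]) / span * 100.0


def normalize_end_anchored(series) -> np.ndarray:
    """Percent of the final value; the last cycle is declared 100%."""
    v = _as_values(series)
    if v.size == 0:
        raise ValueError("empty series")
    if v[-1] == 0:
        raise ZeroDivisionError("end-anchored normalization undefined: final value is 0")
    return v / v[-1] * 100.0


def normalize_start_anchored(series) -> np.ndarray:
    """Percent of the initial value; the untreated sample is 100%."""
    v = _as_values(series)
    if v.size == 0:
        raise ValueError("empty series")
    if v[0] == 0:
        raise ZeroDivisionError("start-anchored normalization undefined: first value is 0")
    return v / v[0] * 100.0


def normalize_per_biomass(auc: float, biomass_gdcw_per_l: float) -> float:
    """Area per unit biomass, mAU·s per (g DCW/L)."""
    if biomass_gdcw_per_l <= 0:
        raise ValueError("biomass must be > 0")
    return auc / biomass_gdcw_per_l


def od_to_dcw(od600: float) -> float:
    """Dry cell weight (g DCW/L) from an OD600 reading via the linear correlation."""
    if od600 < 0:
        raise ValueError("od600 must be >= 0")
    return OD600_DCW_SLOPE * od600


def dcw_to_od(dcw_gdcw_per_l: float) -> float:
    """OD600 required to hit a target dry-cell-weight concentration."""
    if dcw_gdcw_per_l < 0:
        raise ValueError("dcw must be >= 0")
    return dcw_gdcw_per_l / OD600_DCW_SLOPE


def tabulate_recovery(
    cset: ChromatogramSet,
    ft: RegionOfInterest,
    el: RegionOfInterest,
    baseline: bool = False,
) -> pd.DataFrame:
    """Per-cycle area and recovery table for one disruption experiment.

    Traces are ordered by homogenization cycle; the output has one row per
    cycle with FT/EL/total areas and both recovery conventions.
    """
    traces = sorted(cset, key=lambda c: c.meta.cycle)
    cycles = [c.meta.cycle for c in traces]
    if len(set(cycles)) != len(cycles):
        raise ValueError("duplicate cycles in the set; one trace per cycle expected")
    areas = [peak_areas(c, ft, el, baseline=baseline) for c in traces]
    total = np.array([a.auc_total for a in areas])
    df = pd.DataFrame(
        {
            "sample_id": [c.meta.sample_id for c in traces],
            "cycle": cycles,
            "auc_ft": [a.auc_ft for a in areas],
            "auc_el": [a.auc_el for a in areas],
            "auc_total": total,
        }
    )
    df["recovery_eq2_pct"] = relative_recovery_eq2(total)
    df["recovery_end_anchored_pct"] = normalize_end_anchored(total)
    return df
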