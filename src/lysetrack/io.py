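"""Reading, validating, resampling and writing UV chromatograms.

A chromatogram here is a single 280 nm absorbance trace on a uniform time
grid (t = 0 at injection, seconds), typically acquired at 5 Hz over a
5 min anion-exchange run, together with the metadata of the sample it was
recorded from (homogenization cycle, pressure, biomass, fresh/frozen).

On-disk format is instrument-agnostic two-column delimited text
(time_s, absorbance_mau; comma, tab or whitespace separated; one optional
header line). Sample metadata lives in a sidecar delimited table keyed by
``sample_id``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "Chromatogram",
    "ChromatogramSet",
    "ChromatogramFormatError",
    "read_chromatogram",
    "write_chromatogram",
    "read_sample_table",
    "write_sample_table",
    "load_chromatogram_set",
    "write_chromatogram_set",
    "resample_to_grid",
]

#: Maximum allowed relative deviation of the grid spacing; larger is an error
#: because integer-sample alignment assumes a truly uniform grid.
GRID_RELTOL = 1e-6


class ChromatogramFormatError(ValueError):
    """A chromatogram file violates the two-column delimited-text contract."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata of one homogenization sample.

    ``cycle`` 0 is the resuspended, untreated biomass (the "0 sample")
    that anchors start-normalized statistics.
    """

    sample_id: str
    cycle: int = 0
    pressure_bar: float = 0.0
    biomass_gdcw_per_l: float = 1.0
    frozen: bool = False
    condition_label: str | None = None

    def __post_init__(self) -> None:
        if self.cycle < 0:
            raise ValueError(f"cycle must be >= 0, got {self.cycle}")
        if not 0.0 <= self.pressure_bar <= 2000.0:
            raise ValueError(
                f"pressure_bar must be in [0, 2000], got {self.pressure_bar}"
            )
        if not self.biomass_gdcw_per_l > 0:
            raise ValueError(
                f"biomass_gdcw_per_l must be > 0, got {self.biomass_gdcw_per_l}"
            )


@dataclass
class Chromatogram:
    """One absorbance trace at 280 nm on a uniform time grid.

    Parameters
    ----------
    meta : SampleMeta
        Sample the trace was recorded from.
    time_s : ndarray
        Strictly increasing uniform grid, seconds from injection.
    absorbance_mau : ndarray
        Absorbance in mAU, same length as ``time_s``.
    """

    meta: SampleMeta
    time_s: np.ndarray
    absorbance_mau: np.ndarray
    sampling_rate_hz: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.absorbance_mau = np.asarray(self.absorbance_mau, dtype=float)
        if self.time_s.ndim != 1 or self.absorbance_mau.ndim != 1:
            raise ValueError("time and absorbance must be one-dimensional")
        if self.time_s.size != self.absorbance_mau.size:
            raise ValueError(
                f"length mismatch: {self.time_s.size} times vs "
                f"{self.absorbance_mau.size} absorbances"
            )
        if self.time_s.size < 2:
            raise ValueError("a chromatogram needs at least two samples")
        if not (np.isfinite(self.time_s).all() and np.isfinite(self.absorbance_mau).all()):
            raise ValueError("chromatogram contains non-finite values")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"time grid not strictly increasing at sample {row}")
        spacing = float(dt.mean())
        if (dt.max() - dt.min()) / spacing > GRID_RELTOL:
            raise ValueError(
                "time grid is not uniform (relative spacing deviation exceeds "
                f"{GRID_RELTOL:g})"
            )
        if self.sampling_rate_hz <= 0:
            self.sampling_rate_hz = 1.0 / spacing

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def spacing_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def with_absorbance(self, values: np.ndarray, meta: SampleMeta | None = None) -> "Chromatogram":
        """Copy of this trace with new absorbance values on the same grid."""
        return Chromatogram(
            meta=meta if meta is not None else self.meta,
            time_s=self.time_s.copy(),
            absorbance_mau=np.asarray(values, dtype=float),
            sampling_rate_hz=self.sampling_rate_hz,
        )


@dataclass
class ChromatogramSet:
    """Ordered collection of chromatograms sharing one time grid."""

    traces: list[Chromatogram]

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("chromatogram set must not be empty")
        ref = self.traces[0].time_s
        for c in self.traces[1:]:
            if c.time_s.size != ref.size or not np.allclose(
                c.time_s, ref, rtol=0, atol=GRID_RELTOL * max(1.0, abs(ref[-1]))
            ):
                raise ValueError(
                    f"trace {c.meta.sample_id!r} is not on the common time grid"
                )
        ids = [c.meta.sample_id for c in self.traces]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique within a set")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[Chromatogram]:
        return iter(self.traces)

    def __getitem__(self, i: int) -> Chromatogram:
        return self.traces[i]

    @property
    def time_s(self) -> np.ndarray:
        return self.traces[0].time_s

    @property
    def sample_ids(self) -> list[str]:
        return [c.meta.sample_id for c in self.traces]

    def absorbance_matrix(self) -> np.ndarray:
        """Stack the traces into an (n_traces, n_samples) array."""
        return np.vstack([c.absorbance_mau for c in self.traces])

    def with_matrix(self, matrix: np.ndarray) -> "ChromatogramSet":
        """New set with the same grid and metadata but new absorbance rows."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(self), self.time_s.size):
            raise ValueError("matrix shape does not match the set")
        return ChromatogramSet(
            [c.with_absorbance(row) for c, row in zip(self.traces, matrix)]
        )


def _sniff_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # any whitespace


def read_chromatogram(path: str | Path, meta: SampleMeta) -> Chromatogram:
    """Read one two-column (time_s, absorbance_mau) delimited text file.

    The delimiter (comma, tab or whitespace) is auto-detected and a single
    header line is tolerated. Non-numeric rows and non-monotonic time raise
    :class:`ChromatogramFormatError` naming the offending line (1-based,
    counting the header).
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    delimiter: str | None = None
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if delimiter is None and not times:
                delimiter = _sniff_delimiter(line)
            parts = line.split(delimiter)
            parts = [p for p in parts if p != ""]
            if len(parts) != 2:
                raise ChromatogramFormatError(
                    f"{path.name}: expected two columns at line {lineno}"
                )
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                if not times and not header_seen:
                    header_seen = True  # one header line allowed
                    continue
                raise ChromatogramFormatError(
                    f"{path.name}: non-numeric value at line {lineno}"
                ) from None
            if times and t <= times[-1]:
                raise ChromatogramFormatError(
                    f"{path.name}: time not increasing at line {lineno}"
                )
            times.append(t)
            values.append(v)
    if len(times) < 2:
        raise ChromatogramFormatError(f"{path.name}: fewer than two data rows")
    try:
        return Chromatogram(meta=meta, time_s=np.array(times), absorbance_mau=np.array(values))
    except ValueError as exc:
        raise ChromatogramFormatError(f"{path.name}: {exc}") from exc


def write_chromatogram(path: str | Path, chrom: Chromatogram, delimiter: str = ",") -> None:
    """Write a trace as two-column delimited text with a header line."""
    with open(path, "w") as fh:
        fh.write(f"time_s{delimiter}absorbance_mau\n")
        for t, v in zip(chrom.time_s, chrom.absorbance_mau):
            fh.write(f"{t:.17g}{delimiter}{v:.17g}\n")


_META_COLUMNS = [
    "sample_id",
    "cycle",
    "pressure_bar",
    "biomass_gdcw_per_l",
    "frozen",
    "condition_label",
]


def write_sample_table(path: str | Path, metas: Sequence[SampleMeta]) -> None:
    """Write the sidecar metadata table (one row per sample)."""
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "cycle": m.cycle,
                "pressure_bar": m.pressure_bar,
                "biomass_gdcw_per_l": m.biomass_gdcw_per_l,
                "frozen": m.frozen,
                "condition_label": m.condition_label if m.condition_label is not None else "",
            }
            for m in metas
        ],
        columns=_META_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_sample_table(path: str | Path) -> list[SampleMeta]:
    """Read the sidecar metadata table back into :class:`SampleMeta` rows."""
    df = pd.read_csv(path)
    missing = [c for c in _META_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ChromatogramFormatError(
            f"sample table {Path(path).name} lacks columns: {', '.join(missing)}"
        )
    metas = []
    for _, row in df.iterrows():
        label = row.get("condition_label")
        if label is None or (isinstance(label, float) and math.isnan(label)) or label == "":
            label = None
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                cycle=int(row["cycle"]),
                pressure_bar=float(row["pressure_bar"]),
                biomass_gdcw_per_l=float(row["biomass_gdcw_per_l"]),
                frozen=bool(row["frozen"]),
                condition_label=None if label is None else str(label),
            )
        )
    return metas


def load_chromatogram_set(
    directory: str | Path, metadata_path: str | Path | None = None
) -> ChromatogramSet:
    """Load ``<sample_id>.csv`` traces listed in a metadata table.

    ``metadata_path`` defaults to ``samples.csv`` inside ``directory``.
    Traces are returned sorted by homogenization cycle.
    """
    directory = Path(directory)
    metas = read_sample_table(metadata_path or directory / "samples.csv")
    metas = sorted(metas, key=lambda m: (m.cycle, m.sample_id))
    traces = [read_chromatogram(directory / f"{m.sample_id}.csv", m) for m in metas]
    return ChromatogramSet(traces)


def write_chromatogram_set(directory: str | Path, cset: ChromatogramSet) -> None:
    """Write every trace plus the ``samples.csv`` metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for c in cset:
        write_chromatogram(directory / f"{c.meta.sample_id}.csv", c)
    write_sample_table(directory / "samples.csv", [c.meta for c in cset])


def resample_to_grid(cset: ChromatogramSet, rate_hz: float) -> ChromatogramSet:
    """Linearly interpolate every trace onto a common grid at ``rate_hz``.

    The target grid starts at the set's first time point and never extends
    beyond its last, so interpolation never extrapolates. Original traces
    are untouched.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be > 0")
    t = cset.time_s
    step = 1.0 / rate_hz
    n = int(np.floor((t[-1] - t[0]) / step + 1e-9)) + 1
    grid = t[0] + step * np.arange(n)
    if grid[-1] > t[-1] + 1e-9:
        raise ValueError("target grid extends beyond the trace span")
    new_traces = [
        Chromatogram(
            meta=replace(c.meta),
            time_s=grid.copy(),
            absorbance_mau=np.interp(grid, c.time_s, c.absorbance_mau),
            sampling_rate_hz=rate_hz,
        )
        for c in cset
    ]
    return ChromatogramSet(new_traces)
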