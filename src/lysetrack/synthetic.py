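"""Seeded simulators for chromatograms, disruption runs and DoE datasets.

Each simulated run is a flowthrough + elution pair of Gaussian peaks on a
5 Hz, 5 min grid, with a linear baseline drift, white detector noise and
an integer retention jitter — the features that matter for testing
alignment and integration. Cumulative protein release over homogenization
cycles follows a geometric-survival kinetic: if each pass disrupts a
fraction ``e`` of the still-intact cells and a fraction ``f0`` of the
protein is already free at cycle 0 (freeze-thaw pre-lysis), the released
fraction after ``n`` passes is

    f(n) = f0 + (1 - f0) * (1 - (1 - e)**n),

a saturating curve: one pass at high pressure releases most of the
protein and later passes add progressively less.

All generators are pure functions of their explicit seed; no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .doe import DoEDesign, _term_matrix, code_factors
from .io import Chromatogram, ChromatogramSet, SampleMeta

__all__ = [
    "PeakSpec",
    "DisruptionKinetics",
    "SimConfig",
    "simulate_chromatogram",
    "simulate_disruption_experiment",
    "simulate_doe_dataset",
    "fit_disruption_kinetics",
]


@dataclass(frozen=True)
class PeakSpec:
    """Gaussian peak: center and sigma in seconds, area in mAU·s."""

    center_s: float
    width_s: float
    area: float

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError("width_s must be > 0")
        if self.area < 0:
            raise ValueError("area must be >= 0")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        h = self.area / (self.width_s * np.sqrt(2.0 * np.pi))
        return h * np.exp(-0.5 * ((t - self.center_s) / self.width_s) ** 2)


@dataclass(frozen=True)
class DisruptionKinetics:
    """Geometric-survival release model for high-pressure homogenization.

    ``efficiency_per_cycle`` is the fraction of remaining intact cells
    disrupted per pass; ``released_baseline_frac`` the protein already
    free before the first pass.
    """

    efficiency_per_cycle: float
    released_baseline_frac: float = 0.0
    total_protein: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.efficiency_per_cycle <= 1.0:
            raise ValueError("efficiency_per_cycle must be in (0, 1]")
        if not 0.0 <= self.released_baseline_frac < 1.0:
            raise ValueError("released_baseline_frac must be in [0, 1)")
        if self.total_protein <= 0:
            raise ValueError("total_protein must be > 0")

    def release_fraction(self, n_cycles) -> np.ndarray:
        """Cumulative released fraction f(n); nondecreasing, <= 1."""
        n = np.asarray(n_cycles, dtype=float)
        f0, e = self.released_baseline_frac, self.efficiency_per_cycle
        return f0 + (1.0 - f0) * (1.0 - (1.0 - e) ** n)


def _default_ft() -> PeakSpec:
    return PeakSpec(center_s=60.0, width_s=8.0, area=400.0)


def _default_el() -> PeakSpec:
    return PeakSpec(center_s=200.0, width_s=10.0, area=600.0)


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and disturbance settings of the simulated instrument."""

    run_length_s: float = 300.0
    sampling_rate_hz: float = 5.0
    ft_peak: PeakSpec = field(default_factory=_default_ft)
    el_peak: PeakSpec = field(default_factory=_default_el)
    noise_sd: float = 0.2
    baseline_drift: float = 1.0
    shift_jitter_max: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.run_length_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("run length and sampling rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.shift_jitter_max < 0:
            raise ValueError("shift_jitter_max must be >= 0")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.run_length_s * self.sampling_rate_hz))
        return np.arange(n) / self.sampling_rate_hz


def simulate_chromatogram(
    config: SimConfig,
    protein_load: float,
    seed: int,
    meta: SampleMeta | None = None,
) -> Chromatogram:
    """One synthetic trace at a given released-protein fraction.

    The two peak areas scale linearly with ``protein_load``; on top come a
    linear baseline drift, a uniform integer retention shift within
    ``±shift_jitter_max`` samples (edge-replicated) and white noise.
    Identical seeds give bit-identical traces.
    """
    if not 0.0 <= protein_load <= 1.0:
        raise ValueError("protein_load must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t = config.time_grid()
    signal = protein_load * (config.ft_peak.evaluate(t) + config.el_peak.evaluate(t))
    jitter = int(rng.integers(-config.shift_jitter_max, config.shift_jitter_max + 1))
    if jitter:
        from .alignment import shift_with_edge_fill

        signal = shift_with_edge_fill(signal, jitter)
    baseline = config.baseline_drift * t / config.run_length_s
    noise = rng.normal(0.0, config.noise_sd, size=t.size) if config.noise_sd > 0 else 0.0
    if meta is None:
        meta = SampleMeta(sample_id=f"sim_seed{seed}")
    return Chromatogram(
        meta=meta,
        time_s=t,
        absorbance_mau=signal + baseline + noise,
        sampling_rate_hz=config.sampling_rate_hz,
    )


def simulate_disruption_experiment(
    kinetics: DisruptionKinetics,
    n_cycles: int,
    config: SimConfig,
    seed: int,
    pressure_bar: float = 1500.0,
    biomass_gdcw_per_l: float = 10.0,
    frozen: bool = False,
) -> tuple[ChromatogramSet, np.ndarray]:
    """Chromatograms for cycles 0..n plus the true release fractions.

    Cycle ``i`` is simulated at protein load ``f(i)``; the returned truth
    vector lets tests compare computed recoveries against the kinetics.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    cycles = np.arange(n_cycles + 1)
    fractions = kinetics.release_fraction(cycles)
    children = np.random.SeedSequence(seed).spawn(len(cycles))
    traces = []
    for i, child in zip(cycles, children):
        meta = SampleMeta(
            sample_id=f"cycle{i}",
            cycle=int(i),
            pressure_bar=pressure_bar,
            biomass_gdcw_per_l=biomass_gdcw_per_l,
            frozen=frozen,
        )
        traces.append(
            simulate_chromatogram(
                config,
                protein_load=float(fractions[i]),
                seed=int(child.generate_state(1)[0] % (2**31)),
                meta=meta,
            )
        )
    return ChromatogramSet(traces), fractions


def simulate_doe_dataset(
    design: DoEDesign,
    coefficients: dict[str, float],
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Run table with a response drawn from the screening-model family.

    ``coefficients`` are keyed by term name on coded factors: "intercept",
    main effects by factor name, interactions as "name1:name2" — exactly
    the term set of :class:`~lysetrack.doe.FactorialScreeningModel`.
    Unknown keys raise; omitted terms are zero. The response is the model
    value plus seeded Gaussian noise.
    """
    Z = code_factors(design).to_numpy()
    T, names = _term_matrix(Z, design.factor_names, interactions=True)
    unknown = set(coefficients) - set(names)
    if unknown:
        raise ValueError(
            f"coefficients {sorted(unknown)} do not match the model terms {names}"
        )
    beta = np.array([coefficients.get(name, 0.0) for name in names])
    rng = np.random.default_rng(seed)
    response = T @ beta
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=response.size)
    out = design.runs.copy()
    out["response"] = response
    return out


def fit_disruption_kinetics(cycles, auc_total) -> DisruptionKinetics:
    """Least-squares estimate of the release kinetics from an AUC series.

    Fits ``AUC(n) = A * (f0 + (1 - f0) * (1 - (1 - e)**n))`` for the
    per-cycle efficiency ``e``, the pre-lysed fraction ``f0`` and the
    total-protein scale ``A``.
    """
    n = np.asarray(cycles, dtype=float)
    y = np.asarray(auc_total, dtype=float)
    if n.size != y.size or n.size < 3:
        raise ValueError("need matching cycle/AUC series of length >= 3")
    scale = max(y.max(), 1e-12)

    def residuals(theta):
        e, f0, a = theta
        f = f0 + (1.0 - f0) * (1.0 - (1.0 - e) ** n)
        return a * f - y

    f0_guess = float(np.clip(y[0] / scale, 0.0, 0.9))
    res = least_squares(
        residuals,
        x0=(0.8, f0_guess, scale),
        bounds=([1e-6, 0.0, 1e-12], [1.0, 1.0 - 1e-9, np.inf]),
    )
    e, f0, a = res.x
    return DisruptionKinetics(
        efficiency_per_cycle=float(e),
        released_baseline_frac=float(f0),
        total_protein=float(a),
    )
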