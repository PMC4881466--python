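"""Seeded synthetic datasets with the statistical structure the analysis
assumes: spectral time series of the deoxy -> nitrosyl conversion and
single-transition pH titrations, both with additive Gaussian instrument
noise.

Every generator is a pure function of (parameters, seed).  A top-level
seed is split into per-series sub-streams deterministically, so a whole
multi-concentration dataset is reproducible bit-for-bit from one
integer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .inference import M_TO_MM, TitrationSeries, fraction_protonated
from .mechanism import KineticTrace, MechanismParams, simulate_mechanism
from .spectra import ReferenceSpectrum, Spectrum

__all__ = [
    "NoiseModel",
    "SpectralSeries",
    "KineticDataset",
    "trace_to_spectra",
    "default_times",
    "generate_kinetic_dataset",
    "generate_titration_dataset",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian noise, sigma in AU, with a fixed seed."""

    sigma: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def child(self, index: int) -> "NoiseModel":
        """Deterministic sub-stream for series ``index``."""
        sub = np.random.SeedSequence([int(self.seed), int(index)])
        return replace(self, seed=int(sub.generate_state(1)[0]))


@dataclass(frozen=True)
class SpectralSeries:
    """One spectral time series at a fixed nitrite concentration."""

    nitrite: float
    spectra: list[Spectrum]
    truth: KineticTrace
    seed: int


@dataclass(frozen=True)
class KineticDataset:
    """A set of spectral time series across nitrite concentrations, with
    the generating parameters kept as ground truth for recovery tests."""

    params: MechanismParams
    total_heme: float
    sigma: float
    seed: int
    reference_ids: dict = field(default_factory=dict)
    series: list[SpectralSeries] = field(default_factory=list)


def trace_to_spectra(
    trace: KineticTrace,
    refs: dict[str, ReferenceSpectrum],
    noise: NoiseModel,
) -> list[Spectrum]:
    """Timed absorbance spectra from a concentration trace.

    A(lambda, t) = sum_i c_i(t) * 1e3 * epsilon_i(lambda) + N(0, sigma^2)
    for the heme species i in {deoxy, ferric, nitrosyl} (free NO has no
    visible absorbance).  Every species that is populated anywhere in
    the trace must have a reference; all references must share a grid.
    During a clean two-species conversion the constant total heme makes
    absorbance time-invariant wherever the two references cross
    (isosbestic points).
    """
    species = ("deoxy", "ferric", "nitrosyl")
    populated = [
        name for name in species
        if np.max(np.abs(trace.species(name))) > 1e-6 * trace.total_heme
    ]
    missing = [name for name in populated if name not in refs]
    if missing:
        raise ValueError(f"populated species without a reference spectrum: {missing}")
    used = [name for name in species if name in refs]
    grids = [refs[name].wavelengths for name in used]
    for g in grids[1:]:
        if not np.array_equal(g, grids[0]):
            raise ValueError("reference spectra must share one wavelength grid")
    wl = grids[0]
    rng = noise.rng()
    out = []
    for j, t in enumerate(trace.times):
        ab = np.zeros_like(wl)
        for name in used:
            ab = ab + trace.species(name)[j] * M_TO_MM * refs[name].absorbance
        if noise.sigma > 0:
            ab = ab + noise.sigma * rng.standard_normal(wl.size)
        out.append(Spectrum(wl, ab, {"time_s": float(t)}))
    return out


def default_times(p: MechanismParams, n_points: int = 60, span_folds: float = 6.0) -> np.ndarray:
    """Time grid scaled to the expected pseudo-first-order rate.

    Samples ``n_points`` evenly over ``span_folds`` characteristic times
    1/k1', so slow and fast series are equally well resolved.
    """
    k1 = p.k1_prime
    if k1 <= 0:
        raise ValueError("expected rate is zero; supply an explicit time grid")
    return np.linspace(0.0, span_folds / k1, n_points)


def generate_kinetic_dataset(
    p: MechanismParams,
    nitrite_list: list[float],
    total_heme: float,
    times: np.ndarray | None,
    refs: dict[str, ReferenceSpectrum],
    noise: NoiseModel,
) -> KineticDataset:
    """One spectral time series per nitrite concentration.

    Each series is simulated with `simulate_mechanism` and rendered with
    `trace_to_spectra` using a per-series noise sub-stream.  When
    ``times`` is None each series gets a grid scaled to its own expected
    rate (`default_times`).  Nitrite below 5x total heme triggers the
    pseudo-first-order warning but still generates data.
    """
    if not nitrite_list:
        raise ValueError("nitrite_list must not be empty")
    series = []
    for i, nitrite in enumerate(nitrite_list):
        pi = replace(p, nitrite=float(nitrite))
        t = default_times(pi) if times is None else np.asarray(times, dtype=float)
        trace = simulate_mechanism(pi, total_heme, t)
        child = noise.child(i)
        spectra = trace_to_spectra(trace, refs, child)
        series.append(
            SpectralSeries(nitrite=float(nitrite), spectra=spectra, truth=trace,
                           seed=child.seed)
        )
    return KineticDataset(
        params=p,
        total_heme=float(total_heme),
        sigma=noise.sigma,
        seed=noise.seed,
        reference_ids={k: v.species_id for k, v in refs.items()},
        series=series,
    )


def generate_titration_dataset(
    pk: float,
    n: float,
    a_acid: float,
    a_alk: float,
    ph_grid: np.ndarray,
    noise: NoiseModel,
    monitor_wavelength: float = 557.0,
) -> TitrationSeries:
    """Absorbance-vs-pH series from the single-transition model.

    A(pH) = a_alk + (a_acid - a_alk) * c_plus(pH; pK, n) + N(0, sigma^2).
    At pH = pK the noiseless curve passes through the endpoint midpoint.
    """
    ph = np.asarray(ph_grid, dtype=float)
    if ph.size < 4:
        raise ValueError("ph_grid needs at least 4 points")
    if a_acid == a_alk:
        raise ValueError("degenerate endpoints: a_acid == a_alk")
    c_plus = fraction_protonated(ph, pk, n)
    ab = a_alk + (a_acid - a_alk) * c_plus
    if noise.sigma > 0:
        ab = ab + noise.sigma * noise.rng().standard_normal(ph.size)
    return TitrationSeries(
        ph=ph,
        absorbance=ab,
        monitor_wavelength=monitor_wavelength,
        meta={"pk": pk, "n": n, "a_acid": a_acid, "a_alk": a_alk,
              "sigma": noise.sigma, "seed": noise.seed},
    )
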