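"""UV-visible absorption spectra of heme species: construction, peak
analysis, coordination/spin classification and linear unmixing.

Heme proteins report their iron oxidation, coordination and spin state
through the position and shape of the Soret band (~390-440 nm), the
alpha/beta bands (~500-580 nm) and, for high-spin ferric species, a
charge-transfer band near 620-650 nm.  This module represents spectra as
wavelength/absorbance arrays, renders pure-species reference spectra as
sums of Gaussian bands, locates band maxima (directly or through the
second derivative), applies a deterministic rule table to assign a
coordination/spin state from peak positions, and decomposes an observed
spectrum into nonnegative contributions of reference spectra (NNLS).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, signal

__all__ = [
    "Spectrum",
    "Band",
    "SpeciesState",
    "ReferenceSpectrum",
    "DeconvolutionResult",
    "default_grid",
    "build_reference",
    "second_derivative",
    "find_band_maxima",
    "classify_state",
    "deconvolve",
]

#: Soret window used for classification and Soret-peak searches (nm).
SORET_WINDOW = (380.0, 450.0)
#: Window holding the alpha/beta (visible) bands (nm).
VISIBLE_WINDOW = (500.0, 580.0)
#: Charge-transfer band window diagnostic of high-spin ferric heme (nm).
CT_WINDOW = (620.0, 650.0)

_FOUR_LN2 = 4.0 * np.log(2.0)


def default_grid(start: float = 350.0, stop: float = 700.0, step: float = 1.0) -> np.ndarray:
    """Default wavelength grid: 350-700 nm in 1-nm steps (covers the Soret,
    visible and charge-transfer regions of all species handled here)."""
    if step <= 0:
        raise ValueError("grid step must be > 0")
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


@dataclass(frozen=True)
class Spectrum:
    """An absorbance-vs-wavelength record.

    Parameters
    ----------
    wavelengths : array of nm, strictly increasing.
    absorbance : array of AU, same length, all finite.
    meta : optional metadata (``time_s``, ``ph``, ``label``).
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size:
            raise ValueError("wavelengths and absorbance must be 1-D arrays of equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance values must all be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def step(self) -> float:
        """Grid step (nm); raises if the grid is not uniform."""
        d = np.diff(self.wavelengths)
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            raise ValueError("spectrum grid is not uniform")
        return float(d[0])

    def with_meta(self, **meta) -> "Spectrum":
        merged = {**self.meta, **meta}
        return Spectrum(self.wavelengths, self.absorbance, merged)


@dataclass(frozen=True)
class Band:
    """A Gaussian absorption band.

    ``amplitude`` is a relative extinction on a mM^-1 cm^-1-like scale
    (band shapes are not calibrated against an extinction standard).
    """

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"band at {self.center} nm: fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"band at {self.center} nm: amplitude must be >= 0")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        """Evaluate amplitude * exp(-4 ln2 (lambda - center)^2 / fwhm^2)."""
        x = np.asarray(wavelengths, dtype=float)
        return self.amplitude * np.exp(-_FOUR_LN2 * (x - self.center) ** 2 / self.fwhm**2)


_OXIDATIONS = ("ferric", "ferrous")
_LIGATIONS = ("five-coordinate", "six-coordinate", "mixed", "indeterminate")
_SPINS = ("high", "low", "unknown")


@dataclass(frozen=True)
class SpeciesState:
    """Heme iron oxidation, coordination and spin assignment."""

    oxidation: str
    ligation: str
    spin: str = "unknown"
    sixth_ligand: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.oxidation not in _OXIDATIONS:
            raise ValueError(f"oxidation must be one of {_OXIDATIONS}")
        if self.ligation not in _LIGATIONS:
            raise ValueError(f"ligation must be one of {_LIGATIONS}")
        if self.spin not in _SPINS:
            raise ValueError(f"spin must be one of {_SPINS}")
        if self.ligation == "five-coordinate" and self.sixth_ligand is not None:
            raise ValueError("five-coordinate states have no sixth ligand")


@dataclass(frozen=True)
class ReferenceSpectrum:
    """A pure species' extinction profile rendered from Gaussian bands."""

    species_id: str
    bands: tuple[Band, ...]
    spectrum: Spectrum
    state: SpeciesState | None = None

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectrum.wavelengths

    @property
    def absorbance(self) -> np.ndarray:
        return self.spectrum.absorbance


@dataclass(frozen=True)
class DeconvolutionResult:
    """Nonnegative least-squares decomposition of a spectrum.

    ``coefficients`` are concentration-like weights in the inverse units
    of the reference amplitudes; ``fractions`` are molar fractions
    (coefficients normalised to unit sum); ``residual_norm`` is the
    2-norm of the unexplained absorbance (AU).
    """

    species_ids: tuple[str, ...]
    coefficients: np.ndarray
    fractions: np.ndarray
    residual_norm: float
    baseline: float | None = None

    def coefficient(self, species_id: str) -> float:
        return float(self.coefficients[self.species_ids.index(species_id)])

    def fraction(self, species_id: str) -> float:
        return float(self.fractions[self.species_ids.index(species_id)])


def build_reference(
    bands: Sequence[Band],
    grid: np.ndarray | None = None,
    *,
    species_id: str = "reference",
    state: SpeciesState | None = None,
) -> ReferenceSpectrum:
    """Render a reference spectrum as a sum of Gaussian bands on a grid.

    Every band center must lie inside the grid; an empty band list yields
    an all-zero spectrum.
    """
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if wl.ndim != 1 or wl.size < 2 or not np.all(np.diff(wl) > 0):
        raise ValueError("grid must be a strictly increasing 1-D array")
    total = np.zeros_like(wl)
    for band in bands:
        if not (wl[0] <= band.center <= wl[-1]):
            raise ValueError(
                f"band centered at {band.center} nm lies outside the grid "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        total += band.profile(wl)
    return ReferenceSpectrum(
        species_id=species_id,
        bands=tuple(bands),
        spectrum=Spectrum(wl, total, {"label": species_id}),
        state=state,
    )


def second_derivative(s: Spectrum, window: int = 11, polyorder: int = 3) -> Spectrum:
    """Second derivative d2A/dlambda2 by Savitzky-Golay smoothing.

    Band positions that appear only as shoulders in the absorbance show
    up as distinct local minima of the second derivative, which is how
    overlapping Soret components are resolved.
    """
    if window % 2 == 0:
        raise ValueError("window must be an odd point count")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if len(s) < window:
        raise ValueError(f"spectrum has {len(s)} points, shorter than window {window}")
    d2 = signal.savgol_filter(
        s.absorbance, window_length=window, polyorder=polyorder, deriv=2, delta=s.step
    )
    return Spectrum(s.wavelengths, d2, {**s.meta, "derivative_order": 2})


def find_band_maxima(
    s: Spectrum,
    region: tuple[float, float] | None = None,
    min_prominence: float | None = None,
) -> list[float]:
    """Wavelengths of local absorbance maxima in ``region``, ascending.

    ``min_prominence`` defaults to 1% of the maximum absorbance within
    the analysed region; an empty list is a valid result.
    """
    wl, ab = s.wavelengths, s.absorbance
    if region is not None:
        lo, hi = region
        if lo < wl[0] or hi > wl[-1]:
            raise ValueError(f"region {region} outside grid [{wl[0]}, {wl[-1]}]")
        mask = (wl >= lo) & (wl <= hi)
        wl, ab = wl[mask], ab[mask]
    if ab.size < 3:
        return []
    if min_prominence is None:
        top = float(np.max(ab))
        min_prominence = 0.01 * top if top > 0 else 0.0
    idx, _ = signal.find_peaks(ab, prominence=min_prominence)
    return [float(w) for w in wl[idx]]


def _in(window: tuple[float, float], values: Sequence[float]) -> list[float]:
    lo, hi = window
    return [v for v in values if lo <= v <= hi]


def classify_state(peaks: Sequence[float], oxidation: str) -> SpeciesState:
    """Assign coordination and spin from band peak positions.

    Deterministic rule table (peak positions in nm):

    ferric
      - Soret < 400 together with a 620-650 nm charge-transfer band:
        pentacoordinate high-spin (open sixth site).
      - any other pattern: mixed coordination, spin unresolved.

    ferrous
      - Soret in 418-428 only, with a resolved alpha/beta pair in
        520-570 nm whose beta band sits at <= 534 nm: hexacoordinate
        low-spin (endogenous sixth ligand).
      - Soret in 430-440 only: pentacoordinate high-spin.
      - Soret components in both windows: pentacoordinate high-spin if
        the visible pair has a deoxy-like beta band at >= 535 nm,
        otherwise a penta/hexa mixture.

    A spectrum with no Soret-window peak yields an ``indeterminate``
    result carrying a diagnostic note, not an exception.
    """
    if oxidation not in _OXIDATIONS:
        raise ValueError(f"oxidation must be one of {_OXIDATIONS}")
    peaks = sorted(float(p) for p in peaks)
    soret = _in(SORET_WINDOW, peaks)
    if not soret:
        return SpeciesState(
            oxidation,
            "indeterminate",
            "unknown",
            note=f"no peak in the Soret window {SORET_WINDOW}; peaks seen: {peaks}",
        )
    visible = _in(VISIBLE_WINDOW, peaks)
    pair = _in((520.0, 570.0), visible)

    if oxidation == "ferric":
        if min(soret) < 400.0 and _in(CT_WINDOW, peaks):
            return SpeciesState("ferric", "five-coordinate", "high")
        return SpeciesState(
            "ferric", "mixed", "unknown", note="no pentacoordinate ferric signature"
        )

    soret_hexa = _in((418.0, 428.0), soret)
    soret_penta = _in((430.0, 440.0), soret)
    if soret_hexa and not soret_penta:
        if len(pair) >= 2 and min(pair) <= 534.0:
            return SpeciesState("ferrous", "six-coordinate", "low", sixth_ligand="endogenous")
        return SpeciesState(
            "ferrous", "mixed", "unknown", note="hexa-like Soret without a low-spin alpha/beta pair"
        )
    if soret_penta and not soret_hexa:
        return SpeciesState("ferrous", "five-coordinate", "high")
    if soret_penta and soret_hexa:
        if len(pair) >= 2 and min(pair) >= 535.0:
            return SpeciesState("ferrous", "five-coordinate", "high")
        return SpeciesState(
            "ferrous", "mixed", "unknown", note="Soret components in both coordination windows"
        )
    return SpeciesState(
        "ferrous", "mixed", "unknown", note=f"Soret peak(s) {soret} outside the rule windows"
    )


def deconvolve(
    s: Spectrum,
    refs: Sequence[ReferenceSpectrum],
    *,
    fit_baseline: bool = False,
) -> DeconvolutionResult:
    """Decompose ``s`` into nonnegative contributions of reference spectra.

    Solves min ||A c - s||_2 subject to c >= 0 where the columns of A are
    the reference spectra (plus an optional constant-baseline column).
    Fractions are the coefficients normalised to unit sum; the baseline
    coefficient, when fitted, is excluded from the fractions.
    """
    if not refs:
        raise ValueError("at least one reference spectrum is required")
    for r in refs:
        if not np.array_equal(r.wavelengths, s.wavelengths):
            raise ValueError(
                f"reference '{r.species_id}' is rendered on a different wavelength grid"
            )
    cols = [r.absorbance for r in refs]
    if all(np.all(c == 0) for c in cols):
        raise ValueError("all reference spectra are identically zero")
    if fit_baseline:
        cols.append(np.ones_like(s.absorbance))
    a = np.column_stack(cols)
    coef, residual = optimize.nnls(a, s.absorbance)
    baseline = float(coef[-1]) if fit_baseline else None
    species_coef = coef[: len(refs)]
    total = species_coef.sum()
    fractions = species_coef / total if total > 0 else np.zeros_like(species_coef)
    return DeconvolutionResult(
        species_ids=tuple(r.species_id for r in refs),
        coefficients=species_coef,
        fractions=fractions,
        residual_norm=float(residual),
        baseline=baseline,
    )
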