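"""Fitting chain: spectra -> species time courses -> k_obs -> bimolecular
rate -> proton order; and pH titrations -> apparent pK.

The kinetic chain mirrors the standard spectrophotometric workflow for
globin nitrite-reductase assays: each timed spectrum is unmixed into
pure-species concentrations, the deoxy decay (or a single-wavelength
absorbance trace) is fit to a single exponential to obtain the observed
rate constant k_obs, k_obs is regressed on nitrite concentration to give
the bimolecular rate constant k2, and log10(k2) is regressed on -pH to
give the reaction order in [H+].

Titrations of the heme alkaline transition follow a single protonation
equilibrium: the protonated (acid) fraction is

    c_plus(pH) = 1 / (1 + 10^(n (pH - pK)))

and an absorbance-vs-pH series is fit as
A(pH) = a_alk + (a_acid - a_alk) * c_plus(pH; pK, n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .spectra import ReferenceSpectrum, Spectrum, deconvolve

__all__ = [
    "KineticFit",
    "BimolecularFit",
    "ProtonOrderFit",
    "TitrationSeries",
    "TitrationFit",
    "extract_timecourse",
    "fit_exponential",
    "fit_bimolecular",
    "fit_proton_order",
    "fraction_protonated",
    "normalize_titration",
    "fit_titration",
]

logger = logging.getLogger(__name__)

#: Absorbance scale: reference amplitudes are mM^-1 cm^-1-like, so a
#: concentration c (M) contributes c * 1e3 * epsilon(lambda) AU at 1 cm.
M_TO_MM = 1.0e3


@dataclass(frozen=True)
class KineticFit:
    """Single-exponential decay fit y = amplitude*exp(-k_obs*t) + offset."""

    k_obs: float
    amplitude: float
    offset: float
    se_k_obs: float
    r2: float

    def __post_init__(self) -> None:
        if self.k_obs <= 0:
            raise ValueError("k_obs must be > 0 on a successful fit")


@dataclass(frozen=True)
class BimolecularFit:
    """Linear fit k_obs = k2 * [nitrite] + intercept."""

    k2: float
    intercept: float
    se_k2: float
    r2: float

    def __post_init__(self) -> None:
        if self.k2 <= 0:
            raise ValueError("k2 must be > 0 on a successful fit")


@dataclass(frozen=True)
class ProtonOrderFit:
    """Order in [H+]: slope of log10(k2) versus -pH.

    The sign convention makes the slope positive when the rate increases
    with [H+]; a single-proton mechanism predicts slope = 1.
    """

    slope: float
    se_slope: float
    intercept: float


@dataclass(frozen=True)
class TitrationSeries:
    """Absorbance at a monitoring wavelength as a function of pH."""

    ph: np.ndarray
    absorbance: np.ndarray
    monitor_wavelength: float = 557.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if ph.ndim != 1 or ph.shape != ab.shape:
            raise ValueError("ph and absorbance must be 1-D arrays of equal length")
        if np.unique(ph).size != ph.size:
            raise ValueError("ph values must be distinct")
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return self.ph.size


@dataclass(frozen=True)
class TitrationFit:
    """Parameters of the single-transition titration model."""

    pk: float
    n: float
    a_acid: float
    a_alk: float
    se_pk: float
    se_n: float = float("nan")
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if self.a_acid == self.a_alk:
            raise ValueError("degenerate endpoints: a_acid == a_alk")


def extract_timecourse(
    spectra: list[Spectrum], refs: list[ReferenceSpectrum]
) -> pd.DataFrame:
    """Per-species concentration time courses by per-spectrum unmixing.

    Every spectrum must carry increasing ``time_s`` metadata and share
    the reference grid.  Returns a DataFrame indexed by time (s) with
    one column per reference species, in M (reference amplitudes are on
    the mM^-1 cm^-1-like scale), plus a ``residual_norm`` column.
    """
    if not spectra:
        raise ValueError("no spectra given")
    times = []
    for i, s in enumerate(spectra):
        if "time_s" not in s.meta:
            raise ValueError(f"spectrum {i} is missing 'time_s' metadata")
        times.append(float(s.meta["time_s"]))
    t = np.asarray(times)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("spectrum times must be strictly increasing")
    rows = []
    for s in spectra:
        res = deconvolve(s, refs)
        rows.append(list(res.coefficients / M_TO_MM) + [res.residual_norm])
    cols = [r.species_id for r in refs] + ["residual_norm"]
    return pd.DataFrame(rows, index=pd.Index(t, name="time_s"), columns=cols)


def _exp_model(t: np.ndarray, amplitude: float, k: float, offset: float) -> np.ndarray:
    return amplitude * np.exp(-k * t) + offset


def fit_exponential(times: np.ndarray, values: np.ndarray) -> KineticFit:
    """Fit y(t) = amplitude * exp(-k_obs t) + offset.

    Initialised from a log-linear regression of (y - y_inf) with y_inf
    estimated from the tail, then refined by nonlinear least squares.
    A constant series raises ("no decay detected").
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if t.size < 5:
        raise ValueError("at least 5 points are required for an exponential fit")
    span = float(np.max(y) - np.min(y))
    if span == 0.0 or span < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        raise ValueError("no decay detected: values are constant")

    n_tail = max(2, t.size // 10)
    offset0 = float(np.mean(y[-n_tail:]))
    amp0 = float(y[0] - offset0)
    if amp0 == 0.0:
        amp0 = span
    resid = (y - offset0) / amp0
    mask = resid > 1e-3
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
        k0 = max(-slope, 1e-12) if slope < 0 else 1.0 / max(t[-1], 1e-12)
    else:
        k0 = 1.0 / max(t[-1], 1e-12)

    try:
        popt, pcov = optimize.curve_fit(
            _exp_model, t, y, p0=[amp0, k0, offset0], maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    amplitude, k_obs, offset = popt
    if k_obs <= 0:
        raise ValueError(f"no decay detected: fitted rate {k_obs:.3g} s^-1 is not positive")
    fitted = _exp_model(t, *popt)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot)) if ss_tot > 0 else 0.0
    se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    return KineticFit(
        k_obs=float(k_obs), amplitude=float(amplitude), offset=float(offset),
        se_k_obs=se, r2=r2,
    )


def fit_bimolecular(nitrite: np.ndarray, k_obs: np.ndarray) -> BimolecularFit:
    """Ordinary least-squares line k_obs = k2*[NO2-] + intercept."""
    c = np.asarray(nitrite, dtype=float)
    k = np.asarray(k_obs, dtype=float)
    if c.ndim != 1 or c.shape != k.shape:
        raise ValueError("nitrite and k_obs must be 1-D arrays of equal length")
    if np.unique(c).size < 3:
        raise ValueError("at least 3 distinct nitrite concentrations are required")
    res = stats.linregress(c, k)
    r2 = float(res.rvalue**2)
    return BimolecularFit(
        k2=float(res.slope),
        intercept=float(res.intercept),
        se_k2=float(res.stderr),
        r2=r2,
    )


def fit_proton_order(ph: np.ndarray, k2: np.ndarray) -> ProtonOrderFit:
    """Order in [H+] from the slope of log10(k2) vs -pH."""
    p = np.asarray(ph, dtype=float)
    k = np.asarray(k2, dtype=float)
    if p.ndim != 1 or p.shape != k.shape:
        raise ValueError("ph and k2 must be 1-D arrays of equal length")
    if np.unique(p).size < 3:
        raise ValueError("at least 3 distinct pH points are required")
    if np.any(k <= 0):
        raise ValueError("all k2 values must be > 0")
    res = stats.linregress(-p, np.log10(k))
    return ProtonOrderFit(
        slope=float(res.slope), se_slope=float(res.stderr), intercept=float(res.intercept)
    )


def fraction_protonated(ph, pk: float, n: float = 1.0):
    """Protonated (acid) fraction c_plus = 1/(1 + 10^(n (pH - pK)))."""
    if n <= 0:
        raise ValueError("n must be > 0")
    ph = np.asarray(ph, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** (n * (ph - pk)))
    return float(out) if out.ndim == 0 else out


def normalize_titration(
    series: TitrationSeries, a_acid: float, a_alk: float
) -> np.ndarray:
    """Alkaline (deprotonated) molar fraction from raw absorbances.

    fraction_alkaline(pH) = (A - a_acid) / (a_alk - a_acid), clipped to
    [0, 1]; clipping is logged, not an error (it happens with noise).
    """
    if a_acid == a_alk:
        raise ValueError("degenerate endpoints: a_acid == a_alk")
    frac = (series.absorbance - a_acid) / (a_alk - a_acid)
    n_clip = int(np.sum((frac < 0) | (frac > 1)))
    if n_clip:
        logger.info("normalize_titration: clipped %d of %d points into [0, 1]",
                    n_clip, frac.size)
    return np.clip(frac, 0.0, 1.0)


def _titration_model(ph, a_acid, a_alk, pk, n):
    return a_alk + (a_acid - a_alk) / (1.0 + 10.0 ** (n * (ph - pk)))


def fit_titration(series: TitrationSeries, fix_n: float | None = None) -> TitrationFit:
    """Fit the single-transition model to an absorbance-vs-pH series.

    Endpoints a_acid and a_alk are co-fitted with pK (and n, unless
    ``fix_n`` pins the Hill-like coefficient).  Requires at least 4
    distinct pH points spanning >= 1 pH unit around the transition.
    """
    ph = series.ph
    ab = series.absorbance
    if np.unique(ph).size < 4:
        raise ValueError("at least 4 distinct pH points are required")
    if float(np.max(ph) - np.min(ph)) < 1.0:
        raise ValueError("transition not bracketed: pH range spans < 1 unit")

    order = np.argsort(ph)
    ph_s, ab_s = ph[order], ab[order]
    a_acid0, a_alk0 = float(ab_s[0]), float(ab_s[-1])
    if a_acid0 == a_alk0:
        a_alk0 += 1e-6
    mid = 0.5 * (a_acid0 + a_alk0)
    pk0 = float(ph_s[np.argmin(np.abs(ab_s - mid))])

    if fix_n is not None:
        if fix_n <= 0:
            raise ValueError("fix_n must be > 0")

        def model(x, a_acid, a_alk, pk):
            return _titration_model(x, a_acid, a_alk, pk, fix_n)

        p0 = [a_acid0, a_alk0, pk0]
    else:
        model = _titration_model
        p0 = [a_acid0, a_alk0, pk0, 1.0]

    try:
        popt, pcov = optimize.curve_fit(model, ph, ab, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"titration fit did not converge: {exc}") from exc
    a_acid, a_alk, pk = popt[0], popt[1], popt[2]
    n = fix_n if fix_n is not None else float(popt[3])
    if n < 0:  # sign-flipped solution: refit direction is ill-posed
        raise RuntimeError("titration fit returned n < 0; transition not resolved")
    fitted = model(ph, *popt)
    ss_res = float(np.sum((ab - fitted) ** 2))
    ss_tot = float(np.sum((ab - np.mean(ab)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    se_pk = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else float("nan")
    se_n = (
        float(np.sqrt(pcov[3, 3]))
        if fix_n is None and np.all(np.isfinite(pcov))
        else float("nan")
    )
    if not (np.min(ph) - 1.0 <= pk <= np.max(ph) + 1.0):
        raise RuntimeError(
            f"transition not bracketed: fitted pK {pk:.2f} lies outside the data range"
        )
    return TitrationFit(
        pk=float(pk), n=float(n), a_acid=float(a_acid), a_alk=float(a_alk),
        se_pk=se_pk, se_n=se_n, r2=r2,
    )
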