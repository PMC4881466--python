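"""Kinetic model of nitrite reduction by ferrous-deoxy heme.

Under anoxia, a deoxy (Fe2+) heme reduces nitrite to nitric oxide,

    Fe2+ + NO2- + H+  ->  Fe3+ + NO. + OH-        (nitrite reduction)
    Fe2+ + NO.        ->  Fe2+-NO                 (NO capture)

and excess dithionite recycles the ferric product back to the deoxy
form.  With nitrite in large excess over heme the first step is
pseudo-first-order with rate constant k1' = k_nir(pH) * [NO2-], and in
the fast-recycle limit the deoxy pool decays mono-exponentially with
k_obs = k1' while ferrous-nitrosyl accumulates 1:1.

The pH dependence of the bimolecular rate enters through the consumed
proton: k(pH) = k_ref * 10^(order * (ref_pH - pH)), i.e. the rate is
proportional to [H+]^order with order ~ 1 for a single-proton mechanism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MechanismParams",
    "KineticTrace",
    "effective_rate",
    "simulate_mechanism",
    "PseudoFirstOrderWarning",
]


class PseudoFirstOrderWarning(UserWarning):
    """Nitrite excess too small for the pseudo-first-order assumption."""


def effective_rate(k_ref: float, ref_ph: float, ph: float, proton_order: float) -> float:
    """Bimolecular nitrite-reduction rate at ``ph`` (M^-1 s^-1).

    ``k_ref`` is the rate at ``ref_ph``; the reaction consumes
    ``proton_order`` protons, so k scales as [H+]^order:
    k = k_ref * 10^(order * (ref_ph - ph)).
    """
    if not (0.0 < ph < 14.0):
        raise ValueError(f"ph must lie in (0, 14), got {ph}")
    return float(k_ref) * 10.0 ** (proton_order * (ref_ph - ph))


@dataclass(frozen=True)
class MechanismParams:
    """Rate constants and conditions for the nitrite-reduction mechanism.

    Attributes
    ----------
    k_nir : bimolecular nitrite-reduction rate at ``ref_ph`` (M^-1 s^-1).
    k_no_capture : deoxy + NO capture rate (M^-1 s^-1); fast, effectively
        instantaneous at micromolar heme.
    k_rered : pseudo-first-order ferric -> deoxy re-reduction rate (s^-1),
        standing in for excess dithionite.
    nitrite : nitrite concentration (M), held constant (excess).
    ph, ref_ph : working and reference pH.
    proton_order : order of the rate in [H+].
    """

    k_nir: float
    nitrite: float
    k_no_capture: float = 1.0e7
    k_rered: float = 1.0
    ph: float = 7.4
    ref_ph: float = 7.4
    proton_order: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_nir", "k_no_capture", "k_rered", "nitrite"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.ph < 14.0):
            raise ValueError("ph must lie in (0, 14)")
        if not (0.0 < self.ref_ph < 14.0):
            raise ValueError("ref_ph must lie in (0, 14)")

    @property
    def k1_prime(self) -> float:
        """Pseudo-first-order nitrite-reduction rate k_nir(pH)*[NO2-] (s^-1)."""
        return effective_rate(self.k_nir, self.ref_ph, self.ph, self.proton_order) * self.nitrite

    def at_ph(self, ph: float) -> "MechanismParams":
        return replace(self, ph=ph)


@dataclass(frozen=True)
class KineticTrace:
    """Time-resolved species concentrations (M) for one reaction."""

    times: np.ndarray
    conc_deoxy: np.ndarray
    conc_ferric: np.ndarray
    conc_nitrosyl: np.ndarray
    conc_no_free: np.ndarray
    total_heme: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        for name in ("conc_deoxy", "conc_ferric", "conc_nitrosyl", "conc_no_free"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != times.shape:
                raise ValueError(f"{name} must match the time grid shape")
            if np.any(arr < -1e-12):
                raise ValueError(f"{name} has negative concentrations")
            object.__setattr__(self, name, arr)
        heme_sum = self.conc_deoxy + self.conc_ferric + self.conc_nitrosyl
        if np.any(np.abs(heme_sum - self.total_heme) > 1e-9 * self.total_heme):
            raise ValueError("heme species do not sum to total_heme at every time point")

    def __len__(self) -> int:
        return self.times.size

    def species(self, name: str) -> np.ndarray:
        return {
            "deoxy": self.conc_deoxy,
            "ferric": self.conc_ferric,
            "nitrosyl": self.conc_nitrosyl,
            "no_free": self.conc_no_free,
        }[name]


def simulate_mechanism(
    p: MechanismParams, total_heme: float, times: np.ndarray
) -> KineticTrace:
    """Integrate the nitrite-reduction mechanism on a time grid.

    ODE system (k1' = k_nir(pH)*[NO2-], kc = k_no_capture, kr = k_rered)::

        d[deoxy]/dt    = -k1'[deoxy] - kc[deoxy][NO] + kr[ferric]
        d[ferric]/dt   =  k1'[deoxy] - kr[ferric]
        d[NO]/dt       =  k1'[deoxy] - kc[deoxy][NO]
        d[nitrosyl]/dt =  kc[deoxy][NO]

    Nitrite is held constant (pseudo-first-order excess); a warning is
    emitted when nitrite < 5x total heme and the assumption is shaky.
    Heme conservation deoxy + ferric + nitrosyl = total_heme is enforced
    structurally by integrating only (deoxy, ferric, NO).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D grid with at least two points")
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must increase strictly from 0")
    if total_heme <= 0:
        raise ValueError("total_heme must be > 0")
    if 0 < p.nitrite < 5.0 * total_heme:
        warnings.warn(
            f"nitrite ({p.nitrite:.3g} M) is less than 5x total heme "
            f"({total_heme:.3g} M); the pseudo-first-order assumption is weak",
            PseudoFirstOrderWarning,
            stacklevel=2,
        )

    k1 = p.k1_prime
    kc = p.k_no_capture
    kr = p.k_rered

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        deoxy, ferric, no = y
        capture = kc * deoxy * no
        return [
            -k1 * deoxy - capture + kr * ferric,
            k1 * deoxy - kr * ferric,
            k1 * deoxy - capture,
        ]

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        [total_heme, 0.0, 0.0],
        method="LSODA",
        t_eval=times,
        rtol=1e-8,
        atol=1e-12 * total_heme,
    )
    if not sol.success:
        raise RuntimeError(f"mechanism integration failed: {sol.message}")

    deoxy, ferric, no = sol.y
    # solver round-off can leave ~atol-scale negatives; clamp them
    deoxy = np.clip(deoxy, 0.0, None)
    ferric = np.clip(ferric, 0.0, None)
    no = np.clip(no, 0.0, None)
    nitrosyl = np.clip(total_heme - deoxy - ferric, 0.0, None)
    return KineticTrace(
        times=times,
        conc_deoxy=deoxy,
        conc_ferric=ferric,
        conc_nitrosyl=nitrosyl,
        conc_no_free=no,
        total_heme=total_heme,
    )
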