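"""CSV/JSON persistence for spectra, kinetic datasets, titrations and
fit reports.

Formats are deliberately plain: long-format CSVs for spectra
(``wavelength_nm, absorbance`` plus optional ``time_s``/``ph``/``label``),
a JSON manifest recording generator parameters and seeds as the
ground-truth record of a synthetic dataset, and JSON fit reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import TitrationSeries
from .mechanism import KineticTrace, MechanismParams
from .spectra import Spectrum
from .synthetic import KineticDataset

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_spectrum_series",
    "write_spectrum_series",
    "write_trace",
    "read_titration",
    "write_titration",
    "write_kinetic_dataset",
    "read_kinetic_dataset",
    "write_report",
]

MANIFEST_FORMAT = "hemekin-kinetic-dataset/1"


def _meta_columns(s: Spectrum) -> dict:
    return {k: s.meta[k] for k in ("time_s", "ph", "label") if k in s.meta}


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    df = pd.DataFrame({"wavelength_nm": s.wavelengths, "absorbance": s.absorbance})
    for k, v in _meta_columns(s).items():
        df[k] = v
    df.to_csv(path, index=False)


def read_spectrum(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty spectrum file")
    meta = {}
    for k in ("time_s", "ph", "label"):
        if k in df.columns:
            vals = df[k].unique()
            if len(vals) != 1:
                raise ValueError(f"{path}: column '{k}' is not constant; "
                                 "use read_spectrum_series for multi-spectrum files")
            meta[k] = vals[0].item() if hasattr(vals[0], "item") else vals[0]
    df = df.sort_values("wavelength_nm")
    return Spectrum(df["wavelength_nm"].to_numpy(), df["absorbance"].to_numpy(), meta)


def write_spectrum_series(spectra: list[Spectrum], path: str | Path) -> None:
    """Long-format CSV of a timed spectral series (``time_s`` required)."""
    frames = []
    for s in spectra:
        if "time_s" not in s.meta:
            raise ValueError("every spectrum in a series needs 'time_s' metadata")
        frames.append(
            pd.DataFrame({
                "time_s": s.meta["time_s"],
                "wavelength_nm": s.wavelengths,
                "absorbance": s.absorbance,
            })
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectrum_series(path: str | Path) -> list[Spectrum]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty series file")
    out = []
    for t, grp in df.groupby("time_s", sort=True):
        grp = grp.sort_values("wavelength_nm")
        out.append(Spectrum(grp["wavelength_nm"].to_numpy(),
                            grp["absorbance"].to_numpy(), {"time_s": float(t)}))
    return out


def write_trace(trace: KineticTrace, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": trace.times,
        "deoxy_M": trace.conc_deoxy,
        "ferric_M": trace.conc_ferric,
        "nitrosyl_M": trace.conc_nitrosyl,
        "no_free_M": trace.conc_no_free,
    }).to_csv(path, index=False)


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    pd.DataFrame({
        "ph": series.ph,
        "absorbance_au": series.absorbance,
        "monitor_wavelength_nm": series.monitor_wavelength,
    }).to_csv(path, index=False)


def read_titration(path: str | Path) -> TitrationSeries:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty titration file")
    monitor = float(df["monitor_wavelength_nm"].iloc[0]) if "monitor_wavelength_nm" in df else 557.0
    return TitrationSeries(df["ph"].to_numpy(), df["absorbance_au"].to_numpy(), monitor)


def _params_dict(p: MechanismParams) -> dict:
    return {
        "k_nir_M1s1": p.k_nir,
        "k_no_capture_M1s1": p.k_no_capture,
        "k_rered_s1": p.k_rered,
        "ph": p.ph,
        "ref_ph": p.ref_ph,
        "proton_order": p.proton_order,
    }


def write_kinetic_dataset(dataset: KineticDataset, out_dir: str | Path) -> Path:
    """Write a dataset as one CSV per series plus a JSON manifest.

    The manifest carries the generating parameters and per-series seeds,
    making it the ground-truth record for recovery tests.  Returns the
    manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(dataset.series):
        fname = f"series_{i:02d}.csv"
        write_spectrum_series(s.spectra, out / fname)
        entries.append({
            "index": i,
            "file": fname,
            "nitrite_M": s.nitrite,
            "seed": int(s.seed),
            "n_times": len(s.spectra),
        })
    manifest = {
        "format": MANIFEST_FORMAT,
        "seed": int(dataset.seed),
        "sigma_au": dataset.sigma,
        "total_heme_M": dataset.total_heme,
        "truth": _params_dict(dataset.params),
        "references": dataset.reference_ids,
        "series": entries,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return mpath


def read_kinetic_dataset(dataset_dir: str | Path) -> tuple[dict, list[dict]]:
    """Read a dataset manifest and its series (as spectrum lists).

    Returns ``(manifest, series)`` where each series dict has keys
    ``nitrite_M`` and ``spectra``.
    """
    d = Path(dataset_dir)
    mpath = d / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json in {d}")
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed manifest {mpath}: {exc}") from exc
    if manifest.get("format") != MANIFEST_FORMAT:
        raise ValueError(f"unrecognised dataset format: {manifest.get('format')!r}")
    series = []
    for entry in manifest["series"]:
        spectra = read_spectrum_series(d / entry["file"])
        series.append({"nitrite_M": float(entry["nitrite_M"]), "spectra": spectra})
    return manifest, series


def write_report(report: dict, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=_default) + "\n")
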