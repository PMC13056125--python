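"""CSV/JSON readers and writers for the package's data streams.

Formats (all plain text, header rows included):

* force curves      displacement_nm,force_pN  + JSON sidecar (mode,
                    condition, baseline window, metadata)
* spectra           wavelength_nm,value
* platelet tracks   t_s,x_um,y_um,theta_deg   + JSON sidecar (radius_um,
                    group, id)
* device series     t_min,pressure_mmHg  /  t_min,act_s
* efficiency maps   long format row,col,efficiency
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .device import PressureSeries
from .force_spectroscopy import ForceCurve
from .fret import Spectrum
from .kinematics import TrackedPlatelet


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_curve(curve: ForceCurve, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"displacement_nm": curve.displacement,
                  "force_pN": curve.force}).to_csv(path, index=False)
    meta = {"mode": curve.mode, "condition": curve.condition,
            "baseline_window": list(curve.baseline_window),
            "metadata": _jsonable(curve.metadata)}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_curve(path: str | Path) -> ForceCurve:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = _sidecar(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ForceCurve(
        displacement=df["displacement_nm"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        mode=meta.get("mode", "tangential"),
        condition=meta.get("condition", ""),
        baseline_window=tuple(meta.get("baseline_window", (0, 64))),
        metadata=meta.get("metadata", {}),
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"wavelength_nm": spectrum.wavelength,
                  "value": spectrum.value}).to_csv(path, index=False)


def read_spectrum(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df["wavelength_nm"].to_numpy(), df["value"].to_numpy())


def write_track(track: TrackedPlatelet, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"t_s": track.t, "x_um": track.x, "y_um": track.y,
                  "theta_deg": track.orientation}).to_csv(path, index=False)
    meta = {"radius_um": track.radius, "group": track.group, "id": track.id}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_track(path: str | Path) -> TrackedPlatelet:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = _sidecar(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TrackedPlatelet(
        t=df["t_s"].to_numpy(), x=df["x_um"].to_numpy(),
        y=df["y_um"].to_numpy(), orientation=df["theta_deg"].to_numpy(),
        radius=meta.get("radius_um", 1.25),
        group=meta.get("group", ""), id=meta.get("id", ""),
    )


def write_pressure(series: PressureSeries, path: str | Path) -> None:
    pd.DataFrame({"t_min": series.t,
                  "pressure_mmHg": series.pressure}).to_csv(path, index=False)


def read_pressure(path: str | Path, baseline: float = 50.0) -> PressureSeries:
    df = pd.read_csv(path)
    return PressureSeries(t=df["t_min"].to_numpy(),
                          pressure=df["pressure_mmHg"].to_numpy(),
                          baseline=baseline)


def write_act(t_min: np.ndarray, act_s: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"t_min": t_min, "act_s": act_s}).to_csv(path, index=False)


def read_act(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return list(zip(df["t_min"].astype(float), df["act_s"].astype(float)))


def write_map(eff_map: np.ndarray, path: str | Path) -> None:
    rows, cols = np.nonzero(np.isfinite(eff_map))
    pd.DataFrame({"row": rows, "col": cols,
                  "efficiency": eff_map[rows, cols]}).to_csv(path, index=False)


def read_map(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    shape = (int(df["row"].max()) + 1, int(df["col"].max()) + 1)
    out = np.full(shape, np.nan)
    out[df["row"].to_numpy(int), df["col"].to_numpy(int)] = df["efficiency"]
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)
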