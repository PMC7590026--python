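"""CSV readers/writers with unit-bearing column names.

Internal computation is SI throughout; units are declared in the column
headers and converted on load/save. Recognized dialects:

* magnetization: ``H_A_per_m`` (or ``H_kA_per_m``), ``M_Am2_per_kg``
* heating: ``t_s``, ``T_C``
* sar: ``H_A_per_m`` (or ``H_kA_per_m``), ``SAR_W_per_kg``
  (or ``SAR_W_per_g`` / ``SAR_kW_per_kg``)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calorimetry import HeatingCurve
from .magnetometry import MagnetizationCurve
from .sarfit import SarCurve

__all__ = ["read_curve_csv", "write_curve_csv"]

_FIELD_UNITS = {"H_A_per_m": 1.0, "H_kA_per_m": 1e3}
_SAR_UNITS = {"SAR_W_per_kg": 1.0, "SAR_W_per_g": 1e3, "SAR_kW_per_kg": 1e3}


def _pick(df: pd.DataFrame, units: dict[str, float], what: str) -> np.ndarray:
    found = [c for c in df.columns if c in units]
    if not found:
        raise ValueError(
            f"no {what} column found; expected one of {sorted(units)} "
            f"(got {list(df.columns)})")
    if len(found) > 1:
        raise ValueError(f"ambiguous {what} columns {found}")
    col = found[0]
    return df[col].to_numpy(dtype=float) * units[col]


def read_curve_csv(path, kind: str, **kwargs):
    """Load a typed curve from CSV.

    kind is 'magnetization', 'heating' or 'sar'; extra keyword arguments
    (temperature, sample masses, condition, ...) feed the constructed
    object.
    """
    df = pd.read_csv(path)
    if kind == "magnetization":
        H = _pick(df, _FIELD_UNITS, "field")
        if "M_Am2_per_kg" not in df.columns:
            raise ValueError("missing magnetization column 'M_Am2_per_kg'")
        return MagnetizationCurve(H=H, M=df["M_Am2_per_kg"].to_numpy(float),
                                  T=kwargs.get("T", 300.0))
    if kind == "heating":
        for col in ("t_s", "T_C"):
            if col not in df.columns:
                raise ValueError(f"missing column '{col}'")
        return HeatingCurve(t=df["t_s"].to_numpy(float),
                            T=df["T_C"].to_numpy(float), **kwargs)
    if kind == "sar":
        H = _pick(df, _FIELD_UNITS, "field")
        sar = _pick(df, _SAR_UNITS, "SAR")
        return SarCurve(H=H, SAR=sar, **kwargs)
    raise ValueError(f"unknown curve kind {kind!r}")


def write_curve_csv(curve, path) -> Path:
    """Write a curve in its canonical SI dialect (12 significant digits)."""
    path = Path(path)
    if isinstance(curve, MagnetizationCurve):
        df = pd.DataFrame({"H_A_per_m": curve.H, "M_Am2_per_kg": curve.M})
    elif isinstance(curve, HeatingCurve):
        df = pd.DataFrame({"t_s": curve.t, "T_C": curve.T})
    elif isinstance(curve, SarCurve):
        df = pd.DataFrame({"H_A_per_m": curve.H, "SAR_W_per_kg": curve.SAR})
    else:
        raise TypeError(f"cannot serialize {type(curve).__name__}")
    df.to_csv(path, index=False, float_format="%.12g")
    return path
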