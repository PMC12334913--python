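"""Kinetic parameter sets for the shipped hERG gating models.

Parameters are stored on their natural scale (ms^-1 for rate prefactors,
mV^-1 for voltage slopes, uS for conductance).  The published tables print
values against a power-of-ten scale factor; the readers/writers here apply
those factors exactly so a round trip through the delimited-text format is
lossless at the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "KineticParameters",
    "ParameterRanges",
    "beattie_default_parameters",
    "wang_default_parameters",
    "beattie_default_ranges",
    "wang_default_ranges",
    "read_parameters",
    "write_parameters",
]


@dataclass(frozen=True)
class KineticParameters:
    """An ordered, strictly positive kinetic parameter vector plus conductance.

    Attributes
    ----------
    values : ndarray
        Kinetic parameters on natural scale.  Rate prefactors are in ms^-1
        and voltage slopes in mV^-1.
    conductance : float
        Maximal conductance g in uS.
    names : tuple of str
        Labels aligned with ``values``.
    """

    values: np.ndarray
    conductance: float
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("parameter values must be a 1-d vector")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("all kinetic parameters must be finite and > 0")
        if not (np.isfinite(self.conductance) and self.conductance > 0):
            raise ValueError("conductance must be finite and > 0")
        if len(self.names) != values.size:
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def with_values(self, values: np.ndarray, conductance: float | None = None) -> "KineticParameters":
        """Return a copy with replaced values (and optionally conductance)."""
        g = self.conductance if conductance is None else conductance
        return KineticParameters(np.asarray(values, dtype=float), g, self.names)


@dataclass(frozen=True)
class ParameterRanges:
    """Elementwise lower/upper bounds aligned with a KineticParameters vector."""

    lower: np.ndarray
    upper: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower and upper must be 1-d vectors of equal length")
        if np.any(lower <= 0) or np.any(upper <= 0):
            raise ValueError("bounds must be strictly positive")
        if np.any(lower > upper):
            raise ValueError("lower bounds must not exceed upper bounds")
        if len(self.names) != lower.size:
            raise ValueError("names and bounds must have equal length")

    def __len__(self) -> int:
        return self.lower.size

    def contains(self, values: np.ndarray) -> bool:
        v = np.asarray(values, dtype=float)
        return bool(np.all(v >= self.lower) and np.all(v <= self.upper))


# Published room-temperature defaults.  Tuples are (name, printed value,
# printed lower, printed upper, scale factor, unit).  Conductance has no
# fitted range.
_BEATTIE_TABLE = [
    ("p1", 1.68, 1.39, 12.9, 1e-4, "ms^-1"),
    ("p2", 8.06, 1.08, 8.49, 1e-2, "mV^-1"),
    ("p3", 4.34, 2.77, 32.3, 1e-5, "ms^-1"),
    ("p4", 4.07, 2.48, 4.56, 1e-2, "mV^-1"),
    ("p5", 9.07, 6.40, 19.9, 1e-2, "ms^-1"),
    ("p6", 2.67, 2.18, 3.87, 1e-2, "mV^-1"),
    ("p7", 7.32, 7.07, 10.9, 1e-3, "ms^-1"),
    ("p8", 3.22, 2.89, 3.39, 1e-2, "mV^-1"),
]
_BEATTIE_G = (2.44, 1e-1)  # printed value, scale -> uS

_WANG_TABLE = [
    ("kb", 0.67, 0.67, 99993.0, 1e-2, "ms^-1"),
    ("kf", 1.31, 1.31, 99550.0, 1e-2, "ms^-1"),
    ("q1", 1.24, 1.24, 1.81, 1e-1, "ms^-1"),
    ("q2", 1.56, 1.55, 2.06, 1e-2, "mV^-1"),
    ("q3", 0.04, 0.03, 1.02, 1e-2, "ms^-1"),
    ("q4", 10.9, 0.0001, 10.9, 1e-2, "mV^-1"),
    ("q5", 0.24, 0.23, 364.0, 1e-2, "ms^-1"),
    ("q6", 0.0001, 0.0001, 6.44, 1e-2, "mV^-1"),
    ("q7", 3.15, 1.29, 7.69, 1e-4, "ms^-1"),
    ("q8", 3.99, 2.97, 3.99, 1e-2, "mV^-1"),
    ("q9", 5.75, 3.55, 5.75, 1e-3, "ms^-1"),
    ("q10", 2.89, 2.89, 3.34, 1e-2, "mV^-1"),
    ("q11", 0.28, 0.007, 1458.0, 1e-2, "ms^-1"),
    ("q12", 10.7, 1.16, 11.8, 1e-2, "mV^-1"),
]
_WANG_G = (2.11, 1e-1)


def _defaults(table, g_entry) -> KineticParameters:
    names = tuple(row[0] for row in table)
    values = np.array([row[1] * row[4] for row in table])
    return KineticParameters(values, g_entry[0] * g_entry[1], names)


def _ranges(table) -> ParameterRanges:
    names = tuple(row[0] for row in table)
    lower = np.array([row[2] * row[4] for row in table])
    upper = np.array([row[3] * row[4] for row in table])
    return ParameterRanges(lower, upper, names)


def beattie_default_parameters() -> KineticParameters:
    """Default room-temperature parameters of the 4-state model (p1..p8, g)."""
    return _defaults(_BEATTIE_TABLE, _BEATTIE_G)


def wang_default_parameters() -> KineticParameters:
    """Default room-temperature parameters of the 5-state model (kb, kf, q1..q12, g)."""
    return _defaults(_WANG_TABLE, _WANG_G)


def beattie_default_ranges() -> ParameterRanges:
    """Fitted-range bounds for the 4-state model kinetic parameters."""
    return _ranges(_BEATTIE_TABLE)


def wang_default_ranges() -> ParameterRanges:
    """Fitted-range bounds for the 5-state model kinetic parameters."""
    return _ranges(_WANG_TABLE)


_UNITS = {"beattie": dict((r[0], r[5]) for r in _BEATTIE_TABLE),
          "wang": dict((r[0], r[5]) for r in _WANG_TABLE)}


def write_parameters(params: KineticParameters, path: str | Path,
                     ranges: ParameterRanges | None = None) -> None:
    """Write a parameter set (and optional ranges) as delimited text.

    Columns: name, value, unit, lower, upper.  Values are written on natural
    scale with full precision; conductance is stored under name ``g`` in uS.
    """
    rows = []
    units = {}
    for model_units in _UNITS.values():
        units.update(model_units)
    for i, name in enumerate(params.names):
        rows.append({
            "name": name,
            "value": params.values[i],
            "unit": units.get(name, ""),
            "lower": ranges.lower[i] if ranges is not None else np.nan,
            "upper": ranges.upper[i] if ranges is not None else np.nan,
        })
    rows.append({"name": "g", "value": params.conductance, "unit": "uS",
                 "lower": np.nan, "upper": np.nan})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_parameters(path: str | Path) -> tuple[KineticParameters, ParameterRanges | None]:
    """Read a parameter file written by :func:`write_parameters`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"name", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"parameter file {path} must have columns {sorted(required)}")
    g_rows = df[df["name"] == "g"]
    if len(g_rows) != 1:
        raise ValueError("parameter file must contain exactly one 'g' row")
    kin = df[df["name"] != "g"]
    params = KineticParameters(kin["value"].to_numpy(float),
                               float(g_rows["value"].iloc[0]),
                               tuple(kin["name"]))
    ranges = None
    if "lower" in df.columns and kin["lower"].notna().all():
        ranges = ParameterRanges(kin["lower"].to_numpy(float),
                                 kin["upper"].to_numpy(float),
                                 tuple(kin["name"]))
    return params, ranges
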