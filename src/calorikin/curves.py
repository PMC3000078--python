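"""Temperature-scan heat-capacity curves and probe traces.

Containers and I/O for the raw inputs of a constant-rate DSC experiment:
the thermogram (heat capacity vs. temperature at heating rate ``nu``),
the excess-heat-capacity curve obtained after baseline subtraction, and
the auxiliary probe traces (isothermal DLS radius growth, fluorescence
channel pairs, residual-activity time courses).

Curves are stored on their native, possibly non-uniform grid; all
integrals are trapezoidal on that grid.  Temperatures are kept in kelvin
internally (the Arrhenius law needs absolute temperature); files may
declare Celsius and are converted on read.

File format: plain CSV, ``#`` comment lines, columns
``abscissa, ordinate[, ordinate2]``.  No community standard exists for
DSC exports, so the dialect is deliberately minimal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

__all__ = [
    "Thermogram",
    "ExcessCurve",
    "ProbeTrace",
    "read_curve",
    "write_curve",
    "subtract_background",
    "compute_excess",
    "apply_time_response_correction",
]

CELSIUS_OFFSET = 273.15
MIN_GRID_POINTS = 16


class CurveValidationError(ValueError):
    """Raised when a curve violates its structural invariants."""


class CurveParseError(ValueError):
    """Raised when a curve file cannot be parsed."""


def _check_strictly_increasing(x: np.ndarray, name: str) -> None:
    if np.any(np.diff(x) <= 0):
        raise CurveValidationError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class Thermogram:
    """A constant-rate DSC scan.

    Parameters
    ----------
    temperature : array, kelvin, strictly increasing, >= 16 points
    heat_capacity : array, kJ/(mol K), same length, finite
    heating_rate : scan rate nu in K/min, > 0
    annealing_history : optional ``(T_ann [K], t_ann [min])`` pre-incubation
    label : free-text description
    metadata : processing provenance (e.g. background-subtraction mode)
    """

    temperature: np.ndarray
    heat_capacity: np.ndarray
    heating_rate: float = 1.0
    annealing_history: tuple[float, float] | None = None
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature, dtype=float)
        cp = np.asarray(self.heat_capacity, dtype=float)
        object.__setattr__(self, "temperature", T)
        object.__setattr__(self, "heat_capacity", cp)
        if T.ndim != 1 or cp.shape != T.shape:
            raise CurveValidationError("temperature and heat_capacity must be 1-D and equal length")
        if T.size < MIN_GRID_POINTS:
            raise CurveValidationError(f"grid must have at least {MIN_GRID_POINTS} points, got {T.size}")
        _check_strictly_increasing(T, "temperature")
        if not np.all(np.isfinite(cp)):
            raise CurveValidationError("heat_capacity must be finite everywhere")
        if not self.heating_rate > 0:
            raise CurveValidationError("heating_rate must be positive")

    def replace(self, **kw) -> "Thermogram":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ExcessCurve:
    """Excess heat capacity C_p^ex(T) with its cumulative heat Q^ex(T).

    ``total_enthalpy`` is the trapezoidal area under C_p^ex over the grid,
    i.e. the calorimetric enthalpy of the transition(s) [kJ/mol].  Small
    negative C_p^ex excursions from noise are tolerated and flagged via
    ``has_negative_dips``.
    """

    temperature: np.ndarray
    excess_heat_capacity: np.ndarray
    heating_rate: float = 1.0
    label: str = ""
    negative_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature, dtype=float)
        cp = np.asarray(self.excess_heat_capacity, dtype=float)
        object.__setattr__(self, "temperature", T)
        object.__setattr__(self, "excess_heat_capacity", cp)
        if T.ndim != 1 or cp.shape != T.shape:
            raise CurveValidationError("grid and C_p^ex must be 1-D and equal length")
        _check_strictly_increasing(T, "temperature")
        if not np.all(np.isfinite(cp)):
            raise CurveValidationError("C_p^ex must be finite everywhere")

    @property
    def cumulative_heat(self) -> np.ndarray:
        """Q^ex(T): heat absorbed up to T, trapezoidal [kJ/mol]."""
        return cumulative_trapezoid(self.excess_heat_capacity, self.temperature, initial=0.0)

    @property
    def total_enthalpy(self) -> float:
        """Total transition enthalpy, the area under C_p^ex [kJ/mol]."""
        return float(trapezoid(self.excess_heat_capacity, self.temperature))

    @property
    def has_negative_dips(self) -> bool:
        tol = self.negative_tolerance * max(1.0, float(np.max(np.abs(self.excess_heat_capacity), initial=0.0)))
        return bool(np.any(self.excess_heat_capacity < -tol))

    def remaining_heat(self) -> np.ndarray:
        """Integral of C_p^ex from T to the end of the grid [kJ/mol]."""
        q = self.cumulative_heat
        return q[-1] - q


@dataclass(frozen=True)
class ProbeTrace:
    """A non-calorimetric probe trace.

    ``abscissa`` is time [min] for isothermal traces or temperature [K]
    for scans; ``ordinate`` holds R_h [nm], an activity fraction, or the
    I320 fluorescence channel; ``ordinate2`` holds I365 when present.
    ``hold_temperature`` is the incubation temperature of isothermal
    traces [K].
    """

    abscissa: np.ndarray
    ordinate: np.ndarray
    ordinate2: np.ndarray | None = None
    hold_temperature: float | None = None
    kind: str = "generic"
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.abscissa, dtype=float)
        y = np.asarray(self.ordinate, dtype=float)
        object.__setattr__(self, "abscissa", x)
        object.__setattr__(self, "ordinate", y)
        if x.ndim != 1 or y.shape != x.shape:
            raise CurveValidationError("abscissa and ordinate must be 1-D and equal length")
        _check_strictly_increasing(x, "abscissa")
        if not np.all(np.isfinite(y)):
            raise CurveValidationError("ordinate must be finite everywhere")
        if self.ordinate2 is not None:
            y2 = np.asarray(self.ordinate2, dtype=float)
            object.__setattr__(self, "ordinate2", y2)
            if y2.shape != x.shape:
                raise CurveValidationError("both channels must have the same length")
            if not np.all(np.isfinite(y2)):
                raise CurveValidationError("second ordinate must be finite everywhere")


def read_curve(path, *, kind: str = "thermogram", temperature_unit: str = "K",
               heating_rate: float = 1.0, hold_temperature: float | None = None,
               label: str = ""):
    """Read a two- or three-column CSV curve.

    Parameters
    ----------
    kind : ``"thermogram"`` or ``"probe"``
    temperature_unit : ``"K"`` or ``"C"``; Celsius abscissae are converted
        to kelvin (T[K] = T[degC] + 273.15).  Ignored for time-abscissa
        probe traces (pass ``"K"``).

    Rows are sorted by abscissa; duplicate abscissa values are rejected.
    Header comments of the form ``# key: value`` may declare
    ``temperature_unit``, ``heating_rate`` and ``label``, overriding the
    keyword defaults.
    """
    rows: list[list[float]] = []
    meta: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = [p for p in line.replace("\t", ",").split(",") if p.strip() != ""]
            if len(parts) not in (2, 3):
                raise CurveParseError(f"{path}: line {lineno}: expected 2 or 3 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise CurveParseError(f"{path}: line {lineno}: malformed number ({exc})") from None
    if not rows:
        raise CurveParseError(f"{path}: no data rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise CurveParseError(f"{path}: inconsistent column count")
    data = np.asarray(rows, dtype=float)
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    if np.any(np.diff(data[:, 0]) == 0):
        raise CurveValidationError(f"{path}: duplicated abscissa values")

    unit = meta.get("temperature_unit", temperature_unit)
    rate = float(meta.get("heating_rate", heating_rate))
    label = meta.get("label", label)
    x = data[:, 0]
    if unit.upper().startswith("C"):
        x = x + CELSIUS_OFFSET
    elif not unit.upper().startswith("K"):
        raise CurveParseError(f"unknown temperature unit {unit!r}")

    if kind == "thermogram":
        if ncol != 2:
            raise CurveParseError(f"{path}: thermogram files must have exactly 2 columns")
        return Thermogram(x, data[:, 1], heating_rate=rate, label=label)
    if kind == "probe":
        y2 = data[:, 2] if ncol == 3 else None
        return ProbeTrace(x, data[:, 1], ordinate2=y2, hold_temperature=hold_temperature, label=label)
    raise ValueError(f"unknown curve kind {kind!r}")


def write_curve(path, curve, *, comments: dict | None = None) -> None:
    """Write a curve as CSV with ``# key: value`` header comments."""
    header = dict(comments or {})
    if isinstance(curve, Thermogram):
        header.setdefault("temperature_unit", "K")
        header.setdefault("heating_rate", repr(curve.heating_rate))
        if curve.label:
            header.setdefault("label", curve.label)
        cols = [curve.temperature, curve.heat_capacity]
    elif isinstance(curve, ExcessCurve):
        header.setdefault("temperature_unit", "K")
        header.setdefault("heating_rate", repr(curve.heating_rate))
        cols = [curve.temperature, curve.excess_heat_capacity]
    elif isinstance(curve, ProbeTrace):
        cols = [curve.abscissa, curve.ordinate]
        if curve.ordinate2 is not None:
            cols.append(curve.ordinate2)
    else:
        raise TypeError(f"cannot write object of type {type(curve).__name__}")
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        for row in zip(*cols):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def apply_time_response_correction(curve: Thermogram, correction) -> Thermogram:
    """Apply a user-supplied instrument time-response correction.

    Deconvolution of the calorimeter's finite response time is
    instrument specific, so no default is shipped: ``correction`` is any
    callable mapping a :class:`Thermogram` to a :class:`Thermogram` on
    the same grid.  The hook validates the result and records the
    correction in the metadata.
    """
    out = correction(curve)
    if not isinstance(out, Thermogram):
        raise TypeError("correction must return a Thermogram")
    if out.temperature.shape != curve.temperature.shape or np.any(
            np.abs(out.temperature - curve.temperature) > 1e-9):
        raise CurveValidationError("correction must preserve the temperature grid")
    meta = dict(out.metadata)
    meta["time_response_corrected"] = getattr(correction, "__name__", repr(correction))
    return out.replace(metadata=meta)


def subtract_background(sample: Thermogram, inverted: Thermogram,
                        *, mode: str = "half-difference") -> Thermogram:
    """Instrumental-background correction from an inverted-cell rescan.

    The instrument is run twice: normally (protein in the sample cell)
    and inverted (the same protein in the reference cell), so the protein
    signal flips sign between the two records while the instrumental
    drift does not.  Subtracting the inverted curve cancels the drift.

    ``mode="half-difference"`` (default) returns ``(sample - inverted)/2``,
    which recovers the signal at its original amplitude when the two runs
    carry ``+signal + drift`` and ``-signal + drift``.  ``mode="difference"``
    returns the plain difference.  The primary description of the
    procedure does not state the factor of two, so both conventions are
    exposed and the applied mode is recorded in the result metadata.

    The inverted curve is linearly interpolated onto the sample grid; the
    grids must overlap over the sample's full range.
    """
    if mode not in ("half-difference", "difference"):
        raise ValueError(f"unknown mode {mode!r}")
    Ts, Ti = sample.temperature, inverted.temperature
    if Ts[0] < Ti[0] - 1e-9 or Ts[-1] > Ti[-1] + 1e-9:
        raise CurveValidationError("inverted curve does not cover the sample temperature range")
    inv = np.interp(Ts, Ti, inverted.heat_capacity)
    diff = sample.heat_capacity - inv
    if mode == "half-difference":
        diff = diff / 2.0
    meta = dict(sample.metadata)
    meta["background_subtraction_mode"] = mode
    return sample.replace(heat_capacity=diff, metadata=meta)


def compute_excess(curve: Thermogram, baseline: np.ndarray,
                   *, window: tuple[float, float] | None = None) -> ExcessCurve:
    """Subtract a baseline and integrate to the excess-heat-capacity curve.

    ``baseline`` is the chemical (or any other) baseline evaluated on the
    curve's grid.  ``window`` optionally restricts the analysis to a
    temperature interval; it must lie inside the grid.
    """
    T = curve.temperature
    base = np.asarray(baseline, dtype=float)
    if base.shape != T.shape:
        raise CurveValidationError("baseline must be evaluated on the curve's grid")
    if window is not None:
        lo, hi = window
        if lo < T[0] - 1e-9 or hi > T[-1] + 1e-9:
            raise CurveValidationError("analysis window outside the temperature grid")
        mask = (T >= lo) & (T <= hi)
        if mask.sum() < 2:
            raise CurveValidationError("analysis window contains fewer than 2 grid points")
        T = T[mask]
        ex = curve.heat_capacity[mask] - base[mask]
    else:
        ex = curve.heat_capacity - base
    return ExcessCurve(T, ex, heating_rate=curve.heating_rate, label=curve.label)
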