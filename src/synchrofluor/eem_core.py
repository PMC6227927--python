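"""Spectral containers and the synchronous-scan signal chain.

A synchronous fluorescence spectrum is obtained by scanning excitation and
emission monochromators together at a constant offset ``delta_lambda``
(emission minus excitation, in nm).  This module models the raw
excitation-emission matrix (EEM), the 1-D synchronous trace extracted from it,
and the smoothed first-derivative trace whose amplitude at a chosen wavelength
is the analytical signal of a zero-crossing assay.

All intensities are in arbitrary units (a.u.); derivative amplitudes are in
a.u. per nm.  The wavelength axis follows the excitation convention: a
synchronous spectrum point at wavelength ``lam`` is the EEM intensity at
excitation ``lam`` and emission ``lam + delta_lambda``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "SpectraError",
    "DomainError",
    "ValidationError",
    "EdgeProximityWarning",
    "WavelengthGrid",
    "ExcitationEmissionMatrix",
    "SynchronousSpectrum",
    "DerivativeSpectrum",
    "extract_synchronous",
    "subtract_blank",
    "smooth",
    "first_derivative",
    "amplitude_at",
    "grid_from_values",
    "read_eem_csv",
    "write_eem_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "DEFAULT_DELTA_LAMBDA",
    "DEFAULT_SMOOTHING_WINDOW",
]

#: Constant-offset default for synchronous scans (nm).
DEFAULT_DELTA_LAMBDA = 20.0
#: Default odd window length (points) of the quadratic smoothing/derivative filter.
DEFAULT_SMOOTHING_WINDOW = 15

# Fractional-index slack used to snap interpolation requests onto grid nodes,
# so node-aligned extraction reproduces stored matrix values bitwise.
_NODE_SNAP = 1e-9


class SpectraError(ValueError):
    """Base class for spectral-data errors."""


class DomainError(SpectraError):
    """A wavelength request falls outside the data's spectral domain."""


class ValidationError(SpectraError):
    """Structurally invalid spectral data or parameters."""


class EdgeProximityWarning(UserWarning):
    """A readout wavelength sits within half a filter window of the axis edge,
    where the derivative relies on polynomial extension."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, strictly increasing wavelength axis in nm."""

    start: float
    stop: float
    step: float = 1.0

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise ValidationError(f"grid step must be > 0, got {self.step}")
        if not (self.stop > self.start):
            raise ValidationError(
                f"grid stop ({self.stop}) must exceed start ({self.start})"
            )

    @property
    def n(self) -> int:
        return int(math.floor((self.stop - self.start) / self.step + _NODE_SNAP)) + 1

    @property
    def values(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n, dtype=float)

    @property
    def span(self) -> tuple[float, float]:
        return (self.start, self.start + self.step * (self.n - 1))

    def contains(self, wavelength: float) -> bool:
        lo, hi = self.span
        slack = _NODE_SNAP * self.step
        return lo - slack <= wavelength <= hi + slack


@dataclass
class ExcitationEmissionMatrix:
    """2-D fluorescence intensity over excitation (rows) x emission (cols)."""

    excitation: WavelengthGrid
    emission: WavelengthGrid
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        expected = (self.excitation.n, self.emission.n)
        if self.intensity.shape != expected:
            raise ValidationError(
                f"intensity shape {self.intensity.shape} does not match grids {expected}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("EEM intensities must all be finite")


@dataclass
class SynchronousSpectrum:
    """1-D synchronous trace at constant delta_lambda (excitation-axis convention)."""

    delta_lambda: float
    axis: WavelengthGrid
    intensity: np.ndarray
    blank_subtracted: bool = False

    def __post_init__(self) -> None:
        if not (self.delta_lambda > 0):
            raise ValidationError(
                f"delta_lambda must be > 0 nm, got {self.delta_lambda}"
            )
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.axis.n,):
            raise ValidationError(
                f"intensity length {self.intensity.shape} does not match axis ({self.axis.n},)"
            )


@dataclass
class DerivativeSpectrum:
    """Smoothed first derivative of a synchronous spectrum (a.u. per nm)."""

    axis: WavelengthGrid
    amplitude: np.ndarray
    smoothing_window: int
    order: int = 1

    def __post_init__(self) -> None:
        if self.order != 1:
            raise ValidationError("only first-order derivative spectra are supported")
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.shape != (self.axis.n,):
            raise ValidationError(
                f"amplitude length {self.amplitude.shape} does not match axis ({self.axis.n},)"
            )


def _fractional_indices(grid: WavelengthGrid, wavelengths: np.ndarray):
    """Split wavelengths into integer grid indices and snapped fractions."""
    ix = (wavelengths - grid.start) / grid.step
    i0 = np.floor(ix + _NODE_SNAP).astype(int)
    i0 = np.clip(i0, 0, grid.n - 2)
    frac = ix - i0
    frac[np.abs(frac) < _NODE_SNAP] = 0.0
    frac[np.abs(frac - 1.0) < _NODE_SNAP] = 1.0
    return i0, frac


def extract_synchronous(
    eem: ExcitationEmissionMatrix,
    delta_lambda: float = DEFAULT_DELTA_LAMBDA,
    axis: WavelengthGrid | None = None,
) -> SynchronousSpectrum:
    """Extract the constant-offset synchronous spectrum from an EEM.

    For every wavelength ``lam`` on ``axis`` the returned intensity is the EEM
    intensity at excitation ``lam`` / emission ``lam + delta_lambda``,
    bilinearly interpolated; requests that land exactly on grid nodes return
    the stored matrix value bitwise.  When ``axis`` is omitted, the largest
    axis on the excitation grid for which the offset pair stays inside the EEM
    domain is used.
    """
    if not (delta_lambda > 0):
        raise ValidationError(f"delta_lambda must be > 0 nm, got {delta_lambda}")
    if axis is None:
        axis = _largest_valid_axis(eem, delta_lambda)

    lam = axis.values
    ex_lo, ex_hi = eem.excitation.span
    em_lo, em_hi = eem.emission.span
    slack_ex = _NODE_SNAP * eem.excitation.step
    slack_em = _NODE_SNAP * eem.emission.step
    bad_ex = (lam < ex_lo - slack_ex) | (lam > ex_hi + slack_ex)
    bad_em = (lam + delta_lambda < em_lo - slack_em) | (
        lam + delta_lambda > em_hi + slack_em
    )
    bad = bad_ex | bad_em
    if np.any(bad):
        offender = float(lam[np.argmax(bad)])
        raise DomainError(
            f"synchronous pair ({offender:g}, {offender + delta_lambda:g}) nm "
            f"falls outside the EEM domain "
            f"[{ex_lo:g}, {ex_hi:g}] x [{em_lo:g}, {em_hi:g}]"
        )

    i0, fx = _fractional_indices(eem.excitation, lam)
    j0, fy = _fractional_indices(eem.emission, lam + delta_lambda)
    mat = eem.intensity
    vals = (
        (1.0 - fx) * (1.0 - fy) * mat[i0, j0]
        + fx * (1.0 - fy) * mat[i0 + 1, j0]
        + (1.0 - fx) * fy * mat[i0, j0 + 1]
        + fx * fy * mat[i0 + 1, j0 + 1]
    )
    # Node-aligned requests bypass the weighted sum entirely.
    exact = (fx == 0.0) & (fy == 0.0)
    if np.any(exact):
        vals[exact] = mat[i0[exact], j0[exact]]
    return SynchronousSpectrum(delta_lambda=delta_lambda, axis=axis, intensity=vals)


def _largest_valid_axis(
    eem: ExcitationEmissionMatrix, delta_lambda: float
) -> WavelengthGrid:
    ex = eem.excitation
    em_lo, em_hi = eem.emission.span
    lo = max(ex.start, em_lo - delta_lambda)
    hi = min(ex.span[1], em_hi - delta_lambda)
    # Align to excitation grid nodes.
    k_lo = int(math.ceil((lo - ex.start) / ex.step - _NODE_SNAP))
    k_hi = int(math.floor((hi - ex.start) / ex.step + _NODE_SNAP))
    if k_hi <= k_lo:
        raise DomainError(
            f"delta_lambda = {delta_lambda:g} nm leaves no valid synchronous axis "
            f"within the EEM domain"
        )
    return WavelengthGrid(
        start=ex.start + k_lo * ex.step,
        stop=ex.start + k_hi * ex.step,
        step=ex.step,
    )


def subtract_blank(
    sample: SynchronousSpectrum, blank: SynchronousSpectrum
) -> SynchronousSpectrum:
    """Pointwise sample-minus-blank correction; the result keeps its sign."""
    if sample.axis != blank.axis:
        raise ValidationError("sample and blank spectra must share the same axis")
    if sample.delta_lambda != blank.delta_lambda:
        raise ValidationError(
            "sample and blank spectra must share the same delta_lambda"
        )
    return SynchronousSpectrum(
        delta_lambda=sample.delta_lambda,
        axis=sample.axis,
        intensity=sample.intensity - blank.intensity,
        blank_subtracted=True,
    )


def _check_window(window: int, n: int) -> int:
    window = int(window)
    if window % 2 == 0:
        raise ValidationError(f"smoothing window must be odd, got {window}")
    if not (3 <= window <= n):
        raise ValidationError(
            f"smoothing window must satisfy 3 <= window <= {n}, got {window}"
        )
    return window


def smooth(
    spec: SynchronousSpectrum, window: int = DEFAULT_SMOOTHING_WINDOW
) -> SynchronousSpectrum:
    """Quadratic local-polynomial (Savitzky-Golay) smoothing.

    Edge points are handled by evaluating the edge window's fitted polynomial
    (no padding with artificial data).
    """
    window = _check_window(window, spec.axis.n)
    sm = savgol_filter(spec.intensity, window, polyorder=2, mode="interp")
    return replace(spec, intensity=sm)


def first_derivative(
    spec: SynchronousSpectrum, window: int = DEFAULT_SMOOTHING_WINDOW
) -> DerivativeSpectrum:
    """Smoothed first derivative d(intensity)/d(lambda), in a.u. per nm.

    Smoothing and differentiation are a single quadratic Savitzky-Golay pass
    over ``window`` points.
    """
    window = _check_window(window, spec.axis.n)
    amp = savgol_filter(
        spec.intensity,
        window,
        polyorder=2,
        deriv=1,
        delta=spec.axis.step,
        mode="interp",
    )
    return DerivativeSpectrum(axis=spec.axis, amplitude=amp, smoothing_window=window)


def amplitude_at(deriv: DerivativeSpectrum, wavelength: float) -> float:
    """Linearly interpolated derivative amplitude at ``wavelength`` (nm)."""
    lo, hi = deriv.axis.span
    if not deriv.axis.contains(wavelength):
        raise DomainError(
            f"wavelength {wavelength:g} nm outside spectrum span [{lo:g}, {hi:g}] nm"
        )
    guard = (deriv.smoothing_window // 2) * deriv.axis.step
    if wavelength < lo + guard or wavelength > hi - guard:
        warnings.warn(
            f"readout at {wavelength:g} nm lies within half a smoothing window "
            f"({guard:g} nm) of the axis edge",
            EdgeProximityWarning,
            stacklevel=2,
        )
    i0, frac = _fractional_indices(deriv.axis, np.asarray([float(wavelength)]))
    if frac[0] == 0.0:
        return float(deriv.amplitude[i0[0]])
    if frac[0] == 1.0:
        return float(deriv.amplitude[i0[0] + 1])
    return float(
        (1.0 - frac[0]) * deriv.amplitude[i0[0]] + frac[0] * deriv.amplitude[i0[0] + 1]
    )


# ---------------------------------------------------------------------------
# CSV input/output
#
# EEM CSV (wide): first row = emission wavelengths, first column = excitation
# wavelengths, body = intensities.  Spectrum CSV (long): columns
# wavelength_nm, intensity.  Values are written at 9 significant digits; a
# write/read/write cycle is byte-identical.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.9g"


def grid_from_values(values: np.ndarray, what: str = "wavelength") -> WavelengthGrid:
    """Reconstruct a uniform WavelengthGrid from an explicit axis vector."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError(f"{what} axis must be a 1-D vector of >= 2 values")
    diffs = np.diff(values)
    step = float(np.mean(diffs))
    if step <= 0 or not np.allclose(diffs, step, rtol=1e-6, atol=1e-9 * abs(step)):
        raise ValidationError(f"{what} axis must be uniform and strictly increasing")
    return WavelengthGrid(start=float(values[0]), stop=float(values[-1]), step=step)


def write_eem_csv(eem: ExcitationEmissionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        eem.intensity, index=eem.excitation.values, columns=eem.emission.values
    )
    df.to_csv(path, float_format=_FLOAT_FMT, index_label="")


def read_eem_csv(path: str | Path, meta: Mapping[str, Any] | None = None) -> ExcitationEmissionMatrix:
    df = pd.read_csv(path, index_col=0)
    try:
        excitation = grid_from_values(df.index.to_numpy(dtype=float), "excitation")
        emission = grid_from_values(
            np.asarray([float(c) for c in df.columns]), "emission"
        )
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"malformed EEM CSV {path}: {exc}") from exc
    return ExcitationEmissionMatrix(
        excitation=excitation,
        emission=emission,
        intensity=df.to_numpy(dtype=float),
        meta=dict(meta or {}),
    )


def write_spectrum_csv(spec: SynchronousSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.axis.values, "intensity": spec.intensity}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectrum_csv(
    path: str | Path,
    delta_lambda: float = DEFAULT_DELTA_LAMBDA,
    blank_subtracted: bool = False,
) -> SynchronousSpectrum:
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "intensity"):
        if col not in df.columns:
            raise ValidationError(f"spectrum CSV {path} lacks required column '{col}'")
    axis = grid_from_values(df["wavelength_nm"].to_numpy(dtype=float))
    return SynchronousSpectrum(
        delta_lambda=delta_lambda,
        axis=axis,
        intensity=df["intensity"].to_numpy(dtype=float),
        blank_subtracted=blank_subtracted,
    )
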