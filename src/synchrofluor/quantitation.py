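"""Zero-crossing quantitation of binary fluorophore mixtures.

At a zero-crossing wavelength the first-derivative synchronous spectrum of
one component vanishes at every concentration, so the derivative amplitude
measured there depends only on the other component.  This module locates and
verifies such wavelengths, reads derivative amplitudes from mixture EEMs at
the fixed assay wavelengths, inverts the linear calibration, and sweeps the
synchronous offset to check which delta_lambda values admit mutual zero
crossings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .eem_core import (
    DEFAULT_DELTA_LAMBDA,
    DEFAULT_SMOOTHING_WINDOW,
    DerivativeSpectrum,
    DomainError,
    ExcitationEmissionMatrix,
    SpectraError,
    SynchronousSpectrum,
    ValidationError,
    amplitude_at,
    extract_synchronous,
    first_derivative,
    subtract_blank,
)

__all__ = [
    "ZeroCrossingAssay",
    "NoZeroCrossingError",
    "ExtrapolationWarning",
    "find_zero_crossing",
    "measure",
    "quantify",
    "optimize_delta_lambda",
    "default_assays",
    "DEFAULT_ZERO_CROSSING_TOLERANCE",
]

#: Maximum normalized interferent amplitude |1D|/max|1D| tolerated at a
#: candidate zero-crossing wavelength.
DEFAULT_ZERO_CROSSING_TOLERANCE = 0.02


class NoZeroCrossingError(SpectraError):
    """No wavelength keeps the interferent's normalized derivative below
    tolerance across its concentration range (the spectra interfere)."""


class ExtrapolationWarning(UserWarning):
    """A quantified concentration falls outside the calibration's linear range."""


@dataclass
class ZeroCrossingAssay:
    """Fixed-wavelength derivative assay for one analyte.

    ``polarity`` is the sign of the analyte's derivative peak at the readout
    wavelength; measured amplitudes are multiplied by it so calibrations run
    on positive signal scales regardless of which flank of the synchronous
    band the readout sits on.
    """

    analyte: str
    readout_wavelength: float
    delta_lambda: float = DEFAULT_DELTA_LAMBDA
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW
    polarity: int = 1
    calibration: "object | None" = None  # CalibrationCurve, once fitted

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValidationError("assay polarity must be +1 or -1")
        if self.calibration is not None:
            wl = getattr(self.calibration, "wavelength", None)
            if wl is not None and abs(wl - self.readout_wavelength) > 1e-9:
                raise ValidationError(
                    f"assay readout {self.readout_wavelength:g} nm does not match "
                    f"calibration wavelength {wl:g} nm"
                )


def default_assays() -> tuple[ZeroCrossingAssay, ZeroCrossingAssay]:
    """BAM read at 260 nm (rising flank, +1) and TEB read at 290 nm
    (falling flank, -1), both at delta_lambda = 20 nm."""
    return (
        ZeroCrossingAssay(analyte="BAM", readout_wavelength=260.0, polarity=1),
        ZeroCrossingAssay(analyte="TEB", readout_wavelength=290.0, polarity=-1),
    )


def find_zero_crossing(
    deriv_set: Sequence[DerivativeSpectrum],
    search_window: tuple[float, float] | None = None,
    tolerance: float = DEFAULT_ZERO_CROSSING_TOLERANCE,
) -> float:
    """Locate a concentration-independent zero of a derivative-spectrum family.

    Given derivative spectra of one interferent at several concentrations
    spanning its range, returns the wavelength minimizing the worst-case
    normalized amplitude max_i |1D_i(lam)| / max|1D_i|, refined below grid
    resolution by linear interpolation so crossings falling between nodes
    are still found.  Raises :class:`NoZeroCrossingError` when that minimum
    exceeds ``tolerance`` -- the situation in which the component cannot be
    nulled out and the raw spectra interfere.
    """
    if len(deriv_set) < 3:
        raise ValidationError(
            "need >= 3 derivative spectra spanning the interferent's range"
        )
    axis = deriv_set[0].axis
    for d in deriv_set[1:]:
        if d.axis != axis:
            raise ValidationError("all derivative spectra must share one axis")

    lam = axis.values
    if search_window is None:
        mask = np.ones_like(lam, dtype=bool)
    else:
        lo, hi = search_window
        if lo >= hi:
            raise ValidationError("search window must be an increasing (lo, hi) pair")
        if not (axis.contains(lo) and axis.contains(hi)):
            raise ValidationError(
                f"search window ({lo:g}, {hi:g}) nm extends beyond the axis span "
                f"{axis.span}"
            )
        mask = (lam >= lo) & (lam <= hi)

    # Sub-node refinement: evaluate the normalized worst-case envelope on a
    # 10x finer axis via linear interpolation of each spectrum.
    sub = lam[mask]
    fine = np.arange(sub[0], sub[-1] + 0.1 * axis.step, 0.1 * axis.step)
    worst = np.zeros_like(fine)
    for d in deriv_set:
        peak = float(np.max(np.abs(d.amplitude)))
        if peak == 0.0:
            continue  # all-zero spectrum constrains nothing
        interp = np.interp(fine, lam, d.amplitude)
        worst = np.maximum(worst, np.abs(interp) / peak)
    best = int(np.argmin(worst))
    if worst[best] > tolerance:
        raise NoZeroCrossingError(
            f"no common zero crossing: best worst-case normalized amplitude "
            f"{worst[best]:.4f} exceeds tolerance {tolerance:g}"
        )
    return float(fine[best])


def measure(
    sample_eem: ExcitationEmissionMatrix,
    assay: ZeroCrossingAssay,
    blank: SynchronousSpectrum | None = None,
) -> float:
    """Measure the assay's analytical signal from one EEM.

    Composes synchronous extraction, optional blank subtraction, the smoothed
    first derivative, and the interpolated amplitude readout, then applies
    the assay polarity.
    """
    sync = extract_synchronous(sample_eem, assay.delta_lambda)
    if blank is not None:
        sync = subtract_blank(sync, blank)
    deriv = first_derivative(sync, assay.smoothing_window)
    return assay.polarity * amplitude_at(deriv, assay.readout_wavelength)


def quantify(amplitude: float, curve) -> float:
    """Invert the linear calibration: C = (1D - a) / b, in ug/ml.

    Emits :class:`ExtrapolationWarning` when the result lies outside the
    curve's linearity range; the value is returned unclipped.
    """
    if curve.b == 0:
        raise ValidationError("degenerate calibration: slope b = 0")
    conc = (amplitude - curve.a) / curve.b
    lo, hi = curve.range
    if not (lo <= conc <= hi):
        warnings.warn(
            f"{curve.analyte}: quantified {conc:.4g} ug/ml extrapolates beyond "
            f"the calibrated range [{lo:g}, {hi:g}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(conc)


def optimize_delta_lambda(
    models: Sequence,
    candidate_deltas: Sequence[float],
    criterion: Callable[[pd.Series], float] | None = None,
    tolerance: float = DEFAULT_ZERO_CROSSING_TOLERANCE,
) -> pd.DataFrame:
    """Sweep the synchronous offset and score each candidate.

    For every delta_lambda the noiseless synchronous spectra of both models
    are derived, each model's concentration-independent zero crossing is
    searched, and the partner's derivative response (per unit concentration)
    at that crossing is recorded.  A row is feasible when both mutual zero
    crossings exist; the default criterion marks as optimal the feasible row
    maximizing the smaller of the two partner responses (highest usable
    sensitivity for both drugs).
    """
    from .synth_spectra import DEFAULT_EMISSION_GRID, DEFAULT_EXCITATION_GRID, unit_derivative_spectrum
    from .eem_core import WavelengthGrid

    if len(models) != 2:
        raise ValidationError("the offset sweep is defined for exactly two models")
    ex = DEFAULT_EXCITATION_GRID
    em = DEFAULT_EMISSION_GRID

    rows = []
    for delta in candidate_deltas:
        if delta <= 0:
            raise ValidationError(f"delta_lambda candidates must be > 0, got {delta}")
        row: dict[str, object] = {"delta_lambda": float(delta)}
        lo = max(ex.start, em.start - delta)
        hi = min(ex.span[1], em.span[1] - delta)
        if hi - lo < 2 * ex.step:
            row.update(feasible=False, reason="offset leaves no synchronous axis")
            rows.append(row)
            continue
        axis = WavelengthGrid(lo, hi, ex.step)
        lam = axis.values
        derivs = {}
        band_windows = {}
        for m in models:
            rlo, rhi = m.linear_range
            base = unit_derivative_spectrum(m, float(delta), axis)
            derivs[m.name] = [
                DerivativeSpectrum(
                    axis=base.axis,
                    amplitude=c * base.amplitude,
                    smoothing_window=base.smoothing_window,
                )
                for c in (rlo, 0.5 * (rlo + rhi), rhi)
            ]
            # The useful crossing sits inside the interferent's own band
            # (its extremum), so confine the search to where its synchronous
            # intensity holds >= 10% of peak -- far wings are trivially flat.
            sync = m.excitation_profile(lam) * m.emission_profile(lam + delta)
            inside = lam[sync >= 0.1 * sync.max()]
            band_windows[m.name] = (float(inside.min()), float(inside.max()))
        feasible = True
        reason = ""
        for m, partner in (models, models[::-1]):
            try:
                zc = find_zero_crossing(
                    derivs[m.name],
                    search_window=band_windows[m.name],
                    tolerance=tolerance,
                )
            except NoZeroCrossingError:
                feasible = False
                reason = f"no zero crossing for {m.name}"
                break
            row[f"crossing_{m.name}"] = zc
            partner_deriv = unit_derivative_spectrum(partner, float(delta), axis)
            row[f"signal_{partner.name}"] = abs(amplitude_at(partner_deriv, zc))
        row["feasible"] = feasible
        if reason:
            row["reason"] = reason
        rows.append(row)

    table = pd.DataFrame(rows)
    table["optimal"] = False
    feas = table[table["feasible"] == True]  # noqa: E712
    if not feas.empty:
        sig_cols = [c for c in table.columns if c.startswith("signal_")]
        if criterion is None:
            scores = feas[sig_cols].min(axis=1)
        else:
            scores = feas.apply(criterion, axis=1)
        table.loc[scores.idxmax(), "optimal"] = True
    return table
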