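"""Seedable two-fluorophore excitation-emission matrix simulator.

Emulates the measurement situation of the bambuterol (BAM) / terbutaline
(TEB) assay: two fluorophores with strongly overlapping Gaussian excitation
and emission bands, a linear intensity-concentration response over their
working ranges, and additive plus proportional instrument noise.  The default
band parameters are tuned so that, at a synchronous offset of 20 nm, each
analyte's first-derivative trace crosses zero at the partner's readout
wavelength: TEB's derivative vanishes at 260 nm (where BAM is read) and BAM's
vanishes at 290 nm (where TEB is read).

Concentrations are in ug/ml throughout; intensities in arbitrary units.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .eem_core import (
    DEFAULT_DELTA_LAMBDA,
    DEFAULT_SMOOTHING_WINDOW,
    ExcitationEmissionMatrix,
    ValidationError,
    WavelengthGrid,
    extract_synchronous,
    first_derivative,
)

__all__ = [
    "Band",
    "FluorophoreModel",
    "NoiseModel",
    "SimulatedSample",
    "simulate_eem",
    "default_bam_teb_models",
    "default_noise_model",
    "generate_calibration_set",
    "generate_mixture_panel",
    "unit_derivative_spectrum",
    "DEFAULT_EXCITATION_GRID",
    "DEFAULT_EMISSION_GRID",
    "DEFAULT_SYNC_AXIS",
    "BAM_LEVELS",
    "TEB_LEVELS",
    "MIXTURE_RATIOS",
    "READOUT_WAVELENGTHS",
]

#: Default acquisition grids (nm).  1 nm sampling keeps the 260/290 readouts
#: node-aligned; the emission grid is shifted so the 20 nm offset stays in-domain.
DEFAULT_EXCITATION_GRID = WavelengthGrid(200.0, 400.0, 1.0)
DEFAULT_EMISSION_GRID = WavelengthGrid(220.0, 420.0, 1.0)
#: Synchronous axis implied by the default grids at delta_lambda = 20 nm.
DEFAULT_SYNC_AXIS = WavelengthGrid(200.0, 400.0, 1.0)

#: Calibration levels (ug/ml) of the two analytes.
BAM_LEVELS: tuple[float, ...] = (0.2, 0.8, 1.6, 3.2, 4.0, 6.0)
TEB_LEVELS: tuple[float, ...] = (0.2, 0.4, 0.8, 1.6, 3.2, 4.0)

#: Standard binary-mixture panel as (BAM, TEB) concentrations in ug/ml,
#: spanning ratios from 1:1 up to 10:1.
MIXTURE_RATIOS: tuple[tuple[float, float], ...] = (
    (2.0, 0.2),
    (4.0, 0.4),
    (2.0, 1.0),
    (2.0, 2.0),
    (5.0, 1.0),
)

#: Fixed assay readout wavelengths (nm): each analyte is read at the zero
#: crossing of the other's first-derivative synchronous spectrum.
READOUT_WAVELENGTHS: dict[str, float] = {"BAM": 260.0, "TEB": 290.0}

Band = tuple[float, float, float]  # (center nm, sigma nm, weight)


@dataclass(frozen=True)
class FluorophoreModel:
    """Gaussian-band fluorophore with a linear concentration response.

    ``response`` is the EEM intensity (a.u.) per ug/ml at the joint
    excitation/emission band maximum; band profiles are weight-summed
    Gaussians normalized to unit peak.
    """

    name: str
    excitation_bands: tuple[Band, ...]
    emission_bands: tuple[Band, ...]
    response: float
    linear_range: tuple[float, float]

    def __post_init__(self) -> None:
        for bands, label in (
            (self.excitation_bands, "excitation"),
            (self.emission_bands, "emission"),
        ):
            if not bands:
                raise ValidationError(f"{self.name}: {label} bands must be non-empty")
            for center, sigma, weight in bands:
                if sigma <= 0 or weight <= 0:
                    raise ValidationError(
                        f"{self.name}: {label} band sigmas and weights must be > 0"
                    )
        if self.response <= 0:
            raise ValidationError(f"{self.name}: response must be > 0")
        lo, hi = self.linear_range
        if not lo < hi:
            raise ValidationError(f"{self.name}: linear_range min must be < max")

    def excitation_profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return _unit_peak_profile(self.excitation_bands, wavelengths)

    def emission_profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return _unit_peak_profile(self.emission_bands, wavelengths)


def _band_sum(bands: tuple[Band, ...], wavelengths: np.ndarray) -> np.ndarray:
    wavelengths = np.asarray(wavelengths, dtype=float)
    out = np.zeros_like(wavelengths, dtype=float)
    for center, sigma, weight in bands:
        out += weight * np.exp(-0.5 * ((wavelengths - center) / sigma) ** 2)
    return out


@lru_cache(maxsize=128)
def _profile_peak(bands: tuple[Band, ...]) -> float:
    centers = np.array([b[0] for b in bands])
    sigmas = np.array([b[1] for b in bands])
    fine = np.arange(centers.min() - 5 * sigmas.max(), centers.max() + 5 * sigmas.max(), 0.1)
    return float(_band_sum(bands, fine).max())


def _unit_peak_profile(bands: tuple[Band, ...], wavelengths: np.ndarray) -> np.ndarray:
    return _band_sum(bands, wavelengths) / _profile_peak(bands)


@dataclass(frozen=True)
class NoiseModel:
    """Heteroscedastic instrument noise: additive floor plus a proportional term.

    Each EEM point receives ``additive_sd * z1 + proportional_sd * I * z2``
    with independent standard-normal draws.
    """

    additive_sd: float = 0.0
    proportional_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.proportional_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")

    @property
    def is_silent(self) -> bool:
        return self.additive_sd == 0.0 and self.proportional_sd == 0.0


@dataclass
class SimulatedSample:
    """One simulated measurement: true concentrations, the (noisy) EEM, and
    the noiseless first-derivative amplitudes at each assay wavelength."""

    concentrations: dict[str, float]
    eem: ExcitationEmissionMatrix
    truth: dict[str, float] = field(default_factory=dict)
    in_range: dict[str, bool] = field(default_factory=dict)


@lru_cache(maxsize=64)
def unit_derivative_spectrum(
    model: FluorophoreModel,
    delta_lambda: float = DEFAULT_DELTA_LAMBDA,
    axis: WavelengthGrid = DEFAULT_SYNC_AXIS,
    window: int = DEFAULT_SMOOTHING_WINDOW,
):
    """Noiseless first-derivative synchronous spectrum per unit concentration."""
    lam = axis.values
    intensity = (
        model.response
        * model.excitation_profile(lam)
        * model.emission_profile(lam + delta_lambda)
    )
    from .eem_core import SynchronousSpectrum

    sync = SynchronousSpectrum(delta_lambda=delta_lambda, axis=axis, intensity=intensity)
    return first_derivative(sync, window)


def simulate_eem(
    models: Sequence[FluorophoreModel],
    concs: Mapping[str, float],
    grids: tuple[WavelengthGrid, WavelengthGrid] = (
        DEFAULT_EXCITATION_GRID,
        DEFAULT_EMISSION_GRID,
    ),
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> SimulatedSample:
    """Simulate one EEM as a concentration-weighted superposition of the
    models' outer-product band profiles, plus optional noise.

    Identical (models, concs, grids, noise, seed) give bit-identical output.
    """
    by_name = {m.name: m for m in models}
    unknown = set(concs) - set(by_name)
    if unknown:
        raise ValidationError(f"unknown analyte name(s): {sorted(unknown)}")

    ex_grid, em_grid = grids
    ex = ex_grid.values
    em = em_grid.values
    signal = np.zeros((ex_grid.n, em_grid.n), dtype=float)
    for name, c in concs.items():
        m = by_name[name]
        signal += (
            c * m.response * np.outer(m.excitation_profile(ex), m.emission_profile(em))
        )

    intensity = signal
    if noise is not None and not noise.is_silent:
        rng = np.random.default_rng(noise.seed if seed is None else seed)
        intensity = (
            signal
            + noise.additive_sd * rng.standard_normal(signal.shape)
            + noise.proportional_sd * signal * rng.standard_normal(signal.shape)
        )

    eem = ExcitationEmissionMatrix(
        excitation=ex_grid,
        emission=em_grid,
        intensity=intensity,
        meta={"simulated": True, "concentrations_ug_ml": dict(concs)},
    )

    truth: dict[str, float] = {}
    for name, readout in READOUT_WAVELENGTHS.items():
        if name not in by_name:
            continue
        axis = DEFAULT_SYNC_AXIS if _axis_fits(DEFAULT_SYNC_AXIS, grids) else None
        total = 0.0
        for other, c in concs.items():
            deriv = unit_derivative_spectrum(by_name[other], DEFAULT_DELTA_LAMBDA,
                                             axis or DEFAULT_SYNC_AXIS)
            idx = int(round((readout - deriv.axis.start) / deriv.axis.step))
            if 0 <= idx < deriv.axis.n:
                total += c * deriv.amplitude[idx]
        truth[name] = total

    in_range = {
        name: by_name[name].linear_range[0] <= c <= by_name[name].linear_range[1]
        for name, c in concs.items()
    }
    return SimulatedSample(
        concentrations=dict(concs), eem=eem, truth=truth, in_range=in_range
    )


def _axis_fits(
    axis: WavelengthGrid, grids: tuple[WavelengthGrid, WavelengthGrid]
) -> bool:
    ex, em = grids
    return (
        ex.contains(axis.start)
        and ex.contains(axis.span[1])
        and em.contains(axis.start + DEFAULT_DELTA_LAMBDA)
        and em.contains(axis.span[1] + DEFAULT_DELTA_LAMBDA)
    )


def default_bam_teb_models(validate: bool = True) -> tuple[FluorophoreModel, FluorophoreModel]:
    """Default BAM/TEB band models.

    Single Gaussian excitation/emission bands with 20 nm Stokes shifts,
    placed so the delta_lambda=20 synchronous band of TEB peaks at 260 nm
    and that of BAM peaks at 290 nm; a single-band synchronous spectrum
    peaks where its derivative crosses zero at every concentration, which is
    exactly the zero-crossing geometry the assay relies on.  The 20 nm
    Stokes shifts also make delta_lambda = 20 the sensitivity-optimal offset
    (synchronous intensity peaks when the offset matches the Stokes shift).
    Response factors are scaled so the noiseless calibration slopes at the
    readout wavelengths are of the same magnitude as a real instrument's
    (tens of a.u. per ug/ml).

    With ``validate`` the mutual zero crossings are located numerically and
    checked to lie within 1 nm of the 260/290 nm readouts.
    """
    bam = FluorophoreModel(
        name="BAM",
        excitation_bands=((290.0, 24.0, 1.0),),
        emission_bands=((310.0, 24.0, 1.0),),
        response=625.0,
        linear_range=(0.2, 6.0),
    )
    teb = FluorophoreModel(
        name="TEB",
        excitation_bands=((260.0, 20.0, 1.0),),
        emission_bands=((280.0, 20.0, 1.0),),
        response=1750.0,
        linear_range=(0.2, 4.0),
    )
    if validate:
        from .quantitation import find_zero_crossing

        for model, partner_readout in ((teb, 260.0), (bam, 290.0)):
            lo, hi = model.linear_range
            derivs = []
            for c in (lo, 0.5 * (lo + hi), hi):
                d = unit_derivative_spectrum(model)
                from .eem_core import DerivativeSpectrum

                derivs.append(
                    DerivativeSpectrum(
                        axis=d.axis,
                        amplitude=c * d.amplitude,
                        smoothing_window=d.smoothing_window,
                    )
                )
            zc = find_zero_crossing(
                derivs, search_window=(partner_readout - 15, partner_readout + 15)
            )
            if abs(zc - partner_readout) > 1.0:
                raise ValidationError(
                    f"{model.name} zero crossing at {zc:g} nm drifts more than "
                    f"1 nm from the {partner_readout:g} nm readout"
                )
    return bam, teb


def default_noise_model(
    models: Sequence[FluorophoreModel] | None = None, seed: int = 0
) -> NoiseModel:
    """Default instrument noise for the simulated assay.

    The proportional term is 0.5% of the local signal; the additive floor is
    0.05% of the largest top-of-calibration EEM intensity across the models,
    keeping the derivative readout at the lowest calibration level within a
    few percent relative noise.
    """
    if models is None:
        models = default_bam_teb_models(validate=False)
    top = max(m.response * m.linear_range[1] for m in models)
    return NoiseModel(additive_sd=0.0005 * top, proportional_sd=0.005, seed=seed)


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def generate_calibration_set(
    model: FluorophoreModel,
    concentrations: Sequence[float] | None = None,
    replicates: int = 1,
    noise: NoiseModel | None = None,
    seed: int = 0,
    companions: Sequence[FluorophoreModel] = (),
) -> list[SimulatedSample]:
    """Single-analyte calibration series at the standard levels.

    Defaults: BAM levels 0.2-6.0 and TEB levels 0.2-4.0 ug/ml (six each).
    Deterministic for a fixed seed; replicate EEMs differ only through noise.
    """
    if concentrations is None:
        concentrations = {"BAM": BAM_LEVELS, "TEB": TEB_LEVELS}.get(model.name)
        if concentrations is None:
            raise ValidationError(
                f"no default calibration levels for analyte '{model.name}'"
            )
    if len(concentrations) == 0:
        raise ValidationError("calibration concentration list must be non-empty")
    lo, hi = model.linear_range
    for c in concentrations:
        if not (lo <= c <= hi):
            raise ValidationError(
                f"{model.name}: level {c} ug/ml outside linear range [{lo}, {hi}]"
            )
    models = (model, *companions)
    seeds = _child_seeds(seed, len(concentrations) * replicates)
    out = []
    k = 0
    for c in concentrations:
        for _ in range(replicates):
            out.append(
                simulate_eem(models, {model.name: c}, noise=noise, seed=seeds[k])
            )
            k += 1
    return out


def generate_mixture_panel(
    models: Sequence[FluorophoreModel],
    ratios: Sequence[tuple[float, float]] | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> list[SimulatedSample]:
    """Binary-mixture panel; ``ratios`` are (first, second) concentrations in
    ug/ml matching the order of ``models``.  Defaults to the standard
    five-mixture (BAM, TEB) panel."""
    if ratios is None:
        ratios = MIXTURE_RATIOS
    if len(ratios) == 0:
        raise ValidationError("mixture ratio list must be non-empty")
    if len(models) != 2:
        raise ValidationError("mixture panels are defined for exactly two models")
    seeds = _child_seeds(seed, len(ratios))
    out = []
    for s, (c1, c2) in zip(seeds, ratios):
        out.append(
            simulate_eem(
                models,
                {models[0].name: c1, models[1].name: c2},
                noise=noise,
                seed=s,
            )
        )
    return out


# --------------------------------------------------------------------------
# Model JSON round trip
# --------------------------------------------------------------------------

def models_to_json(models: Sequence[FluorophoreModel], path: str | Path) -> None:
    payload = [asdict(m) for m in models]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def models_from_json(path: str | Path) -> list[FluorophoreModel]:
    payload = json.loads(Path(path).read_text())
    out = []
    for d in payload:
        out.append(
            FluorophoreModel(
                name=d["name"],
                excitation_bands=tuple(tuple(b) for b in d["excitation_bands"]),
                emission_bands=tuple(tuple(b) for b in d["emission_bands"]),
                response=float(d["response"]),
                linear_range=tuple(d["linear_range"]),
            )
        )
    return out
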