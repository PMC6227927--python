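"""Published validation measurements for the BAM/TEB derivative assay.

Reference tables from the originating method validation of the
first-derivative synchronous spectrofluorimetric determination of bambuterol
(BAM, read at 260 nm) and terbutaline (TEB, read at 290 nm): calibration
performance constants, pure-form and synthetic-mixture recovery panels, the
pharmacopoeial HPLC comparison recoveries, precision replicates, and
formulation assays.  These are fixed experimental results used as inputs to
the statistics layer (recovery summaries, t/F method comparison, LOD/LOQ
arithmetic); nothing here is computed by this package.
"""

from __future__ import annotations

from types import MappingProxyType

# --------------------------------------------------------------------------
# Calibration performance constants (per analyte).
# a/b: intercept and slope of 1D = a + b*C; s_* are the OLS standard
# deviations; rsd/error summarize replicate recoveries (%); lod/loq in ug/ml.
# --------------------------------------------------------------------------
CALIBRATION_PERFORMANCE = MappingProxyType(
    {
        "BAM": MappingProxyType(
            {
                "wavelength_nm": 260.0,
                "n": 6,
                "range_ug_ml": (0.2, 6.0),
                "a": 18.21,
                "b": 13.65,
                "r": 0.9999,
                "s_yx": 0.143,
                "s_a": 0.096,
                "s_b": 0.029,
                "rsd_pct": 1.11,
                "error_pct": 0.45,
                "lod_ug_ml": 0.023,
                "loq_ug_ml": 0.0701,
            }
        ),
        "TEB": MappingProxyType(
            {
                "wavelength_nm": 290.0,
                "n": 6,
                "range_ug_ml": (0.2, 4.0),
                "a": 8.29,
                "b": 27.57,
                "r": 0.9999,
                "s_yx": 0.733,
                "s_a": 0.464,
                "s_b": 0.201,
                "rsd_pct": 1.70,
                "error_pct": 0.69,
                "lod_ug_ml": 0.056,
                "loq_ug_ml": 0.169,
            }
        ),
    }
)

# --------------------------------------------------------------------------
# Pure-form accuracy panels: (taken, found) in ug/ml for the proposed
# method, and the reference-method percentage recoveries it is compared to.
# --------------------------------------------------------------------------
PURE_FORM_PROPOSED = MappingProxyType(
    {
        "BAM": (
            (0.20, 0.204),
            (0.80, 0.790),
            (1.60, 1.596),
            (3.20, 3.207),
            (4.00, 4.013),
            (6.00, 5.989),
        ),
        "TEB": (
            (0.20, 0.207),
            (0.40, 0.406),
            (0.80, 0.805),
            (1.60, 1.585),
            (3.20, 3.163),
            (4.00, 4.034),
        ),
    }
)

# Recovery columns as published (2 d.p.); the panel's summary statistics
# derive from these rounded values, which is why they are carried separately
# from the taken/found pairs above.
PURE_FORM_RECOVERIES = MappingProxyType(
    {
        "BAM": (102.00, 98.75, 99.75, 100.22, 100.33, 99.83),
        "TEB": (103.50, 101.50, 100.63, 99.06, 98.84, 100.85),
    }
)

PURE_FORM_REFERENCE_RECOVERIES = MappingProxyType(
    {
        "BAM": (99.34, 100.89, 99.67),
        "TEB": (100.56, 99.26, 100.28),
    }
)

# --------------------------------------------------------------------------
# Synthetic binary-mixture panel: (BAM, TEB) amounts taken in ug/ml and the
# percentage recovery of each analyte, plus reference-method recoveries.
# --------------------------------------------------------------------------
MIXTURE_PANEL = (
    ((2.00, 0.20), (100.24, 102.14)),
    ((4.00, 0.40), (99.62, 101.32)),
    ((2.00, 1.00), (99.64, 98.62)),
    ((5.00, 1.00), (101.32, 99.11)),
    ((2.00, 2.00), (98.37, 99.32)),
)

MIXTURE_REFERENCE_RECOVERIES = MappingProxyType(
    {
        "BAM": (99.35, 98.62, 99.44),
        "TEB": (98.35, 101.24, 99.64),
    }
)

# --------------------------------------------------------------------------
# Intra-/inter-day precision: per concentration (ug/ml), the reported
# mean +/- sd of replicate recoveries (%), n = 3 determinations per cell.
# --------------------------------------------------------------------------
PRECISION = MappingProxyType(
    {
        "BAM": MappingProxyType(
            {
                "intra-day": ((0.40, 102.00, 1.33), (3.20, 100.17, 1.66), (6.00, 99.94, 1.30)),
                "inter-day": ((0.40, 99.25, 0.65), (3.20, 100.09, 0.79), (6.00, 101.37, 1.97)),
            }
        ),
        "TEB": MappingProxyType(
            {
                "intra-day": ((0.20, 100.42, 0.81), (3.20, 99.86, 0.30), (4.00, 100.61, 1.23)),
                "inter-day": ((0.20, 99.42, 1.68), (3.20, 99.09, 1.72), (4.00, 99.33, 1.68)),
            }
        ),
    }
)

# --------------------------------------------------------------------------
# Formulation assays: (taken, found) ug/ml for the proposed method and the
# reference method, per commercial preparation.
# --------------------------------------------------------------------------
FORMULATIONS = MappingProxyType(
    {
        "Bambec tablet": MappingProxyType(
            {
                "analyte": "BAM",
                "proposed": ((1.00, 1.026), (2.50, 2.447), (4.00, 4.027)),
                "reference": ((20.00, 20.376), (40.00, 39.185), (60.00, 60.345)),
            }
        ),
        "Aironyl tablet": MappingProxyType(
            {
                "analyte": "TEB",
                "proposed": ((1.25, 1.272), (2.50, 2.456), (4.00, 4.024)),
                "reference": ((12.50, 12.655), (25.00, 24.692), (40.00, 40.164)),
            }
        ),
        "Bambedil syrup": MappingProxyType(
            {
                "analyte": "BAM",
                "proposed": ((1.00, 0.983), (2.50, 2.535), (4.00, 3.983)),
                "reference": ((20.00, 20.44), (40.00, 39.98), (60.00, 59.53)),
            }
        ),
        "Aironyl syrup": MappingProxyType(
            {
                "analyte": "TEB",
                "proposed": ((1.25, 1.262), (2.50, 2.476), (4.00, 4.013)),
                "reference": ((12.50, 12.49), (25.00, 25.39), (40.00, 39.47)),
            }
        ),
    }
)


def pure_form_recoveries(analyte: str) -> tuple[float, ...]:
    """Published percentage recoveries of the pure-form panel."""
    return PURE_FORM_RECOVERIES[analyte]


def mixture_recoveries(analyte: str) -> tuple[float, ...]:
    """Percentage recoveries of one analyte across the mixture panel."""
    idx = {"BAM": 0, "TEB": 1}[analyte]
    return tuple(rec[idx] for _, rec in MIXTURE_PANEL)
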