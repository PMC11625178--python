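"""Per-method evaluation equations: from raw readouts to concentrations.

Every operation is a pure function from a signal (plus dilution factor) to a
:class:`~hemoquant.calibration.QuantResult`.  Out-of-range assay-side values
are flagged against the registry validity ranges; negative back-calculated
concentrations are flagged, never truncated (truncation would bias recovery
statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

from .calibration import (
    APOHRP_HB_INTERCEPT_NM,
    APOHRP_HB_SLOPE,
    APOHRP_RANGES_NM,
    FLAG_ABOVE_RANGE,
    FLAG_BELOW_RANGE,
    FLAG_NEGATIVE,
    FLAG_SEMIQUANT,
    HAK_HEME_RANGE_UM,
    HAK_HB_CROSS,
    HAK_INTERCEPT,
    HAK_SLOPE,
    HARBOE_FACTOR,
    HARBOE_RANGE_UM,
    HARBOE_SCALE,
    HEMASTIX_HB_RANGE_NM,
    HEMASTIX_HEME_RANGE_NM,
    PYRIDINE_EPSILON_MM,
    REGISTRY,
    SLS_RANGES_UM,
    CalibrationCurve,
    QuantResult,
    apply_calibration,
)
from .spectra import PyridineChannels

__all__ = [
    "PYRIDINE_MODES",
    "EQ1_PARSES",
    "uvvis_direct",
    "harboe_hb",
    "pyridine_hemochromogen",
    "sls_modified",
    "heme_assay_kit_total",
    "hemastix_classify",
    "HemastixResult",
    "apohrp_quantify",
    "apohrp_apparent_heme_from_hb",
]

EQ1_PARSES = ("printed", "bracketed")


def _range_flags(assay_value: float, valid_range: tuple[float, float]) -> set[str]:
    flags = set()
    lo, hi = valid_range
    if assay_value < lo:
        flags.add(FLAG_BELOW_RANGE)
    elif assay_value > hi:
        flags.add(FLAG_ABOVE_RANGE)
    return flags


# --------------------------------------------------------------------------- #
# direct UV/Vis
# --------------------------------------------------------------------------- #

_DIRECT_KEYS = {"heme": "direct_heme_380", "hemoglobin": "direct_hb_405"}


def uvvis_direct(analyte: str, signal: float, df: float = 1.0) -> QuantResult:
    """Invert the direct Soret-band calibration (heme at 380 nm, Hb at 405 nm)."""
    try:
        curve = REGISTRY[_DIRECT_KEYS[analyte]]
    except KeyError:
        raise ValueError(f"unknown analyte {analyte!r}; expected heme or hemoglobin")
    return apply_calibration(curve, signal, df)


# --------------------------------------------------------------------------- #
# Harboe polychromatic correction
# --------------------------------------------------------------------------- #


def harboe_hb(a380: float, a415: float, a450: float, df: float = 1.0) -> QuantResult:
    """Hemoglobin from the three-wavelength Harboe correction.

    ``c(Hb)[uM] = df * 0.155 * (83.6 * (2*A415 - A380 - A450))``; the
    combination cancels any flat background, so a constant spectrum nulls it.
    """
    if min(a380, a415, a450) < 0:
        raise ValueError("absorbances must be >= 0")
    if df < 1:
        raise ValueError("dilution factor must be >= 1")
    assay_value = HARBOE_FACTOR * (HARBOE_SCALE * (2.0 * a415 - a380 - a450))
    conc = df * assay_value
    flags = _range_flags(assay_value, HARBOE_RANGE_UM)
    if conc < 0:
        flags.add(FLAG_NEGATIVE)
    return QuantResult(
        analyte="hemoglobin", concentration=conc, method="harboe",
        flags=frozenset(flags), assay_value=assay_value, dilution_factor=df,
    )


# --------------------------------------------------------------------------- #
# pyridine hemochromogen
# --------------------------------------------------------------------------- #

#: mode -> (epsilon key or None for the linear fit, analyte, assay-side range uM)
PYRIDINE_MODES = {
    "reduced_556_heme": ("e556_heme", "heme", (7.5, 37.5)),
    "reduced_556_hb": ("e556_hb", "hemoglobin", (1.3, 12.7)),
    "published_557": ("e557_heme", "heme", (7.5, 37.5)),
    "difference_557_540": ("e557_540_heme", "heme", (25.0, 37.5)),
    "linear_fit": (None, "heme", (7.5, 37.5)),
}


def pyridine_hemochromogen(
    readouts: Union[PyridineChannels, Sequence[float]],
    mode: str = "reduced_556_heme",
    pathlength: float = 1.0,
    df: float = 1.0,
) -> QuantResult:
    """Heme (or hemoglobin) from the pyridine hemochromogen channels.

    Epsilon modes convert ``c[uM] = 1000 * A / (eps[mM^-1 cm^-1] * L)``; the
    difference mode uses the reduced-state 557 - 540 nm absorbance; the
    ``linear_fit`` mode inverts the empirical 556 nm calibration line.  The
    1:1 sample:reagent mixing of the protocol is part of the caller-supplied
    ``df`` (the published epsilon values absorb their own protocol dilution).
    """
    if mode not in PYRIDINE_MODES:
        raise ValueError(f"unknown pyridine mode {mode!r}")
    if df < 1:
        raise ValueError("dilution factor must be >= 1")
    ch = PyridineChannels(*readouts)
    eps_key, analyte, valid_range = PYRIDINE_MODES[mode]

    if mode == "linear_fit":
        res = apply_calibration(REGISTRY["pyridine_heme_linear"], ch.a556_reduced, df)
        flags = set(res.flags) - {FLAG_BELOW_RANGE, FLAG_ABOVE_RANGE}
        flags |= _range_flags(res.assay_value, valid_range)
        return QuantResult(
            analyte=analyte, concentration=res.concentration,
            method="pyridine_linear_fit", flags=frozenset(flags),
            assay_value=res.assay_value, dilution_factor=df,
        )

    if mode == "difference_557_540":
        signal = ch.a557_reduced - ch.a540_reduced
    elif mode == "published_557":
        signal = ch.a557_reduced
    else:
        signal = ch.a556_reduced
    assay_value = 1000.0 * signal / (PYRIDINE_EPSILON_MM[eps_key] * pathlength)
    conc = df * assay_value
    flags = _range_flags(assay_value, valid_range)
    if conc < 0:
        flags.add(FLAG_NEGATIVE)
    return QuantResult(
        analyte=analyte, concentration=conc, method=f"pyridine_{mode}",
        flags=frozenset(flags), assay_value=assay_value, dilution_factor=df,
    )


# --------------------------------------------------------------------------- #
# modified SLS method
# --------------------------------------------------------------------------- #


def sls_modified(
    analyte: str, signal: float, curve: CalibrationCurve, df: float = 1.0
) -> QuantResult:
    """Surfactant (SLS) method on the shifted Soret bands: heme at 395 nm,
    hemoglobin at 413 nm, via a fitted standard curve."""
    if analyte not in SLS_RANGES_UM:
        raise ValueError(f"unknown analyte {analyte!r}")
    if curve.analyte != analyte:
        raise ValueError(
            f"curve is calibrated for {curve.analyte!r}, not {analyte!r}")
    res = apply_calibration(curve, signal, df)
    flags = set(res.flags) - {FLAG_BELOW_RANGE, FLAG_ABOVE_RANGE}
    flags |= _range_flags(res.assay_value, SLS_RANGES_UM[analyte])
    return QuantResult(
        analyte=analyte, concentration=res.concentration, method="sls_modified",
        flags=frozenset(flags), assay_value=res.assay_value, dilution_factor=df,
    )


# --------------------------------------------------------------------------- #
# Heme Assay Kit
# --------------------------------------------------------------------------- #


def heme_assay_kit_total(a400: float, df: float = 1.0, parse: str = "printed") -> QuantResult:
    """Apparent total heme from the Heme Assay Kit at 400 nm (no Hb correction).

    This is the combined labile-heme estimator evaluated at ``c_hb = 0``:
    ``df * 25.64 * A400 + 4.85`` under the as-printed parse (the ``bracketed``
    parse scales the intercept with ``df`` as well; the two agree at df = 1).
    Flags follow the kit's 8-32 uM assay-side heme range.
    """
    if a400 < 0:
        raise ValueError("a400 must be >= 0")
    if df < 1:
        raise ValueError("dilution factor must be >= 1")
    if parse not in EQ1_PARSES:
        raise ValueError(f"unknown parse {parse!r}")
    assay_value = HAK_SLOPE * a400 + HAK_INTERCEPT
    if parse == "printed":
        conc = df * HAK_SLOPE * a400 + HAK_INTERCEPT
    else:
        conc = df * assay_value
    flags = _range_flags(assay_value, HAK_HEME_RANGE_UM)
    return QuantResult(
        analyte="heme", concentration=conc, method="heme_assay_kit",
        flags=frozenset(flags), assay_value=assay_value, dilution_factor=df,
    )


# --------------------------------------------------------------------------- #
# Hemastix reagent strips
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class HemastixResult:
    """Semiquantitative strip outcome; invariant within a bin."""

    category: str  # negative | positive | saturated
    flags: frozenset[str] = frozenset({FLAG_SEMIQUANT})


def hemastix_classify(c_heme: float, c_hb: float) -> HemastixResult:
    """Bin a sample by strip color response (concentrations in nM).

    Positive within heme 10-1000 nM or hemoglobin 2.5-250 nM (closed bounds);
    saturated above either upper bound; negative below both lower bounds.
    """
    if c_heme < 0 or c_hb < 0:
        raise ValueError("concentrations must be >= 0")
    heme_lo, heme_hi = HEMASTIX_HEME_RANGE_NM
    hb_lo, hb_hi = HEMASTIX_HB_RANGE_NM
    if c_heme > heme_hi or c_hb > hb_hi:
        return HemastixResult("saturated")
    if c_heme >= heme_lo or c_hb >= hb_lo:
        return HemastixResult("positive")
    return HemastixResult("negative")


# --------------------------------------------------------------------------- #
# apoHRP reconstitution assay
# --------------------------------------------------------------------------- #


def apohrp_quantify(apparent_heme_signal: float, substrate: str = "TMB") -> QuantResult:
    """apoHRP-based heme estimate (nM): identity on the apparent-heme signal
    with substrate-specific validity flags (TMB or o-dianisidine)."""
    if apparent_heme_signal < 0:
        raise ValueError("signal must be >= 0")
    if substrate not in APOHRP_RANGES_NM:
        raise ValueError(f"unknown substrate {substrate!r}")
    flags = _range_flags(apparent_heme_signal, APOHRP_RANGES_NM[substrate])
    return QuantResult(
        analyte="heme", concentration=apparent_heme_signal,
        method=f"apohrp_{substrate}", flags=frozenset(flags),
        assay_value=apparent_heme_signal, dilution_factor=1.0,
    )


def apohrp_apparent_heme_from_hb(c_hb: float) -> float:
    """Apparent heme (nM) reported by the apoHRP assay for pure hemoglobin:
    ``3.629 * c(Hb)[nM] + 21.86``, the empirical cross-reactivity relation."""
    if c_hb < 0:
        raise ValueError("c_hb must be >= 0")
    return APOHRP_HB_SLOPE * c_hb + APOHRP_HB_INTERCEPT_NM
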