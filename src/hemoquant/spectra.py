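"""Synthetic plasma absorbance spectra and assay readouts with known ground truth.

Plasma spectra are modelled as Beer-Lambert mixtures of four components on a
300-700 nm grid (1 nm step):

* **labile heme** -- a broad Soret band at 380 nm plus a weak charge-transfer
  band near 610 nm;
* **hemoglobin** (tetramer) -- an oxyhemoglobin Soret band peaking at 410 nm
  with the 541/577 nm Q bands;
* **bilirubin** -- a single visible band at 455 nm (icteric plasma);
* **turbidity** -- a Rayleigh-like ``(700/lambda)^4`` scattering baseline
  (lipemic plasma), indexed so one turbidity unit gives 1.0 AU at 700 nm
  undiluted at the default pathlength.

Band amplitudes are calibrated against the package's published evaluation
equations rather than literature extinction coefficients, so that every
downstream quantifier round-trips exactly on zero-noise synthetic data: the
hemoglobin amplitude is solved so the Harboe equation recovers the true
tetramer concentration, and the heme amplitude matches the slope of the direct
380 nm calibration curve.  The heme and bilirubin band widths are solved so
that the Harboe combination ``2*A415 - A380 - A450`` vanishes for those
species, reproducing the Harboe method's robustness to added heme and to
icteric backgrounds.

Per-assay scalar readouts (:class:`AssayReadoutSet`) are generated by forward
models that are the exact inverses of each method's evaluation equation, so
quantifier-vs-generator round trips are testable without laboratory data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .calibration import (
    APOHRP_HB_INTERCEPT_NM,
    APOHRP_HB_SLOPE,
    HAK_HB_CROSS,
    HAK_INTERCEPT,
    HAK_SLOPE,
    HARBOE_FACTOR,
    HARBOE_SCALE,
    PYRIDINE_EPSILON_MM,
    REGISTRY,
)

__all__ = [
    "GRID",
    "DILUTION_GRID",
    "DEFAULT_NOISE_SIGMA",
    "PATHLENGTH_200UL",
    "PATHLENGTH_100UL",
    "HEME_PER_TETRAMER",
    "PANEL_STATES",
    "ComponentSpectrum",
    "SampleComposition",
    "MeasuredSpectrum",
    "PyridineChannels",
    "AssayReadoutSet",
    "PanelSample",
    "build_component_library",
    "simulate_spectrum",
    "simulate_assay_readouts",
    "simulate_plasma_panel",
    "hak_signal_at_dilution",
]

# --------------------------------------------------------------------------- #
# constants
# --------------------------------------------------------------------------- #

GRID: np.ndarray = np.arange(300.0, 701.0)  # nm, 1 nm step
#: Allowed dilution factors (powers of two covering reported factors 1-72).
DILUTION_GRID: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64, 128)
#: Default per-wavelength / per-channel Gaussian noise, AU (plate-reader class).
DEFAULT_NOISE_SIGMA = 0.005
#: Effective optical pathlengths for common microplate fill volumes, cm.
PATHLENGTH_200UL = 0.58
PATHLENGTH_100UL = 0.29
DEFAULT_PATHLENGTH = PATHLENGTH_200UL
#: Heme groups per hemoglobin tetramer (ground-truth bookkeeping).
HEME_PER_TETRAMER = 4

SPECIES = ("labile-heme", "hemoglobin", "bilirubin", "turbidity")

# Generator plumbing constants for channels without a published forward model.
_PYRIDINE_557_TO_556 = 0.98     # reduced 557 nm shoulder relative to the 556 peak
_PYRIDINE_OX_TO_RED = 0.30      # oxidized-state 556 nm signal relative to reduced
SLS_SLOPE_HEME_395 = 0.022      # AU per uM heme at 395 nm
SLS_SLOPE_HB_413 = 0.150        # AU per uM Hb tetramer at 413 nm
_SLS_BAND_SIGMA = 25.0          # nm; Gaussian tails give the 395/413 cross terms
SLS_CROSS_HEME_413 = SLS_SLOPE_HEME_395 * math.exp(-((413 - 395) ** 2) / (2 * _SLS_BAND_SIGMA**2))
SLS_CROSS_HB_395 = SLS_SLOPE_HB_413 * math.exp(-((395 - 413) ** 2) / (2 * _SLS_BAND_SIGMA**2))
_APOHRP_NM_PER_AU = 100.0       # converts the AU noise sigma to the nM channel


def _gauss(lam: np.ndarray | float, center: float, sigma: float):
    lam = np.asarray(lam, dtype=float)
    return np.exp(-((lam - center) ** 2) / (2.0 * sigma**2))


@lru_cache(maxsize=None)
def _harboe_blind_sigma(center: float) -> float:
    """Band width for which 2*g(415) - g(380) - g(450) vanishes for a Gaussian
    band at ``center``; makes the species invisible to the Harboe combination."""

    def comb(sigma: float) -> float:
        g = lambda lam: math.exp(-((lam - center) ** 2) / (2.0 * sigma**2))
        return 2.0 * g(415.0) - g(380.0) - g(450.0)

    return brentq(comb, 20.0, 60.0, xtol=1e-13, rtol=8.9e-16)


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ComponentSpectrum:
    """Specific absorbance of one mixture component on the wavelength grid.

    Units are AU per uM per cm for the three chromophores and AU per unit
    turbidity index per cm for the scattering baseline.
    """

    species: str
    wavelengths: np.ndarray
    specific_absorbance: np.ndarray

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.wavelengths.shape != self.specific_absorbance.shape:
            raise ValueError("grid/absorbance length mismatch")
        if np.any(self.specific_absorbance < 0):
            raise ValueError("specific absorbance must be nonnegative")

    def at(self, wavelength: float) -> float:
        """Specific absorbance at one wavelength (linear interpolation)."""
        return float(np.interp(wavelength, self.wavelengths, self.specific_absorbance))


@dataclass(frozen=True)
class SampleComposition:
    """Ground-truth analyte content of one sample.

    Hemoglobin is in tetramer uM; total heme bookkeeping is
    ``4 * c_hb + c_labile_heme``.  ``interaction_coeff`` switches on the
    hyperchromic Hb-heme cross term at 405 nm (off by default; its magnitude
    is a free parameter of the generator).
    """

    c_labile_heme: float = 0.0   # uM
    c_hb: float = 0.0            # uM tetramer
    c_bilirubin: float = 0.0     # uM
    turbidity_index: float = 0.0
    interaction_coeff: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_labile_heme", "c_hb", "c_bilirubin", "turbidity_index"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def c_total_heme(self) -> float:
        """Total heme equivalents, uM (4 heme per tetramer)."""
        return HEME_PER_TETRAMER * self.c_hb + self.c_labile_heme


@dataclass(frozen=True)
class MeasuredSpectrum:
    """A plate-reader absorbance spectrum with its measurement metadata."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    pathlength: float = DEFAULT_PATHLENGTH
    dilution_factor: int = 1
    noise_sigma: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("grid/absorbance length mismatch")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be > 0")
        if self.dilution_factor not in DILUTION_GRID:
            raise ValueError(
                f"dilution factor {self.dilution_factor} not on the allowed grid "
                f"{DILUTION_GRID}"
            )

    def at(self, wavelength: float) -> float:
        return float(np.interp(wavelength, self.wavelengths, self.absorbance))

    def harboe_triplet(self) -> tuple[float, float, float]:
        """(A380, A415, A450) for the polychromatic Harboe correction."""
        return self.at(380.0), self.at(415.0), self.at(450.0)

    def max_absorbance(self, window: tuple[float, float] = (340.0, 700.0)) -> float:
        mask = (self.wavelengths >= window[0]) & (self.wavelengths <= window[1])
        if not mask.any():
            raise ValueError("spectrum does not cover the requested window")
        return float(self.absorbance[mask].max())

    def at_dilution(self, df: int) -> "MeasuredSpectrum":
        """The same sample re-measured at dilution ``df`` (signal rescaled)."""
        if df not in DILUTION_GRID:
            raise ValueError(f"dilution factor {df} not on the allowed grid")
        scale = self.dilution_factor / df
        return replace(self, absorbance=self.absorbance * scale, dilution_factor=df)


class PyridineChannels(NamedTuple):
    """Pyridine hemochromogen absorbances (1 cm cuvette, 1:1 reagent mix
    handled as caller-supplied dilution)."""

    a556_reduced: float
    a556_oxidized: float
    a540_reduced: float
    a557_reduced: float


@dataclass(frozen=True)
class AssayReadoutSet:
    """Scalar readouts of every assay for one sample, generated at df = 1."""

    hak_A400: float
    harboe_triplet: tuple[float, float, float]
    pyridine: PyridineChannels
    sls: tuple[float, float]            # (A395, A413)
    apohrp_apparent_heme: float         # nM equivalent
    direct: tuple[float, float]         # (A380, A405)


@dataclass(frozen=True)
class PanelSample:
    """One simulated plasma sample: ground truth plus its measurements."""

    sample_id: str
    state: str
    composition: SampleComposition
    spectrum: MeasuredSpectrum
    readouts: AssayReadoutSet


# --------------------------------------------------------------------------- #
# component library
# --------------------------------------------------------------------------- #


def _hb_shape(lam) -> np.ndarray:
    """Relative oxyhemoglobin spectrum: Soret at 410 nm plus 541/577 Q bands."""
    return (
        _gauss(lam, 410.0, 16.0)
        + 0.100 * _gauss(lam, 541.0, 12.0)
        + 0.105 * _gauss(lam, 577.0, 11.0)
    )


def _heme_shape(lam) -> np.ndarray:
    """Relative labile-heme spectrum: broad Soret at 380 nm + weak 610 nm CT band.

    The Soret width is solved so the Harboe combination vanishes for heme.
    """
    sigma = _harboe_blind_sigma(380.0)
    return _gauss(lam, 380.0, sigma) + 0.025 * _gauss(lam, 610.0, 20.0)


def _bilirubin_shape(lam) -> np.ndarray:
    sigma = _harboe_blind_sigma(455.0)
    return _gauss(lam, 455.0, sigma)


def _turbidity_shape(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    return (700.0 / lam) ** 4


def _hb_amplitude() -> float:
    """Amplitude (AU/uM/cm) making the Harboe equation exact at the default
    pathlength: 0.155 * 83.6 * (2*eps415 - eps380 - eps450) * L = 1."""
    comb = float(2.0 * _hb_shape(415.0) - _hb_shape(380.0) - _hb_shape(450.0))
    return 1.0 / (HARBOE_FACTOR * HARBOE_SCALE * comb * DEFAULT_PATHLENGTH)


def _heme_amplitude() -> float:
    """Amplitude matching the direct 380 nm calibration slope at the default
    pathlength (the printed intercept is an instrument blank, not simulated)."""
    slope = REGISTRY["direct_heme_380"].slope  # AU per uM
    return slope / (float(_heme_shape(380.0)) * DEFAULT_PATHLENGTH)


_BILIRUBIN_EPS_455 = 0.055  # AU/uM/cm (visible-band extinction of bilirubin)


def build_component_library(grid: Optional[Sequence[float]] = None) -> Mapping[str, ComponentSpectrum]:
    """Return the four calibrated component spectra on ``grid`` (default 300-700 nm).

    Raises ``ValueError`` if the grid does not cover 300-700 nm.
    """
    lam = GRID if grid is None else np.asarray(grid, dtype=float)
    if lam.min() > 300.0 or lam.max() < 700.0:
        raise ValueError("wavelength grid must cover 300-700 nm")
    lib = {
        "labile-heme": ComponentSpectrum(
            "labile-heme", lam, _heme_amplitude() * _heme_shape(lam)),
        "hemoglobin": ComponentSpectrum(
            "hemoglobin", lam, _hb_amplitude() * _hb_shape(lam)),
        "bilirubin": ComponentSpectrum(
            "bilirubin", lam,
            _BILIRUBIN_EPS_455 / float(_bilirubin_shape(455.0)) * _bilirubin_shape(lam)),
        "turbidity": ComponentSpectrum(
            "turbidity", lam, _turbidity_shape(lam) / DEFAULT_PATHLENGTH),
    }
    return lib


# --------------------------------------------------------------------------- #
# forward models
# --------------------------------------------------------------------------- #


def simulate_spectrum(
    comp: SampleComposition,
    pathlength: float = DEFAULT_PATHLENGTH,
    df: int = 1,
    sigma: float = DEFAULT_NOISE_SIGMA,
    seed: Optional[int] = None,
    grid: Optional[Sequence[float]] = None,
) -> MeasuredSpectrum:
    """Beer-Lambert mixture spectrum of one sample.

    ``A(lambda) = L * sum_s eps_s(lambda) * c_s / df`` plus the turbidity
    baseline, the optional hyperchromic Hb-heme cross term at 405 nm, and
    i.i.d. Gaussian noise of standard deviation ``sigma`` (AU).  Deterministic
    for a fixed seed; a zero composition at zero noise is the zero spectrum.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    lib = build_component_library(grid)
    lam = next(iter(lib.values())).wavelengths
    conc = {
        "labile-heme": comp.c_labile_heme,
        "hemoglobin": comp.c_hb,
        "bilirubin": comp.c_bilirubin,
        "turbidity": comp.turbidity_index,
    }
    a = np.zeros_like(lam)
    for species, c in conc.items():
        if c:
            a = a + lib[species].specific_absorbance * c
    a = a * (pathlength / df)
    if comp.interaction_coeff:
        a = a + (
            comp.interaction_coeff
            * (comp.c_hb / df) * (comp.c_labile_heme / df)
            * pathlength * _gauss(lam, 405.0, 16.0)
        )
    if sigma > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, sigma, size=lam.shape)
    return MeasuredSpectrum(
        wavelengths=lam, absorbance=a, pathlength=pathlength,
        dilution_factor=df, noise_sigma=sigma, seed=seed,
    )


def hak_signal_at_dilution(a400_undiluted: float, df: int) -> float:
    """Heme Assay Kit absorbance after diluting the sample by ``df``.

    The kit responds to the assay-side total ``c = c_labile + 2.59 * c_hb`` as
    ``A400 = (c - 4.85) / 25.64`` (clamped at 0 AU), so dilution acts on the
    concentration, not linearly on the signal.
    """
    apparent = HAK_SLOPE * a400_undiluted + HAK_INTERCEPT  # assay-side uM at df=1
    return max(0.0, (apparent / df - HAK_INTERCEPT) / HAK_SLOPE)


def simulate_assay_readouts(
    comp: SampleComposition,
    sigma: float = DEFAULT_NOISE_SIGMA,
    seed: Optional[int] = None,
) -> AssayReadoutSet:
    """Forward-model every assay readout for one sample at df = 1.

    Each channel is the exact inverse of the corresponding evaluation equation
    (direct curves, Harboe via the spectral model, pyridine epsilon relations,
    Heme Assay Kit response, apoHRP cross-reactivity), clamped at zero signal,
    with independent Gaussian noise of ``sigma`` AU added per channel (the
    apoHRP channel converts at 100 nM per AU).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    heq = comp.c_total_heme  # uM heme equivalents

    d_heme = REGISTRY["direct_heme_380"]
    d_hb = REGISTRY["direct_hb_405"]
    direct = (
        max(0.0, d_heme.signal_at(comp.c_labile_heme)),
        max(0.0, d_hb.signal_at(comp.c_hb)),
    )

    zero_noise = simulate_spectrum(comp, sigma=0.0)
    harboe = zero_noise.harboe_triplet()

    a556r = PYRIDINE_EPSILON_MM["e556_heme"] * heq / 1000.0  # 1 cm cuvette
    a557r = _PYRIDINE_557_TO_556 * a556r
    a540r = a557r - PYRIDINE_EPSILON_MM["e557_540_heme"] * heq / 1000.0
    pyridine = PyridineChannels(a556r, _PYRIDINE_OX_TO_RED * a556r, a540r, a557r)

    sls = (
        SLS_SLOPE_HEME_395 * comp.c_labile_heme + SLS_CROSS_HB_395 * comp.c_hb,
        SLS_SLOPE_HB_413 * comp.c_hb + SLS_CROSS_HEME_413 * comp.c_labile_heme,
    )

    apohrp = (
        APOHRP_HB_SLOPE * comp.c_hb * 1000.0
        + APOHRP_HB_INTERCEPT_NM
        + comp.c_labile_heme * 1000.0
    )

    hak = max(0.0, (comp.c_labile_heme + HAK_HB_CROSS * comp.c_hb - HAK_INTERCEPT) / HAK_SLOPE)

    if sigma > 0:
        rng = np.random.default_rng(seed)
        noise = lambda: float(rng.normal(0.0, sigma))
        hak += noise()
        harboe = tuple(v + noise() for v in harboe)
        pyridine = PyridineChannels(*(v + noise() for v in pyridine))
        sls = tuple(v + noise() for v in sls)
        apohrp += noise() * _APOHRP_NM_PER_AU
        direct = tuple(v + noise() for v in direct)

    return AssayReadoutSet(
        hak_A400=hak, harboe_triplet=tuple(harboe), pyridine=pyridine,
        sls=tuple(sls), apohrp_apparent_heme=apohrp, direct=tuple(direct),
    )


# --------------------------------------------------------------------------- #
# plasma panel generator
# --------------------------------------------------------------------------- #

#: Hemolysis-state concentration ranges (log-uniform draws), uM except the
#: dimensionless turbidity index.  Anchored to the reported plasma panels:
#: non-hemolytic < 5 uM Hb, severe > 100 uM Hb with heme up to ~1056 uM,
#: icteric samples with very low Hb (~0.3-3 uM) and ~30-44 uM heme.
PANEL_STATES: Mapping[str, dict] = {
    "non-hemolytic": {"hb": (0.3, 5.0), "heme": (1.0, 20.0)},
    "mild": {"hb": (5.0, 100.0), "heme": (20.0, 250.0)},
    "severe": {"hb": (100.0, 1080.0), "heme": (154.0, 1056.0)},
    "icteric": {"hb": (0.3, 3.0), "heme": (30.0, 44.0), "bilirubin": (50.0, 300.0)},
    "lipemic": {"hb": (0.3, 10.0), "heme": (1.0, 40.0), "turbidity": (0.5, 3.0)},
}

DEFAULT_STATE_WEIGHTS: Mapping[str, float] = {
    "non-hemolytic": 0.30, "mild": 0.25, "severe": 0.20,
    "icteric": 0.15, "lipemic": 0.10,
}


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def simulate_plasma_panel(
    n: int,
    state_weights: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
) -> list[PanelSample]:
    """Simulate ``n`` plasma samples across hemolysis states with ground truth.

    States are drawn from ``state_weights`` (must sum to 1 over known states);
    concentrations are drawn log-uniformly within the state-specific ranges.
    Bit-reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = dict(DEFAULT_STATE_WEIGHTS if state_weights is None else state_weights)
    unknown = set(weights) - set(PANEL_STATES)
    if unknown:
        raise ValueError(f"unknown states: {sorted(unknown)}")
    w = np.array([weights.get(s, 0.0) for s in PANEL_STATES], dtype=float)
    if np.any(w < 0) or not math.isclose(w.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("state weights must be nonnegative and sum to 1")

    rng = np.random.default_rng(seed)
    states = list(PANEL_STATES)
    width = max(3, len(str(n)))
    panel: list[PanelSample] = []
    for i in range(n):
        state = states[int(rng.choice(len(states), p=w / w.sum()))]
        ranges = PANEL_STATES[state]
        comp = SampleComposition(
            c_hb=_log_uniform(rng, *ranges["hb"]),
            c_labile_heme=_log_uniform(rng, *ranges["heme"]),
            c_bilirubin=_log_uniform(rng, *ranges["bilirubin"]) if "bilirubin" in ranges else 0.0,
            turbidity_index=_log_uniform(rng, *ranges["turbidity"]) if "turbidity" in ranges else 0.0,
        )
        spec_seed = int(rng.integers(2**31))
        readout_seed = int(rng.integers(2**31))
        spectrum = simulate_spectrum(comp, sigma=noise_sigma, seed=spec_seed)
        readouts = simulate_assay_readouts(comp, sigma=noise_sigma, seed=readout_seed)
        panel.append(PanelSample(
            sample_id=f"S{i + 1:0{width}d}", state=state, composition=comp,
            spectrum=spectrum, readouts=readouts,
        ))
    return panel
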