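"""Canine photoreceptor spectral sensitivities, pre-receptoral filtering,
excitations, and photoreceptor contrasts.

The dog is a dichromat with an L/M ("L") cone, an S cone, rods, and
melanopsin-expressing ipRGCs.  Spectral sensitivities are modeled with the
A1 visual-pigment nomogram (alpha band as a sum of exponential terms plus a
Gaussian beta band), peak wavelengths 555, 429, 506 and 480 nm for L, S,
rod and melanopsin respectively.  Pre-receptoral filtering by the canine
crystalline lens is applied as a pointwise transmittance product before
excitations are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Photopigment",
    "SpectralSensitivity",
    "LensTransmittance",
    "ExcitationVector",
    "ContrastReport",
    "CANINE_PIGMENTS",
    "A1_TEMPLATE_PARAMS",
    "default_grid",
    "pigment_template",
    "sigmoidal_lens",
    "apply_prereceptoral_filter",
    "excitation",
    "contrast",
    "canine_sensitivities",
]

# Default wavelength support: 380-780 nm at 2 nm, rectangular summation.
GRID_MIN_NM = 380.0
GRID_MAX_NM = 780.0
GRID_STEP_NM = 2.0

#: A1 pigment template constants: alpha band 1/(sum of exponentials + D)
#: in x = lambda_max / lambda, beta band Gaussian in lambda.  Stored as
#: data so alternative template fits can be swapped in via config.
A1_TEMPLATE_PARAMS: dict[str, float] = {
    "A": 69.7,
    "B": 28.0,
    "b": 0.922,
    "C": -14.9,
    "c": 1.104,
    "D": 0.674,
    # a = a0 + a1 * exp(-(lambda_max - a2)^2 / a3)
    "a0": 0.8795,
    "a1": 0.0459,
    "a2": 300.0,
    "a3": 11940.0,
    # beta band: A_beta * exp(-((lambda - (m0 + m1*lmax)) / (s0 + s1*lmax))^2)
    "A_beta": 0.26,
    "m0": 189.0,
    "m1": 0.315,
    "s0": -40.5,
    "s1": 0.195,
}


class InvalidGridError(ValueError):
    """Wavelength grid is not strictly increasing / uniformly spaced."""


class NoOverlapError(ValueError):
    """Two spectral quantities share no wavelength range."""


class InvalidSpectrumError(ValueError):
    """Spectral power is negative where it must be non-negative."""


@dataclass(frozen=True)
class Photopigment:
    """A visual pigment identified by its peak wavelength.

    Parameters
    ----------
    name:
        Mechanism label ("L", "S", "rod", "mel").
    lambda_max:
        Wavelength of peak sensitivity, nm.  Must lie in (300, 700).
    template_params:
        Template constants; defaults to the A1 set.
    """

    name: str
    lambda_max: float
    template_params: dict[str, float] = field(default_factory=lambda: dict(A1_TEMPLATE_PARAMS))

    def __post_init__(self) -> None:
        if not (300.0 < self.lambda_max < 700.0):
            raise ValueError(f"lambda_max {self.lambda_max} nm outside template validity (300, 700)")


#: Canonical canine pigment set.
CANINE_PIGMENTS: dict[str, Photopigment] = {
    "L": Photopigment("L", 555.0),
    "S": Photopigment("S", 429.0),
    "rod": Photopigment("rod", 506.0),
    "mel": Photopigment("mel", 480.0),
}


@dataclass(frozen=True)
class SpectralSensitivity:
    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        _check_grid(wl)
        if v.shape != wl.shape:
            raise ValueError("values and wavelengths must have identical shape")
        if np.any(v < 0):
            raise ValueError("sensitivity values must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class LensTransmittance:
    wavelengths: np.ndarray
    transmittance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        t = np.asarray(self.transmittance, dtype=float)
        _check_grid(wl)
        if np.any((t < 0) | (t > 1)):
            raise ValueError("transmittance must lie in [0, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "transmittance", t)


@dataclass(frozen=True)
class ExcitationVector:
    """Per-pigment excitation in arbitrary linear units."""

    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass(frozen=True)
class ContrastReport:
    """Per-pigment bipolar Weber contrast plus the unipolar contrast of each arm.

    ``bipolar[p] = (e_p(pos) - e_p(neg)) / (2 e_p(background))``;
    ``unipolar_pos`` / ``unipolar_neg`` are each arm's Weber contrast against
    the background.  Which pigments were targeted vs nominally silenced is
    carried alongside for reporting.
    """

    bipolar: dict[str, float]
    unipolar_pos: dict[str, float]
    unipolar_neg: dict[str, float]
    targeted: tuple[str, ...] = ()
    silenced: tuple[str, ...] = ()

    def max_abs_silenced(self) -> float:
        if not self.silenced:
            return 0.0
        return max(abs(self.bipolar[p]) for p in self.silenced)

    def min_abs_targeted(self) -> float:
        if not self.targeted:
            return 0.0
        return min(abs(self.bipolar[p.lstrip("+-")]) for p in self.targeted)


def default_grid() -> np.ndarray:
    """380-780 nm wavelength grid at 2 nm step."""
    return np.arange(GRID_MIN_NM, GRID_MAX_NM + GRID_STEP_NM / 2, GRID_STEP_NM)


def _check_grid(wl: np.ndarray) -> None:
    if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
        raise InvalidGridError("wavelength grid must be 1-D and strictly increasing")


def pigment_template(pigment: Photopigment, grid: np.ndarray | None = None) -> SpectralSensitivity:
    """Evaluate the A1 pigment template on a wavelength grid.

    The alpha band is ``1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D)``
    with ``x = lambda_max / lambda`` and ``a`` a mild function of lambda_max;
    the beta band is a Gaussian in wavelength whose center and width are
    linear in lambda_max.  The sum is peak-normalized to 1.
    """
    if grid is None:
        grid = default_grid()
    wl = np.asarray(grid, dtype=float)
    _check_grid(wl)
    p = pigment.template_params
    lmax = pigment.lambda_max
    x = lmax / wl
    a = p["a0"] + p["a1"] * np.exp(-((lmax - p["a2"]) ** 2) / p["a3"])
    alpha = 1.0 / (
        np.exp(p["A"] * (a - x))
        + np.exp(p["B"] * (p["b"] - x))
        + np.exp(p["C"] * (p["c"] - x))
        + p["D"]
    )
    m_beta = p["m0"] + p["m1"] * lmax
    s_beta = p["s0"] + p["s1"] * lmax
    beta = p["A_beta"] * np.exp(-(((wl - m_beta) / s_beta) ** 2))
    s = alpha + beta
    return SpectralSensitivity(wl, s / s.max())


def sigmoidal_lens(
    grid: np.ndarray | None = None,
    half_height_nm: float = 400.0,
    slope_nm: float = 10.0,
) -> LensTransmittance:
    """Parametric canine lens transmittance: logistic short-wave cutoff.

    Transmittance is effectively unity above ~500 nm and falls sigmoidally
    toward the UV with half-height at ``half_height_nm``.
    """
    if grid is None:
        grid = default_grid()
    wl = np.asarray(grid, dtype=float)
    t = 1.0 / (1.0 + np.exp(-(wl - half_height_nm) / slope_nm))
    return LensTransmittance(wl, t)


def _resample(wl_from: np.ndarray, v: np.ndarray, wl_to: np.ndarray) -> np.ndarray:
    if wl_to[0] > wl_from[-1] or wl_to[-1] < wl_from[0]:
        raise NoOverlapError("wavelength ranges do not overlap")
    return np.interp(wl_to, wl_from, v)


def apply_prereceptoral_filter(
    s: SpectralSensitivity, t: LensTransmittance
) -> SpectralSensitivity:
    """Pointwise product of a sensitivity with a transmittance.

    The result is *not* re-normalized: filtering shifts and lowers the
    effective peak, which is the physically meaningful curve for excitation.
    Grids are resampled onto the sensitivity's grid when they differ.
    """
    tv = (
        t.transmittance
        if np.array_equal(t.wavelengths, s.wavelengths)
        else _resample(t.wavelengths, t.transmittance, s.wavelengths)
    )
    out = s.values * tv
    obj = object.__new__(SpectralSensitivity)
    object.__setattr__(obj, "wavelengths", s.wavelengths)
    object.__setattr__(obj, "values", out)
    return obj


def canine_sensitivities(
    grid: np.ndarray | None = None,
    lens: LensTransmittance | None = None,
    pigments: dict[str, Photopigment] | None = None,
) -> dict[str, SpectralSensitivity]:
    """Filtered sensitivities for the canonical canine pigment set."""
    if grid is None:
        grid = default_grid()
    if pigments is None:
        pigments = CANINE_PIGMENTS
    if lens is None:
        lens = sigmoidal_lens(grid)
    return {
        name: apply_prereceptoral_filter(pigment_template(pig, grid), lens)
        for name, pig in pigments.items()
    }


def excitation(
    spectrum: np.ndarray,
    sensitivities: dict[str, SpectralSensitivity],
    grid: np.ndarray | None = None,
) -> ExcitationVector:
    """Photoreceptor excitations: e_p = sum_lambda S_p(l) Phi(l) dl.

    Rectangular summation on the shared uniform grid; ``spectrum`` must be
    non-negative.
    """
    phi = np.asarray(spectrum, dtype=float)
    if np.any(phi < -1e-12 * max(1.0, np.abs(phi).max(initial=0.0))):
        raise InvalidSpectrumError("spectral power must be non-negative")
    out: dict[str, float] = {}
    for name, s in sensitivities.items():
        wl = s.wavelengths
        if grid is not None and not np.array_equal(np.asarray(grid, float), wl):
            phi_p = _resample(np.asarray(grid, float), phi, wl)
        else:
            phi_p = phi
        if phi_p.shape != wl.shape:
            raise ValueError("spectrum length does not match sensitivity grid")
        dlam = wl[1] - wl[0]
        out[name] = float(np.sum(s.values * np.clip(phi_p, 0.0, None)) * dlam)
    return ExcitationVector(out)


def contrast(
    arm_pos: np.ndarray,
    arm_neg: np.ndarray,
    background: np.ndarray,
    sensitivities: dict[str, SpectralSensitivity],
    targeted: tuple[str, ...] = (),
    silenced: tuple[str, ...] = (),
) -> ContrastReport:
    """Bipolar and unipolar Weber contrasts of a spectral modulation.

    All three spectra must share the sensitivities' grid.  Background
    excitation must be strictly positive for every pigment.
    """
    e_pos = excitation(arm_pos, sensitivities)
    e_neg = excitation(arm_neg, sensitivities)
    e_bg = excitation(background, sensitivities)
    bipolar: dict[str, float] = {}
    uni_pos: dict[str, float] = {}
    uni_neg: dict[str, float] = {}
    for name in sensitivities:
        eb = e_bg[name]
        if eb <= 0:
            raise ZeroDivisionError(f"zero background excitation for pigment {name!r}")
        bipolar[name] = (e_pos[name] - e_neg[name]) / (2.0 * eb)
        uni_pos[name] = (e_pos[name] - eb) / eb
        uni_neg[name] = (e_neg[name] - eb) / eb
    return ContrastReport(bipolar, uni_pos, uni_neg, tuple(targeted), tuple(silenced))
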