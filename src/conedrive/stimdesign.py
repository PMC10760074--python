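"""Silent-substitution modulation design on a multiprimary device, plus
temporal waveform construction for the pupillometry and fMRI protocols.

A modulation is a symmetric pair of device-settings vectors around a fixed
half-on background: ``pos = bg + d`` and ``neg = bg - d``.  Because device
output is linear in settings and the background is fixed, the bipolar Weber
contrast on every pigment is linear in ``d``; the design problem — maximize
the minimum targeted contrast subject to silencing constraints and the
settings gamut — is solved by a seeded multi-start constrained search
(SLSQP on the epigraph form).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .photoreceptors import (
    ContrastReport,
    SpectralSensitivity,
    contrast,
)

__all__ = [
    "DeviceModel",
    "SpectralModulation",
    "TemporalProfile",
    "InfeasibleModulationError",
    "design_modulation",
    "make_waveform",
    "validate_modulation",
]


class InfeasibleModulationError(RuntimeError):
    """Silencing tolerance unattainable within the device gamut."""

    def __init__(self, message: str, residuals: dict[str, float]):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class DeviceModel:
    """Linear multiprimary light engine.

    ``spectrum(w) = nd_factor * (primaries @ w + dark_light)`` for settings
    ``w`` with per-primary bounds [0, 1].
    """

    wavelengths: np.ndarray
    primaries: np.ndarray  # (n_wavelengths, n_primaries)
    nd_factor: float = 1.0
    dark_light: np.ndarray | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.primaries, dtype=float)
        if np.any(P < 0):
            raise ValueError("primary spectra must be non-negative")
        object.__setattr__(self, "primaries", P)
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))
        if self.dark_light is None:
            object.__setattr__(self, "dark_light", np.zeros(P.shape[0]))

    @property
    def n_primaries(self) -> int:
        return self.primaries.shape[1]

    def spectrum(self, settings: np.ndarray) -> np.ndarray:
        w = np.asarray(settings, dtype=float)
        return self.nd_factor * (self.primaries @ w + self.dark_light)


@dataclass(frozen=True)
class SpectralModulation:
    background_settings: np.ndarray
    pos_settings: np.ndarray
    neg_settings: np.ndarray
    targeted: tuple[str, ...]
    silenced: tuple[str, ...]
    contrast_report: ContrastReport

    def __post_init__(self) -> None:
        bg = np.asarray(self.background_settings, float)
        pos = np.asarray(self.pos_settings, float)
        neg = np.asarray(self.neg_settings, float)
        if not np.allclose(pos + neg, 2 * bg, atol=1e-9):
            raise ValueError("modulation arms must be symmetric about the background")
        for w in (bg, pos, neg):
            if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
                raise ValueError("settings outside [0, 1] gamut")


@dataclass(frozen=True)
class TemporalProfile:
    """Temporal structure of a stimulus presentation.

    ``sinusoid``: slow sinusoidal transition between the two arms
    (pupillometry; 1/6 Hz, 360 s).  ``blocked_flicker``: square-wave
    alternation between the arms at the flicker frequency, gated by 12 s
    on / 12 s off blocks with 1.5 s half-cosine ramps (fMRI; 432 s).
    """

    kind: str = "sinusoid"
    frequency: float = 1.0 / 6.0
    duration: float = 360.0
    block_on: float = 12.0
    block_off: float = 12.0
    ramp: float = 1.5
    sample_rate: float = 60.0

    def __post_init__(self) -> None:
        if self.kind not in ("sinusoid", "blocked_flicker"):
            raise ValueError(f"unknown temporal profile kind {self.kind!r}")
        if self.kind == "blocked_flicker" and self.ramp > self.block_on / 2:
            raise ValueError("ramp longer than half the on-block")
        if self.sample_rate < 2 * self.frequency:
            raise ValueError("sample_rate below Nyquist for the flicker frequency")


def _contrast_matrix(
    device: DeviceModel,
    background: np.ndarray,
    sensitivities: dict[str, SpectralSensitivity],
) -> tuple[list[str], np.ndarray]:
    """Rows map a settings perturbation d to bipolar contrast per pigment."""
    wl = device.wavelengths
    dlam = wl[1] - wl[0]
    names = list(sensitivities)
    S = np.stack([sensitivities[n].values for n in names])  # (n_pig, n_wl)
    M = (S @ device.primaries) * dlam * device.nd_factor  # (n_pig, n_prim)
    e_bg = M @ background + device.nd_factor * (S @ device.dark_light) * dlam
    if np.any(e_bg <= 0):
        raise ZeroDivisionError("background excitation must be strictly positive")
    return names, M / e_bg[:, None]


def _parse_signs(targeted: tuple[str, ...]) -> tuple[list[str], np.ndarray]:
    """'L' or '+L' → +1, '-S' → −1 (opponent mode)."""
    names, signs = [], []
    for t in targeted:
        if t.startswith("-"):
            names.append(t[1:])
            signs.append(-1.0)
        else:
            names.append(t.lstrip("+"))
            signs.append(1.0)
    return names, np.asarray(signs)


def design_modulation(
    device: DeviceModel,
    targeted: tuple[str, ...],
    silenced: tuple[str, ...],
    sensitivities: dict[str, SpectralSensitivity],
    tolerance: float = 1e-3,
    background_settings: np.ndarray | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> SpectralModulation:
    """Design a silent-substitution modulation by constrained max-min search.

    Maximizes the minimum signed contrast on the targeted pigments while
    holding every silenced pigment's |contrast| within ``tolerance`` and all
    settings within the gamut.  Targeted labels may carry a leading ``-``
    to request opponent (opposite-sign) drive, e.g. ``("L", "-S")``.
    Multi-start (seeded) to mitigate local minima; deterministic for a
    given seed.
    """
    t_names, t_signs = _parse_signs(tuple(targeted))
    silenced = tuple(silenced)
    if set(t_names) & set(silenced):
        raise ValueError("targeted and silenced pigment sets must be disjoint")
    n = device.n_primaries
    bg = (
        0.5 * np.ones(n)
        if background_settings is None
        else np.asarray(background_settings, dtype=float)
    )
    names, C = _contrast_matrix(device, bg, sensitivities)
    idx = {p: i for i, p in enumerate(names)}
    Ct = np.array([t_signs[k] * C[idx[p]] for k, p in enumerate(t_names)])
    Cs = np.array([C[idx[p]] for p in silenced]).reshape(len(silenced), n)
    lo, hi = -np.minimum(bg, 1 - bg), np.minimum(bg, 1 - bg)

    # epigraph: variables z = (d, t); maximize t s.t. Ct @ d >= t, |Cs @ d| <= tol
    def neg_obj(z):
        return -z[-1]

    def neg_obj_grad(z):
        g = np.zeros(n + 1)
        g[-1] = -1.0
        return g

    cons = [
        {
            "type": "ineq",
            "fun": lambda z: Ct @ z[:n] - z[-1],
            "jac": lambda z: np.hstack([Ct, -np.ones((Ct.shape[0], 1))]),
        }
    ]
    if len(silenced):
        cons.append(
            {
                "type": "ineq",
                "fun": lambda z: tolerance - Cs @ z[:n],
                "jac": lambda z: np.hstack([-Cs, np.zeros((Cs.shape[0], 1))]),
            }
        )
        cons.append(
            {
                "type": "ineq",
                "fun": lambda z: tolerance + Cs @ z[:n],
                "jac": lambda z: np.hstack([Cs, np.zeros((Cs.shape[0], 1))]),
            }
        )
    bounds = list(zip(lo, hi)) + [(None, None)]

    rng = np.random.default_rng(seed)
    best_z, best_val = None, -np.inf
    for start in range(max(1, n_starts)):
        d0 = np.zeros(n) if start == 0 else rng.uniform(lo, hi)
        if len(silenced):  # project start toward the silencing subspace
            d0 = d0 - Cs.T @ np.linalg.lstsq(Cs @ Cs.T, Cs @ d0, rcond=None)[0]
            d0 = np.clip(d0, lo, hi)
        z0 = np.hstack([d0, min(Ct @ d0) if len(t_names) else 0.0])
        res = minimize(
            neg_obj,
            z0,
            jac=neg_obj_grad,
            bounds=bounds,
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 300, "ftol": 1e-10},
        )
        d = np.clip(res.x[:n], lo, hi)
        sil_ok = (not len(silenced)) or np.all(np.abs(Cs @ d) <= tolerance * (1 + 1e-6))
        val = min(Ct @ d) if len(t_names) else 0.0
        if sil_ok and val > best_val:
            best_val, best_z = val, d
    if best_z is None or best_val <= 0:
        resid = {p: float(abs((Cs @ (best_z if best_z is not None else np.zeros(n)))[j]))
                 for j, p in enumerate(silenced)}
        raise InfeasibleModulationError(
            "no feasible modulation with positive targeted contrast", resid
        )
    d = best_z
    pos, neg = bg + d, bg - d
    report = contrast(
        device.spectrum(pos),
        device.spectrum(neg),
        device.spectrum(bg),
        sensitivities,
        targeted=tuple(targeted),
        silenced=silenced,
    )
    return SpectralModulation(bg, pos, neg, tuple(targeted), silenced, report)


def light_flux_modulation(
    device: DeviceModel,
    sensitivities: dict[str, SpectralSensitivity],
    contrast_level: float = 0.95,
    background_settings: np.ndarray | None = None,
) -> SpectralModulation:
    """Scaling modulation: arms (1 +/- c) * background, equal contrast on all pigments."""
    n = device.n_primaries
    bg = (
        0.5 * np.ones(n)
        if background_settings is None
        else np.asarray(background_settings, dtype=float)
    )
    d = contrast_level * bg
    report = contrast(
        device.spectrum(bg + d),
        device.spectrum(bg - d),
        device.spectrum(bg),
        sensitivities,
        targeted=tuple(sensitivities),
        silenced=(),
    )
    return SpectralModulation(bg, bg + d, bg - d, tuple(sensitivities), (), report)


def make_waveform(
    profile: TemporalProfile, modulation: SpectralModulation
) -> tuple[np.ndarray, np.ndarray]:
    """Time-indexed settings trajectory for a modulation.

    Returns ``(t, settings)`` with settings of shape (n_samples, n_primaries).

    sinusoid: ``settings(t) = bg + sin(2 pi f t) * (pos - bg)``.
    blocked_flicker: square-wave alternation between the arms at the flicker
    frequency, gated on/off in blocks with half-cosine onset/offset
    envelopes; background between blocks.
    """
    t = np.arange(0.0, profile.duration, 1.0 / profile.sample_rate)
    bg = np.asarray(modulation.background_settings, float)
    d = np.asarray(modulation.pos_settings, float) - bg
    if profile.kind == "sinusoid":
        mod = np.sin(2 * np.pi * profile.frequency * t)
    else:
        cycle = profile.block_on + profile.block_off
        t_in = np.mod(t, cycle)
        on = t_in < profile.block_on
        env = np.zeros_like(t)
        ramp = profile.ramp
        rising = on & (t_in < ramp)
        falling = on & (t_in > profile.block_on - ramp)
        env[on] = 1.0
        if ramp > 0:
            env[rising] = 0.5 * (1 - np.cos(np.pi * t_in[rising] / ramp))
            env[falling] = 0.5 * (
                1 - np.cos(np.pi * (profile.block_on - t_in[falling]) / ramp)
            )
        square = np.sign(np.sin(2 * np.pi * profile.frequency * t))
        mod = env * square
    return t, bg[None, :] + mod[:, None] * d[None, :]


def block_envelope(profile: TemporalProfile, t: np.ndarray) -> np.ndarray:
    """On/off block gating envelope (half-cosine ramps) evaluated at times t."""
    cycle = profile.block_on + profile.block_off
    t_in = np.mod(np.asarray(t, float), cycle)
    on = t_in < profile.block_on
    env = np.where(on, 1.0, 0.0)
    r = profile.ramp
    if r > 0:
        rising = on & (t_in < r)
        falling = on & (t_in > profile.block_on - r)
        env = np.where(rising, 0.5 * (1 - np.cos(np.pi * t_in / r)), env)
        env = np.where(
            falling, 0.5 * (1 - np.cos(np.pi * (profile.block_on - t_in) / r)), env
        )
    return env


def validate_modulation(
    modulation: SpectralModulation,
    device: DeviceModel,
    sensitivities: dict[str, SpectralSensitivity],
    perturbation_sd: float = 0.01,
    n_draws: int = 200,
    seed: int = 0,
) -> dict:
    """Monte-Carlo robustness of a modulation to primary-spectrum imprecision.

    Each draw perturbs every primary multiplicatively by N(1, perturbation_sd)
    (independently per primary) and re-evaluates the realized contrasts.
    Returns the per-draw bipolar contrasts and quantiles of the worst
    silenced-pigment |contrast|.
    """
    if perturbation_sd < 0:
        raise ValueError("perturbation magnitude must be non-negative")
    rng = np.random.default_rng(seed)
    draws = []
    worst_silenced = []
    for _ in range(n_draws):
        gains = (
            np.ones(device.n_primaries)
            if perturbation_sd == 0
            else rng.normal(1.0, perturbation_sd, device.n_primaries)
        )
        dev = DeviceModel(
            device.wavelengths,
            device.primaries * np.clip(gains, 0.0, None)[None, :],
            device.nd_factor,
            device.dark_light,
        )
        rep = contrast(
            dev.spectrum(modulation.pos_settings),
            dev.spectrum(modulation.neg_settings),
            dev.spectrum(modulation.background_settings),
            sensitivities,
            targeted=modulation.targeted,
            silenced=modulation.silenced,
        )
        draws.append(rep.bipolar)
        worst_silenced.append(rep.max_abs_silenced())
    worst = np.asarray(worst_silenced)
    return {
        "draws": draws,
        "max_abs_silenced_quantiles": {
            "q50": float(np.quantile(worst, 0.50)),
            "q95": float(np.quantile(worst, 0.95)),
            "max": float(worst.max()),
        },
    }
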