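"""Synthetic study generator: a simulated multiprimary light engine,
pupillometry sessions, and blocked-flicker BOLD sessions under canine
retinal-disease presets.

Disease presets carry multiplicative response gains per photoreceptor
mechanism (L, S, rod, melanopsin).  The wild-type preset has unit gains;
RCD1 (rod-cone dysplasia) has severe rod loss with spared cones; XLPRA2
has partial cone and rod loss; CRD2 (cone-rod dystrophy) has essentially
complete cone loss; CRD2_treated restores function in the treated (left)
eye only.  The gains are nominal, documented free parameters — the source
disease descriptions are qualitative.

All outputs are deterministic given the seed, and every emitted file is
readable by the corresponding analysis stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .boldmodel import HrfBasis, StimulusDesign, build_design, hrf_basis
from .boldprep import BoldSeries
from .pupil import FRAME_RATE_HZ, PUPIL_FREQ_HZ, PupilTimeSeries
from .stimdesign import DeviceModel

__all__ = [
    "DiseasePreset",
    "SessionSpec",
    "PupilResponseParams",
    "BoldMapParams",
    "PRESETS",
    "synth_device",
    "synth_pupil_session",
    "synth_bold_session",
    "synth_border_points",
    "default_cortex_mask",
    "default_lgn_mask",
]


@dataclass(frozen=True)
class DiseasePreset:
    """Mechanism response gains of a disease model, optionally per-eye."""

    name: str
    gains: dict[str, float]  # {L, S, rod, mel} in [0, 1]
    eye_gain: dict[str, float] = field(default_factory=lambda: {"left": 1.0, "right": 1.0})

    def __post_init__(self) -> None:
        for g in self.gains.values():
            if not (0.0 <= g <= 1.0):
                raise ValueError("mechanism gains must lie in [0, 1]")


PRESETS: dict[str, DiseasePreset] = {
    "WT": DiseasePreset("WT", {"L": 1.0, "S": 1.0, "rod": 1.0, "mel": 1.0}),
    "RCD1": DiseasePreset("RCD1", {"L": 1.0, "S": 1.0, "rod": 0.05, "mel": 1.0}),
    "XLPRA2": DiseasePreset("XLPRA2", {"L": 0.4, "S": 0.4, "rod": 0.3, "mel": 1.0}),
    "CRD2": DiseasePreset("CRD2", {"L": 0.0, "S": 0.0, "rod": 0.05, "mel": 1.0}),
    # gene therapy to the left eye restores cone-driven response there only
    "CRD2_treated": DiseasePreset(
        "CRD2_treated",
        {"L": 1.0, "S": 1.0, "rod": 0.05, "mel": 1.0},
        eye_gain={"left": 1.0, "right": 0.1},
    ),
}


@dataclass(frozen=True)
class SessionSpec:
    """Acquisition bookkeeping of one measurement session."""

    modality: str = "pupil"  # "pupil" | "bold"
    acquisitions_per_condition: int = 4
    conditions: tuple[str, ...] = ("LS", "RodMel", "LightFlux")
    duration: float = 360.0
    seed: int = 0

    @property
    def total_acquisitions(self) -> int:
        return self.acquisitions_per_condition * len(self.conditions)


def bold_session_spec(seed: int = 0) -> SessionSpec:
    """18-acquisition fMRI session: 6 per stimulus (3 per eye)."""
    return SessionSpec(
        modality="bold",
        acquisitions_per_condition=6,
        conditions=("LS", "LminusS", "LightFlux"),
        duration=432.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# device

def synth_device(
    n_primaries: int = 56,
    fwhm_nm: float = 16.0,
    wavelengths: np.ndarray | None = None,
    seed: int = 0,
) -> DeviceModel:
    """Gaussian-primary light engine spanning 400-700 nm, equal peak power.

    Emulates a digital light synthesis engine with many narrowband
    primaries.  Deterministic; the seed is accepted for interface symmetry
    with the other generators.
    """
    if n_primaries < 3:
        raise ValueError("need at least 3 primaries")
    if wavelengths is None:
        from .photoreceptors import default_grid

        wavelengths = default_grid()
    wl = np.asarray(wavelengths, float)
    centers = np.linspace(400.0, 700.0, n_primaries)
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    P = np.exp(-((wl[:, None] - centers[None, :]) ** 2) / (2 * sigma**2))
    return DeviceModel(wl, P)


# ---------------------------------------------------------------------------
# pupillometry sessions

#: Nominal bipolar contrasts per stimulus condition and mechanism, standing
#: in for a designed modulation set when none is supplied.
NOMINAL_CONTRASTS: dict[str, dict[str, float]] = {
    "LightFlux": {"L": 0.95, "S": 0.95, "rod": 0.95, "mel": 0.95},
    "LS": {"L": 0.47, "S": 0.47, "rod": 0.001, "mel": 0.001},
    "RodMel": {"L": 0.001, "S": 0.001, "rod": 0.5, "mel": 0.5},
    "LminusS": {"L": 0.25, "S": -0.25, "rod": 0.001, "mel": 0.001},
}

#: Relative pupil drive per unit contrast per mechanism.  Cone-dominated:
#: the stimulation frequency is fast for melanopsin and the photopic
#: background saturates the rods.
PUPIL_DRIVE_WEIGHTS: dict[str, float] = {"L": 1.0, "S": 0.25, "rod": 0.08, "mel": 0.02}


@dataclass(frozen=True)
class PupilResponseParams:
    """Generative parameters of the pupil response model.

    ``lf_amplitude_pct`` anchors the wild-type light-flux response
    amplitude (% area change); other conditions scale by their
    mechanism-weighted, gain-weighted contrast.  ``ls_lf_ratio``, when
    set, pins the L+S : light-flux amplitude ratio directly.
    """

    lf_amplitude_pct: float = 10.0
    ls_lf_ratio: float | None = None
    phase_rad: float = -2.0
    noise_sd_pct: float = 2.0
    blink_rate_hz: float = 0.1
    blink_duration_s: float = 0.3
    contrasts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in NOMINAL_CONTRASTS.items()}
    )
    base_area_px2: float = 5000.0


def _pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, zero mean, normalized to the requested SD."""
    white = rng.standard_normal(n)
    F = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    F[1:] /= np.sqrt(f[1:])
    F[0] = 0.0
    x = np.fft.irfft(F, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def condition_amplitude(
    condition: str, preset: DiseasePreset, params: PupilResponseParams
) -> float:
    """Generative pupil amplitude (% area change) of one condition."""

    def drive(cond: str) -> float:
        return sum(
            PUPIL_DRIVE_WEIGHTS[m] * preset.gains[m] * abs(c)
            for m, c in params.contrasts[cond].items()
        )

    wt_lf_drive = sum(
        PUPIL_DRIVE_WEIGHTS[m] * abs(c) for m, c in params.contrasts["LightFlux"].items()
    )
    amp = params.lf_amplitude_pct * drive(condition) / wt_lf_drive
    if condition == "LS" and params.ls_lf_ratio is not None:
        amp = params.ls_lf_ratio * params.lf_amplitude_pct * drive("LightFlux") / wt_lf_drive
    return amp


def synth_pupil_session(
    preset: DiseasePreset | str,
    spec: SessionSpec | None = None,
    params: PupilResponseParams | None = None,
) -> dict[str, list[PupilTimeSeries]]:
    """Simulate one pupillometry session: per-condition area series.

    Each acquisition is ``area(t) = A0 * (1 + y(t)/100)`` with
    ``y = amp * sin(2 pi f t + phi) + pink noise``, and Poisson blink
    events masking short windows.  Returns percent-change-ready series
    grouped by condition; 12 acquisitions in the default session.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    spec = spec or SessionSpec()
    params = params or PupilResponseParams()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * FRAME_RATE_HZ))
    t = np.arange(n) / FRAME_RATE_HZ
    out: dict[str, list[PupilTimeSeries]] = {}
    for cond in spec.conditions:
        amp = condition_amplitude(cond, preset, params)
        series = []
        for _ in range(spec.acquisitions_per_condition):
            y = amp * np.sin(2 * np.pi * PUPIL_FREQ_HZ * t + params.phase_rad)
            y = y + _pink_noise(n, params.noise_sd_pct, rng)
            valid = np.ones(n, bool)
            n_blinks = rng.poisson(params.blink_rate_hz * spec.duration)
            width = int(round(params.blink_duration_s * FRAME_RATE_HZ))
            for start in rng.integers(0, max(n - width, 1), n_blinks):
                valid[start : start + width] = False
            series.append(PupilTimeSeries(t, y, valid))
        out[cond] = series
    return out


def pupil_area_series(ts: PupilTimeSeries, base_area_px2: float = 5000.0) -> np.ndarray:
    """Convert a percent-change series to raw pupil area (px^2)."""
    return base_area_px2 * (1.0 + ts.area_pct_change / 100.0)


def synth_border_points(
    center: tuple[float, float] = (320.0, 240.0),
    semi_axes: tuple[float, float] = (50.0, 45.0),
    orientation: float = 0.3,
    n_points: int = 60,
    noise_px: float = 0.0,
    n_outliers: int = 0,
    outlier_offset_px: float = 20.0,
    seed: int = 0,
) -> np.ndarray:
    """Candidate pupil-border points on an ellipse, with optional noise and
    gross outliers (emulating eyelash / Purkinje contamination)."""
    rng = np.random.default_rng(seed)
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    a, b = semi_axes
    x = a * np.cos(theta)
    y = b * np.sin(theta)
    c, s = np.cos(orientation), np.sin(orientation)
    pts = np.column_stack([center[0] + c * x - s * y, center[1] + s * x + c * y])
    if noise_px > 0:
        pts += rng.normal(0, noise_px, pts.shape)
    if n_outliers > 0:
        idx = rng.choice(n_points, n_outliers, replace=False)
        pts[idx] += rng.normal(outlier_offset_px, 5.0, (n_outliers, 2))
    return pts


# ---------------------------------------------------------------------------
# BOLD sessions

DEFAULT_BOLD_SHAPE = (24, 24, 16)


def default_cortex_mask(shape: tuple = DEFAULT_BOLD_SHAPE) -> np.ndarray:
    """Bilateral, mirror-symmetric 'visual cortex' blob pair (posterior,
    dorsal); scales with the volume shape."""
    nx, ny, nz = shape
    m = np.zeros(shape, bool)
    x0, x1 = nx // 6, nx // 3
    y0, y1 = 7 * ny // 12, 5 * ny // 6
    z0, z1 = 5 * nz // 8, 7 * nz // 8
    m[x0:x1, y0:y1, z0:z1] = True
    m[nx - x1 : nx - x0, y0:y1, z0:z1] = True
    return m


def default_lgn_mask(shape: tuple = DEFAULT_BOLD_SHAPE) -> np.ndarray:
    """Bilateral 'LGN' blob pair, smaller and central (responses simulated
    with negative sign)."""
    nx, ny, nz = shape
    m = np.zeros(shape, bool)
    x0, x1 = nx // 3, nx * 5 // 12
    y0, y1 = 5 * ny // 12, 13 * ny // 24
    z0, z1 = 3 * nz // 8, 9 * nz // 16
    m[x0:x1, y0:y1, z0:z1] = True
    m[nx - x1 : nx - x0, y0:y1, z0:z1] = True
    return m


@dataclass(frozen=True)
class BoldMapParams:
    """Generative parameters of one BOLD session.

    Amplitudes are percent-signal-change betas in the forward-model
    convention (response = beta x (unit square wave convolved with the
    peak-normalized HRF kernel)).  Noise is AR(1) in time; drift is a
    per-voxel random linear trend; spikes are single-TR global offsets.
    """

    shape: tuple = DEFAULT_BOLD_SHAPE
    n_tr: int = 144
    tr: float = 3.0
    n_acquisitions: int = 6
    cortex_amplitude_pct: float = 0.4
    lgn_amplitude_pct: float = -0.2
    eye_amplitude_override: dict[str, float] | None = None  # cortex beta per eye
    noise_sd_pct: float = 0.25
    ar1_rho: float = 0.3
    drift_pct: float = 0.5  # max |linear drift| over one acquisition
    spike_schedule: tuple[tuple[int, int], ...] = ()  # (acquisition, tr)
    spike_amplitude_pct: float = 5.0
    motion_coupling_pct: float = 0.05
    baseline: float = 1000.0
    hrf_weights: tuple[float, float, float] = (1.0, 0.0, 0.0)


def _ar1(shape: tuple, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    w = rng.standard_normal(shape) * sd * np.sqrt(max(1.0 - rho**2, 1e-12))
    return lfilter([1.0], [1.0, -rho], w, axis=-1)


def _block_response(design: StimulusDesign, basis: HrfBasis, weights: np.ndarray) -> np.ndarray:
    """Uncentered TR-sampled response of the unit square wave under the
    peak-normalized kernel defined by ``weights``."""
    from .boldmodel import OVERSAMPLE, _normalize_kernel

    w = np.asarray(weights, float)
    peak = _normalize_kernel(w[None], basis)[0]
    w = w / peak
    box = build_design(design, OVERSAMPLE)
    k = basis.kernel(w)
    conv = np.convolve(box, k)[: box.size] * basis.dt
    return conv[::OVERSAMPLE]


def _motion_table(n_tr: int, rng: np.random.Generator) -> np.ndarray:
    """Slow pseudo-physiological rigid-body parameters (mm / rad)."""
    t = np.arange(n_tr)
    cols = []
    for j in range(6):
        freq = rng.uniform(0.01, 0.08)
        amp = rng.uniform(0.02, 0.1) * (1.0 if j < 3 else 0.01)
        walk = np.cumsum(rng.normal(0, amp / 20, n_tr))
        cols.append(amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)) + walk)
    return np.column_stack(cols)


def synth_bold_session(
    preset: DiseasePreset | str,
    params: BoldMapParams | None = None,
    stimulus_label: str = "lightflux",
    seed: int = 0,
) -> dict:
    """Simulate the 6 concatenated acquisitions of one stimulus type.

    Acquisitions 0-2 stimulate the left eye, 3-5 the right eye.  The
    cortical blob responds with positive sign and the LGN blob with
    negative sign; amplitudes scale with the preset's cone gains and
    per-eye gain (or an explicit per-eye override).  Returns
    ``{"acquisitions": [BoldSeries], "motion": [table], "design":
    StimulusDesign, "cortex_mask", "lgn_mask", "true_betas"}``.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    params = params or BoldMapParams()
    rng = np.random.default_rng(seed)
    design = StimulusDesign(
        tr=params.tr,
        duration=params.n_tr * params.tr,
        n_acquisitions=params.n_acquisitions,
    )
    basis = hrf_basis(params.tr)
    resp = _block_response(design, basis, np.asarray(params.hrf_weights))
    cortex = default_cortex_mask(params.shape)
    lgn = default_lgn_mask(params.shape)
    n_vox = int(np.prod(params.shape))
    cone_gain = 0.5 * (preset.gains["L"] + preset.gains["S"])

    acqs, motions, true_betas = [], [], []
    for a in range(params.n_acquisitions):
        eye = "left" if a < params.n_acquisitions // 2 else "right"
        if params.eye_amplitude_override is not None:
            amp_cortex = params.eye_amplitude_override[eye]
        else:
            amp_cortex = params.cortex_amplitude_pct * cone_gain * preset.eye_gain[eye]
        amp_lgn = params.lgn_amplitude_pct * cone_gain * preset.eye_gain[eye]
        true_betas.append({"eye": eye, "cortex": amp_cortex, "lgn": amp_lgn})

        # the evoked component is centered so that the amplitude is defined
        # relative to the acquisition mean — the same anchor the analysis
        # uses for percent signal change
        resp_c = resp - resp.mean()
        pct = np.zeros((n_vox, params.n_tr))
        pct[cortex.reshape(-1)] += amp_cortex * resp_c[None, :]
        pct[lgn.reshape(-1)] += amp_lgn * resp_c[None, :]
        # drift + AR(1) noise
        slope = rng.uniform(-params.drift_pct, params.drift_pct, n_vox)
        tt = np.linspace(-0.5, 0.5, params.n_tr)
        pct += slope[:, None] * tt[None, :]
        pct += _ar1((n_vox, params.n_tr), params.ar1_rho, params.noise_sd_pct, rng)
        # motion-coupled nuisance in a random voxel subset
        motion = _motion_table(params.n_tr, rng)
        coupled = rng.random(n_vox) < 0.1
        weights = rng.normal(0, params.motion_coupling_pct, (coupled.sum(), 6))
        mstd = motion.std(axis=0)
        mstd[mstd == 0] = 1.0
        pct[coupled] += weights @ (motion / mstd).T
        # scheduled single-TR global spikes
        for acq_i, tr_i in params.spike_schedule:
            if acq_i == a:
                if not (0 <= tr_i < params.n_tr):
                    raise ValueError("spike schedule outside the acquisition time range")
                pct[:, tr_i] += params.spike_amplitude_pct
        raw = params.baseline * (1.0 + pct / 100.0)
        acqs.append(
            BoldSeries(
                raw.reshape(params.shape + (params.n_tr,)),
                tr=params.tr,
                acquisition_id=f"{stimulus_label}-{a:02d}",
                eye=eye,
                stimulus_label=stimulus_label,
            )
        )
        motions.append(motion)
    return {
        "acquisitions": acqs,
        "motion": motions,
        "design": design,
        "basis": basis,
        "cortex_mask": cortex,
        "lgn_mask": lgn,
        "true_betas": true_betas,
    }


def protocol_json(design: StimulusDesign) -> str:
    onsets = np.arange(0.0, design.duration, design.block_on + design.block_off)
    return json.dumps(
        {
            "tr": design.tr,
            "block_on": design.block_on,
            "block_off": design.block_off,
            "n_acq": design.n_acquisitions,
            "onsets": onsets.tolist(),
        },
        indent=2,
    )
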