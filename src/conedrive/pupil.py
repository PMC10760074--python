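"""Pupillometry analysis: ellipse fitting of pupil border points with
iterative outlier trimming, acquisition-level QC, percent-change area
series, sinusoidal response estimation at the stimulation frequency, and
exhaustive-bootstrap standard errors.

The consensual pupil response to a slow (1/6 Hz) sinusoidal spectral
modulation is summarized by the amplitude and phase of a sine/cosine
regression on the percent-change pupil area series.  Session-level error
is estimated by exhaustively enumerating every multiset of the available
acquisitions (sampling with replacement), averaging the time series
frame-wise, refitting, and taking the standard deviation of the resulting
amplitudes (and, circularly, phases).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
from skimage.measure import EllipseModel

__all__ = [
    "BorderPoints",
    "EllipseFit",
    "PupilTimeSeries",
    "PupilResponseFit",
    "DegenerateFitError",
    "UnderSampledError",
    "fit_ellipse",
    "qc_acquisition",
    "percent_change_series",
    "fit_sinusoid",
    "bootstrap_sem",
    "n_multisets",
]

PUPIL_FREQ_HZ = 1.0 / 6.0
FRAME_RATE_HZ = 60.0
QC_POOR_FRACTION = 0.5  # exclude an acquisition iff poor fraction strictly exceeds this
POOR_RMSE_PX = 2.0  # "poor fit": residual RMSE above this, or < 5 surviving points


class DegenerateFitError(ValueError):
    """Border points do not determine an ellipse."""


class UnderSampledError(ValueError):
    """Too few valid frames to estimate the sinusoidal response."""


@dataclass(frozen=True)
class BorderPoints:
    timestamp: float
    points: np.ndarray  # (n, 2) pixel coordinates


@dataclass(frozen=True)
class EllipseFit:
    center_x: float
    center_y: float
    a: float  # semi-major, px
    b: float  # semi-minor, px
    orientation: float
    area: float  # px^2
    rmse: float
    quality_flag: str  # "good" | "poor"
    n_points: int


@dataclass(frozen=True)
class PupilTimeSeries:
    time: np.ndarray
    area_pct_change: np.ndarray
    valid_mask: np.ndarray


@dataclass(frozen=True)
class PupilResponseFit:
    amplitude: float  # % area change, peak deviation
    phase: float  # radians in (-pi, pi]
    frequency: float
    sem_amplitude: float = float("nan")
    sem_phase: float = float("nan")
    n_acq: int = 1


def _ellipse_residuals(model: EllipseModel, pts: np.ndarray) -> np.ndarray:
    return model.residuals(pts)


def fit_ellipse(
    points: BorderPoints | np.ndarray,
    max_iter: int = 10,
    residual_threshold_px: float = 3.0,
) -> EllipseFit:
    """Direct least-squares ellipse fit with iterative trimming of
    poorly-fit border points (eyelashes, Purkinje reflections).

    Fit -> drop points with residual above the threshold -> refit, until
    the surviving set is stable or ``max_iter`` is reached.  The result is
    flagged "poor" when fewer than 5 points survive or the final RMSE
    exceeds the poor-fit threshold.
    """
    pts = points.points if isinstance(points, BorderPoints) else np.asarray(points, float)
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise DegenerateFitError("at least 5 border points are required")

    keep = np.ones(len(pts), dtype=bool)
    model = None
    for _ in range(max_iter):
        if keep.sum() < 5:
            break
        model = EllipseModel.from_estimate(pts[keep])
        if not model:
            raise DegenerateFitError("ellipse fit failed (degenerate points)")
        res = _ellipse_residuals(model, pts[keep])
        # trim gently: contaminated fits inflate residuals of sound points,
        # so drop at most the worst decile per pass
        cutoff = max(residual_threshold_px, float(np.quantile(res, 0.9)))
        new_keep = keep.copy()
        new_keep[np.flatnonzero(keep)[res > cutoff]] = False
        if new_keep.sum() == keep.sum():
            keep = new_keep
            break
        keep = new_keep

    if model is None or not model:
        raise DegenerateFitError("ellipse fit failed (degenerate points)")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta
    if keep.sum() < 5:
        rmse = float("inf")
    else:
        rmse = float(np.sqrt(np.mean(_ellipse_residuals(model, pts[keep]) ** 2)))
    if a < b:
        a, b = b, a
        theta += math.pi / 2
    flag = "good" if (keep.sum() >= 5 and rmse <= POOR_RMSE_PX) else "poor"
    return EllipseFit(
        center_x=float(xc),
        center_y=float(yc),
        a=float(a),
        b=float(b),
        orientation=float(np.mod(theta + math.pi / 2, math.pi) - math.pi / 2),
        area=float(math.pi * a * b),
        rmse=rmse,
        quality_flag=flag,
        n_points=int(keep.sum()),
    )


def qc_acquisition(fits: list[EllipseFit]) -> tuple[bool, float]:
    """Acquisition-level QC: exclude iff poor-fit frames are strictly more
    than half of the acquisition.

    Returns ``(include, fraction_poor)``.
    """
    if not fits:
        raise ValueError("empty fit sequence")
    frac = sum(f.quality_flag == "poor" for f in fits) / len(fits)
    return frac <= QC_POOR_FRACTION, frac


def percent_change_series(
    time: np.ndarray, area: np.ndarray, valid: np.ndarray | None = None
) -> PupilTimeSeries:
    """Express pupil area as percent change about the valid-frame mean."""
    t = np.asarray(time, float)
    a = np.asarray(area, float)
    v = np.ones_like(a, bool) if valid is None else np.asarray(valid, bool)
    mean = a[v].mean()
    pct = 100.0 * (a - mean) / mean
    return PupilTimeSeries(t, pct, v)


def fit_sinusoid(series: PupilTimeSeries, frequency: float = PUPIL_FREQ_HZ) -> PupilResponseFit:
    """Least-squares sinusoid at the stimulation frequency.

    Regressors {1, sin(2 pi f t), cos(2 pi f t)} on valid frames;
    amplitude = sqrt(b_sin^2 + b_cos^2), phase = atan2(b_cos, b_sin)
    in (-pi, pi].
    """
    v = series.valid_mask
    t = series.time[v]
    y = series.area_pct_change[v]
    if t.size < 3 or (t.max() - t.min()) < 2.0 / frequency:
        raise UnderSampledError("need at least two full cycles of valid data")
    X = np.column_stack(
        [np.ones_like(t), np.sin(2 * np.pi * frequency * t), np.cos(2 * np.pi * frequency * t)]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    amplitude = float(np.hypot(beta[1], beta[2]))
    phase = float(math.atan2(beta[2], beta[1]))
    return PupilResponseFit(amplitude=amplitude, phase=phase, frequency=frequency)


def n_multisets(n: int) -> int:
    """Number of size-n multisets from n items: C(2n-1, n)."""
    return math.comb(2 * n - 1, n)


def _circular_sd(phases: np.ndarray) -> float:
    """SD of angles after rotation to the circular mean."""
    z = np.exp(1j * phases)
    mean_angle = np.angle(z.mean())
    rotated = np.angle(np.exp(1j * (phases - mean_angle)))
    return float(rotated.std())


def bootstrap_sem(
    acquisition_series: list[PupilTimeSeries],
    frequency: float = PUPIL_FREQ_HZ,
) -> PupilResponseFit:
    """Exhaustive bootstrap over acquisitions of one stimulus condition.

    Enumerates every multiset of size n drawn with replacement from the n
    acquisitions (C(2n-1, n) of them; 35 for n = 4), averages the series
    frame-wise within each multiset, refits the sinusoid, and reports the
    SD of the resulting amplitudes (and circular SD of phases) as the SEM.
    The point estimate comes from the plain (unresampled) average.
    """
    n = len(acquisition_series)
    if n < 2:
        raise ValueError("need at least 2 acquisitions for the exhaustive bootstrap")
    lengths = {s.time.size for s in acquisition_series}
    if len(lengths) != 1:
        raise ValueError("acquisition series lengths are not aligned")
    t = acquisition_series[0].time
    Y = np.stack([s.area_pct_change for s in acquisition_series])
    V = np.stack([s.valid_mask for s in acquisition_series])

    def averaged(indices: tuple[int, ...]) -> PupilTimeSeries:
        Yw = Y[list(indices)]
        Vw = V[list(indices)]
        counts = Vw.sum(axis=0)
        valid = counts > 0
        with np.errstate(invalid="ignore"):
            mean = np.where(valid, (Yw * Vw).sum(axis=0) / np.maximum(counts, 1), 0.0)
        return PupilTimeSeries(t, mean, valid)

    point = fit_sinusoid(averaged(tuple(range(n))), frequency)
    amps, phases = [], []
    for combo in combinations_with_replacement(range(n), n):
        fit = fit_sinusoid(averaged(combo), frequency)
        amps.append(fit.amplitude)
        phases.append(fit.phase)
    return PupilResponseFit(
        amplitude=point.amplitude,
        phase=point.phase,
        frequency=frequency,
        sem_amplitude=float(np.std(amps)),
        sem_phase=_circular_sd(np.asarray(phases)),
        n_acq=n,
    )
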