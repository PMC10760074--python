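"""Forward-model fitting of blocked-flicker BOLD sessions.

The neural model is a square-wave representation of the 12 s on / 12 s off
stimulus blocks, with a separate response amplitude (beta, in percent
signal change) for each of the concatenated acquisitions.  The square wave
is convolved with a hemodynamic response function (HRF) expressed as a
weighted combination of a three-component basis (canonical double-gamma
kernel, its temporal derivative, and its dispersion derivative).  Per
voxel, the three HRF weights (shared across acquisitions) and the
per-acquisition betas are jointly estimated by minimizing the L2 norm of
the residual.

Identifiability: the kernel is peak-normalized to 1 after fitting (and at
every iteration), so the betas carry the full response amplitude and sign
(negative responses, as seen in the LGN, are representable).

The joint problem is bilinear, so it is solved by alternating exact linear
steps — betas given the kernel are per-acquisition OLS; kernel weights
given the betas are OLS — iterated to convergence with seeded multi-start
on the weights.  Both steps are vectorized across voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.special import gammaln

from .boldprep import BoldSeries

__all__ = [
    "StimulusDesign",
    "HrfBasis",
    "VoxelFits",
    "RoiResult",
    "build_design",
    "hrf_basis",
    "percent_signal_change",
    "fit_forward_model",
    "r2_map",
    "define_rois",
    "roi_response",
]

DEFAULT_TR_S = 3.0
BLOCK_ON_S = 12.0
BLOCK_OFF_S = 12.0
ACQ_DURATION_S = 432.0
OVERSAMPLE = 10  # internal sub-TR resolution for convolution


@dataclass(frozen=True)
class StimulusDesign:
    """Blocked on/off protocol of one acquisition, repeated per acquisition."""

    tr: float = DEFAULT_TR_S
    block_on: float = BLOCK_ON_S
    block_off: float = BLOCK_OFF_S
    duration: float = ACQ_DURATION_S
    n_acquisitions: int = 6
    onset: float = 0.0

    @property
    def n_tr(self) -> int:
        return int(round(self.duration / self.tr))


@dataclass(frozen=True)
class HrfBasis:
    """HRF basis sampled at the sub-TR resolution; columns unit-norm."""

    dt: float
    kernels: np.ndarray  # (n_samples, 3)

    def kernel(self, weights: np.ndarray) -> np.ndarray:
        return self.kernels @ np.asarray(weights, float)


@dataclass
class VoxelFits:
    """Per-voxel forward-model estimates over a voxel set.

    ``betas`` are per-acquisition response amplitudes in percent signal
    change; ``hrf_weights`` the shared kernel weights (kernel peak = 1);
    ``r2`` the raw coefficient of determination of the full model.
    """

    betas: np.ndarray  # (n_vox, n_acq)
    hrf_weights: np.ndarray  # (n_vox, 3)
    r2: np.ndarray  # (n_vox,)
    voxel_index: np.ndarray | None = None  # flat indices into the volume
    shape: tuple | None = None

    @property
    def mean_beta(self) -> np.ndarray:
        return self.betas.mean(axis=1)


@dataclass(frozen=True)
class RoiResult:
    label: str
    mask: np.ndarray  # boolean volume
    mean_pct: float = float("nan")
    sem_pct: float = float("nan")
    n_acq: int = 0

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def build_design(design: StimulusDesign, oversample: int = OVERSAMPLE) -> np.ndarray:
    """Unit-height boxcar of one acquisition at sub-TR resolution.

    Returns an array of length ``n_tr * oversample`` sampled at
    ``dt = tr / oversample``; the first on-block starts at the protocol
    onset (t = 0 by default).
    """
    dt = design.tr / oversample
    t = np.arange(design.n_tr * oversample) * dt
    cycle = design.block_on + design.block_off
    t_rel = t - design.onset
    return np.where((t_rel >= 0) & (np.mod(t_rel, cycle) < design.block_on), 1.0, 0.0)


def _double_gamma(t: np.ndarray, peak: float, under: float, ratio: float, disp: float) -> np.ndarray:
    """SPM-style double-gamma HRF; shape parameters peak/disp and under/disp."""

    def gpdf(x, a, b):
        x = np.clip(x, 1e-12, None)
        return np.exp(a * np.log(b) + (a - 1) * np.log(x) - b * x - gammaln(a))

    return gpdf(t, peak / disp, 1.0 / disp) - ratio * gpdf(t, under / disp, 1.0 / disp)


def hrf_basis(
    tr: float = DEFAULT_TR_S,
    oversample: int = OVERSAMPLE,
    duration: float = 32.0,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    dispersion: float = 1.0,
) -> HrfBasis:
    """Three-component HRF basis: canonical double-gamma kernel, its
    temporal derivative, and its dispersion derivative, each unit-norm."""
    dt = tr / oversample
    t = np.arange(0.0, duration, dt)
    h0 = _double_gamma(t, peak_s, undershoot_s, undershoot_ratio, dispersion)
    h1 = np.gradient(h0, dt)
    dd = 0.01
    h2 = (h0 - _double_gamma(t, peak_s, undershoot_s, undershoot_ratio, dispersion + dd)) / dd
    B = np.column_stack([h0, h1, h2])
    B = B / np.linalg.norm(B, axis=0)
    return HrfBasis(dt, B)


def percent_signal_change(series: BoldSeries) -> np.ndarray:
    """Per-voxel percent change about the acquisition mean; (n_vox, n_tr).

    Voxels with non-positive mean are mapped to all-zero traces.
    """
    flat = series.data.reshape(-1, series.n_tr)
    mean = flat.mean(axis=1, keepdims=True)
    ok = mean[:, 0] > 0
    out = np.zeros_like(flat)
    out[ok] = 100.0 * (flat[ok] - mean[ok]) / mean[ok]
    return out


def _tr_regressors(design: StimulusDesign, basis: HrfBasis, oversample: int = OVERSAMPLE) -> np.ndarray:
    """Convolve the boxcar with each basis kernel; sample at TR onsets.

    Returns column-centered regressors of shape (n_tr, 3) — centering
    plays the role of the per-acquisition intercept since the percent
    signal change traces are zero-mean by construction.
    """
    box = build_design(design, oversample)
    R = np.empty((design.n_tr, basis.kernels.shape[1]))
    for j in range(basis.kernels.shape[1]):
        conv = np.convolve(box, basis.kernels[:, j])[: box.size] * basis.dt
        R[:, j] = conv[::oversample]
    return R - R.mean(axis=0)


def _normalize_kernel(w: np.ndarray, basis: HrfBasis) -> np.ndarray:
    """Per-voxel signed kernel peak (value at the max-|k| sample)."""
    k = basis.kernels @ w.T  # (n_samples, n_vox)
    idx = np.argmax(np.abs(k), axis=0)
    return k[idx, np.arange(k.shape[1])]


def fit_forward_model(
    acquisitions: list[BoldSeries],
    design: StimulusDesign,
    basis: HrfBasis | None = None,
    mask: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    n_starts: int = 3,
    seed: int = 0,
) -> VoxelFits:
    """Jointly fit per-acquisition betas and shared HRF weights per voxel.

    ``acquisitions`` are concatenated in the given order; each is converted
    to percent signal change about its own mean before fitting, and the
    convolution never bleeds across acquisition boundaries (the regressor
    is built per acquisition).  ``mask`` restricts fitting to a voxel
    subset (boolean volume).  The search is alternating OLS with
    ``n_starts`` seeded initializations of the HRF weights; the per-voxel
    solution with the lowest residual is kept.
    """
    if basis is None:
        basis = hrf_basis(design.tr)
    n_acq = len(acquisitions)
    shape = acquisitions[0].data.shape[:3]
    if mask is not None:
        vox = np.flatnonzero(np.asarray(mask, bool).reshape(-1))
    else:
        vox = np.arange(int(np.prod(shape)))
    # percent signal change on the fitted voxel subset only
    Y = np.empty((vox.size, n_acq, acquisitions[0].n_tr))
    for a, acq in enumerate(acquisitions):
        flat = acq.data.reshape(-1, acq.n_tr)[vox]
        mean = flat.mean(axis=1, keepdims=True)
        ok = mean[:, 0] > 0
        Y[:, a, :] = 0.0
        Y[ok, a, :] = 100.0 * (flat[ok] - mean[ok]) / mean[ok]
    n_vox = vox.size

    Rc = _tr_regressors(design, basis)  # (t, 3) — same protocol every acquisition
    A = Rc.T @ Rc  # (3, 3)
    yR = np.einsum("vat,tj->vaj", Y, Rc)  # (v, a, 3); fixed across iterations
    ss_y = np.einsum("vat,vat->v", Y, Y)

    rng = np.random.default_rng(seed)
    w_canon = np.array([1.0, 0.0, 0.0])

    best_sse = np.full(n_vox, np.inf)
    best_w = np.tile(w_canon, (n_vox, 1))
    best_beta = np.zeros((n_vox, n_acq))

    for start in range(max(1, n_starts)):
        w0 = w_canon if start == 0 else w_canon + rng.normal(0, 0.3, 3)
        W = np.tile(w0 / max(np.abs(_normalize_kernel(w0[None], basis)[0]), 1e-12), (n_vox, 1))
        beta = np.zeros((n_vox, n_acq))
        for _ in range(max_iter):
            # beta step: per-acquisition OLS on the centered kernel regressor
            num = np.einsum("vaj,vj->va", yR, W)
            den = np.einsum("vj,jk,vk->v", W, A, W)
            beta = num / np.clip(den, 1e-30, None)[:, None]
            # weight step: OLS on the 3 basis-convolved regressors
            b2 = (beta**2).sum(axis=1)  # sum_a beta^2 (A is acquisition-invariant)
            rhs = np.einsum("va,vaj->vj", beta, yR)
            Av = b2[:, None, None] * A[None] + 1e-12 * np.eye(3)[None]
            W_new = np.linalg.solve(Av, rhs[:, :, None])[:, :, 0]
            peak = _normalize_kernel(W_new, basis)
            safe = np.abs(peak) > 1e-12
            W_new[safe] /= peak[safe, None]
            W_new[~safe] = w_canon
            beta[safe] *= peak[safe, None]
            delta = np.abs(W_new - W).max()
            W = W_new
            if delta < tol:
                break
        num = np.einsum("vaj,vj->va", yR, W)
        den = np.einsum("vj,jk,vk->v", W, A, W)
        beta = num / np.clip(den, 1e-30, None)[:, None]
        sse = ss_y - 2 * np.einsum("va,vaj,vj->v", beta, yR, W) + (beta**2).sum(1) * den
        better = sse < best_sse
        best_sse[better] = sse[better]
        best_w[better] = W[better]
        best_beta[better] = beta[better]

    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_y > 0, 1.0 - best_sse / ss_y, 0.0)
    return VoxelFits(best_beta, best_w, r2, voxel_index=vox, shape=shape)


def r2_map(
    acquisitions: list[BoldSeries],
    design: StimulusDesign,
    basis: HrfBasis | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """R-squared volume of the forward model fit to the across-acquisition
    average time series (single shared beta per voxel).

    Zero-variance voxels get R² = 0.
    """
    shape = acquisitions[0].data.shape[:3]
    avg = np.mean([percent_signal_change(a) for a in acquisitions], axis=0)
    avg_series = BoldSeries(
        (avg + 100.0).reshape(shape + (design.n_tr,)), tr=design.tr
    )  # re-offset so percent_signal_change round-trips
    fits = fit_forward_model([avg_series], design, basis=basis, mask=mask)
    vol = np.zeros(int(np.prod(shape)))
    vol[fits.voxel_index] = np.clip(fits.r2, 0.0, None)
    return vol.reshape(shape)


def define_rois(
    r2_vol: np.ndarray,
    threshold: float | None = None,
    min_size: int = 10,
    top_fraction: float = 0.005,
    mask: np.ndarray | None = None,
) -> list[RoiResult]:
    """Threshold and binarize an R² map into discrete regions.

    When ``threshold`` is None it is set to the (1 - top_fraction)
    quantile of in-mask R² values.  Components are 26-connected; those
    smaller than ``min_size`` are dropped; survivors are labelled by size
    ("cortex" for the largest, "lgn" for the next, then "roi3", ...).
    """
    vol = np.asarray(r2_vol, float)
    inmask = np.ones(vol.shape, bool) if mask is None else np.asarray(mask, bool)
    if threshold is None:
        threshold = float(np.quantile(vol[inmask], 1.0 - top_fraction))
    binary = (vol >= threshold) & inmask
    labels, n = cc_label(binary, structure=np.ones((3, 3, 3), int))
    comps = [(labels == i).sum() for i in range(1, n + 1)]
    keep = [(i + 1, c) for i, c in enumerate(comps) if c >= min_size]
    keep.sort(key=lambda x: -x[1])
    if not keep:
        import warnings

        warnings.warn("no components survive the R² threshold")
        return []
    names = ["cortex", "lgn"] + [f"roi{i}" for i in range(3, len(keep) + 1)]
    return [RoiResult(name, labels == lab) for name, (lab, _) in zip(names, keep)]


def roi_response(
    fits: VoxelFits,
    roi: RoiResult | np.ndarray,
    acquisition_subset: np.ndarray | list[int] | None = None,
) -> RoiResult:
    """Mean percent-signal-change response within an ROI.

    Betas are averaged over ROI voxels separately for each acquisition;
    the report is the mean and SEM (SD/sqrt(n)) over those per-acquisition
    values.  ``acquisition_subset`` restricts to e.g. one eye's
    acquisitions.
    """
    mask = roi.mask if isinstance(roi, RoiResult) else np.asarray(roi, bool)
    label = roi.label if isinstance(roi, RoiResult) else "roi"
    flat_idx = np.flatnonzero(mask.reshape(-1))
    pos = {v: i for i, v in enumerate(fits.voxel_index)}
    rows = [pos[v] for v in flat_idx if v in pos]
    if not rows:
        raise IndexError("ROI contains no fitted voxels")
    betas = fits.betas[rows]  # (n_roi_vox, n_acq)
    if acquisition_subset is not None:
        betas = betas[:, list(acquisition_subset)]
    per_acq = betas.mean(axis=0)
    n = per_acq.size
    sem = float(per_acq.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return RoiResult(label, mask, mean_pct=float(per_acq.mean()), sem_pct=sem, n_acq=n)
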