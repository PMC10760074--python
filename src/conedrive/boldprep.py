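"""BOLD time-series hygiene: per-voxel linear detrending, MAD-based spike
detection, motion-derived confound construction with PCA reduction,
confound regression, and hemispheric mirror-averaging.

Operates on 4-D volumes already in template space (spatial registration,
distortion and rigid-body motion correction are upstream).  The stage order
follows the analysis narrative: detrend -> spike detection -> confound
regression -> mirror averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoldSeries",
    "SpikeEvents",
    "ConfoundMatrix",
    "linear_detrend",
    "detect_spikes",
    "motion_confounds",
    "regress_confounds",
    "mirror_average",
]

VOXEL_MAD_K = 6.0  # voxel-level outlier: value >= median + 6 MAD (over time)
TR_MAD_K = 25.0  # TR-level: noisy-voxel count >= median + 25 MAD
PCA_VARIANCE = 0.95  # retained fraction of 24-motion-regressor variance


@dataclass
class BoldSeries:
    """4-D BOLD acquisition (x, y, z, t) with protocol metadata."""

    data: np.ndarray
    tr: float = 3.0
    acquisition_id: str = ""
    eye: str = "left"
    stimulus_label: str = "lightflux"

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4 or d.shape[3] < 2:
            raise ValueError("BOLD data must be 4-D with at least 2 time points")
        if not np.all(np.isfinite(d)):
            raise ValueError("BOLD data must be finite")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        self.data = d

    @property
    def n_tr(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class SpikeEvents:
    flagged_trs: np.ndarray  # sorted TR indices
    noisy_voxel_counts: np.ndarray  # per-TR counts from stage 1
    voxel_mad_k: float = VOXEL_MAD_K
    tr_mad_k: float = TR_MAD_K

    def confound_columns(self, n_tr: int) -> np.ndarray:
        """One delta (indicator) regressor per flagged TR; (n_tr, n_flagged)."""
        cols = np.zeros((n_tr, len(self.flagged_trs)))
        for j, tr in enumerate(self.flagged_trs):
            cols[tr, j] = 1.0
        return cols


@dataclass(frozen=True)
class ConfoundMatrix:
    columns: np.ndarray  # (t, k)
    provenance: tuple[str, ...]
    variance_explained: float = float("nan")

    @property
    def k(self) -> int:
        return self.columns.shape[1]


def linear_detrend(series: BoldSeries) -> BoldSeries:
    """Remove each voxel's least-squares linear trend, preserving its mean."""
    if series.n_tr < 3:
        raise ValueError("need at least 3 time points to detrend")
    d = series.data
    t = np.arange(series.n_tr, dtype=float)
    tc = t - t.mean()
    flat = d.reshape(-1, series.n_tr)
    slope = (flat @ tc) / (tc @ tc)
    out = flat - slope[:, None] * tc[None, :]
    return BoldSeries(
        out.reshape(d.shape),
        tr=series.tr,
        acquisition_id=series.acquisition_id,
        eye=series.eye,
        stimulus_label=series.stimulus_label,
    )


def detect_spikes(
    series: BoldSeries,
    voxel_k: float = VOXEL_MAD_K,
    tr_k: float = TR_MAD_K,
    two_sided: bool = False,
    mask: np.ndarray | None = None,
) -> SpikeEvents:
    """Two-stage MAD spike detector for transient global artifacts.

    Stage 1 (per voxel, over time): a sample is an outlier iff it lies at
    least ``voxel_k`` MAD above that voxel's median (one-sided by default;
    ``two_sided`` switches to |deviation|).  Stage 2 (per TR): count the
    outlier voxels in each TR; a TR is flagged iff its count lies at least
    ``tr_k`` MAD above the median count, with the count-MAD floored at one
    count (on clean data most TRs have zero noisy voxels and the raw MAD
    collapses to 0).  Degenerate inputs flag nothing: a voxel with zero
    temporal MAD contributes no outliers, and a uniform count vector (e.g.
    constant data) yields no flagged TRs.
    """
    d = series.data
    flat = d.reshape(-1, series.n_tr)
    if mask is not None:
        flat = flat[np.asarray(mask, bool).reshape(-1)]
    med = np.median(flat, axis=1, keepdims=True)
    mad = np.median(np.abs(flat - med), axis=1, keepdims=True)
    dev = np.abs(flat - med) if two_sided else flat - med
    with np.errstate(invalid="ignore"):
        outlier = (mad > 0) & (dev >= voxel_k * mad)
    counts = outlier.sum(axis=0).astype(float)

    cmed = np.median(counts)
    cmad = np.median(np.abs(counts - cmed))
    if np.all(counts == counts[0]):
        # uniform counts carry no outlier information (e.g. constant data)
        flagged = np.array([], dtype=int)
    else:
        # floor the count-MAD at 1 (its resolution): on clean data most TRs
        # have zero noisy voxels and the raw MAD collapses to 0
        flagged = np.flatnonzero(counts >= cmed + tr_k * max(cmad, 1.0))
    return SpikeEvents(flagged, counts, voxel_mad_k=voxel_k, tr_mad_k=tr_k)


def build_motion_regressors(motion_params: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-body parameters to the 24-regressor set: originals,
    backward-difference temporal derivatives (first row 0), and squares of
    both."""
    mp = np.asarray(motion_params, dtype=float)
    if mp.ndim != 2 or mp.shape[1] < 6:
        raise ValueError("motion parameters must be a (t, 6) table")
    mp = mp[:, :6]
    deriv = np.vstack([np.zeros((1, 6)), np.diff(mp, axis=0)])
    return np.hstack([mp, deriv, mp**2, deriv**2])


def motion_confounds(motion_params: np.ndarray, variance: float = PCA_VARIANCE) -> ConfoundMatrix:
    """24 motion regressors reduced by PCA.

    From the 6 rigid-body parameters build 24 columns — the originals,
    their backward-difference temporal derivatives (first row 0), and the
    squares of both — then center and keep the smallest leading set of
    principal components whose cumulative variance reaches ``variance``
    (default 95%).
    """
    X = build_motion_regressors(motion_params)  # (t, 24)
    Xc = X - X.mean(axis=0)
    total_var = float((Xc**2).sum())
    if total_var == 0:
        warnings.warn("zero motion: no confound components retained")
        return ConfoundMatrix(np.empty((X.shape[0], 0)), (), 0.0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var_frac = np.cumsum(s**2) / (s**2).sum()
    k = int(np.searchsorted(var_frac, variance) + 1)
    pcs = U[:, :k] * s[:k]
    return ConfoundMatrix(
        pcs,
        tuple(f"motion-pca" for _ in range(k)),
        variance_explained=float(var_frac[k - 1]),
    )


def combine_confounds(
    motion: ConfoundMatrix | None, spikes: SpikeEvents | None, n_tr: int
) -> ConfoundMatrix:
    """Stack motion-PCA and spike indicator columns into one matrix."""
    cols, prov = [], []
    if motion is not None and motion.k:
        cols.append(motion.columns)
        prov += list(motion.provenance)
    if spikes is not None and len(spikes.flagged_trs):
        cols.append(spikes.confound_columns(n_tr))
        prov += [f"spike-{tr}" for tr in spikes.flagged_trs]
    if not cols:
        return ConfoundMatrix(np.empty((n_tr, 0)), ())
    return ConfoundMatrix(
        np.hstack(cols),
        tuple(prov),
        variance_explained=motion.variance_explained if motion is not None else float("nan"),
    )


def regress_confounds(series: BoldSeries, confounds: ConfoundMatrix) -> BoldSeries:
    """Project each voxel onto the complement of the confound span,
    restoring the voxel mean.  Rank-deficient confound sets are reduced to
    an orthonormal basis (dependent columns dropped with a warning)."""
    C = np.asarray(confounds.columns, float)
    if C.shape[0] != series.n_tr:
        raise ValueError("confound rows must match the number of TRs")
    if C.shape[1] == 0:
        return series
    Cc = C - C.mean(axis=0)
    Q, R = np.linalg.qr(Cc)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} rank-deficient confound column(s)")
        Q = Q[:, keep]
    d = series.data
    flat = d.reshape(-1, series.n_tr)
    means = flat.mean(axis=1, keepdims=True)
    resid = (flat - means) - (flat - means) @ Q @ Q.T
    return BoldSeries(
        (resid + means).reshape(d.shape),
        tr=series.tr,
        acquisition_id=series.acquisition_id,
        eye=series.eye,
        stimulus_label=series.stimulus_label,
    )


def mirror_average(volume: np.ndarray, axis: int = 0) -> np.ndarray:
    """Average a volume with its sagittal mirror image: (v + flip(v)) / 2.

    The midline is the center of the mirrored axis, which requires the
    volume to be in template space with the sagittal plane at the axis
    midpoint.  The output is exactly mirror-symmetric and the operation is
    idempotent.
    """
    v = np.asarray(volume, dtype=float)
    return 0.5 * (v + np.flip(v, axis=axis))
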