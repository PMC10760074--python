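"""Configuration, file I/O glue, and the end-to-end study orchestrator.

``run_study`` chains the pipeline in the order the analysis runs: design
the spectral modulations on the synthetic device, simulate (or load) the
pupillometry and fMRI sessions, run both analysis pipelines, and emit
per-condition tables plus a machine-readable manifest of every artifact
with content hashes.  All floating-point outputs are serialized with 9
significant digits so manifests are stable across runs with the same
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boldmodel, boldprep, pupil, stimdesign, synth
from .photoreceptors import canine_sensitivities, default_grid

__all__ = ["RunConfig", "run_study", "load_config", "save_config"]

log = logging.getLogger("conedrive")

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_NUMERICAL_ERROR = 4


@dataclass
class RunConfig:
    """Study-level configuration with per-stage overrides.

    Thresholds carry the analysis defaults: spike detection at 6 / 25 MAD,
    motion PCA at 95% variance, acquisition QC at the 50% poor-frame
    boundary, and a silencing tolerance of 1e-3 contrast.
    """

    preset: str = "WT"
    seed: int = 0
    out_dir: str = "conedrive_out"
    n_primaries: int = 56
    fwhm_nm: float = 16.0
    silencing_tolerance: float = 1e-3
    design_n_starts: int = 20
    pupil_acq_per_condition: int = 4
    pupil_noise_sd_pct: float = 2.0
    bold_shape: tuple = (24, 24, 16)
    bold_n_tr: int = 144
    spike_voxel_k: float = 6.0
    spike_tr_k: float = 25.0
    pca_variance: float = 0.95
    qc_poor_fraction: float = 0.5
    overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.preset not in synth.PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if not (0 < self.pca_variance <= 1):
            raise ValueError("pca_variance must lie in (0, 1]")
        if not (0 <= self.qc_poor_fraction <= 1):
            raise ValueError("qc_poor_fraction must lie in [0, 1]")
        if self.silencing_tolerance <= 0:
            raise ValueError("silencing tolerance must be positive")


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["bold_shape"] = list(cfg.bold_shape)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "bold_shape" in d:
        d["bold_shape"] = tuple(d["bold_shape"])
    return RunConfig(**d)


def _fmt(x: float) -> float:
    """Round to 9 significant digits for stable serialization."""
    return float(f"{x:.9g}")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# --------------------------------------------------------------------------
# format glue

def load_spectrum_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read `wavelength_nm,value` CSV into (wavelengths, values)."""
    df = pd.read_csv(path)
    return df["wavelength_nm"].to_numpy(float), df["value"].to_numpy(float)


def save_spectrum_csv(path: str | Path, wavelengths: np.ndarray, values: np.ndarray) -> None:
    pd.DataFrame({"wavelength_nm": wavelengths, "value": values}).to_csv(path, index=False)


def load_area_series_csv(path: str | Path) -> pupil.PupilTimeSeries:
    """Read `t_s,area_px2,valid` CSV into a percent-change series."""
    df = pd.read_csv(path)
    return pupil.percent_change_series(
        df["t_s"].to_numpy(float),
        df["area_px2"].to_numpy(float),
        df["valid"].to_numpy(bool) if "valid" in df else None,
    )


def save_area_series_csv(path: str | Path, ts: pupil.PupilTimeSeries, base_area: float = 5000.0) -> None:
    pd.DataFrame(
        {
            "t_s": ts.time,
            "area_px2": synth.pupil_area_series(ts, base_area),
            "valid": ts.valid_mask.astype(int),
        }
    ).to_csv(path, index=False)


def load_motion_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(float)[:, :6]


def save_bold_nifti(path: str | Path, series: boldprep.BoldSeries) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(series.data.astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, series.tr))
    nib.save(img, str(path))


def load_bold_nifti(path: str | Path, **meta) -> boldprep.BoldSeries:
    import nibabel as nib

    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 3.0
    return boldprep.BoldSeries(np.asarray(img.dataobj, float), tr=meta.pop("tr", tr), **meta)


# --------------------------------------------------------------------------
# pipelines

def preprocess_bold(
    series: boldprep.BoldSeries,
    motion: np.ndarray,
    voxel_k: float = 6.0,
    tr_k: float = 25.0,
    pca_variance: float = 0.95,
) -> tuple[boldprep.BoldSeries, boldprep.SpikeEvents]:
    """Detrend -> spike detection -> motion-PCA + spike confound regression."""
    detrended = boldprep.linear_detrend(series)
    spikes = boldprep.detect_spikes(detrended, voxel_k=voxel_k, tr_k=tr_k)
    mot = boldprep.motion_confounds(motion, variance=pca_variance)
    conf = boldprep.combine_confounds(mot, spikes, detrended.n_tr)
    return boldprep.regress_confounds(detrended, conf), spikes


def analyze_pupil_session(
    session: dict[str, list[pupil.PupilTimeSeries]],
) -> dict[str, pupil.PupilResponseFit]:
    """Exhaustive-bootstrap response fits per stimulus condition."""
    return {cond: pupil.bootstrap_sem(series) for cond, series in session.items()}


def analyze_bold_session(
    session: dict,
    fit_mask: np.ndarray | None = None,
    spike_voxel_k: float = 6.0,
    spike_tr_k: float = 25.0,
    pca_variance: float = 0.95,
) -> dict:
    """Preprocess and forward-model one synthetic BOLD session; summarize
    cortex/LGN responses per eye."""
    design = session["design"]
    cleaned = []
    for series, motion in zip(session["acquisitions"], session["motion"]):
        c, _ = preprocess_bold(
            series, motion, voxel_k=spike_voxel_k, tr_k=spike_tr_k, pca_variance=pca_variance
        )
        cleaned.append(c)
    mask = fit_mask
    if mask is None:
        mask = session["cortex_mask"] | session["lgn_mask"]
    fits = boldmodel.fit_forward_model(cleaned, design, basis=session["basis"], mask=mask)
    n_acq = len(cleaned)
    left = np.arange(n_acq // 2)
    right = np.arange(n_acq // 2, n_acq)
    out = {"fits": fits, "rois": {}}
    for name in ("cortex", "lgn"):
        roi_mask = session[f"{name}_mask"]
        out["rois"][name] = {
            "all": boldmodel.roi_response(fits, roi_mask),
            "left_eye": boldmodel.roi_response(fits, roi_mask, acquisition_subset=left),
            "right_eye": boldmodel.roi_response(fits, roi_mask, acquisition_subset=right),
        }
    return out


def run_study(config: RunConfig) -> dict:
    """Full synthetic study: design -> synthesize -> analyze -> report.

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}

    # stage 1: stimulus design on the synthetic device
    log.info("designing modulations")
    grid = default_grid()
    sens = canine_sensitivities(grid)
    device = synth.synth_device(config.n_primaries, config.fwhm_nm, grid, seed=config.seed)
    ls = stimdesign.design_modulation(
        device,
        ("L", "S"),
        ("rod", "mel"),
        sens,
        tolerance=config.silencing_tolerance,
        n_starts=config.design_n_starts,
        seed=config.seed,
    )
    rodmel = stimdesign.design_modulation(
        device,
        ("rod", "mel"),
        ("L", "S"),
        sens,
        tolerance=config.silencing_tolerance,
        n_starts=config.design_n_starts,
        seed=config.seed,
    )
    lf = stimdesign.light_flux_modulation(device, sens)
    modulations = {"LS": ls, "RodMel": rodmel, "LightFlux": lf}
    manifest["stages"]["design"] = {
        name: {p: _fmt(c) for p, c in m.contrast_report.bipolar.items()}
        for name, m in modulations.items()
    }

    # stage 2: pupillometry
    log.info("simulating and analyzing pupillometry session")
    contrasts = {
        name: {p: m.contrast_report.bipolar[p] for p in sens} for name, m in modulations.items()
    }
    contrasts["LminusS"] = synth.NOMINAL_CONTRASTS["LminusS"]
    pparams = synth.PupilResponseParams(
        noise_sd_pct=config.pupil_noise_sd_pct, contrasts=contrasts
    )
    pupil_session = synth.synth_pupil_session(
        config.preset,
        synth.SessionSpec(
            acquisitions_per_condition=config.pupil_acq_per_condition, seed=config.seed
        ),
        pparams,
    )
    pupil_fits = analyze_pupil_session(pupil_session)
    pupil_table = {
        cond: {
            "amplitude_pct": _fmt(f.amplitude),
            "phase_rad": _fmt(f.phase),
            "sem_amplitude": _fmt(f.sem_amplitude),
            "sem_phase": _fmt(f.sem_phase),
            "n_acq": f.n_acq,
        }
        for cond, f in pupil_fits.items()
    }
    manifest["stages"]["pupil"] = pupil_table
    (out_dir / "pupil_fits.json").write_text(json.dumps(pupil_table, indent=2))

    # stage 3: fMRI
    log.info("simulating and analyzing BOLD session")
    bparams = synth.BoldMapParams(shape=tuple(config.bold_shape), n_tr=config.bold_n_tr)
    bold_session = synth.synth_bold_session(config.preset, bparams, seed=config.seed)
    bold = analyze_bold_session(
        bold_session,
        spike_voxel_k=config.spike_voxel_k,
        spike_tr_k=config.spike_tr_k,
        pca_variance=config.pca_variance,
    )
    rows = []
    for roi_name, eyes in bold["rois"].items():
        for eye_name, res in eyes.items():
            rows.append(
                {
                    "preset": config.preset,
                    "roi": roi_name,
                    "eye": eye_name,
                    "mean_pct": _fmt(res.mean_pct),
                    "sem": _fmt(res.sem_pct),
                    "n_acq": res.n_acq,
                }
            )
    roi_df = pd.DataFrame(rows)
    roi_df.to_csv(out_dir / "roi_responses.csv", index=False)
    manifest["stages"]["bold"] = rows

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    for f in sorted(out_dir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _hash_file(f)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
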