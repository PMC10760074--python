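"""Block design construction, forward-model fitting, R² maps, ROIs."""

import numpy as np
import pytest

from conedrive.boldmodel import (
    OVERSAMPLE,
    StimulusDesign,
    build_design,
    define_rois,
    fit_forward_model,
    hrf_basis,
    r2_map,
    roi_response,
)
from conedrive.boldprep import BoldSeries
from conedrive.synth import _block_response


@pytest.fixture(scope="module")
def design():
    return StimulusDesign()  # TR 3 s, 12 s on / 12 s off, 432 s


@pytest.fixture(scope="module")
def basis(design):
    return hrf_basis(design.tr)


def make_noiseless_series(design, basis, betas, shape=(2, 2, 1), weights=(1.0, 0.0, 0.0)):
    """Acquisitions whose every voxel responds with the given per-acquisition
    betas under the peak-normalized kernel."""
    resp = _block_response(design, basis, np.asarray(weights))
    resp = resp - resp.mean()  # amplitude defined about the acquisition mean
    out = []
    for b in betas:
        pct = b * resp
        raw = 1000.0 * (1 + pct / 100.0)
        vol = np.broadcast_to(raw, shape + (design.n_tr,)).copy()
        out.append(BoldSeries(vol, tr=design.tr))
    return out


class TestBuildDesign:
    def test_block_count_and_duty_cycle(self, design):
        box = build_design(design)
        onsets = np.flatnonzero(np.diff(np.concatenate([[0.0], box])) == 1)
        assert len(onsets) == 18  # 432 s / 24 s cycle
        assert box.mean() == pytest.approx(0.5)

    def test_first_block_occupies_first_four_trs(self, design):
        box = build_design(design)
        tr_samples = box[:: OVERSAMPLE][:8]
        np.testing.assert_array_equal(tr_samples, [1, 1, 1, 1, 0, 0, 0, 0])


class TestForwardModel:
    def test_noiseless_beta_recovery(self, design, basis):
        """Known kernel and betas are recovered essentially exactly."""
        true_betas = [0.5, 0.4, 0.6, 0.5, 0.45, 0.55]
        acqs = make_noiseless_series(design, basis, true_betas)
        fits = fit_forward_model(acqs, design, basis=basis, n_starts=1)
        for v in range(fits.betas.shape[0]):
            np.testing.assert_allclose(fits.betas[v], true_betas, atol=1e-3)
        assert np.all(fits.r2 > 0.999)
        assert fits.mean_beta[0] == pytest.approx(np.mean(true_betas), abs=1e-3)

    def test_noiseless_recovery_with_shifted_kernel(self, design, basis):
        """A kernel off the canonical shape (nonzero derivative weights) is
        absorbed by the HRF weights, leaving betas unbiased."""
        true_betas = [0.3, 0.5, 0.2, 0.4, 0.6, 0.35]
        acqs = make_noiseless_series(design, basis, true_betas, weights=(1.0, 0.4, 0.2))
        fits = fit_forward_model(acqs, design, basis=basis, n_starts=3, seed=0)
        np.testing.assert_allclose(fits.betas[0], true_betas, atol=1e-3)

    def test_negative_response_sign_preserved(self, design, basis):
        """Thalamic-style negative responses stay negative."""
        acqs = make_noiseless_series(design, basis, [-0.4] * 6)
        fits = fit_forward_model(acqs, design, basis=basis, n_starts=1)
        assert np.all(fits.betas < -0.35)

    def test_null_voxel_mean_beta_centered_at_zero(self, design, basis):
        """Across seeds, pure-noise voxels give mean betas centered on 0."""
        means = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            acqs = [
                BoldSeries(1000 + rng.standard_normal((1, 1, 1, design.n_tr)), tr=design.tr)
                for _ in range(6)
            ]
            fits = fit_forward_model(acqs, design, basis=basis, n_starts=1)
            means.append(fits.mean_beta[0])
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 2.5 * se + 1e-3

    def test_joint_fit_matches_per_acquisition_ols_with_fixed_kernel(self, design, basis):
        """With the kernel fixed at truth, jointly fitted betas equal
        acquisition-by-acquisition OLS projections."""
        true_betas = [0.5, -0.2, 0.9, 0.1, 0.4, 0.7]
        acqs = make_noiseless_series(design, basis, true_betas)
        fits = fit_forward_model(acqs, design, basis=basis, n_starts=1)
        resp = _block_response(design, basis, np.array([1.0, 0.0, 0.0]))
        rc = resp - resp.mean()
        for a, acq in enumerate(acqs):
            flat = acq.data.reshape(-1, design.n_tr)[0]
            y = 100.0 * (flat - flat.mean()) / flat.mean()
            beta_ols = (rc @ y) / (rc @ rc)
            assert fits.betas[0, a] == pytest.approx(beta_ols, abs=1e-6)


class TestR2:
    def test_r2_matches_brute_force_sums(self, design, basis):
        rng = np.random.default_rng(0)
        resp = _block_response(design, basis, np.array([1.0, 0.0, 0.0]))
        noise = rng.normal(0, 0.3, design.n_tr)
        pct = 0.5 * resp + noise
        raw = 1000 * (1 + pct / 100.0)
        acq = BoldSeries(np.broadcast_to(raw, (1, 1, 1, design.n_tr)).copy(), tr=design.tr)
        fits = fit_forward_model([acq], design, basis=basis, n_starts=1)
        # brute-force R^2 from the fitted parameters
        flat = raw
        y = 100.0 * (flat - flat.mean()) / flat.mean()
        kern_resp = _block_response(design, basis, fits.hrf_weights[0])
        model = fits.betas[0, 0] * (kern_resp - kern_resp.mean())
        sse = np.sum((y - model) ** 2)
        sst = np.sum(y**2)
        assert fits.r2[0] == pytest.approx(1 - sse / sst, abs=1e-9)

    def test_degenerate_voxel_r2_zero(self, design, basis):
        acq = BoldSeries(np.full((1, 1, 1, design.n_tr), 500.0), tr=design.tr)
        vol = r2_map([acq], design, basis=basis)
        assert vol[0, 0, 0] == 0.0

    def test_perfect_voxel_r2_one(self, design, basis):
        acqs = make_noiseless_series(design, basis, [0.5], shape=(1, 1, 1))
        vol = r2_map(acqs, design, basis=basis)
        assert vol[0, 0, 0] == pytest.approx(1.0, abs=1e-6)


class TestRois:
    def test_two_blobs_found(self):
        vol = np.zeros((20, 20, 10))
        vol[2:6, 2:6, 2:6] = 0.9  # 64 voxels
        vol[12:15, 12:15, 4:7] = 0.8  # 27 voxels
        rois = define_rois(vol, threshold=0.5, min_size=10)
        assert len(rois) == 2
        assert rois[0].label == "cortex" and rois[0].size == 64
        assert rois[1].label == "lgn" and rois[1].size == 27

    def test_threshold_above_max_empty(self):
        vol = np.random.default_rng(0).random((10, 10, 5)) * 0.2
        with pytest.warns(UserWarning):
            assert define_rois(vol, threshold=0.9) == []

    def test_min_size_drops_small_components(self):
        vol = np.zeros((20, 20, 10))
        vol[2:6, 2:6, 2:6] = 0.9
        vol[15, 15, 8] = 0.95  # singleton
        rois = define_rois(vol, threshold=0.5, min_size=10)
        assert len(rois) == 1 and rois[0].size == 64


class TestRoiResponse:
    def test_homogeneous_roi_equals_voxel_mean(self, design, basis):
        betas = [0.5, 0.4, 0.6, 0.5, 0.45, 0.55]
        acqs = make_noiseless_series(design, basis, betas, shape=(3, 3, 1))
        fits = fit_forward_model(acqs, design, basis=basis, n_starts=1)
        roi = np.ones((3, 3, 1), bool)
        res = roi_response(fits, roi)
        assert res.mean_pct == pytest.approx(np.mean(betas), abs=1e-3)
        assert res.n_acq == 6

    def test_sem_matches_arithmetic_oracle(self, design, basis):
        betas = [0.5, 0.4, 0.6, 0.5, 0.45, 0.55]
        acqs = make_noiseless_series(design, basis, betas, shape=(2, 2, 1))
        fits = fit_forward_model(acqs, design, basis=basis, n_starts=1)
        res = roi_response(fits, np.ones((2, 2, 1), bool))
        per_acq = fits.betas.mean(axis=0)
        assert res.sem_pct == pytest.approx(per_acq.std(ddof=1) / np.sqrt(6), rel=1e-9)

    def test_acquisition_subset(self, design, basis):
        betas = [0.9, 0.9, 0.9, 0.1, 0.1, 0.1]
        acqs = make_noiseless_series(design, basis, betas, shape=(2, 2, 1))
        fits = fit_forward_model(acqs, design, basis=basis, n_starts=1)
        left = roi_response(fits, np.ones((2, 2, 1), bool), acquisition_subset=[0, 1, 2])
        right = roi_response(fits, np.ones((2, 2, 1), bool), acquisition_subset=[3, 4, 5])
        assert left.mean_pct == pytest.approx(0.9, abs=1e-3)
        assert right.mean_pct == pytest.approx(0.1, abs=1e-3)

    def test_empty_roi_rejected(self, design, basis):
        acqs = make_noiseless_series(design, basis, [0.5] * 6)
        fits = fit_forward_model(acqs, design, basis=basis, n_starts=1)
        with pytest.raises(IndexError):
            roi_response(fits, np.zeros((2, 2, 1), bool))
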