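import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stdifftcv.io_sequence import ImageFrame
from stdifftcv.levelset import (
    CVWeights,
    LevelSetField,
    checkerboard_phi,
    cv_energy,
    cv_evolve,
    dirac_eps,
    heaviside_eps,
    mask_from_phi,
    phi_from_mask,
    tcv_sequence,
)
from stdifftcv.metrics import dice


def energy_oracle(phi, img, w):
    """Direct per-pixel summation of the regularized functional."""
    h, wd = phi.shape
    hphi = np.empty_like(phi)
    for i in range(h):
        for j in range(wd):
            hphi[i, j] = 0.5 * (1 + (2 / np.pi) * np.arctan(phi[i, j] / w.epsilon))
    c1 = (img * hphi).sum() / hphi.sum()
    c2 = (img * (1 - hphi)).sum() / (1 - hphi).sum()
    p = np.pad(phi, 1, mode="edge")
    total = 0.0
    for i in range(h):
        for j in range(wd):
            gx = 0.5 * (p[i + 1, j + 2] - p[i + 1, j])
            gy = 0.5 * (p[i + 2, j + 1] - p[i, j + 1])
            delta = w.epsilon / (np.pi * (w.epsilon**2 + phi[i, j] ** 2))
            total += w.mu * delta * np.hypot(gy, gx)
            total += w.nu * hphi[i, j]
            total += w.lambda1 * hphi[i, j] * (img[i, j] - c1) ** 2
            total += w.lambda2 * (1 - hphi[i, j]) * (img[i, j] - c2) ** 2
    return total, c1, c2


class TestEnergy:
    def test_matched_two_valued_image_zero_fit(self):
        """With phi saturated and matching the two regions, the fitting
        terms vanish and (mu = nu = 0) the energy is ~0."""
        img = np.where(np.arange(16)[None, :] < 8, 0.4, 0.9) * np.ones((16, 1))
        phi = np.where(img >= 0.5, 1e9, -1e9)
        w = CVWeights(mu=0.0, nu=0.0)
        energy, c1, c2 = cv_energy(phi, img, w)
        assert energy == pytest.approx(0.0, abs=1e-6)
        assert c1 == pytest.approx(0.9, abs=1e-6)
        assert c2 == pytest.approx(0.4, abs=1e-6)

    def test_constant_image_zero_energy(self):
        rng = np.random.default_rng(0)
        phi = rng.normal(0, 2, (12, 12))
        energy, c1, c2 = cv_energy(phi, np.full((12, 12), 7.0),
                                   CVWeights(mu=0.0, nu=0.0))
        assert c1 == pytest.approx(7.0) and c2 == pytest.approx(7.0)
        assert energy == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 255, (16, 16))
        phi = rng.normal(0, 3, (16, 16))
        w = CVWeights()
        energy, c1, c2 = cv_energy(phi, img, w)
        exp_energy, exp_c1, exp_c2 = energy_oracle(phi, img, w)
        assert energy == pytest.approx(exp_energy, abs=1e-9 * max(exp_energy, 1))
        assert c1 == pytest.approx(exp_c1, abs=1e-9)
        assert c2 == pytest.approx(exp_c2, abs=1e-9)

    def test_phase_swap_symmetry(self):
        """With mu = nu = 0 and lambda1 = lambda2 the energy is invariant
        under exchanging the two phases (phi -> -phi)."""
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 255, (16, 16))
        phi = rng.normal(0, 3, (16, 16))
        w = CVWeights(mu=0.0, nu=0.0)
        e1, _, _ = cv_energy(phi, img, w)
        e2, _, _ = cv_energy(-phi, img, w)
        assert e1 == pytest.approx(e2, rel=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(-1e6, 1e6), st.floats(0.1, 10))
def test_heaviside_partition_of_unity(z, eps):
    assert heaviside_eps(z, eps) + heaviside_eps(-z, eps) == pytest.approx(
        1.0, abs=1e-15)
    assert dirac_eps(z, eps) >= 0


class TestEvolve:
    def test_disk_converges_with_monotone_energy(self, disk_image,
                                                 enclosing_circle_phi):
        img, truth = disk_image
        res = cv_evolve(enclosing_circle_phi, img, CVWeights())
        assert dice(res.mask, truth) >= 0.99
        trace = np.array(res.energy_trace)
        rel = np.diff(trace) / np.maximum(np.abs(trace[:-1]), 1.0)
        assert np.all(rel <= 1e-6)
        assert res.i_final <= CVWeights().max_iter

    def test_agrees_with_reference_chan_vese(self, disk_image):
        """Independent cross-check against the scikit-image implementation."""
        from skimage.segmentation import chan_vese

        img, truth = disk_image
        ref = chan_vese(img / 255.0, mu=0.2, lambda1=1, lambda2=1, dt=0.5,
                        max_num_iter=500, init_level_set="checkerboard")
        mine = cv_evolve(checkerboard_phi(img.shape), img, CVWeights())
        fg = mine.mask if img[mine.mask].mean() > img[~mine.mask].mean() \
            else ~mine.mask
        ref_fg = ref if img[ref].mean() > img[~ref].mean() else ~ref
        assert dice(fg, ref_fg) >= 0.98

    def test_empty_phase_flagged(self):
        res = cv_evolve(np.full((16, 16), -5.0), np.full((16, 16), 9.0),
                        CVWeights(max_iter=2))
        assert res.empty_phase_flag


class TestTemporalLinking:
    def test_handoff_is_bit_exact(self, disk_image, enclosing_circle_phi):
        img, _ = disk_image
        w = CVWeights(max_iter=120)
        results = tcv_sequence([img, img], enclosing_circle_phi, w)
        first = cv_evolve(enclosing_circle_phi, img, w)
        second = cv_evolve(first.phi, img, w)
        np.testing.assert_array_equal(results[1][1].phi, second.phi)

    def test_warm_start_converges_faster(self, disk_image, enclosing_circle_phi):
        img, _ = disk_image
        w = CVWeights()
        cold = cv_evolve(enclosing_circle_phi, img, w)
        warm = cv_evolve(cold.phi, img, w)
        assert warm.i_final <= cold.i_final

    def test_identical_frames_identical_masks(self, disk_image,
                                              enclosing_circle_phi):
        img, _ = disk_image
        results = tcv_sequence([img] * 3, enclosing_circle_phi, CVWeights())
        for mask, _ in results[1:]:
            np.testing.assert_array_equal(mask.labels, results[0][0].labels)

    def test_moving_disk_tracked(self):
        from stdifftcv.simulate import CellSpec, SimConfig, generate_sequence

        cfg = SimConfig(
            shape=(64, 64), n_frames=6, n_cells=1,
            cells=(CellSpec(center=(26.0, 26.0), velocity=(1.4, 1.4),
                            radii=(12.0, 12.0), amplitude=180.0),),
            background=20.0, noise_sd=2.0, seed=13)
        seq, gt = generate_sequence(cfg)
        phi0 = phi_from_mask(gt[0].binary, redistance=True)
        results = tcv_sequence(seq, phi0, CVWeights())
        for (mask, _), ref in zip(results, gt):
            assert dice(mask, ref) >= 0.95


class TestMaskPhiConversions:
    def test_round_trip_preserves_mask(self):
        rng = np.random.default_rng(4)
        mask = rng.uniform(0, 1, (20, 20)) > 0.7
        for redistance in (False, True):
            phi = phi_from_mask(mask, redistance=redistance)
            np.testing.assert_array_equal(phi >= 0, mask)

    def test_mask_from_phi_labels_components(self):
        phi = np.full((10, 10), -1.0)
        phi[1:3, 1:3] = 1.0
        phi[7:9, 7:9] = 1.0
        mask = mask_from_phi(phi)
        assert mask.n_instances == 2
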