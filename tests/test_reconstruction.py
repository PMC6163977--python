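"""Posterior sampling, marginals, point estimates and 2-D slices."""

import numpy as np
import pytest

import infomech as im
from infomech.information import CovarianceModel
from infomech.models import MaterialParams
from infomech.reconstruction import PosteriorSamples


def make_posterior(points, misfits, param="mu", bounds=None):
    """Hand-built single-parameter posterior sample for estimator tests."""
    bounds = bounds or im.default_bounds()
    h = im.hypothesis("H3") if param == "mu" else None
    phys = np.column_stack([im.from_normalized(points[:, 0], bounds[param])])
    return PosteriorSamples(
        hypothesis=h,
        bounds=bounds,
        points=points,
        physical=phys,
        misfits=misfits,
        seed=0,
        protocol=im.DEFAULT_PROTOCOL,
    )


def noiseless_obs(hid, m, protocol, var=1e-6):
    clean = im.simulate(hid, m, protocol)
    return im.ObservationSet(
        times=clean.times,
        stresses=clean.stresses,
        strains=clean.strains,
        variances=np.full(clean.strains.shape, var),
        provenance={
            "origin": "synthetic",
            "protocol": {
                "sigma_max": protocol.sigma_max,
                "half_duration": protocol.half_duration,
                "dt_sample": protocol.dt_sample,
            },
        },
    )


class TestReconstruct:
    def test_noiseless_identifiable_1d(self, protocol):
        """With exact H3 data and mu at the cube centre, the minimum-misfit
        sample recovers the modulus to better than 2%."""
        obs = noiseless_obs("H3", MaterialParams(mu=1e6), protocol)
        ps = im.reconstruct("H3", obs, seed=0)
        best = ps.physical[np.argmin(ps.misfits), 0]
        assert abs(best - 1e6) / 1e6 < 0.02

    def test_weights_concentrate_as_noise_shrinks(self, protocol):
        """Likelihood concentration: smaller observation variance makes the
        maximum weight dominate the mean weight more strongly."""
        ratios = []
        for var in (1e-2, 1e-4, 1e-6):
            obs = noiseless_obs("H3", MaterialParams(mu=1e6), protocol, var=var)
            ps = im.reconstruct("H3", obs, n_samples=4096, seed=1)
            w = ps.weights
            ratios.append(w.max() / w.mean())
        assert ratios[0] < ratios[1] < ratios[2]

    def test_deterministic_given_seed(self, noisy_obs):
        a = im.reconstruct("H1", noisy_obs, n_samples=1024, seed=9)
        b = im.reconstruct("H1", noisy_obs, n_samples=1024, seed=9)
        np.testing.assert_array_equal(a.misfits, b.misfits)
        np.testing.assert_array_equal(a.points, b.points)

    def test_default_run_completes_quickly(self, posterior):
        # the reference configuration at N = 2^16: a sub-minute desk-scale run
        assert posterior.n == 2**16
        assert np.all(np.isfinite(posterior.misfits))


class TestMarginals:
    def test_uniform_weights_recover_flat_prior(self):
        pts = im.sample_unit_cube(200_000, 1, seed=2)
        ps = make_posterior(pts, np.zeros(len(pts)))
        curve = im.marginal_1d(ps, "mu", nbins=16)
        # flat density 1 within multinomial noise
        assert np.all(np.abs(curve.density - 1.0) < 0.05)

    def test_gaussian_weights_recover_mode_and_spread(self):
        pts = im.sample_unit_cube(200_000, 1, seed=3)
        u = pts[:, 0]
        J = 0.5 * (u - 0.5) ** 2 / 0.05**2
        ps = make_posterior(pts, J)
        curve = im.marginal_1d(ps, "mu")
        b = ps.bounds["mu"]
        # mode at the cube centre = geometric mean of the bounds
        center = im.from_normalized(0.5, b)
        assert abs(curve.mode - center) / center < b.log_span / 64  # within a bin
        # physical std of a narrow log-normal: m_c * log_span * sd_u
        expected_std = center * b.log_span * 0.05
        assert abs(curve.std - expected_std) / expected_std < 0.15

    def test_marginal_density_normalized(self, posterior):
        for name in ("mu", "eta", "A"):
            curve = im.marginal_1d(posterior, name)
            area = curve.density.sum() / curve.density.shape[0]
            assert area == pytest.approx(1.0, abs=1e-9)
            assert np.all(curve.density >= 0)

    def test_eta_marginal_peaks_near_true_viscosity(self, posterior):
        """The reference dataset pins the viscosity near 10 MPa*s."""
        curve = im.marginal_1d(posterior, "eta")
        assert abs(curve.mode - 1.0e7) / 1.0e7 < 0.25

    def test_inactive_parameter_rejected(self, noisy_obs):
        ps = im.reconstruct("H2", noisy_obs, n_samples=1024, seed=0)
        with pytest.raises(ValueError):
            im.marginal_1d(ps, "A")

    def test_all_zero_weights_signal_falsification(self):
        pts = im.sample_unit_cube(100, 1, seed=4)
        ps = make_posterior(pts, np.full(100, np.inf))
        with pytest.raises(ValueError, match="falsified"):
            im.marginal_1d(ps, "mu")

    def test_mode_stable_when_doubling_samples(self, noisy_obs):
        """Monte-Carlo self-consistency for the well-identified parameters:
        doubling N moves the marginal mode by less than one histogram bin."""
        a = im.reconstruct("H1", noisy_obs, seed=0)
        b = im.reconstruct("H1", noisy_obs, n_samples=2**17, seed=0)
        for name in ("mu", "eta"):
            ca, cb = im.marginal_1d(a, name), im.marginal_1d(b, name)
            bin_factor = np.exp(ca.bounds.log_span / 64)
            assert abs(np.log(ca.mode / cb.mode)) < np.log(bin_factor)


class TestPointEstimate:
    def test_single_sample_returns_it(self):
        pts = np.array([[0.3]])
        ps = make_posterior(pts, np.array([1.0]))
        est = im.point_estimate(ps)
        assert est["joint_mode"]["mu"] == pytest.approx(ps.physical[0, 0])

    def test_tie_breaks_to_lowest_index(self):
        pts = np.array([[0.2], [0.8], [0.5]])
        ps = make_posterior(pts, np.array([1.0, 1.0, 2.0]))
        est = im.point_estimate(ps)
        assert est["sample_index"] == 0

    def test_estimate_matches_maximum_weight_sample(self, posterior):
        est = im.point_estimate(posterior)
        k = int(np.argmax(posterior.weights))
        for j, name in enumerate(posterior.hypothesis.active_params):
            assert est["joint_mode"][name] == pytest.approx(posterior.physical[k, j])


class TestJointSlice:
    def test_single_parameter_hypothesis_refused(self, noisy_obs):
        with pytest.raises(ValueError, match="fewer than two"):
            im.joint_slice_2d("H3", noisy_obs, ("mu", "eta"))

    def test_missing_clamp_value_rejected(self, noisy_obs):
        with pytest.raises(ValueError, match="fixed"):
            im.joint_slice_2d("H1", noisy_obs, ("mu", "eta"))

    def test_symmetric_toy_peaks_at_centre(self, protocol):
        """Noiseless centred H2 data: the 2-D slice peaks at the cube centre."""
        obs = noiseless_obs("H2", MaterialParams(mu=1e6, eta=1e7), protocol, var=1e-4)
        ax_mu, ax_eta, grid = im.joint_slice_2d("H2", obs, ("mu", "eta"), resolution=41)
        i, j = np.unravel_index(np.argmax(grid), grid.shape)
        assert abs(i - 20) <= 1 and abs(j - 20) <= 1

    def test_mu_A_ridge_is_strongly_correlated(self, noisy_obs, posterior):
        """The mu-A slice shows the elongated ridge typical of correlated
        linear/nonlinear moduli: |corr| of the high-density region > 0.5."""
        est = im.point_estimate(posterior)
        fixed = {"eta": im.to_normalized(est["marginal_modes"]["eta"],
                                         posterior.bounds["eta"])}
        # fine resolution: the mu direction of the ridge is much narrower
        # than the A direction
        _, _, grid = im.joint_slice_2d("H1", noisy_obs, ("mu", "A"),
                                       fixed=fixed, resolution=512)
        ii, jj = np.meshgrid(np.arange(512), np.arange(512), indexing="ij")
        w = grid / grid.sum()
        mi, mj = (w * ii).sum(), (w * jj).sum()
        cov = (w * (ii - mi) * (jj - mj)).sum()
        rho = cov / np.sqrt((w * (ii - mi) ** 2).sum() * (w * (jj - mj) ** 2).sum())
        assert abs(rho) > 0.5
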