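"""FRAP fitting: erf profiles, recovery regression, TIRF correction, groups."""

import itertools
import math

import numpy as np
import pytest

from pcpkit.config import InvalidParameterError, SimConfig
from pcpkit.frap import (Kymograph, compare_groups, erf_profile,
                         extract_kymograph, fit_erf_profile, fit_recovery,
                         fit_stripe_profile, stripe_profile, tirf_frap_correct)
from pcpkit.synthetic import (FrapTruth, render_boundary_frap_movie,
                              render_tirf_frap_movie, simulate_frap_movie)


def _sweep_dx(D: float) -> float:
    # resolve the erf width relative to the diffusion scale
    return max(0.05, 0.1 * math.sqrt(D / 0.01))


def _simulate_kymo(D, k, seed, snr=20.0):
    dx = _sweep_dx(D)
    T = min(2.0 / k, 600.0) if k > 0 else 100.0 * dx**2 / max(D, 1e-6)
    L_final = math.sqrt(4 * D * T + (2 * dx) ** 2)
    dom = max(6 * L_final, 40 * dx, 20.0)
    truth = FrapTruth(D=D, k=k, A=0.8, U0=100.0, dx=dx, domain_length=dom)
    frames, _, _ = simulate_frap_movie(truth, T, T / 30,
                                       noise_sigma=truth.U0 / snr,
                                       rng=np.random.default_rng(seed))
    return Kymograph(frames, dx=dx, dt=T / 30), T


class TestErfFit:
    def test_flat_profile_returns_zero_depth(self):
        x = np.linspace(0, 20, 50)
        fit = fit_erf_profile(x, np.full(50, 100.0))
        assert fit.flat
        assert fit.U0 == pytest.approx(100.0)
        assert fit.A == 0.0

    def test_midpoint_identity(self):
        x = np.linspace(0, 30, 200)
        y = erf_profile(x, 100.0, 0.6, 14.0, 2.5)
        fit = fit_erf_profile(x, y)
        mid = erf_profile(fit.x0, fit.U0, fit.A, fit.x0, fit.L)
        assert mid == pytest.approx(fit.U0 * (1 - fit.A / 2), rel=1e-6)

    def test_noiseless_parameters_recovered(self):
        x = np.linspace(0, 30, 120)
        y = erf_profile(x, 100.0, 0.8, 12.3, 2.0)
        fit = fit_erf_profile(x, y)
        assert fit.U0 == pytest.approx(100.0, rel=1e-4)
        assert fit.A == pytest.approx(0.8, rel=1e-4)
        assert fit.x0 == pytest.approx(12.3, rel=1e-4)
        assert fit.L == pytest.approx(2.0, rel=1e-4)

    def test_agrees_with_grid_search_oracle(self):
        """Exhaustive coarse grid search over (A, x0, L) finds the same
        minimum as the least-squares fit, within the grid resolution."""
        x = np.linspace(0, 24, 60)
        y = erf_profile(x, 100.0, 0.7, 10.0, 3.0)
        best = (np.inf, None)
        for A in np.arange(0.1, 1.01, 0.1):
            for x0 in np.arange(6.0, 14.1, 0.5):
                for L in np.arange(1.0, 6.1, 0.5):
                    sse = np.sum((y - erf_profile(x, 100.0, A, x0, L)) ** 2)
                    if sse < best[0]:
                        best = (sse, (A, x0, L))
        fit = fit_erf_profile(x, y)
        A_g, x0_g, L_g = best[1]
        assert abs(fit.A - A_g) <= 0.1
        assert abs(fit.x0 - x0_g) <= 0.5
        assert abs(fit.L - L_g) <= 0.5

    def test_stripe_profile_noiseless_recovery(self):
        x = np.linspace(0, 40, 160)
        y = stripe_profile(x, 90.0, 0.7, 15.0, 25.0, 2.0)
        fit = fit_stripe_profile(x, y)
        assert fit.A == pytest.approx(0.7, rel=1e-3)
        assert fit.xl == pytest.approx(15.0, rel=1e-3)
        assert fit.xr == pytest.approx(25.0, rel=1e-3)
        assert fit.L == pytest.approx(2.0, rel=1e-3)

    def test_too_short_profile_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_erf_profile(np.arange(5.0), np.arange(5.0))


class TestRecoveryFit:
    def test_pure_diffusion_recovery(self):
        kymo, T = _simulate_kymo(0.1, 0.0, seed=0)
        fit = fit_recovery(kymo)
        assert abs(fit.D / 0.1 - 1) < 0.15
        assert fit.k < 0.1 / T

    def test_pure_exchange_recovery(self):
        truth = FrapTruth(D=1e-6, k=0.01, A=0.8, U0=100.0, dx=0.1,
                          domain_length=30.0)
        frames, _, _ = simulate_frap_movie(truth, 200.0, 8.0, noise_sigma=5.0,
                                           rng=np.random.default_rng(1))
        fit = fit_recovery(Kymograph(frames, dx=0.1, dt=8.0))
        assert abs(fit.k / 0.01 - 1) < 0.10
        assert fit.D < 0.01

    def test_time_invariant_kymograph_returns_zero_rates(self):
        x = np.linspace(0, 30, 120)
        profile = erf_profile(x, 100.0, 0.8, 15.0, 2.0)
        kymo = Kymograph(np.tile(profile, (10, 1)), dx=0.25, dt=2.0)
        fit = fit_recovery(kymo)
        assert fit.D == pytest.approx(0.0, abs=1e-9)
        assert fit.k == pytest.approx(0.0, abs=1e-9)

    def test_width_growth_monotone_for_pure_diffusion(self):
        kymo, _ = _simulate_kymo(0.1, 0.0, seed=2, snr=50.0)
        fit = fit_recovery(kymo)
        L2 = np.array([f.L for f in fit.frames]) ** 2
        # smoothness: the regression residuals stay small and the overall
        # trend is strictly increasing
        assert L2[-1] > L2[0]
        drops = np.diff(L2) < -0.05 * L2.max()
        assert drops.mean() < 0.1

    def test_registration_offset_changes_only_x0(self):
        kymo, _ = _simulate_kymo(0.1, 0.0, seed=3, snr=1e6)
        fit = fit_recovery(kymo)
        shifted = Kymograph(np.pad(kymo.intensity, ((0, 0), (40, 0)),
                                   mode="edge"), dx=kymo.dx, dt=kymo.dt)
        fit2 = fit_recovery(shifted)
        assert fit2.D == pytest.approx(fit.D, rel=0.05)
        assert fit2.k == pytest.approx(fit.k, abs=1e-4)
        x0s = np.array([f.x0 for f in fit.frames[:5]])
        x0s2 = np.array([f.x0 for f in fit2.frames[:5]])
        assert np.allclose(x0s2 - x0s, 40 * kymo.dx, atol=3 * kymo.dx)

    def test_too_few_frames_rejected(self):
        x = np.linspace(0, 30, 120)
        profile = erf_profile(x, 100.0, 0.8, 15.0, 2.0)
        with pytest.raises(InvalidParameterError):
            fit_recovery(Kymograph(np.tile(profile, (4, 1)), dx=0.25, dt=2.0))


class TestKymographExtraction:
    POLY = np.array([[32.0, 0.0], [32.0, 399.0]])

    def test_static_boundary_zero_shifts(self):
        sim = SimConfig(seed=2, pixel_size=100.0, image_shape=(64, 400))
        truth = FrapTruth(D=0.1, A=0.8, dx=0.1, domain_length=40.0)
        movie, _, _ = render_boundary_frap_movie(truth, 60.0, 3.0, sim,
                                                 noise_sigma=1.0)
        kymo = extract_kymograph(movie, self.POLY, dt=3.0, pixel_size=100.0)
        assert np.abs(kymo.shifts).max() < 0.25
        assert kymo.dx == pytest.approx(0.1)

    def test_injected_drift_recovered(self):
        """1 px/frame of along-boundary drift: cumulative registration shifts
        track the truth within 0.25 px."""
        truth = FrapTruth(D=0.0, k=0.0, A=0.8, dx=0.1, domain_length=40.0)
        for seed in (2, 5, 9):
            sim = SimConfig(seed=seed, pixel_size=100.0, image_shape=(64, 400))
            movie, times, _ = render_boundary_frap_movie(
                truth, 60.0, 3.0, sim, drift_along_px_per_frame=1.0,
                noise_sigma=1.0)
            kymo = extract_kymograph(movie, self.POLY, dt=3.0, pixel_size=100.0)
            assert np.abs(kymo.shifts - np.arange(len(times))).max() < 0.25

    def test_default_strip_width_is_nine(self):
        import inspect

        sig = inspect.signature(extract_kymograph)
        assert sig.parameters["strip_width"].default == 9

    def test_even_strip_width_rejected(self):
        movie = np.zeros((3, 16, 16))
        with pytest.raises(InvalidParameterError):
            extract_kymograph(movie, np.array([[8.0, 0.0], [8.0, 15.0]]),
                              dt=1.0, pixel_size=100.0, strip_width=8)

    def test_polyline_outside_frame_rejected(self):
        movie = np.zeros((3, 16, 16))
        with pytest.raises(InvalidParameterError):
            extract_kymograph(movie, np.array([[8.0, 0.0], [8.0, 30.0]]),
                              dt=1.0, pixel_size=100.0)


class TestTirfCorrection:
    ROI = ((6, 54), (0, 320))
    BG = ((0, 3), (0, 320))
    REF = ((6, 54), (280, 315))

    def test_null_movie_corrects_to_flat(self):
        sim = SimConfig(seed=1, pixel_size=200.0, image_shape=(60, 320))
        truth = FrapTruth(D=0.1, A=0.0, U0=100.0, geometry="stripe",
                          dx=0.2, domain_length=60.0)
        movie, _, _ = render_tirf_frap_movie(truth, 20.0, 2.0, sim,
                                             noise_sigma=0.5)
        kymo = tirf_frap_correct(movie, self.ROI, self.BG, self.REF,
                                 dt=2.0, pixel_size=200.0)
        assert np.std(kymo.intensity) / np.mean(kymo.intensity) < 0.02

    def test_injected_photobleaching_removed(self):
        """Global 0.005/s photobleaching: after correction the reference
        region is flat to <1% of U0 over the movie."""
        sim = SimConfig(seed=4, pixel_size=200.0, image_shape=(60, 320))
        truth = FrapTruth(D=0.3, A=0.8, U0=100.0, geometry="stripe",
                          stripe_halfwidth=3.0, dx=0.2, domain_length=60.0)
        movie, _, _ = render_tirf_frap_movie(truth, 25.0, 1.0, sim,
                                             photobleach_rate=0.005,
                                             noise_sigma=1.0)
        kymo = tirf_frap_correct(movie, self.ROI, self.BG, self.REF,
                                 dt=1.0, pixel_size=200.0)
        ref_trace = kymo.intensity[:, 280:315].mean(axis=1)
        drift = np.polyfit(np.arange(len(ref_trace)), ref_trace, 1)[0] \
            * len(ref_trace)
        assert abs(drift) < 0.01 * 100.0

    def test_stripe_bleach_diffusion_recovered(self):
        """TIRF stripe movie at D = 0.3 µm²/s: recovered within 20%."""
        sim = SimConfig(seed=0, pixel_size=200.0, image_shape=(60, 320))
        truth = FrapTruth(D=0.3, A=0.8, U0=100.0, geometry="stripe",
                          stripe_halfwidth=3.0, dx=0.2, domain_length=60.0)
        movie, _, _ = render_tirf_frap_movie(truth, 25.0, 1.0, sim,
                                             photobleach_rate=0.005,
                                             noise_sigma=5.0)
        kymo = tirf_frap_correct(movie, self.ROI, self.BG, self.REF,
                                 dt=1.0, pixel_size=200.0)
        fit = fit_recovery(kymo, geometry="stripe")
        assert abs(fit.D / 0.3 - 1) < 0.2

    def test_dead_reference_rejected(self):
        movie = np.zeros((5, 60, 320))
        with pytest.raises(InvalidParameterError):
            tirf_frap_correct(movie, self.ROI, self.BG, self.REF,
                              dt=1.0, pixel_size=200.0)


class TestCompareGroups:
    @staticmethod
    def _fits(D_values, k_values):
        from pcpkit.frap import RecoveryFit

        return [RecoveryFit(D=d, L0=0.1, k=k, A0=0.8, frames=[],
                            times=np.arange(3.0), n_excluded=0, r2_L2=1.0)
                for d, k in zip(D_values, k_values)]

    def test_identical_groups_null_contrast(self):
        rng = np.random.default_rng(0)
        d = rng.lognormal(0, 0.1, 8)
        groups = {"a": self._fits(d, d), "b": self._fits(d, d)}
        summary, pairwise = compare_groups(groups)
        assert summary.mean_D.iloc[0] == pytest.approx(summary.mean_D.iloc[1])
        assert pairwise.p_D.iloc[0] == pytest.approx(1.0)

    def test_hundredfold_separation_significant(self):
        """Bound vs unbound mobility (100x in D) at n=10 gives p < 0.001."""
        rng = np.random.default_rng(1)
        slow = rng.lognormal(np.log(0.001), 0.3, 10)
        fast = rng.lognormal(np.log(0.1), 0.3, 10)
        groups = {"complex": self._fits(slow, slow),
                  "unbound": self._fits(fast, fast)}
        _, pairwise = compare_groups(groups)
        assert pairwise.p_D.iloc[0] < 1e-3

    def test_sem_matches_direct_formula(self):
        vals = np.array([0.1, 0.2, 0.4, 0.15, 0.3])
        groups = {"g": self._fits(vals, vals), "h": self._fits(vals, vals)}
        summary, _ = compare_groups(groups)
        expected = vals.std(ddof=1) / math.sqrt(len(vals))
        assert summary.sem_D.iloc[0] == pytest.approx(expected)

    def test_small_groups_excluded(self):
        groups = {"tiny": self._fits([0.1], [0.0]),
                  "ok": self._fits([0.1, 0.2], [0.0, 0.0])}
        summary, _ = compare_groups(groups)
        assert list(summary.group) == ["ok"]
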