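"""Piecewise momentum regression, inhibitory hill, maps, RS alignment."""

import numpy as np
import pandas as pd
import pytest

from refix.durations import (
    align_rs_trials,
    binned_duration_map,
    find_return_event,
    fit_hill,
    fit_piecewise,
    fit_piecewise_per_subject,
    momentum_observations,
    residual_null_band,
)
from refix.synthetic import CohortSpec, generate_cohort, generate_momentum_observations
from tests.conftest import make_trajectory

TRUE = dict(beta0=200.0, s1=0.383, s2=0.002, c=117.0, u=0.39, o=-2.75)


def model(dphi, da, p=TRUE):
    return (p["beta0"] + p["s1"] * np.minimum(dphi, p["c"])
            + p["s2"] * np.maximum(dphi - p["c"], 0)
            + p["u"] * np.minimum(da, 0) + p["o"] * np.maximum(da, 0))


class TestFitPiecewise:
    def test_noise_free_exact_recovery(self, rng):
        dphi = rng.uniform(0, 180, 3000)
        da = rng.uniform(-8, 8, 3000)
        fit = fit_piecewise(dphi, da, model(dphi, da))
        assert fit.sse == pytest.approx(0.0, abs=1e-6)
        assert fit.c == pytest.approx(TRUE["c"], abs=1e-3)
        assert fit.s1 == pytest.approx(TRUE["s1"], abs=1e-6)
        assert fit.s2 == pytest.approx(TRUE["s2"], abs=1e-6)
        assert fit.u == pytest.approx(TRUE["u"], abs=1e-6)
        assert fit.o == pytest.approx(TRUE["o"], abs=1e-6)
        assert fit.beta0 == pytest.approx(TRUE["beta0"], abs=1e-4)

    def test_constant_durations(self, rng):
        dphi = rng.uniform(0, 180, 200)
        da = rng.uniform(-5, 5, 200)
        fit = fit_piecewise(dphi, da, np.full(200, 250.0))
        assert fit.beta0 == pytest.approx(250.0, abs=1e-8)
        for slope in (fit.s1, fit.s2, fit.u, fit.o):
            assert slope == pytest.approx(0.0, abs=1e-8)
        assert fit.r2 == 0.0
        assert not fit.c_identifiable

    def test_single_slope_flags_unidentifiable_breakpoint(self, rng):
        dphi = rng.uniform(0, 180, 500)
        da = rng.uniform(-5, 5, 500)
        dur = 180.0 + 0.4 * dphi  # one slope, no break
        fit = fit_piecewise(dphi, da, dur)
        # matches the plain linear fit and flags c as unidentifiable
        X = np.column_stack([np.ones_like(dphi), dphi,
                             np.minimum(da, 0), np.maximum(da, 0)])
        beta, _, _, _ = np.linalg.lstsq(X, dur, rcond=None)
        sse_lin = float(np.sum((dur - X @ beta) ** 2))
        assert fit.sse == pytest.approx(sse_lin, abs=1e-6)
        assert not fit.c_identifiable

    def test_degenerate_design_raises(self):
        with pytest.raises(ValueError, match="angle"):
            fit_piecewise(np.full(50, 90.0), np.zeros(50), np.ones(50) * 200)

    def test_r2_equals_sse_decomposition(self, rng):
        dphi, da, dur = generate_momentum_observations(2000, seed=9)
        fit = fit_piecewise(dphi, da, dur)
        sst = np.sum((dur - dur.mean()) ** 2)
        assert fit.r2 == pytest.approx(1 - fit.sse / sst, abs=1e-12)

    def test_recovery_with_noise(self):
        # 50 ms noise, n = 50,000: recovery within ~4 Monte-Carlo
        # standard deviations of the generative truth
        tol = dict(c=10.0, s1=0.035, s2=0.09, u=0.45, o=0.42)
        dphi, da, dur = generate_momentum_observations(50_000, seed=1)
        fit = fit_piecewise(dphi, da, dur)
        for name, t in tol.items():
            assert getattr(fit, name) == pytest.approx(TRUE[name], abs=t)


class TestFitHill:
    def test_flat_durations_give_no_hill(self, rng):
        d = rng.uniform(0, 10, 500)
        fit = fit_hill(d, 200.0 + rng.normal(0, 1, 500))
        assert abs(fit.k) < 1.0
        assert fit.r2 < 0.02

    def test_generative_recovery(self, rng):
        d = rng.uniform(0, 10, 5000)
        dur = 200.0 + 30.0 * np.exp(-d ** 2 / 8.0)  # sigma = 2
        fit = fit_hill(d, dur)
        assert fit.sigma == pytest.approx(2.0, abs=0.25)
        assert fit.k == pytest.approx(30.0, abs=0.5)
        assert fit.intercept == pytest.approx(200.0, abs=0.5)

    def test_hill_on_piecewise_residuals_explains_nothing(self):
        dphi, da, dur = generate_momentum_observations(30_000, seed=4)
        spec = CohortSpec()
        rng = np.random.default_rng(5)
        dist_ac = rng.uniform(0, 12, len(dur))
        fit = fit_piecewise(dphi, da, dur)
        hill = fit_hill(dist_ac, fit.residuals)
        assert hill.r2 < 0.001

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            fit_hill(np.ones(10), np.ones(10), sigma_grid=np.array([]))


class TestModelCompetition:
    def test_piecewise_beats_hill_on_momentum_data(self, small_cohort):
        obs = momentum_observations(small_cohort.trajectories)
        pw = fit_piecewise(obs["dphi"].to_numpy(), obs["da"].to_numpy(),
                           obs["duration"].to_numpy())
        hill = fit_hill(
            np.hypot(obs["cx"] - obs["ax"], obs["cy"] - obs["ay"]).to_numpy(),
            obs["duration"].to_numpy())
        assert pw.r2 > hill.r2


class TestBinnedDurationMap:
    def test_single_cell(self):
        m = binned_duration_map(np.array([10.0, 20.0]), np.array([0.5, 0.7]),
                                np.array([100.0, 200.0]))
        assert np.nansum(m.count) == 2
        assert np.nanmax(m.mean) == pytest.approx(150.0)

    def test_hand_averages_two_cells(self):
        dphi = np.array([10.0, 20.0, 100.0, 110.0])
        da = np.zeros(4) + 0.5
        dur = np.array([100.0, 120.0, 300.0, 340.0])
        m = binned_duration_map(dphi, da, dur, dphi_bin=30, da_bin=2)
        vals = sorted(m.mean[~np.isnan(m.mean)])
        assert vals == pytest.approx([110.0, 320.0])

    def test_refinement_preserves_global_mean(self, rng):
        dphi = rng.uniform(0, 180, 800)
        da = rng.uniform(-6, 6, 800)
        dur = rng.normal(230, 40, 800)
        coarse = binned_duration_map(dphi, da, dur, 30, 2)
        fine = binned_duration_map(dphi, da, dur, 1, 1)
        assert coarse.global_mean == pytest.approx(dur.mean(), abs=1e-9)
        assert fine.global_mean == pytest.approx(dur.mean(), abs=1e-9)

    def test_invalid_bin_raises(self):
        with pytest.raises(ValueError):
            binned_duration_map(np.ones(3), np.ones(3), np.ones(3), 0, 1)


class TestResidualNullBand:
    def test_band_widens_with_sparser_cells(self, rng):
        resid = rng.normal(0, 50, 2000)
        counts = np.array([[5, 500]])
        lo, hi = residual_null_band(resid, counts, n_boot=500, seed=0)
        assert (hi[0, 0] - lo[0, 0]) > (hi[0, 1] - lo[0, 1])
        assert np.isnan(residual_null_band(resid, np.array([[0]]),
                                           n_boot=10, seed=0)[0]).all()

    def test_generating_model_residuals_inside_band(self):
        # cell means of the true model's residuals stay inside the null
        # band in the well-sampled cells
        dphi, da, dur = generate_momentum_observations(20_000, seed=6)
        fit = fit_piecewise(dphi, da, dur)
        m = binned_duration_map(dphi, da, fit.residuals, 30, 2)
        lo, hi = residual_null_band(fit.residuals, m.count, n_boot=400, seed=1)
        well = m.count >= 50
        inside = (m.mean[well] >= lo[well]) & (m.mean[well] <= hi[well])
        assert inside.mean() >= 0.9


class TestAlignRsTrials:
    def test_constant_durations_give_flat_identical_curves(self):
        trajs = []
        for k in range(6):
            pts = [(0, 0), (5, 0), (0.3, 0.2), (5, 5), (8, 2)]
            trajs.append(make_trajectory(pts, durations=[200] * 5,
                                         subject="a", trial=f"r{k}"))
            pts2 = [(0, 0), (4, 1), (8, 0), (4, -4), (0, -8)]
            trajs.append(make_trajectory(pts2, durations=[200] * 5,
                                         subject="a", trial=f"c{k}"))
        curve = align_rs_trials(trajs, seed=0, n_boot=100)
        valid = ~np.isnan(curve.rs_mean) & ~np.isnan(curve.control_mean)
        assert np.allclose(curve.rs_mean[valid], 200.0)
        assert np.allclose(curve.control_mean[valid], 200.0)

    def test_injected_bonus_detected_and_removed_by_correction(self):
        spec = CohortSpec(n_subjects=6, n_images=6, trials_per_image=6,
                          p_return_1back=0.06, p_return_2back=0.0,
                          return_bonus_ms=60.0, noise_sd=30.0)
        cohort = generate_cohort(spec, seed=21)
        raw = align_rs_trials(cohort.trajectories, seed=1, n_boot=200)
        k0 = list(raw.offsets).index(0)
        # raw curves separate at the aligned return fixation
        assert raw.rs_mean[k0] - raw.control_mean[k0] > 20.0
        corrected = align_rs_trials(cohort.trajectories, use_corrected=True,
                                    seed=1, n_boot=200)
        # the bonus is spatial, not momentum: correction keeps it
        assert corrected.rs_mean[k0] - corrected.control_mean[k0] > 10.0

    def test_point_mass_alignment_distribution(self):
        # all RS trials return at the same position: controls align there
        trajs = []
        for k in range(4):
            trajs.append(make_trajectory(
                [(0, 0), (5, 0), (0.2, 0.1), (6, 6), (9, 1)],
                subject="a", trial=f"r{k}"))
            trajs.append(make_trajectory(
                [(0, 0), (4, 2), (8, 0), (4, -4), (0, -8)],
                subject="a", trial=f"c{k}"))
        curve = align_rs_trials(trajs, seed=0, n_boot=50)
        # every control contributes at the RS align position (2), so the
        # control curve is defined across the same offsets as the RS curve
        assert np.isnan(curve.control_mean).sum() == np.isnan(
            curve.rs_mean).sum()

    def test_find_return_event(self):
        t = make_trajectory([(0, 0), (5, 0), (5, 5), (0.4, 0.3), (7, 7)])
        assert find_return_event(t, nback=None, radius=2.0) == (0, 3)
        assert find_return_event(t, nback=2, radius=2.0) == (0, 3)
        assert find_return_event(t, nback=1, radius=2.0) is None


class TestPerSubjectFits:
    def test_per_subject_fit_returns_all_subjects(self, small_cohort):
        obs = momentum_observations(small_cohort.trajectories)
        fits = fit_piecewise_per_subject(obs)
        assert set(fits) == set(obs["subject"].unique())
        for f in fits.values():
            assert 0.0 <= f.r2 <= 1.0
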