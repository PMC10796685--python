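"""Population sampling, rate encoding, noise, fSNR and velocity profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bimanual as bm
from bimanual.synth import (
    BIN_S,
    NO_MOVEMENT,
    UNI_LEFT,
    UNI_RIGHT,
    Frames,
    KinematicFrame,
    measure_fsnr,
)


class TestSamplePopulation:
    def test_perfect_correlation_gives_parallel_columns(self):
        pop = bm.sample_population(32, rho_x=1.0, rho_y=1.0, lat_scale=0.5, seed=0)
        for jr, jl in ((0, 2), (1, 3)):
            r, l = pop.tuning_uni[:, jr], pop.tuning_uni[:, jl]
            cos = r @ l / (np.linalg.norm(r) * np.linalg.norm(l))
            assert cos == pytest.approx(1.0, abs=1e-12)

    def test_zero_lat_scale_gives_zero_laterality_column(self):
        pop = bm.sample_population(32, rho_x=0.2, rho_y=0.2, lat_scale=0.0, seed=1)
        assert np.all(pop.laterality == 0.0)

    def test_zero_rho_mean_empirical_correlation(self):
        # Monte-Carlo over 100 seeds at 192 channels: mean x-column correlation
        # should be within +/-0.03 of the programmed rho = 0
        corrs = []
        for seed in range(100):
            pop = bm.sample_population(192, rho_x=0.0, rho_y=0.5, lat_scale=0.0, seed=seed)
            r, l = pop.tuning_uni[:, 0], pop.tuning_uni[:, 2]
            corrs.append(np.corrcoef(r, l)[0, 1])
        assert abs(np.mean(corrs)) < 0.03

    def test_empirical_correlation_near_rho(self):
        pop = bm.sample_population(192, rho_x=0.7, rho_y=-0.4, lat_scale=1.0, seed=2)
        for rho, (jr, jl) in ((0.7, (0, 2)), (-0.4, (1, 3))):
            c = np.corrcoef(pop.tuning_uni[:, jr], pop.tuning_uni[:, jl])[0, 1]
            assert c == pytest.approx(rho, abs=0.05)

    def test_exact_correlation_mode(self):
        pop = bm.sample_population(
            64, rho_x=0.45, rho_y=0.8, lat_scale=1.0, seed=3, exact_correlation=True
        )
        for rho, (jr, jl) in ((0.45, (0, 2)), (0.8, (1, 3))):
            r = pop.tuning_uni[:, jr] - pop.tuning_uni[:, jr].mean()
            l = pop.tuning_uni[:, jl] - pop.tuning_uni[:, jl].mean()
            c = r @ l / (np.linalg.norm(r) * np.linalg.norm(l))
            assert c == pytest.approx(rho, abs=1e-9)

    def test_suppression_and_context_correlation_by_construction(self, small_pop):
        for j, col in enumerate(("rx", "ry", "lx", "ly")):
            ratio = np.linalg.norm(small_pop.tuning_bi[:, j]) / np.linalg.norm(
                small_pop.tuning_uni[:, j]
            )
            expected = 1.0 if col.startswith("r") else 0.66
            assert ratio == pytest.approx(expected, abs=1e-9)

    def test_laterality_norm_scaling(self):
        pop = bm.sample_population(64, rho_x=0.3, rho_y=0.3, lat_scale=0.5, seed=4)
        ref = np.mean([np.linalg.norm(pop.tuning_uni[:, j]) for j in range(4)])
        assert np.linalg.norm(pop.laterality) == pytest.approx(0.5 * ref, rel=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_channels=1),
            dict(rho_x=1.5),
            dict(rho_y=np.nan),
            dict(lat_scale=-0.1),
            dict(magnitudes=-1.0),
            dict(suppression=(1.0, -0.5)),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(n_channels=16, rho_x=0.5, rho_y=0.5, lat_scale=1.0, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            bm.sample_population(**base)


class TestEncodeRates:
    def test_baseline_only(self):
        pop = bm.sample_population(16, rho_x=0.5, rho_y=0.5, lat_scale=0.0, seed=0)
        frames = Frames(np.zeros((5, 4)), np.full(5, NO_MOVEMENT, dtype=np.int8))
        rates = bm.encode_rates(pop, frames)
        assert np.allclose(rates, np.tile(pop.baseline, (5, 1)))

    def test_single_channel_arithmetic(self):
        pop = bm.SimPopulation(
            n_channels=1,
            baseline=np.array([10.0]),
            tuning_uni=np.array([[2.0, 0.0, 0.0, 0.0]]),
            tuning_bi=np.array([[2.0, 0.0, 0.0, 0.0]]),
            laterality=np.array([0.0]),
            rho_x=0,
            rho_y=0,
            lat_scale=0,
            seed=0,
        )
        frames = Frames(np.array([[0.5, 0, 0, 0]]), np.array([UNI_RIGHT], dtype=np.int8))
        assert bm.encode_rates(pop, frames)[0, 0] == pytest.approx(11.0)

    def test_laterality_flip_changes_rate_by_twice_blat(self, small_pop):
        d = np.array([[0.0, 0.0, 0.0, 0.0]])
        right = bm.encode_rates(small_pop, Frames(d, np.array([UNI_RIGHT], dtype=np.int8)))
        left = bm.encode_rates(small_pop, Frames(d, np.array([UNI_LEFT], dtype=np.int8)))
        assert np.allclose(left - right, -2 * small_pop.laterality)

    @given(alpha=st.floats(-2, 2), seed=st.integers(0, 10))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_linearity_in_velocity(self, alpha, seed):
        pop = bm.sample_population(8, rho_x=0.5, rho_y=0.5, lat_scale=1.0, seed=seed)
        rng = np.random.default_rng(seed)
        d = rng.uniform(-1, 1, (1, 4))
        d[:, 2:] = 0
        ctx = np.array([UNI_RIGHT], dtype=np.int8)
        base = bm.encode_rates(pop, Frames(np.zeros((1, 4)), ctx))
        r1 = bm.encode_rates(pop, Frames(d, ctx)) - base
        r2 = bm.encode_rates(pop, Frames(alpha * d, ctx)) - base
        assert np.allclose(r2, alpha * r1, atol=1e-9)

    def test_kinematic_frame_invariants(self):
        with pytest.raises(ValueError):
            KinematicFrame(d_lx=0.5, context=UNI_RIGHT)
        with pytest.raises(ValueError):
            KinematicFrame(d_rx=0.5, context=NO_MOVEMENT)


class TestNoise:
    def test_sigma_zero_clips_only(self):
        rates = np.array([[-1.0, 0.5], [2.0, -0.1]])
        out = bm.add_noise_and_clip(rates, bm.NoiseModel(0.0), seed=0)
        assert np.allclose(out, np.maximum(rates, 0.0))

    def test_output_nonnegative_and_variance(self):
        rates = np.full((1000, 100), 50.0)  # high baseline: clipping inactive
        out = bm.add_noise_and_clip(rates, bm.NoiseModel(2.0), seed=1)
        assert out.min() >= 0.0
        assert np.var(out - rates) == pytest.approx(4.0, rel=0.05)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            bm.NoiseModel(-1.0)


class TestUnimanualDataset:
    def test_wedge_balance_and_shapes(self, uni_pop):
        ds = bm.generate_unimanual_dataset(uni_pop, n_per_hand=16, seed=0)
        table = ds.trial_table
        for code, col in ((UNI_RIGHT, "wedge_r"), (UNI_LEFT, "wedge_l")):
            wedges = table[table["type"] == code][col]
            assert sorted(np.bincount(wedges, minlength=8)) == [2] * 8
        # 400 ms trials at 20-ms bins -> 20 bins per trial
        assert (table["end"] - table["start"]).eq(20).all()

    def test_targets_are_unit_vectors(self, uni_pop):
        ds = bm.generate_unimanual_dataset(uni_pop, n_per_hand=16, seed=1)
        d = ds.labels.d
        norms = np.linalg.norm(d[:, :2], axis=1) + np.linalg.norm(d[:, 2:], axis=1)
        assert np.allclose(norms, 1.0)

    def test_too_few_trials_rejected(self, uni_pop):
        with pytest.raises(ValueError):
            bm.generate_unimanual_dataset(uni_pop, n_per_hand=7)

    def test_seeded_reproducibility(self, uni_pop):
        a = bm.generate_unimanual_dataset(uni_pop, n_per_hand=16, seed=42)
        b = bm.generate_unimanual_dataset(uni_pop, n_per_hand=16, seed=42)
        assert np.array_equal(a.rates, b.rates)
        assert a.trial_table.equals(b.trial_table)


class TestSession:
    def test_epochs_tile_each_trial(self, session_noiseless):
        for r in session_noiseless.trial_table.itertuples():
            assert r.start < r.go < r.move_end < r.end
        table = session_noiseless.trial_table
        assert (table["start"].iloc[1:].to_numpy() == table["end"].iloc[:-1].to_numpy()).all()

    def test_hdf5_round_trip(self, session_noisy, tmp_path):
        path = str(tmp_path / "session.h5")
        session_noisy.to_hdf5(path)
        back = bm.SessionData.from_hdf5(path)
        assert np.allclose(back.rates, session_noisy.rates, atol=1e-4)
        assert np.array_equal(back.labels.context, session_noisy.labels.context)
        assert len(back.trial_table) == len(session_noisy.trial_table)


class TestFsnr:
    def test_perfect_decode_is_infinite(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((100, 2))
        assert bm.estimate_fsnr(y, y) == np.inf

    def test_identity_gain_with_noise(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((20000, 2))
        decoded = y + 0.5 * rng.standard_normal(y.shape)
        assert bm.estimate_fsnr(decoded, y) == pytest.approx(2.0, rel=0.05)

    def test_gain_two_sigma_one(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((20000, 2))
        decoded = 2 * y + rng.standard_normal(y.shape)
        assert bm.estimate_fsnr(decoded, y) == pytest.approx(2.0, rel=0.05)

    def test_degenerate_pointing_rejected(self):
        y = np.tile([1.0, 0.0], (10, 1))
        with pytest.raises(ValueError):
            bm.estimate_fsnr(y, y)


class TestCalibrateSigma:
    def test_closed_loop_self_check_and_monotonicity(self, uni_pop):
        ds = bm.generate_unimanual_dataset(uni_pop, n_per_hand=120, seed=0)
        n1 = bm.calibrate_sigma(uni_pop, ds, target_fsnr=2.0, tol=0.05, seed=1)
        n2 = bm.calibrate_sigma(uni_pop, ds, target_fsnr=1.0, tol=0.05, seed=1)
        assert n2.sigma > n1.sigma  # halving the target increases sigma
        noisy = ds.copy_with(rates=bm.add_noise_and_clip(ds.rates, n1, seed=2))
        achieved = np.mean(list(measure_fsnr(noisy).values()))
        # independent noise draw: allow a little slack beyond the bisection tol
        assert achieved == pytest.approx(2.0, abs=0.15)

    def test_unreachable_target_names_bracket(self, uni_pop):
        ds = bm.generate_unimanual_dataset(uni_pop, n_per_hand=32, seed=0)
        with pytest.raises(ValueError, match="bracket"):
            bm.calibrate_sigma(uni_pop, ds, target_fsnr=1e-6, sigma_bounds=(1e-4, 1.0))


class TestKinematicProfiles:
    def test_minjerk_boundary_and_peak(self):
        mj, _ = bm.kinematic_profiles(distance=2.0, move_duration=1.0, reaction_time=0.2)
        assert mj[0] == pytest.approx(0.0, abs=0.05)
        assert mj[-1] == pytest.approx(0.0, abs=0.05)
        assert mj.max() == pytest.approx(1.875 * 2.0 / 1.0, rel=2e-3)

    @pytest.mark.parametrize("distance,duration", [(1.0, 1.0), (0.7, 1.6), (2.5, 0.9)])
    def test_displacement_conservation(self, distance, duration):
        mj, sat = bm.kinematic_profiles(distance, duration, reaction_time=0.2)
        assert mj.sum() * BIN_S == pytest.approx(distance, rel=1e-6)
        assert sat.sum() * BIN_S == pytest.approx(distance, rel=1e-6)

    def test_saturated_profile_shape(self):
        _, sat = bm.kinematic_profiles(1.0, 1.0, reaction_time=0.2)
        react_bins = int(0.2 / BIN_S)
        assert np.allclose(sat[:react_bins], 0.0)
        # plateau at maximum speed, then taper to zero
        peak = sat.max()
        assert sat[react_bins + 2] == pytest.approx(peak, rel=1e-6)
        assert sat[-1] < 0.2 * peak
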