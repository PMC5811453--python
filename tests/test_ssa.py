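import numpy as np
import pytest

from afmosc.errors import ParameterError
from afmosc.io import Quantity, TimeSeries
from afmosc.preprocess import detrend_standardize
from afmosc.ssa import (
    ComponentSeries,
    EigentripleGroup,
    SingularSpectrum,
    build_fb_trajectory,
    diagonal_average,
    eigendecompose,
    group_eigentriples,
    select_leading,
    ssa_filter,
)


def explicit_fb_matrix(x, p):
    """Brute-force row-by-row construction of the forward-backward matrix."""
    x = np.asarray(x, float)
    N = len(x)
    rows = []
    for i in range(1, N - p + 1):  # forward rows (x_{p+i-1}, ..., x_i), 1-based
        rows.append([x[p + i - 1 - m - 1] for m in range(p)])
    for j in range(1, N - p + 1):  # backward rows (x_{j+1}, ..., x_{j+p})
        rows.append([x[j + m + 1 - 1] for m in range(p)])
    return np.array(rows)


def make_std(values, fs=0.5):
    """Wrap an array as a standardized series via the real preprocess path."""
    t = np.arange(len(values)) / fs
    ts = TimeSeries(t, values, Quantity.ADHESION_FORCE, sampling_rate=fs)
    return detrend_standardize(ts)


def fake_spectrum(eigenvalues):
    """A SingularSpectrum with given eigenvalues and orthonormal dummy vectors."""
    lam = np.asarray(eigenvalues, float)
    d = len(lam)
    return SingularSpectrum(
        eigenvalues=lam,
        left_vectors=np.eye(2 * d, d),
        right_vectors=np.eye(d),
        p=d,
        N=2 * d,
    )


class TestBuildFbTrajectory:
    def test_small_example_rows(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])  # x1..x4, p=2
        T = build_fb_trajectory(x, p=2)
        np.testing.assert_array_equal(
            T.entries, [[2, 1], [3, 2], [2, 3], [3, 4]]
        )
        assert T.entries.shape == (4, 2)

    @pytest.mark.parametrize("n,p", [(10, 3), (24, 8), (64, 32), (31, 11)])
    def test_matches_explicit_construction(self, n, p):
        x = np.random.default_rng(n).normal(size=n)
        T = build_fb_trajectory(x, p=p)
        np.testing.assert_array_equal(T.entries, explicit_fb_matrix(x, p))
        assert T.entries.shape == (2 * (n - p), p)
        assert T.forward_rows.shape == T.backward_rows.shape == (n - p, p)

    def test_auto_order_is_half_length(self):
        x = np.random.default_rng(0).normal(size=900)
        T = build_fb_trajectory(x, p="auto")
        assert T.p == 450
        assert T.entries.shape == (900, 450)

    @pytest.mark.parametrize("p", [1, 0, 10, -2])
    def test_bad_order_rejected(self, p):
        with pytest.raises(ParameterError):
            build_fb_trajectory(np.arange(10.0), p=p)


class TestEigendecompose:
    def test_rank_one_matrix(self):
        from afmosc.ssa import TrajectoryMatrix

        u = np.array([1.0, 2.0, 2.0, 1.0, 0.5, 0.5])
        v = np.array([3.0, 0.0, 4.0])
        T = TrajectoryMatrix(entries=np.outer(u, v), p=3, N=6)
        spec = eigendecompose(T)
        assert spec.d == 1
        assert spec.eigenvalues[0] == pytest.approx(np.sum(u**2) * np.sum(v**2))

    def test_reconstruction_and_energy(self):
        x = np.random.default_rng(1).normal(size=48)
        T = build_fb_trajectory(x, p=20)
        spec = eigendecompose(T)
        recon = spec.eigentriple_matrix(np.arange(1, spec.d + 1))
        err = np.linalg.norm(recon - T.entries) / np.linalg.norm(T.entries)
        assert err < 1e-8
        assert spec.eigenvalues.sum() == pytest.approx(
            np.linalg.norm(T.entries) ** 2, rel=1e-8
        )

    def test_matches_svd_oracle_small_n(self):
        x = np.random.default_rng(7).normal(size=64)
        p = 32
        T = build_fb_trajectory(x, p=p)
        spec = eigendecompose(T)
        sv_oracle = np.linalg.svd(explicit_fb_matrix(x, p), compute_uv=False)
        np.testing.assert_allclose(
            np.sqrt(spec.eigenvalues), sv_oracle[: spec.d], rtol=1e-8
        )

    def test_orthonormal_vectors_and_fractions(self):
        x = np.random.default_rng(2).normal(size=60)
        spec = eigendecompose(build_fb_trajectory(x, p=25))
        np.testing.assert_allclose(
            spec.left_vectors.T @ spec.left_vectors, np.eye(spec.d), atol=1e-8
        )
        np.testing.assert_allclose(
            spec.right_vectors.T @ spec.right_vectors, np.eye(spec.d), atol=1e-8
        )
        assert spec.fractions.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(spec.eigenvalues) <= 0)

    def test_pure_sinusoid_has_two_eigenvalues(self):
        n = 64
        x = np.sin(2 * np.pi * np.arange(n) / 8)  # period 8
        spec = eigendecompose(build_fb_trajectory(x, p=32))
        above = np.sum(spec.eigenvalues > 1e-10 * spec.eigenvalues[0])
        assert above == 2
        # near-degenerate pair
        assert (
            spec.eigenvalues[0] - spec.eigenvalues[1]
        ) / spec.eigenvalues[0] < 0.05

    def test_white_noise_has_no_dominant_pair(self):
        low = 0
        for seed in range(50):
            x = np.random.default_rng(seed).normal(size=200)
            spec = eigendecompose(build_fb_trajectory(x, p=100))
            low += spec.cumulative_fractions[1] < 0.2
        assert low == 50


class TestSelectLeading:
    @pytest.mark.parametrize(
        "threshold,expected",
        [(0.6, [1, 2]), (0.5, [1]), (1.0, [1, 2, 3]), (0.99, [1, 2, 3]), (0.05, [1])],
    )
    def test_inclusive_prefix_rule(self, threshold, expected):
        spec = fake_spectrum([0.5, 0.3, 0.2])
        assert select_leading(spec, threshold) == expected

    @pytest.mark.parametrize("threshold", [0.0, -0.1, 1.5])
    def test_bad_threshold(self, threshold):
        with pytest.raises(ParameterError):
            select_leading(fake_spectrum([1.0]), threshold)


class TestGrouping:
    def test_pairing_even(self):
        groups = group_eigentriples(fake_spectrum([4.0, 3.0, 2.0, 1.0]), [1, 2, 3, 4])
        assert [g.member_indices for g in groups] == [(1, 2), (3, 4)]

    def test_trailing_singleton(self):
        groups = group_eigentriples(fake_spectrum([4.0, 3.0, 2.0]), [1, 2, 3])
        assert [g.member_indices for g in groups] == [(1, 2), (3,)]

    def test_group_matrices_sum_to_trajectory(self):
        x = np.random.default_rng(5).normal(size=40)
        T = build_fb_trajectory(x, p=16)
        spec = eigendecompose(T)
        groups = group_eigentriples(spec, list(range(1, spec.d + 1)))
        total = np.sum([g.matrix for g in groups], axis=0)
        err = np.linalg.norm(total - T.entries) / np.linalg.norm(T.entries)
        assert err < 1e-8

    def test_empty_leading_rejected(self):
        with pytest.raises(ParameterError):
            group_eigentriples(fake_spectrum([1.0]), [])


class TestDiagonalAverage:
    def test_full_rank_identity(self):
        x = np.random.default_rng(9).normal(size=50)
        T = build_fb_trajectory(x, p=21)
        spec = eigendecompose(T)
        g = EigentripleGroup(1, tuple(range(1, spec.d + 1)), spec)
        out = diagonal_average(g)
        np.testing.assert_allclose(out.values, x, atol=1e-10)

    def test_constant_antidiagonals_give_constant(self):
        # a constant series embeds to constant blocks; averaging returns it
        x = np.full(30, 3.25)
        x[0] += 0  # keep exactly constant
        from afmosc.ssa import _diagonal_average_matrix

        T = build_fb_trajectory(x, p=10)
        out = _diagonal_average_matrix(T.entries, 30, 10)
        np.testing.assert_allclose(out, 3.25, atol=1e-12)

    def test_completeness_over_all_groups(self):
        x = np.random.default_rng(11).normal(size=60)
        s = make_std(x)
        T = build_fb_trajectory(s, p="auto")
        spec = eigendecompose(T)
        groups = group_eigentriples(spec, list(range(1, spec.d + 1)))
        total = np.sum([diagonal_average(g).values for g in groups], axis=0)
        np.testing.assert_allclose(total, s.values, atol=1e-8)


class TestSsaFilter:
    def test_threshold_one_returns_input(self):
        s = make_std(np.random.default_rng(3).normal(size=80))
        filtered, _, _ = ssa_filter(s, 1.0)
        np.testing.assert_allclose(filtered.values, s.values, atol=1e-8)

    def test_noiseless_two_tone_near_full_threshold(self):
        # a pure two-tone series has an exactly rank-4 embedding, so the
        # leading 4 eigentriples at threshold 0.99 reconstruct it completely
        from afmosc.preprocess import StandardizedSeries, TrendModel

        n, fs = 256, 0.5
        t = np.arange(n) / fs
        x = 3 * np.sin(2 * np.pi * (8 / (n / fs)) * t) + 1.5 * np.sin(
            2 * np.pi * (24 / (n / fs)) * t + 1
        )
        values = x / np.std(x, ddof=1)
        s = StandardizedSeries(
            times=t,
            values=values,
            sampling_rate=fs,
            trend=TrendModel(0.0, 0.0, 0.0, float(np.std(x, ddof=1))),
            source_quantity=Quantity.ADHESION_FORCE,
        )
        filtered, _, spec = ssa_filter(s, 0.99)
        assert spec.d == 4
        rms = np.sqrt(np.mean((filtered.values - s.values) ** 2))
        assert rms < 1e-6

    def test_denoising_beats_raw_over_seeds(self):
        # sinusoid at SNR 1; SSA-filtered series should be closer to the
        # clean tone than the raw data in nearly all draws
        n, fs, f0 = 400, 0.5, 0.01
        t = np.arange(n) / fs
        amp = np.sqrt(2.0)  # unit-variance tone; noise sigma 1 -> SNR 1
        wins = 0
        for seed in range(50):
            clean = amp * np.sin(2 * np.pi * f0 * t + 0.3)
            noisy = clean + np.random.default_rng(seed).normal(0, 1.0, n)
            s = make_std(noisy + 60)
            filtered, _, _ = ssa_filter(s, 0.1)
            # compare on the standardized scale: rescale the clean tone the same way
            clean_std = (clean - clean.mean()) / s.trend.std
            raw_rmse = np.sqrt(np.mean((s.values - clean_std) ** 2))
            filt_rmse = np.sqrt(np.mean((filtered.values - clean_std) ** 2))
            wins += filt_rmse < raw_rmse
        assert wins >= 45

    def test_min_pairs_guard_extends_leading_set(self):
        t = np.arange(300) / 0.5
        x = (
            4 * np.sin(2 * np.pi * 0.008 * t)
            + 2 * np.sin(2 * np.pi * 0.03 * t + 1)
            + np.random.default_rng(0).normal(0, np.sqrt(10), 300)
        )
        s = make_std(x + 70)
        filtered_plain, _, _ = ssa_filter(s, 0.1)
        filtered_guard, groups, _ = ssa_filter(s, 0.1, min_pairs=2)
        assert len(filtered_guard.member_indices) >= 4
        assert len(filtered_guard.member_indices) >= len(
            filtered_plain.member_indices
        )
        assert len(groups) >= 2
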