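import numpy as np
import pytest

from neurofuse.gedbounds import (
    BandBoundaries,
    GEDError,
    GEDSweep,
    assign_canonical,
    clean_mean_covariance,
    cluster_bands,
    detect_bands,
    ged_at_frequency,
    ged_sweep,
    individualized_band_power,
    similarity_matrix,
)
from neurofuse.io_preprocess import DEFAULT_CHANNELS, Recording, epoch
from neurofuse.synthetic_data import OscillationSpec, SubjectSpec, generate_subject


def planted_recording(seed=0, peaks=((6.0, 2.0), (10.0, 2.0)), gain=1.8):
    amp_front = {c: (gain if c in ("F3", "F4", "C3", "C4") else 0.5)
                 for c in DEFAULT_CHANNELS}
    amp_back = {c: (gain if c in ("O1", "O2", "C3", "C4") else 0.5)
                for c in DEFAULT_CHANNELS}
    maps = [amp_front, amp_back]
    spec = SubjectSpec(
        oscillations=[
            OscillationSpec(p, w, maps[i % 2], phase_seed=i + 1)
            for i, (p, w) in enumerate(peaks)
        ],
        noise_gain=1.0, duration=60.0, fs=250.0, seed=seed,
    )
    return generate_subject(spec)[0]


class TestCleanCovariance:
    def test_identical_epochs(self, rng):
        base = rng.standard_normal((4, 500))
        rec = Recording(np.tile(base, (1, 10)), fs=250.0, labels=list("abcd"))
        eps = epoch(rec, 2.0)
        cov = clean_mean_covariance(eps)
        single = np.cov(base)
        np.testing.assert_allclose(cov, single, rtol=1e-8)

    def test_outlier_dropped(self, rng):
        data = rng.standard_normal((100, 4, 100))
        data[37] *= 100.0
        from neurofuse.io_preprocess import EpochSet

        eps = EpochSet(data=data, fs=50.0, labels=list("abcd"), epoch_len=2.0)
        cov = clean_mean_covariance(eps)
        clean = data[np.arange(100) != 37]
        clean_cov = np.stack(
            [np.cov(e) for e in clean]
        ).mean(axis=0)
        np.testing.assert_allclose(cov, clean_cov, rtol=1e-8)

    def test_needs_four_epochs(self, rng):
        from neurofuse.io_preprocess import EpochSet

        eps = EpochSet(data=rng.standard_normal((3, 2, 50)), fs=25.0,
                       labels=["a", "b"], epoch_len=2.0)
        with pytest.raises(GEDError):
            clean_mean_covariance(eps)


class TestGED:
    def test_identity_case(self, white_recording):
        # S == R -> all generalized eigenvalues 1
        eps = epoch(white_recording, 2.0)
        R = clean_mean_covariance(eps)
        from neurofuse.gedbounds import _solve_ged

        evals, evecs = _solve_ged(R, R)
        np.testing.assert_allclose(evals, 1.0, atol=1e-8)

    def test_planted_rhythm_eigenvalue(self):
        rec = planted_recording(seed=2, peaks=((10.0, 2.0),))
        l10, _ = ged_at_frequency(rec, 10.0)
        l20, _ = ged_at_frequency(rec, 20.0)
        assert l10[0] > l20[0]

    def test_r_orthogonality(self, alpha_recording):
        eps = epoch(alpha_recording, 2.0)
        from neurofuse.gedbounds import _regularize

        R = _regularize(clean_mean_covariance(eps), 0.01)
        evals, W = ged_at_frequency(alpha_recording, 10.0, R=R)
        G = W.T @ R @ W
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() / np.abs(np.diag(G)).max() < 1e-6

    def test_eigenvalues_real(self, white_recording):
        evals, _ = ged_at_frequency(white_recording, 12.0)
        assert np.isrealobj(evals)

    def test_out_of_range_frequency(self, white_recording):
        with pytest.raises(GEDError):
            ged_at_frequency(white_recording, 200.0)


class TestSweep:
    def test_grid_size(self, alpha_recording):
        sweep = ged_sweep(alpha_recording, 2.0, 45.0, 0.5)
        assert sweep.grid.size == 87
        assert sweep.lambda_max.shape == (87,)
        assert sweep.eigvecs.shape == (87, 8)

    def test_white_noise_flat(self):
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rec = Recording(rng.standard_normal((8, 15000)), fs=250.0,
                            labels=list(DEFAULT_CHANNELS))
            sweep = ged_sweep(rec, 2.0, 45.0, 1.0)
            ratios.append(sweep.lambda_max.max() / sweep.lambda_max.min())
        assert all(r < 2.0 for r in ratios)

    def test_two_planted_peaks(self):
        rec = planted_recording(seed=3)
        sweep = ged_sweep(rec, 2.0, 45.0, 0.5)
        lam = sweep.lambda_max
        for target in (6.0, 10.0):
            window = (sweep.grid >= target - 1.5) & (sweep.grid <= target + 1.5)
            peak_f = sweep.grid[window][np.argmax(lam[window])]
            assert abs(peak_f - target) <= 0.5

    def test_scale_invariance(self):
        rec = planted_recording(seed=4)
        sweep1 = ged_sweep(rec, 2.0, 30.0, 1.0)
        sweep2 = ged_sweep(rec.copy_with(rec.data * 7.5), 2.0, 30.0, 1.0)
        np.testing.assert_allclose(sweep1.lambda_max, sweep2.lambda_max, rtol=1e-8)

    def test_empty_grid(self, white_recording):
        with pytest.raises(GEDError):
            ged_sweep(white_recording, 40.0, 30.0)


class TestSimilarity:
    def test_identical_vectors(self):
        V = np.tile([1.0, 2.0, 3.0, -1.0], (3, 1))
        sweep = GEDSweep(grid=np.arange(3.0), lambda_max=np.ones(3), eigvecs=V)
        sim = similarity_matrix(sweep)
        np.testing.assert_allclose(sim, 1.0)

    def test_orthogonal_vectors(self):
        V = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        sweep = GEDSweep(grid=np.arange(2.0), lambda_max=np.ones(2), eigvecs=V)
        sim = similarity_matrix(sweep)
        assert sim[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_unit_diagonal(self, alpha_recording):
        sweep = ged_sweep(alpha_recording, 5.0, 20.0, 1.0)
        sim = similarity_matrix(sweep)
        np.testing.assert_allclose(sim, sim.T)
        np.testing.assert_allclose(np.diag(sim), 1.0)
        assert (sim >= 0).all() and (sim <= 1).all()


class TestClusterAssign:
    def test_block_diagonal(self):
        grid = np.arange(2.0, 13.5, 0.5)
        n1 = int((8.0 - 2.0) / 0.5) + 1  # 2..8 inclusive
        sim = np.zeros((grid.size, grid.size))
        sim[:n1, :n1] = 1.0
        sim[n1:, n1:] = 1.0
        bounds = cluster_bands(sim, grid, method="dbscan")
        assert len(bounds.intervals) == 2
        assert bounds.intervals[0] == (2.0, 8.0)
        assert bounds.intervals[1] == (8.5, 13.0)

    def test_all_ones_single_interval(self):
        grid = np.arange(2.0, 10.5, 0.5)
        sim = np.ones((grid.size, grid.size))
        bounds = cluster_bands(sim, grid, method="dbscan")
        assert bounds.intervals == [(2.0, 10.0)]

    def test_assign_canonical_theta(self):
        b = assign_canonical(BandBoundaries(intervals=[(4.2, 7.6)]))
        assert b.canonical["theta"] == (4.2, 7.6)
        assert b.canonical["alpha"] is None

    def test_assign_beyond_beta_unassigned(self):
        b = assign_canonical(BandBoundaries(intervals=[(35.0, 40.0)]))
        assert all(v is None for v in b.canonical.values())

    def test_assign_empty(self):
        b = assign_canonical(BandBoundaries(intervals=[]))
        assert all(v is None for v in b.canonical.values())

    def test_merge_within_band(self):
        b = assign_canonical(BandBoundaries(intervals=[(8.5, 9.5), (11.0, 12.5)]))
        assert b.canonical["alpha"] == (8.5, 12.5)


class TestRecovery:
    def test_planted_band_recovery(self):
        hits = 0
        for seed in range(10):
            rec = planted_recording(seed=seed)
            b = detect_bands(rec)
            th, al = b.canonical["theta"], b.canonical["alpha"]
            ok = (
                th is not None and al is not None
                and abs(th[0] - 5.0) <= 1.0 and abs(th[1] - 7.0) <= 1.0
                and abs(al[0] - 9.0) <= 1.0 and abs(al[1] - 11.0) <= 1.0
            )
            hits += ok
        assert hits >= 8

    def test_method_agreement_on_separated_bands(self):
        agree = 0
        for seed in range(5):
            rec = planted_recording(seed=seed)
            bd = detect_bands(rec, method="dbscan")
            bt = detect_bands(rec, method="trough")
            same = all(
                (bd.canonical[b] is None) == (bt.canonical[b] is None)
                for b in ("theta", "alpha")
            )
            agree += same
        assert agree >= 4

    def test_boundaries_scale_invariant(self):
        rec = planted_recording(seed=1)
        b1 = detect_bands(rec)
        b2 = detect_bands(rec.copy_with(rec.data * 20.0))
        assert b1.intervals == b2.intervals


class TestBandPower:
    def test_tone_power_concentrated(self):
        t = np.arange(15000) / 250.0
        data = np.tile(np.sin(2 * np.pi * 10.0 * t), (8, 1))
        data += 0.01 * np.random.default_rng(0).standard_normal(data.shape)
        rec = Recording(data, fs=250.0, labels=list(DEFAULT_CHANNELS))
        bounds = assign_canonical(
            BandBoundaries(intervals=[(8.0, 13.0), (14.0, 30.0)])
        )
        tbl = individualized_band_power(rec, bounds)
        alpha = tbl[(tbl.band == "alpha")].power.mean()
        beta = tbl[(tbl.band == "beta")].power.mean()
        assert alpha / beta > 10

    def test_amplitude_scaling(self, alpha_recording):
        bounds = assign_canonical(BandBoundaries(intervals=[(8.0, 13.0)]))
        p1 = individualized_band_power(alpha_recording, bounds)
        p2 = individualized_band_power(
            alpha_recording.copy_with(alpha_recording.data * 2.0), bounds
        )
        np.testing.assert_allclose(p2.power, 4.0 * p1.power, rtol=1e-8)

    def test_unassigned_band_missing(self, alpha_recording):
        bounds = assign_canonical(BandBoundaries(intervals=[(8.0, 13.0)]))
        tbl = individualized_band_power(alpha_recording, bounds)
        assert tbl[tbl.band == "delta"].power.isna().all()
        assert tbl[tbl.band == "alpha"].power.notna().all()

    def test_no_assigned_bands_error(self, alpha_recording):
        with pytest.raises(GEDError):
            individualized_band_power(
                alpha_recording, BandBoundaries(intervals=[])
            )
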