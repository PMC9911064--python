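"""Site frequency spectra, the sweep spectrum and the CLR scan."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from domscan.simulate import SimulationConfig, SweepSpec, simulate_cohort
from domscan.sweep import (
    SFS,
    SweepModel,
    background_sfs,
    default_alpha_grid,
    fold_sfs,
    loess_fit,
    loess_smooth,
    project_distribution,
    project_sfs,
    scan_genome,
)
from domscan.types import Window, WindowTrack
from domscan.variant_io import tile_windows

from conftest import build_matrix


def neutral_sfs(n):
    p = 1.0 / np.arange(1, n)
    return SFS(n, p / p.sum())


class TestBackgroundSFS:
    def test_counting(self):
        # 4 haplotypes, derived counts {1,1,2,3} -> (0.5, 0.25, 0.25)
        cols = [[1, 0, 0, 0], [0, 1, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0]]
        m = build_matrix(cols)
        sfs = background_sfs(m)
        assert np.allclose(sfs.probs, [0.5, 0.25, 0.25])

    def test_folding(self):
        folded = fold_sfs(SFS(4, np.array([0.5, 0.25, 0.25])))
        assert np.allclose(folded.probs, [0.75, 0.25, 0.0])
        assert folded.folded

    def test_no_polymorphism_rejected(self):
        m = build_matrix([[0, 0, 0, 0]])
        with pytest.raises(ValueError):
            background_sfs(m)

    def test_neutral_simulation_matches_one_over_j(self):
        # near-independent SNPs: many short segments with ~1 SNP each
        cfg = SimulationConfig(
            chrom_lengths={"chr1": 1_000_000},
            segment_length=100,
            samples={"Guatemalan": 10, "Mexican": 0, "Lowland": 0},
        )
        matrix, _ = simulate_cohort(cfg, seed=21)
        sfs = background_sfs(matrix, "Guatemalan")
        n_snps = matrix.n_sites
        expected = neutral_sfs(20).probs
        stat, p = chisquare(sfs.probs * n_snps, expected * n_snps)
        assert p > 0.01


class TestProjection:
    def test_identity_at_m_equals_n(self):
        sfs = neutral_sfs(10)
        q = project_sfs(sfs, 10)
        assert np.allclose(q[1:-1], sfs.probs) and q[0] == 0 and q[-1] == 0

    def test_n3_enumeration(self):
        # analytic hypergeometric projection of a 2-class spectrum to m=2
        p1, p2 = 0.3, 0.7
        q = project_distribution(np.array([0.0, p1, p2, 0.0]), 2)
        assert q[1] == pytest.approx(2 / 3 * p1 + 2 / 3 * p2)
        assert q[0] == pytest.approx(p1 / 3)
        assert q[2] == pytest.approx(p2 / 3)

    def test_composition_and_mass_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(5, 15))
            p = rng.random(n + 1)
            p /= p.sum()
            m = int(rng.integers(3, n))
            mp = int(rng.integers(2, m))
            direct = project_distribution(p, mp)
            composed = project_distribution(project_distribution(p, m), mp)
            assert np.allclose(direct, composed, atol=1e-12)
            assert abs(direct.sum() - 1.0) < 1e-12

    def test_projecting_up_rejected(self):
        with pytest.raises(ValueError):
            project_distribution(np.array([0, 1.0, 0]), 5)

    @given(
        weights=st.lists(st.floats(0.01, 1.0), min_size=6, max_size=12),
        m_frac=st.floats(0.1, 1.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_projection_preserves_mass_for_arbitrary_spectra(self, weights, m_frac):
        p = np.array(weights)
        p /= p.sum()
        n = p.size - 1
        m = max(2, int(m_frac * n))
        q = project_distribution(p, m)
        assert abs(q.sum() - 1.0) < 1e-12
        assert np.all(q >= -1e-15)


class TestSweepSpectrum:
    def test_normalises_for_random_parameters(self):
        rng = np.random.default_rng(1)
        model = SweepModel(neutral_sfs(10))
        for _ in range(20):
            d = float(rng.uniform(10, 1e5))
            alpha = float(10 ** rng.uniform(-6, -2))
            total = sum(
                model.sweep_site_prob(j, d, alpha) for j in range(1, 10)
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_background_limit_at_large_alpha_d(self):
        sfs = neutral_sfs(10)
        model = SweepModel(sfs)
        for j in range(1, 10):
            assert model.sweep_site_prob(j, d=40.0, alpha=1.0) == pytest.approx(
                sfs.probs[j - 1], abs=1e-9
            )
        # just below the shortcut threshold the mixture itself is converged
        mix = model.mixture(-math.expm1(-29.5))
        assert np.abs(mix - sfs.probs).sum() < 1e-6

    def test_degenerate_at_zero_escape(self):
        model = SweepModel(neutral_sfs(6))
        with pytest.raises(ValueError):
            model.mixture(0.0)

    @pytest.mark.parametrize("n,p_e", [(4, 0.5), (10, 0.2)])
    def test_monte_carlo_generative_oracle(self, n, p_e):
        """The analytic mixture matches simulation of the capture process."""
        sfs = neutral_sfs(n)
        model = SweepModel(sfs)
        rng = np.random.default_rng(12345)
        draws = 200_000
        full = sfs.full()
        b = rng.binomial(n, p_e, size=draws)
        j = np.empty(draws, dtype=int)
        for bv in range(n + 1):
            sel = b == bv
            cnt = int(sel.sum())
            if cnt == 0:
                continue
            if bv == n:
                j[sel] = rng.choice(np.arange(n + 1), p=full, size=cnt)
            else:
                q = project_distribution(full, bv + 1)
                i = rng.choice(np.arange(bv + 2), p=q, size=cnt)
                swept = rng.random(cnt) < i / (bv + 1)
                j[sel] = np.where(swept, n - bv + i - 1, i)
        poly = (j >= 1) & (j <= n - 1)
        obs = np.bincount(j[poly], minlength=n + 1)[1:n]
        freq = obs / obs.sum()
        exact = model.mixture(p_e)
        se = np.sqrt(np.maximum(exact * (1 - exact) / obs.sum(), 1e-12))
        assert np.all(np.abs(freq - exact) <= 3 * se)


class TestCLR:
    def test_nonnegative_and_zero_at_null_argmax(self):
        rng = np.random.default_rng(2)
        sfs = neutral_sfs(10)
        model = SweepModel(sfs)
        positions = np.sort(rng.integers(0, 100_000, size=200))
        counts = rng.choice(np.arange(1, 10), p=sfs.probs, size=200)
        for x in (0.0, 50_000.0, 99_000.0):
            lam, alpha = model.clr_at_position(x, positions, counts)
            assert lam >= 0.0
            if math.isinf(alpha):
                assert lam == 0.0

    def test_invariant_to_snp_order(self):
        rng = np.random.default_rng(3)
        model = SweepModel(neutral_sfs(8))
        positions = rng.integers(0, 50_000, size=100)
        counts = rng.integers(1, 8, size=100)
        lam1, _ = model.clr_at_position(25_000, positions, counts)
        perm = rng.permutation(100)
        lam2, _ = model.clr_at_position(25_000, positions[perm], counts[perm])
        assert lam1 == pytest.approx(lam2, rel=1e-6)

    def test_sweep_center_beats_distant_position(self):
        wins = 0
        for rep in range(5):
            cfg = SimulationConfig(
                chrom_lengths={"chr1": 1_000_000},
                samples={"Guatemalan": 10, "Mexican": 0, "Lowland": 0},
                sweeps=[SweepSpec("Guatemalan", "chr1", 495_000, radius=50_000, s=0.05)],
            )
            matrix, _ = simulate_cohort(cfg, seed=400 + rep)
            model = SweepModel(background_sfs(matrix, "Guatemalan"))
            from domscan.sweep import derived_counts

            pos, counts = derived_counts(matrix, "Guatemalan", "chr1")
            lam_center, _ = model.clr_at_position(495_000, pos, counts)
            lam_far, _ = model.clr_at_position(995_000, pos, counts)
            wins += lam_center > lam_far
        assert wins >= 4

    def test_scan_bookkeeping(self):
        cfg = SimulationConfig(
            chrom_lengths={"chr1": 100_000},
            samples={"Guatemalan": 5, "Mexican": 0, "Lowland": 0},
        )
        matrix, _ = simulate_cohort(cfg, seed=8)
        track = tile_windows({"chr1": 100_000}, 10_000)
        scan_genome(matrix, "Guatemalan", track)
        assert len(track) == 10
        assert all("CLR" in w.values for w in track)

    def test_folded_scan_runs(self):
        cfg = SimulationConfig(
            chrom_lengths={"chr1": 100_000},
            samples={"Guatemalan": 5, "Mexican": 0, "Lowland": 0},
        )
        matrix, _ = simulate_cohort(cfg, seed=8)
        track = tile_windows({"chr1": 100_000}, 10_000)
        scan_genome(matrix, "Guatemalan", track, folded=True)
        assert all(w.values["CLR"] >= 0 for w in track)

    def test_alpha_grid_spans_and_ends_with_null(self):
        grid = default_alpha_grid()
        assert np.isinf(grid[-1])
        assert grid[0] < grid[-2]
        assert grid.size == 41


class TestLoess:
    def test_constant_reproduced_exactly(self):
        x = np.arange(50.0)
        y = np.full(50, 3.7)
        assert np.allclose(loess_fit(x, y), 3.7)

    def test_quadratic_reproduced_exactly(self):
        x = np.arange(60.0)
        y = 2.0 + 0.5 * x - 0.01 * x**2
        assert np.allclose(loess_fit(x, y, degree=2), y, atol=1e-8)

    def test_spike_localises(self):
        x = np.arange(101.0)
        y = np.zeros(101)
        y[50] = 10.0
        sm = loess_fit(x, y, span=0.3)
        assert abs(int(np.argmax(sm)) - 50) <= 1

    def test_agrees_with_reference_lowess(self):
        import statsmodels.api as smapi

        rng = np.random.default_rng(4)
        for _ in range(3):
            x = np.sort(rng.uniform(0, 100, size=80))
            y = np.sin(x / 10) + rng.normal(0, 0.2, size=80)
            mine = loess_fit(x, y, span=0.5, degree=1)
            ref = smapi.nonparametric.lowess(y, x, frac=0.5, it=0, return_sorted=False)
            assert np.abs(mine - ref).max() < 1e-6

    def test_track_smoothing_fills_gaps_with_zero(self):
        wins = [Window("chr1", i * 10, i * 10 + 10) for i in range(20)]
        for i, w in enumerate(wins):
            if i != 10:
                w.values["CLR"] = 0.0
        wins[10].values["CLR"] = 5.0
        track = WindowTrack(wins)
        # window 3 has no value: counts as zero, everything smooth
        del track[3].values["CLR"]
        loess_smooth(track, "CLR", span=0.5)
        assert all("CLR_smooth" in w.values for w in track)

    def test_short_chromosome_returned_unsmoothed(self, caplog):
        wins = [Window("chr1", i * 10, i * 10 + 10, values={"CLR": float(i)}) for i in range(3)]
        track = WindowTrack(wins)
        loess_smooth(track, "CLR")
        assert [w.values["CLR_smooth"] for w in track] == [0.0, 1.0, 2.0]
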