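"""Sampler correctness: Metropolis criterion, Boltzmann statistics,
replica exchange bookkeeping, tuning, and reproducibility."""

import numpy as np
import pytest

import naturalmoves as nm
from naturalmoves.energy import KB, CustomTerm, EnergyModel, HarmonicTether
from naturalmoves.moves import MoveGenerator, MoveSet
from naturalmoves.sampler import metropolis_accept


def point_conf(n=1):
    return nm.Conformation(
        atom_name=np.array(["CA"] * n),
        res_id=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n),
        res_name=np.array(["ALA"] * n),
        element=np.array(["C"] * n),
        coords=np.zeros((n, 3)),
        model_kind="cg3",
    )


def harmonic_system(k=1.0, max_trans=1.8):
    conf = point_conf()
    model = EnergyModel(
        terms=[HarmonicTether(np.array([0]), np.zeros((1, 3)), k=k)]
    )
    ms = MoveSet(
        [MoveGenerator(kind="rigid", label="site", atoms=np.array([0]), max_trans=max_trans)]
    )
    return conf, model, ms


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-1.0, 300.0, rng) for _ in range(100))

    def test_half_acceptance_at_kT_ln2(self):
        rng = np.random.default_rng(1)
        dE = KB * 300.0 * np.log(2.0)
        acc = np.mean([metropolis_accept(dE, 300.0, rng) for _ in range(10_000)])
        assert acc == pytest.approx(0.5, abs=0.02)

    def test_infinite_and_nan_rejected(self):
        rng = np.random.default_rng(2)
        assert not metropolis_accept(np.inf, 300.0, rng)
        assert not metropolis_accept(np.nan, 300.0, rng)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            metropolis_accept(0.0, 0.0, np.random.default_rng(0))


class TestRunMC:
    def test_zero_iterations_initial_frame_only(self, toy_groove):
        conf, model, ms = harmonic_system()
        cfg = nm.SamplerConfig(temperatures=(300.0,), iterations=0, seed=0)
        traj, stats = nm.run_mc(conf, ms, model, cfg)
        assert traj.n_frames == 1
        assert stats.acceptance_rate == 0.0

    def test_identical_seeds_identical_trajectories(self):
        conf, model, ms = harmonic_system()
        cfg = nm.SamplerConfig(temperatures=(300.0,), iterations=500, seed=123, sample_interval=50)
        t1, _ = nm.run_mc(conf, ms, model, cfg)
        t2, _ = nm.run_mc(conf, ms.copy(), model, cfg)
        for f1, f2 in zip(t1.frames, t2.frames):
            np.testing.assert_array_equal(f1, f2)

    def test_harmonic_equipartition(self):
        """Sampled coordinate variance matches k_B T / k (equipartition)."""
        conf, model, ms = harmonic_system(k=1.0)
        cfg = nm.SamplerConfig(
            temperatures=(300.0,), iterations=50_000, seed=11, sample_interval=10
        )
        traj, _ = nm.run_mc(conf, ms, model, cfg)
        x = np.array(traj.frames)[:, 0, :]
        burn = len(x) // 5
        var = x[burn:].var(axis=0).mean()
        assert var == pytest.approx(KB * 300.0 / 1.0, rel=0.05)


class TestParallelTempering:
    def test_equal_temperature_swaps_always_accepted(self):
        # beta_i == beta_j makes log p = 0, i.e. certain acceptance; realize
        # it with a ladder so tight the energies barely matter
        conf, model, ms = harmonic_system()
        cfg = nm.SamplerConfig(
            temperatures=(300.0, 300.0000001),
            iterations=400,
            seed=5,
            exchange_interval=50,
            sample_interval=100,
        )
        _, stats = nm.run_parallel_tempering(conf, ms, model, cfg)
        assert stats.exchange_attempted > 0
        assert stats.exchange_accepted == stats.exchange_attempted

    def test_exchange_bookkeeping(self):
        conf, model, ms = harmonic_system()
        cfg = nm.SamplerConfig(
            temperatures=(300.0, 450.0, 600.0),
            iterations=600,
            seed=6,
            exchange_interval=50,
            sample_interval=100,
        )
        trajs, stats = nm.run_parallel_tempering(conf, ms, model, cfg)
        assert len(trajs) == 3
        assert 0 <= stats.exchange_accepted <= stats.exchange_attempted
        assert all(0.0 <= r <= 1.0 for r in stats.per_replica_acceptance)

    def test_each_replica_matches_its_own_temperature(self):
        """In a 2-replica PT run each ladder temperature reproduces its own
        harmonic variance k_B T / k."""
        conf, model, ms = harmonic_system(k=1.0)
        cfg = nm.SamplerConfig(
            temperatures=(300.0, 529.0),
            iterations=50_000,
            seed=7,
            exchange_interval=50,
            sample_interval=10,
        )
        trajs, _ = nm.run_parallel_tempering(conf, ms, model, cfg)
        for T, traj in zip((300.0, 529.0), trajs):
            x = np.array(traj.frames)[:, 0, :]
            var = x[len(x) // 5 :].var(axis=0).mean()
            assert var == pytest.approx(KB * T / 1.0, rel=0.05)

    def test_single_temperature_degenerates_to_plain_mc(self):
        conf, model, ms = harmonic_system()
        cfg = nm.SamplerConfig(temperatures=(300.0,), iterations=200, seed=8)
        trajs, stats = nm.run_parallel_tempering(conf, ms, model, cfg)
        assert len(trajs) == 1 and stats.exchange_attempted == 0


class TestDetailedBalance:
    def test_double_well_transition_counts_symmetric(self):
        """Empirical coarse-state transition asymmetry on a 1D double well is
        consistent with detailed balance (chi-square, alpha = 0.01)."""
        conf = point_conf()
        a, h = 1.0, 1.0  # wells at x = +-1, barrier height h

        def well(c):
            x = c[0, 0]
            return h * (x**2 - a**2) ** 2 / a**4

        model = EnergyModel(terms=[CustomTerm(np.array([0]), well)])
        ms = MoveSet(
            [MoveGenerator(kind="rigid", label="x", atoms=np.array([0]), max_trans=1.2)]
        )
        cfg = nm.SamplerConfig(
            temperatures=(600.0,), iterations=40_000, seed=13, sample_interval=1
        )
        traj, _ = nm.run_mc(conf, ms, model, cfg)
        xs = np.array(traj.frames)[:, 0, 0]
        bins = np.digitize(xs, [-0.5, 0.5])  # 3 coarse states
        from collections import Counter

        counts = Counter(zip(bins[:-1], bins[1:]))
        chi2 = 0.0
        dof = 0
        for i in range(3):
            for j in range(i + 1, 3):
                nij, nji = counts.get((i, j), 0), counts.get((j, i), 0)
                if nij + nji >= 10:
                    chi2 += (nij - nji) ** 2 / (nij + nji)
                    dof += 1
        from scipy.stats import chi2 as chi2_dist

        assert dof >= 1
        assert chi2 <= chi2_dist.ppf(0.99, dof)


class TestTuning:
    def test_tiny_steps_grow(self):
        conf, model, ms = harmonic_system(max_trans=1e-3)
        tuned = nm.tune_step_sizes(conf, ms, model, 300.0, target_rate=0.25, budget=2000, seed=0)
        assert tuned.generators[0].max_trans > ms.generators[0].max_trans

    def test_huge_steps_shrink_until_target(self):
        conf, model, ms = harmonic_system(max_trans=50.0)
        tuned = nm.tune_step_sizes(conf, ms, model, 300.0, target_rate=0.25, budget=4000, seed=1)
        assert tuned.generators[0].max_trans < 50.0
        cfg = nm.SamplerConfig(temperatures=(300.0,), iterations=4000, seed=2, sample_interval=500)
        _, stats = nm.run_mc(conf, tuned, model, cfg)
        assert stats.acceptance_rate >= 0.25

    def test_zero_target_rejected(self):
        conf, model, ms = harmonic_system()
        with pytest.raises(ValueError):
            nm.tune_step_sizes(conf, ms, model, 300.0, target_rate=0.0)

    def test_input_moveset_not_mutated(self):
        conf, model, ms = harmonic_system(max_trans=1e-3)
        before = ms.generators[0].max_trans
        nm.tune_step_sizes(conf, ms, model, 300.0, budget=1000, seed=3)
        assert ms.generators[0].max_trans == before
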