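"""Operator-splitting solver: time window, occupancy, leaver sampling, and
the two operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetrd.engine import build_tables
from tetrd.mesh import compute_geometry, generate_cuboid_mesh
from tetrd.model import (
    DiffusionRateTable,
    ModelSpec,
    Species,
    build_diffusion_rates,
)
from tetrd.opsplit import (
    ConfigurationError,
    OccupancyTracker,
    OpSplitSim,
    compute_tau,
    run_opsplit,
    sample_leavers,
)
from tetrd.recorder import Recorder


def _rate_table(d_total):
    d_total = np.atleast_2d(np.asarray(d_total, dtype=float))
    return DiffusionRateTable(diff_species=["X"] * d_total.shape[1],
                              diff_indices=np.arange(d_total.shape[1]),
                              d_k=np.zeros(d_total.shape[:1] + (4,) + d_total.shape[1:]),
                              d_total=d_total)


class TestComputeTau:
    def test_reciprocal_of_single_entry(self):
        assert compute_tau(_rate_table([[1000.0]])) == pytest.approx(0.001)

    def test_min_over_entries(self):
        assert compute_tau(_rate_table([[10.0, 250.0], [40.0, 0.0]])) == pytest.approx(1 / 250)

    def test_no_positive_rate_raises(self):
        with pytest.raises(ConfigurationError, match="pure-reaction"):
            compute_tau(_rate_table([[0.0, 0.0]]))

    def test_refinement_decreases_tau(self, bench_model):
        """Halving tet edge lengths increases local diffusion rates, so the
        window shrinks (more main-loop iterations for finer meshes)."""
        taus = []
        for counts in [(1, 1, 10), (2, 2, 20)]:
            mesh = generate_cuboid_mesh((10, 10, 100), counts)
            taus.append(compute_tau(
                build_diffusion_rates(mesh, compute_geometry(mesh), bench_model)))
        assert taus[1] < taus[0]


class TestSampleLeavers:
    def test_zero_rate_gives_zero(self):
        assert sample_leavers(100.0, 50, 0.0, 0.1, np.random.default_rng(0)) == 0

    def test_clamped_to_current_count(self):
        rng = np.random.default_rng(0)
        assert sample_leavers(1e6, 7, 10.0, 1.0, rng) == 7

    def test_stochastic_rounding_mean(self):
        """mean_occ=100, d_total*tau=0.3: mean leavers ~ 30 over 1e5 draws;
        an integer mean is deterministic, a fractional one splits between the
        two adjacent integers."""
        rng = np.random.default_rng(123)
        draws = np.array([sample_leavers(100.0, 1000, 3.0, 0.1, rng) for _ in range(1000)])
        assert (draws == 30).all()  # mu = 30 exactly: no rounding noise
        draws = np.array([sample_leavers(100.0, 1000, 3.047, 0.1, rng)
                          for _ in range(100_000)])
        assert set(np.unique(draws)) == {30, 31}
        sigma = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 30.47) < 3 * sigma

    @given(mean_occ=st.floats(0, 1e4), n_now=st.integers(0, 1000),
           d_total=st.floats(0, 1e3), tau=st.floats(0, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_property(self, mean_occ, n_now, d_total, tau):
        n = sample_leavers(mean_occ, n_now, d_total, tau, np.random.default_rng(0))
        assert 0 <= n <= n_now


class TestOccupancy:
    def test_constant_count_mean_is_exact(self):
        occ = OccupancyTracker.zeros(1, 1)
        hosted = np.array([0])
        occ.reset(hosted, 0.0)
        counts = np.full((1, 1), 10, dtype=np.int64)
        occ.finalize(counts, hosted, np.array([0]), 0.4)
        assert occ.mean(hosted, 0.4)[0, 0] == pytest.approx(10.0)

    def test_midwindow_step_piecewise_integral(self):
        """Count stepping 10 -> 12 at tau/2 gives mean occupancy 11."""
        tau = 0.2
        occ = OccupancyTracker.zeros(1, 1)
        hosted = np.array([0])
        occ.reset(hosted, 0.0)
        counts = np.full((1, 1), 10, dtype=np.int64)
        # the accrual a solver performs at the moment of the change:
        occ.integral[0, 0] += counts[0, 0] * (tau / 2 - occ.last_update[0, 0])
        occ.last_update[0, 0] = tau / 2
        counts[0, 0] = 12
        occ.finalize(counts, hosted, np.array([0]), tau)
        assert occ.mean(hosted, tau)[0, 0] == pytest.approx(11.0)

    def test_no_reactions_keeps_mean_at_start_count(self, bar60, diffusion_only_model):
        sim = OpSplitSim.from_model(bar60, diffusion_only_model,
                                    counts=np.full((60, 1), 7, dtype=np.int64), seed=0)
        sim.solver.reaction_window(0.0, sim.tau)
        np.testing.assert_allclose(sim.solver.occ.mean(sim.solver.hosted, sim.tau), 7.0)


class TestReactionWindowStatistics:
    def test_windowed_reactions_match_plain_ssa_in_one_voxel(self, single_tet, ab_model):
        """Splitting does not alter pure reaction kinetics in a single voxel:
        the distribution of n_C after many windows matches an unsplit SSA run
        of the same duration (KS over seeds)."""
        from scipy.stats import ks_2samp

        from tetrd.ssa import make_state, run_exact

        tables = build_tables(single_tet, compute_geometry(single_tet), ab_model)
        t_end, n_windows, n_runs = 0.02, 40, 300
        nc_split, nc_exact = [], []
        for sd in range(n_runs):
            from tetrd.opsplit import RankSolver, rank_rng

            sol = RankSolver(tables, np.array([0]), rank_rng(sd, 0))
            sol.counts[0] = [30, 50, 0]
            for w in range(n_windows):
                sol.reaction_window(w * t_end / n_windows, (w + 1) * t_end / n_windows)
            nc_split.append(sol.counts[0, 2])
            st = make_state(single_tet, ab_model,
                            counts=np.array([[30, 50, 0]], dtype=np.int64),
                            seed=sd + 10_000, tables=tables)
            run_exact(st, t_end)
            nc_exact.append(st.counts[0, 2])
        assert ks_2samp(nc_split, nc_exact).pvalue > 0.01


class TestDiffusionOperator:
    def test_single_neighbor_receives_all_leavers(self, two_tet, diffusion_only_model):
        sim = OpSplitSim.from_model(two_tet, diffusion_only_model,
                                    counts=np.array([[1000], [0]], dtype=np.int64), seed=2)
        sol = sim.solver
        sol.reaction_window(0.0, sim.tau)  # establishes occupancy
        before = sol.counts.sum()
        sol.diffusion_operator(sim.tau)
        assert sol.counts.sum() == before  # every leaver landed in the other tet
        assert sol.counts[1, 0] > 0

    def test_symmetric_pair_equalizes(self, two_tet):
        """Detailed balance: two mirror tets end up sharing molecules evenly,
        with fluctuations on the binomial sqrt(n) scale.

        A faster pace-setter species sets tau, so the tracked species hops
        with d*tau = 1/3 per window (at d*tau = 1 the split scheme degenerates
        to a deterministic full swap between two identical tets)."""
        model = ModelSpec([Species("X", 100.0), Species("pace", 300.0)], [])
        sim = OpSplitSim.from_model(two_tet, model,
                                    counts=np.array([[2000, 0], [0, 0]], dtype=np.int64),
                                    seed=4)
        diffs = []
        n_windows = 400
        for w in range(n_windows):
            sim.solver.reaction_window(w * sim.tau, (w + 1) * sim.tau)
            sim.solver.diffusion_operator(sim.tau)
            if w >= 100:  # past relaxation
                diffs.append(sim.solver.counts[0, 0] - sim.solver.counts[1, 0])
        diffs = np.array(diffs, dtype=float)
        assert abs(diffs.mean()) < 3 * np.sqrt(2000)
        assert diffs.std() < 3 * np.sqrt(2000)
        assert sim.solver.counts[:, 0].sum() == 2000


class TestFreeDiffusionAgainstExact:
    def test_msd_and_seedwise_distribution_match_exact_ssa(self):
        """Free diffusion from a center tet: the split solver reproduces the
        Einstein MSD within 5%, and the per-seed MSD distributions of the two
        solvers agree (two-sample KS over independent seeds — molecules
        within one run are correlated, so seeds are the independent unit)."""
        from scipy.stats import ks_2samp

        from tetrd.ssa import make_state, run_exact

        D, t, n_mol, n_seeds = 100.0, 0.01, 2000, 30
        mesh = generate_cuboid_mesh((10, 10, 10), (10, 10, 10))
        geom = compute_geometry(mesh)
        model = ModelSpec([Species("X", D)], [])
        tables = build_tables(mesh, geom, model)
        center = int(np.argmin(((geom.barycenters - 5.0) ** 2).sum(axis=1)))
        counts = np.zeros((mesh.n_tets, 1), dtype=np.int64)
        counts[center, 0] = n_mol
        disp2 = ((geom.barycenters - geom.barycenters[center]) ** 2).sum(axis=1)

        msd_exact = np.empty(n_seeds)
        msd_split = np.empty(n_seeds)
        for sd in range(n_seeds):
            st = make_state(mesh, model, counts=counts.copy(), seed=21 + sd,
                            tables=tables)
            run_exact(st, t)
            msd_exact[sd] = (st.counts[:, 0] * disp2).sum() / n_mol
            sim = OpSplitSim.from_model(mesh, model, counts=counts.copy(),
                                        seed=5000 + sd, tables=tables)
            run_opsplit(sim, t)
            msd_split[sd] = (sim.solver.counts[:, 0] * disp2).sum() / n_mol
        assert msd_exact.mean() == pytest.approx(6 * D * t, rel=0.05)
        assert msd_split.mean() == pytest.approx(6 * D * t, rel=0.05)
        assert ks_2samp(msd_exact, msd_split).pvalue > 0.01


class TestRunOpSplit:
    def test_t_end_zero_is_identity(self, bar60, bench_model):
        sim = OpSplitSim.from_model(bar60, bench_model, seed=1)
        before = sim.solver.counts.copy()
        run_opsplit(sim, 0.0)
        np.testing.assert_array_equal(sim.solver.counts, before)
        assert sim.iterations == 0

    def test_pure_diffusion_total_conservation(self, bar60):
        model = ModelSpec([Species(n, d) for n, d in [("X", 100.0), ("Y", 10.0)]], [],
                          init_counts={"X": 5000, "Y": 3000})
        sim = OpSplitSim.from_model(bar60, model, seed=9)
        rec = Recorder(sim.tau, ["X", "Y"])
        run_opsplit(sim, 30 * sim.tau, recorder=rec)
        for snap in rec.samples:
            np.testing.assert_array_equal(snap, [5000, 3000])

    def test_partial_final_window_counts_as_iteration(self, bar60, diffusion_only_model):
        sim = OpSplitSim.from_model(bar60, diffusion_only_model,
                                    counts=np.full((60, 1), 5, dtype=np.int64), seed=0)
        tau = sim.tau
        run_opsplit(sim, 1.5 * tau)
        assert sim.iterations == 2
        assert sim.t == pytest.approx(1.5 * tau)
        assert sim.tau == tau  # window constant for the whole run
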