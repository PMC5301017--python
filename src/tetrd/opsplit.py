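"""Operator-splitting reaction–diffusion solver.

The run is divided into windows of a constant diffusion time window

    τ = min over all diffusive (S, tet) of 1 / d_S,tet ,

fixed at initialization (it depends only on model and geometry, never on the
molecule population).  Each window alternates two operators:

1. **Reaction SSA** — an exact SSA restricted to reaction events, run for the
   window, while accruing per-(tet, diffusive species) occupancy: the time
   integral of the molecule count over the window.  Products created
   mid-window accrue occupancy from their creation time.
2. **Diffusion** — for each (tet, diffusive species), the expected number of
   leavers is μ = mean-occupancy · d_S,tet · window length, clamped to the
   current count; the integer number of leavers is ⌊μ⌋ plus a Bernoulli draw
   on the fraction (stochastic rounding), and leavers are split among the
   face neighbors multinomially with probabilities d_k/d_S,tet.

The same :class:`RankSolver` runs the whole mesh (serial split solver) or a
hosted subset of tets under a partition (parallel protocol); in the latter
case leavers bound for tets hosted elsewhere are registered to per-neighbor
remote change buffers instead of being applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import SystemTables, _fw_build, build_tables, reaction_window_kernel
from .mesh import TetMesh, compute_geometry
from .model import DiffusionRateTable, ModelSpec

__all__ = [
    "ConfigurationError",
    "OccupancyTracker",
    "RankSolver",
    "OpSplitSim",
    "compute_tau",
    "sample_leavers",
    "reaction_window",
    "diffusion_operator",
    "run_opsplit",
    "rank_rng",
]

_KERNEL_CHUNK = 20_000_000


class ConfigurationError(ValueError):
    pass


def compute_tau(rates: DiffusionRateTable) -> float:
    """Global diffusion time window: min of 1/d_S,tet over all entries with a
    positive local rate.  Computed once at initialization and held constant
    for the whole run."""
    pos = rates.d_total[rates.d_total > 0]
    if pos.size == 0:
        raise ConfigurationError(
            "no diffusive species has a positive local diffusion rate anywhere; "
            "use the pure-reaction exact-SSA path instead"
        )
    return float(1.0 / pos.max())


def rank_rng(seed: int, rank: int, n_ranks: int | None = None) -> np.random.Generator:
    """Independent per-rank stream derived from (master seed, rank).

    Spawned children of a SeedSequence are keyed by the spawn index, so child
    ``rank`` is the same stream regardless of how many ranks exist — the
    1-rank serial split solver and rank 0 of any parallel run share a stream.
    """
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(rank + 1)[rank])


def sample_leavers(mean_occ: float, n_now: int, d_total: float, tau: float,
                   rng: np.random.Generator) -> int:
    """Integer number of molecules leaving a tet in one window.

    Expected leavers μ = mean_occ·d_total·τ, clamped to the current count;
    the integer draw is ⌊μ⌋ + Bernoulli(frac(μ)) (stochastic rounding), so
    0 ≤ N ≤ n_now always and E[N] = min(μ, n_now).
    """
    if min(mean_occ, n_now, d_total, tau) < 0:
        raise ValueError("sample_leavers inputs must be nonnegative")
    mu = min(mean_occ * d_total * tau, float(n_now))
    base = math.floor(mu)
    n = base + (1 if rng.random() < mu - base else 0)
    return min(n, n_now)


@dataclass
class OccupancyTracker:
    """Time integral of molecule count per (tet, diffusive species) over the
    current window, maintained by accruing (old count)·(elapsed) on every
    count change."""

    integral: np.ndarray  # (n_tets, ND), molecule·s
    last_update: np.ndarray  # (n_tets, ND), s
    window_start: float = 0.0

    @classmethod
    def zeros(cls, n_tets: int, nd: int) -> "OccupancyTracker":
        return cls(np.zeros((n_tets, nd)), np.zeros((n_tets, nd)))

    def reset(self, hosted: np.ndarray, t0: float) -> None:
        self.integral[hosted] = 0.0
        self.last_update[hosted] = t0
        self.window_start = t0

    def finalize(self, counts: np.ndarray, hosted: np.ndarray,
                 diff_sp: np.ndarray, t1: float) -> None:
        """Close the integrals at the window boundary t1."""
        elapsed = t1 - self.last_update[hosted]
        self.integral[hosted] += counts[np.ix_(hosted, diff_sp)] * elapsed
        self.last_update[hosted] = t1

    def mean(self, hosted: np.ndarray, window: float) -> np.ndarray:
        """Mean occupancy over a window of the given length (molecules)."""
        return self.integral[hosted] / window


class RankSolver:
    """Windowed reaction–diffusion stepping over a hosted set of tets.

    ``tet_rank`` / ``rank`` / ``buffers`` configure the partitioned case;
    with ``tet_rank=None`` every destination is local and the solver is the
    serial operator-splitting solver.
    """

    def __init__(self, tables: SystemTables, hosted: np.ndarray,
                 rng: np.random.Generator, tet_rank: np.ndarray | None = None,
                 rank: int = 0):
        self.tables = tables
        self.hosted = np.sort(np.asarray(hosted, dtype=np.int64))
        self.rng = rng
        self.tet_rank = tet_rank
        self.rank = rank
        self.buffers: dict[int, object] = {}  # neighbor rank -> RemoteChangeBuffer
        self.counts = np.zeros((tables.n_tets, tables.NS), dtype=np.int64)
        self.occ = OccupancyTracker.zeros(tables.n_tets, tables.ND)
        nh = len(self.hosted)
        self.prop = np.zeros(nh * tables.NR)

    def set_counts(self, counts: np.ndarray) -> None:
        self.counts[self.hosted] = counts[self.hosted]

    def hosted_totals(self) -> np.ndarray:
        return self.counts[self.hosted].sum(axis=0)

    # -- reaction SSA operator ------------------------------------------------

    def reaction_window(self, t0: float, t1: float) -> None:
        """Run the reaction-only SSA on hosted tets over [t0, t1], accruing
        occupancy; occupancy integrals are finalized at t1."""
        tb = self.tables
        self.occ.reset(self.hosted, t0)
        if tb.NR > 0 and t1 > t0:
            self.prop[:] = tb.reaction_propensities(self.counts, self.hosted).ravel()
            tree = _fw_build(self.prop)
            while True:
                steps = reaction_window_kernel(
                    self.rng, self.counts, self.prop, tree, self.hosted, t0, t1,
                    tb.c, tb.r1, tb.r2, tb.delta, tb.sp_rxn_ptr, tb.sp_rxn_ix,
                    tb.sp_diff, self.occ.integral, self.occ.last_update,
                    _KERNEL_CHUNK,
                )
                if steps < _KERNEL_CHUNK:
                    break
        if tb.ND:
            self.occ.finalize(self.counts, self.hosted, tb.diff_sp, t1)

    # -- diffusion operator ---------------------------------------------------

    def diffusion_operator(self, window: float) -> None:
        """Distribute leavers for every hosted (tet, diffusive species).

        The per-neighbor multinomial split is drawn as a chain of conditional
        binomials (exactly equivalent, vectorizable over tets).  Same-rank
        destinations are applied immediately; cross-rank destinations are
        registered to the destination rank's remote change buffer.
        """
        tb = self.tables
        H = self.hosted
        nh = len(H)
        if tb.ND == 0 or window <= 0 or nh == 0:
            return
        mean_occ = self.occ.mean(H, window)  # (nh, ND)
        for j in range(tb.ND):
            s = int(tb.diff_sp[j])
            d_tot = tb.dtot[H, j]
            n_now = self.counts[H, s]
            mu = np.minimum(mean_occ[:, j] * d_tot * window, n_now)
            base = np.floor(mu)
            leave = base.astype(np.int64) + (self.rng.random(nh) < mu - base)
            np.minimum(leave, n_now, out=leave)
            self.counts[H, s] -= leave
            rem = leave
            d_rem = d_tot.copy()
            for f in range(4):
                dkf = tb.dk[H, f, j]
                with np.errstate(divide="ignore", invalid="ignore"):
                    p = np.where(d_rem > 0, dkf / d_rem, 0.0)
                p[p > 1.0 - 1e-12] = 1.0  # absorb roundoff on the last live face
                np.clip(p, 0.0, 1.0, out=p)
                nf = self.rng.binomial(rem, p)
                rem = rem - nf
                d_rem = d_rem - dkf
                nz = np.flatnonzero(nf)
                if nz.size == 0:
                    continue
                dests = tb.nbr[H[nz], f]
                if self.tet_rank is None:
                    np.add.at(self.counts[:, s], dests, nf[nz])
                else:
                    dest_ranks = self.tet_rank[dests]
                    local = dest_ranks == self.rank
                    np.add.at(self.counts[:, s], dests[local], nf[nz][local])
                    for dest, cnt, drank in zip(dests[~local], nf[nz][~local],
                                                dest_ranks[~local]):
                        self.buffers[int(drank)].register(int(dest), s, int(cnt))

    def apply_remote(self, tet: int, s: int, delta: int) -> None:
        """Apply one incoming cross-rank molecule change."""
        self.counts[tet, s] += delta


@dataclass
class OpSplitSim:
    """Serial operator-splitting simulation (single rank hosting the mesh)."""

    tables: SystemTables
    tau: float
    solver: RankSolver
    t: float = 0.0
    iterations: int = 0  # completed τ-grid windows

    @classmethod
    def from_model(cls, mesh: TetMesh, model: ModelSpec,
                   counts: np.ndarray | None = None, seed: int = 0,
                   tables: SystemTables | None = None) -> "OpSplitSim":
        if tables is None:
            tables = build_tables(mesh, compute_geometry(mesh), model)
        tau = compute_tau(tables.rates)
        rng = rank_rng(seed, 0)
        solver = RankSolver(tables, np.arange(tables.n_tets), rng)
        if counts is None:
            from .ssa import place_uniform
            counts = place_uniform(tables, model.init_counts, rng)
        solver.set_counts(np.asarray(counts, dtype=np.int64))
        return cls(tables=tables, tau=tau, solver=solver)

    def totals(self) -> np.ndarray:
        return self.solver.hosted_totals()


def reaction_window(sim: OpSplitSim, t0: float, t1: float) -> OpSplitSim:
    """Module-level handle on the reaction SSA operator (one window)."""
    sim.solver.reaction_window(t0, t1)
    return sim


def diffusion_operator(sim: OpSplitSim, window: float) -> OpSplitSim:
    """Module-level handle on the diffusion operator (one window)."""
    sim.solver.diffusion_operator(window)
    return sim


def run_opsplit(sim: OpSplitSim, t_end: float, recorder=None) -> OpSplitSim:
    """Alternate the two operators until t_end.

    Implemented as the 1-rank instance of the parallel main loop, which the
    protocol degenerates to (no boundaries, no buffers), so serial and
    parallel trajectories at equal seed are bitwise identical.
    """
    from .parallel import _run_windows

    _run_windows([sim.solver], sim, t_end, recorder)
    return sim
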