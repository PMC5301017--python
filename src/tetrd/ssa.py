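"""Serial exact spatial SSA: the reference solver the split scheme is checked
against.

Three interchangeable event-selection routines are provided:

* :func:`direct_step` — the classic Direct method (linear cumulative table),
* :func:`cr_step` — composition–rejection selection over power-of-two
  propensity groups (:class:`CRGroups`),
* the compiled Fenwick-tree fast path used by :func:`run_exact`.

All three sample the same continuous-time Markov jump process; the per-step
Python routines exist as transparent references and for small-system tests,
the kernel for long trajectories.

Kinetic events follow the layout of :mod:`tetrd.engine`: reaction instances
first (tet-major), then one diffusion instance per (tet, diffusive species).
A diffusion instance carries the total hop propensity d_S,tet·n and draws the
destination face on firing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import (
    SystemTables,
    _fw_build,
    build_tables,
    ssa_kernel,
)
from .mesh import TetMesh, compute_geometry
from .model import ModelSpec

__all__ = [
    "SimState",
    "EventDeps",
    "CRGroups",
    "InternalConsistencyError",
    "make_state",
    "place_uniform",
    "build_event_deps",
    "direct_step",
    "cr_step",
    "run_exact",
]

_KERNEL_CHUNK = 20_000_000


class InternalConsistencyError(RuntimeError):
    """The cumulative selection table and the propensity array disagree."""


@dataclass
class SimState:
    """Mutable state of one exact-SSA realization."""

    tables: SystemTables
    counts: np.ndarray  # (n_tets, NS) int64
    rng: np.random.Generator
    t: float = 0.0
    prop: np.ndarray = field(init=False)  # flat, kernel event layout
    last_event: int = field(default=-1, init=False)  # set by the step routines

    def __post_init__(self):
        self.counts = np.ascontiguousarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("initial molecule counts must be nonnegative")
        self.refresh_propensities()

    def refresh_propensities(self) -> None:
        self.prop = self.tables.event_propensities(self.counts)

    def totals(self) -> np.ndarray:
        """Whole-mesh total per species."""
        return self.counts.sum(axis=0)


def make_state(mesh: TetMesh, model: ModelSpec, counts: np.ndarray | None = None,
               seed: int | np.random.Generator = 0, tables: SystemTables | None = None) -> SimState:
    """Convenience constructor; ``counts=None`` places ``model.init_counts``
    uniformly (volume-weighted) across the mesh."""
    if tables is None:
        tables = build_tables(mesh, compute_geometry(mesh), model)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if counts is None:
        counts = place_uniform(tables, tables.model.init_counts, rng)
    return SimState(tables=tables, counts=counts, rng=rng)


def place_uniform(tables: SystemTables, totals: dict[str, int],
                  rng: np.random.Generator) -> np.ndarray:
    """Distribute whole-mesh totals uniformly over the volume: each molecule
    lands in a tet with probability proportional to its volume."""
    p = tables.volumes / tables.volumes.sum()
    counts = np.zeros((tables.n_tets, tables.NS), dtype=np.int64)
    for name, total in totals.items():
        s = tables.model.species_index(name)
        counts[:, s] = rng.multinomial(int(total), p)
    return counts


# ---------------------------------------------------------------------------
# Dependency lists


@dataclass
class EventDeps:
    """Per kinetic event, the event ids whose propensity must be recomputed
    after it fires.

    A reaction touches only its own tet, so its list covers same-tet events
    reading any species it changes.  A diffusion instance moves one molecule
    to a face-neighbor chosen at firing time, so its list conservatively
    covers the source tet and all face neighbors (the destination is one of
    them)."""

    deps: list[np.ndarray]

    def __getitem__(self, e: int) -> np.ndarray:
        return self.deps[e]

    def __len__(self) -> int:
        return len(self.deps)


def _events_reading(tables: SystemTables, tet: int, species: set[int]) -> set[int]:
    """Events in ``tet`` whose propensity reads any of ``species``."""
    out: set[int] = set()
    m, NR, ND = tables.n_tets, tables.NR, tables.ND
    for s in species:
        for q in range(tables.sp_rxn_ptr[s], tables.sp_rxn_ptr[s + 1]):
            out.add(tet * NR + int(tables.sp_rxn_ix[q]))
        j = tables.sp_diff[s]
        if j >= 0:
            out.add(m * NR + tet * ND + int(j))
    return out


def diffusion_event_closure(tables: SystemTables, tet: int, j: int, dest: int) -> set[int]:
    """Exact update closure of one diffusion firing with a known destination:
    events reading the moved species in the source and destination tets.

    :func:`build_event_deps` stores the destination-agnostic superset (the
    union of this over all face neighbors), since the destination is only
    drawn at firing time."""
    s = int(tables.diff_sp[j])
    return _events_reading(tables, tet, {s}) | _events_reading(tables, dest, {s})


def build_event_deps(mesh: TetMesh, model: ModelSpec,
                     tables: SystemTables | None = None) -> EventDeps:
    if tables is None:
        tables = build_tables(mesh, compute_geometry(mesh), model)
    m, NR, ND = tables.n_tets, tables.NR, tables.ND
    deps: list[np.ndarray] = []
    for tet in range(m):
        for rx in range(NR):
            changed = set(np.flatnonzero(tables.delta[rx]).tolist())
            deps.append(np.array(sorted(_events_reading(tables, tet, changed)), dtype=np.int64))
    for tet in range(m):
        for j in range(ND):
            s = int(tables.diff_sp[j])
            touched = _events_reading(tables, tet, {s})
            for f in range(4):
                nb = int(tables.nbr[tet, f])
                if nb >= 0:
                    touched |= _events_reading(tables, nb, {s})
            deps.append(np.array(sorted(touched), dtype=np.int64))
    return EventDeps(deps)


# ---------------------------------------------------------------------------
# Event application shared by the per-step routines


def _apply_event(state: SimState, e: int) -> None:
    """Apply the stoichiometric footprint of event ``e`` (draws the
    destination face for diffusion instances)."""
    tb = state.tables
    m, NR, ND = tb.n_tets, tb.NR, tb.ND
    if e < m * NR:
        tet, rx = divmod(e, NR)
        state.counts[tet] += tb.delta[rx]
        if (state.counts[tet] < 0).any():
            raise InternalConsistencyError(f"negative count after reaction event {e}")
    else:
        tet, j = divmod(e - m * NR, ND)
        s = int(tb.diff_sp[j])
        u = state.rng.random() * tb.dtot[tet, j]
        dest = -1
        acc = 0.0
        for f in range(4):
            if tb.dk[tet, f, j] > 0.0:
                acc += tb.dk[tet, f, j]
                dest = int(tb.nbr[tet, f])
                if u <= acc:
                    break
        state.counts[tet, s] -= 1
        state.counts[dest, s] += 1
        if state.counts[tet, s] < 0:
            raise InternalConsistencyError(f"negative count after diffusion event {e}")


def _recompute(state: SimState, events: np.ndarray) -> None:
    tb = state.tables
    m, NR, ND = tb.n_tets, tb.NR, tb.ND
    for e in events:
        e = int(e)
        if e < m * NR:
            tet, rx = divmod(e, NR)
            s1, s2 = tb.r1[rx], tb.r2[rx]
            cc = tb.c[tet, rx]
            if s2 < 0:
                a = cc * state.counts[tet, s1]
            elif s1 == s2:
                n = state.counts[tet, s1]
                a = cc * n * (n - 1) * 0.5
            else:
                a = cc * state.counts[tet, s1] * state.counts[tet, s2]
        else:
            tet, j = divmod(e - m * NR, ND)
            a = tb.dtot[tet, j] * state.counts[tet, tb.diff_sp[j]]
        state.prop[e] = a


def _select_cumulative(prop: np.ndarray, r: float, a0: float) -> int:
    cum = np.cumsum(prop)
    e = int(np.searchsorted(cum, r, side="right"))
    if e >= len(prop):
        if r - cum[-1] > 16 * np.finfo(float).eps * max(a0, 1.0):
            raise InternalConsistencyError(
                f"selection point {r} beyond cumulative total {cum[-1]}"
            )
        e = int(np.flatnonzero(prop > 0)[-1])
    return e


def direct_step(state: SimState, deps: EventDeps, t_end: float = math.inf) -> SimState:
    """One Direct-method step: Exp(a0) waiting time, linear selection,
    stoichiometry, deps-driven propensity refresh.

    With zero total propensity the system is depleted and time jumps to
    ``t_end`` with no event.
    """
    a0 = float(state.prop.sum())
    if a0 <= 0.0:
        state.t = t_end
        state.last_event = -1
        return state
    dt = state.rng.exponential(1.0 / a0)
    if state.t + dt > t_end:
        state.t = t_end
        state.last_event = -1
        return state
    state.t += dt
    e = _select_cumulative(state.prop, state.rng.random() * a0, a0)
    state.last_event = e
    _apply_event(state, e)
    _recompute(state, deps[e])
    return state


# ---------------------------------------------------------------------------
# Composition–rejection selection


class CRGroups:
    """Power-of-two propensity groups for O(1) event selection.

    Group ``g`` holds events with propensity in [2^(g-1), 2^g); events below
    ``floor`` (default 1e-12 s⁻¹) leave the structure entirely.  Selection
    picks a group proportionally to its propensity sum, then
    rejection-samples uniformly within the group against the group's upper
    bound.
    """

    def __init__(self, prop: np.ndarray, floor: float = 1e-12):
        self.floor = float(floor)
        self.val = np.asarray(prop, dtype=float).copy()
        self.members: dict[int, list[int]] = {}
        self.pos: dict[int, tuple[int, int]] = {}  # event -> (group, slot)
        self.sums: dict[int, float] = {}
        for e, a in enumerate(self.val):
            if a >= self.floor:
                self._insert(e, a)

    @staticmethod
    def _group_of(a: float) -> int:
        return math.frexp(a)[1]  # 2^(g-1) <= a < 2^g

    def _insert(self, e: int, a: float) -> None:
        g = self._group_of(a)
        lst = self.members.setdefault(g, [])
        self.pos[e] = (g, len(lst))
        lst.append(e)
        self.sums[g] = self.sums.get(g, 0.0) + a

    def _remove(self, e: int) -> None:
        g, slot = self.pos.pop(e)
        lst = self.members[g]
        last = lst.pop()
        if last != e:
            lst[slot] = last
            self.pos[last] = (g, slot)
        self.sums[g] -= self.val[e]
        if not lst:
            del self.members[g], self.sums[g]

    def update(self, e: int, a: float) -> None:
        """Set event ``e``'s propensity, migrating groups if it crossed a
        power-of-two boundary.  Membership changes at most once per call."""
        old = self.val[e]
        in_struct = e in self.pos
        if in_struct and a >= self.floor and self._group_of(a) == self.pos[e][0]:
            g = self.pos[e][0]
            self.sums[g] += a - old
            self.val[e] = a
            return
        if in_struct:
            self._remove(e)
        self.val[e] = a
        if a >= self.floor:
            self._insert(e, a)

    def total(self) -> float:
        return sum(self.sums.values())

    def sample(self, rng: np.random.Generator) -> int:
        r = rng.random() * self.total()
        acc = 0.0
        groups = sorted(self.members)
        g = groups[-1]
        for gg in groups:
            acc += self.sums[gg]
            if r <= acc:
                g = gg
                break
        lst = self.members[g]
        bound = math.ldexp(1.0, g)  # 2^g, upper bound of the group
        while True:
            e = lst[int(rng.random() * len(lst))]
            if rng.random() * bound <= self.val[e]:
                return e

    def check(self) -> None:
        """Verify every member sits inside its group's bounds."""
        for g, lst in self.members.items():
            lo, hi = math.ldexp(1.0, g - 1), math.ldexp(1.0, g)
            for e in lst:
                if not (lo <= self.val[e] < hi):
                    raise InternalConsistencyError(
                        f"event {e} propensity {self.val[e]} outside group [{lo}, {hi})"
                    )


def cr_step(state: SimState, groups: CRGroups, deps: EventDeps,
            t_end: float = math.inf) -> SimState:
    """One composition–rejection step; distributionally identical to
    :func:`direct_step`."""
    a0 = groups.total()
    if a0 <= 0.0:
        state.t = t_end
        state.last_event = -1
        return state
    dt = state.rng.exponential(1.0 / a0)
    if state.t + dt > t_end:
        state.t = t_end
        state.last_event = -1
        return state
    state.t += dt
    e = groups.sample(state.rng)
    state.last_event = e
    _apply_event(state, e)
    _recompute(state, deps[e])
    for upd in deps[e]:
        groups.update(int(upd), state.prop[int(upd)])
    return state


# ---------------------------------------------------------------------------
# Trajectory runner


def run_exact(state: SimState, t_end: float, recorder=None, method: str = "tree",
              deps: EventDeps | None = None) -> SimState:
    """Advance the exact SSA to ``t_end``, sampling the recorder grid.

    ``method='tree'`` uses the compiled Fenwick-tree Direct kernel (the
    default for long runs); ``'direct'`` and ``'cr'`` run the per-step Python
    routines.
    """
    tb = state.tables
    tiny = 1e-12 * max(t_end, 1.0)
    targets = [t_end] if t_end > state.t else []
    if recorder is not None:
        if state.t == 0.0:
            recorder.record(0.0, state.counts)
        grid = recorder.grid(t_end)
        targets = [tt for tt in grid if tt > state.t + tiny]
        if targets and targets[-1] < t_end - tiny:
            targets.append(t_end)
    if method == "tree":
        tree = _fw_build(state.prop)
        for tt in targets:
            while state.t < tt:
                state.t, _ = ssa_kernel(
                    state.rng, state.counts, state.prop, tree, state.t, tt,
                    tb.c, tb.r1, tb.r2, tb.delta, tb.sp_rxn_ptr, tb.sp_rxn_ix,
                    tb.nbr, tb.dk, tb.dtot, tb.diff_sp, tb.sp_diff, _KERNEL_CHUNK,
                )
            if recorder is not None:
                recorder.record(tt, state.counts)
        return state
    if method in ("direct", "cr"):
        if deps is None:
            deps = build_event_deps(tb.mesh, tb.model, tables=tb)
        groups = CRGroups(state.prop) if method == "cr" else None
        for tt in targets:
            while state.t < tt:
                if method == "direct":
                    direct_step(state, deps, t_end=tt)
                else:
                    cr_step(state, groups, deps, t_end=tt)
            if recorder is not None:
                recorder.record(tt, state.counts)
        return state
    raise ValueError(f"unknown method {method!r}")
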