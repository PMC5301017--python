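"""Flattened simulation tables and compiled event-loop kernels.

The kernels implement the Direct-method distribution (exponential waiting
time from the total propensity, event picked proportionally) with event
selection through a Fenwick (binary-indexed) tree over the propensity array,
so that both selection and propensity maintenance are O(log N) per event.
NumPy ``Generator`` objects are passed straight into the kernels, so the
stream is shared with (and reproducible from) the Python side.

Event layout for the full spatial SSA over ``m`` tets, ``NR`` reaction
channels and ``ND`` diffusive species:

* reaction instance  (tet, rx)  -> event id  tet*NR + rx
* diffusion instance (tet, j)   -> event id  m*NR + tet*ND + j

A diffusion instance aggregates the per-face hops of species ``j`` out of
``tet`` (propensity d_S,tet · n); the destination face is picked on firing
with probability d_k/d_S,tet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .mesh import GeomTables, TetMesh
from .model import DiffusionRateTable, ModelSpec, build_diffusion_rates

__all__ = ["SystemTables", "build_tables"]

_TINY = 1e-300


@dataclass
class SystemTables:
    """Arrays describing one (mesh, model) system, shared by all solvers."""

    mesh: TetMesh
    geom: GeomTables
    model: ModelSpec
    rates: DiffusionRateTable
    volumes: np.ndarray  # (m,)
    c: np.ndarray  # (m, NR) per-tet scaled rate constants
    r1: np.ndarray  # (NR,) first reactant species, -1 never
    r2: np.ndarray  # (NR,) second reactant species or -1
    delta: np.ndarray  # (NR, NS) net stoichiometric change
    sp_rxn_ptr: np.ndarray  # CSR over species: reactions with species as reactant
    sp_rxn_ix: np.ndarray
    nbr: np.ndarray  # (m, 4) neighbor tet or -1
    dk: np.ndarray  # (m, 4, ND)
    dtot: np.ndarray  # (m, ND)
    diff_sp: np.ndarray  # (ND,) species index per diffusive column
    sp_diff: np.ndarray  # (NS,) diffusive column per species or -1

    @property
    def n_tets(self) -> int:
        return self.mesh.n_tets

    @property
    def NS(self) -> int:
        return len(self.model.species)

    @property
    def NR(self) -> int:
        return len(self.model.reactions)

    @property
    def ND(self) -> int:
        return len(self.diff_sp)

    @property
    def n_events(self) -> int:
        return self.n_tets * (self.NR + self.ND)

    # -- propensity initialization (vectorized; the kernels maintain these
    #    incrementally afterwards)

    def reaction_propensities(self, counts: np.ndarray, tets: np.ndarray | None = None) -> np.ndarray:
        """(len(tets), NR) mass-action propensities from a count matrix."""
        if tets is None:
            tets = np.arange(self.n_tets)
        out = np.empty((len(tets), self.NR))
        for rx in range(self.NR):
            s1, s2 = self.r1[rx], self.r2[rx]
            cc = self.c[tets, rx]
            if s2 < 0:
                out[:, rx] = cc * counts[tets, s1]
            elif s1 == s2:
                n = counts[tets, s1]
                out[:, rx] = cc * n * (n - 1) * 0.5
            else:
                out[:, rx] = cc * counts[tets, s1] * counts[tets, s2]
        return out

    def diffusion_propensities(self, counts: np.ndarray) -> np.ndarray:
        """(m, ND) total hop propensities d_S,tet · n."""
        if self.ND == 0:
            return np.zeros((self.n_tets, 0))
        return self.dtot * counts[:, self.diff_sp]

    def event_propensities(self, counts: np.ndarray) -> np.ndarray:
        """Flat propensity array in kernel event layout."""
        return np.concatenate(
            [self.reaction_propensities(counts).ravel(), self.diffusion_propensities(counts).ravel()]
        )


def build_tables(mesh: TetMesh, geom: GeomTables, model: ModelSpec) -> SystemTables:
    NS, NR = len(model.species), len(model.reactions)
    rates = build_diffusion_rates(mesh, geom, model)
    c = np.empty((mesh.n_tets, NR))
    r1 = np.full(NR, -1, dtype=np.int64)
    r2 = np.full(NR, -1, dtype=np.int64)
    delta = np.zeros((NR, NS), dtype=np.int64)
    from .model import MOLECULES_PER_UM3_UM

    for rx, rxn in enumerate(model.reactions):
        c[:, rx] = rxn.k if rxn.order == 1 else rxn.k / (MOLECULES_PER_UM3_UM * geom.volumes)
        reactants = []
        for name, nu in rxn.lhs.items():
            reactants += [model.species_index(name)] * nu
        r1[rx] = reactants[0]
        if len(reactants) == 2:
            r2[rx] = reactants[1]
        for name, nu in rxn.lhs.items():
            delta[rx, model.species_index(name)] -= nu
        for name, nu in rxn.rhs.items():
            delta[rx, model.species_index(name)] += nu

    # species -> reactions with that species as a reactant (propensity deps)
    lists: list[list[int]] = [[] for _ in range(NS)]
    for rx in range(NR):
        lists[r1[rx]].append(rx)
        if r2[rx] >= 0 and r2[rx] != r1[rx]:
            lists[r2[rx]].append(rx)
    sp_rxn_ptr = np.zeros(NS + 1, dtype=np.int64)
    sp_rxn_ptr[1:] = np.cumsum([len(l) for l in lists])
    sp_rxn_ix = np.array([rx for l in lists for rx in l] or [], dtype=np.int64)

    sp_diff = np.full(NS, -1, dtype=np.int64)
    for j, s in enumerate(rates.diff_indices):
        sp_diff[s] = j
    return SystemTables(
        mesh=mesh, geom=geom, model=model, rates=rates,
        volumes=geom.volumes, c=c, r1=r1, r2=r2, delta=delta,
        sp_rxn_ptr=sp_rxn_ptr, sp_rxn_ix=sp_rxn_ix,
        nbr=mesh.neighbors, dk=rates.d_k, dtot=rates.d_total,
        diff_sp=rates.diff_indices, sp_diff=sp_diff,
    )


# ---------------------------------------------------------------------------
# Fenwick tree over the flat propensity array (1-based internal indexing)


@njit(cache=True, inline="always")
def _fw_update(tree, i, delta):
    n = tree.shape[0] - 1
    i += 1
    while i <= n:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True)
def _fw_build(prop):
    n = prop.shape[0]
    tree = np.zeros(n + 1)
    for i in range(n):
        if prop[i] != 0.0:
            _fw_update(tree, i, prop[i])
    return tree


@njit(cache=True, inline="always")
def _fw_total(tree):
    n = tree.shape[0] - 1
    total = 0.0
    i = n
    while i > 0:
        total += tree[i]
        i -= i & (-i)
    return total


@njit(cache=True, inline="always")
def _fw_find(tree, r):
    """Smallest event id whose cumulative propensity exceeds r."""
    n = tree.shape[0] - 1
    idx = 0
    bit = 1
    while bit << 1 <= n:
        bit <<= 1
    while bit:
        nxt = idx + bit
        if nxt <= n and tree[nxt] < r:
            idx = nxt
            r -= tree[nxt]
        bit >>= 1
    return idx  # zero-based


@njit(cache=True, inline="always")
def _rxn_prop(counts, tet, rx, c, r1, r2):
    a = c[tet, rx]
    s1, s2 = r1[rx], r2[rx]
    if s2 < 0:
        return a * counts[tet, s1]
    if s1 == s2:
        n = counts[tet, s1]
        return a * n * (n - 1) * 0.5
    return a * counts[tet, s1] * counts[tet, s2]


@njit(cache=True, inline="always")
def _update_after_change(counts, tet, s, prop, tree, c, r1, r2,
                         sp_rxn_ptr, sp_rxn_ix, dtot, sp_diff, NR, ND, m):
    """Refresh propensities that read (tet, s): dependent reactions in the
    tet plus the tet's own diffusion instance of s."""
    for q in range(sp_rxn_ptr[s], sp_rxn_ptr[s + 1]):
        rx = sp_rxn_ix[q]
        e = tet * NR + rx
        new = _rxn_prop(counts, tet, rx, c, r1, r2)
        if new != prop[e]:
            _fw_update(tree, e, new - prop[e])
            prop[e] = new
    j = sp_diff[s]
    if j >= 0:
        e = m * NR + tet * ND + j
        new = dtot[tet, j] * counts[tet, s]
        if new != prop[e]:
            _fw_update(tree, e, new - prop[e])
            prop[e] = new


@njit(cache=True)
def ssa_kernel(rng, counts, prop, tree, t, t_end,
               c, r1, r2, delta, sp_rxn_ptr, sp_rxn_ix,
               nbr, dk, dtot, diff_sp, sp_diff, max_steps):
    """Advance the full spatial SSA to t_end (or max_steps events).

    Returns (t, steps).  If the total propensity vanishes, time jumps to
    t_end with no event (depleted-system semantics).
    """
    m, NS = counts.shape
    NR = c.shape[1]
    ND = dtot.shape[1]
    steps = 0
    while steps < max_steps:
        a0 = _fw_total(tree)
        if a0 <= _TINY:
            t = t_end
            break
        dt = rng.exponential(1.0 / a0)
        if t + dt > t_end:
            t = t_end
            break
        t += dt
        e = _fw_find(tree, rng.random() * a0)
        if e >= m * (NR + ND):
            e = m * (NR + ND) - 1
        # guard against float drift in the tree selecting a dead event
        if e >= m * NR:
            d0 = e - m * NR
            true_a = dtot[d0 // ND, d0 % ND] * counts[d0 // ND, diff_sp[d0 % ND]]
        else:
            true_a = _rxn_prop(counts, e // NR, e % NR, c, r1, r2)
        if true_a <= 0.0:
            if prop[e] != true_a:
                _fw_update(tree, e, true_a - prop[e])
                prop[e] = true_a
            continue
        if e >= m * NR:  # diffusion instance
            d = e - m * NR
            tet = d // ND
            j = d % ND
            s = diff_sp[j]
            u = rng.random() * dtot[tet, j]
            acc = 0.0
            dest = -1
            for f in range(4):
                if dk[tet, f, j] > 0.0:
                    acc += dk[tet, f, j]
                    dest = nbr[tet, f]
                    if u <= acc:
                        break
            counts[tet, s] -= 1
            _update_after_change(counts, tet, s, prop, tree, c, r1, r2,
                                 sp_rxn_ptr, sp_rxn_ix, dtot, sp_diff, NR, ND, m)
            counts[dest, s] += 1
            _update_after_change(counts, dest, s, prop, tree, c, r1, r2,
                                 sp_rxn_ptr, sp_rxn_ix, dtot, sp_diff, NR, ND, m)
        else:  # reaction instance
            tet = e // NR
            rx = e % NR
            for s in range(NS):
                dl = delta[rx, s]
                if dl != 0:
                    counts[tet, s] += dl
                    _update_after_change(counts, tet, s, prop, tree, c, r1, r2,
                                         sp_rxn_ptr, sp_rxn_ix, dtot, sp_diff, NR, ND, m)
        steps += 1
    return t, steps


@njit(cache=True)
def reaction_window_kernel(rng, counts, prop, tree, hosted, t0, t1,
                           c, r1, r2, delta, sp_rxn_ptr, sp_rxn_ix, sp_diff,
                           occ_int, occ_last, max_steps):
    """Reaction-only SSA over the hosted tets for one time window [t0, t1].

    ``prop``/``tree`` cover hosted reaction events only (event id
    h*NR + rx for hosted slot h).  On every count change of a diffusive
    species the occupancy integral (molecule·s) of that (tet, species) is
    accrued up to the event time, so that occ_int/window is the within-window
    mean count once the caller finalizes the integral at t1.
    """
    NS = counts.shape[1]
    NR = c.shape[1]
    t = t0
    steps = 0
    while steps < max_steps:
        a0 = _fw_total(tree)
        if a0 <= _TINY:
            break
        dt = rng.exponential(1.0 / a0)
        if t + dt > t1:
            break
        t += dt
        e = _fw_find(tree, rng.random() * a0)
        if e >= prop.shape[0]:
            e = prop.shape[0] - 1
        h = e // NR
        rx = e % NR
        tet = hosted[h]
        true_a = _rxn_prop(counts, tet, rx, c, r1, r2)
        if true_a <= 0.0:  # float drift guard
            if prop[e] != true_a:
                _fw_update(tree, e, true_a - prop[e])
                prop[e] = true_a
            continue
        for s in range(NS):
            dl = delta[rx, s]
            if dl != 0:
                j = sp_diff[s]
                if j >= 0:
                    occ_int[tet, j] += counts[tet, s] * (t - occ_last[tet, j])
                    occ_last[tet, j] = t
                counts[tet, s] += dl
                for q in range(sp_rxn_ptr[s], sp_rxn_ptr[s + 1]):
                    rx2 = sp_rxn_ix[q]
                    e2 = h * NR + rx2
                    new = _rxn_prop(counts, tet, rx2, c, r1, r2)
                    if new != prop[e2]:
                        _fw_update(tree, e2, new - prop[e2])
                        prop[e2] = new
        steps += 1
    return steps
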