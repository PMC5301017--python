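"""Benchmark fixtures and the cross-solver statistical comparison harness.

The split scheme is approximate by design (the constant-window splitting
introduces small, controlled errors), so solver agreement is judged
statistically — per-(species, time) two-sample Kolmogorov–Smirnov tests over
independent seeds with Benjamini–Hochberg correction across the grid — while
conservation laws are checked exactly elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .control import MeshSpec, RunConfig, run_sim

__all__ = ["ComparisonResult", "make_benchmark", "compare_solvers"]


def make_benchmark(density_scale: float = 1.0,
                   mesh_counts: tuple[int, int, int] = (5, 5, 50),
                   dims: tuple[float, float, float] = (10.0, 10.0, 100.0),
                   t_end: float = 1.0,
                   record_interval: float = 0.25,
                   solver: str = "opsplit",
                   seed: int = 0) -> RunConfig:
    """Benchmark run config: the 10-species model, uniformly placed, on a
    generated cuboid mesh of the 10×10×100 μm³ box.

    ``density_scale`` multiplies every initial count (0.1 and 10 are the
    low/high molecule-density settings; 1 totals 55,000 molecules).
    """
    if density_scale <= 0:
        raise ValueError("density_scale must be positive")
    cfg = RunConfig(
        model_file="builtin:benchmark",
        mesh=MeshSpec(dims=dims, counts=mesh_counts),
        solver=solver,
        seed=seed,
        t_end=t_end,
        record_interval=record_interval,
        density_scale=density_scale,
    )
    cfg.load_model()  # raises if the scale zeroes every count
    return cfg


@dataclass
class ComparisonResult:
    """Per-(species, time) agreement between two solvers over seeds.

    ``frame`` columns: species, time, mean/CI of both solvers, two-sided KS
    statistic and p-value; ``reject`` marks Benjamini–Hochberg discoveries at
    level ``alpha``.
    """

    solver_a: str
    solver_b: str
    n_seeds: int
    alpha: float
    frame: pd.DataFrame

    @property
    def all_pass(self) -> bool:
        """No BH-corrected rejection anywhere on the (species × time) grid."""
        return not self.frame["reject"].any()

    def ci_overlap(self) -> pd.Series:
        f = self.frame
        return (f["lo_a"] <= f["hi_b"]) & (f["lo_b"] <= f["hi_a"])

    def summary(self) -> dict:
        return {
            "solvers": [self.solver_a, self.solver_b],
            "n_seeds": self.n_seeds,
            "alpha": self.alpha,
            "cells": int(len(self.frame)),
            "min_p": float(self.frame["p_value"].min()),
            "rejections": int(self.frame["reject"].sum()),
            "all_ci_overlap": bool(self.ci_overlap().all()),
        }

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json

        Path(path).write_text(json.dumps(self.summary(), indent=1))


def _collect(config: RunConfig, solver: str, seeds: np.ndarray, statistic: str):
    """Run one solver over seeds; return dict (species, time) -> sample
    vector of the chosen statistic."""
    cfg = config.model_copy(update={"solver": solver})
    if statistic == "half-z":
        cfg = cfg.model_copy(update={"record_mode": "per-tet"})
    samples: dict[tuple[str, float], list[float]] = {}
    mesh = None
    half_mask = None
    for sd in seeds:
        rec, _ = run_sim(cfg, seed=int(sd))
        if statistic == "half-z" and half_mask is None:
            mesh = cfg.mesh.build()
            bary_z = mesh.vertices[mesh.tets].mean(axis=1)[:, 2]
            half_mask = bary_z < np.median(bary_z)
        for t, snap in zip(rec.times, rec.samples):
            if statistic == "total":
                vals = snap if snap.ndim == 1 else snap.sum(axis=0)
            else:
                vals = snap[half_mask].sum(axis=0)
            for s, name in enumerate(rec.species_names):
                samples.setdefault((name, t), []).append(float(vals[s]))
    return samples


def compare_solvers(config: RunConfig, solver_a: str, solver_b: str,
                    n_seeds: int, alpha: float = 0.01,
                    statistic: str = "total") -> ComparisonResult:
    """Run both solvers with ``n_seeds`` independent seeds and compare the
    per-(species, time) distributions of the chosen statistic.

    ``statistic='total'`` compares whole-mesh species totals;
    ``'half-z'`` compares counts in the lower half of the mesh (a spatial
    redistribution check).
    """
    seeds = config.seed + np.arange(n_seeds)
    sa = _collect(config, solver_a, seeds, statistic)
    sb = _collect(config, solver_b, seeds, statistic)
    if set(sa) != set(sb):
        raise ValueError("recording grids of the two solvers do not match")
    rows = []
    for (name, t) in sorted(sa):
        xa = np.array(sa[(name, t)])
        xb = np.array(sb[(name, t)])
        ks = stats.ks_2samp(xa, xb, method="auto")
        sem_a = stats.sem(xa) if len(xa) > 1 else 0.0
        sem_b = stats.sem(xb) if len(xb) > 1 else 0.0
        rows.append({
            "species": name, "time": t,
            "mean_a": xa.mean(), "lo_a": xa.mean() - 1.96 * sem_a, "hi_a": xa.mean() + 1.96 * sem_a,
            "mean_b": xb.mean(), "lo_b": xb.mean() - 1.96 * sem_b, "hi_b": xb.mean() + 1.96 * sem_b,
            "ks_stat": ks.statistic, "p_value": ks.pvalue,
        })
    frame = pd.DataFrame(rows)
    # BH across the (species × time) grid; t=0 cells are identical by
    # construction (p=1) and participate harmlessly
    frame["reject"] = _benjamini_hochberg(frame["p_value"].to_numpy(), alpha)
    return ComparisonResult(solver_a=solver_a, solver_b=solver_b,
                            n_seeds=n_seeds, alpha=alpha, frame=frame)


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean rejection mask at FDR level alpha."""
    m = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.flatnonzero(below).max()
        reject[order[: k + 1]] = True
    return reject
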