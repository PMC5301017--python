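"""Run configuration, solver façade, and timing/scaling reports.

A :class:`RunConfig` (YAML or JSON, schema-validated) fully determines a run:
model, mesh source, partition source, solver, seed, horizon, recording.  All
randomness flows from the seed; the virtual-rank backend is deterministic
given (config, seed), so the counts CSV is byte-identical across repeats.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .mesh import TetMesh, compute_geometry, generate_cuboid_mesh, load_mesh
from .model import ModelSpec, benchmark_model
from .engine import build_tables
from .recorder import Recorder

log = logging.getLogger("tetrd")

__all__ = [
    "MeshSpec",
    "PartitionSpec",
    "RunConfig",
    "ScalingMetrics",
    "load_config",
    "run_sim",
    "run_from_config",
    "scaling_report",
    "weak_scaling_efficiency",
]


class MeshSpec(BaseModel):
    """Mesh source: a file (native-text or msh2) or a cuboid generator spec."""

    file: Optional[str] = None
    format: str = "native-text"
    dims: Optional[tuple[float, float, float]] = None
    counts: Optional[tuple[int, int, int]] = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.file is None) == (self.dims is None or self.counts is None):
            raise ValueError("mesh: give either 'file' or both 'dims' and 'counts'")
        return self

    def build(self) -> TetMesh:
        if self.file is not None:
            return load_mesh(self.file, format=self.format)
        return generate_cuboid_mesh(self.dims, self.counts)


class PartitionSpec(BaseModel):
    """Partition source: a Metis-style .epart file or a linear grid spec."""

    file: Optional[str] = None
    parts: tuple[int, int, int] = (1, 1, 1)

    def build(self, mesh: TetMesh):
        from .parallel import partition_linear, read_partition_file

        if self.file is not None:
            return read_partition_file(self.file, mesh)
        return partition_linear(mesh, self.parts)


class RunConfig(BaseModel):
    """One simulation run.  ``model_file`` is a model JSON path, or the
    built-in name ``builtin:benchmark`` for the packaged 10-species model."""

    model_config = ConfigDict(protected_namespaces=())

    model_file: str
    mesh: MeshSpec
    partition: PartitionSpec = Field(default_factory=PartitionSpec)
    solver: Literal["ssa", "opsplit", "parallel"] = "opsplit"
    seed: int
    t_end: float = Field(ge=0.0)
    record_interval: float = Field(gt=0.0)
    record_mode: Literal["total", "per-tet"] = "total"
    density_scale: float = Field(default=1.0, gt=0.0)
    output: str = "counts.csv"

    @model_validator(mode="after")
    def _interval_fits(self):
        if self.t_end > 0 and self.record_interval > self.t_end:
            raise ValueError("record_interval must not exceed t_end")
        return self

    def load_model(self) -> ModelSpec:
        if self.model_file == "builtin:benchmark":
            model = benchmark_model()
        else:
            model = ModelSpec.from_json(self.model_file)
        if self.density_scale != 1.0:
            scaled = {k: int(round(v * self.density_scale))
                      for k, v in model.init_counts.items()}
            if model.init_counts and not any(scaled.values()):
                raise ValueError(
                    f"density_scale={self.density_scale} zeroes every initial count"
                )
            model = ModelSpec(model.species, model.reactions, scaled)
        return model

    # -- serialization (round-trip identity) --------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True))

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        return cls.model_validate(doc)


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.from_dict(doc)


# ---------------------------------------------------------------------------


def run_sim(config: RunConfig, seed: int | None = None):
    """Execute a configured run in memory.

    Returns (recorder, info) where info carries τ (split solvers), rank
    count, iteration count and per-rank timing.
    """
    from . import opsplit, parallel, ssa

    seed = config.seed if seed is None else seed
    model = config.load_model()
    mesh = config.mesh.build()
    tables = build_tables(mesh, compute_geometry(mesh), model)
    recorder = Recorder(config.record_interval, model.species_names, mode=config.record_mode)
    info: dict = {"solver": config.solver, "seed": seed, "n_tets": mesh.n_tets}

    if config.solver == "ssa":
        state = ssa.make_state(mesh, model, seed=seed, tables=tables)
        tic = time.perf_counter()
        ssa.run_exact(state, config.t_end, recorder=recorder)
        info.update(n_ranks=1, wall_time=time.perf_counter() - tic)
        return recorder, info

    if config.solver == "opsplit":
        sim = opsplit.OpSplitSim.from_model(mesh, model, seed=seed, tables=tables)
        tic = time.perf_counter()
        opsplit.run_opsplit(sim, config.t_end, recorder=recorder)
        info.update(tau=sim.tau, n_ranks=1, iterations=sim.iterations,
                    wall_time=time.perf_counter() - tic)
        log.info("opsplit run: tau=%.3e s, %d iterations", sim.tau, sim.iterations)
        return recorder, info

    part = config.partition.build(mesh)
    sim = parallel.ParallelSim.from_model(mesh, model, part, seed=seed, tables=tables)
    tic = time.perf_counter()
    parallel.run_parallel_loop(sim, config.t_end, recorder=recorder)
    info.update(
        tau=sim.tau, n_ranks=part.n_ranks, iterations=sim.iterations,
        wall_time=time.perf_counter() - tic,
        timing=[{"rank": tr.rank, "t_comp": tr.t_comp, "t_sync": tr.t_sync,
                 "t_idle": tr.t_idle, "t_total": tr.t_total} for tr in sim.timing],
    )
    log.info("parallel run: tau=%.3e s, %d ranks, %d iterations",
             sim.tau, part.n_ranks, sim.iterations)
    return recorder, info


def run_from_config(config: RunConfig, seed: int | None = None) -> tuple[Path, Path]:
    """Run and write artifacts: counts CSV (atomic) and a timing/meta JSON
    next to it.  Returns both paths."""
    recorder, info = run_sim(config, seed=seed)
    out = Path(config.output)
    out.parent.mkdir(parents=True, exist_ok=True)
    recorder.write_csv(out)
    meta = out.with_suffix(".timing.json")
    tmp = meta.with_suffix(".tmp")
    tmp.write_text(json.dumps(info, indent=1))
    tmp.replace(meta)
    return out, meta


# ---------------------------------------------------------------------------
# Scaling metrics (reporting only; wall-clock is hardware-dependent)


@dataclass
class ScalingMetrics:
    """Strong-scaling speedup S_p/q = T_q/T_p and efficiency
    E_p/q = S_p/q · q/p, relative to a baseline rank count q."""

    baseline: int
    speedup: dict[int, float]
    efficiency: dict[int, float]
    note: str = "hardware-dependent — not an acceptance surface"

    def to_json(self, path) -> None:
        doc = {"baseline": self.baseline, "note": self.note,
               "speedup": {str(k): v for k, v in self.speedup.items()},
               "efficiency": {str(k): v for k, v in self.efficiency.items()}}
        Path(path).write_text(json.dumps(doc, indent=1))


def scaling_report(times: dict[int, float], q: int) -> ScalingMetrics:
    """``times`` maps rank count p -> wall-clock T_p (seconds)."""
    if q not in times:
        raise ValueError(f"baseline rank count {q} not among measured runs {sorted(times)}")
    if len(times) < 2:
        raise ValueError("need at least two rank counts to report scaling")
    tq = times[q]
    speedup = {p: tq / tp for p, tp in times.items()}
    efficiency = {p: speedup[p] * q / p for p in times}
    return ScalingMetrics(baseline=q, speedup=speedup, efficiency=efficiency)


def weak_scaling_efficiency(t_base: float, t_scaled: float) -> float:
    """E_k = T_N,p / T_kN,kp for a problem and rank count both grown k-fold."""
    return t_base / t_scaled
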