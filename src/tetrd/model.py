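"""Biochemical model description and stochastic rate computation.

Units follow the micron/second convention common in subvolume simulators:
diffusion coefficients in μm²/s, volumes in μm³, first-order rate constants
in s⁻¹ and second-order constants in (μM·s)⁻¹.  The unit bridge between
concentration-based constants and per-event stochastic rates is
1 μM·μm³ = 602.214076 molecules (exact, from the CODATA Avogadro constant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mesh import GeomTables, TetMesh

__all__ = [
    "MOLECULES_PER_UM3_UM",
    "Species",
    "Reaction",
    "ModelSpec",
    "DiffusionRateTable",
    "scaled_rate_constant",
    "reaction_propensity",
    "build_diffusion_rates",
    "benchmark_model",
]

#: molecules per (μM · μm³); 1e-21 mol · N_A
MOLECULES_PER_UM3_UM = 602.214076


@dataclass(frozen=True)
class Species:
    name: str
    D: float  # diffusion coefficient, μm²/s; 0 = immobile

    def __post_init__(self):
        if self.D < 0:
            raise ValueError(f"species {self.name}: D must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction of order 1 or 2.

    ``lhs``/``rhs`` map species name -> positive integer stoichiometry.
    ``k`` is in s⁻¹ (order 1) or (μM·s)⁻¹ (order 2).  Reversible reactions
    are stored as two records.
    """

    lhs: dict[str, int]
    rhs: dict[str, int]
    k: float

    def __post_init__(self):
        for side in (self.lhs, self.rhs):
            for name, nu in side.items():
                if not isinstance(nu, int) or nu <= 0:
                    raise ValueError(f"stoichiometry of {name} must be a positive integer")
        if self.order not in (1, 2):
            raise ValueError(f"reaction order {self.order} unsupported (only 1 and 2)")

    @property
    def order(self) -> int:
        return sum(self.lhs.values())

    @property
    def name(self) -> str:
        def side(d):
            return " + ".join(f"{nu if nu > 1 else ''}{s}" for s, nu in sorted(d.items()))
        return f"{side(self.lhs)} -> {side(self.rhs)}"


@dataclass
class ModelSpec:
    species: list[Species]
    reactions: list[Reaction]
    #: optional whole-mesh initial totals, species name -> count
    init_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        declared = set(names)
        for r in self.reactions:
            missing = (set(r.lhs) | set(r.rhs)) - declared
            if missing:
                raise ValueError(f"reaction {r.name!r} references undeclared species {sorted(missing)}")

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    @property
    def diffusive_species(self) -> list[Species]:
        return [s for s in self.species if s.D > 0]

    # -- JSON model file: {species:[{name,D}], reactions:[{lhs,rhs,k}], init:{...}}
    def to_json(self, path) -> None:
        doc = {
            "species": [{"name": s.name, "D": s.D} for s in self.species],
            "reactions": [{"lhs": r.lhs, "rhs": r.rhs, "k": r.k} for r in self.reactions],
            "init": self.init_counts,
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        doc = json.loads(Path(path).read_text())
        return cls(
            species=[Species(d["name"], float(d["D"])) for d in doc["species"]],
            reactions=[
                Reaction({k: int(v) for k, v in d["lhs"].items()},
                         {k: int(v) for k, v in d["rhs"].items()}, float(d["k"]))
                for d in doc["reactions"]
            ],
            init_counts={k: int(v) for k, v in doc.get("init", {}).items()},
        )


def scaled_rate_constant(k: float, order: int, V: float) -> float:
    """Per-event stochastic rate c (s⁻¹) from a deterministic rate constant.

    Order 1: c = k.  Order 2: c = k / (602.214076 · V), converting the
    (μM·s)⁻¹ constant to a per-pair collision rate in a voxel of V μm³.
    """
    if V <= 0:
        raise ValueError(f"voxel volume must be positive, got {V}")
    if order == 1:
        return k
    if order == 2:
        return k / (MOLECULES_PER_UM3_UM * V)
    raise ValueError(f"unsupported reaction order {order}")


def reaction_propensity(rxn: Reaction, counts: dict[str, int], V: float) -> float:
    """Mass-action propensity a (s⁻¹) given molecule counts in a voxel.

    a = c·n_A for A→…, c·n_A·n_B for A+B→…, c·n_A·(n_A−1)/2 for 2A→….
    """
    for name, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for {name}")
    c = scaled_rate_constant(rxn.k, rxn.order, V)
    reactants = list(rxn.lhs.items())
    if rxn.order == 1:
        (name, _), = reactants
        return c * counts.get(name, 0)
    if len(reactants) == 1:  # 2A -> ...
        name, _ = reactants[0]
        n = counts.get(name, 0)
        return c * n * (n - 1) / 2.0
    (na, _), (nb, _) = reactants
    return c * counts.get(na, 0) * counts.get(nb, 0)


@dataclass
class DiffusionRateTable:
    """Per-(tet, diffusive species) local diffusion rates.

    ``d_k[i, f, j]`` (s⁻¹) is the per-molecule hop rate of diffusive species
    ``j`` from tet ``i`` through local face ``f``:  d_k = D·A_k/(h_k·V_i),
    with A the shared-face area, h the barycenter distance and V the source
    volume.  ``d_total[i, j] = Σ_f d_k`` is the paper-style local rate whose
    reciprocal bounds the diffusion time window.
    """

    diff_species: list[str]  # names, order matches last axis
    diff_indices: np.ndarray  # (n_diff,) indices into ModelSpec.species
    d_k: np.ndarray  # (n_tets, 4, n_diff)
    d_total: np.ndarray  # (n_tets, n_diff)


def build_diffusion_rates(mesh: TetMesh, geom: GeomTables, model: ModelSpec) -> DiffusionRateTable:
    """Assemble the d_k / d_S,tet table for all diffusive species."""
    diff = [(i, s) for i, s in enumerate(model.species) if s.D > 0]
    nd = len(diff)
    d_k = np.zeros((mesh.n_tets, 4, nd))
    if nd:
        with np.errstate(divide="ignore", invalid="ignore"):
            per_face = np.where(
                mesh.neighbors >= 0,
                geom.face_areas / (geom.bary_dist * geom.volumes[:, None]),
                0.0,
            )  # (n_tets, 4), 1/μm²
        Ds = np.array([s.D for _, s in diff])
        d_k = per_face[:, :, None] * Ds[None, None, :]
    return DiffusionRateTable(
        diff_species=[s.name for _, s in diff],
        diff_indices=np.array([i for i, _ in diff], dtype=np.int64),
        d_k=d_k,
        d_total=d_k.sum(axis=1),
    )


def benchmark_model() -> ModelSpec:
    """The 10-species / 4-reversible-reaction benchmark model.

    Species A..J carry diffusion coefficients 100, 90, …, 10 μm²/s and
    whole-mesh initial totals 1000, 2000, …, 10000 molecules.  The four
    reversible reactions (stored as 8 irreversible records) are
    A+B⇄C (kf 1000 (μM·s)⁻¹, kb 100 s⁻¹), C+D⇄E (100, 10),
    F+G⇄H (10, 1) and H+I⇄J (1, 1).
    """
    names = [chr(ord("A") + i) for i in range(10)]
    species = [Species(n, 100.0 - 10.0 * i) for i, n in enumerate(names)]
    init = {n: 1000 * (i + 1) for i, n in enumerate(names)}
    pairs = [
        ({"A": 1, "B": 1}, {"C": 1}, 1000.0, 100.0),
        ({"C": 1, "D": 1}, {"E": 1}, 100.0, 10.0),
        ({"F": 1, "G": 1}, {"H": 1}, 10.0, 1.0),
        ({"H": 1, "I": 1}, {"J": 1}, 1.0, 1.0),
    ]
    reactions = []
    for lhs, rhs, kf, kb in pairs:
        reactions.append(Reaction(lhs, rhs, kf))
        reactions.append(Reaction(rhs, lhs, kb))
    return ModelSpec(species=species, reactions=reactions, init_counts=init)
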