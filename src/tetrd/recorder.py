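"""Trajectory recording with a fixed sampling interval.

Two CSV contracts: per-tet rows ``time,tet,species,count`` and the
whole-compartment aggregate ``time,species,count``.  Both solvers share this
recorder, so outputs are file-level comparable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Recorder"]


class Recorder:
    """Samples molecule counts every ``interval`` seconds.

    mode='total' stores whole-mesh totals per species; mode='per-tet' stores
    the full (tet, species) matrix at each sample time.
    """

    def __init__(self, interval: float, species_names: list[str], mode: str = "total"):
        if interval <= 0:
            raise ValueError("record interval must be positive")
        if mode not in ("total", "per-tet"):
            raise ValueError(f"unknown recorder mode {mode!r}")
        self.interval = float(interval)
        self.species_names = list(species_names)
        self.mode = mode
        self.times: list[float] = []
        self.samples: list[np.ndarray] = []

    def grid(self, t_end: float) -> np.ndarray:
        """Sample times in (0, t_end]: multiples of the interval, plus t_end."""
        n = int(np.floor(t_end / self.interval + 1e-9))
        pts = self.interval * np.arange(1, n + 1)
        if n == 0 or t_end - pts[-1] > 1e-9 * max(t_end, 1.0):
            pts = np.append(pts, t_end)
        return pts

    def record(self, t: float, counts: np.ndarray) -> None:
        self.times.append(float(t))
        self.samples.append(counts.sum(axis=0) if self.mode == "total" else counts.copy())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        if self.mode == "total":
            for t, snap in zip(self.times, self.samples):
                for s, name in enumerate(self.species_names):
                    rows.append((t, name, int(snap[s])))
            return pd.DataFrame(rows, columns=["time", "species", "count"])
        for t, snap in zip(self.times, self.samples):
            for tet in range(snap.shape[0]):
                for s, name in enumerate(self.species_names):
                    rows.append((t, tet, name, int(snap[tet, s])))
        return pd.DataFrame(rows, columns=["time", "tet", "species", "count"])

    def write_csv(self, path) -> None:
        """Atomic write: the file appears complete or not at all."""
        path = Path(path)
        tmp = path.with_suffix(path.suffix + ".tmp")
        self.to_frame().to_csv(tmp, index=False)
        tmp.replace(path)
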