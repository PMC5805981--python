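"""Engine-agnostic trajectory container and serialization.

A :class:`Trajectory` stores a time grid, per-species columns (integer copy
numbers for the CME engine, real concentrations for the hybrid engines),
promoter occupancies, and the un-thinned promoter switching events that the
period-detection protocols consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "SwitchRecord"]


@dataclass
class SwitchRecord:
    """Un-thinned promoter switching events: times + occupancies just after."""

    times: np.ndarray
    s_X: np.ndarray
    s_Y: np.ndarray
    labels: list[str] | None = None

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Trajectory:
    """Time-ordered sample path from any of the simulation engines.

    ``columns`` holds the species columns keyed by name.  CME trajectories
    carry ``N_X``/``N_Y`` (piecewise-constant snapshots); hybrid engines
    carry concentrations ``x``/``y`` (piecewise-smooth dense output).
    ``meta`` records the engine, parameter set and seed of the run.
    """

    times: np.ndarray
    columns: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)
    switches: SwitchRecord | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for k, v in self.columns.items():
            if len(v) != n:
                raise ValueError(f"column {k!r} length {len(v)} != times length {n}")
        if n > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def t_end(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0

    def concentration(self, species: str) -> np.ndarray:
        """Concentration of species 'x' or 'y' regardless of engine."""
        if species in self.columns:
            return np.asarray(self.columns[species], dtype=float)
        count = f"N_{species.upper()}"
        if count in self.columns:
            omega = float(self.meta.get("params", {}).get("Omega", 1.0))
            return np.asarray(self.columns[count], dtype=float) / omega
        raise KeyError(f"no column for species {species!r}")

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, **self.columns})
        return df

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the trajectory as CSV plus a JSON meta sidecar."""
        self.frame().to_csv(path, index=False)
        if sidecar:
            with open(str(path) + ".meta.json", "w") as fh:
                json.dump(_jsonable(self.meta), fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        meta: dict = {}
        try:
            with open(str(path) + ".meta.json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            pass
        times = df.pop("time").to_numpy()
        cols = {k: df[k].to_numpy() for k in df.columns if k != "event"}
        return cls(times=times, columns=cols, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
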