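"""Multi-individual time-series containers and their delimited-text format.

The on-disk format is a long table with columns ``cell_id, time, y0[, y1,
...]`` — one row per (cell, observation time).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd

__all__ = ["Individual", "Dataset"]


@dataclass
class Individual:
    """One cell's observation times (strictly increasing) and observations."""

    times: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim == 1:
            self.y = self.y[:, None]
        if self.times.ndim != 1 or self.y.shape[0] != self.times.shape[0]:
            raise ValueError("y must have one row per observation time")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")


@dataclass
class Dataset:
    individuals: List[Individual]

    @property
    def M(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, i: int) -> Individual:
        return self.individuals[i]

    def permuted(self, order) -> "Dataset":
        return Dataset([self.individuals[i] for i in order])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ind in enumerate(self.individuals):
            df = pd.DataFrame(ind.y, columns=[f"y{k}" for k in range(ind.y.shape[1])])
            df.insert(0, "time", ind.times)
            df.insert(0, "cell_id", i)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        ycols = [c for c in df.columns if c.startswith("y")]
        individuals = []
        for _, grp in df.groupby("cell_id", sort=True):
            grp = grp.sort_values("time")
            individuals.append(Individual(grp["time"].to_numpy(), grp[ycols].to_numpy()))
        return cls(individuals)

    def write(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: Union[str, Path]) -> "Dataset":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
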