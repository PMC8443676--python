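"""Plasmid-count histograms: the two-column (types, count) table shared by
the genome pipeline and the distribution-fitting machinery."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Histogram"]


@dataclass(frozen=True)
class Histogram:
    """Counts of genomes (or cells) carrying i = 0..max unique plasmid types.

    Counts are nonnegative reals: observed data are integers, but exact
    expected counts from a model distribution are also accepted so that
    noiseless self-consistency fits are possible.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.ndim != 1 or len(c) == 0:
            raise ValueError("counts must be a nonempty 1-D array")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if c.sum() <= 0:
            raise ValueError("histogram must contain at least one observation")

    @property
    def bins(self) -> np.ndarray:
        return np.arange(len(self.counts))

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.total

    @classmethod
    def from_samples(cls, samples: Sequence[int]) -> "Histogram":
        samples = np.asarray(samples, dtype=int)
        if np.any(samples < 0):
            raise ValueError("samples must be nonnegative counts")
        return cls(np.bincount(samples))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Histogram":
        df = pd.read_csv(path, sep="\t")
        if not {"types", "count"} <= set(df.columns):
            raise ValueError(
                f"histogram table must have columns 'types' and 'count', got {list(df.columns)}"
            )
        types = df["types"].to_numpy(dtype=int)
        counts = np.zeros(int(types.max()) + 1)
        counts[types] = df["count"].to_numpy(dtype=float)
        return cls(counts)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"types": self.bins, "count": self.counts}).to_csv(
            path, sep="\t", index=False
        )
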