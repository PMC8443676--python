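"""Synthetic genome collections for end-to-end pipeline testing.

A real complete-genome assembly summary (order 17,725 genomes) is not
redistributable, so this module generates a statistically faithful
stand-in: per-genome plasmid counts drawn from a Wright-Fisher
stationary distribution (defaults: strong positive epistasis with
Delta = 9.8e-3, q = 5.4e-3, the regime genome-wide plasmid-count fits
identify), replicon tables with chromosome/plasmid rows
and genus labels, an optional fraction of "incomplete" genomes whose
chromosome falls below the 0.5 Mb completeness cutoff, and cas-HMM hit
tables with true hits (E < 1e-30) and decoys.  Every generator is
deterministic for a given seed and writes a ground-truth sidecar so
consumers can be checked exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .histogram import Histogram
from .wright_fisher import EpistasisSpec, stationary_distribution

__all__ = [
    "GeneratorSpec",
    "sample_plasmid_counts",
    "generate_assembly_table",
    "generate_cas_tables",
]

# weighted toward a few heavily sequenced genera, as in public collections
_DEFAULT_GENERA = (
    ("Escherichia", 0.16),
    ("Klebsiella", 0.08),
    ("Salmonella", 0.08),
    ("Staphylococcus", 0.07),
    ("Pseudomonas", 0.07),
    ("Streptococcus", 0.06),
    ("Bacillus", 0.06),
    ("Lactobacillus", 0.05),
    ("Vibrio", 0.05),
    ("Streptomyces", 0.05),
    ("Rhizobium", 0.05),
    ("Synechococcus", 0.04),
    ("Clostridium", 0.04),
    ("Burkholderia", 0.04),
    ("Mycobacterium", 0.04),
    ("Flavobacterium", 0.06),
)


@dataclass(frozen=True)
class GeneratorSpec:
    """What world to emulate: distribution source, table dialect, nuisances."""

    n_genomes: int = 17_725
    epistasis: EpistasisSpec = field(
        default_factory=lambda: EpistasisSpec(form="positive", Delta=9.8e-3)
    )
    q: float = 5.4e-3
    probabilities: Sequence[float] | None = None  # explicit source, overrides the above
    chromosome_bp: tuple[int, int] = (1_000_000, 6_000_000)
    plasmid_bp: tuple[int, int] = (2_000, 200_000)
    incomplete_bp: tuple[int, int] = (100_000, 450_000)
    fraction_incomplete: float = 0.0
    genus_pool: tuple[tuple[str, float], ...] = _DEFAULT_GENERA
    cas_probability: float | Callable[[int], float] = 0.4
    decoy_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not 0.0 <= self.fraction_incomplete < 1.0:
            raise ValueError("fraction_incomplete must lie in [0, 1)")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("explicit probabilities must be a valid distribution")

    def source_distribution(self) -> np.ndarray:
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            return p / p.sum()
        return stationary_distribution(self.epistasis, self.q).f


def sample_plasmid_counts(
    spec: GeneratorSpec, seed: int
) -> tuple[np.ndarray, Histogram]:
    """Per-genome unique-plasmid-type counts and their exact tally."""
    f = spec.source_distribution()
    rng = np.random.default_rng(seed)
    counts = rng.choice(len(f), size=spec.n_genomes, p=f)
    return counts, Histogram.from_samples(counts)


def generate_assembly_table(
    counts: Sequence[int],
    spec: GeneratorSpec,
    seed: int,
    path: str | Path | None = None,
    sidecar_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Replicon table (one chromosome row + one row per plasmid) plus a
    ground-truth sidecar with per-genome counts, genera and completeness.

    A ``fraction_incomplete`` share of genomes receives a sub-0.5 Mb
    chromosome and should be dropped by the completeness filter.
    """
    counts = np.asarray(counts, dtype=int)
    rng = np.random.default_rng(seed)
    n = len(counts)
    genera = np.array([g for g, _ in spec.genus_pool])
    weights = np.array([w for _, w in spec.genus_pool], dtype=float)
    weights /= weights.sum()
    genus_of = rng.choice(genera, size=n, p=weights)
    incomplete = rng.random(n) < spec.fraction_incomplete

    rows: list[tuple[str, str, str, int, str]] = []
    truth: dict[str, dict] = {}
    for g in range(n):
        acc = f"SYN_{g + 1:06d}"
        if incomplete[g]:
            lo, hi = spec.incomplete_bp
        else:
            lo, hi = spec.chromosome_bp
        chrom_len = int(rng.integers(lo, hi + 1))
        rows.append((acc, "chromosome_1", "Chromosome", chrom_len, genus_of[g]))
        lo_p, hi_p = spec.plasmid_bp
        for k in range(int(counts[g])):
            length = int(np.exp(rng.uniform(np.log(lo_p), np.log(hi_p))))
            rows.append((acc, f"plasmid_{k + 1}", "Plasmid", length, genus_of[g]))
        truth[acc] = {
            "plasmid_count": int(counts[g]),
            "genus": str(genus_of[g]),
            "complete": bool(not incomplete[g]),
        }
    df = pd.DataFrame(
        rows,
        columns=["assembly_accession", "replicon_name", "replicon_role", "length_bp", "genus"],
    )
    sidecar = {"n_genomes": n, "genomes": truth}
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    if sidecar_path is not None:
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return df, sidecar


def generate_cas_tables(
    assembly_counts: dict[str, int],
    spec: GeneratorSpec,
    seed: int,
    path: str | Path | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """cas-HMM hit table: true hits (log-uniform E in [1e-60, 1e-31]) for
    carriers, decoy hits (E in [1e-29, 1e-5]) for a fraction of
    non-carriers.  Returns the table and the true carrier set.

    ``spec.cas_probability`` may depend on the genome's plasmid count to
    emulate (or break) carriage/plasmid independence.
    """
    rng = np.random.default_rng(seed)
    prob = spec.cas_probability
    models = ("cas1", "cas2", "cas3", "cas9", "cas10")
    rows: list[tuple[str, str, float]] = []
    carriers: set[str] = set()
    for acc, count in assembly_counts.items():
        p = prob(count) if callable(prob) else prob
        if rng.random() < p:
            carriers.add(acc)
            for _ in range(int(rng.integers(1, 3))):
                evalue = 10.0 ** rng.uniform(-60, -31)
                rows.append((acc, str(rng.choice(models)), evalue))
        elif rng.random() < spec.decoy_fraction:
            evalue = 10.0 ** rng.uniform(-29, -5)
            rows.append((acc, str(rng.choice(models)), evalue))
    df = pd.DataFrame(rows, columns=["assembly_accession", "model_name", "evalue"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df, carriers
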