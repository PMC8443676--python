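"""Parsing and filtering of assembly-summary-like genome tables.

Input is a flat tab-separated surrogate for an NCBI complete-genome
assembly summary: one row per replicon with columns
``assembly_accession``, ``replicon_name``, ``replicon_role``,
``length_bp`` and ``genus``.  The pipeline implements the standard
hygiene for complete bacterial genomes: drop assemblies lacking a chromosome longer
than 0.5 Mb (mislabeled incomplete assemblies), count replicons whose
role is "plasmid" (case-insensitive) per genome, optionally exclude
human-associated genera, and stratify by cas-gene presence using a
profile-HMM hit table thresholded at E-value < 1e-30.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .histogram import Histogram

__all__ = [
    "GenomeRecord",
    "load_assembly_table",
    "completeness_filter",
    "plasmid_count_histogram",
    "exclude_genera",
    "cas_positive_assemblies",
    "split_by_cas",
    "CHROMOSOME_MIN_BP",
    "CAS_EVALUE_THRESHOLD",
]

#: strict lower bound on chromosome length for a genome to count as complete
CHROMOSOME_MIN_BP = 500_000
#: strict upper bound on the E-value of a valid cas-gene hit
CAS_EVALUE_THRESHOLD = 1e-30

_ASSEMBLY_COLUMNS = ["assembly_accession", "replicon_name", "replicon_role", "length_bp", "genus"]
_CAS_COLUMNS = ["assembly_accession", "model_name", "evalue"]
_ROLES = {"chromosome", "plasmid"}


@dataclass
class GenomeRecord:
    """One genome: its replicons (role, length), genus, optional cas flag."""

    assembly_id: str
    replicons: list[tuple[str, int]] = field(default_factory=list)
    genus: str = ""
    cas_positive: bool | None = None

    @property
    def plasmid_count(self) -> int:
        return sum(1 for role, _ in self.replicons if role == "plasmid")

    def has_complete_chromosome(self, min_bp: int = CHROMOSOME_MIN_BP) -> bool:
        return any(
            role == "chromosome" and length > min_bp for role, length in self.replicons
        )


def _normalize_role(raw: str) -> str:
    role = str(raw).strip().lower()
    return role if role in _ROLES else "other"


def load_assembly_table(path: str | Path) -> list[GenomeRecord]:
    """Parse a replicon table into one GenomeRecord per assembly.

    Malformed rows (missing fields, non-positive or non-integer lengths)
    raise with their 1-based file line numbers; duplicated
    (assembly, replicon) pairs are an error.  An empty file yields an
    empty list with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"assembly table {path} is empty")
        return []
    missing = set(_ASSEMBLY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assembly table is missing columns: {sorted(missing)}")
    if df.empty:
        warnings.warn(f"assembly table {path} contains no data rows")
        return []

    lengths = pd.to_numeric(df["length_bp"], errors="coerce")
    bad = df["assembly_accession"].isna() | df["replicon_name"].isna()
    bad |= lengths.isna() | (lengths <= 0) | (lengths != lengths.round())
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header and 1-basing
        raise ValueError(f"malformed assembly-table rows at lines: {lines}")
    dup = df.duplicated(subset=["assembly_accession", "replicon_name"], keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup]]
        raise ValueError(f"duplicate (assembly, replicon) rows at lines: {lines}")

    records: dict[str, GenomeRecord] = {}
    genus = df["genus"].fillna("")
    for acc, role, length, gen in zip(
        df["assembly_accession"], df["replicon_role"], lengths.astype(int), genus
    ):
        rec = records.get(acc)
        if rec is None:
            rec = records[acc] = GenomeRecord(assembly_id=acc, genus=str(gen).strip())
        rec.replicons.append((_normalize_role(role), int(length)))
    return list(records.values())


def completeness_filter(records: Iterable[GenomeRecord]) -> list[GenomeRecord]:
    """Keep genomes with at least one chromosome strictly longer than 0.5 Mb."""
    return [r for r in records if r.has_complete_chromosome()]


def plasmid_count_histogram(
    records: Sequence[GenomeRecord], group_by_genus: bool = False
) -> Histogram | dict[str, Histogram]:
    """Tally unique plasmid types (plasmid-role replicons) per genome."""
    if not group_by_genus:
        return Histogram.from_samples([r.plasmid_count for r in records])
    groups: dict[str, list[int]] = {}
    n_unassigned = 0
    for r in records:
        key = r.genus if r.genus else "unassigned"
        if not r.genus:
            n_unassigned += 1
        groups.setdefault(key, []).append(r.plasmid_count)
    if n_unassigned:
        warnings.warn(
            f"{n_unassigned} genomes lack a genus label; collected under 'unassigned'"
        )
    return {g: Histogram.from_samples(v) for g, v in groups.items()}


def exclude_genera(
    records: Iterable[GenomeRecord], genera: Sequence[str]
) -> list[GenomeRecord]:
    """Remove genomes whose genus matches the list (case-insensitive, exact)."""
    if not genera:
        raise ValueError("the exclusion list must be nonempty")
    excluded = {g.strip().lower() for g in genera}
    return [r for r in records if r.genus.strip().lower() not in excluded]


def cas_positive_assemblies(
    hits: str | Path | pd.DataFrame, threshold: float = CAS_EVALUE_THRESHOLD
) -> set[str]:
    """Assemblies with at least one cas-HMM hit below the E-value threshold
    (strictly below — a hit exactly at the threshold does not count)."""
    if isinstance(hits, (str, Path)):
        try:
            hits = pd.read_csv(hits, sep="\t", dtype={"assembly_accession": str})
        except pd.errors.EmptyDataError:
            return set()
    missing = set(_CAS_COLUMNS) - set(hits.columns)
    if missing:
        raise ValueError(f"cas hit table is missing columns: {sorted(missing)}")
    if hits.empty:
        return set()
    evalues = pd.to_numeric(hits["evalue"], errors="coerce")
    if evalues.isna().any() or (evalues < 0).any():
        raise ValueError("cas hit table contains negative or unparsable E-values")
    keep = evalues < threshold
    return set(hits.loc[keep, "assembly_accession"])


def split_by_cas(
    records: Sequence[GenomeRecord], cas_positive: set[str]
) -> tuple[Histogram | None, Histogram | None]:
    """Plasmid-count histograms for cas-containing vs cas-free genomes.

    Either stratum may be None when empty.
    """
    pos = [r.plasmid_count for r in records if r.assembly_id in cas_positive]
    neg = [r.plasmid_count for r in records if r.assembly_id not in cas_positive]
    h_pos = Histogram.from_samples(pos) if pos else None
    h_neg = Histogram.from_samples(neg) if neg else None
    return h_pos, h_neg
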