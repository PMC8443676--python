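#!/usr/bin/env python
"""Synthetic genome collection: filtering, histograms, epistasis-model fits.

Generates a 17,725-genome synthetic collection whose plasmid counts are
drawn from the strong-positive-epistasis stationary distribution
(Delta = 9.8e-3, q = 5.4e-3), runs it through the completeness filter and
histogram stages, stratifies by cas carriage (independent of plasmid
count), and compares epistasis-model fits.  Writes
results/genome_histogram.tsv, results/genome_fits.tsv and
results/cas_split_tv.tsv.
"""
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from plasmidsim import (
    EpistasisSpec,
    GenomeRecord,
    GeneratorSpec,
    cas_positive_assemblies,
    compare_fits,
    completeness_filter,
    distribution_distance,
    generate_assembly_table,
    generate_cas_tables,
    load_assembly_table,
    plasmid_count_histogram,
    split_by_cas,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)
SEED = 20_260_917  # fixed date-derived seed for a reproducible narrative

TRUE_DELTA, TRUE_Q = 9.8e-3, 5.4e-3

spec = GeneratorSpec(
    n_genomes=17_725,
    epistasis=EpistasisSpec("positive", TRUE_DELTA),
    q=TRUE_Q,
    fraction_incomplete=0.05,
    cas_probability=0.4,
)

from plasmidsim import sample_plasmid_counts

counts, _ = sample_plasmid_counts(spec, SEED)
with tempfile.TemporaryDirectory() as tmp:
    table = Path(tmp) / "genomes.tsv"
    _, sidecar = generate_assembly_table(counts, spec, SEED + 1, path=table)
    records = load_assembly_table(table)

complete = completeness_filter(records)
print(f"genomes: {len(records)} generated, {len(complete)} pass the >0.5 Mb chromosome filter")

hist = plasmid_count_histogram(complete)
hist.to_tsv(RESULTS / "genome_histogram.tsv")
print(f"histogram over 0..{len(hist.counts) - 1} plasmid types "
      f"(zero-plasmid fraction {hist.probabilities[0]:.3f})")

print("\n== epistasis-model comparison ==")
ranked = compare_fits(hist, ["positive", "none", "negative"], seed=SEED % 1000)
rows = []
for r in ranked:
    rows.append((r.form, r.Delta, r.q, r.a, r.ratio, r.objective, r.identifiability_warning))
    print(f"{r.form:>8}: Delta={r.Delta:.3g} q={r.q:.3g} q/Delta={r.ratio:.3f} "
          f"objective={r.objective:.4f}"
          + ("  [only q/Delta identifiable]" if r.identifiability_warning else ""))
pd.DataFrame(
    rows, columns=["form", "Delta", "q", "a", "ratio", "objective", "identifiability_warning"]
).to_csv(RESULTS / "genome_fits.tsv", sep="\t", index=False)
best = ranked[0]
true_ratio = TRUE_Q / TRUE_DELTA
print(f"best form: {best.form}; recovered q/Delta = {best.ratio:.3f} "
      f"(generator: {true_ratio:.3f}, error {abs(best.ratio - true_ratio) / true_ratio:.1%})")
print("the exponential-like histogram demands positive epistasis — the")
print("no-epistasis fit has too short a tail; only the invasion/cost ratio")
print("is individually identifiable in this regime.")

print("\n== cas stratification (carriage independent of plasmid count) ==")
acc_counts = {a: v["plasmid_count"] for a, v in sidecar["genomes"].items() if v["complete"]}
cas_df, carriers = generate_cas_tables(acc_counts, spec, SEED + 2)
cas_set = cas_positive_assemblies(cas_df)
recs = [r for r in complete]
h_pos, h_neg = split_by_cas(recs, cas_set)
tv = distribution_distance(h_pos.probabilities, h_neg.probabilities)
pd.DataFrame(
    {"stratum": ["cas_positive", "cas_negative"], "n": [h_pos.total, h_neg.total]}
).assign(tv_distance=tv).to_csv(RESULTS / "cas_split_tv.tsv", sep="\t", index=False)
print(f"cas+ n={int(h_pos.total)}, cas- n={int(h_neg.total)}, TV = {tv:.4f}")
print("matched strata under independent carriage — the null model against")
print("which a defense-system effect on plasmid carriage would be judged.")
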