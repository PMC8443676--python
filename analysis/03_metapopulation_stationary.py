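#!/usr/bin/env python
"""Wright-Fisher metapopulation: stationary plasmid-count distributions.

Solves the analytic stationary distribution of unique plasmid types per
deme for the three epistasis forms at Delta = 0.01, q = 0.005, verifies
the fixed-point property against the epoch resampling kernel, and checks
the stochastic simulation against the analytic solution in the large-N
regime where demographic noise is subdominant.  Writes
results/wf_stationary.tsv and results/wf_simulation_check.tsv.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from plasmidsim import (
    EpistasisSpec,
    WFParams,
    distribution_distance,
    epoch_probabilities,
    simulate_epochs,
    stationary_distribution,
    tail_ratio_diagnostics,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

DELTA, Q = 0.01, 0.005

print("== analytic stationary distributions (Delta=0.01, q=0.005) ==")
rows = []
dists = {}
for form in ("positive", "none", "negative"):
    sd = stationary_distribution(EpistasisSpec(form, DELTA), Q)
    dists[form] = sd
    for i, p in enumerate(sd.f):
        rows.append((form, i, p))
    ratios, constant = tail_ratio_diagnostics(sd)
    tail = sd.f[4:].sum()
    print(f"{form:>8}: mean={sd.mean:.3f}  P(i>=4)={tail:.2e}  "
          f"first ratios {np.round(ratios[:3], 4)}  geometric={constant}")
pd.DataFrame(rows, columns=["form", "i", "probability"]).to_csv(
    RESULTS / "wf_stationary.tsv", sep="\t", index=False
)
print("positive epistasis -> exponential tail with constant ratio")
print("q(1-Delta)/((1-q)Delta); no epistasis -> Poisson-like; negative -> truncated.")

print("\n== fixed-point property ==")
for form, sd in dists.items():
    p = epoch_probabilities(sd.f, sd.epistasis, Q)
    folded = p[:-1].copy()
    folded[-1] += p[-1]
    print(f"{form:>8}: max residual {np.max(np.abs(folded - sd.f)):.2e}")

print("\n== stochastic simulation vs analytic (positive epistasis) ==")
rows = []
for N in (1000, 10_000, 100_000):
    params = WFParams(
        N=N, q=Q, epistasis=EpistasisSpec("positive", DELTA),
        i_max=50, epochs=20_000, seed=1,
    )
    history = simulate_epochs(params)
    avg = history[2001:].mean(axis=0) / N
    tv = distribution_distance(avg, dists["positive"].f)
    rows.append((N, tv))
    print(f"N={N:>6}: TV(time average, analytic) = {tv:.4f}")
pd.DataFrame(rows, columns=["N", "tv_distance"]).to_csv(
    RESULTS / "wf_simulation_check.tsv", sep="\t", index=False
)
print("the analytic recursion is the infinite-N fixed point: agreement")
print("tightens as N grows; at N~1000 the plasmid-free class is nearly")
print("neutral (selection ~ invasion) and drifts, so time averages wander.")
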