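"""Independent brute-force oracles shared across test modules.

These deliberately use explicit Python loops and sorting — no pandas
groupby machinery — so they cannot share a bug with the implementation.
"""

import numpy as np
import pandas as pd


def brute_force_rollup(tbl):
    """Explicit-loop top-3 / min-2 / max-10 precursor-to-protein rollup."""
    out = {}
    samples = list(dict.fromkeys(tbl["sample"]))
    for protein in sorted(set(tbl["protein"])):
        sub = tbl[tbl["protein"] == protein]
        peptides = sorted(set(sub["peptide"]))
        if len(peptides) < 2:
            continue  # single-hit exclusion
        pep_q = {}
        for pep in peptides:
            for s in samples:
                vals = sorted(sub[(sub["peptide"] == pep) & (sub["sample"] == s)]["intensity"],
                              reverse=True)
                if vals:
                    pep_q[(pep, s)] = sum(vals[:3])
        means = {}
        for pep in peptides:
            obs = [pep_q[(pep, s)] for s in samples if (pep, s) in pep_q]
            means[pep] = sum(obs) / len(obs)
        ranked = sorted(peptides, key=lambda p: (-means[p], p))[:10]
        out[protein] = {}
        for s in samples:
            obs = [pep_q[(pep, s)] for pep in ranked if (pep, s) in pep_q]
            out[protein][s] = sum(obs) / len(obs) if obs else np.nan
        out[protein]["__n"] = len(ranked)
    return out


def random_precursor_table(rng, n_proteins=15):
    """Small randomized long-format table with missingness and single hits."""
    rows = []
    for p in range(n_proteins):
        pid = f"Q{p:03d}"
        for j in range(rng.integers(1, 14)):
            pep = f"{pid}_pep{j:02d}"
            for k in range(rng.integers(1, 6)):
                for s in ("s1", "s2", "s3", "s4"):
                    if rng.random() < 0.85:
                        rows.append((pid, pep, f"{pep}_z{k}", s,
                                     float(rng.lognormal(12, 1.5))))
    return pd.DataFrame(rows, columns=["protein", "peptide", "precursor",
                                       "sample", "intensity"])
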