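"""DIA label-free quantitation: top-3 rollup, normalization, differential filtering.

The chain mirrors the standard precursor -> peptide -> protein rollup used
for data-independent-acquisition proteomics of microdissected tissue:

1. peptide quantity per sample = sum of its 3 most intense precursors;
2. protein quantity per sample = mean over its retained peptides, where
   retention keeps at most the 10 peptides with the highest cross-sample
   mean quantity ("min peptides = 2, max peptides = 10") and drops
   single-hit proteins (a single distinct peptide) entirely;
3. global normalization: per-sample scaling so every sample's median
   log2 quantity equals the grand median of those medians;
4. differential abundance: Welch's t on log2 quantities per protein,
   Benjamini-Hochberg FDR across tested proteins, and the significance
   rule FDR <= 0.05 AND |log2 FC| >= 0.58 (fold change >= 1.5).

Missing values stay missing (no imputation): an intensity below the
detection limit carries no quantitative information. Proteins with fewer
than two observed values in either group are reported as untested rather
than silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LFC_THRESHOLD",
    "FDR_THRESHOLD",
    "ProteinQuantMatrix",
    "rollup_top3",
    "global_normalize",
    "differential_expression",
    "localization_summary",
    "LOCALIZATION_CATEGORIES",
    "read_precursor_table",
]

logger = logging.getLogger(__name__)

#: Differential-abundance gates: fold change >= 1.5 i.e. |log2 FC| >= 0.58.
LFC_THRESHOLD = 0.58
FDR_THRESHOLD = 0.05

TOP_N_PRECURSORS = 3
MIN_PEPTIDES = 2
MAX_PEPTIDES = 10

PRECURSOR_COLUMNS = ["protein", "peptide", "precursor", "sample", "intensity"]

LOCALIZATION_CATEGORIES = ("nuclear", "cytosol", "plasma_membrane", "extracellular_matrix")


@dataclass
class ProteinQuantMatrix:
    """Protein x sample quantity matrix with peptide support counts.

    ``quantities`` is a DataFrame indexed by protein with one column per
    sample (NaN = missing); ``n_peptides`` counts the peptides that
    contributed to each protein after the max-10 cap; ``groups`` maps
    sample -> group label when a design is known.
    """

    quantities: pd.DataFrame
    n_peptides: pd.Series
    groups: pd.Series | None = None
    #: retained peptide-level quantities, (protein, peptide) x sample
    peptide_quantities: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.quantities.index.equals(self.n_peptides.index):
            self.n_peptides = self.n_peptides.reindex(self.quantities.index)
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.quantities.to_numpy(dtype=float), initial=0.0) < 0:
                raise ValueError("protein quantities must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.quantities.columns)


def read_precursor_table(path, sep=None) -> pd.DataFrame:
    """Load a long-format precursor table (CSV/TSV with a header).

    Required columns: protein, peptide, precursor, sample, intensity.
    A ``group`` column, if present, is kept.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in PRECURSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _validate_precursors(tbl: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PRECURSOR_COLUMNS if c not in tbl.columns]
    if missing:
        raise ValueError(f"precursor table missing columns {missing}")
    tbl = tbl.dropna(subset=["intensity"])
    if (tbl["intensity"] < 0).any():
        raise ValueError("precursor intensities must be non-negative")
    key = ["protein", "peptide", "precursor", "sample"]
    if tbl.duplicated(subset=key).any():
        raise ValueError("duplicate (protein, peptide, precursor, sample) records")
    return tbl


def rollup_top3(tbl: pd.DataFrame) -> ProteinQuantMatrix:
    """Precursor -> peptide -> protein rollup with the top-3 / min-2 / max-10 rules.

    Per (peptide, sample): sum of the 3 largest precursor intensities (all of
    them when fewer than 3 were observed). Per protein: peptides are ranked
    by cross-sample mean quantity (lexicographic peptide tie-break) and only
    the top 10 contribute; the protein quantity per sample is the mean of the
    retained peptides observed in that sample. Proteins with fewer than two
    distinct peptides are excluded (single-hit exclusion).
    """
    tbl = _validate_precursors(tbl)
    if tbl.empty:
        warnings.warn("empty precursor table: returning an empty quantity matrix")
        return ProteinQuantMatrix(pd.DataFrame(), pd.Series(dtype=int))

    # Peptide quantity: top-3 precursor sum within (protein, peptide, sample).
    # Rank-by-cumcount keeps this a pure vectorised groupby (ties are
    # harmless: any 3 of equal intensities sum identically).
    key = ["protein", "peptide", "sample"]
    ranked = tbl.sort_values("intensity", ascending=False, kind="stable")
    ranked = ranked[ranked.groupby(key, sort=False).cumcount() < TOP_N_PRECURSORS]
    top3 = ranked.groupby(key, sort=True)["intensity"].sum()
    pep = top3.unstack("sample")  # (protein, peptide) x sample

    n_pep = pep.groupby(level="protein").size()
    keep = n_pep[n_pep >= MIN_PEPTIDES].index
    dropped = len(n_pep) - len(keep)
    if dropped:
        logger.info("single-hit exclusion removed %d protein(s)", dropped)
    pep = pep.loc[pep.index.get_level_values("protein").isin(keep)]
    if pep.empty:
        warnings.warn("no protein passed the min-peptides filter")
        return ProteinQuantMatrix(pd.DataFrame(columns=tbl["sample"].unique()),
                                  pd.Series(dtype=int))

    # Max-10 cap: rank peptides inside each protein by cross-sample mean,
    # lexicographic peptide id as the deterministic tie-break.
    rank_key = pep.mean(axis=1, skipna=True).rename("mean_q").reset_index()
    rank_key = rank_key.sort_values(["protein", "mean_q", "peptide"],
                                    ascending=[True, False, True])
    retained = rank_key.groupby("protein").head(MAX_PEPTIDES)
    idx = pd.MultiIndex.from_frame(retained[["protein", "peptide"]])
    pep = pep.loc[pep.index.isin(idx)]

    prot = pep.groupby(level="protein").mean()  # skipna mean per sample
    n_retained = pep.groupby(level="protein").size().rename("n_peptides")
    samples = pd.unique(tbl["sample"])
    prot = prot.reindex(columns=samples)

    groups = None
    if "group" in tbl.columns:
        g = tbl.drop_duplicates("sample").set_index("sample")["group"]
        groups = g.reindex(prot.columns)
    return ProteinQuantMatrix(prot, n_retained, groups,
                              peptide_quantities=pep.reindex(columns=samples))


def global_normalize(m: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Median-center samples in log2 space ("global normalization").

    Every sample is rescaled so its median log2 quantity (over observed,
    positive entries) equals the grand median of the per-sample medians.
    Missing values are untouched.
    """
    q = m.quantities
    if q.empty:
        raise ValueError("cannot normalize an empty quantity matrix")
    with np.errstate(divide="ignore"):
        logq = np.log2(q.where(q > 0))
    medians = logq.median(axis=0, skipna=True)
    bad = medians.index[medians.isna()].tolist()
    if bad:
        raise ValueError(f"sample(s) with no observed quantities: {bad}")
    target = float(medians.median())
    scale = np.power(2.0, target - medians)
    return ProteinQuantMatrix(q * scale, m.n_peptides.copy(),
                              None if m.groups is None else m.groups.copy())


def differential_expression(m: ProteinQuantMatrix, group_a: str, group_b: str,
                            fdr_threshold: float = FDR_THRESHOLD,
                            lfc_threshold: float = LFC_THRESHOLD) -> pd.DataFrame:
    """Per-protein Welch t on log2 quantities with Benjamini-Hochberg FDR.

    ``log2_fc`` is mean(log2 group A) - mean(log2 group B). Proteins with
    fewer than two observed values in either group get ``tested = False``
    and NaN statistics. Returns a DataFrame indexed by protein with columns
    n_peptides, log2_fc, p_value, fdr, significant, tested.
    """
    if m.groups is None:
        raise ValueError("quantity matrix carries no group labels")
    groups = m.groups
    for g in (group_a, group_b):
        if g not in set(groups.dropna()):
            raise ValueError(f"unknown group label {g!r}; have {sorted(set(groups.dropna()))}")
    q = m.quantities
    with np.errstate(divide="ignore"):
        la = np.log2(q.loc[:, groups == group_a].where(lambda d: d > 0)).to_numpy()
        lb = np.log2(q.loc[:, groups == group_b].where(lambda d: d > 0)).to_numpy()

    na = np.sum(np.isfinite(la), axis=1)
    nb = np.sum(np.isfinite(lb), axis=1)
    tested = (na >= 2) & (nb >= 2)

    lfc = np.full(len(q), np.nan)
    pval = np.full(len(q), np.nan)
    if tested.any():
        a = np.ma.masked_invalid(la[tested])
        b = np.ma.masked_invalid(lb[tested])
        lfc[tested] = (a.mean(axis=1) - b.mean(axis=1)).filled(np.nan)
        res = stats.ttest_ind(la[tested], lb[tested], axis=1,
                              equal_var=False, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
        # Zero within-group variance on both sides gives NaN; identical
        # groups are maximally non-significant.
        p = np.where(np.isnan(p) & np.isclose(lfc[tested], 0.0), 1.0, p)
        pval[tested] = p

    fdr = np.full(len(q), np.nan)
    ok = tested & np.isfinite(pval)
    if ok.any():
        fdr[ok] = multipletests(pval[ok], method="fdr_bh")[1]
    significant = ok & (fdr <= fdr_threshold) & (np.abs(lfc) >= lfc_threshold)

    return pd.DataFrame(
        {
            "n_peptides": m.n_peptides.reindex(q.index).to_numpy(),
            "log2_fc": lfc,
            "p_value": pval,
            "fdr": fdr,
            "significant": significant,
            "tested": tested,
        },
        index=q.index.rename("protein"),
    )


def localization_summary(proteins, loc: dict[str, set[str]]) -> dict:
    """Percent of proteins carrying each cellular-localization category.

    ``loc`` maps protein -> subset of the four-category vocabulary (nuclear,
    cytosol, plasma_membrane, extracellular_matrix). Categories overlap, so
    the percentages may sum past 100. ``multi_local_percent`` is the percent
    of proteins annotated with at least two categories; proteins absent from
    the table count toward ``n_unannotated`` and score zero categories.
    """
    proteins = list(proteins)
    out = {c: 0.0 for c in LOCALIZATION_CATEGORIES}
    out.update(multi_local_percent=0.0, n_proteins=len(proteins), n_unannotated=0)
    if not proteins:
        return out
    n_multi = 0
    n_unannotated = 0
    for p in proteins:
        cats = set(loc.get(p, ()))
        unknown = cats - set(LOCALIZATION_CATEGORIES)
        if unknown:
            raise ValueError(f"protein {p!r} has unknown categories {sorted(unknown)}")
        if p not in loc:
            n_unannotated += 1
        for c in cats:
            out[c] += 1
        if len(cats) >= 2:
            n_multi += 1
    n = len(proteins)
    for c in LOCALIZATION_CATEGORIES:
        out[c] = 100.0 * out[c] / n
    out["multi_local_percent"] = 100.0 * n_multi / n
    out["n_unannotated"] = n_unannotated
    return out
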