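"""Mutation-morphology association testing.

Frequently mutated genes (> 15% of patients by default) are tested
against each of the 150 patient-level image features with a two-sided
Mann-Whitney U test; fold change is the ratio of the feature medians
(mutated / nonmutated); q-values are Benjamini-Hochberg adjusted over
the full gene x feature family (a per-gene family mode is available).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def select_frequent_genes(
    mutations: pd.DataFrame, threshold: float = 0.15
) -> pd.Series:
    """Genes somatically mutated in strictly more than ``threshold`` of
    patients, as a frequency Series sorted by descending frequency
    (ties broken alphabetically).

    ``mutations`` is a patients x genes binary matrix (1 = non-silent
    mutation, 0 = wild type); any other value is an error.
    """
    vals = mutations.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mutation matrix must be binary {0, 1}")
    freq = mutations.mean(axis=0)
    freq = freq[freq > threshold]
    order = sorted(freq.index, key=lambda g: (-freq[g], g))
    return freq.loc[order]


def mann_whitney_two_sided(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group a, p).

    Exact p by enumeration when the combined sample size is <= 12 with
    no ties; otherwise the normal approximation with tie and continuity
    corrections.  Two identical constant samples (zero-variance
    degenerate case) give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if not np.isfinite(p):  # all observations tied: no evidence either way
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, order-preserving.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_association(
    features: pd.DataFrame,
    mutations: pd.DataFrame,
    threshold: float = 0.15,
    alpha: float = 0.05,
    fdr_family: str = "global",
) -> pd.DataFrame:
    """Test every frequent gene against every image feature.

    Patients are aligned on the (sorted) intersection of the two
    tables' indices, so the result is invariant to row order.  Genes
    with fewer than 2 patients in either group are flagged untestable
    and excluded from the FDR family.  Fold change with a zero
    nonmutated median is recorded as NaN rather than infinity.

    Returns a DataFrame with columns gene, feature, U, p, q,
    fold_change, significant (q < alpha), testable.
    """
    if fdr_family not in ("global", "per_gene"):
        raise ValueError("fdr_family must be 'global' or 'per_gene'")
    shared = sorted(set(features.index) & set(mutations.index))
    if not shared:
        raise ValueError("no shared patients between features and mutations")
    X = features.loc[shared]
    M = mutations.loc[shared]
    genes = select_frequent_genes(M, threshold=threshold)

    records = []
    for gene in genes.index:
        labels = M[gene].to_numpy()
        mut = X.loc[labels == 1]
        wt = X.loc[labels == 0]
        testable = len(mut) >= 2 and len(wt) >= 2
        for feat in X.columns:
            a = mut[feat].to_numpy(dtype=float)
            b = wt[feat].to_numpy(dtype=float)
            if testable:
                U, p = mann_whitney_two_sided(a, b)
            else:
                U, p = np.nan, np.nan
            med_wt = float(np.median(b)) if b.size else np.nan
            med_mut = float(np.median(a)) if a.size else np.nan
            fc = med_mut / med_wt if med_wt != 0 else np.nan
            records.append(
                {
                    "gene": gene,
                    "feature": feat,
                    "U": U,
                    "p": p,
                    "fold_change": fc,
                    "testable": testable,
                }
            )
    table = pd.DataFrame(records)
    table["q"] = np.nan
    ok = table["testable"] & table["p"].notna()
    if ok.any():
        if fdr_family == "global":
            table.loc[ok, "q"] = benjamini_hochberg(table.loc[ok, "p"].to_numpy())
        else:
            for gene in genes.index:
                sel = ok & (table["gene"] == gene)
                if sel.any():
                    table.loc[sel, "q"] = benjamini_hochberg(table.loc[sel, "p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return table
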