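"""Image-feature / gene-expression integration.

For a prognostic image feature, compute its Spearman correlation with
every gene's expression across the shared patients, take the top
(|rho| >= 0.3, capped at 100) genes, and test user-supplied gene sets
(GMT) for over-representation with a one-sided hypergeometric test,
BH-adjusted across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from histomorph.mutassoc import benjamini_hochberg


def spearman_profile(feature: pd.Series, expression: pd.DataFrame) -> pd.Series:
    """Spearman rho between one feature and every gene's expression.

    ``expression`` is genes x patients.  Patients are matched on the
    intersection of indices (at least 10 required).  Ties get average
    ranks; genes with missing values are correlated over their pairwise
    complete patients.
    """
    shared = sorted(set(feature.index) & set(expression.columns))
    if len(shared) < 10:
        raise ValueError(f"need >= 10 shared patients, got {len(shared)}")
    f = feature.loc[shared].to_numpy(dtype=float)
    E = expression[shared].to_numpy(dtype=float)

    out = np.full(E.shape[0], np.nan)
    complete = ~np.isnan(E).any(axis=1)
    if complete.any():
        rf = sps.rankdata(f)
        RG = sps.rankdata(E[complete], axis=1)
        rf_c = rf - rf.mean()
        RG_c = RG - RG.mean(axis=1, keepdims=True)
        denom = np.sqrt((RG_c**2).sum(axis=1) * (rf_c**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            out[complete] = (RG_c @ rf_c) / denom
    for i in np.flatnonzero(~complete):
        g = E[i]
        ok = ~np.isnan(g)
        if ok.sum() >= 3:
            out[i] = sps.spearmanr(f[ok], g[ok]).statistic
    return pd.Series(out, index=expression.index, name=str(feature.name))


@dataclass
class TopGenes:
    """Genes selected for enrichment, or a flagged skip when too few
    genes pass the correlation threshold."""

    genes: list[str]
    rho: pd.Series
    skipped: bool


def select_top_genes(
    profile: pd.Series,
    threshold: float = 0.3,
    cap: int = 100,
    min_genes: int = 10,
    strict_gt: bool = False,
) -> TopGenes:
    """Top correlated genes: |rho| >= threshold (or > with
    ``strict_gt``), ranked by |rho| descending (ties alphabetical),
    truncated at ``cap``.  If fewer than ``min_genes`` qualify the
    result is flagged ``skipped`` and enrichment should not be run.
    """
    rho = profile.dropna()
    a = rho.abs()
    qual = a > threshold if strict_gt else a >= threshold
    ranked = sorted(rho.index[qual], key=lambda g: (-a[g], g))[:cap]
    return TopGenes(genes=list(ranked), rho=rho.loc[ranked], skipped=len(ranked) < min_genes)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: one gene set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3 and parts[0]:
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def hypergeometric_enrichment(
    query: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each
    gene set, with BH q-values across sets.

    Sets are intersected with the universe first; the query must be a
    subset of the universe.  Sorted by ascending p.
    """
    uni = set(universe)
    q = set(query)
    if not uni:
        raise ValueError("empty universe")
    if not q:
        raise ValueError("empty query gene set")
    if not q <= uni:
        missing = sorted(q - uni)[:5]
        raise ValueError(f"query genes outside universe, e.g. {missing}")
    M, n = len(uni), len(q)
    rows = []
    for name, members in gene_sets.items():
        s = set(members) & uni
        if not s:
            continue
        k = len(s & q)
        p = float(sps.hypergeom.sf(k - 1, M, len(s), n))
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": len(s),
                "query_size": n,
                "universe_size": M,
                "p": min(max(p, np.nextafter(0, 1)), 1.0),
            }
        )
    table = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size", "query_size", "universe_size", "p"])
    if len(table):
        table["q"] = benjamini_hochberg(table["p"].to_numpy())
    else:
        table["q"] = []
    return table.sort_values(["p", "gene_set"]).reset_index(drop=True)
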