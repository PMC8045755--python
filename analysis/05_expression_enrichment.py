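"""Image-feature / gene-expression integration on the demo cohort.

For the most frequently selected prognostic features (from
04_prognostic_model.py), compute Spearman correlations with every
gene's expression, select the top correlated genes (|rho| >= 0.3,
capped at 100), and test the synthetic gene sets for hypergeometric
over-representation.  The demo plants three driven genes, one per
prognostic feature, collected in the DRIVEN_SET gene set.

Writes results/correlation_<feature>.csv and
results/enrichment_<feature>.csv.

Run from the repository root:  python analysis/05_expression_enrichment.py
"""

from pathlib import Path

import pandas as pd

from histomorph.exprcorr import (
    hypergeometric_enrichment,
    read_gmt,
    select_top_genes,
    spearman_profile,
)

ROOT = Path(__file__).resolve().parents[1]
DEMO = ROOT / "scratch" / "demo"
RESULTS = ROOT / "results"

if __name__ == "__main__":
    RESULTS.mkdir(exist_ok=True)
    features = pd.read_csv(DEMO / "features.csv", index_col=0)
    expression = pd.read_csv(DEMO / "expression.csv", index_col=0)
    gene_sets = read_gmt(DEMO / "sets.gmt")
    selection = pd.read_csv(RESULTS / "selection.csv")
    top_features = selection.loc[selection["frequency"] > 0.8, "feature"].head(5)

    for feat in top_features:
        profile = spearman_profile(features[feat], expression)
        profile.rename("spearman_rho").to_csv(RESULTS / f"correlation_{feat}.csv")
        top = select_top_genes(profile, threshold=0.3, cap=100, min_genes=3)
        print(f"{feat}: {len(top.genes)} genes at |rho| >= 0.3", end="")
        if top.skipped:
            print("  (too few; enrichment skipped)")
            continue
        enr = hypergeometric_enrichment(top.genes, gene_sets, list(expression.index))
        enr.to_csv(RESULTS / f"enrichment_{feat}.csv", index=False)
        best = enr.iloc[0]
        print(f"; top set {best['gene_set']} (overlap {best['overlap']}, q={best['q']:.3g})")
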