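"""Generate the synthetic study inputs.

Two kinds of data are produced under scratch/demo/:

* an imaging cohort — 20 patients x 1 tile of elliptical nuclei with
  ground-truth masks and nucleus tables, for the segmentation ->
  morphometry -> aggregation path;
* a statistical cohort — 200 patients with the 150 canonical
  patient-level features, a planted TP53-like mutation shifting
  area_mean by 1.5 pooled SD at 50% frequency, a 3-feature
  proportional-hazards survival signal, an expression matrix with 13
  feature-driven genes plus 300 noise genes, and a toy GMT gene-set
  file whose DRIVEN_SET collects the genes tied to area_bin6.

Run from the repository root:  python analysis/01_simulate.py
"""

import json
from pathlib import Path

import numpy as np

from histomorph.pipeline import write_mask_png
from histomorph.studies import PLANTED_BETAS
from histomorph.synthdata import (
    CohortSpec,
    TileSpec,
    generate_cohort,
    generate_expression,
    generate_tile,
)

SEED = 20260923
ROOT = Path(__file__).resolve().parents[1]
DEMO = ROOT / "scratch" / "demo"

import imageio.v3 as iio  # noqa: E402


def simulate_tiles() -> None:
    rng = np.random.default_rng(SEED)
    for i in range(20):
        pid = f"P{i + 1:04d}"
        (DEMO / "tiles" / pid).mkdir(parents=True, exist_ok=True)
        (DEMO / "truth" / pid).mkdir(parents=True, exist_ok=True)
        spec = TileSpec(
            n_nuclei=60,
            area_mean=float(rng.uniform(160, 260)),
            ratio_mean=float(rng.uniform(1.2, 1.9)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, mask, truth = generate_tile(spec)
        iio.imwrite(DEMO / "tiles" / pid / "tile1.png", image)
        write_mask_png(DEMO / "truth" / pid / "tile1.png", mask)
        truth.to_csv(DEMO / "truth" / pid / "tile1.csv", index=False)
    print(f"wrote 20 patients x 1 tile under {DEMO / 'tiles'}")


def simulate_cohort() -> None:
    # ten "cell-cycle-like" genes driven by the planted prognostic
    # feature area_bin6, three by minor_mean
    driven = tuple(
        (f"CCG{i + 1:02d}", "area_bin6", s)
        for i, s in enumerate([0.6, 0.55, 0.5, 0.5, 0.45, 0.45, 0.4, 0.4, 0.35, 0.35])
    ) + tuple((f"MMG{i + 1}", "minor_mean", -0.5) for i in range(3))
    spec = CohortSpec(
        n_patients=200,
        mutation_genes=(("TP53", 0.5, "area_mean", 1.5),),
        cox_betas=PLANTED_BETAS,
        expression_genes=driven,
        n_noise_genes=300,
        seed=SEED,
    )
    cohort, truth = generate_cohort(spec)
    expr = generate_expression(cohort, spec)
    feature_cols = [c for c in cohort.columns if not c.startswith(("mut_", "time_", "event"))]
    cohort[feature_cols].to_csv(DEMO / "features.csv")
    cohort[["time_months", "event"]].to_csv(DEMO / "clinical.csv")
    muts = cohort[["mut_TP53"]].rename(columns={"mut_TP53": "TP53"})
    muts.to_csv(DEMO / "mutations.csv")
    expr.to_csv(DEMO / "expression.csv")
    (DEMO / "truth.json").write_text(json.dumps(truth, indent=1))
    # toy gene sets: one enriched in the driven genes, two random
    rng = np.random.default_rng(SEED + 1)
    noise = [g for g in expr.index if g.startswith("GENE")]
    sets = {
        "DRIVEN_SET": [f"CCG{i + 1:02d}" for i in range(10)]
        + list(rng.choice(noise, 5, replace=False)),
        "RANDOM_SET_A": list(rng.choice(noise, 25, replace=False)),
        "RANDOM_SET_B": list(rng.choice(noise, 25, replace=False)),
    }
    lines = [f"{name}\tsynthetic\t" + "\t".join(genes) for name, genes in sets.items()]
    (DEMO / "sets.gmt").write_text("\n".join(lines) + "\n")
    print(
        f"wrote statistical cohort (n=200, {int(muts['TP53'].sum())} TP53-mutant, "
        f"{int(cohort['event'].sum())} deaths) under {DEMO}"
    )


if __name__ == "__main__":
    DEMO.mkdir(parents=True, exist_ok=True)
    simulate_tiles()
    simulate_cohort()
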