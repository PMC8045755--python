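"""Cohort-level simulation studies: calibration and power.

Each study repeatedly draws synthetic cohorts from
:mod:`histomorph.synthdata` under stated conditions, runs the relevant
pipeline stage, and tallies a rate:

* type-I calibration of the log-rank screening filter and of the
  mutation-association tests under null cohorts (no planted effects);
* a selection-bias audit of the full LOOCV stratification under the
  global null (its final log-rank p must not be anti-conservative);
* power / recovery under planted effects: lasso sign recovery of a
  3-feature proportional-hazards signal, LOOCV stratification power,
  detection of a mutation-linked feature shift, and univariable Cox CI
  coverage of a known hazard ratio.

All functions are deterministic given ``seed``; replicate cohorts use
seeds ``seed, seed+1, ...``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from histomorph.mutassoc import run_association
from histomorph.patientfeat import feature_names
from histomorph.survmodel import (
    cox_regression,
    fit_lasso_cox,
    logrank_filter,
    logrank_test,
    loocv_risk_indices,
)
from histomorph.synthdata import CohortSpec, generate_cohort

#: Features carrying the planted survival signal in the recovery studies.
PLANTED_BETAS = {"area_bin6": 0.8, "minor_mean": -0.8, "bMean_bin10": 0.8}


def _seed_range(seed: int, n: int) -> range:
    return range(seed, seed + n)


def filter_type1_rate(n_patients: int = 200, n_seeds: int = 100, seed: int = 0) -> float:
    """Fraction of null features retained by the log-rank filter.

    Every feature of every null cohort is an independent null trial, so
    the rate is pooled over 150 features x ``n_seeds`` cohorts; it
    should sit near the filter's nominal alpha of 0.05.
    """
    names = feature_names()
    retained = total = 0
    for s in _seed_range(seed, n_seeds):
        cohort, _ = generate_cohort(CohortSpec(n_patients=n_patients, seed=s))
        kept = logrank_filter(cohort[names], cohort["time_months"], cohort["event"])
        retained += len(kept)
        total += len(names)
    return retained / total


def association_type1_rate(
    n_patients: int = 200, n_seeds: int = 100, seed: int = 0
) -> float:
    """Raw p < 0.05 rate of the Mann-Whitney association tests under a
    null cohort with one mutation label (frequency 0.5, zero shift)."""
    names = feature_names()
    hits = total = 0
    for s in _seed_range(seed, n_seeds):
        spec = CohortSpec(
            n_patients=n_patients,
            mutation_genes=(("NULLGENE", 0.5, "area_mean", 0.0),),
            seed=s,
        )
        cohort, _ = generate_cohort(spec)
        mut = cohort[["mut_NULLGENE"]].rename(columns={"mut_NULLGENE": "NULLGENE"})
        table = run_association(cohort[names], mut)
        hits += int((table["p"] < 0.05).sum())
        total += len(table)
    return hits / total


def null_stratification_rate(
    n_patients: int = 100, n_seeds: int = 50, seed: int = 0, alpha: float = 0.05
) -> float:
    """Fraction of null cohorts whose LOOCV median-split stratification
    reaches log-rank p < ``alpha``.

    Under the global null this must not exceed ~2x nominal; a higher
    rate would mean the leave-one-out protocol leaks survival
    information into the risk index.  A degenerate risk distribution
    (every fold empty) counts as not significant.
    """
    names = feature_names()
    hits = 0
    for s in _seed_range(seed, n_seeds):
        cohort, _ = generate_cohort(CohortSpec(n_patients=n_patients, seed=s))
        try:
            result, _ = loocv_risk_indices(
                cohort[names], cohort["time_months"], cohort["event"], seed=s
            )
        except ValueError:
            continue
        groups = (result.group == "high-risk").astype(int).to_numpy()
        if groups.sum() in (0, groups.size):
            continue
        _, p = logrank_test(
            groups,
            cohort.loc[result.risk.index, "time_months"].to_numpy(),
            cohort.loc[result.risk.index, "event"].to_numpy(),
        )
        hits += p < alpha
    return hits / n_seeds


def lasso_sign_recovery_rate(
    n_patients: int = 300, n_seeds: int = 100, seed: int = 0
) -> float:
    """Fraction of planted-signal cohorts where the lasso-Cox fit gives
    every planted feature a nonzero coefficient of the correct sign."""
    names = feature_names()
    hits = 0
    for s in _seed_range(seed, n_seeds):
        cohort, _ = generate_cohort(
            CohortSpec(n_patients=n_patients, cox_betas=PLANTED_BETAS, seed=s)
        )
        model = fit_lasso_cox(
            cohort[names], cohort["time_months"], cohort["event"], seed=s
        )
        hits += all(
            np.sign(model.coefficients.get(f, 0.0)) == np.sign(b)
            for f, b in PLANTED_BETAS.items()
        )
    return hits / n_seeds


def stratification_power_rate(
    n_patients: int = 300, n_seeds: int = 25, seed: int = 0, p_threshold: float = 0.01
) -> float:
    """Fraction of planted-signal cohorts whose LOOCV median split
    separates survival at log-rank p < ``p_threshold``."""
    names = feature_names()
    hits = 0
    for s in _seed_range(seed, n_seeds):
        cohort, _ = generate_cohort(
            CohortSpec(n_patients=n_patients, cox_betas=PLANTED_BETAS, seed=s)
        )
        result, _ = loocv_risk_indices(
            cohort[names], cohort["time_months"], cohort["event"], seed=s
        )
        _, p = logrank_test(
            (result.group == "high-risk").astype(int).to_numpy(),
            cohort.loc[result.risk.index, "time_months"].to_numpy(),
            cohort.loc[result.risk.index, "event"].to_numpy(),
        )
        hits += p < p_threshold
    return hits / n_seeds


def mutation_shift_power_rate(
    n_patients: int = 200,
    effect_size: float = 1.5,
    frequency: float = 0.5,
    n_seeds: int = 100,
    seed: int = 0,
) -> float:
    """Fraction of cohorts where a planted mutation-linked shift of
    ``effect_size`` pooled SD on one feature is called significant
    (q < 0.05) by the association pipeline."""
    names = feature_names()
    hits = 0
    for s in _seed_range(seed, n_seeds):
        spec = CohortSpec(
            n_patients=n_patients,
            mutation_genes=(("G", frequency, "area_mean", effect_size),),
            seed=s,
        )
        cohort, _ = generate_cohort(spec)
        mut = cohort[["mut_G"]].rename(columns={"mut_G": "G"})
        table = run_association(cohort[names], mut)
        q = table.loc[table["feature"] == "area_mean", "q"].iloc[0]
        hits += q < 0.05
    return hits / n_seeds


def cox_hr_coverage(
    true_hr: float = 2.0, n_patients: int = 300, n_seeds: int = 100, seed: int = 0
) -> float:
    """Coverage of the univariable Cox 95% CI for a known hazard ratio
    between two equal groups with exponential survival."""
    hits = 0
    for s in _seed_range(seed, n_seeds):
        rng = np.random.default_rng(s)
        g = np.repeat([0, 1], n_patients // 2)
        t_event = rng.exponential(1.0 / (0.05 * true_hr**g))
        t_cens = rng.exponential(1.0 / 0.02, size=g.size)
        t = np.minimum(t_event, t_cens)
        e = (t_event <= t_cens).astype(int)
        out = cox_regression(t, e, pd.DataFrame({"g": g}), mode="univariable")
        hits += out["ci_low"].iloc[0] <= true_hr <= out["ci_high"].iloc[0]
    return hits / n_seeds


def segmentation_recovery(seed: int = 7, n_nuclei: int = 50) -> dict:
    """Detection statistics on one well-separated synthetic tile:
    matched nuclei (centroid within 5 px), spurious detections, and the
    worst matched-area relative error."""
    from scipy.spatial import cKDTree

    from histomorph.imaging import segment_nuclei
    from histomorph.synthdata import TileSpec, generate_tile

    image, _, truth = generate_tile(
        TileSpec(n_nuclei=n_nuclei, min_separation=30, seed=seed)
    )
    result = segment_nuclei(image)
    if result.n_nuclei == 0:
        return {"matched": 0, "spurious": 0, "n_true": len(truth), "max_area_error": np.nan}
    tree = cKDTree(result.centroids)
    d, idx = tree.query(truth[["row", "col"]].to_numpy())
    matched = d <= 5
    ratios = result.areas[idx[matched]] / truth.loc[matched, "area"].to_numpy()
    return {
        "matched": int(matched.sum()),
        "spurious": int(result.n_nuclei - len(set(idx[matched]))),
        "n_true": int(len(truth)),
        "max_area_error": float(np.abs(ratios - 1).max()) if matched.any() else np.nan,
    }
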