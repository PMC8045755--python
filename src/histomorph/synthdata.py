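"""Ground-truthed synthetic data: tiles, cohorts, expression.

Three generators emulate the statistical structure the pipeline assumes:

* :func:`generate_tile` draws elliptical "nuclei" with lognormal areas and
  aspect ratios on a uniform background, with a hard-core minimum
  separation between centroids, returning the RGB image, an instance
  label mask, and a ground-truth nucleus table.
* :func:`generate_cohort` draws a patient cohort whose 150 patient-level
  features are independent Gaussians, plants mutation-linked feature
  shifts (in pooled-SD units) and proportional-hazards survival signal
  (exponential baseline, independent exponential censoring, months).
* :func:`generate_expression` emits a gene x patient matrix where chosen
  genes are noisy monotone transforms of chosen features at a target
  Spearman strength and the remaining genes are independent noise.

Everything is seed-deterministic: identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from histomorph.patientfeat import feature_names

_MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class TileSpec:
    """Parameters of one synthetic tile.

    ``area_mean``/``area_sd`` are the mean and SD (px^2) of the lognormal
    nucleus-area distribution; ``ratio_mean``/``ratio_sd`` likewise for
    the major/minor aspect ratio (clipped to >= 1).  ``min_separation``
    is a hard-core minimum distance between nucleus centroids in px.
    """

    width: int = 512
    height: int = 512
    n_nuclei: int = 50
    area_mean: float = 200.0
    area_sd: float = 60.0
    ratio_mean: float = 1.5
    ratio_sd: float = 0.35
    nucleus_color: tuple[int, int, int] = (88, 60, 150)
    background_color: tuple[int, int, int] = (232, 212, 224)
    min_separation: float = 25.0
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("tile dimensions must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.area_mean <= 0:
            raise ValueError("area_mean must be > 0")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


class OvercrowdedTileError(RuntimeError):
    """Raised when nuclei cannot be placed at the requested separation."""


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given natural-scale mean/SD."""
    if sd <= 0:
        return float(np.log(mean)), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


def generate_tile(
    spec: TileSpec,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one synthetic tile.

    Returns
    -------
    image : uint8 array (height, width, 3)
    mask : uint16 array (height, width), labels 1..n_nuclei, 0 background
    truth : DataFrame with one row per nucleus
        Columns: id, row, col (centroid), area (drawn pixel count),
        major, minor (full axis lengths, px), ratio, orientation (rad).

    Raises
    ------
    OvercrowdedTileError
        If a nucleus cannot be placed within the attempt budget.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=np.uint16)
    image = np.empty((h, w, 3), dtype=float)
    image[:] = np.asarray(spec.background_color, dtype=float)

    mu_a, sg_a = _lognormal_params(spec.area_mean, spec.area_sd)
    mu_r, sg_r = _lognormal_params(spec.ratio_mean, spec.ratio_sd)

    rows_out = []
    centers: list[tuple[float, float]] = []
    for k in range(spec.n_nuclei):
        area = float(rng.lognormal(mu_a, sg_a))
        ratio = max(1.0, float(rng.lognormal(mu_r, sg_r)))
        b = np.sqrt(area / (np.pi * ratio))  # semi-minor
        a = b * ratio  # semi-major
        theta = float(rng.uniform(0.0, np.pi))
        placed = False
        for _ in range(_MAX_ATTEMPTS):
            margin = a + 1.0
            if 2 * margin >= min(h, w):
                break
            r0 = float(rng.uniform(margin, h - margin))
            c0 = float(rng.uniform(margin, w - margin))
            if centers:
                d2 = [(r0 - r) ** 2 + (c0 - c) ** 2 for r, c in centers]
                if min(d2) < spec.min_separation**2:
                    continue
            rr, cc = draw_ellipse(r0, c0, a, b, shape=(h, w), rotation=theta)
            if rr.size == 0 or mask[rr, cc].any():
                continue
            mask[rr, cc] = k + 1
            jitter = rng.normal(0.0, 3.0, size=3)
            image[rr, cc] = np.clip(np.asarray(spec.nucleus_color, float) + jitter, 0, 255)
            centers.append((r0, c0))
            rows_out.append(
                {
                    "id": k + 1,
                    "row": r0,
                    "col": c0,
                    "area": int(rr.size),
                    "major": 2.0 * a,
                    "minor": 2.0 * b,
                    "ratio": ratio,
                    "orientation": theta,
                }
            )
            placed = True
            break
        if not placed:
            raise OvercrowdedTileError(
                f"overcrowded tile: could not place nucleus {k + 1}/{spec.n_nuclei} "
                f"at min_separation={spec.min_separation} within {_MAX_ATTEMPTS} attempts"
            )

    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)
    truth = pd.DataFrame(
        rows_out,
        columns=["id", "row", "col", "area", "major", "minor", "ratio", "orientation"],
    )
    return image, mask, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Statistical design of a synthetic patient cohort.

    mutation_genes : list of (gene, frequency, feature, effect_size)
        Each gene is mutated with the given Bernoulli frequency; mutated
        patients have the named patient-level feature shifted by
        effect_size pooled standard deviations.
    cox_betas : feature -> planted log-hazard coefficient
        Applied to the z-scored feature in an exponential
        proportional-hazards model with rate
        ``baseline_hazard * exp(sum beta_j z_j)`` (per month).
    censoring_rate : independent exponential censoring rate (per month).
    expression_genes : list of (gene, driving feature, target Spearman).
    n_noise_genes : additional independent-noise genes in the
        expression matrix.
    """

    n_patients: int = 200
    mutation_genes: tuple[tuple[str, float, str, float], ...] = ()
    cox_betas: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.015
    expression_genes: tuple[tuple[str, str, float], ...] = ()
    n_noise_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        valid = set(feature_names())
        for gene, freq, feat, _ in self.mutation_genes:
            if not 0.0 < freq < 1.0:
                raise ValueError(f"{gene}: mutation frequency must be in (0,1)")
            _check_feature(feat, valid)
        for feat in self.cox_betas:
            _check_feature(feat, valid)
        for _, feat, _ in self.expression_genes:
            _check_feature(feat, valid)
        object.__setattr__(self, "mutation_genes", tuple(self.mutation_genes))
        object.__setattr__(self, "expression_genes", tuple(self.expression_genes))


def _check_feature(name: str, valid: set[str]) -> None:
    if name not in valid:
        preview = ", ".join(sorted(valid)[:5])
        raise ValueError(
            f"unknown feature name {name!r}; valid names are the 150 canonical "
            f"patient-level features ({preview}, ...)"
        )


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table with planted mutation and survival structure.

    The 150 patient-level features are modeled directly as independent
    Gaussians with unit SD around a positive baseline of 10 (the tile ->
    aggregation path produces genuinely constrained feature vectors;
    this generator targets the cohort-level statistics the downstream
    tests consume, and the positive baseline keeps median-ratio fold
    changes well-defined).  Mutation shifts are
    ``effect_size x pooled SD`` added to mutated patients; survival times
    are exponential with rate ``baseline_hazard * exp(sum beta z)`` on
    z-scored (post-shift) features, censored by an independent
    exponential clock.

    Returns
    -------
    cohort : DataFrame indexed by patient id
        150 feature columns, ``mut_<gene>`` binary columns,
        ``time_months`` and ``event``.
    truth : dict
        Planted labels, shifts, and betas.
    """
    rng = np.random.default_rng(spec.seed)
    names = feature_names()
    n = spec.n_patients
    X = 10.0 + rng.standard_normal((n, len(names)))
    df = pd.DataFrame(X, columns=names)
    df.index = [f"P{i + 1:04d}" for i in range(n)]
    df.index.name = "patient_id"

    truth: dict = {"mutations": {}, "shifts": {}, "betas": dict(spec.cox_betas)}
    for gene, freq, feat, effect in spec.mutation_genes:
        labels = (rng.random(n) < freq).astype(int)
        pooled_sd = float(df[feat].std(ddof=0))
        df.loc[labels == 1, feat] += effect * pooled_sd
        df[f"mut_{gene}"] = labels
        truth["mutations"][gene] = labels.tolist()
        truth["shifts"][gene] = {"feature": feat, "effect_size": effect, "pooled_sd": pooled_sd}

    z = (df[names] - df[names].mean()) / df[names].std(ddof=0).replace(0.0, 1.0)
    lp = np.zeros(n)
    for feat, beta in spec.cox_betas.items():
        lp += beta * z[feat].to_numpy()
    rate = spec.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if spec.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    df["time_months"] = np.minimum(t_event, t_cens)
    df["event"] = (t_event <= t_cens).astype(int)
    truth["linear_predictor"] = lp.tolist()
    return df, truth


def generate_expression(cohort: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Draw a gene x patient expression matrix tied to cohort features.

    Each driven gene is a monotone (linear) transform of the z-scored
    driving feature mixed with Gaussian noise; for bivariate normal data
    with Pearson correlation r the Spearman correlation is
    (6/pi)*asin(r/2), so the mixing weight is chosen by inverting that
    relation at the target strength.  A target of +/-1 yields zero noise
    and hence an exactly monotone transform (Spearman exactly +/-1).
    Undriven ("noise") genes are independent standard normals.
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)
    n = len(cohort)
    rows = {}
    for gene, feat, strength in spec.expression_genes:
        if not -1.0 <= strength <= 1.0:
            raise ValueError(f"{gene}: target Spearman strength must be in [-1, 1]")
        r = 2.0 * np.sin(np.pi * strength / 6.0)  # Pearson giving that Spearman
        f = cohort[feat].to_numpy(dtype=float)
        zf = (f - f.mean()) / (f.std() or 1.0)
        noise = rng.standard_normal(n)
        rows[gene] = r * zf + np.sqrt(max(0.0, 1.0 - r * r)) * noise
    for i in range(spec.n_noise_genes):
        rows[f"GENE{i + 1:05d}"] = rng.standard_normal(n)
    expr = pd.DataFrame(rows, index=cohort.index).T
    expr.index.name = "gene"
    return expr
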