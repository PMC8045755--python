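"""Patient-level feature aggregation.

Each patient's nuclei (pooled over all of their slides) are summarized,
per cell-level feature, into a 10-bin histogram of proportions plus five
distribution statistics (mean, std, skewness, kurtosis, entropy), giving
10 x 15 = 150 patient-level features.  Histogram bin edges are fitted once
on a reference cohort and reused verbatim for every patient so that the
histogram features are comparable across patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: The 10 cell-level features, in canonical order.
CELL_FEATURES: tuple[str, ...] = (
    "area",
    "major",
    "minor",
    "ratio",
    "rMean",
    "gMean",
    "bMean",
    "distMean",
    "distMax",
    "distMin",
)

#: Per cell-level feature: bins 1-10 then the five statistics.
_SUFFIXES: tuple[str, ...] = tuple(f"bin{i}" for i in range(1, 11)) + (
    "mean",
    "std",
    "skewness",
    "kurtosis",
    "entropy",
)

N_BINS = 10


def feature_names() -> list[str]:
    """Return the 150 canonical patient-level feature names in order.

    Features are grouped by cell-level feature; within each group the
    order is ``<F>_bin1`` .. ``<F>_bin10``, ``<F>_mean``, ``<F>_std``,
    ``<F>_skewness``, ``<F>_kurtosis``, ``<F>_entropy``.
    """
    return [f"{feat}_{suf}" for feat in CELL_FEATURES for suf in _SUFFIXES]


def _nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * n)-th order statistic."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    k = int(np.ceil(pct / 100.0 * n))
    k = min(max(k, 1), n)
    return float(v[k - 1])


@dataclass(frozen=True)
class BinScheme:
    """Cohort-shared histogram bin edges: 11 strictly increasing edges
    (10 bins) per cell-level feature."""

    edges: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, e in self.edges.items():
            e = np.asarray(e, dtype=float)
            if e.shape != (N_BINS + 1,):
                raise ValueError(f"{name}: expected {N_BINS + 1} edges, got {e.shape}")
            if not np.all(np.diff(e) > 0):
                raise ValueError(f"{name}: edges must be strictly increasing")
            object.__setattr__(self, "edges", {**self.edges, name: e})

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_bins": N_BINS,
            "derivation": "equal-width over [P1, P99] (nearest-rank) of pooled reference values",
            "edges": {k: [float(x) for x in v] for k, v in self.edges.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BinScheme":
        payload = json.loads(Path(path).read_text())
        return cls(edges={k: np.asarray(v, dtype=float) for k, v in payload["edges"].items()})


def fit_bin_scheme(pooled: dict[str, np.ndarray]) -> BinScheme:
    """Fit the cohort-shared bin scheme from pooled cell-level values.

    For each feature, bins are 10 equal-width intervals spanning the
    nearest-rank 1st to 99th percentile of the pooled values; the
    percentile clamp keeps extreme outliers from stretching the bins.

    Parameters
    ----------
    pooled
        Mapping from cell-level feature name to the 1-D array of that
        feature's values pooled over the reference cohort's nuclei.

    Raises
    ------
    ValueError
        If a feature's pooled values are (effectively) constant, making
        an equal-width split impossible ("degenerate feature range").
    """
    edges: dict[str, np.ndarray] = {}
    for name, values in pooled.items():
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            raise ValueError(f"{name}: need at least 2 finite pooled values")
        lo = _nearest_rank_percentile(v, 1)
        hi = _nearest_rank_percentile(v, 99)
        if hi <= lo:
            raise ValueError(f"{name}: degenerate feature range [{lo}, {hi}]")
        edges[name] = np.linspace(lo, hi, N_BINS + 1)
    return BinScheme(edges=edges)


def _histogram_proportions(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # Values below the first edge count in bin 1, above the last in bin 10.
    clipped = np.clip(values, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return counts / values.size


def _shannon_entropy(proportions: np.ndarray) -> float:
    p = proportions[proportions > 0]
    return float(-np.sum(p * np.log(p)))


def _summarize(values: np.ndarray, edges: np.ndarray) -> dict[str, float]:
    props = _histogram_proportions(values, edges)
    out = {f"bin{i + 1}": float(props[i]) for i in range(N_BINS)}
    mean = float(np.mean(values))
    dev = values - mean
    m2 = float(np.mean(dev**2))  # population variance
    out["mean"] = mean
    out["std"] = float(np.sqrt(m2))
    # Moment coefficients: g1 = m3/m2^1.5, non-excess kurtosis m4/m2^2;
    # both defined as 0 for an (effectively) constant sample.
    if m2 > (1e-9 * max(1.0, abs(mean))) ** 2:
        out["skewness"] = float(np.mean(dev**3) / m2**1.5)
        out["kurtosis"] = float(np.mean(dev**4) / m2**2)
    else:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    out["entropy"] = _shannon_entropy(props)
    return out


def aggregate_patient(
    cell_tables: list[pd.DataFrame] | pd.DataFrame, scheme: BinScheme
) -> pd.Series:
    """Aggregate one patient's cell-level tables into the 150-feature vector.

    All slides of the patient are pooled into a single cell table before
    aggregation, so the result is invariant to how cells are split across
    slides.  Histogram entries are proportions of cells per bin; the five
    statistics are computed on the raw (unbinned) values.  Nuclei with
    missing distance features (isolated nodes) are excluded from the
    distance-feature aggregation only.

    Raises
    ------
    ValueError
        If the patient has no nuclei at all ("empty patient").
    """
    if isinstance(cell_tables, pd.DataFrame):
        cell_tables = [cell_tables]
    pooled = pd.concat(cell_tables, ignore_index=True) if cell_tables else pd.DataFrame()
    if pooled.empty:
        raise ValueError("empty patient: no nuclei across slides")

    out: dict[str, float] = {}
    for feat in CELL_FEATURES:
        if feat not in pooled.columns:
            raise KeyError(f"cell table missing feature column {feat!r}")
        values = pooled[feat].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            # e.g. every nucleus isolated: distance block undefined
            for suf in _SUFFIXES:
                out[f"{feat}_{suf}"] = np.nan
            continue
        summary = _summarize(values, scheme.edges[feat])
        for suf in _SUFFIXES:
            out[f"{feat}_{suf}"] = summary[suf]
    return pd.Series(out, index=feature_names(), name=str(pooled.get("patient_id", [None])[0] or ""))


def aggregate_cohort(
    cells_by_patient: dict[str, list[pd.DataFrame] | pd.DataFrame],
    scheme: BinScheme | None = None,
) -> tuple[pd.DataFrame, BinScheme]:
    """Aggregate every patient of a cohort; fit the bin scheme on the
    cohort's pooled cells if none is supplied.

    Returns the (patients x 150) feature matrix and the scheme used.
    """
    if scheme is None:
        frames = []
        for tables in cells_by_patient.values():
            if isinstance(tables, pd.DataFrame):
                frames.append(tables)
            else:
                frames.extend(tables)
        pooled_all = pd.concat(frames, ignore_index=True)
        scheme = fit_bin_scheme(
            {f: pooled_all[f].dropna().to_numpy(dtype=float) for f in CELL_FEATURES}
        )
    rows = {pid: aggregate_patient(tables, scheme) for pid, tables in cells_by_patient.items()}
    matrix = pd.DataFrame.from_dict(rows, orient="index")[feature_names()]
    matrix.index.name = "patient_id"
    return matrix, scheme
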