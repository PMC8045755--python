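"""Prognostic modeling: log-rank filtering, lasso-penalized Cox, and
leave-one-out cross-validated risk indices.

Within each leave-one-out fold, every patient-level feature is
dichotomized at the training median and screened with an (uncorrected)
two-group log-rank test at p < 0.05; the retained features enter an
L1-penalized Cox model whose regularization strength is chosen by
10-fold cross-validated partial log-likelihood (Verweij & van
Houwelingen).  The held-out patient's risk index is the linear predictor
of their (training-standardized) features under the fold's coefficients.
After all folds, patients are split at the median risk index into
low-risk and high-risk groups.

The two-group log-rank statistic is implemented directly (and
vectorized across features, which makes the per-fold screening cheap);
lifelines serves as the independent oracle in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv


# ---------------------------------------------------------------------------
# Log-rank


def logrank_statistics(
    groups: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-group log-rank chi-square over feature columns.

    ``groups`` is an (n,) or (n, p) binary array: column j defines the
    "group 1" membership for test j.  Returns (chi2, p) arrays of length
    p.  A column with an empty group (zero variance split) yields
    chi2 = 0, p = 1.
    """
    G = np.asarray(groups, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = G.shape
    order = np.argsort(time, kind="stable")
    t_s, e_s, G_s = time[order], event[order], G[order]
    # suffix sums: group-1 members at risk from index i onward
    suffix = np.vstack([np.cumsum(G_s[::-1], axis=0)[::-1], np.zeros((1, p))])

    _, first = np.unique(t_s, return_index=True)
    d = np.add.reduceat(e_s, first)  # events per distinct time
    d1 = np.add.reduceat(G_s * e_s[:, None], first, axis=0)  # group-1 events
    n_at = (n - first).astype(float)
    n1 = suffix[first]
    mask = d > 0
    d, d1, n_at, n1 = d[mask], d1[mask], n_at[mask], n1[mask]
    O1 = d1.sum(axis=0)
    E1 = (d[:, None] * n1 / n_at[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_terms = (
            d[:, None]
            * (n_at - d)[:, None]
            * n1
            * (n_at[:, None] - n1)
            / (n_at**2 * (n_at - 1))[:, None]
        )
        v_terms[n_at <= 1] = 0.0
        V = v_terms.sum(axis=0)
        chi2 = np.where(V > 0, (O1 - E1) ** 2 / V, 0.0)
    pvals = np.where(V > 0, sps.chi2.sf(chi2, df=1), 1.0)
    return chi2, pvals


def logrank_test(groups, time, event) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi-square, p).

    Both groups must be non-empty.
    """
    g = np.asarray(groups, dtype=int)
    if g.sum() == 0 or g.sum() == g.size:
        raise ValueError("both groups must contain at least one patient")
    chi2, p = logrank_statistics(g, time, event)
    return float(chi2[0]), float(p[0])


def logrank_filter(
    features: pd.DataFrame, time, event, alpha: float = 0.05
) -> list[str]:
    """Median-dichotomized log-rank screening of every feature.

    Each feature is split at its (training) median, with ties assigned
    to the ">= median" group; features whose two-group log-rank p is
    below ``alpha`` are retained.  No multiplicity correction is applied
    at this screening step, to keep trending features.  Zero-variance
    features are never retained (their split is degenerate).
    """
    X = features.to_numpy(dtype=float)
    med = np.median(X, axis=0)
    G = (X >= med).astype(float)
    # degenerate splits (all True / all False) yield p = 1 automatically
    _, pvals = logrank_statistics(G, np.asarray(time, float), np.asarray(event, int))
    empty = (G.sum(axis=0) == 0) | (G.sum(axis=0) == G.shape[0])
    return [f for f, pv, bad in zip(features.columns, pvals, empty) if not bad and pv < alpha]


# ---------------------------------------------------------------------------
# Partial likelihood and lasso-Cox


def breslow_loglik_multi(LP: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Breslow partial log-likelihood for each column of ``LP`` (n, k)."""
    LP = np.asarray(LP, dtype=float)
    if LP.ndim == 1:
        LP = LP[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t_s, e_s, lp_s = time[order], event[order], LP[order]
    # suffix log-sum-exp per column (stabilized)
    mx = lp_s.max(axis=0, keepdims=True)
    suffix = np.log(np.cumsum(np.exp(lp_s[::-1] - mx), axis=0)[::-1]) + mx
    _, first = np.unique(t_s, return_index=True)
    d = np.add.reduceat(e_s, first).astype(float)
    event_lp = (lp_s * e_s[:, None]).sum(axis=0)
    return event_lp - (d[:, None] * suffix[first]).sum(axis=0)


def breslow_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a linear predictor."""
    return float(breslow_loglik_multi(lp, time, event)[0])


@dataclass
class FoldModel:
    """One training fold's fitted model."""

    heldout_id: str | None
    filtered_features: list[str]
    coefficients: dict[str, float]  # nonzero only
    alpha: float | None
    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.coefficients

    def risk_index(self, x: pd.Series) -> float:
        """Linear predictor for one patient's feature vector."""
        r = 0.0
        for f, beta in self.coefficients.items():
            r += beta * (float(x[f]) - self.center[f]) / self.scale[f]
        return r


def fit_lasso_cox(
    features: pd.DataFrame,
    time,
    event,
    inner_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 30,
    lambda_rule: str = "min",
    heldout_id: str | None = None,
) -> FoldModel:
    """Fit an L1-penalized Cox model with inner-CV lambda selection.

    Features are z-scored by training statistics.  A regularization path
    is fitted on the full training set; the strength is chosen by
    ``inner_folds``-fold cross-validated partial log-likelihood
    (Verweij-van Houwelingen contribution ll(all) - ll(without fold)),
    at the maximum ("min" deviance rule) or, with ``lambda_rule='1se'``,
    the strongest penalty within one standard error of it.  Ties prefer
    the stronger penalty.
    """
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    names = list(features.columns)
    if not names:
        return FoldModel(heldout_id, [], {}, None)
    n_events = int(event.sum())
    if n_events < 2:
        warnings.warn("fewer than 2 events: emitting empty model", stacklevel=2)
        return FoldModel(heldout_id, names, {}, None)

    X = features.to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    def _coxnet(**kw):
        return CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alpha_min_ratio=0.01, fit_baseline_model=False, **kw
        )

    try:
        path = _coxnet(n_alphas=n_alphas).fit(Z, y)
    except (ValueError, ArithmeticError) as exc:
        warnings.warn(f"coxnet path failed ({exc}); emitting empty model", stacklevel=2)
        return FoldModel(heldout_id, names, {}, None)
    alphas = np.asarray(path.alphas_)

    k = min(inner_folds, n_events)
    k = max(k, 2)
    splitter = KFold(n_splits=min(k, len(time)), shuffle=True, random_state=seed)
    cvll = np.zeros((splitter.get_n_splits(), alphas.size))
    ll_all_cache = None
    for fold_i, (tr, _te) in enumerate(splitter.split(Z)):
        try:
            m = _coxnet(alphas=alphas).fit(Z[tr], y[tr])
        except (ValueError, ArithmeticError):
            cvll[fold_i] = np.nan
            continue
        coefs = np.asarray(m.coef_)  # (p, n_alphas_fit)
        fitted = np.asarray(m.alphas_)
        cols = np.array([int(np.argmin(np.abs(fitted - a))) for a in alphas])
        LP = Z @ coefs[:, cols]  # (n, n_alphas)
        cvll[fold_i] = breslow_loglik_multi(LP, time, event) - breslow_loglik_multi(
            LP[tr], time[tr], event[tr]
        )
        ll_all_cache = True
    if ll_all_cache is None:
        return FoldModel(heldout_id, names, {}, None)

    mean_cvll = np.nanmean(cvll, axis=0)
    if not np.isfinite(mean_cvll).any():
        return FoldModel(heldout_id, names, {}, None)
    best = int(np.nanargmax(mean_cvll))
    if lambda_rule == "1se":
        se = np.nanstd(cvll, axis=0, ddof=1) / np.sqrt(np.sum(np.isfinite(cvll), axis=0))
        thresh = mean_cvll[best] - se[best]
        # alphas are descending: the first index meeting the bar is the
        # strongest acceptable penalty
        best = int(np.flatnonzero(mean_cvll >= thresh)[0])
    alpha_best = float(alphas[best])

    with warnings.catch_warnings():
        # an all-zero solution at the chosen penalty is a legitimate outcome
        warnings.filterwarnings("ignore", message="all coefficients are zero")
        final = _coxnet(alphas=[alpha_best]).fit(Z, y)
    beta = np.asarray(final.coef_).ravel()
    coef = {f: float(b) for f, b in zip(names, beta) if b != 0.0}
    return FoldModel(
        heldout_id=heldout_id,
        filtered_features=names,
        coefficients=coef,
        alpha=alpha_best,
        center={f: float(c) for f, c in zip(names, center)},
        scale={f: float(s) for f, s in zip(names, scale)},
    )


# ---------------------------------------------------------------------------
# LOOCV risk indices


@dataclass
class RiskResult:
    """Per-patient LOOCV risk indices and the median-split grouping."""

    risk: pd.Series
    group: pd.Series  # "low-risk" / "high-risk"
    cutoff: float


def fit_fold(
    train_features: pd.DataFrame,
    train_time,
    train_event,
    alpha: float = 0.05,
    inner_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 30,
    lambda_rule: str = "min",
    heldout_id: str | None = None,
) -> FoldModel:
    """One training fold: log-rank screening then lasso-Cox.

    Sees only the training rows it is given, so leaving the held-out
    patient out of the inputs is sufficient to guarantee no leakage.
    """
    retained = logrank_filter(train_features, train_time, train_event, alpha=alpha)
    if not retained:
        return FoldModel(heldout_id, [], {}, None)
    return fit_lasso_cox(
        train_features[retained],
        train_time,
        train_event,
        inner_folds=inner_folds,
        seed=seed,
        n_alphas=n_alphas,
        lambda_rule=lambda_rule,
        heldout_id=heldout_id,
    )


def loocv_risk_indices(
    features: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    alpha: float = 0.05,
    inner_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 30,
    lambda_rule: str = "min",
) -> tuple[RiskResult, list[FoldModel]]:
    """Leave-one-out cross-validated risk index for every patient.

    Screening, standardization, and lambda selection all happen strictly
    inside each training set.  Patients with non-positive follow-up time
    are dropped with a warning (they break the partial likelihood).
    After all folds the cohort is split at the median risk index; ties
    at the cutoff go to the low-risk group.
    """
    time = pd.Series(np.asarray(time, float), index=features.index)
    event = pd.Series(np.asarray(event, int), index=features.index)
    ok = time > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} patients with non-positive time", stacklevel=2)
        features, time, event = features.loc[ok], time.loc[ok], event.loc[ok]

    risks = {}
    folds: list[FoldModel] = []
    for pid in features.index:
        tr = features.index != pid
        model = fit_fold(
            features.loc[tr],
            time.loc[tr],
            event.loc[tr],
            alpha=alpha,
            inner_folds=inner_folds,
            seed=seed,
            n_alphas=n_alphas,
            lambda_rule=lambda_rule,
            heldout_id=str(pid),
        )
        folds.append(model)
        risks[pid] = model.risk_index(features.loc[pid]) if not model.is_empty else 0.0

    risk = pd.Series(risks, name="risk_index")
    if risk.nunique() == 1:
        raise ValueError("degenerate risk distribution: all risk indices identical")
    cutoff = float(risk.median())
    group = pd.Series(
        np.where(risk > cutoff, "high-risk", "low-risk"), index=risk.index, name="group"
    )
    return RiskResult(risk=risk, group=group, cutoff=cutoff), folds


def summarize_selection(folds: list[FoldModel]) -> pd.DataFrame:
    """Selection frequency and mean coefficient across LOOCV folds.

    One row per feature that was ever selected: count of folds with a
    nonzero coefficient, total fold count, and the mean coefficient over
    the selecting folds only; sorted by count descending (ties
    alphabetical).
    """
    if not folds:
        raise ValueError("need at least one fold model")
    n = len(folds)
    counts: dict[str, int] = {}
    sums: dict[str, float] = {}
    for m in folds:
        for f, b in m.coefficients.items():
            counts[f] = counts.get(f, 0) + 1
            sums[f] = sums.get(f, 0.0) + b
    rows = [
        {
            "feature": f,
            "count": c,
            "n_folds": n,
            "frequency": c / n,
            "mean_coefficient": sums[f] / c,
        }
        for f, c in counts.items()
    ]
    table = pd.DataFrame(rows, columns=["feature", "count", "n_folds", "frequency", "mean_coefficient"])
    return table.sort_values(["count", "feature"], ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Classical survival summaries


def cox_regression(
    time,
    event,
    terms: pd.DataFrame,
    references: dict[str, str] | None = None,
    mode: str = "multivariable",
) -> pd.DataFrame:
    """Cox proportional-hazards summaries for binary covariates.

    ``terms`` holds 0/1 covariates (1 = non-reference level).
    ``mode='univariable'`` fits each term alone; ``'multivariable'``
    fits all jointly.  Returns per term: HR, 95% CI, Wald p, and the
    declared reference-group label.

    Raises
    ------
    ValueError
        On non-binary terms, or when the fit fails (e.g. complete
        separation or zero events in a level), with a diagnostic.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if mode not in ("univariable", "multivariable"):
        raise ValueError("mode must be 'univariable' or 'multivariable'")
    for col in terms.columns:
        if not np.isin(terms[col].to_numpy(), (0, 1)).all():
            raise ValueError(f"term {col!r} must be binary 0/1")
    references = references or {}
    base = pd.DataFrame(
        {"time": np.asarray(time, float), "event": np.asarray(event, int)},
        index=terms.index,
    )

    def _fit(cols: list[str]) -> pd.DataFrame:
        df = pd.concat([base, terms[cols]], axis=1)
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, ValueError) as exc:
            raise ValueError(
                f"Cox fit failed for terms {cols} (possible complete separation "
                f"or zero events in a level): {exc}"
            ) from exc
        s = cph.summary
        return pd.DataFrame(
            {
                "term": s.index,
                "HR": np.exp(s["coef"]).to_numpy(),
                "ci_low": np.exp(s["coef lower 95%"]).to_numpy(),
                "ci_high": np.exp(s["coef upper 95%"]).to_numpy(),
                "p": s["p"].to_numpy(),
            }
        )

    if mode == "multivariable":
        out = _fit(list(terms.columns))
    else:
        out = pd.concat([_fit([c]) for c in terms.columns], ignore_index=True)
    out["reference"] = [references.get(t, "") for t in out["term"]]
    return out


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as a (time, survival, at_risk)
    table, for plotting and CSV export."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), np.asarray(event, int))
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(),
            "survival": surv.to_numpy(),
            "at_risk": table["at_risk"].reindex(surv.index).to_numpy(),
        }
    )
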