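"""End-to-end workflow orchestration.

Runs the stages in order — segment tiles, extract cell-level features,
aggregate to patient-level features, then (as inputs permit) the
mutation association, the LOOCV lasso-Cox prognosis, and the
expression-correlation/enrichment analyses — writing every artifact as
CSV/JSON into one output directory together with a provenance record
(config hash, seeds, package version).  Re-running with an identical
config and inputs reproduces identical outputs; stages whose outputs
already exist under the same provenance hash are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from histomorph import __version__
from histomorph.cellfeat import extract_cell_features
from histomorph.exprcorr import (
    hypergeometric_enrichment,
    read_gmt,
    select_top_genes,
    spearman_profile,
)
from histomorph.imaging import (
    SegmentationConfig,
    filter_large_nuclei,
    normalize_stain,
    segment_nuclei,
)
from histomorph.mutassoc import run_association
from histomorph.patientfeat import BinScheme, aggregate_cohort
from histomorph.survmodel import (
    cox_regression,
    km_curve,
    logrank_test,
    loocv_risk_indices,
    summarize_selection,
)

log = logging.getLogger("histomorph")

_DEFAULTS = {
    "alpha": 0.05,
    "mutation_threshold": 0.15,
    "correlation_threshold": 0.3,
    "gene_cap": 100,
    "percentile": 95.0,
    "seed": 0,
    "selection_frequency_min": 0.8,
    "bin_scheme": "fit",
}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _validate_paths(config: dict) -> None:
    for key in ("tiles", "features", "clinical", "mutations", "expression", "gmt", "masks"):
        val = config.get(key)
        if val is not None and not Path(val).exists():
            raise FileNotFoundError(f"config path {key!r} does not exist: {val}")
    if config.get("tiles") is None and config.get("features") is None:
        raise ValueError("config must supply either 'tiles' or precomputed 'features'")


def segment_tile_image(
    image: np.ndarray,
    roi: np.ndarray | None = None,
    config: SegmentationConfig | None = None,
    percentile: float = 95.0,
    normalize: bool = True,
):
    """Normalize, segment, and size-filter one tile; returns the
    filtered :class:`~histomorph.imaging.SegmentationResult`."""
    if normalize:
        image, _ = normalize_stain(image)
    result = segment_nuclei(image, config)
    if roi is not None:
        labels = result.labels.copy()
        labels[~roi.astype(bool)] = 0
        from histomorph.imaging import _result_from_labels

        keep = np.unique(labels)
        keep = keep[keep > 0]
        remap = np.zeros(int(result.labels.max()) + 1, dtype=np.int32)
        remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
        result = _result_from_labels(remap[labels])
    if result.n_nuclei:
        result = filter_large_nuclei(result, percentile=percentile)
    return result


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute the full workflow described by ``config``.

    Recognized keys: ``tiles`` (directory of per-patient subdirectories
    of PNG/TIFF tiles) or ``features`` (precomputed patients x 150 CSV);
    optional ``masks`` (ROI PNGs mirroring the tile tree), ``clinical``
    (patient_id, time_months, event, and optionally stage/grade/msi),
    ``mutations`` (patients x genes binary CSV), ``expression``
    (genes x patients CSV), ``gmt``; thresholds and ``seed`` as in
    ``_DEFAULTS``.
    """
    cfg = {**_DEFAULTS, **config}
    _validate_paths(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    chash = _config_hash(cfg)
    prov_path = out / "provenance.json"
    prior_hash = None
    if prov_path.exists():
        try:
            prior_hash = json.loads(prov_path.read_text()).get("config_hash")
        except json.JSONDecodeError:
            prior_hash = None

    def _cached(*files: str) -> bool:
        return prior_hash == chash and all((out / f).exists() for f in files)

    try:
        features = _stage_features(cfg, out, _cached)
        if cfg.get("clinical"):
            _stage_prognosis(cfg, out, features, _cached)
        if cfg.get("mutations"):
            _stage_association(cfg, out, features, _cached)
        if cfg.get("expression"):
            _stage_exprcorr(cfg, out, features, _cached)
    finally:
        log.removeHandler(handler)
        handler.close()

    prov_path.write_text(
        json.dumps(
            {
                "config_hash": chash,
                "config": {k: str(v) for k, v in cfg.items()},
                "seed": cfg["seed"],
                "version": __version__,
            },
            indent=1,
        )
    )
    return out


def _stage_features(cfg: dict, out: Path, cached) -> pd.DataFrame:
    if cfg.get("features"):
        return pd.read_csv(cfg["features"], index_col=0)
    if cached("features.csv", "bins.json"):
        log.info("features: cached")
        return pd.read_csv(out / "features.csv", index_col=0)
    try:
        tiles_root = Path(cfg["tiles"])
        masks_root = Path(cfg["masks"]) if cfg.get("masks") else None
        seg_cfg = SegmentationConfig(**cfg.get("segmentation", {}))
        cells_by_patient: dict[str, list[pd.DataFrame]] = {}
        for patient_dir in sorted(p for p in tiles_root.iterdir() if p.is_dir()):
            tables = []
            for tile_path in sorted(patient_dir.glob("*.png")) + sorted(
                patient_dir.glob("*.tif*")
            ):
                image = np.asarray(iio.imread(tile_path))[..., :3]
                roi = None
                if masks_root is not None:
                    mp = masks_root / patient_dir.name / tile_path.name
                    if mp.exists():
                        roi = np.asarray(iio.imread(mp)) > 0
                result = segment_tile_image(
                    image, roi=roi, config=seg_cfg, percentile=cfg["percentile"]
                )
                tables.append(extract_cell_features(result.labels, image))
                log.info("segmented %s: %d nuclei", tile_path, result.n_nuclei)
            if tables:
                cells_by_patient[patient_dir.name] = tables
        scheme = None
        if cfg["bin_scheme"] != "fit":
            scheme = BinScheme.from_json(cfg["bin_scheme"])
        features, scheme = aggregate_cohort(cells_by_patient, scheme)
        scheme.to_json(out / "bins.json")
        features.to_csv(out / "features.csv")
        log.info("features: %d patients x %d features", *features.shape)
        return features
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("features", exc) from exc


def _stage_prognosis(cfg: dict, out: Path, features: pd.DataFrame, cached) -> None:
    if cached("risk.csv", "selection.csv", "folds.json"):
        log.info("prognosis: cached")
        return
    try:
        clinical = pd.read_csv(cfg["clinical"], index_col=0)
        shared = sorted(set(features.index) & set(clinical.index))
        X = features.loc[shared]
        cl = clinical.loc[shared]
        result, folds = loocv_risk_indices(
            X,
            cl["time_months"],
            cl["event"],
            alpha=cfg["alpha"],
            seed=cfg["seed"],
        )
        risk = pd.DataFrame({"risk_index": result.risk, "group": result.group})
        risk.index.name = "patient_id"
        risk.to_csv(out / "risk.csv")
        summarize_selection(folds).to_csv(out / "selection.csv", index=False)
        (out / "folds.json").write_text(
            json.dumps([asdict(f) for f in folds], indent=1)
        )
        ok = result.risk.index[cl.loc[result.risk.index, "time_months"] > 0]
        chi2, p = logrank_test(
            (result.group.loc[ok] == "high-risk").astype(int).to_numpy(),
            cl.loc[ok, "time_months"].to_numpy(),
            cl.loc[ok, "event"].to_numpy(),
        )
        terms = pd.DataFrame(
            {"risk_high": (result.group.loc[ok] == "high-risk").astype(int)}, index=ok
        )
        refs = {"risk_high": "low-risk"}
        for col, ref in (("stage", "I+II"), ("grade", "G1+G2"), ("msi", "MSS")):
            if col in cl.columns and cl.loc[ok, col].nunique() == 2:
                terms[col] = cl.loc[ok, col]
                refs[col] = ref
        summaries = []
        for mode in ("univariable", "multivariable"):
            s = cox_regression(
                cl.loc[ok, "time_months"], cl.loc[ok, "event"], terms, refs, mode=mode
            )
            s["model"] = mode
            summaries.append(s)
        pd.concat(summaries, ignore_index=True).to_csv(out / "cox_summary.csv", index=False)
        km_tables = []
        for grp in ("low-risk", "high-risk"):
            ids = ok[result.group.loc[ok] == grp]
            t = km_curve(cl.loc[ids, "time_months"], cl.loc[ids, "event"])
            t["group"] = grp
            km_tables.append(t)
        pd.concat(km_tables, ignore_index=True).to_csv(out / "km_risk.csv", index=False)
        log.info("prognosis: stratification log-rank chi2=%.3f p=%.3g", chi2, p)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("prognosis", exc) from exc


def _stage_association(cfg: dict, out: Path, features: pd.DataFrame, cached) -> None:
    if cached("assoc.csv"):
        log.info("association: cached")
        return
    try:
        mutations = pd.read_csv(cfg["mutations"], index_col=0)
        table = run_association(
            features,
            mutations,
            threshold=cfg["mutation_threshold"],
            alpha=cfg["alpha"],
        )
        table.to_csv(out / "assoc.csv", index=False)
        log.info(
            "association: %d tests, %d significant at q<%.2g",
            len(table),
            int(table["significant"].sum()),
            cfg["alpha"],
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("association", exc) from exc


def _stage_exprcorr(cfg: dict, out: Path, features: pd.DataFrame, cached) -> None:
    try:
        expression = pd.read_csv(cfg["expression"], index_col=0)
        sel_path = out / "selection.csv"
        if sel_path.exists():
            sel = pd.read_csv(sel_path)
            top_feats = sel.loc[
                sel["frequency"] > cfg["selection_frequency_min"], "feature"
            ].tolist()[:5]
        else:
            top_feats = []
        if not top_feats:
            log.info("exprcorr: no frequently selected features; skipping")
            return
        gene_sets = read_gmt(cfg["gmt"]) if cfg.get("gmt") else {}
        universe = list(expression.index)
        for feat in top_feats:
            profile = spearman_profile(features[feat], expression)
            profile.rename("spearman_rho").to_csv(out / f"corr_{feat}.csv")
            top = select_top_genes(
                profile,
                threshold=cfg["correlation_threshold"],
                cap=cfg["gene_cap"],
            )
            if top.skipped:
                log.info("exprcorr %s: too few correlated genes, enrichment skipped", feat)
                continue
            if gene_sets:
                enr = hypergeometric_enrichment(top.genes, gene_sets, universe)
                enr.to_csv(out / f"enrichment_{feat}.csv", index=False)
                log.info("exprcorr %s: %d gene sets tested", feat, len(enr))
    except Exception as exc:  # noqa: BLE001
        raise StageError("exprcorr", exc) from exc


def write_mask_png(path: str | Path, labels: np.ndarray) -> None:
    """Write an instance label mask as 16-bit single-channel PNG."""
    if labels.max() > np.iinfo(np.uint16).max:
        warnings.warn("label overflow: mask clipped to uint16", stacklevel=2)
    iio.imwrite(Path(path), labels.astype(np.uint16))
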