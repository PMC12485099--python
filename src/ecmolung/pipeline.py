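"""End-to-end orchestration: simulate -> segment -> ROIs -> features ->
selection -> models -> evaluation -> competing-risk analysis.

A run is driven by a JSON-serializable config with one namespace per
stage and a single master seed; every artifact is written to the output
directory together with a manifest recording the config, the seed and a
checksum per artifact, so a rerun with the same config reproduces the
deterministic outputs bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import survival_analysis as surv
from .feature_extraction import extract_all
from .feature_selection import SelectionConfig, finalize_signature, run_cv_discovery
from .mask_ops import segment_by_threshold
from .predictive_models import (
    classification_report,
    fit_logistic,
    published_model,
    roc_auc,
    youden_cutoff,
)
from .roi_extraction import build_registry
from .synthetic_data import CohortSpec, PhantomSpec, generate_cohort, generate_phantom

log = logging.getLogger(__name__)

CLINICAL_COVARIATES = ["age", "pmean", "lactate", "crp"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {"n_subjects": 60},
    "phantom": {"grid_shape": [64, 64, 64], "voxel_size_mm": [3.0, 3.0, 3.0]},
    "segment": {"hu_cutoff": -200.0},
    "select": {"enabled": True, "n_repeats": 2, "n_folds": 5},
    "models": {"published": None},  # or "imaging" | "clinical" | "combined"
    "survival": {"enabled": True},
}


def fractions_for_normal_vent(nv: float) -> tuple[float, float, float, float]:
    """Map a target normally-aerated fraction to four compartment fractions.

    The non-normal remainder is split in fixed proportions
    (hyperinflated : poorly aerated : non-aerated = 0.09 : 0.455 : 0.455),
    matching the shape of a diseased-lung HU histogram.
    """
    nv = float(np.clip(nv, 0.0, 1.0))
    rest = 1.0 - nv
    f = (0.09 * rest, nv, 0.455 * rest, 0.455 * rest)
    return tuple(v / sum(f) for v in f)


def simulate_subject_features(
    nv: float,
    seed: int,
    grid_shape=(64, 64, 64),
    voxel_size_mm=(3.0, 3.0, 3.0),
    hu_cutoff: float = -200.0,
    subject_id: str = "",
) -> pd.Series:
    """Phantom -> threshold segmentation -> 42 ROIs -> 592 features."""
    rng = np.random.default_rng(seed)
    spec = PhantomSpec(
        grid_shape=tuple(grid_shape),
        voxel_size_mm=tuple(voxel_size_mm),
        compartment_fractions=fractions_for_normal_vent(nv),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    # per-subject size variation: scale the default ellipsoids by +/-10%
    scale = 0.9 + 0.2 * rng.random()
    spec.lung_geometry = tuple(
        (center, tuple(s * scale for s in semi)) for center, semi in spec.lung_geometry
    )
    vol, _truth = generate_phantom(spec)
    lung = segment_by_threshold(vol, hu_cutoff=hu_cutoff)
    registry = build_registry(vol, lung)
    return extract_all(vol, lung, registry, subject_id=subject_id)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge(base: dict, override: dict | None) -> dict:
    out = json.loads(json.dumps(base))
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None = None, out_dir: str | Path = "ecmolung_run") -> dict:
    """Execute all enabled stages; returns the manifest."""
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "seed": seed, "stages": {}, "artifacts": {}}
    rng = np.random.default_rng(seed)

    def _stage(name):
        t0 = time.time()
        log.info("stage %s started", name)
        return t0

    def _done(name, t0):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 2)}
        log.info("stage %s finished in %.1fs", name, manifest["stages"][name]["seconds"])

    def _write_df(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        manifest["artifacts"][name] = _sha256(path)

    def _write_json(obj, name: str):
        path = out / name
        path.write_text(json.dumps(obj, indent=2, default=float))
        manifest["artifacts"][name] = _sha256(path)

    # --- simulate cohort + imaging ---------------------------------------
    t0 = _stage("simulate")
    cohort = generate_cohort(CohortSpec(seed=int(rng.integers(0, 2**31 - 1)), **cfg["cohort"]))
    feats = []
    for i, row in cohort.iterrows():
        feats.append(
            simulate_subject_features(
                row["normal_vent"],
                seed=int(rng.integers(0, 2**31 - 1)),
                grid_shape=cfg["phantom"]["grid_shape"],
                voxel_size_mm=cfg["phantom"]["voxel_size_mm"],
                hu_cutoff=cfg["segment"]["hu_cutoff"],
                subject_id=row["subject_id"],
            )
        )
    features = pd.DataFrame(feats).reset_index(drop=True)
    features.insert(0, "subject_id", cohort["subject_id"].to_numpy())
    _write_df(cohort, "cohort.csv")
    _write_df(features, "features.csv")
    _done("simulate", t0)

    outcome = (cohort["event_code"] == 1).astype(int).to_numpy()
    imaging = features.drop(columns="subject_id")
    # distribution statistics of empty/near-empty ROIs are missing by design;
    # features incomplete across the cohort are excluded from modelling
    n_incomplete = int(imaging.isna().any().sum())
    if n_incomplete:
        log.info("dropping %d feature(s) with missing values", n_incomplete)
        imaging = imaging.dropna(axis=1)

    # --- feature selection -------------------------------------------------
    signature = ["normal_ventilated"]
    if cfg["select"].get("enabled", True) and len(np.unique(outcome)) == 2:
        t0 = _stage("select")
        sel_cfg = SelectionConfig(
            n_repeats=int(cfg["select"].get("n_repeats", 2)),
            n_folds=int(cfg["select"].get("n_folds", 5)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        result = run_cv_discovery(imaging, outcome, sel_cfg)
        result = finalize_signature(result, imaging, outcome)
        signature = result.signature or signature
        _write_json(
            {
                "signature": result.signature,
                "borda_scores": result.borda_scores.to_dict(),
                "ranks": result.ranks.to_dict(),
                "fold_aurocs": result.fold_aurocs,
            },
            "selection.json",
        )
        _done("select", t0)

    # --- models ------------------------------------------------------------
    t0 = _stage("fit")
    models = {}
    if cfg["models"].get("published"):
        name = cfg["models"]["published"]
        models[name] = published_model(name)
    else:
        models["imaging"] = fit_logistic(imaging[signature], outcome)
        models["clinical"] = fit_logistic(cohort[CLINICAL_COVARIATES], outcome)
        combined_X = pd.concat([cohort[CLINICAL_COVARIATES], imaging[signature]], axis=1)
        models["combined"] = fit_logistic(combined_X, outcome)
    _write_json({k: m.to_dict() for k, m in models.items()}, "models.json")
    _done("fit", t0)

    # --- evaluation ----------------------------------------------------------
    t0 = _stage("evaluate")
    data_all = pd.concat([cohort, imaging], axis=1)
    evaluation = {}
    probs = {}
    for name, model in models.items():
        p = model.predict_proba(data_all)
        probs[name] = p
        cutoff = model.cutoff if model.cutoff is not None else youden_cutoff(p, outcome)
        entry = {"cutoff": cutoff, **classification_report(p, outcome, cutoff)}
        if len(np.unique(outcome)) == 2:
            entry.update(roc_auc(p, outcome, seed=seed))
        evaluation[name] = entry
    _write_json(evaluation, "evaluation.json")
    _done("evaluate", t0)

    # --- survival ------------------------------------------------------------
    if cfg["survival"].get("enabled", True):
        t0 = _stage("survival")
        name = "combined" if "combined" in models else next(iter(models))
        model = models[name]
        cutoff = evaluation[name]["cutoff"]
        records = cohort[["subject_id", "time_days", "event_code"]].copy()
        records["group"] = (probs[name] >= cutoff).astype(int)
        results: dict = {"risk_model": name}
        if records["group"].nunique() == 2:
            results["logrank"] = surv.logrank_test(records)
            for ev, label in ((1, "ecmo"), (2, "death")):
                if (records["event_code"] == ev).sum() >= 2:
                    entry = {"grays": surv.grays_test(records, event=ev)}
                    try:
                        fg = surv.fine_gray_fit(records, event=ev)
                        entry.update(shr=fg.shr, shr_ci=[fg.ci_lower, fg.ci_upper], p=fg.p)
                    except ValueError as err:
                        entry["fine_gray_error"] = str(err)
                    results[label] = entry
        _write_json(results, "survival.json")
        _done("survival", t0)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
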