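"""End-to-end orchestration: synthesise -> preprocess -> voxel features ->
habitats -> region features -> selection -> models -> evaluation.

The pipeline is leakage-free by construction: the cohort is split first and
every data-dependent fit (habitat K-means, feature selection, classifier,
decision threshold, missing-value medians) uses training rows/voxels only.
A manifest recording the seed, config hash and package versions is written
with the artifacts, and two runs with equal manifests produce identical
metrics.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from .config import RunConfig
from .habitats import HabitatMap, HabitatModel, assign_habitats, fit_habitat_model
from .image import VolumePair, preprocess_pair, save_nifti
from .models import ModelBundle, train_classifier, univariable_logistic_screen
from .regionfeat import FeatureTable, build_feature_tables
from .selection import SelectionResult, run_selection_cascade
from .synthetic import Cohort, generate_cohort
from .voxelfeat import VoxelFeatureMatrix, compute_voxel_features, stack_voxel_features

log = logging.getLogger("habitatrx")


def split_cohort(
    records: pd.DataFrame,
    ratio: float = 0.7,
    stratify: str = "label",
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified train/test split of patient ids.

    Per class, ``round(class_n * ratio)`` patients are drawn (seeded) into
    the training set; the split is disjoint and exhaustive.
    """
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls, grp in records.groupby(stratify, sort=True):
        ids = grp["patient_id"].tolist()
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 patients")
        n_train = int(round(len(ids) * ratio))
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train += [ids[i] for i in perm[:n_train]]
        test += [ids[i] for i in perm[n_train:]]
    return sorted(train), sorted(test)


@dataclass
class PipelineResult:
    """Everything a pipeline run produced, in memory."""

    config: RunConfig
    cohort: Cohort
    train_ids: list[str]
    test_ids: list[str]
    habitat_model: HabitatModel
    habitat_maps: dict[str, HabitatMap]
    whole_table: FeatureTable
    habitat_table: FeatureTable
    selections: dict[str, SelectionResult]
    clinical_factors: list[str]
    clinical_pvalues: pd.Series
    bundles: dict[str, ModelBundle]
    report: ev.EvalReport
    manifest: dict = field(default_factory=dict)


def _stage(name: str, t0: float) -> float:
    t1 = time.monotonic()
    log.info("stage %-16s %6.1f s", name, t1 - t0)
    return t1


def compute_all_voxel_features(
    pairs: list[VolumePair], config: RunConfig
) -> dict[str, VoxelFeatureMatrix]:
    vf = config.voxel_features
    return {
        p.patient_id: compute_voxel_features(
            p, vf.kernel_radius, vf.n_bins, vf.glcm_mode
        )
        for p in pairs
    }


def _model_tables(
    result_tables: dict[str, pd.DataFrame],
    cohort: Cohort,
) -> dict[str, pd.DataFrame]:
    clin = cohort.clinical.set_index("patient_id")
    result_tables["clinical"] = clin[
        ["age", "PV", "tPSA", "fPSA", "f_t_ratio", "PSAD"]
    ].astype(float)
    return result_tables


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> PipelineResult:
    """Run the whole analysis under one config; see the module docstring.

    ``cohort`` may be supplied (e.g. loaded from disk) to skip synthesis.
    """
    t0 = time.monotonic()
    seed = config.seed
    if cohort is None:
        cohort = generate_cohort(config.phantom, config.clinical, seed)
    t0 = _stage("synthesise", t0)

    pairs = cohort.pairs
    if config.preprocess != "none":
        target = 1.0 if config.preprocess == "full" else None
        pairs = [
            preprocess_pair(p, target_spacing=target) if target is not None
            else _bias_only(p)
            for p in pairs
        ]
        t0 = _stage("preprocess", t0)

    clin = cohort.clinical.set_index("patient_id")
    labels_all = (clin["label"] == "csPCa").astype(int)
    train_ids, test_ids = split_cohort(cohort.clinical, config.train_ratio, seed=seed)

    vfms = compute_all_voxel_features(pairs, config)
    t0 = _stage("voxel features", t0)

    pooled_train = stack_voxel_features([vfms[p] for p in train_ids])
    cl = config.clustering
    hmodel = fit_habitat_model(
        pooled_train, (cl.k_min, cl.k_max), seed=seed, n_init=cl.n_init,
        subsample_cap=cl.subsample_cap,
    )
    shape_by_id = {p.patient_id: p.shape for p in pairs}
    hmaps = {
        pid: assign_habitats(vfms[pid], hmodel, shape_by_id[pid]) for pid in clin.index
    }
    t0 = _stage("habitats", t0)

    rf = config.region_features
    whole_tbl, hab_tbl = build_feature_tables(
        pairs, [hmaps[p.patient_id] for p in pairs],
        n_bins=rf.n_bins, min_region_voxels=rf.min_region_voxels,
    )
    hab_tbl = hab_tbl.impute_training_median(train_ids)
    t0 = _stage("region features", t0)

    y_train = labels_all.loc[train_ids].to_numpy()
    y_test = labels_all.loc[test_ids].to_numpy()

    selections = {
        "radiomics": run_selection_cascade(
            whole_tbl.frame.loc[train_ids], y_train, config.selection, seed
        ),
        "habitat": run_selection_cascade(
            hab_tbl.frame.loc[train_ids], y_train, config.selection, seed
        ),
    }
    t0 = _stage("selection", t0)

    factors, pvals = univariable_logistic_screen(clin.loc[train_ids], y_train)
    if not factors:  # degenerate screen: keep the single most significant
        factors = [pvals.idxmin()]
    feature_frames = {
        "clinical": clin[factors].astype(float),
        "radiomics": whole_tbl.frame[selections["radiomics"].kept],
        "habitat": hab_tbl.frame[selections["habitat"].kept],
    }
    bundles = {
        kind: train_classifier(
            frame.loc[train_ids], y_train, config.learner, seed, kind=kind
        )
        for kind, frame in feature_frames.items()
    }
    t0 = _stage("models", t0)

    report = ev.EvalReport()
    test_scores = {}
    for kind, bundle in bundles.items():
        scores = bundle.predict_proba(feature_frames[kind].loc[test_ids])
        test_scores[kind] = scores
        report.models[kind] = ev.evaluate_model(scores, y_test, bundle.threshold)
    for a in test_scores:
        for b in test_scores:
            if a < b:
                report.delong[(a, b)] = ev.delong_test(
                    test_scores[a], test_scores[b], y_test
                )
    t0 = _stage("evaluation", t0)

    if config.cv.enabled:
        report.cv_aucs = run_repeated_cv(
            config, cohort, pairs, vfms, feature_frames_full={
                "clinical": clin[["age", "PV", "tPSA", "fPSA", "f_t_ratio", "PSAD"]].astype(float),
                "radiomics": whole_tbl.frame,
            },
            labels=labels_all,
        )
        t0 = _stage("cross-validation", t0)

    manifest = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "config": config.model_dump(mode="json"),
        "versions": _versions(),
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "selected_k": hmodel.k,
    }
    result = PipelineResult(
        config=config, cohort=cohort, train_ids=train_ids, test_ids=test_ids,
        habitat_model=hmodel, habitat_maps=hmaps, whole_table=whole_tbl,
        habitat_table=hab_tbl, selections=selections, clinical_factors=factors,
        clinical_pvalues=pvals, bundles=bundles, report=report, manifest=manifest,
    )
    if config.output_dir:
        write_artifacts(result, Path(config.output_dir))
        _stage("artifacts", t0)
    return result


def _bias_only(pair: VolumePair) -> VolumePair:
    from .image import correct_bias

    support = pair.gland_mask if pair.gland_mask is not None else pair.lesion_mask
    return VolumePair(
        t2=correct_bias(pair.t2, support),
        adc=correct_bias(pair.adc, support),
        spacing=pair.spacing,
        lesion_mask=pair.lesion_mask,
        patient_id=pair.patient_id,
        gland_mask=pair.gland_mask,
    )


def run_repeated_cv(
    config: RunConfig,
    cohort: Cohort,
    pairs: list[VolumePair],
    vfms: dict[str, VoxelFeatureMatrix],
    feature_frames_full: dict[str, pd.DataFrame],
    labels: pd.Series,
) -> dict[str, np.ndarray]:
    """Five-repeat four-fold CV with per-fold refits of every stage.

    The habitat fold pipeline refits K-means on the fold's training voxels,
    reassigns habitats, rebuilds the habitat table and reruns selection;
    clinical/radiomics folds rerun their screens/cascades.
    """
    ids = cohort.clinical["patient_id"].tolist()
    y = labels.loc[ids].to_numpy()
    cl, rf = config.clustering, config.region_features
    out: dict[str, np.ndarray] = {}

    def clinical_fold(tr, te, fold_seed):
        frame = feature_frames_full["clinical"]
        sub = frame.loc[[ids[i] for i in tr]]
        factors, pvals = univariable_logistic_screen(sub, y[tr])
        if not factors:
            factors = [pvals.idxmin()]
        bundle = train_classifier(sub[factors], y[tr], config.learner, fold_seed,
                                  kind="clinical")
        return bundle.predict_proba(frame.loc[[ids[i] for i in te]])

    def radiomics_fold(tr, te, fold_seed):
        frame = feature_frames_full["radiomics"]
        sel = run_selection_cascade(
            frame.loc[[ids[i] for i in tr]], y[tr], config.selection, fold_seed
        )
        bundle = train_classifier(
            frame.loc[[ids[i] for i in tr], sel.kept], y[tr], config.learner,
            fold_seed, kind="radiomics",
        )
        return bundle.predict_proba(frame.loc[[ids[i] for i in te]])

    shape_by_id = {p.patient_id: p.shape for p in pairs}

    def habitat_fold(tr, te, fold_seed):
        tr_ids = [ids[i] for i in tr]
        te_ids = [ids[i] for i in te]
        pooled = stack_voxel_features([vfms[p] for p in tr_ids])
        hmodel = fit_habitat_model(
            pooled, (cl.k_min, cl.k_max), seed=fold_seed, n_init=cl.n_init,
            subsample_cap=cl.subsample_cap,
        )
        hmaps = [assign_habitats(vfms[p.patient_id], hmodel, shape_by_id[p.patient_id])
                 for p in pairs]
        _, hab_tbl = build_feature_tables(
            pairs, hmaps, n_bins=rf.n_bins, min_region_voxels=rf.min_region_voxels
        )
        hab_tbl = hab_tbl.impute_training_median(tr_ids)
        sel = run_selection_cascade(
            hab_tbl.frame.loc[tr_ids], y[tr], config.selection, fold_seed
        )
        bundle = train_classifier(
            hab_tbl.frame.loc[tr_ids, sel.kept], y[tr], config.learner,
            fold_seed, kind="habitat",
        )
        return bundle.predict_proba(hab_tbl.frame.loc[te_ids])

    folds = {"clinical": clinical_fold, "radiomics": radiomics_fold,
             "habitat": habitat_fold}
    for kind, fn in folds.items():
        out[kind] = ev.repeated_cv(y, fn, config.cv.repeats, config.cv.folds,
                                   config.seed)
    return out


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("habitatrx", "numpy", "scipy", "pandas", "scikit-learn",
                "scikit-image", "nibabel", "numba"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    """Write habitat maps, feature tables, audits and metrics to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    hab_dir = out_dir / "habitats"
    hab_dir.mkdir(exist_ok=True)
    spacing_by_id = {p.patient_id: p.spacing for p in result.cohort.pairs}
    for pid, hmap in result.habitat_maps.items():
        save_nifti(hmap.labels, spacing_by_id[pid], hab_dir / f"{pid}_habitats.nii.gz")
    ch = pd.DataFrame(
        {"k": list(result.habitat_model.ch_curve),
         "ch": list(result.habitat_model.ch_curve.values())}
    )
    ch.to_csv(out_dir / "ch_curve.csv", index=False)
    result.whole_table.frame.to_csv(out_dir / "features_whole.csv")
    result.habitat_table.frame.to_csv(out_dir / "features_habitat.csv")
    (out_dir / "feature_manifest.json").write_text(json.dumps(
        {**result.whole_table.manifest, **result.habitat_table.manifest}, indent=2))
    audit = {
        kind: {
            "kept": sel.kept,
            "mi_kept": sel.mi_kept,
            "mrmr_order": sel.mrmr_order,
            "lasso_kept": sel.lasso_kept,
            "lambda_star": sel.lambda_star,
        }
        for kind, sel in result.selections.items()
    }
    audit["clinical"] = {
        "kept": result.clinical_factors,
        "p_values": {k: (None if not np.isfinite(v) else v)
                     for k, v in result.clinical_pvalues.items()},
    }
    (out_dir / "selection_audit.json").write_text(json.dumps(audit, indent=2))
    metrics = {
        name: {
            "auc": m.auc, "ci": list(m.ci), "threshold": m.threshold,
            **{k: (None if isinstance(v, float) and not np.isfinite(v) else v)
               for k, v in m.metrics.items()},
        }
        for name, m in result.report.models.items()
    }
    metrics["delong"] = {f"{a}_vs_{b}": {"z": z, "p": p}
                         for (a, b), (z, p) in result.report.delong.items()}
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    for name, m in result.report.models.items():
        m.calibration.to_csv(out_dir / f"calibration_{name}.csv", index=False)
        m.dca.to_csv(out_dir / f"dca_{name}.csv", index=False)
    if result.report.cv_aucs:
        pd.DataFrame(result.report.cv_aucs).to_csv(out_dir / "cv_aucs.csv", index=False)
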