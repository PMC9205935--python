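"""End-to-end study orchestration on phantom or on-disk cohorts.

Stages: cohort generation/loading -> preprocessing -> feature
extraction (234 per modality) -> perturbation robustness + ICC filter
-> redundancy clustering -> CV occurrence-aggregation signature
discovery per feature-class scope (MFO, SOT, LoG, All) and modality ->
final model fit on the full training data -> evaluation on training and
validation cohorts. Every artifact lands in the run directory with a
JSON provenance trail; the feature funnel (234 -> stable -> clustered
-> candidates -> signature) is logged per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models_eval, robustness, redundancy, signature as sig_mod
from .features import family_of, extract_all
from .grids import RoiMask, VolumetricImage, check_aligned
from .outcomes import BINARY, SURVIVAL, OutcomeData
from .phantom import CohortBundle, OutcomeSpec, PhantomConfig, generate_cohort
from .preprocess import PreprocessConfig, preprocess_subject

logger = logging.getLogger(__name__)

SCOPES = ("MFO", "SOT", "LoG", "All")
MODALITIES = ("MR", "CT")


@dataclass
class PipelineConfig:
    endpoint_kind: str = BINARY
    n_train: int = 16
    n_valid: int = 10
    seed: int = 0
    n_bins: int = 32
    scopes: tuple[str, ...] = SCOPES
    modalities: tuple[str, ...] = MODALITIES
    joint: bool = True
    use_clinical: bool = False
    reps: int = 33
    folds: int = 3
    k_select: int = 5
    icc_threshold: float = 0.8
    cluster_threshold: float = 0.8
    n_boot: int = 400
    # perturbation grids; defaults give the full 81-variant factorial
    volume_fractions: tuple[float, ...] = robustness.VOLUME_FRACTIONS
    translations_mm: tuple[float, ...] = robustness.TRANSLATIONS_MM
    robustness_max_subjects: int | None = None
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    outcome: OutcomeSpec = field(default_factory=OutcomeSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    def config_hash(self) -> str:
        payload = json.dumps(_as_jsonable(dataclasses.asdict(self)),
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub in (("phantom", PhantomConfig),
                         ("outcome", OutcomeSpec),
                         ("preprocess", PreprocessConfig)):
            if key in kwargs:
                kwargs[key] = sub(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in kwargs[key].items()})
        for key in ("scopes", "modalities", "volume_fractions",
                    "translations_mm"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ------------------------------------------------------------------ I/O

def read_cohort(manifest_path: str | Path) -> CohortBundle:
    """Load a cohort previously written by :func:`radsig.phantom.write_cohort`."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = manifest_path.parent
    subjects = []
    for entry in manifest["subjects"]:
        mr = VolumetricImage.from_nifti(root / entry["mr"], modality="MR")
        ct = VolumetricImage.from_nifti(root / entry["ct"], modality="CT")
        mask_mr = RoiMask.from_nifti(root / entry["mask_mr"])
        mask_ct = RoiMask.from_nifti(root / entry["mask_ct"])
        check_aligned(mr, mask_mr)
        check_aligned(ct, mask_ct)
        subjects.append({"subject_id": entry["subject_id"], "mr": mr, "ct": ct,
                         "mask_mr": mask_mr, "mask_ct": mask_ct})
    outcomes = OutcomeData.from_frame(
        pd.read_csv(root / manifest["outcomes"], index_col="subject_id"))
    clinical = None
    if manifest.get("clinical"):
        clinical = pd.read_csv(root / manifest["clinical"],
                               index_col="subject_id")
    return CohortBundle(subjects, outcomes, clinical,
                        truth=manifest.get("truth", {}))


def write_feature_table(table: pd.DataFrame, path: str | Path,
                        meta: dict | None = None) -> None:
    table.to_csv(path)
    if meta is not None:
        Path(str(path) + ".meta.json").write_text(
            json.dumps(_as_jsonable(meta), indent=1))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_as_jsonable(report), indent=1))


# ------------------------------------------------------------ stages

def extract_cohort_features(bundle: CohortBundle,
                            config: PipelineConfig,
                            keep_preprocessed: bool = False):
    """Preprocess + extract every subject; returns (table, preprocessed)."""
    vectors = {}
    preprocessed = {}
    for subj in bundle.subjects:
        pre = preprocess_subject(subj["mr"], subj["ct"], subj["mask_mr"],
                                 subj["mask_ct"], config.preprocess,
                                 mr_body_mask=_known_body_mask(subj))
        vectors[subj["subject_id"]] = extract_all(pre, config.n_bins)
        if keep_preprocessed:
            preprocessed[subj["subject_id"]] = pre
    table = pd.DataFrame.from_dict(vectors, orient="index")
    table.index.name = "subject_id"
    return table, preprocessed


def _known_body_mask(subj) -> RoiMask | None:
    body = subj["mr"].meta.get("body_mask")
    if body is None:
        return None
    return RoiMask(body, subj["mr"].spacing_mm, subj["mr"].origin_mm)


def run_stability_stage(preprocessed: dict, config: PipelineConfig
                        ) -> list[robustness.StabilityResult]:
    settings = robustness.enumerate_perturbations(
        config.volume_fractions, config.translations_mm,
        base_seed=config.seed)
    ids = sorted(preprocessed)
    if config.robustness_max_subjects:
        ids = ids[:config.robustness_max_subjects]
    tables = {sid: robustness.perturb_and_extract(
        preprocessed[sid], settings, config.n_bins) for sid in ids}
    return robustness.icc_filter(tables, config.icc_threshold)


def scope_columns(columns, modality: str, scope: str) -> list[str]:
    cols = [c for c in columns if c.startswith(f"{modality}_")]
    if scope == "All":
        return cols
    return [c for c in cols if family_of(c) == scope]


def _final_model(features: list[str], clinical_cols: list[str],
                 train_table, valid_table, train_out, valid_out,
                 train_clin, valid_clin, endpoint_kind, config):
    """Fit on the full training data with frozen transforms; evaluate both."""
    params = sig_mod.fit_yeo_johnson(train_table[features])
    ztr = sig_mod.apply_transform(params, train_table[features])
    zva = sig_mod.apply_transform(params, valid_table[features])
    if clinical_cols:
        enc_tr = pd.get_dummies(train_clin, drop_first=True, dtype=float)
        enc_va = pd.get_dummies(valid_clin, drop_first=True, dtype=float)
        enc_va = enc_va.reindex(columns=enc_tr.columns, fill_value=0.0)
        ztr = pd.concat([ztr, enc_tr[clinical_cols]], axis=1)
        zva = pd.concat([zva, enc_va[clinical_cols]], axis=1)
    if endpoint_kind == BINARY:
        model = models_eval.fit_logistic(ztr, train_out.labels)
        rep_tr = models_eval.evaluate_binary(
            model, ztr, train_out.labels, n_boot=config.n_boot,
            seed=config.seed)
        rep_va = models_eval.evaluate_binary(
            model, zva, valid_out.labels, threshold=rep_tr.cutoff,
            n_boot=config.n_boot, seed=config.seed + 1)
    else:
        model = models_eval.fit_cox(ztr, train_out.times, train_out.events)
        rep_tr = models_eval.evaluate_survival(
            model, ztr, train_out.times, train_out.events,
            n_boot=config.n_boot, seed=config.seed)
        rep_va = models_eval.evaluate_survival(
            model, zva, valid_out.times, valid_out.events,
            threshold=rep_tr.cutoff, n_boot=config.n_boot,
            seed=config.seed + 1)
    return model, params, rep_tr, rep_va


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 train_bundle: CohortBundle | None = None,
                 valid_bundle: CohortBundle | None = None) -> dict:
    """Execute the full study flow; returns the summary dict (also on disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    logger.info("pipeline start (config %s)", cfg_hash)

    if train_bundle is None:
        train_bundle = generate_cohort(config.phantom, config.outcome,
                                       config.n_train, config.seed)
    if valid_bundle is None:
        valid_bundle = generate_cohort(config.phantom, config.outcome,
                                       config.n_valid, config.seed + 500)

    train_table, preprocessed = extract_cohort_features(
        train_bundle, config, keep_preprocessed=True)
    valid_table, _ = extract_cohort_features(valid_bundle, config)
    write_feature_table(train_table, out / "features_train.csv",
                        {"config_hash": cfg_hash})
    write_feature_table(valid_table, out / "features_valid.csv",
                        {"config_hash": cfg_hash})
    logger.info("extracted %d features for %d train / %d valid subjects",
                train_table.shape[1], len(train_table), len(valid_table))

    stability = run_stability_stage(preprocessed, config)
    stab_tab = robustness.stability_table(stability)
    stab_tab.to_csv(out / "stability.csv")
    stable = robustness.stable_features(stability)
    logger.info("stability filter kept %d / %d features", len(stable),
                stab_tab.shape[0])

    endpoint = config.endpoint_kind
    train_out, valid_out = train_bundle.outcomes, valid_bundle.outcomes
    rows = []
    signatures: dict[str, sig_mod.Signature] = {}

    def evaluate_and_row(name, features, clinical_cols=()):
        if not features and not clinical_cols:
            rows.append({"model": name, "signature": "No feature selected"})
            return
        model, params, rep_tr, rep_va = _final_model(
            features, list(clinical_cols), train_table, valid_table,
            train_out, valid_out, train_bundle.clinical,
            valid_bundle.clinical, endpoint, config)
        write_report({"coefficients": model.coefficients,
                      "yeo_johnson_lambdas": params.lambdas,
                      "z_means": params.means, "z_sds": params.sds,
                      "config_hash": cfg_hash},
                     out / f"model_{name}.json")
        rows.append({
            "model": name,
            "signature": "+".join(features + list(clinical_cols)),
            "train_estimate": rep_tr.metric.estimate,
            "train_ci_low": rep_tr.metric.ci_low,
            "train_ci_high": rep_tr.metric.ci_high,
            "valid_estimate": rep_va.metric.estimate,
            "valid_ci_low": rep_va.metric.ci_low,
            "valid_ci_high": rep_va.metric.ci_high,
            "cutoff": rep_tr.cutoff,
            "valid_logrank_p": rep_va.logrank_p,
            "valid_calibration_p": rep_va.calibration_p,
        })

    for modality in config.modalities:
        for scope in config.scopes:
            cols = [c for c in scope_columns(stable, modality, scope)]
            name = f"{modality}_{scope}"
            if len(cols) < 2:
                logger.info("%s: %d stable features; skipping", name, len(cols))
                rows.append({"model": name, "signature": "No feature selected"})
                continue
            reduced, assignment, _ = redundancy.reduce_redundancy(
                train_table[cols], train_out, endpoint,
                config.cluster_threshold)
            logger.info("%s: %d stable -> %d representatives", name,
                        len(cols), reduced.shape[1])
            sig, records, occ = sig_mod.discover_signature(
                reduced, train_out, endpoint, config.reps, config.folds,
                seed=config.seed, k=config.k_select)
            signatures[name] = sig
            logger.info("%s signature: %s", name, sig.features or "none")
            evaluate_and_row(name, sig.features)

    if config.joint and all(m in config.modalities for m in ("MR", "CT")):
        for scope in config.scopes:
            a = signatures.get(f"MR_{scope}")
            b = signatures.get(f"CT_{scope}")
            if a is None or b is None:
                continue
            joint = sig_mod.join_signatures(a, b, train_table)
            signatures[f"Joint_{scope}"] = joint
            evaluate_and_row(f"Joint_{scope}", joint.features)

    if config.use_clinical and train_bundle.clinical is not None:
        for scope in config.scopes:
            base = signatures.get(f"Joint_{scope}") or signatures.get(
                f"MR_{scope}")
            if base is None or base.is_empty:
                continue
            enc = pd.get_dummies(train_bundle.clinical, drop_first=True,
                                 dtype=float)
            with_clin = sig_mod.add_clinical(base, train_bundle.clinical,
                                             train_out, endpoint)
            evaluate_and_row(f"Clinical_{scope}", with_clin.features,
                             with_clin.clinical)

    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.csv", index=False)
    write_report({"config_hash": cfg_hash,
                  "funnel": {"extracted": int(train_table.shape[1]),
                             "stable": len(stable)},
                  "signatures": {k: v.members for k, v in signatures.items()}},
                 out / "run_report.json")
    return {"summary": summary, "signatures": signatures,
            "stability": stab_tab, "config_hash": cfg_hash}
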