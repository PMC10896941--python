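"""End-to-end workspace orchestration on synthetic cohorts.

`run_pipeline` wires the stages together: simulate a five-site cohort,
pretrain one contrastive encoder per resolution, embed and splice every
slide, train the MIL patch classifier and the transformer aggregator for
the modeled feature, predict held-out slides, stage patients, and write a
metrics report. Every artifact is stamped with the config hash and seed;
splits are patient-level (all five slides of a patient share a split) and
stratified by the patient's true OLGA stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contrastive, mil, multiscale, staging, synthetic
from .aggregator import AggregatorConfig, aggregate, save_aggregator, train_aggregator
from .contrastive import AugmentationPolicy, EncoderConfig
from .metrics import auc, binarize_grades, sens_spec_at_cutoff, weighted_kappa
from .mil import Bag, MILConfig
from .staging import FEATURES, PatientRecord, SlideGrades, stage_patient
from .synthetic import SyntheticSpec

logger = logging.getLogger("gasmil")


class ConfigError(ValueError):
    pass


@dataclass
class SplitConfig:
    test_frac: float = 0.2
    val_frac: float = 0.2  # fraction of the training cohort held out internally


@dataclass
class PretrainConfig:
    backbone: str = "small-cnn"
    embed_dim: int = 64
    projection_dim: int = 32
    temperature: float = 0.5
    epochs: int = 3
    batch_size: int = 32
    lr: float = 1e-3
    n_slides: int = 24     # training slides sampled for pretraining
    n_patches: int = 256   # fine-scale patches subsampled from them


@dataclass
class RunConfig:
    workspace: str = "workspace"
    seed: int = 0
    log_level: str = "INFO"
    target_feature: str = "atrophy"  # feature whose grade drives the rendered lesions
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    splits: SplitConfig = field(default_factory=SplitConfig)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    mil: MILConfig = field(default_factory=MILConfig)
    aggregator: AggregatorConfig = field(default_factory=AggregatorConfig)
    staging_rule: str = "mean"
    n_boot: int = 200

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("workspace")  # output location does not define the experiment
        d.pop("log_level")
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_SUBCONFIGS = {"synthetic": SyntheticSpec, "splits": SplitConfig,
               "pretrain": PretrainConfig, "mil": MILConfig, "aggregator": AggregatorConfig}


def _build_dataclass(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if k in _SUBCONFIGS and isinstance(v, dict):
            kwargs[k] = _build_dataclass(_SUBCONFIGS[k], v, f"{path}.{k}")
        elif isinstance(v, list):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def load_config(path: Path | str) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are an error."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    cfg = _build_dataclass(RunConfig, data, "config")
    # nested dicts with int keys arrive as str from YAML/JSON round-trips
    lf = cfg.synthetic.lesion_fraction
    cfg.synthetic.lesion_fraction = {int(k): float(v) for k, v in lf.items()}
    la = cfg.synthetic.lesion_amplitude
    cfg.synthetic.lesion_amplitude = {int(k): float(v) for k, v in la.items()}
    return cfg


def stratified_patient_split(stages: pd.DataFrame, test_frac: float, val_frac: float,
                             seed: int) -> dict[str, str]:
    """Patient -> split, stratified by true OLGA stage; 5 slides stay together."""
    rng = np.random.default_rng(seed)
    split: dict[str, str] = {}
    for _, grp in stages.groupby("olga"):
        pids = list(grp["patient_id"])
        rng.shuffle(pids)
        n_test = max(1, int(round(test_frac * len(pids)))) if len(pids) > 1 else 0
        test, rest = pids[:n_test], pids[n_test:]
        n_val = max(1, int(round(val_frac * len(rest)))) if len(rest) > 1 else 0
        val, train = rest[:n_val], rest[n_val:]
        for p in test:
            split[p] = "test"
        for p in val:
            split[p] = "val"
        for p in train:
            split[p] = "train"
    return split


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> pretrain -> embed -> MIL -> aggregate -> stage -> evaluate.

    Returns the metrics report (also written to <workspace>/metrics.json).
    Deterministic for a fixed config: rerunning yields an identical report.
    """
    logging.basicConfig(level=config.log_level)
    ws = Path(config.workspace)
    ws.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    feature = config.target_feature
    if feature not in FEATURES:
        raise ConfigError(f"target_feature must be one of {FEATURES}")
    spec = dataclasses.replace(config.synthetic, seed=config.seed)

    # -- simulate --------------------------------------------------------
    logger.info("simulating cohort of %d patients", spec.n_patients)
    slide_specs, truth = synthetic.generate_cohort(spec)
    split = stratified_patient_split(truth.stages, config.splits.test_frac,
                                     config.splits.val_frac, seed=config.seed + 1)
    truth.slides["split"] = truth.slides["patient_id"].map(split)
    truth.slides.to_csv(ws / "truth_slides.csv", index=False)
    truth.stages.to_csv(ws / "truth_stages.csv", index=False)

    # -- pretrain one encoder per resolution -----------------------------
    rng = np.random.default_rng(config.seed + 2)
    train_specs = [s for s in slide_specs if split[s.patient_id] == "train"]
    sample = list(rng.choice(len(train_specs),
                             size=min(config.pretrain.n_slides, len(train_specs)),
                             replace=False))
    child_pool, parent_pool = [], []
    for i in sample:
        s = train_specs[i]
        _, patches, _ = synthetic.generate_slide(
            getattr(s.grades, feature), spec, s.seed, s.slide_id)
        child_pool.extend(patches[0.5])
        parent_pool.extend(patches[2.0])
    if len(child_pool) > config.pretrain.n_patches:
        keep = rng.choice(len(child_pool), size=config.pretrain.n_patches, replace=False)
        child_pool = [child_pool[i] for i in keep]
    policy = AugmentationPolicy()
    encoders = {}
    for mpp, pool in ((0.5, child_pool), (2.0, parent_pool)):
        ecfg = EncoderConfig(
            backbone=config.pretrain.backbone, embed_dim=config.pretrain.embed_dim,
            projection_dim=config.pretrain.projection_dim,
            temperature=config.pretrain.temperature, mpp=mpp)
        logger.info("pretraining %s encoder at %.1f MPP on %d patches",
                    ecfg.backbone, mpp, len(pool))
        enc, log = contrastive.train_encoder(
            pool, ecfg, policy, epochs=config.pretrain.epochs,
            batch_size=min(config.pretrain.batch_size, len(pool)),
            lr=config.pretrain.lr, seed=config.seed + 3)
        encoders[mpp] = enc
        contrastive.save_encoder(ws / f"encoder_{mpp}", enc)

    # -- embed + splice every slide into a bag ---------------------------
    logger.info("embedding %d slides", len(slide_specs))
    bags: list[Bag] = []
    for s in slide_specs:
        _, patches, _ = synthetic.generate_slide(
            getattr(s.grades, feature), spec, s.seed, s.slide_id)
        child_rec = contrastive.embed(patches[0.5], encoders[0.5])
        parent_rec = contrastive.embed(patches[2.0], encoders[2.0])
        ms = multiscale.splice(child_rec, parent_rec)
        bags.append(Bag(
            slide_id=s.slide_id,
            instances=np.stack([m.vector for m in ms]),
            refs=[m.ref for m in ms],
            labels=s.grades,
            split=split[s.patient_id],
        ))

    # -- MIL patch classifier + key patches ------------------------------
    mil_cfg = dataclasses.replace(config.mil, feature=feature, seed=config.seed + 4)
    logger.info("training MIL patch classifier (%s)", feature)
    clf, mil_log = mil.train_patch_classifier(bags, mil_cfg)
    mil.save_classifier(ws / "mil_classifier", clf)
    selected = [mil.select_top_k_embeddings(b, clf, mil_cfg.k_select) for b in bags]

    # -- transformer aggregator ------------------------------------------
    agg_cfg = dataclasses.replace(config.aggregator, k_select=mil_cfg.k_select,
                                  seed=config.seed + 5)
    grades = [getattr(b.labels, feature) for b in bags]
    logger.info("training transformer aggregator")
    model, agg_log = train_aggregator(selected, grades, agg_cfg,
                                      splits=[b.split for b in bags])
    save_aggregator(ws / "aggregator", model)

    # -- predict ---------------------------------------------------------
    preds = []
    for b, sel in zip(bags, selected):
        p = aggregate(sel, model, slide_id=b.slide_id, feature=feature)
        preds.append({
            "slide_id": b.slide_id, "split": b.split, "feature": feature,
            "true_grade": getattr(b.labels, feature), "pred_grade": p.grade,
            "binary_score": p.binary_score,
            "mil_score": mil.slide_score(clf, b),
        })
    pred_df = pd.DataFrame(preds)
    pred_df.to_csv(ws / "slide_predictions.csv", index=False)

    # -- stage patients --------------------------------------------------
    # Predicted stages use predicted grades for the modeled feature; the
    # staging matrices read only atrophy (OLGA) and IM (OLGIM) grades.
    pred_grade = dict(zip(pred_df["slide_id"], pred_df["pred_grade"]))
    stage_rows = []
    for pid, grp in truth.slides.groupby("patient_id"):
        sites = {}
        for _, row in grp.iterrows():
            g = {f: 0 for f in FEATURES}
            g[feature] = int(pred_grade[row["slide_id"]])
            sites[row["site"]] = SlideGrades(**g)
        res = stage_patient(PatientRecord(pid, sites), config.staging_rule)
        stage_rows.append({"patient_id": pid, "olga": res.olga, "olgim": res.olgim,
                           "split": split[pid]})
    pred_stage_df = pd.DataFrame(stage_rows)
    pred_stage_df.to_csv(ws / "patient_stage_predictions.csv", index=False)

    # staging from perfect slide grades must reproduce the stored truth
    truth_recheck = staging.stage_frame(
        truth.slides.melt(id_vars=["slide_id", "patient_id", "site", "split"],
                          value_vars=list(FEATURES),
                          var_name="feature", value_name="grade"),
        rule="mean")
    merged = truth_recheck.merge(truth.stages, on="patient_id", suffixes=("_re", ""))
    stage_match = float(((merged["olga_re"] == merged["olga"])
                         & (merged["olgim_re"] == merged["olgim"])).mean())

    # -- evaluate --------------------------------------------------------
    test = pred_df[pred_df["split"] == "test"]
    y_bin = binarize_grades(test["true_grade"])
    report = {
        "config_hash": chash,
        "seed": config.seed,
        "n_patients": spec.n_patients,
        "n_slides": len(bags),
        "feature": feature,
        "mil_final_train_loss": mil_log[-1]["train_loss"] if mil_log else None,
        "aggregator_final_train_loss": agg_log[-1]["train_loss"] if agg_log else None,
        "stage_exact_match_from_true_grades": stage_match,
    }
    if len(np.unique(y_bin)) > 1:
        a = auc(y_bin, test["binary_score"].to_numpy(), n_boot=config.n_boot,
                seed=config.seed + 6)
        sens, spec_ = sens_spec_at_cutoff(y_bin, test["binary_score"].to_numpy())
        report["test_slide_auc"] = a.point
        report["test_slide_auc_ci"] = [a.ci_low, a.ci_high]
        report["test_slide_sensitivity"] = sens
        report["test_slide_specificity"] = spec_
    kap = weighted_kappa(test["true_grade"].to_numpy(), test["pred_grade"].to_numpy(),
                         k=4, weights="quadratic", n_boot=config.n_boot,
                         seed=config.seed + 7)
    report["test_slide_weighted_kappa"] = kap.point
    # patient level: predicted stage vs truth on test patients
    mstage = pred_stage_df.merge(truth.stages, on="patient_id", suffixes=("_pred", ""))
    mtest = mstage[mstage["split"] == "test"]
    col = "olga" if feature == "atrophy" else "olgim"
    if len(mtest) > 1:
        report[f"test_patient_{col}_kappa"] = weighted_kappa(
            mtest[col].to_numpy(), mtest[f"{col}_pred"].to_numpy(), k=5,
            n_boot=0).point
    (ws / "metrics.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("report written to %s", ws / "metrics.json")
    return report
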