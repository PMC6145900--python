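"""End-to-end orchestration: simulate -> preprocess -> split -> train -> compare.

A :class:`RunConfig` fixes every stage's parameters and one master seed; all
per-stage random streams are derived from it by stable named substreams, so a
completed run directory can be re-executed bit-identically at the same scale.
The evaluation stage is the only consumer of the test partition: the training
stage refuses to see test node ids (leakage guard), the test partition is
never oversampled or augmented, and the three models (DualNet, radiomics
random forest, clinical logistic) are compared on the identical test nodes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import extract_radiomics, logistic_benchmark, normalize_features, rf_fit
from .evaluate import EvalReport, evaluate_ene_subset
from .models import ModelSpec, build_model
from .preprocess import NodeSample, PreprocessSpec
from .splits import AugmentPlan, SplitPlan, augment_partition, oversample_ene
from .synthetic import make_desk_dataset
from .training import TrainSpec, samples_to_arrays, train

__all__ = ["RunConfig", "substream", "run_pipeline", "radiomics_for_samples", "covariate_frame"]


def substream(master_seed: int, name: str) -> int:
    """Derive a stable per-stage seed (< 2^31) from the master seed and a name."""
    h = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    out_dir: str = "runs/run"
    seed: int = 0
    scale: str = "desk"  # 'desk' is the CPU-sized configuration
    n_per_class: int = 60
    oversample_factor: int = 2
    rf_estimators: int = 300
    max_epochs: int = 30
    variant: str = "dualnet"
    merge_hpv: bool = False

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def assert_no_test_leakage(train_ids: set[str], test_ids: set[str]) -> None:
    overlap = {i.split("#")[0] for i in train_ids} & {i.split("#")[0] for i in test_ids}
    if overlap:
        raise RuntimeError(
            f"test partition referenced during training: {sorted(overlap)[:5]} ..."
        )


def radiomics_for_samples(samples: list[NodeSample], spacing=(1.5, 1.5, 3.0)) -> pd.DataFrame:
    """Radiomic features from each sample's box input (support = dilated ROI)."""
    rows = []
    for s in samples:
        mask = s.box_input != 0
        rows.append(extract_radiomics(s.box_input, mask, spacing))
    return pd.DataFrame(rows, index=[s.node_id for s in samples])


def covariate_frame(samples: list[NodeSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        d = s.covariates.to_dict()
        d["roi_diameter_mm"] = s.roi_diameter_mm
        rows.append(d)
    return pd.DataFrame(rows, index=[s.node_id for s in samples])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full desk-scale comparison; returns reports and writes artifacts."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(msg):
        log.append(f"[{time.time() - t0:7.1f}s] {msg}")

    if config.scale != "desk":
        raise NotImplementedError("full-resolution runs require external data; use scale='desk'")

    stage("simulate+preprocess+split")
    data = make_desk_dataset(config.n_per_class, seed=substream(config.seed, "phantom"))
    train_s, val_s, test_s = data["train"], data["validation"], data["test"]
    assert_no_test_leakage(
        {s.node_id for s in train_s + val_s}, {s.node_id for s in test_s}
    )

    stage("oversample+augment")
    os_seed = substream(config.seed, "oversample")
    train_os = oversample_ene(train_s, config.oversample_factor, seed=os_seed)
    val_os = oversample_ene(val_s, config.oversample_factor, seed=os_seed + 1)
    train_aug = augment_partition(train_os, AugmentPlan(seed=substream(config.seed, "augment")))

    stage(f"train {config.variant}")
    mspec = ModelSpec.desk(variant=config.variant, merge_hpv=config.merge_hpv)
    tspec = TrainSpec(max_epochs=config.max_epochs, seed=substream(config.seed, "train"))
    model = build_model(mspec, seed=substream(config.seed, "init"))
    _, history = train(model, train_aug, val_os, tspec)

    stage("predict DLNN on test")
    test_inputs, test_targets = samples_to_arrays(test_s)
    probs_dl = model.predict_proba(
        box=test_inputs["box"], small=test_inputs["small"], hpv=test_inputs["hpv"]
    )

    stage("radiomics random forest")
    fit_s = train_s + val_s  # combined train+validation, no augmentation
    spacing = (1.5, 1.5, 3.0)
    feats_fit = radiomics_for_samples(fit_s, spacing)
    feats_test = radiomics_for_samples(test_s, spacing)
    feats_fit_n, scale_series = normalize_features(feats_fit)
    feats_test_n, _ = normalize_features(feats_test, scale_series)
    y_fit = np.array([s.target for s in fit_s])
    rf_seed = substream(config.seed, "rf")
    probs_rf = np.zeros((len(test_s), 2))
    for j in range(2):
        clf = rf_fit(feats_fit_n, y_fit[:, j], n_estimators=config.rf_estimators, seed=rf_seed + j)
        probs_rf[:, j] = clf.predict_proba(feats_test_n.to_numpy())[:, 1]

    stage("clinical logistic benchmark")
    cov_fit = covariate_frame(fit_s)
    cov_test = covariate_frame(test_s)
    probs_lr = np.zeros((len(test_s), 2))
    logit_results = {}
    for j, endpoint in enumerate(("nm", "ene")):
        res = logistic_benchmark(
            cov_fit, y_fit[:, j], endpoint=endpoint, seed=substream(config.seed, f"logit-{endpoint}")
        )
        logit_results[endpoint] = res
        probs_lr[:, j] = res.predict(cov_test)

    stage("evaluate on the common test partition")
    diameters = np.array([s.roi_diameter_mm for s in test_s])
    reports: dict[str, dict[str, EvalReport]] = {}
    for name, probs in (("dualnet", probs_dl), ("random_forest", probs_rf), ("logistic", probs_lr)):
        reports[name] = evaluate_ene_subset(
            diameters, probs[:, 0], probs[:, 1], test_targets[:, 0], test_targets[:, 1], model=name
        )

    # ---- artifacts --------------------------------------------------------
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "split_counts": data["split"].counts,
        "n_train_aug": len(train_aug),
        "n_val_oversampled": len(val_os),
        "best_epoch": history.best_epoch,
        "elapsed_s": round(time.time() - t0, 1),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    hist_df = pd.DataFrame(
        {
            "epoch": np.arange(1, len(history.val_loss) + 1),
            "train_loss": history.train_loss,
            "val_loss": history.val_loss,
            "lr": history.lr,
            "checkpoint": history.checkpoint,
        }
    )
    hist_df.to_csv(out / "history.tsv", sep="\t", index=False)
    report_json = {
        m: {e: r.to_dict() for e, r in eps.items()} for m, eps in reports.items()
    }
    (out / "reports.json").write_text(json.dumps(report_json, indent=2))
    text = "\n\n".join(r.to_text() for eps in reports.values() for r in eps.values())
    (out / "reports.txt").write_text(text + "\n")
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return {"reports": reports, "history": history, "manifest": manifest, "logit": logit_results}
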