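"""End-to-end orchestration: simulate -> label -> split -> balance -> train -> evaluate.

Every stage communicates through declared file interfaces (cohort manifests,
fold tables, report CSVs), so a run can be replayed from any intermediate
artifact.  Each run writes a provenance record (config hash, seeds, library
versions) and a plain-text log with per-stage input/output counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .angiosomes import DEFAULT_FRACTIONS, PartitionError, grade_thermogram
from .balancing import AugmentationPolicy, inverse_frequency_weights, offline_balance
from .classifier import (
    Model,
    NetworkConfig,
    TrainConfig,
    build_network,
    predict,
    save_model,
    train_network,
)
from .cohort import LabeledCohort, load_cohort
from .core import DEFAULT_WINDOW, EncodeMode, encode_for_network, segment_foot
from .evaluation import EvalReport, classwise_metrics, confusion, stratified_folds
from .synthetic import generate_cohort

__all__ = ["ConfigError", "validate_config", "label_cohort", "encode_cohort", "run_pipeline"]

log = logging.getLogger("thermofoot")


class ConfigError(ValueError):
    """Raised for invalid or incomplete pipeline configuration."""


_DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": None,  # e.g. {"per_class": {0: 5, ...}, "noise_sd": 0.1}
    "cohort": None,  # manifest path for an externally prepared cohort
    "label": {
        "window": list(DEFAULT_WINDOW),
        "fractions": list(DEFAULT_FRACTIONS),
        "ambient_ceiling": 22.0,
    },
    "encode": {"mode": "rectangular"},
    "folds": {},  # k is required, no default: an unset k is a config error
    "balance": {"target_per_class": None, "policy": {}},
    "network": {},
    "training": {
        "epochs": 30,
        "batch_size": 32,
        "learning_rate": 1e-3,
        "use_class_weights": True,
        "online_augment": True,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def validate_config(config: dict) -> dict:
    """Merge with defaults and fail fast on missing/invalid required keys."""
    cfg = _merge(_DEFAULT_CONFIG, config or {})
    folds = cfg.get("folds") or {}
    if "k" not in folds:
        raise ConfigError("config missing required key folds.k")
    if not isinstance(folds["k"], int) or folds["k"] < 2:
        raise ConfigError(f"folds.k must be an integer >= 2, got {folds['k']!r}")
    if cfg.get("simulate") is None and cfg.get("cohort") is None:
        raise ConfigError("config needs either a simulate section or a cohort manifest")
    if cfg["training"]["epochs"] < 1:
        raise ConfigError("training.epochs must be >= 1")
    mode = cfg["encode"]["mode"]
    try:
        EncodeMode(mode)
    except ValueError as exc:
        raise ConfigError(f"unknown encode.mode {mode!r}") from exc
    if "seed" not in cfg or cfg["seed"] is None:
        raise ConfigError("config must pin a seed")
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def label_cohort(
    cohort: LabeledCohort,
    *,
    fractions: tuple[float, float] = DEFAULT_FRACTIONS,
    ambient_ceiling: float = 22.0,
) -> pd.DataFrame:
    """Grade every foot: regional means, TCI and class, one row per sample.

    Feet that cannot be segmented or partitioned are flagged in the `error`
    column and skipped by downstream stages; the run continues.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rows = []
    for rec in cohort:
        row: dict = {
            "subject_id": rec.sample_id,
            "side": rec.thermogram.side.value,
            "group": rec.thermogram.group.value,
        }
        try:
            res = grade_thermogram(
                rec.thermogram,
                fractions=tuple(fractions),
                ambient_ceiling=ambient_ceiling,
            )
        except (PartitionError, ValueError) as exc:
            row.update(
                {m: np.nan for m in ("mean_MPA", "mean_LPA", "mean_MCA", "mean_LCA")}
            )
            row.update({"tci": np.nan, "class": pd.NA, "error": str(exc)})
        else:
            row.update(
                {
                    "mean_MPA": res.regional_means[0],
                    "mean_LPA": res.regional_means[1],
                    "mean_MCA": res.regional_means[2],
                    "mean_LCA": res.regional_means[3],
                    "tci": res.tci,
                    "class": res.severity_class,
                    "error": "",
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def encode_cohort(
    cohort: LabeledCohort,
    mode: EncodeMode | str = EncodeMode.RECTANGULAR,
    window: tuple[float, float] = DEFAULT_WINDOW,
    ambient_ceiling: float = 22.0,
) -> np.ndarray:
    """Segment and encode every record; returns an (N, H, W) float array."""
    arrays = []
    for rec in cohort:
        mask = segment_foot(rec.thermogram, ambient_ceiling=ambient_ceiling)
        arrays.append(
            encode_for_network(rec.thermogram, mask, mode=mode, window=window).values
        )
    return np.stack(arrays)


def _class_histogram(labels) -> dict[str, int]:
    vals, counts = np.unique(np.asarray(labels, dtype=int), return_counts=True)
    return {str(int(v)): int(c) for v, c in zip(vals, counts)}


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute all stages in order and return the run summary dict.

    Artifacts per run: cohort/ (matrices + manifest), labeling.csv,
    folds.csv, per-fold reports + checkpoints, summary.json, run.log,
    provenance.json.  Deterministic given the same config.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_pipeline(cfg, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_pipeline(cfg: dict, outdir: Path) -> dict:
    seed = int(cfg["seed"])
    provenance = {
        "config_hash": _config_hash(cfg),
        "config": cfg,
        "seed": seed,
        "versions": {"thermofoot": __version__, "numpy": np.__version__},
    }
    with (outdir / "provenance.json").open("w") as fh:
        json.dump(provenance, fh, indent=2, default=str)

    # --- stage: simulate or load -------------------------------------------
    if cfg["simulate"] is not None:
        sim = cfg["simulate"]
        per_class = {int(k): int(v) for k, v in sim["per_class"].items()}
        cohort = generate_cohort(
            per_class,
            seed=seed,
            noise_sd=float(sim.get("noise_sd", 0.0)),
            shape=tuple(sim.get("shape", (180, 80))),
            out_dir=outdir / "cohort",
        )
        log.info("simulate: generated %d thermograms -> %s", len(cohort), outdir / "cohort")
    else:
        cohort = load_cohort(cfg["cohort"])
        log.info("load: read %d thermograms from %s", len(cohort), cfg["cohort"])

    # --- stage: label -------------------------------------------------------
    lbl_cfg = cfg["label"]
    labeling = label_cohort(
        cohort,
        fractions=tuple(lbl_cfg["fractions"]),
        ambient_ceiling=float(lbl_cfg["ambient_ceiling"]),
    )
    labeling.to_csv(outdir / "labeling.csv", index=False)
    ok = labeling["error"] == ""
    usable_idx = np.flatnonzero(ok.to_numpy())
    labels = labeling.loc[ok, "class"].astype(int).to_numpy()
    hist = _class_histogram(labels)
    with (outdir / "class_histogram.json").open("w") as fh:
        json.dump(hist, fh, indent=2)
    log.info("label: %d/%d feet graded, histogram=%s", len(usable_idx), len(cohort), hist)
    cohort = cohort.subset(usable_idx).with_updated_labels(list(labels))

    # --- stage: split -------------------------------------------------------
    k = int(cfg["folds"]["k"])
    split = stratified_folds(cohort.labels, k=k, seed=seed)
    pd.DataFrame(
        {
            "subject_id": [r.sample_id for r in cohort],
            "class": cohort.labels,
            "fold": split.assignments,
        }
    ).to_csv(outdir / "folds.csv", index=False)
    log.info("split: %d samples into %d stratified folds", len(cohort), k)

    # --- stages per fold: balance, train, evaluate -------------------------
    window = tuple(lbl_cfg["window"])
    ceiling = float(lbl_cfg["ambient_ceiling"])
    mode = EncodeMode(cfg["encode"]["mode"])
    tr_cfg = cfg["training"]
    pol_kwargs = dict(cfg["balance"].get("policy", {}))
    pol_kwargs.setdefault("seed", seed)
    policy = AugmentationPolicy(**pol_kwargs)
    # 6-class when controls are present (labels 0..5); diabetic-only cohorts
    # run the 5-class task with labels shifted to 0..4
    has_controls = "0" in hist
    num_classes = 6 if has_controls else 5
    if not has_controls:
        cohort = cohort.with_updated_labels([int(l) - 1 for l in cohort.labels])
    net_over = dict(cfg["network"])
    if "conv_filters" in net_over:
        net_over["conv_filters"] = tuple(net_over["conv_filters"])
    if "input_shape" in net_over:
        net_over["input_shape"] = tuple(net_over["input_shape"])
    net_over.setdefault("num_classes", num_classes)
    net_over.setdefault(
        "input_shape", EncodeMode(mode).target_shape
    )
    net_cfg = NetworkConfig(**net_over)

    fold_reports: list[EvalReport] = []
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for fold, train_idx, val_idx in split:
        train_cohort = cohort.subset(train_idx)
        val_cohort = cohort.subset(val_idx)

        balanced = offline_balance(
            train_cohort,
            policy,
            target_per_class=cfg["balance"].get("target_per_class"),
            seed=seed + fold,
        )
        balanced.manifest().to_csv(outdir / f"fold{fold}_train_manifest.csv", index=False)
        log.info(
            "balance fold %d: train %d -> %d (target hit), val untouched %d",
            fold, len(train_cohort), len(balanced), len(val_cohort),
        )

        x_train = encode_cohort(balanced, mode, window, ceiling)
        y_train = balanced.labels
        x_val = encode_cohort(val_cohort, mode, window, ceiling)
        y_val = val_cohort.labels

        class_weights = None
        if tr_cfg.get("use_class_weights", True):
            counts = np.bincount(y_train, minlength=num_classes)
            class_weights = inverse_frequency_weights(np.maximum(counts, 1))
        online = policy if tr_cfg.get("online_augment", True) else None
        model = build_network(net_cfg, seed=seed + fold)
        history = train_network(
            model,
            x_train,
            y_train,
            x_val,
            y_val,
            TrainConfig(
                epochs=int(tr_cfg["epochs"]),
                batch_size=int(tr_cfg["batch_size"]),
                learning_rate=float(tr_cfg["learning_rate"]),
                class_weights=class_weights,
                online_policy=online,
                seed=seed + fold,
            ),
        )
        pd.DataFrame(history).to_csv(outdir / f"fold{fold}_history.csv", index=False)
        save_model(model, outdir / f"fold{fold}_model.npz")

        y_hat, _ = predict(model, x_val)
        cm = confusion(y_val, y_hat, num_classes)
        report = classwise_metrics(cm, fold=fold)
        fold_reports.append(report)
        pooled_true.append(y_val)
        pooled_pred.append(y_hat)
        report.to_frame().to_csv(outdir / f"fold{fold}_report.csv")
        np.savetxt(outdir / f"fold{fold}_confusion.csv", cm, fmt="%d", delimiter=",")
        log.info(
            "evaluate fold %d: %d val samples, macro=%s",
            fold, len(val_cohort), {k_: round(v, 4) for k_, v in report.macro().items()},
        )

    # --- stage: aggregate ---------------------------------------------------
    macro_over_folds = {
        name: float(np.mean([r.macro()[name] for r in fold_reports]))
        for name in fold_reports[0].macro()
    }
    pooled_cm = confusion(
        np.concatenate(pooled_true), np.concatenate(pooled_pred), num_classes
    )
    pooled_report = classwise_metrics(pooled_cm)
    np.savetxt(outdir / "pooled_confusion.csv", pooled_cm, fmt="%d", delimiter=",")
    pooled_report.to_frame().to_csv(outdir / "pooled_report.csv")

    summary = {
        "config_hash": provenance["config_hash"],
        "n_samples": len(cohort),
        "class_histogram": hist,
        "k": k,
        "macro_over_folds": macro_over_folds,
        "pooled": pooled_report.to_json_dict(),
        "per_fold": [r.to_json_dict() for r in fold_reports],
    }
    with (outdir / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("aggregate: %d folds, macro_over_folds=%s",
             k, {k_: round(v, 4) for k_, v in macro_over_folds.items()})
    return summary
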