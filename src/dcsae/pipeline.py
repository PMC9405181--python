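"""End-to-end pipeline: normalize -> select -> (tune) -> train -> evaluate.

A :class:`PipelineConfig` mirrors the module configurations in nested
sections and can be loaded from a YAML file.  :func:`run_pipeline` executes
the stages in order inside a stratified cross-validation harness — min-max
normalization and feature selection are re-fitted on every training fold to
avoid leakage — then fits a final model on the full table and writes masks,
model, reports and a manifest into a run directory.  All randomness derives
from the explicit seeds in the config, so a rerun with the same config
reproduces every numeric output.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import coa, kha, metrics
from .data import (
    FeatureTable,
    apply_minmax,
    fit_minmax,
    read_feature_table,
    write_feature_table,
)
from .model import DcsaeConfig, make_views, predict, train_dcsae
from .synth import SynthConfig, generate

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_model", "load_model"]


@dataclass
class PipelineConfig:
    """Nested pipeline settings; defaults follow the reference protocol
    (learning rate 0.01, dropout 0.5, 50 epochs, 10-fold CV)."""

    data_path: str | None = None
    label_column: str = "y"
    label_scheme: str = "binary"
    synth: SynthConfig | None = None
    selection_enabled: bool = True
    selection_alpha: float = 0.99
    coa_packs: int = 2
    coa_coyotes: int = 5
    coa_iterations: int = 20
    tuning_enabled: bool = False
    kha_krill: int = 8
    kha_iterations: int = 10
    model: DcsaeConfig = field(default_factory=DcsaeConfig)
    cv_folds: int = 10
    seed: int = 0
    output_dir: str = "runs/latest"

    def __post_init__(self) -> None:
        if self.data_path is None and self.synth is None:
            raise ValueError("config needs either data_path or a synth section")


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file with nested sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    synth_raw = raw.pop("synth", None)
    model_raw = raw.pop("model", None)
    kwargs = dict(raw)
    if synth_raw is not None:
        if "informative_indices" in synth_raw:
            synth_raw["informative_indices"] = tuple(synth_raw["informative_indices"])
        kwargs["synth"] = SynthConfig(**synth_raw)
    if model_raw is not None:
        for key in ("hidden_sizes_f", "hidden_sizes_g"):
            if key in model_raw:
                model_raw[key] = tuple(model_raw[key])
        kwargs["model"] = DcsaeConfig(**model_raw)
    return PipelineConfig(**kwargs)


def _load_table(config: PipelineConfig) -> FeatureTable:
    if config.data_path is not None:
        return read_feature_table(
            config.data_path, config.label_column, config.label_scheme
        )
    table, _ = generate(config.synth)
    return table


def _fold_fit_predict(config: PipelineConfig):
    """Build the per-fold train/predict callback; stashes masks and scores."""
    records: list[dict] = []

    def fit_predict(train_x, train_y, test_x):
        params = fit_minmax(FeatureTable(train_x, train_y))
        tr = apply_minmax(FeatureTable(train_x, train_y), params)
        te = apply_minmax(FeatureTable(test_x, np.zeros(len(test_x), dtype=int)), params)
        tr_values, te_values = tr.values, te.values
        mask_idx = np.arange(train_x.shape[1])
        if config.selection_enabled:
            d = train_x.shape[1]
            coa_cfg = coa.CoaConfig(
                np.zeros(d),
                np.ones(d),
                n_packs=config.coa_packs,
                coyotes_per_pack=config.coa_coyotes,
                max_iterations=config.coa_iterations,
                rng_seed=config.seed,
            )
            fit_cfg = coa.FsFitnessConfig(
                total_features=d,
                error_estimator=coa.make_cv_error_estimator(
                    tr_values, train_y, seed=config.seed
                ),
                alpha_weight=config.selection_alpha,
            )
            mask, cost, _ = coa.select_features(tr_values, train_y, coa_cfg, fit_cfg)
            mask_idx = mask.indices
            tr_values = tr_values[:, mask_idx]
            te_values = te_values[:, mask_idx]
        else:
            cost = None
        model_cfg = replace(config.model, rng_seed=config.seed)
        model = train_dcsae(make_views(tr_values, train_y, model_cfg.view_mode), model_cfg)
        pred, scores = predict(model, te_values)
        records.append(
            {"mask": mask_idx.tolist(), "cost": cost, "scores": scores, "pred": pred}
        )
        return pred

    return fit_predict, records


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and write all artifacts to the run directory.

    Returns the run directory path.  Artifacts: ``table.csv`` (input data),
    ``mask.txt``/``mask.json`` (selected features, final fit),
    ``model.npz``/``model.json``, ``report.json`` (per-fold and pooled
    metrics), ``roc.csv``, ``summary.csv`` and ``manifest.json`` (seeds,
    stage timings; the only file containing wall-clock times).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {"seed": config.seed, "stages": []}

    t0 = time.perf_counter()
    table = _load_table(config)
    write_feature_table(table, out / "table.csv", config.label_column)
    timings["data"] = time.perf_counter() - t0
    manifest["stages"].append("data")
    manifest["n_samples"] = table.n_samples
    manifest["n_features"] = table.n_features

    # Cross-validated evaluation with per-fold refit of every stage.
    t0 = time.perf_counter()
    fit_predict, records = _fold_fit_predict(config)
    fold_reports, pooled, pooled_cm = metrics.kfold_evaluate(
        table.values, table.labels, fit_predict, k=config.cv_folds, seed=config.seed
    )
    timings["cross_validation"] = time.perf_counter() - t0
    manifest["stages"].append("cross_validation")

    # Pooled ROC over the test folds.
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    test_labels = np.concatenate(
        [table.labels[te] for _, te in skf.split(table.values, table.labels)]
    )
    all_scores = np.vstack([r["scores"] for r in records])
    roc_curves, macro_auc = metrics.roc_curve(all_scores, test_labels, pooled.class_labels)

    # Final fit on the full table (normalize -> select -> optional tune -> train).
    t0 = time.perf_counter()
    params = fit_minmax(table)
    norm = apply_minmax(table, params)
    values = norm.values
    mask_idx = np.arange(table.n_features)
    best_cost = None
    if config.selection_enabled:
        d = table.n_features
        coa_cfg = coa.CoaConfig(
            np.zeros(d),
            np.ones(d),
            n_packs=config.coa_packs,
            coyotes_per_pack=config.coa_coyotes,
            max_iterations=config.coa_iterations,
            rng_seed=config.seed,
        )
        fit_cfg = coa.FsFitnessConfig(
            total_features=d,
            error_estimator=coa.make_cv_error_estimator(values, table.labels, seed=config.seed),
            alpha_weight=config.selection_alpha,
        )
        mask, best_cost, trace = coa.select_features(
            values, table.labels, coa_cfg, fit_cfg
        )
        mask_idx = mask.indices
        values = values[:, mask_idx]
        (out / "mask.txt").write_text(
            "\n".join(table.feature_names[i] for i in mask_idx) + "\n"
        )
        (out / "mask.json").write_text(
            json.dumps(
                {
                    "n_selected": int(len(mask_idx)),
                    "indices": mask_idx.tolist(),
                    "best_cost": best_cost,
                    "alpha": config.selection_alpha,
                    "beta": 1.0 - config.selection_alpha,
                    "seed": config.seed,
                    "iterations": config.coa_iterations,
                    "trace": trace,
                },
                indent=2,
            )
        )
    timings["selection"] = time.perf_counter() - t0
    manifest["stages"].append("selection")

    model_cfg = replace(config.model, rng_seed=config.seed)
    if config.tuning_enabled:
        t0 = time.perf_counter()
        space = kha.HyperparamSpace.default()
        kha_cfg = kha.KhaConfig(
            np.zeros(space.n_dims),
            np.ones(space.n_dims),
            n_krill=config.kha_krill,
            max_iterations=config.kha_iterations,
            rng_seed=config.seed,
        )
        model_cfg, tuned_err, tune_trace, tune_log = kha.tune_dcsae(
            values, table.labels, space, kha_cfg, model_cfg
        )
        model_cfg = replace(model_cfg, rng_seed=config.seed)
        with open(out / "tuning.csv", "w") as fh:
            fh.write("iteration,best_fitness\n")
            for i, v in enumerate(tune_trace):
                fh.write(f"{i},{v}\n")
        (out / "tuned_config.json").write_text(
            json.dumps({**_config_dict(model_cfg), "validation_error": tuned_err}, indent=2)
        )
        timings["tuning"] = time.perf_counter() - t0
        manifest["stages"].append("tuning")

    t0 = time.perf_counter()
    model = train_dcsae(make_views(values, table.labels, model_cfg.view_mode), model_cfg)
    save_model(model, out / "model.npz", out / "model.json")
    timings["training"] = time.perf_counter() - t0
    manifest["stages"].append("training")

    # Reports.
    report = {
        "pooled": pooled.to_dict(),
        "per_fold": [r.to_dict() for r in fold_reports],
        "pooled_confusion": pooled_cm.counts.tolist(),
        "macro_auc": macro_auc,
        "n_selected_features": int(len(mask_idx)),
        "best_cost": best_cost,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    _write_summary_csv(out / "summary.csv", fold_reports, pooled)
    with open(out / "roc.csv", "w") as fh:
        fh.write("class,fpr,tpr,threshold\n")
        for c, (fpr, tpr, thr, _) in roc_curves.items():
            for x, y, t in zip(fpr, tpr, thr):
                fh.write(f"{c},{x},{y},{t}\n")
    manifest["timings_seconds"] = timings
    manifest["config"] = _config_dict(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _config_dict(cfg) -> dict:
    d = asdict(cfg)
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _write_summary_csv(path, fold_reports, pooled) -> None:
    """Per-fold rows plus a pooled row, one column per averaged metric."""
    cols = ["sensitivity", "specificity", "precision", "accuracy", "f_score", "mcc"]
    with open(path, "w") as fh:
        fh.write("fold," + ",".join(cols) + "\n")
        for i, rep in enumerate(fold_reports):
            vals = [rep.averaged.get(c, rep.accuracy if c == "accuracy" else 0.0) for c in cols]
            vals[cols.index("accuracy")] = rep.accuracy
            fh.write(f"{i}," + ",".join(f"{v:.6f}" for v in vals) + "\n")
        vals = [pooled.averaged.get(c, 0.0) for c in cols]
        vals[cols.index("accuracy")] = pooled.accuracy
        fh.write("pooled," + ",".join(f"{v:.6f}" for v in vals) + "\n")


def save_model(model, npz_path, json_path) -> None:
    """Serialize parameter arrays plus a JSON manifest of the config."""
    arrays: dict[str, np.ndarray] = {}
    for name, net in (
        ("enc_f", model.encoder_f),
        ("dec_f", model.decoder_f),
        ("enc_g", model.encoder_g),
        ("dec_g", model.decoder_g),
    ):
        for i, (w, b) in enumerate(zip(net.weights, net.biases)):
            arrays[f"{name}_w{i}"] = w
            arrays[f"{name}_b{i}"] = b
    arrays["u"] = model.u
    arrays["v"] = model.v
    if model.class_centroids is not None:
        arrays["centroids"] = model.class_centroids
        arrays["class_labels"] = model.class_labels
    np.savez(npz_path, **arrays)
    Path(json_path).write_text(
        json.dumps(
            {
                "config": _config_dict(model.config),
                "n_components": model.n_components,
                "activations": {
                    "encoder_f": list(model.encoder_f.activations),
                    "encoder_g": list(model.encoder_g.activations),
                    "decoder_f": list(model.decoder_f.activations),
                    "decoder_g": list(model.decoder_g.activations),
                },
                "training_log": model.training_log,
            },
            indent=2,
        )
    )


def load_model(npz_path, json_path):
    """Inverse of :func:`save_model`."""
    from .model import DcsaeModel, Mlp

    meta = json.loads(Path(json_path).read_text())
    cfg_raw = meta["config"]
    for key in ("hidden_sizes_f", "hidden_sizes_g"):
        cfg_raw[key] = tuple(cfg_raw[key])
    cfg = DcsaeConfig(**cfg_raw)
    data = np.load(npz_path)
    nets = {}
    rng = np.random.default_rng(0)
    for name in ("enc_f", "dec_f", "enc_g", "dec_g"):
        ws, bs = [], []
        i = 0
        while f"{name}_w{i}" in data:
            ws.append(data[f"{name}_w{i}"])
            bs.append(data[f"{name}_b{i}"])
            i += 1
        sizes = (ws[0].shape[0], *(w.shape[1] for w in ws))
        key = {"enc_f": "encoder_f", "enc_g": "encoder_g",
               "dec_f": "decoder_f", "dec_g": "decoder_g"}[name]
        net = Mlp(sizes, tuple(meta["activations"][key]), rng)
        net.weights = ws
        net.biases = bs
        nets[name] = net
    model = DcsaeModel(
        nets["enc_f"], nets["dec_f"], nets["enc_g"], nets["dec_g"],
        cfg, meta["n_components"],
        u=data["u"], v=data["v"],
        training_log=meta["training_log"],
    )
    if "centroids" in data:
        model.class_centroids = data["centroids"]
        model.class_labels = data["class_labels"]
    return model
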