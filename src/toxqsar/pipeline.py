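"""End-to-end orchestration: generate/ingest -> screen -> split -> (tune) ->
fit -> evaluate -> validate -> sensitize, with JSON report bundling.

Leakage discipline: the external test rows are only touched by the final
evaluation; every fitted statistic (filters, scalers, fold models, tuning)
comes from training rows.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import bnn, ensemble, gbm, symreg, tuning, validation
from .datamodel import (CompoundTable, PredictionSet, read_table, write_table,
                        summarize, ValidationError, DEFAULT_MONOTONE,
                        TARGET_NAME)
from .metrics import (conformal_intervals, interval_metrics, metrics_report,
                      point_metrics, residual_diagnostics, rto_validation)
from .partition import FoldPlan, SplitPlan, cluster_aware_split, kfold
from .preprocess import (filter_correlated, filter_low_variance, rank_select,
                         standardize)
from .sensitivity import directional_analysis
from .synthetic import GeneratorConfig, calibrate, generate

logger = logging.getLogger("toxqsar")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (documented scheme: SeedSequence of
    the global seed and the CRC32 of the stage name)."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0])


@dataclass
class PipelineConfig:
    seed: int = 0
    input_path: Optional[str] = None
    n_synthetic: int = 800
    test_fraction: float = 0.2
    n_clusters: int = 10
    var_tau: float = 1e-8
    r_max: float = 0.9
    k_select: Optional[int] = None        # None = keep all survivors
    cv_folds: int = 10
    models: tuple = ("gbm", "bnn", "ensemble")
    tune_budget: int = 0
    nominal: float = 0.95
    n_perm: int = 20
    n_anchors: int = 200
    grid_size: int = 21
    gbm_overrides: dict = field(default_factory=dict)
    bnn_overrides: dict = field(default_factory=dict)
    sr_overrides: dict = field(default_factory=dict)
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.input_path is not None and self.n_synthetic:
            # exactly one input source: a provided path wins
            self.n_synthetic = 0
        if not self.models:
            raise ValidationError("no models enabled")
        unknown = set(self.models) - {"gbm", "bnn", "sr", "ensemble"}
        if unknown:
            raise ValidationError(f"unknown models {sorted(unknown)}")
        if "ensemble" in self.models and not {"gbm", "bnn"} <= set(self.models):
            raise ValidationError("ensemble requires both gbm and bnn members")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _log_stage(name: str, t0: float) -> None:
    logger.info("[%s] done in %.2fs", name, time.time() - t0)


class _GBMAdapter:
    """fit/predict_set wrapper giving the point model CV-residual conformal
    intervals (5-fold internal)."""

    def __init__(self, config: gbm.GBMConfig, columns, level=0.95):
        self.config = config
        self.columns = columns
        self.level = level
        self.model = None
        self._q_residuals = None

    def fit(self, X, y):
        inner = kfold(len(y), k=5, seed=self.config.seed + 13)
        resid = np.empty(len(y))
        for f in range(1, 6):
            tr, va = inner.train_indices(f), inner.val_indices(f)
            m = gbm.fit(X[tr], y[tr], self.config, columns=self.columns)
            resid[va] = y[va] - m.predict(X[va])
        self._q_residuals = resid
        self.model = gbm.fit(X, y, self.config, columns=self.columns)
        return self

    def predict(self, X):
        return self.model.predict(X)

    def predict_set(self, X, y=None) -> PredictionSet:
        y_hat = self.model.predict(X)
        obs = y_hat if y is None else y
        return conformal_intervals(obs, y_hat, self._q_residuals, self.level)


class _BNNAdapter:
    def __init__(self, config: bnn.BNNConfig):
        self.config = config
        self.model = None

    def fit(self, X, y):
        self.model = bnn.fit(X, y, self.config)
        return self

    def predict(self, X):
        return bnn.predict_dist(self.model, X).y_hat

    def predict_set(self, X, y=None) -> PredictionSet:
        return bnn.predict_dist(self.model, X, y=y)


def _cv_metrics(adapter_factory, X, y, folds: FoldPlan, nominal: float):
    """Out-of-fold metrics and the per-fold table (report schema)."""
    oof = np.empty(len(y))
    fold_rows = []
    fold_models = []
    for f in range(1, folds.k + 1):
        tr, va = folds.train_indices(f), folds.val_indices(f)
        ad = adapter_factory().fit(X[tr], y[tr])
        pred = np.asarray(ad.predict(X[va]), dtype=float)
        oof[va] = pred
        ps = PredictionSet(y[va], pred)
        pm = point_metrics(ps)
        fold_rows.append({
            "fold": f, "train_size": len(tr), "val_size": len(va),
            "rmse": pm.rmse, "r2": pm.r2,
            "mean_actual": float(y[va].mean()),
            "mean_predicted": float(pred.mean()),
            "std_actual": float(y[va].std(ddof=1)),
            "std_predicted": float(pred.std(ddof=1)),
        })
        fold_models.append(ad)
    pm = point_metrics(PredictionSet(y, oof))
    return pm, fold_rows, oof, fold_models


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages and return the bundled run report."""
    report: dict = {"provenance": {"seed": config.seed,
                                   "config": config.to_dict(),
                                   "config_hash": config.config_hash()}}
    try:
        return _run(config, report)
    except ValidationError:
        raise
    except Exception as exc:
        stage = report.get("_stage", "unknown")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc


def _run(config: PipelineConfig, report: dict) -> dict:
    nominal = config.nominal

    # ------------------------------------------------------------ ingest
    report["_stage"] = "ingest"
    t0 = time.time()
    if config.input_path:
        table = read_table(config.input_path)
        gen_cfg = None
    else:
        gen_cfg = calibrate(GeneratorConfig())
        table = generate(gen_cfg, config.n_synthetic,
                         seed=stage_seed(config.seed, "generate"))
    if table.y is None:
        raise ValidationError("input table has no target column")
    report["data"] = {"n": table.n, "p": table.p, "columns": table.columns,
                      "summary": summarize(table)}
    _log_stage("ingest", t0)

    # ------------------------------------------------------------- split
    report["_stage"] = "split"
    t0 = time.time()
    split = cluster_aware_split(table.X, config.test_fraction,
                                config.n_clusters,
                                seed=stage_seed(config.seed, "split"))
    train = table.subset(split.train_idx)
    test = table.subset(split.test_idx)
    test_hash = hashlib.sha256(test.X.tobytes()).hexdigest()
    report["split"] = {"n_train": train.n, "n_test": test.n,
                       "rebalanced_count": split.rebalanced_count,
                       "clusters_in_test": sorted(split.clusters_in_test)}
    _log_stage("split", t0)

    # -------------------------------------------------------- preprocess
    report["_stage"] = "preprocess"
    t0 = time.time()
    train_f, dropped_var = filter_low_variance(train, config.var_tau)
    train_f, dropped_corr = filter_correlated(train_f, config.r_max)
    folds = kfold(train_f.n, config.cv_folds,
                  seed=stage_seed(config.seed, "cv"))
    if config.k_select is not None:
        sel_report = rank_select(train_f, config.k_select, folds)
        keep = [nm for nm, _ in sel_report.selected]
        selected = [(nm, s) for nm, s in sel_report.selected]
    else:
        keep = train_f.columns
        selected = None
    train_r = train.select_columns(keep)
    test_r = test.select_columns(keep)
    train_z, scaler = standardize(train_r, train_r)
    test_z, _ = (standardize(train_r, test_r)[0], None)
    report["preprocess"] = {
        "dropped_low_variance": dropped_var,
        "dropped_correlated": [[a, b, r] for a, b, r in dropped_corr],
        "selected": selected, "kept_columns": keep,
    }
    _log_stage("preprocess", t0)

    constraints = {nm: DEFAULT_MONOTONE.get(nm, 0) for nm in keep}
    gbm_kwargs = {"constraints": constraints,
                  "seed": stage_seed(config.seed, "gbm"),
                  **config.gbm_overrides}

    # ------------------------------------------------------------ tuning
    report["_stage"] = "tune"
    if config.tune_budget > 0 and "gbm" in config.models:
        t0 = time.time()
        space = tuning.gbm_search_space()
        tune_folds = kfold(train_z.n, min(3, config.cv_folds),
                           seed=stage_seed(config.seed, "tunefolds"))

        def objective(hp: dict) -> float:
            losses = []
            for f in range(1, tune_folds.k + 1):
                tr = tune_folds.train_indices(f)
                va = tune_folds.val_indices(f)
                ad = _GBMAdapter(gbm.GBMConfig(**{**gbm_kwargs, **hp}),
                                 keep, nominal)
                ad.fit(train_z.X[tr], train_z.y[tr])
                ps = ad.predict_set(train_z.X[va], train_z.y[va])
                losses.append(tuning.composite_loss(
                    point_metrics(ps), interval_metrics(ps, nominal)))
            return float(np.mean(losses))

        result = tuning.optimize(objective, space, config.tune_budget,
                                 seed=stage_seed(config.seed, "tune"))
        gbm_kwargs.update(result.best_config)
        report["tuning"] = result.to_dict()
        _log_stage("tune", t0)

    # --------------------------------------------------------------- fit
    report["_stage"] = "fit"
    t0 = time.time()
    adapters = {}
    cv_rmse = {}
    report["cv"] = {}
    report["importances"] = None

    if "gbm" in config.models:
        class _PlainGBM:
            def fit(self, X, y):
                self.model = gbm.fit(X, y, gbm.GBMConfig(**gbm_kwargs),
                                     columns=keep)
                return self

            def predict(self, X):
                return self.model.predict(X)

        pm, fold_rows, oof, fold_models = _cv_metrics(
            _PlainGBM, train_z.X, train_z.y, folds, nominal)
        cv_rmse["gbm"] = pm.rmse
        report["cv"]["gbm"] = {"oof": pm.to_dict(), "folds": fold_rows}
        report["importances"] = gbm.average_importance(
            [fm.model for fm in fold_models])
        # final refit; intervals are CV-residual conformal from the OOF errors
        final_gbm = _GBMAdapter(gbm.GBMConfig(**gbm_kwargs), keep, nominal)
        final_gbm.model = gbm.fit(train_z.X, train_z.y,
                                  gbm.GBMConfig(**gbm_kwargs), columns=keep)
        final_gbm._q_residuals = train_z.y - oof
        adapters["gbm"] = final_gbm

    if "bnn" in config.models:
        bnn_cfg = bnn.BNNConfig(seed=stage_seed(config.seed, "bnn"),
                                **config.bnn_overrides)

        def bnn_factory():
            return _BNNAdapter(bnn_cfg)
        pm, fold_rows, oof, _ = _cv_metrics(
            bnn_factory, train_z.X, train_z.y, folds, nominal)
        cv_rmse["bnn"] = pm.rmse
        report["cv"]["bnn"] = {"oof": pm.to_dict(), "folds": fold_rows}
        adapters["bnn"] = bnn_factory().fit(train_z.X, train_z.y)

    if "sr" in config.models:
        sr_cfg = symreg.SRConfig(seed=stage_seed(config.seed, "sr"),
                                 **config.sr_overrides)
        champ, hof = symreg.evolve(train_z.X, train_z.y, sr_cfg, columns=keep)
        report["sr"] = {"expression": champ.to_infix(),
                        "prefix": champ.to_prefix(),
                        "train_rmse": champ.rmse,
                        "complexity": list(champ.complexity()),
                        "hall_of_fame": [e.to_infix() for e in hof]}
        adapters["sr"] = champ
    _log_stage("fit", t0)

    # ---------------------------------------------------------- evaluate
    report["_stage"] = "evaluate"
    t0 = time.time()
    pred_sets = {}
    report["test"] = {}
    for name in ("gbm", "bnn"):
        if name in adapters:
            ps = adapters[name].predict_set(test_z.X, test_z.y)
            pred_sets[name] = ps
    if "sr" in adapters:
        pred_sets["sr"] = PredictionSet(test_z.y,
                                        adapters["sr"].evaluate(test_z.X))
    if "ensemble" in config.models:
        ens = ensemble.fit_weights([cv_rmse["gbm"], cv_rmse["bnn"]],
                                   ["gbm", "bnn"])
        pred_sets["ensemble"] = ensemble.predict(
            [pred_sets["gbm"], pred_sets["bnn"]], ens, level=nominal)
        report["ensemble"] = json.loads(ens.to_json())

    for name, ps in pred_sets.items():
        entry = {"metrics": metrics_report(ps, nominal),
                 "rto": rto_validation(ps).to_dict()}
        if ps.sigma is not None and np.all(ps.sigma > 0):
            entry["residual_diagnostics"] = residual_diagnostics(ps).to_dict()
        report["test"][name] = entry
    _log_stage("evaluate", t0)

    # ---------------------------------------------------------- validate
    report["_stage"] = "validate"
    t0 = time.time()
    if "gbm" in adapters:
        scramble_cfg = gbm.GBMConfig(**{**gbm_kwargs,
                                        "n_estimators": min(
                                            80, gbm_kwargs.get("n_estimators",
                                                               300))})

        def scramble_factory(Xtr, ytr):
            return gbm.fit(Xtr, ytr, scramble_cfg, columns=keep).predict

        report["yscramble"] = validation.yscrambling(
            scramble_factory, train_z.X, train_z.y, config.n_perm,
            seed=stage_seed(config.seed, "yscramble")).to_dict()

    widths = None
    for name in ("bnn", "ensemble", "gbm"):
        if name in pred_sets and pred_sets[name].has_intervals():
            widths = pred_sets[name].upper - pred_sets[name].lower
            width_source = name
            break
    ad_rep = validation.ad_assess(train_r, test_r, widths=widths)
    report["ad"] = {k: v for k, v in ad_rep.to_dict().items()
                    if k not in ("distances", "in_domain")}
    if widths is not None:
        errors = np.abs(pred_sets[width_source].y
                        - pred_sets[width_source].y_hat)
        try:
            report["associations"] = validation.uncertainty_associations(
                ad_rep.distances, widths, errors)
            report["associations"]["width_source"] = width_source
        except ValidationError:
            report["associations"] = None
    _log_stage("validate", t0)

    # ---------------------------------------------------------- sensitize
    report["_stage"] = "sensitize"
    t0 = time.time()
    if "gbm" in adapters:
        sens = directional_analysis(
            adapters["gbm"].predict, train_z,
            n_anchors=min(config.n_anchors, train_z.n),
            grid_size=config.grid_size,
            seed=stage_seed(config.seed, "sensitivity"))
        report["sensitivity"] = sens.to_dict()
    _log_stage("sensitize", t0)

    if hashlib.sha256(test.X.tobytes()).hexdigest() != test_hash:
        raise ValidationError("leakage audit failed: test rows were modified")
    report["provenance"]["leakage_audit"] = "test partition untouched"
    report.pop("_stage")

    if config.out_dir:
        _write_outputs(config, report, table, pred_sets, test)
    return report


def _write_outputs(config, report, table, pred_sets, test):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    for name, ps in pred_sets.items():
        import pandas as pd
        df = pd.DataFrame({"compound_id": test.ids, "y_true": ps.y,
                           "y_pred": ps.y_hat})
        for col in ("lower", "upper", "sigma"):
            v = getattr(ps, col)
            if v is not None:
                df[col] = v
        df.to_csv(out / f"predictions_{name}.csv", index=False)
    tables = report_tables(report)
    tdir = out / "tables"
    tdir.mkdir(exist_ok=True)
    for name, (text, csv_text) in tables.items():
        (tdir / f"{name}.csv").write_text(csv_text)
        (tdir / f"{name}.txt").write_text(text)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


FOLD_COLUMNS = ["fold", "train_size", "val_size", "rmse", "r2",
                "mean_actual", "mean_predicted", "std_actual",
                "std_predicted"]


def _format_table(rows: list[dict], columns: list[str]) -> tuple[str, str]:
    """Aligned text + CSV rendering of a list of records."""
    def fmt(v):
        if isinstance(v, float):
            return f"{v:.4f}"
        return str(v)
    widths = {c: max([len(c)] + [len(fmt(r.get(c, ""))) for r in rows])
              for c in columns}
    lines = ["  ".join(c.ljust(widths[c]) for c in columns)]
    for r in rows:
        lines.append("  ".join(fmt(r.get(c, "")).ljust(widths[c])
                               for c in columns))
    csv_lines = [",".join(columns)]
    for r in rows:
        csv_lines.append(",".join(fmt(r.get(c, "")) for c in columns))
    return "\n".join(lines) + "\n", "\n".join(csv_lines) + "\n"


def report_tables(report: dict) -> dict:
    """Render fold, metric-comparison, calibration, and sensitivity tables."""
    out = {}
    cv = report.get("cv", {})
    if "gbm" in cv:
        out["folds"] = _format_table(cv["gbm"]["folds"], FOLD_COLUMNS)
    test = report.get("test")
    if test:
        rows = []
        for name, entry in test.items():
            row = {"model": name}
            row.update({k: v for k, v in entry["metrics"].items()
                        if v is not None})
            rows.append(row)
        cols = ["model", "rmse", "r2", "mare", "mae", "pi", "tic",
                "coverage", "calibration_error", "sharpness", "nll"]
        cols = [c for c in cols if any(c in r for r in rows)]
        out["metrics"] = _format_table(rows, cols)
        cal_rows = []
        for name, entry in test.items():
            m = entry["metrics"]
            if m.get("coverage") is not None:
                cal_rows.append({
                    "model": name, "coverage": m["coverage"],
                    "calibration_error": m["calibration_error"],
                    "avg_interval_width": m["pi"],
                    "sharpness": m["sharpness"], "nll": m["nll"]})
        if cal_rows:
            out["calibration"] = _format_table(
                cal_rows, ["model", "coverage", "calibration_error",
                           "avg_interval_width", "sharpness", "nll"])
    sens = report.get("sensitivity")
    if sens:
        rows = [{"metric": k, "value": v} for k, v in sens.items()
                if k not in ("per_descriptor",)]
        out["sensitivity"] = _format_table(rows, ["metric", "value"])
    return out
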