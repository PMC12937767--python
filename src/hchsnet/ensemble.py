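"""Soft-voting gradient-boosting ensemble over the fused features.

Modelling follows the statsmodels convention: ``LesionEnsembleModel``
holds the data and configuration, ``fit()`` returns a
``LesionEnsembleResults`` object that carries the fitted boosters and
everything derived from them (predictions, metrics, importances,
summary table).

Three boosters are trained independently on identical data — XGBoost
(regularized second-order objective), LightGBM (leaf-wise growth with
gradient-based one-side sampling) and scikit-learn's histogram
gradient-boosting classifier — each with 500 iterations, maximum depth
6 and learning rate 0.03. The ensemble prediction is the unweighted
arithmetic mean of the three class-probability distributions followed
by an argmax (soft voting, the default); a hard majority-vote mode is
available behind a flag. Exact ties break to the lowest label index and
are logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import MetricsReport, bootstrap_ci, compute_metrics, confusion

logger = logging.getLogger(__name__)

FAMILIES = ("xgboost", "lightgbm", "histgb")


@dataclass
class BoosterConfig:
    """Hyperparameters shared by all three ensemble members."""

    family: str = "xgboost"
    iterations: int = 500
    max_depth: int = 6
    learning_rate: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.iterations <= 0 or self.max_depth <= 0 or self.learning_rate <= 0:
            raise ValueError("iterations, max_depth and learning_rate must be positive")


def default_configs(seed: int = 0, iterations: int = 500) -> list[BoosterConfig]:
    """One config per family, with per-member derived seeds."""
    return [
        BoosterConfig(family=f, iterations=iterations, seed=seed + k)
        for k, f in enumerate(FAMILIES)
    ]


def _build_estimator(cfg: BoosterConfig):
    if cfg.family == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=cfg.iterations,
            max_depth=cfg.max_depth,
            learning_rate=cfg.learning_rate,
            random_state=cfg.seed,
            n_jobs=1,
            tree_method="hist",
            importance_type="gain",
            verbosity=0,
        )
    if cfg.family == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=cfg.iterations,
            max_depth=cfg.max_depth,
            learning_rate=cfg.learning_rate,
            random_state=cfg.seed,
            n_jobs=1,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
        )
    if cfg.family == "histgb":
        from sklearn.ensemble import HistGradientBoostingClassifier

        return HistGradientBoostingClassifier(
            max_iter=cfg.iterations,
            max_depth=cfg.max_depth,
            learning_rate=cfg.learning_rate,
            random_state=cfg.seed,
            early_stopping=False,
        )
    raise ValueError(cfg.family)


def _schema_hash(feature_names: list[str]) -> str:
    return hashlib.sha256("\x1f".join(feature_names).encode()).hexdigest()[:16]


class LesionEnsembleModel:
    """Three-booster soft-voting classifier over fused lesion features.

    Parameters
    ----------
    X : (n, p) array or DataFrame
        Fused feature matrix (any block subset; column names are frozen
        into the model schema).
    y : sequence of str
        Class labels; at least two distinct classes required.
    configs : list of BoosterConfig, optional
        One per ensemble member; defaults to the three families at the
        standard 500 / depth-6 / 0.03 setting.
    vote : "soft" | "hard"
        Probability averaging (default) or majority voting.
    """

    def __init__(self, X, y, configs=None, vote="soft", label_order=None,
                 feature_names=None, seed=0):
        if isinstance(X, pd.DataFrame):
            feature_names = feature_names or list(X.columns)
            X = X.to_numpy(dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(list(y))
        if self.X.shape[0] != len(self.y):
            raise ValueError("X rows and y length differ")
        classes = sorted(set(self.y))
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to train")
        self.label_order = list(label_order) if label_order else classes
        if set(self.y) - set(self.label_order):
            raise ValueError("labels outside label_order")
        self.configs = configs or default_configs(seed=seed)
        if vote not in ("soft", "hard"):
            raise ValueError("vote must be 'soft' or 'hard'")
        self.vote = vote
        self.feature_names = (
            list(feature_names)
            if feature_names
            else [f"x{i}" for i in range(self.X.shape[1])]
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_col: str = "label",
                       feature_cols=None, **kwargs) -> "LesionEnsembleModel":
        """Build from a table holding feature columns plus a label column."""
        cols = feature_cols or [c for c in frame.columns if c != label_col]
        return cls(frame[cols], frame[label_col], feature_names=list(cols), **kwargs)

    def fit(self) -> "LesionEnsembleResults":
        """Train every member on identical data; returns the Results."""
        y_idx = np.array([self.label_order.index(v) for v in self.y])
        Xd = pd.DataFrame(self.X, columns=self.feature_names)
        estimators = []
        for cfg in self.configs:
            est = _build_estimator(cfg)
            est.fit(Xd, y_idx)
            estimators.append(est)
        return LesionEnsembleResults(model=self, estimators=estimators)


@dataclass
class LesionEnsembleResults:
    """Fitted ensemble: predictions, metrics, importances, persistence."""

    model: LesionEnsembleModel
    estimators: list = field(default_factory=list)

    def __post_init__(self):
        self.label_order = self.model.label_order
        self.schema_hash = _schema_hash(self.model.feature_names)

    # ---- prediction -------------------------------------------------

    def _check_schema(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if _schema_hash(list(X.columns)) != self.schema_hash:
                raise ValueError("feature schema mismatch with the fitted model")
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.model.feature_names):
            raise ValueError(
                f"expected {len(self.model.feature_names)} features, got {X.shape[1]}"
            )
        return X

    def member_proba(self, X) -> list[np.ndarray]:
        """Per-member class-probability matrices, columns in label order."""
        X = self._check_schema(X)
        Xd = pd.DataFrame(X, columns=self.model.feature_names)
        return [est.predict_proba(Xd) for est in self.estimators]

    def predict_proba(self, X) -> np.ndarray:
        """Unweighted mean of the member probability distributions."""
        return np.mean(self.member_proba(X), axis=0)

    def predict(self, X) -> np.ndarray:
        """Argmax class labels under the configured voting mode."""
        if self.model.vote == "hard":
            votes = np.stack([p.argmax(axis=1) for p in self.member_proba(X)])
            n_class = len(self.label_order)
            scores = np.stack(
                [(votes == k).sum(axis=0) for k in range(n_class)], axis=1
            ).astype(float)
        else:
            scores = self.predict_proba(X)
        best = scores.argmax(axis=1)
        ties = (scores == scores.max(axis=1, keepdims=True)).sum(axis=1) > 1
        if ties.any():
            logger.info("%d exact prediction ties broken to lowest label index",
                        int(ties.sum()))
        return np.array([self.label_order[k] for k in best])

    # ---- evaluation -------------------------------------------------

    def evaluate(self, X, y_true, with_ci: bool = False, B: int = 1000,
                 seed: int = 0) -> MetricsReport:
        """Full metric battery (optionally with bootstrap 95% CIs)."""
        probs = self.predict_proba(X)
        y_pred = self.predict(X)
        cm = confusion(y_true, y_pred, self.label_order)
        report = compute_metrics(cm, y_true=list(y_true), probs=probs)
        if with_ci:
            for m in ("accuracy", "macro_f1", "macro_recall"):
                report.ci[m] = bootstrap_ci(
                    list(y_true), y_pred, self.label_order,
                    metric_id=m, B=B, seed=seed,
                )
        return report

    def feature_importance(self, block_of: list[str] | None = None) -> pd.DataFrame:
        """Gain-based importances, averaged over the members that expose
        them (XGBoost, LightGBM), ranked descending.

        Each member's gains are normalized to sum to one before
        averaging so no single booster dominates the ranking. The
        histogram booster exposes no gain statistic and is excluded.
        """
        names = self.model.feature_names
        gains = []
        for cfg, est in zip(self.model.configs, self.estimators):
            if cfg.family == "xgboost":
                g = np.asarray(est.feature_importances_, dtype=float)
            elif cfg.family == "lightgbm":
                g = est.booster_.feature_importance(importance_type="gain").astype(float)
            else:
                continue
            s = g.sum()
            gains.append(g / s if s > 0 else g)
        imp = np.mean(gains, axis=0)
        df = pd.DataFrame({"feature": names, "importance": imp})
        if block_of is not None:
            df["block"] = block_of
        return df.sort_values("importance", ascending=False).reset_index(drop=True)

    # ---- reporting --------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary table."""
        train_acc = float((self.predict(self.model.X) == self.model.y).mean())
        lines = [
            "Lesion ensemble (gradient boosting, %s voting)" % self.model.vote,
            "=" * 56,
            f"n obs: {len(self.model.y):>6}    n features: {self.model.X.shape[1]:>4}"
            f"    classes: {len(self.label_order)}",
            f"label order: {', '.join(self.label_order)}",
            f"schema hash: {self.schema_hash}",
            "-" * 56,
            f"{'member':<12}{'iterations':>11}{'depth':>7}{'lr':>7}{'seed':>7}",
        ]
        for cfg in self.model.configs:
            lines.append(
                f"{cfg.family:<12}{cfg.iterations:>11}{cfg.max_depth:>7}"
                f"{cfg.learning_rate:>7.3g}{cfg.seed:>7}"
            )
        lines += ["-" * 56, f"training accuracy: {train_acc:.4f}"]
        return "\n".join(lines)

    # ---- persistence ------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write a model bundle: native booster files plus a JSON manifest."""
        import joblib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files = []
        for cfg, est in zip(self.model.configs, self.estimators):
            if cfg.family == "xgboost":
                fn = "xgboost.json"
                est.get_booster().save_model(directory / fn)
            elif cfg.family == "lightgbm":
                fn = "lightgbm.txt"
                est.booster_.save_model(str(directory / fn))
            else:
                fn = "histgb.joblib"
                joblib.dump(est, directory / fn)
            files.append(fn)
        manifest = {
            "label_order": self.label_order,
            "schema_hash": self.schema_hash,
            "feature_names": self.model.feature_names,
            "vote": self.model.vote,
            "configs": [asdict(c) for c in self.model.configs],
            "files": files,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "LesionEnsembleResults":
        """Load a bundle; predictions match pre-save predictions exactly."""
        import joblib

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        configs = [BoosterConfig(**c) for c in manifest["configs"]]
        estimators = []
        n_class = len(manifest["label_order"])
        for cfg, fn in zip(configs, manifest["files"]):
            if cfg.family == "xgboost":
                import xgboost

                booster = xgboost.Booster()
                booster.load_model(directory / fn)
                est = _XGBWrapper(booster, n_class)
            elif cfg.family == "lightgbm":
                import lightgbm

                booster = lightgbm.Booster(model_file=str(directory / fn))
                est = _LGBWrapper(booster)
            else:
                est = joblib.load(directory / fn)
            estimators.append(est)
        # rebuild a shell model carrying the schema (no training data)
        shell = LesionEnsembleModel.__new__(LesionEnsembleModel)
        shell.label_order = manifest["label_order"]
        shell.feature_names = manifest["feature_names"]
        shell.configs = configs
        shell.vote = manifest["vote"]
        shell.X = np.empty((0, len(manifest["feature_names"])))
        shell.y = np.empty((0,))
        return cls(model=shell, estimators=estimators)


class _LGBWrapper:
    """predict_proba facade over a raw LightGBM booster loaded from file."""

    def __init__(self, booster):
        self.booster = booster

    def predict_proba(self, X):
        p = self.booster.predict(X)
        if p.ndim == 1:  # binary objective emits P(class 1)
            p = np.column_stack([1.0 - p, p])
        return p


class _XGBWrapper:
    """predict_proba facade over a raw XGBoost booster loaded from file."""

    def __init__(self, booster, n_class: int):
        self.booster = booster
        self.n_class = n_class

    def predict_proba(self, X):
        import xgboost

        p = self.booster.predict(xgboost.DMatrix(X))
        if p.ndim == 1:
            p = np.column_stack([1.0 - p, p])
        return p


ABLATION_CONFIGS = ["s", "h", "hs", "c", "cs", "ch", "chs", "chsm"]


def run_ablation(
    train_features: pd.DataFrame,
    train_labels,
    test_features: pd.DataFrame,
    test_labels,
    configurations: list[str] = ABLATION_CONFIGS,
    seed: int = 0,
    iterations: int = 500,
) -> pd.DataFrame:
    """Train and score the ensemble on every feature-block subset.

    ``train_features`` / ``test_features`` must carry the canonical
    column names (colorH_00 ..., haralick_*, hu_*, meta_*); each
    configuration string selects blocks by letter: c = color,
    h = haralick, s = shape (Hu), m = metadata.
    """
    from .features import feature_names as _fn

    rows = []
    for blocks in configurations:
        cols = _fn(blocks)
        model = LesionEnsembleModel(
            train_features[cols], train_labels,
            configs=default_configs(seed=seed, iterations=iterations),
            feature_names=cols,
        )
        res = model.fit()
        rep = res.evaluate(test_features[cols], test_labels)
        rows.append({
            "blocks": blocks, "n_features": len(cols),
            **{k: v for k, v in rep.to_dict().items() if k != "ci"},
        })
    return pd.DataFrame(rows)
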