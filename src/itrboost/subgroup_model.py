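"""Gradient-boosted estimation of the treatment-contrast score f(X).

A :class:`SubgroupModel` is a boosted regression-tree ensemble trained with
the modified loss of :mod:`itrboost.losses` as a custom objective: each
round's gradient and diagonal Hessian come from :func:`losses.loss_gradient`
(scaled to the sum over patients, the convention the boosting engine's
regularisation lambda is calibrated against).  The fitted score f̂(X) is a
monotone transform of the treatment contrast; thresholding it at zero
yields the individualized treatment rule.

Sign convention: for continuous and binary endpoints a larger outcome is
better, so f̂ > 0 recommends treatment.  The survival loss is on the
log-hazard scale, where treatment benefit means a *lower* hazard, so
f̂ < 0 recommends treatment by default.  Both are overridable via
``benefit_direction``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import xgboost as xgb

from .losses import LossConfig, composite_loss, loss_gradient
from .trial_data import Endpoint, TrialDataset

__all__ = [
    "BoostingParams",
    "SubgroupModel",
    "ImportanceTable",
    "NoInformativeSplitsError",
    "fit_subgroup_model",
    "predict_score",
    "assign_subgroup",
    "evaluate_loss",
    "biomarker_importance",
]

POSITIVE_SCORE = "positive_score"
NEGATIVE_SCORE = "negative_score"


class NoInformativeSplitsError(RuntimeError):
    """The fitted ensemble contains no splits, so importance is undefined."""


@dataclass(frozen=True)
class BoostingParams:
    """Boosting hyperparameters.

    Defaults follow the reference configuration for exploratory subgroup
    search in trial-sized data: slow learning (0.01) on depth-1 stumps
    with a strong L2 leaf penalty (lambda = 5) for 300 rounds, histogram
    tree construction.
    """

    learning_rate: float = 0.01
    max_depth: int = 1
    reg_lambda: float = 5.0
    n_rounds: int = 300
    tree_method: str = "hist"
    seed: int = 0
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be nonnegative")

    def to_xgb(self) -> dict[str, Any]:
        params = {
            "eta": self.learning_rate,
            "max_depth": self.max_depth,
            "lambda": self.reg_lambda,
            "tree_method": self.tree_method,
            "seed": self.seed,
            "base_score": 0.0,
            "nthread": 1,  # bit-reproducible histogram sums
            "disable_default_eval_metric": 1,
        }
        params.update(self.extra)
        return params


@dataclass
class SubgroupModel:
    """Fitted contrast estimator f̂(X) with its training history."""

    booster: xgb.Booster
    config: LossConfig
    params: BoostingParams
    feature_names: list[str]
    history: list[float]
    benefit_direction: str
    encoded_columns: list[str]
    categorical_levels: dict[str, list] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        """Native booster file plus a JSON sidecar with the loss config."""
        path = Path(path)
        self.booster.save_model(str(path))
        sidecar = {
            "loss_config": {
                "endpoint": self.config.endpoint.kind,
                "loss_type": self.config.loss_type,
                "tau": self.config.tau,
                "weight_inside_risk_set": self.config.weight_inside_risk_set,
            },
            "params": {k: v for k, v in asdict(self.params).items()},
            "feature_names": self.feature_names,
            "history": self.history,
            "benefit_direction": self.benefit_direction,
            "encoded_columns": self.encoded_columns,
            "categorical_levels": self.categorical_levels,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "SubgroupModel":
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(str(path))
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        lc = meta["loss_config"]
        config = LossConfig(
            endpoint=Endpoint(lc["endpoint"]),
            loss_type=lc["loss_type"],
            tau=lc["tau"],
            weight_inside_risk_set=lc["weight_inside_risk_set"],
        )
        params = BoostingParams(**meta["params"])
        return cls(
            booster=booster,
            config=config,
            params=params,
            feature_names=meta["feature_names"],
            history=meta["history"],
            benefit_direction=meta["benefit_direction"],
            encoded_columns=meta["encoded_columns"],
            categorical_levels=meta["categorical_levels"],
        )


@dataclass(frozen=True)
class ImportanceTable:
    """Gain-share ranking of biomarkers used by the ensemble.

    ``gain_share`` sums to 1 over the listed biomarkers; ``rank`` is dense
    by descending gain.  Only biomarkers with at least one split appear.
    """

    table: pd.DataFrame  # columns: biomarker, gain_share, split_frequency, rank

    def __len__(self) -> int:
        return len(self.table)

    def top(self) -> str:
        return str(self.table.iloc[0]["biomarker"])


def _encode(
    X: pd.DataFrame, levels: dict[str, list] | None = None
) -> tuple[pd.DataFrame, dict[str, list]]:
    """One-hot expand categorical biomarkers; numeric pass through.

    ``levels`` pins the category sets when encoding prediction data so the
    encoded column block matches training.
    """
    X = X.copy()
    cat_cols = [c for c in X.columns if not pd.api.types.is_numeric_dtype(X[c])]
    if levels is None:
        levels = {c: sorted(pd.unique(X[c].dropna()).tolist()) for c in cat_cols}
    for c in cat_cols:
        if c not in levels:
            raise KeyError(f"unexpected categorical biomarker {c!r}")
        X[c] = pd.Categorical(X[c], categories=levels[c])
    enc = pd.get_dummies(X, columns=cat_cols, dummy_na=False, dtype=float)
    return enc, levels


def fit_subgroup_model(
    dataset: TrialDataset,
    config: LossConfig,
    params: BoostingParams | None = None,
    benefit_direction: str | None = None,
    early_stopping_rounds: int | None = None,
    validation_fraction: float = 0.0,
) -> SubgroupModel:
    """Train the boosted contrast estimator under the modified loss.

    The custom objective supplies the analytic gradient/Hessian of the
    composite loss; the per-round training loss (mean scale) is recorded
    in ``history``.  Deterministic given seed, params and data.  Early
    stopping is off by default (a fixed number of rounds is the reference
    behaviour); pass ``early_stopping_rounds`` with a positive
    ``validation_fraction`` to enable it.
    """
    if params is None:
        params = BoostingParams()
    if config.endpoint != dataset.endpoint:
        raise ValueError(
            f"config endpoint {config.endpoint.kind} != dataset {dataset.endpoint.kind}"
        )
    if benefit_direction is None:
        benefit_direction = (
            NEGATIVE_SCORE if config.endpoint.is_survival else POSITIVE_SCORE
        )
    if benefit_direction not in (POSITIVE_SCORE, NEGATIVE_SCORE):
        raise ValueError(f"unknown benefit_direction {benefit_direction!r}")

    enc, levels = _encode(dataset.X)
    dtrain = xgb.DMatrix(
        enc.to_numpy(dtype=float), feature_names=list(enc.columns), missing=np.nan
    )
    n = dataset.n

    def objective(preds: np.ndarray, _dm: xgb.DMatrix):
        gh = loss_gradient(dataset, preds, config)
        # sum-over-patients scale so reg_lambda acts per leaf as documented
        return gh.g * n, gh.h * n

    def metric(preds: np.ndarray, _dm: xgb.DMatrix):
        return "mloss", composite_loss(dataset, preds, config)

    history: list[float] = []

    class _LossHistory(xgb.callback.TrainingCallback):
        # evals_result truncates metrics to float32; record full precision
        def after_iteration(self, booster, epoch, evals_log):
            preds = booster.predict(dtrain, output_margin=True)
            history.append(float(composite_loss(dataset, preds, config)))
            return False

    evals_result: dict = {}
    evals = [(dtrain, "train")]
    fit_kwargs: dict[str, Any] = {}
    if early_stopping_rounds is not None:
        if not 0 < validation_fraction < 1:
            raise ValueError("early stopping requires validation_fraction in (0,1)")
        rng = np.random.default_rng(params.seed)
        val_idx = rng.choice(n, size=max(1, int(round(validation_fraction * n))), replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[val_idx] = True
        dval = xgb.DMatrix(
            enc.to_numpy(dtype=float)[mask],
            feature_names=list(enc.columns),
            missing=np.nan,
        )
        evals = [(dtrain, "train"), (dval, "valid")]
        fit_kwargs["early_stopping_rounds"] = early_stopping_rounds

    booster = xgb.train(
        params.to_xgb(),
        dtrain,
        num_boost_round=params.n_rounds,
        obj=objective,
        custom_metric=metric,
        evals=evals,
        evals_result=evals_result,
        verbose_eval=False,
        callbacks=[_LossHistory()],
        **fit_kwargs,
    )
    return SubgroupModel(
        booster=booster,
        config=config,
        params=params,
        feature_names=list(dataset.X.columns),
        history=history,
        benefit_direction=benefit_direction,
        encoded_columns=list(enc.columns),
        categorical_levels=levels,
    )


def _prediction_matrix(model: SubgroupModel, X: pd.DataFrame) -> xgb.DMatrix:
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise KeyError(f"prediction data lacks biomarker columns: {missing}")
    X = X[model.feature_names]  # name-based alignment; order-insensitive
    enc, _ = _encode(X, levels=model.categorical_levels)
    enc = enc.reindex(columns=model.encoded_columns, fill_value=0.0)
    return xgb.DMatrix(
        enc.to_numpy(dtype=float),
        feature_names=model.encoded_columns,
        missing=np.nan,
    )


def predict_score(model: SubgroupModel, X: pd.DataFrame) -> np.ndarray:
    """Raw contrast score f̂ per row (deterministic, name-aligned)."""
    dm = _prediction_matrix(model, X)
    return np.asarray(model.booster.predict(dm, output_margin=True), dtype=float)


def assign_subgroup(model: SubgroupModel, X: pd.DataFrame) -> np.ndarray:
    """ITR recommendation in {+1, -1} per row.

    +1 (treat) iff f̂ is strictly on the benefit side of zero; a score of
    exactly zero carries no evidence of benefit and maps to -1.
    """
    f = predict_score(model, X)
    if model.benefit_direction == POSITIVE_SCORE:
        return np.where(f > 0, 1, -1)
    return np.where(f < 0, 1, -1)


def evaluate_loss(model: SubgroupModel, dataset: TrialDataset) -> float:
    """Composite modified loss of the model's scores on a dataset."""
    if dataset.endpoint != model.config.endpoint:
        raise ValueError("dataset endpoint does not match the model's loss config")
    f = predict_score(model, dataset.X)
    return composite_loss(dataset, f, model.config)


def biomarker_importance(model: SubgroupModel) -> ImportanceTable:
    """Gain-share importance of biomarkers, aggregated over one-hot levels.

    Gain shares are total split gain normalised to sum to 1; split
    frequency is reported alongside.  Raises
    :class:`NoInformativeSplitsError` when the ensemble never split.
    """
    gain = model.booster.get_score(importance_type="total_gain")
    freq = model.booster.get_score(importance_type="weight")
    if not gain:
        raise NoInformativeSplitsError(
            "ensemble contains no informative splits; cannot rank biomarkers"
        )

    def _origin(col: str) -> str:
        # map one-hot column back to its source biomarker
        for name in model.feature_names:
            if col == name or col.startswith(name + "_"):
                return name
        return col

    rows: dict[str, dict[str, float]] = {}
    for col, g in gain.items():
        name = _origin(col)
        r = rows.setdefault(name, {"gain": 0.0, "freq": 0.0})
        r["gain"] += g
        r["freq"] += freq.get(col, 0.0)
    total_gain = sum(r["gain"] for r in rows.values())
    total_freq = sum(r["freq"] for r in rows.values())
    table = pd.DataFrame(
        {
            "biomarker": list(rows),
            "gain_share": [r["gain"] / total_gain for r in rows.values()],
            "split_frequency": [
                r["freq"] / total_freq if total_freq > 0 else 0.0 for r in rows.values()
            ],
        }
    ).sort_values(["gain_share", "biomarker"], ascending=[False, True], ignore_index=True)
    # dense rank by descending gain
    table["rank"] = table["gain_share"].rank(method="dense", ascending=False).astype(int)
    return ImportanceTable(table=table)


def plot_importance(table: ImportanceTable, path: str | Path) -> None:
    """Horizontal bar plot of gain shares (artifact only; numbers in table)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.table.iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.5))
    ax.barh(df["biomarker"], df["gain_share"], color="#4878d0")
    ax.set_xlabel("gain share")
    ax.set_title("Predictive biomarker importance")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
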