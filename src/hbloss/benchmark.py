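"""Benchmarking: accuracy metrics, learner slate, and the formula shoot-out.

Two evaluations are provided:

* **Model selection** — a slate of seven supervised learners (linear
  regression, ridge, AdaBoost, random forest, RBF support-vector
  regression, k-nearest neighbours, a three-hidden-layer neural network)
  is compared on a 25% held-out test split after a five-fold
  cross-validated grid search on the training portion.  Accuracy is scored
  by mean squared error and explained variance.

* **Formula benchmark** — every registered closed-form estimator (the new
  formula plus the Meunier/Gross/Ward/Bourke/Mercuriali/Lisander legacy
  calculators) is evaluated record-by-record against the observed loss.
  Native outputs are first converted to grams of hemoglobin (RBC mL / 2.87,
  blood mL / 6.79) so all formulas are judged on a common scale; reported
  per formula: Pearson correlation, Hb-equivalent mean absolute error, the
  least-squares slope of residual vs predicted (zero for an unbiased,
  linear predictor) and the mean residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .cohort import CohortTable, complete_case_filter
from .formulas import legacy_blood_loss
from .model import build_design
from .units import to_hb_grams

LOSS_QUANTITY = {"new": "hb_g", "meunier": "blood_mL", "gross": "blood_mL",
                 "ward": "blood_mL", "bourke": "blood_mL",
                 "mercuriali": "rbc_mL", "lisander": "rbc_mL"}


def compute_metrics(y, yhat) -> dict:
    """MSE, explained variance, MAE and Pearson correlation.

    MSE = sum((yhat - y)^2)/n;  EV = 1 - Var(y - yhat)/Var(y) with the
    population variance (divisor n);  MAE = sum(|yhat - y|)/n.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between observed and predicted")
    if y.size < 2:
        raise ValueError("need at least two observations")
    var_y = np.var(y)  # population variance
    if var_y == 0:
        raise ValueError("explained variance undefined: zero variance in observations")
    mse = float(np.mean((yhat - y) ** 2))
    ev = float(1.0 - np.var(y - yhat) / var_y)
    mae = float(np.mean(np.abs(yhat - y)))
    sd_hat = yhat.std()
    pearson = float(np.corrcoef(y, yhat)[0, 1]) if sd_hat > 0 else float("nan")
    return {"mse": mse, "ev": ev, "mae": mae, "pearson": pearson}


@dataclass
class BenchmarkReport:
    formulas: Optional[pd.DataFrame] = None     # per-formula metrics
    learners: Optional[pd.DataFrame] = None     # per-learner test MSE / EV
    chosen_hyperparams: dict = field(default_factory=dict)
    excluded_counts: dict = field(default_factory=dict)
    residual_pairs: dict = field(default_factory=dict)  # formula -> (predicted, residual)
    seed: Optional[int] = None
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# formula benchmark


def benchmark_formulas(table: CohortTable, collect_pairs: bool = False) -> BenchmarkReport:
    """Score every registered formula against observed loss on a cohort.

    Records missing the inputs a given formula needs (e.g. hematocrit for
    the Hct-based legacy forms) are excluded for that formula only, with
    counts reported.
    """
    report = BenchmarkReport(excluded_counts={})
    rows, pairs = [], {}
    records = list(table)
    observed_all = np.array(
        [r.observed_hb_loss if r.observed_hb_loss is not None else np.nan for r in records]
    )
    for fid, qty in LOSS_QUANTITY.items():
        preds, obs = [], []
        excluded = 0
        for rec, y in zip(records, observed_all):
            if np.isnan(y):
                excluded += 1
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est = legacy_blood_loss(fid, rec.profile, rec.labs)
            except ValueError:
                excluded += 1
                continue
            preds.append(to_hb_grams(est.value, est.quantity))
            obs.append(y)
        report.excluded_counts[fid] = excluded
        if len(obs) < 2:
            continue
        preds_a, obs_a = np.array(preds), np.array(obs)
        m = compute_metrics(obs_a, preds_a)
        resid = obs_a - preds_a
        # least-squares line of residual on predicted: slope 0 <=> no
        # systematic under/over-estimation across the prediction range
        slope, intercept = np.polyfit(preds_a, resid, 1)
        rows.append(
            {
                "formula": fid,
                "quantity": qty,
                "n": len(obs_a),
                "pearson": m["pearson"],
                "mae_hb_g": m["mae"],
                "resid_slope": float(slope),
                "resid_intercept": float(intercept),
                "mean_resid": float(resid.mean()),
            }
        )
        if collect_pairs:
            pairs[fid] = np.column_stack([preds_a, resid])
    report.formulas = pd.DataFrame(rows).set_index("formula")
    report.residual_pairs = pairs
    return report


# ---------------------------------------------------------------------------
# learner slate


def _learner_slate(seed: int, quick: bool) -> dict:
    """Seven learners with CV grids centred on the reference hyperparameters."""
    slate = {
        "linear": (LinearRegression(), {}),
        "ridge": (Ridge(), {"alpha": [1.0, 5.0, 10.0] if quick else [0.5, 1.0, 5.0, 10.0, 25.0]}),
        "adaboost": (
            AdaBoostRegressor(estimator=DecisionTreeRegressor(max_depth=3), random_state=seed),
            {"n_estimators": [100] if quick else [50, 100]},
        ),
        "random_forest": (
            RandomForestRegressor(random_state=seed),
            {"n_estimators": [40], "max_depth": [4] if quick else [2, 4, 6]},
        ),
        "svr": (
            Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))]),
            {"svr__C": [9.0] if quick else [1.0, 9.0, 27.0],
             "svr__epsilon": [0.9] if quick else [0.3, 0.9, 2.7]},
        ),
        "knn": (
            Pipeline([("scale", StandardScaler()), ("knn", KNeighborsRegressor())]),
            {"knn__n_neighbors": [20] if quick else [5, 10, 20, 40]},
        ),
        "neural_net": (
            Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "mlp",
                        MLPRegressor(
                            hidden_layer_sizes=(64, 32, 16),
                            activation="relu",
                            solver="adam",
                            max_iter=800,
                            random_state=seed,
                        ),
                    ),
                ]
            ),
            {},
        ),
    }
    return slate


def model_selection(
    table: CohortTable,
    seed: int = 0,
    learners: Optional[list] = None,
    quick: bool = True,
) -> BenchmarkReport:
    """Hold out 25% of the cohort, grid-search each learner with 5-fold CV,
    and report test MSE and explained variance per learner.

    ``quick=True`` collapses grids to the reference hyperparameters (plus a
    small neighbourhood for ridge); ``quick=False`` searches wider grids.
    A single seed drives the holdout split, fold assignment and any
    stochastic learner.
    """
    complete, _ = complete_case_filter(table)
    if len(complete) < 100:
        raise ValueError("model selection needs at least 100 complete records")
    design = build_design(complete, structure="full", standardize=True)
    X = design.X.drop(columns=["const"]).to_numpy()
    y = design.response.to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=0.25, random_state=seed)
    cv = KFold(n_splits=5, shuffle=True, random_state=seed)

    slate = _learner_slate(seed, quick)
    if learners is not None:
        slate = {k: v for k, v in slate.items() if k in learners}
    rows, chosen, notes = [], {}, []
    for name, (est, grid) in slate.items():
        try:
            if grid:
                gs = GridSearchCV(est, grid, cv=cv, scoring="neg_mean_squared_error")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gs.fit(X_tr, y_tr)
                best = gs.best_estimator_
                chosen[name] = gs.best_params_
            else:
                best = est
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    best.fit(X_tr, y_tr)
                chosen[name] = {}
            yhat = best.predict(X_te)
            m = compute_metrics(y_te, yhat)
            rows.append({"learner": name, "test_mse": m["mse"], "test_ev": m["ev"]})
        except Exception as exc:  # pragma: no cover - environment-dependent
            notes.append(f"learner {name!r} skipped: {exc}")
    return BenchmarkReport(
        learners=pd.DataFrame(rows).set_index("learner"),
        chosen_hyperparams=chosen,
        seed=seed,
        notes=notes,
    )
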