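"""Two-way regression models between microclimate and EDA features.

Three regressor families — random forest, RBF support vector machine and
ordinary least squares — are evaluated under two schemes: leave-one-
subject-out (LOSO, one fold per subject, the held-out subject's rows never
seen in training) and repeated seeded 70/30 shuffle splits. The mean
held-out R² per (family, scheme, target) fills the model-comparison grid;
Shapley attributions explain the fitted models. The forward direction maps
the 12 environmental variables to each EDA index; the reverse direction
maps the six EDA indices to temperature, CO2, humidity and IR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import ShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from microeda.ingest import ENV_COLUMNS
from microeda.features import EDA_FEATURES
from microeda.shapley import AttributionSummary, linear_shapley, shapley_values

FAMILIES = ("linear", "random_forest", "support_vector")

#: reverse-model targets: the four environmental drivers examined one by one
REVERSE_TARGETS = ["Temperature", "CO2", "Humid", "IR"]


@dataclass(frozen=True)
class ModelSpec:
    """Regressor family, hyperparameters and the seed that fixes it."""

    family: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")


@dataclass
class EvalResult:
    """Held-out R² of one (target, family, scheme) cell."""

    target: str
    family: str
    scheme: str  # "loso" | "split_70_30"
    mean_r2: float
    fold_r2: list[float]
    model: object = None  # fitted on all rows, for attribution
    feature_names: list[str] = field(default_factory=list)
    seed: int = 0


def make_estimator(spec: ModelSpec):
    """Instantiate the sklearn regressor for a model spec."""
    hp = dict(spec.hyperparameters)
    if spec.family == "random_forest":
        hp.setdefault("n_estimators", 500)
        return RandomForestRegressor(random_state=spec.seed, **hp)
    if spec.family == "support_vector":
        hp.setdefault("kernel", "rbf")
        hp.setdefault("C", 1.0)
        hp.setdefault("epsilon", 0.1)
        return Pipeline([("scale", StandardScaler()), ("svr", SVR(**hp))])
    return LinearRegression(**hp)


def evaluate(table: pd.DataFrame, target: str, features: list[str],
             spec: ModelSpec, scheme: str = "split_70_30", *,
             subject_col: str = "subject", n_repeats: int = 5,
             label_filter: str | None = None) -> EvalResult:
    """Train/evaluate one model; R² is computed on held-out rows only.

    ``scheme="loso"`` makes one fold per subject; ``scheme="split_70_30"``
    averages ``n_repeats`` seeded 70/30 shuffle splits (a single split has
    no mean to report). ``label_filter`` restricts rows to one stress label
    (e.g. ``"high"``) before fitting.
    """
    df = table.dropna(subset=[target] + features)
    if label_filter is not None:
        df = df[df["label"] == label_filter]
    X = df[features].to_numpy(dtype=float)
    y = df[target].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"target {target!r} is constant")
    fold_r2: list[float] = []
    if scheme == "loso":
        subjects = df[subject_col].to_numpy()
        uniq = np.unique(subjects)
        if uniq.size < 2:
            raise ValueError("LOSO needs at least 2 subjects")
        for s in uniq:
            held = subjects == s
            assert held.sum() and (~held).sum(), "empty LOSO fold"
            est = make_estimator(spec)
            est.fit(X[~held], y[~held])
            fold_r2.append(float(r2_score(y[held], est.predict(X[held]))))
    elif scheme == "split_70_30":
        splitter = ShuffleSplit(n_splits=n_repeats, test_size=0.3,
                                random_state=spec.seed)
        for tr, te in splitter.split(X):
            est = make_estimator(spec)
            est.fit(X[tr], y[tr])
            fold_r2.append(float(r2_score(y[te], est.predict(X[te]))))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    final = make_estimator(spec)
    final.fit(X, y)
    return EvalResult(target=target, family=spec.family, scheme=scheme,
                      mean_r2=float(np.mean(fold_r2)), fold_r2=fold_r2,
                      model=final, feature_names=list(features),
                      seed=spec.seed)


def rank_models(results: list[EvalResult]) -> list[str]:
    """Families ordered by descending mean R² across results; ties broken
    alphabetically."""
    if not results:
        return []
    df = pd.DataFrame([(r.family, r.mean_r2) for r in results],
                      columns=["family", "r2"])
    agg = df.groupby("family")["r2"].mean()
    return sorted(agg.index, key=lambda f: (-agg[f], f))


def model_grid(table: pd.DataFrame, targets: list[str], features: list[str],
               *, seed: int = 0, n_repeats: int = 5,
               rf_params: dict | None = None,
               label_filter: str | None = None) -> pd.DataFrame:
    """The model-comparison grid: rows = scheme × family, columns = targets,
    cells = mean held-out R²."""
    rows = {}
    for scheme in ("loso", "split_70_30"):
        for family in ("random_forest", "support_vector", "linear"):
            hp = rf_params if (family == "random_forest" and rf_params) else {}
            spec = ModelSpec(family=family, hyperparameters=hp, seed=seed)
            name = f"{scheme}-{family}"
            rows[name] = {}
            for tgt in targets:
                try:
                    res = evaluate(table, tgt, features, spec, scheme,
                                   n_repeats=n_repeats,
                                   label_filter=label_filter)
                    rows[name][tgt] = res.mean_r2
                except ValueError:
                    rows[name][tgt] = np.nan
    return pd.DataFrame(rows).T[targets]


def shapley_summary(result: EvalResult, table: pd.DataFrame, *,
                    seed: int = 0, max_instances: int = 100,
                    background_size: int = 32,
                    method: str = "auto") -> AttributionSummary:
    """Shapley attribution summary for a fitted model.

    Uses the closed form for linear models, subset enumeration when
    affordable, and a fixed-seed permutation estimator otherwise. The
    background sample and explained instances are subsampled with ``seed``.
    """
    if result.model is None:
        raise ValueError("model not fitted")
    feats = result.feature_names
    df = table.dropna(subset=feats)
    X_all = df[feats].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    bg_idx = rng.choice(len(X_all), size=min(background_size, len(X_all)),
                        replace=False)
    inst_idx = rng.choice(len(X_all), size=min(max_instances, len(X_all)),
                          replace=False)
    background, X = X_all[bg_idx], X_all[inst_idx]
    model = result.model
    if result.family == "linear":
        return linear_shapley(model.coef_, model.intercept_, X, background,
                              feature_names=feats, seed=seed)
    return shapley_values(model.predict, X, background, feature_names=feats,
                          seed=seed, method=method)


def forward_models(table: pd.DataFrame, *, spec: ModelSpec | None = None,
                   targets: list[str] | None = None,
                   scheme: str = "split_70_30", seed: int = 0,
                   n_repeats: int = 5, attribution: bool = True,
                   max_instances: int = 100) -> dict:
    """Environment → EDA-feature models (one per EDA index)."""
    spec = spec or ModelSpec(seed=seed)
    targets = targets or [f for f in EDA_FEATURES if f in table.columns]
    feats = [c for c in ENV_COLUMNS if c in table.columns]
    out = {}
    for tgt in targets:
        res = evaluate(table, tgt, feats, spec, scheme, n_repeats=n_repeats)
        attr = shapley_summary(res, table, seed=seed,
                               max_instances=max_instances) if attribution else None
        out[tgt] = {"eval": res, "attribution": attr}
    return out


def reverse_models(table: pd.DataFrame, *, spec: ModelSpec | None = None,
                   scheme: str = "split_70_30", seed: int = 0,
                   n_repeats: int = 5, attribution: bool = True,
                   max_instances: int = 100) -> dict:
    """EDA-feature → environment models (temperature, CO2, humidity, IR)."""
    spec = spec or ModelSpec(seed=seed)
    feats = [f for f in EDA_FEATURES if f in table.columns]
    out = {}
    for tgt in [t for t in REVERSE_TARGETS if t in table.columns]:
        res = evaluate(table, tgt, feats, spec, scheme, n_repeats=n_repeats)
        attr = shapley_summary(res, table, seed=seed,
                               max_instances=max_instances) if attribution else None
        out[tgt] = {"eval": res, "attribution": attr}
    return out
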