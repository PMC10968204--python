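"""Interventional Shapley attributions for regression models.

Shapley values distribute a prediction's deviation from a baseline (the
mean prediction over a background sample) across input features. Two
estimators are provided:

* ``exact`` — enumerates all feature subsets (feasible for <= ~12 features)
  with the interventional value function v(S) = E_b[f(x_S, b_~S)].
* ``permutation`` — averages marginal contributions over a fixed-seed
  sample of feature orderings; each ordering's contributions telescope to
  f(x) - baseline, so local accuracy holds exactly for any number of
  permutations.

Both satisfy local accuracy: sum(phi) + baseline = E_b[f(x with all
features)] averaged over the background, which for the full coalition is
just f(x).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd


@dataclass
class AttributionSummary:
    """Per-instance Shapley values plus a global ranking.

    ``values`` is (n_instances, n_features); ``baseline`` the mean model
    prediction over the background sample; ``ordering`` feature names
    sorted by decreasing mean |value|.
    """

    feature_names: list[str]
    values: np.ndarray
    baseline: float
    method: str
    seed: int

    @property
    def mean_abs(self) -> pd.Series:
        s = pd.Series(np.abs(self.values).mean(axis=0), index=self.feature_names)
        return s.sort_values(ascending=False, kind="stable")

    @property
    def ordering(self) -> list[str]:
        # deterministic: ties broken by feature name
        s = pd.Series(np.abs(self.values).mean(axis=0), index=self.feature_names)
        return sorted(self.feature_names, key=lambda f: (-s[f], f))

    def to_frame(self) -> pd.DataFrame:
        ma = self.mean_abs
        return pd.DataFrame({
            "feature": ma.index,
            "mean_abs_attribution": ma.to_numpy(),
            "rank": np.arange(1, len(ma) + 1),
        })

    def plot(self, path=None, title: str = "mean |attribution|"):
        """Horizontal bar summary of global feature importance; saves to
        ``path`` if given, else returns the matplotlib axes."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ma = self.mean_abs.iloc[::-1]
        fig, ax = plt.subplots(figsize=(6, 0.4 * len(ma) + 1))
        ax.barh(ma.index, ma.to_numpy())
        ax.set_xlabel(title)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return None
        return ax


def _value_function(predict, X: np.ndarray, background: np.ndarray,
                    mask: np.ndarray) -> np.ndarray:
    """v(S) for every instance: mean over background of f(x_S, b_~S)."""
    n, k = X.shape
    m = background.shape[0]
    synth = np.repeat(background[None, :, :], n, axis=0)  # (n, m, k)
    synth[:, :, mask] = X[:, None, mask]
    preds = predict(synth.reshape(n * m, k))
    return np.asarray(preds, dtype=float).reshape(n, m).mean(axis=1)


def _exact(predict, X, background):
    n, k = X.shape
    values = np.zeros((n, k))
    v_cache = {}
    for code in range(2 ** k):
        mask = np.array([(code >> i) & 1 for i in range(k)], dtype=bool)
        v_cache[code] = _value_function(predict, X, background, mask)
    w = [factorial(s) * factorial(k - s - 1) / factorial(k) for s in range(k)]
    for i in range(k):
        for code in range(2 ** k):
            if (code >> i) & 1:
                continue
            s = bin(code).count("1")
            values[:, i] += w[s] * (v_cache[code | (1 << i)] - v_cache[code])
    # v(empty set) = E_b f(b), identical for every instance
    baseline = float(v_cache[0][0]) if n else 0.0
    return values, baseline


def _permutation(predict, X, background, rng, n_permutations):
    n, k = X.shape
    values = np.zeros((n, k))
    for _ in range(n_permutations):
        order = rng.permutation(k)
        mask = np.zeros(k, dtype=bool)
        v_prev = _value_function(predict, X, background, mask)
        for i in order:
            mask[i] = True
            v_next = _value_function(predict, X, background, mask)
            values[:, i] += v_next - v_prev
            v_prev = v_next
    values /= n_permutations
    baseline = float(_value_function(predict, X[:1], background,
                                     np.zeros(k, dtype=bool))[0]) if n else 0.0
    return values, baseline


def shapley_values(predict, X, background, feature_names=None, *,
                   seed: int = 0, method: str = "auto",
                   n_permutations: int = 64) -> AttributionSummary:
    """Interventional Shapley attributions for ``predict`` at rows of X.

    ``predict`` maps an (n, k) array to n predictions; ``background`` is
    the reference sample defining the baseline distribution. ``method`` is
    ``"exact"``, ``"permutation"`` or ``"auto"`` (exact when the subset
    enumeration is affordable).
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    if X.ndim != 2 or background.ndim != 2 or X.shape[1] != background.shape[1]:
        raise ValueError("X and background must be 2-D with matching columns")
    k = X.shape[1]
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(k)]
    rng = np.random.default_rng(seed)
    if method == "auto":
        method = "exact" if 2 ** k * background.shape[0] * X.shape[0] <= 2_000_000 \
            else "permutation"
    if method == "exact":
        values, baseline = _exact(predict, X, background)
    elif method == "permutation":
        values, baseline = _permutation(predict, X, background, rng, n_permutations)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AttributionSummary(feature_names=list(feature_names), values=values,
                              baseline=baseline, method=method, seed=seed)


def linear_shapley(coef, intercept, X, background, feature_names=None,
                   seed: int = 0) -> AttributionSummary:
    """Closed-form Shapley values for a linear model: phi = w * (x - E[b])."""
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    coef = np.asarray(coef, dtype=float)
    mu = background.mean(axis=0)
    values = (X - mu) * coef
    baseline = float(coef @ mu + intercept)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    return AttributionSummary(feature_names=list(feature_names), values=values,
                              baseline=baseline, method="linear_exact", seed=seed)
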