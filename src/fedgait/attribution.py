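"""Shapley-value feature attributions for trained tabular models.

Attributions explain one model prediction at a time: feature i's Shapley
value is its average marginal contribution to the prediction over all
orders in which features can be revealed, with unrevealed features drawn
from a background population. The sum of a sample's attributions equals
the prediction minus the base value (the mean prediction over the
background) — the efficiency property — exactly, because both estimators
below are averages of telescoping permutation walks.

Two estimators are provided and switch automatically on dimensionality:

* exact enumeration over all 2^p coalitions with Shapley weights, used
  for p <= 12 features;
* antithetic permutation sampling (each sampled permutation is paired
  with its reverse) for larger p, deterministic given the seed, with a
  Monte-Carlo standard error per attribution.

Feature importance is ranked by mean absolute Shapley value (MAS) across
the explained samples. A feature constant at the same value in both the
samples and the background can never change a prediction when revealed,
so its attribution is exactly zero — the mechanism by which a
client-locally-constant input (a participant's sex) loses all importance
in per-participant federated models.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AttributionResult",
    "shapley_attribute",
    "compare_importance",
    "top_n_overlap",
]


@dataclass
class AttributionResult:
    """Per-sample per-feature Shapley values on the model-output scale."""

    feature_names: list[str]
    shap_values: np.ndarray  # (n_samples, n_features)
    base_value: float
    stderr: np.ndarray | None = None  # (n_samples, n_features) for sampling
    metadata: dict = field(default_factory=dict)

    @property
    def mas(self) -> np.ndarray:
        """Mean absolute Shapley value per feature."""
        return np.abs(self.shap_values).mean(axis=0)

    @property
    def ranking(self) -> list[str]:
        """Features ordered by MAS descending (ties: stable by name order)."""
        order = np.argsort(-self.mas, kind="stable")
        return [self.feature_names[i] for i in order]

    def rank_of(self, feature: str) -> int:
        """1-based importance rank of a feature."""
        return self.ranking.index(feature) + 1

    def to_long_frame(self, X: np.ndarray | None = None) -> pd.DataFrame:
        """Beeswarm-ready long format: sample_id, feature, value, shap."""
        n, p = self.shap_values.shape
        rows = {
            "sample_id": np.repeat(np.arange(n), p),
            "feature": np.tile(np.asarray(self.feature_names, object), n),
            "shap": self.shap_values.ravel(),
        }
        if X is not None:
            rows["value"] = np.asarray(X).ravel()
        return pd.DataFrame(rows)


def _exact_shapley(predict_fn, X, background):
    n, p = X.shape
    nb = len(background)
    subsets = list(itertools.product([False, True], repeat=p))
    weights = [
        math.factorial(s) * math.factorial(p - s - 1) / math.factorial(p)
        for s in range(p)
    ]
    values = np.empty((n, p))
    for si, x in enumerate(X):
        # v(S) = mean over background rows of f(background with S set to x)
        v = np.empty(len(subsets))
        for ci, mask in enumerate(subsets):
            hybrid = background.copy()
            cols = np.asarray(mask)
            hybrid[:, cols] = x[cols]
            v[ci] = float(np.mean(predict_fn(hybrid)))
        index = {mask: i for i, mask in enumerate(subsets)}
        phi = np.zeros(p)
        for mask in subsets:
            for i in range(p):
                if mask[i]:
                    continue
                with_i = tuple(
                    True if j == i else mask[j] for j in range(p)
                )
                phi[i] += weights[sum(mask)] * (v[index[with_i]] - v[index[mask]])
        values[si] = phi
    return values, None


def _sampled_shapley(predict_fn, X, background, n_permutations, rng):
    n, p = X.shape
    nb = len(background)
    half = max(1, n_permutations // 2)
    perms = []
    for _ in range(half):
        perm = rng.permutation(p)
        perms.append(perm)
        perms.append(perm[::-1])  # antithetic pair
    n_perm = len(perms)
    values = np.empty((n, p))
    stderr = np.empty((n, p))
    for si, x in enumerate(X):
        # one permutation walk per (permutation, background row):
        # z starts at the background row; features revealed in permutation
        # order take x's value; marginal contributions telescope to
        # f(x) - f(background row).
        per_perm = np.empty((n_perm, p))
        for pi, perm in enumerate(perms):
            # build all p+1 prefix states for every background row at once
            states = np.repeat(background[None, :, :], p + 1, axis=0)
            for step, feat in enumerate(perm):
                states[step + 1 :, :, feat] = x[feat]
            preds = predict_fn(states.reshape(-1, p)).reshape(p + 1, nb)
            marginals = np.diff(preds.mean(axis=1))  # (p,) in walk order
            per_perm[pi, perm] = marginals
        values[si] = per_perm.mean(axis=0)
        stderr[si] = per_perm.std(axis=0, ddof=1) / math.sqrt(n_perm)
    return values, stderr


def shapley_attribute(
    predict_fn,
    samples: np.ndarray,
    background: np.ndarray,
    feature_names=None,
    n_permutations: int = 20,
    seed: int = 0,
    exact_threshold: int = 12,
    metadata: dict | None = None,
) -> AttributionResult:
    """Shapley attributions of ``predict_fn`` for each row of ``samples``.

    ``samples`` and ``background`` must be preprocessed exactly as the
    model's training inputs were. Enumeration is exact for
    ``p <= exact_threshold`` features; otherwise ``n_permutations``
    antithetic permutation walks are averaged (seeded, deterministic).
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if len(background) == 0:
        raise ValueError("empty background population")
    if background.shape[1] != X.shape[1]:
        raise ValueError(
            f"feature mismatch: samples have {X.shape[1]}, "
            f"background has {background.shape[1]}"
        )
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    p = X.shape[1]
    feature_names = list(feature_names or [f"x{i}" for i in range(p)])
    if len(feature_names) != p:
        raise ValueError("feature_names length mismatch")

    base = float(np.mean(predict_fn(background)))
    if p <= exact_threshold:
        values, stderr = _exact_shapley(predict_fn, X, background)
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        values, stderr = _sampled_shapley(
            predict_fn, X, background, n_permutations, rng
        )
        method = "permutation-sampling"
    meta = {"method": method, "n_background": len(background), "seed": seed}
    meta.update(metadata or {})
    return AttributionResult(
        feature_names=feature_names,
        shap_values=values,
        base_value=base,
        stderr=stderr,
        metadata=meta,
    )


def compare_importance(results: dict[str, AttributionResult]) -> pd.DataFrame:
    """Per-feature MAS and rank for several models, with rank deltas.

    Rank deltas are relative to the first model in the dict (insertion
    order); positive delta = the feature lost importance in that model.
    """
    if not results:
        raise ValueError("no attribution results given")
    names = None
    for res in results.values():
        if names is None:
            names = res.feature_names
        elif res.feature_names != names:
            raise ValueError("mismatched feature sets between results")
    table = pd.DataFrame(index=pd.Index(names, name="feature"))
    first = next(iter(results))
    for model, res in results.items():
        ranks = pd.Series(
            {f: i + 1 for i, f in enumerate(res.ranking)}, name=model
        )
        table[f"mas_{model}"] = pd.Series(res.mas, index=names)
        table[f"rank_{model}"] = ranks.reindex(names)
    for model in results:
        if model != first:
            table[f"rank_delta_{model}"] = (
                table[f"rank_{model}"] - table[f"rank_{first}"]
            )
    return table.sort_values(f"rank_{first}")


def top_n_overlap(a: AttributionResult, b: AttributionResult, n: int = 10) -> int:
    """Number of features shared by the two models' top-n MAS rankings."""
    return len(set(a.ranking[:n]) & set(b.ranking[:n]))
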