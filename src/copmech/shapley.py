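"""Exact Shapley attribution by full coalition enumeration.

For a model ``f`` and an instance ``x``, the interventional value of a
coalition S is the mean model output with the features in S taken from
``x`` and the rest marginalized over a background sample:

    v(S) = mean_z f(x_S, z_{D \\ S})

The Shapley value of feature i is the weighted average of its marginal
contributions over all coalitions not containing i:

    phi_i = sum_{S subseteq D\\{i}} |S|! (d-|S|-1)! / d! * [v(S u {i}) - v(S)]

With d features this costs 2^d value evaluations; each evaluation is a
batched model call over the background, so the whole report is one model
call on a (2^d * n_background, d) matrix. Efficiency (phi summing to
f(x) minus the base value), the null-player property and symmetry hold
by construction and are asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

__all__ = ["ShapleyReport", "exact_shapley", "shap_summary"]

MAX_FEATURES = 12


@dataclass
class ShapleyReport:
    phi: np.ndarray
    base_value: float
    prediction: float
    feature_names: list[str]
    instance: np.ndarray


def _coalition_values(predict_fn, instance, background) -> dict[frozenset, float]:
    d = len(instance)
    n_bg = len(background)
    subsets = [frozenset(s) for r in range(d + 1)
               for s in combinations(range(d), r)]
    # one batched model call over all (subset, background row) composites
    big = np.tile(background, (len(subsets), 1))
    for si, S in enumerate(subsets):
        block = slice(si * n_bg, (si + 1) * n_bg)
        for i in S:
            big[block, i] = instance[i]
    out = np.asarray(predict_fn(big), float).ravel()
    if out.shape != (len(big),):
        raise ValueError("predict_fn must return one scalar per input row")
    return {
        S: float(out[si * n_bg:(si + 1) * n_bg].mean())
        for si, S in enumerate(subsets)
    }


def exact_shapley(
    predict_fn,
    instance,
    background,
    feature_names: list[str] | None = None,
) -> ShapleyReport:
    """Exact interventional Shapley attributions for one instance.

    ``predict_fn`` maps a 2-D array (n, d) to n scalar outputs (for a
    classifier, typically the positive-class probability).
    """
    instance = np.asarray(instance, float).ravel()
    background = np.atleast_2d(np.asarray(background, float))
    d = len(instance)
    if d > MAX_FEATURES:
        raise ValueError(f"exact enumeration supports at most {MAX_FEATURES} "
                         f"features, got {d}")
    if background.shape[1] != d:
        raise ValueError("background and instance dimensions differ")
    if len(background) == 0:
        raise ValueError("background must be nonempty")
    values = _coalition_values(predict_fn, instance, background)
    phi = np.zeros(d)
    fact = [factorial(r) for r in range(d + 1)]
    for i in range(d):
        rest = [j for j in range(d) if j != i]
        for r in range(d):
            w = fact[r] * fact[d - r - 1] / fact[d]
            for S in combinations(rest, r):
                fs = frozenset(S)
                phi[i] += w * (values[fs | {i}] - values[fs])
    base = values[frozenset()]
    pred = values[frozenset(range(d))]
    if abs(phi.sum() - (pred - base)) > 1e-9 * max(1.0, abs(pred - base)):
        raise AssertionError("Shapley additivity violated (numerical fault)")
    names = feature_names or [f"x{i}" for i in range(d)]
    return ShapleyReport(phi=phi, base_value=base, prediction=pred,
                         feature_names=list(names), instance=instance)


def shap_summary(reports: list[ShapleyReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-instance reports into ranking and dependence data.

    Returns ``(ranking, dependence)``: mean |phi| per feature sorted
    descending, and per-feature (value, phi) pairs for dependence plots.
    """
    if not reports:
        raise ValueError("no reports to summarize")
    names = reports[0].feature_names
    if any(r.feature_names != names for r in reports):
        raise ValueError("inconsistent feature sets across reports")
    phis = np.array([r.phi for r in reports])
    vals = np.array([r.instance for r in reports])
    ranking = pd.DataFrame({
        "feature": names,
        "mean_abs_phi": np.abs(phis).mean(axis=0),
        "mean_phi": phis.mean(axis=0),
    }).sort_values("mean_abs_phi", ascending=False).reset_index(drop=True)
    dependence = pd.DataFrame({
        "feature": np.repeat(names, len(reports)),
        "value": vals.T.ravel(),
        "phi": phis.T.ravel(),
    })
    return ranking, dependence
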