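"""Shapley-value attribution of model probabilities to input features.

The value function is the marginal-expectation convention: for a coalition S,
v(S) is the model's mean probability over reference rows with the features in
S pinned to the explained sample.  phi is therefore in probability units and
sums (efficiency) to f(x) minus the mean prediction over the reference set.
Two independent code paths are provided: exact subset enumeration (feasible up
to 12 features; serves as the oracle) and Castro-style permutation sampling
with one reference row per permutation (unbiased, seeded, any feature count),
with the small efficiency residual redistributed proportionally to |phi|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np


@dataclass
class ShapReport:
    """Per-sample Shapley values plus the aggregates used for interpretation."""

    phi: np.ndarray                      # (n_samples, n_features)
    features: np.ndarray                 # the explained samples (n, d)
    schema: tuple = ()
    season: str | None = None
    mean_abs: np.ndarray | None = None   # per-feature mean |phi|
    pearson_r: np.ndarray | None = None  # per-feature corr(feature, phi)
    estimator: dict = field(default_factory=dict)


def exact_shapley(model_fn, x, reference_set) -> np.ndarray:
    """Exact Shapley values by subset enumeration (at most 12 features).

    v(S) = mean over reference rows r of f(x_S combined with r outside S).
    """
    x = np.asarray(x, dtype=float).ravel()
    R = np.atleast_2d(np.asarray(reference_set, dtype=float))
    d = len(x)
    if d > 12:
        raise ValueError(f"{d} features: exact enumeration capped at 12; "
                         "use sampled_shapley")
    n_ref = len(R)
    # v(S) for every subset, evaluated in one batched call per subset
    v = np.empty(2 ** d)
    for mask in range(2 ** d):
        inS = np.array([(mask >> j) & 1 for j in range(d)], dtype=bool)
        X = R.copy()
        X[:, inS] = x[inS]
        v[mask] = float(np.mean(model_fn(X)))
    phi = np.zeros(d)
    for j in range(d):
        others = [k for k in range(d) if k != j]
        for size in range(d):
            w = factorial(size) * factorial(d - size - 1) / factorial(d)
            for S in combinations(others, size):
                mask = sum(1 << k for k in S)
                phi[j] += w * (v[mask | (1 << j)] - v[mask])
    return phi


def sampled_shapley(model_fn, x, reference_set, n_permutations: int = 128,
                    seed: int = 0) -> np.ndarray:
    """Permutation-sampling Shapley estimate (Castro et al. scheme).

    Each permutation draws one reference row and morphs it into the explained
    sample feature by feature in permutation order; the marginal change in
    model output at each insertion accrues to that feature.  The estimator is
    unbiased for the marginal-expectation value function; the residual between
    sum(phi) and f(x) - mean_ref f is redistributed proportionally to |phi| so
    efficiency holds exactly.  Deterministic for a fixed seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    R = np.atleast_2d(np.asarray(reference_set, dtype=float))
    if len(R) == 0:
        raise ValueError("reference set is empty")
    d = len(x)
    rng = np.random.default_rng(seed)
    phi = np.zeros(d)
    for _ in range(n_permutations):
        perm = rng.permutation(d)
        r = R[rng.integers(len(R))]
        # rows[k] = r with the first k features of perm replaced by x
        rows = np.tile(r, (d + 1, 1))
        cur = r.copy()
        for k, j in enumerate(perm):
            cur[j] = x[j]
            rows[k + 1] = cur
        out = np.asarray(model_fn(rows), dtype=float)
        phi[perm] += np.diff(out)
    phi /= n_permutations
    target = float(np.mean(model_fn(x[None, :]))) - float(np.mean(model_fn(R)))
    residual = target - phi.sum()
    weights = np.abs(phi)
    if weights.sum() > 0:
        phi = phi + residual * weights / weights.sum()
    else:
        phi = phi + residual / d
    return phi


def shap_for_samples(model_fn, X, reference_set, n_permutations: int = 128,
                     seed: int = 0, schema=(), season=None) -> ShapReport:
    """Sampled Shapley values for a batch of samples, one seeded stream each."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(X))]
    phi = np.stack([
        sampled_shapley(model_fn, x, reference_set, n_permutations, sd)
        for x, sd in zip(X, seeds)
    ])
    report = ShapReport(phi=phi, features=X, schema=tuple(schema), season=season,
                        estimator={"n_permutations": n_permutations, "seed": seed,
                                   "n_reference": int(len(np.atleast_2d(reference_set)))})
    return aggregate_shap(report)


def aggregate_shap(report: ShapReport) -> ShapReport:
    """Fill per-feature mean |phi| and Pearson r(feature, phi) on a report.

    r summarizes the directionality of a feature's effect; it is NaN (flagged)
    for constant feature or phi columns, and needs at least 3 samples.
    """
    phi, X = report.phi, report.features
    if len(phi) < 3:
        raise ValueError("need at least 3 samples to aggregate Shapley values")
    report.mean_abs = np.abs(phi).mean(axis=0)
    d = phi.shape[1]
    r = np.full(d, np.nan)
    for j in range(d):
        fx, fp = X[:, j], phi[:, j]
        if np.std(fx) > 0 and np.std(fp) > 0:
            r[j] = float(np.corrcoef(fx, fp)[0, 1])
    report.pearson_r = r
    return report


def delta_shap(shap_future: ShapReport, shap_present: ShapReport):
    """Mean per-feature change in Shapley values, future minus present.

    Both reports must share the feature schema (same model and reference
    convention).  Returns (delta_mean, delta_maps) where delta_maps is the
    per-sample difference when the two reports align sample-for-sample (same
    cells), else None.
    """
    if shap_future.schema != shap_present.schema or \
            shap_future.phi.shape[1] != shap_present.phi.shape[1]:
        raise ValueError("Shapley reports have mismatched feature schemas")
    delta_mean = shap_future.phi.mean(axis=0) - shap_present.phi.mean(axis=0)
    delta_maps = None
    if shap_future.phi.shape == shap_present.phi.shape:
        delta_maps = shap_future.phi - shap_present.phi
    return delta_mean, delta_maps
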