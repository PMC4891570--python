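"""NormFinder model-based stability estimation.

Fits the additive two-way model ``y_ij = alpha_i + beta_j + eps_ij`` to the
log quantities of gene i in sample j, where beta_j absorbs the shared
per-sample loading and alpha_i the gene's abundance.  A gene's stability
value rho is the square root of its estimated residual variance (single
group) or combines shrunken between-group bias with within-group sampling
error (grouped mode); lower rho means more stable.

The variance decomposition needs at least three genes: with g <= 2 the
gene-specific residual variance is not identifiable from the double-centered
residuals.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import DataError
from .results import NormfinderResult
from .transform import LogQuantityMatrix


def _as_y(lqm: Union[LogQuantityMatrix, pd.DataFrame]) -> pd.DataFrame:
    y = lqm.y if isinstance(lqm, LogQuantityMatrix) else lqm
    arr = y.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("log-quantity matrix must be finite")
    return y


def _variance_estimates(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene residual variances from the double-centered residuals.

    Returns (raw sigma^2 before clipping, clipped sigma^2).  The estimator
    z_i = sum_j r_ij^2/(n-1), corrected by the factor g/(g-2) and the
    shared term sum_k z_k/(g(g-1)), is unbiased for the gene-specific
    residual variance under the additive model.
    """
    g, n = arr.shape
    if g < 3:
        raise DataError(
            "NormFinder requires >= 3 genes: the per-gene variance estimator "
            "is degenerate for g <= 2"
        )
    if n < 3:
        raise DataError("NormFinder requires >= 3 samples")
    r = arr - arr.mean(axis=1, keepdims=True) - arr.mean(axis=0, keepdims=True)
    r += arr.mean()
    z = (r**2).sum(axis=1) / (n - 1)
    raw = (g / (g - 2)) * (z - z.sum() / (g * (g - 1)))
    return raw, np.maximum(raw, 0.0)


def stability_single_group(
    lqm: Union[LogQuantityMatrix, pd.DataFrame],
) -> NormfinderResult:
    """Single-group stability: rho_i = sqrt(clipped sigma^2_i)."""
    y = _as_y(lqm)
    raw, sigma2 = _variance_estimates(y.to_numpy(dtype=float))
    clipped = tuple(g for g, v in zip(y.index, raw) if v < 0)
    return NormfinderResult(
        stability=pd.Series(np.sqrt(sigma2), index=y.index, name="rho"),
        variance=pd.Series(sigma2, index=y.index, name="sigma2"),
        grouped=False,
        clipped=clipped,
    )


def stability_with_groups(
    lqm: Union[LogQuantityMatrix, pd.DataFrame],
    groups: Union[Mapping[str, str], pd.Series],
) -> NormfinderResult:
    """Grouped stability combining between-group bias and within-group noise.

    Per group: gene variances are estimated as in single-group mode
    restricted to the group's samples; the raw gene-by-group difference
    d_gi (group mean of the fully double-centered residuals) is shrunk by
    an empirical-Bayes factor ``var_d / (var_d + sigma^2_gi/n_g)``, where
    var_d is the across-genes variance of d with its sampling contribution
    removed (clipped at 0, in which case all d-tilde are 0).  Stability is
    the mean over groups of ``|d-tilde| + sqrt(sigma^2_gi/n_g)``.
    """
    y = _as_y(lqm)
    arr = y.to_numpy(dtype=float)
    g, n = arr.shape
    labels = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    missing = [s for s in y.columns if s not in labels.index or pd.isna(labels[s])]
    if missing:
        raise DataError(f"sample {missing[0]!r} has no group label")
    labels = labels.reindex(y.columns)
    group_names = sorted(labels.unique())
    if len(group_names) < 2:
        raise DataError("grouped mode requires >= 2 groups")
    cols = {gr: np.flatnonzero((labels == gr).to_numpy()) for gr in group_names}
    for gr, idx in cols.items():
        if len(idx) < 2:
            raise DataError(f"group {gr!r} has {len(idx)} sample(s); >= 2 required")

    # full double-centered residuals -> gene-by-group interaction d
    r = arr - arr.mean(axis=1, keepdims=True) - arr.mean(axis=0, keepdims=True)
    r += arr.mean()

    rho = np.zeros(g)
    sigma2_by_group = {}
    d_tilde = pd.DataFrame(0.0, index=y.index, columns=group_names)
    clipped: list[str] = []
    for gr in group_names:
        idx = cols[gr]
        n_g = len(idx)
        sub = arr[:, idx]
        if n_g >= 3:
            raw_s2, s2 = _variance_estimates(sub)
            clipped.extend(gg for gg, v in zip(y.index, raw_s2) if v < 0)
        else:
            # too few samples for the unbiased estimator; fall back to the
            # plain residual mean square within the group
            rr = sub - sub.mean(axis=1, keepdims=True)
            rr -= rr.mean(axis=0, keepdims=True)
            s2 = (rr**2).sum(axis=1) / max(n_g - 1, 1)
        sigma2_by_group[gr] = s2
        d = r[:, idx].mean(axis=1)
        # prior variance of the true group differences: observed spread of d
        # minus its average sampling variance, clipped at zero
        var_d = (d**2).sum() / (g - 1) - s2.mean() / n_g
        if var_d <= 0:
            dt = np.zeros(g)
        else:
            dt = d * var_d / (var_d + s2 / n_g)
        d_tilde[gr] = dt
        rho += np.abs(dt) + np.sqrt(s2 / n_g)
    rho /= len(group_names)

    variance = pd.Series(
        np.mean([sigma2_by_group[gr] for gr in group_names], axis=0),
        index=y.index,
        name="sigma2",
    )
    return NormfinderResult(
        stability=pd.Series(rho, index=y.index, name="rho"),
        variance=variance,
        grouped=True,
        group_bias=d_tilde,
        clipped=tuple(dict.fromkeys(clipped)),
    )


def stability_from_cq(cq: pd.DataFrame) -> NormfinderResult:
    """Single-group stability straight from a gene x sample Cq table.

    Uses y = -Cq, which differs from log2 relative quantities only by
    per-gene constants, so stability values and rankings are identical.
    """
    return stability_single_group(-cq.astype(float))


def rank_by_stability(res: NormfinderResult) -> list[str]:
    """Genes ordered by ascending rho; ties broken by the gene ordering."""
    order_index = {g: i for i, g in enumerate(res.stability.index)}
    return sorted(res.stability.index, key=lambda g: (res.stability[g], order_index[g]))
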