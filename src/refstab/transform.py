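"""Cq -> relative quantity transforms and standard-curve efficiencies.

The stability algorithms operate on relative quantities
``Q = E^(minCq - Cq)`` computed per gene, where E is the amplification
efficiency (fold of product per cycle; 2 = perfect doubling).  The sample
with the lowest Cq of a gene gets Q = 1 exactly; every extra cycle divides
Q by E.  E comes either from a fixed base (default 2) or from per-gene
dilution-series standard curves via ``E = 10^(-1/slope)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .io import CqMatrix


@dataclass
class QuantityMatrix:
    """Per-gene relative quantities Q in (0, 1], max exactly 1 per gene."""

    q: pd.DataFrame
    efficiency_mode: str
    efficiencies: pd.Series
    meta: Optional[pd.DataFrame] = None
    assays: Optional[pd.DataFrame] = None

    @property
    def genes(self) -> list[str]:
        return list(self.q.index)

    @property
    def samples(self) -> list[str]:
        return list(self.q.columns)


@dataclass
class LogQuantityMatrix:
    """Log-scale quantities y = log(Q)/log(log_base); per-gene max is 0."""

    y: pd.DataFrame
    log_base: float = 2.0
    meta: Optional[pd.DataFrame] = None

    @property
    def genes(self) -> list[str]:
        return list(self.y.index)

    @property
    def samples(self) -> list[str]:
        return list(self.y.columns)


@dataclass
class StandardCurve:
    """OLS fit of Cq against log10 template dilution for one assay."""

    gene_id: str
    points: list[tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float
    efficiency: float


def relative_quantities(
    m: CqMatrix,
    mode: str = "fixed_base",
    base: float = 2.0,
) -> QuantityMatrix:
    """Transform a complete Cq matrix into relative quantities.

    In ``fixed_base`` mode every gene uses ``base`` as efficiency (the
    conventional Q = 2^(minCq - Cq)); ``per_gene`` mode reads each gene's
    measured efficiency from the attached assay table, for sensitivity
    analysis and efficiency-corrected quantification.
    """
    if m.cq.isna().any().any():
        raise DataError("Cq matrix must be complete (aggregate/drop first)")
    if mode == "fixed_base":
        if base <= 1:
            raise DataError(f"efficiency must exceed 1, got {base}")
        eff = pd.Series(float(base), index=m.cq.index)
    elif mode == "per_gene":
        if m.assays is None or "efficiency" not in m.assays.columns:
            raise DataError("per_gene mode requires an assay table with efficiencies")
        missing = [g for g in m.cq.index if g not in m.assays.index]
        if missing:
            raise DataError(f"no assay efficiency for gene {missing[0]!r}")
        eff = m.assays["efficiency"].astype(float).reindex(m.cq.index)
        if (eff <= 1).any():
            bad = eff[eff <= 1].index[0]
            raise DataError(f"efficiency must exceed 1 (gene {bad!r})")
    else:
        raise ValueError(f"unknown efficiency mode {mode!r}")

    delta = m.cq.min(axis=1).to_numpy()[:, None] - m.cq.to_numpy()
    q = np.power(eff.to_numpy()[:, None], delta)
    qdf = pd.DataFrame(q, index=m.cq.index, columns=m.cq.columns)
    return QuantityMatrix(
        q=qdf, efficiency_mode=mode, efficiencies=eff, meta=m.meta, assays=m.assays
    )


def log_quantities(qm: QuantityMatrix, log_base: float = 2.0) -> LogQuantityMatrix:
    """Take per-gene log quantities; monotone and order-preserving."""
    if (qm.q.to_numpy() <= 0).any():
        raise DataError("all quantities must be positive before log transform")
    if log_base <= 0 or log_base == 1:
        raise ValueError("log_base must be positive and != 1")
    y = np.log(qm.q.to_numpy()) / np.log(log_base)
    return LogQuantityMatrix(
        y=pd.DataFrame(y, index=qm.q.index, columns=qm.q.columns),
        log_base=float(log_base),
        meta=qm.meta,
    )


def efficiency_from_standard_curve(
    points: Sequence[tuple[float, float]],
    gene_id: str = "",
) -> StandardCurve:
    """Fit a dilution-series standard curve and derive the PCR efficiency.

    ``points`` are (log10 dilution, Cq) pairs; Cq regressed on log10
    dilution by ordinary least squares.  Efficiency is ``10^(-1/slope)``; a
    slope of -3.3219 corresponds to perfect doubling (E = 2).  More
    template must lower Cq, so a non-negative slope is an error.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise DataError(f"standard curve needs >= 3 points, got {len(pts)}")
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if len(np.unique(xs)) < 2:
        raise DataError("standard curve needs >= 2 distinct dilutions")
    fit = stats.linregress(xs, ys)
    if fit.slope >= 0:
        raise DataError(
            f"standard-curve slope must be negative (got {fit.slope:.4f}): "
            "more template must reduce Cq"
        )
    return StandardCurve(
        gene_id=gene_id,
        points=pts,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=float(10.0 ** (-1.0 / fit.slope)),
    )
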