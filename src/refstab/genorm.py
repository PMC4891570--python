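"""geNorm stability analysis.

A candidate's M value is the mean, over all other candidates, of the
sample standard deviation of the pairwise log2 expression ratio; genes
whose ratio to every other candidate is constant across samples get M = 0.
Stepwise exclusion repeatedly removes the highest-M gene until two remain
(those two share the top rank, since a pair has a single ratio).  The
pairwise-variation curve V_n/n+1 compares normalization factors built from
the n and n+1 top-ranked genes; the smallest n with V below the cutoff
(conventionally 0.15) is the recommended number of reference genes.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .results import ExclusionStep, NormalizationFactors, StabilityReport, VCurve
from .transform import QuantityMatrix

DEFAULT_V_CUTOFF = 0.15


def _log2_matrix(qm: QuantityMatrix, genes: Sequence[str]) -> np.ndarray:
    q = qm.q.loc[list(genes)].to_numpy(dtype=float)
    if not np.all(np.isfinite(q)) or (q <= 0).any():
        raise DataError("all relative quantities must be finite and positive")
    return np.log2(q)


def pairwise_stability_m(
    qm: QuantityMatrix, genes: Optional[Sequence[str]] = None
) -> pd.Series:
    """M value per gene: mean SD (n-1 denominator) of its pairwise log2 ratios."""
    genes = list(genes) if genes is not None else qm.genes
    if len(genes) < 2:
        raise DataError("M value requires at least 2 genes")
    if len(qm.samples) < 2:
        raise DataError("M value requires at least 2 samples")
    y = _log2_matrix(qm, genes)
    g = len(genes)
    # SD across samples of y_j - y_k for every ordered pair (g small: <= dozens)
    diffs = y[:, None, :] - y[None, :, :]
    sds = diffs.std(axis=2, ddof=1)
    m = sds.sum(axis=1) / (g - 1)  # diagonal contributes 0
    return pd.Series(m, index=genes, name="M")


def stepwise_exclusion(qm: QuantityMatrix) -> StabilityReport:
    """Rank genes by iterative exclusion of the least stable candidate.

    At each round, M is recomputed over the remaining genes and the gene
    with the highest M is removed (ties broken toward the gene latest in
    the matrix's gene order, so results are deterministic).  Stops at two
    genes, which are reported as joint best with their shared M.  Each
    gene's reported stability is its M at the round it was excluded.
    """
    genes = qm.genes
    if len(genes) < 3:
        raise DataError("stepwise exclusion requires at least 3 genes")
    order_index = {g: i for i, g in enumerate(genes)}
    remaining = list(genes)
    trace: list[ExclusionStep] = []
    excluded_order: list[str] = []
    per_gene_value: dict[str, float] = {}
    step = 1
    while len(remaining) > 2:
        m = pairwise_stability_m(qm, remaining)
        max_m = m.max()
        tied = [g for g in remaining if m[g] == max_m]
        excluded = max(tied, key=lambda g: order_index[g])
        after = [g for g in remaining if g != excluded]
        avg_after = float(pairwise_stability_m(qm, after).mean())
        trace.append(
            ExclusionStep(
                step=step,
                remaining=tuple(remaining),
                m_values={g: float(m[g]) for g in remaining},
                excluded=excluded,
                avg_m=avg_after,
            )
        )
        per_gene_value[excluded] = float(m[excluded])
        excluded_order.append(excluded)
        remaining = after
        step += 1
    final_m = pairwise_stability_m(qm, remaining)
    pair_m = float(final_m.iloc[0])
    trace.append(
        ExclusionStep(
            step=step,
            remaining=tuple(remaining),
            m_values={g: float(final_m[g]) for g in remaining},
            excluded=None,
            avg_m=pair_m,
        )
    )
    # final pair tied best; positions 1-2 by gene order for display only
    pair_sorted = sorted(remaining, key=lambda g: order_index[g])
    for g in pair_sorted:
        per_gene_value[g] = pair_m
    ranking = pair_sorted + list(reversed(excluded_order))
    values = pd.Series({g: per_gene_value[g] for g in genes}, name="M")
    return StabilityReport(
        algorithm="genorm",
        per_gene_value=values,
        ranking=ranking,
        exclusion_trace=trace,
        tied_best=(pair_sorted[0], pair_sorted[1]),
    )


def normalization_factor(
    qm: QuantityMatrix, gene_set: Sequence[str]
) -> NormalizationFactors:
    """Per-sample NF: geometric mean of the member genes' relative quantities."""
    gene_set = list(gene_set)
    if not gene_set:
        raise DataError("normalization factor requires a non-empty gene set")
    missing = [g for g in gene_set if g not in qm.q.index]
    if missing:
        raise DataError(f"gene {missing[0]!r} not in quantity matrix")
    y = _log2_matrix(qm, gene_set)
    nf = np.exp2(y.mean(axis=0))
    return NormalizationFactors(
        gene_set=tuple(gene_set),
        nf=pd.Series(nf, index=qm.samples, name="NF"),
    )


def pairwise_variation_curve(
    qm: QuantityMatrix,
    ranking: Sequence[str],
    cutoff: float = DEFAULT_V_CUTOFF,
) -> VCurve:
    """V_n/n+1 = SD across samples of log2(NF_n / NF_{n+1}) for n = 2..G-1.

    ``ranking`` (best to worst, typically from :func:`stepwise_exclusion`)
    defines the nested gene sets.
    """
    ranking = list(ranking)
    if len(ranking) < 3:
        raise DataError("V curve requires at least 3 ranked genes")
    if cutoff <= 0:
        raise DataError("cutoff must be positive")
    pairs: list[tuple[int, float]] = []
    for n in range(2, len(ranking)):
        nf_n = normalization_factor(qm, ranking[:n]).nf.to_numpy()
        nf_n1 = normalization_factor(qm, ranking[: n + 1]).nf.to_numpy()
        v = float(np.std(np.log2(nf_n / nf_n1), ddof=1))
        pairs.append((n, v))
    return VCurve(pairs=pairs, cutoff=float(cutoff))


def optimal_gene_count(v: VCurve) -> Optional[int]:
    """Smallest n with V_n below the cutoff; None when no n qualifies.

    A None result means no tested combination reached acceptable
    normalization-factor stability (see ``VCurve.advisory``); the
    conventional fallback is to use at least the three most stable genes.
    """
    if not v.pairs:
        raise DataError("V curve is empty")
    return v.optimal_n
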