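"""Cross-algorithm consensus and the per-sample-set batch driver.

Two rankings of the same candidate panel rarely coincide exactly; the
conventional consensus questions are (i) how much the top halves overlap,
(ii) whether the two algorithms agree on the least stable pair, and
(iii) whether one algorithm's best gene sits inside the other's top k.
``run_all_sets`` applies the full geNorm + NormFinder workflow to each
experimental subset and bundles the answers.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from . import genorm, normfinder, transform
from .exceptions import DataError
from .io import CqMatrix, Selector, subset_by_experiment
from .results import ConsensusReport, SetBundle


def compare_rankings(
    a: Sequence[str],
    b: Sequence[str],
    k: Optional[int] = None,
    sample_set: str = "",
    a_values: Optional[pd.Series] = None,
    b_values: Optional[pd.Series] = None,
) -> ConsensusReport:
    """Compare two stability rankings (best first) over the same gene set.

    ``k`` defaults to half the panel.  The least-stable comparison uses the
    bottom two of each ranking; when stability values are supplied and the
    value at the bottom-2 boundary is tied, all tied genes are included and
    the report is flagged (``boundary_tie``).
    """
    a, b = list(a), list(b)
    if sorted(a) != sorted(b):
        raise DataError("rankings cover different gene sets")
    if len(set(a)) != len(a):
        raise DataError("ranking contains duplicate genes")
    if k is None:
        k = len(a) // 2
    if not 1 <= k <= len(a):
        raise DataError(f"k={k} out of range for {len(a)} genes")

    def bottom(ranking: list[str], values: Optional[pd.Series]) -> tuple[set[str], bool]:
        worst = set(ranking[-2:])
        tie = False
        if values is not None and len(ranking) > 2:
            boundary = values[ranking[-2]]
            for g in ranking[:-2]:
                if values[g] == boundary:
                    worst.add(g)
                    tie = True
        return worst, tie

    bot_a, tie_a = bottom(a, a_values)
    bot_b, tie_b = bottom(b, b_values)
    return ConsensusReport(
        sample_set=sample_set,
        genorm_ranking=a,
        normfinder_ranking=b,
        k=k,
        top_k_overlap=frozenset(a[:k]) & frozenset(b[:k]),
        least_stable_agreement=frozenset(bot_a & bot_b),
        normfinder_best_in_genorm_top_k=b[0] in set(a[:k]),
        boundary_tie=tie_a or tie_b,
    )


def analyze_set(
    m: CqMatrix,
    name: str = "",
    base: float = 2.0,
    efficiency_mode: str = "fixed_base",
    v_cutoff: float = genorm.DEFAULT_V_CUTOFF,
    top_k: Optional[int] = None,
    group_col: Optional[str] = None,
) -> SetBundle:
    """Full stability workflow for one (already subset) Cq matrix."""
    qm = transform.relative_quantities(m, mode=efficiency_mode, base=base)
    gn = genorm.stepwise_exclusion(qm)
    vcurve = genorm.pairwise_variation_curve(qm, gn.ranking, cutoff=v_cutoff)
    lqm = transform.log_quantities(qm)
    if group_col is not None:
        if m.meta is None or group_col not in m.meta.columns:
            raise DataError(f"no metadata column {group_col!r} for grouping")
        nf_res = normfinder.stability_with_groups(lqm, m.meta[group_col])
    else:
        nf_res = normfinder.stability_single_group(lqm)
    nf_ranking = normfinder.rank_by_stability(nf_res)
    cons = compare_rankings(
        gn.ranking,
        nf_ranking,
        k=top_k,
        sample_set=name,
        a_values=gn.per_gene_value,
        b_values=nf_res.stability,
    )
    return SetBundle(
        name=name,
        n_samples=m.n_samples,
        genorm=gn,
        normfinder=nf_res,
        normfinder_ranking=nf_ranking,
        vcurve=vcurve,
        consensus=cons,
    )


def run_all_sets(
    dataset: CqMatrix,
    set_definitions: Sequence[tuple[str, Selector]],
    **kwargs,
) -> list[SetBundle]:
    """Run the workflow on every defined sample set.

    ``set_definitions`` is an ordered list of (name, selector) pairs (see
    :func:`refstab.io.subset_by_experiment`).  Failures in one set are
    captured in its bundle's ``error`` field and do not abort the batch.
    """
    bundles: list[SetBundle] = []
    for name, selector in set_definitions:
        try:
            if isinstance(selector, Mapping) and not selector:
                sub = dataset  # empty selector keeps every sample
            else:
                sub = subset_by_experiment(dataset, selector)
            bundles.append(analyze_set(sub, name=name, **kwargs))
        except Exception as exc:  # collected, not fatal to the batch
            bundles.append(SetBundle(name=name, error=str(exc)))
    return bundles
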