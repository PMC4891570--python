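"""Efficiency-corrected relative quantification of a target gene.

Pfaffl-style ratio-to-calibrator: the target's relative quantity
``E_t^(minCq - Cq)`` is divided by the per-sample normalization factor
(geometric mean of the reference genes' quantities), then rescaled so the
calibrator sample or condition mean equals 1.  With all efficiencies at 2
and a single reference gene this reduces algebraically to the classic
2^-ddCq.  Side-by-side runs under different normalizer choices expose how
an unstable reference distorts the apparent expression profile.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import genorm
from .exceptions import DataError
from .results import NormalizationFactors, RelExpressionTable
from .transform import QuantityMatrix


def normalize_target(
    target_cq: pd.Series,
    refs: NormalizationFactors,
    target_efficiency: float = 2.0,
    calibrator: str = "",
    conditions: Optional[pd.Series] = None,
) -> RelExpressionTable:
    """Quantify a target gene relative to a reference set and calibrator.

    ``target_cq`` maps sample -> Cq for the target; its samples must be a
    subset of the reference NF's samples.  ``calibrator`` names either a
    sample or, when ``conditions`` labels are given, a condition whose mean
    ratio is scaled to 1.  When ``conditions`` is provided, per-condition
    mean +/- SD over biological replicates is reported alongside.
    """
    if target_efficiency <= 1:
        raise DataError(f"target efficiency must exceed 1, got {target_efficiency}")
    target_cq = target_cq.astype(float)
    missing = [s for s in target_cq.index if s not in refs.nf.index]
    if missing:
        raise DataError(f"sample {missing[0]!r} has no normalization factor")
    nf = refs.nf.reindex(target_cq.index)
    if (nf <= 0).any():
        raise DataError("normalization factors must be positive")

    q_target = np.power(target_efficiency, target_cq.min() - target_cq)
    ratio = q_target / nf

    if conditions is not None:
        conditions = conditions.reindex(target_cq.index)
        if conditions.isna().any():
            bad = conditions[conditions.isna()].index[0]
            raise DataError(f"sample {bad!r} has no condition label")
        cal_mask = conditions == calibrator
        if not cal_mask.any():
            cal_mask = target_cq.index == calibrator
    else:
        cal_mask = target_cq.index == calibrator
    if not cal_mask.any():
        raise DataError(f"calibrator {calibrator!r} matches no sample or condition")
    scaled = ratio / ratio[cal_mask].mean()

    aggregated = None
    if conditions is not None:
        aggregated = (
            scaled.groupby(conditions).agg(["mean", "std"]).rename_axis("condition")
        )
    return RelExpressionTable(
        target_gene=str(target_cq.name or "target"),
        normalizer=tuple(refs.gene_set),
        calibrator=str(calibrator),
        values=scaled,
        aggregated=aggregated,
    )


def compare_normalizers(
    target_cq: pd.Series,
    candidate_sets: Sequence[Sequence[str]],
    qm: QuantityMatrix,
    calibrator: str = "",
    target_efficiency: float = 2.0,
    conditions: Optional[pd.Series] = None,
) -> tuple[list[RelExpressionTable], dict[str, str]]:
    """Quantify the same target under several reference-gene choices.

    Returns the tables (one per candidate set, identical calibrator
    scaling, overlay-ready) plus a dict of per-set error messages for sets
    that failed; failures do not abort the batch.
    """
    target_name = str(target_cq.name or "target")
    tables: list[RelExpressionTable] = []
    errors: dict[str, str] = {}
    for genes in candidate_sets:
        label = "+".join(genes)
        try:
            if target_name in set(genes):
                raise DataError(
                    f"target {target_name!r} cannot normalize itself"
                )
            nf = genorm.normalization_factor(qm, list(genes))
            tables.append(
                normalize_target(
                    target_cq,
                    nf,
                    target_efficiency=target_efficiency,
                    calibrator=calibrator,
                    conditions=conditions,
                )
            )
        except Exception as exc:
            errors[label] = str(exc)
    return tables, errors


def tables_to_long_frame(tables: Sequence[RelExpressionTable]) -> pd.DataFrame:
    """Stack RelExpressionTables into one plot-ready long table."""
    if not tables:
        return pd.DataFrame(
            columns=[
                "sample_id",
                "relative_expression",
                "target_gene",
                "normalizer",
                "calibrator",
            ]
        )
    return pd.concat([t.to_frame() for t in tables], ignore_index=True)
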