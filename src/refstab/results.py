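"""Result containers shared across the analysis modules.

Plain dataclasses wrapping pandas objects; each knows how to export itself
as a flat table (``to_frame``) or a JSON-serialisable dict (``to_dict``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd


@dataclass
class ExclusionStep:
    """One round of geNorm stepwise exclusion.

    ``m_values`` are the per-gene M values computed over ``remaining`` at the
    start of the step; ``avg_m`` is the mean M of the genes left *after*
    ``excluded`` is removed (the quantity plotted on stepwise-exclusion
    stability curves).  The final step has ``excluded=None`` and records the
    shared M of the last pair.
    """

    step: int
    remaining: tuple[str, ...]
    m_values: dict[str, float]
    excluded: Optional[str]
    avg_m: float


@dataclass
class StabilityReport:
    """Per-gene stability values plus ranking for one algorithm.

    ``per_gene_value`` holds M (geNorm) or rho (NormFinder); lower is more
    stable.  For geNorm, the value of each gene is its M at the step where it
    was excluded, so the final two genes share the top value, and
    ``exclusion_trace`` records every round.
    """

    algorithm: str
    per_gene_value: pd.Series
    ranking: list[str]
    exclusion_trace: Optional[list[ExclusionStep]] = None
    tied_best: Optional[tuple[str, str]] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene_id": list(self.ranking),
                "rank": range(1, len(self.ranking) + 1),
                "stability": [self.per_gene_value[g] for g in self.ranking],
            }
        )
        df["algorithm"] = self.algorithm
        return df

    def to_dict(self) -> dict:
        d = {
            "algorithm": self.algorithm,
            "per_gene_value": {g: float(v) for g, v in self.per_gene_value.items()},
            "ranking": list(self.ranking),
        }
        if self.tied_best is not None:
            d["tied_best"] = list(self.tied_best)
        if self.exclusion_trace is not None:
            d["exclusion_trace"] = [
                {
                    "step": s.step,
                    "remaining": list(s.remaining),
                    "m_values": {g: float(v) for g, v in s.m_values.items()},
                    "excluded": s.excluded,
                    "avg_m": float(s.avg_m),
                }
                for s in self.exclusion_trace
            ]
        return d


@dataclass
class NormalizationFactors:
    """Per-sample normalization factor: geometric mean of the member genes' Q."""

    gene_set: tuple[str, ...]
    nf: pd.Series

    def __post_init__(self) -> None:
        self.gene_set = tuple(self.gene_set)


@dataclass
class VCurve:
    """Pairwise-variation curve V_n/n+1 for n = 2..G-1.

    ``optimal_n`` is the smallest n whose V falls below ``cutoff``; ``None``
    plays the role of the "no suitable combination" sentinel, in which case
    ``advisory`` suggests the conventional fallback of using at least the
    three most stable genes.
    """

    pairs: list[tuple[int, float]]
    cutoff: float = 0.15

    @property
    def optimal_n(self) -> Optional[int]:
        for n, v in self.pairs:
            if v < self.cutoff:
                return n
        return None

    @property
    def advisory(self) -> str:
        if self.optimal_n is not None:
            return f"use the {self.optimal_n} most stable reference genes"
        return (
            "no V value fell below the cutoff; no tested combination is "
            "adequate — consider at least the three most stable genes and "
            "interpret normalized results with caution"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": [n for n, _ in self.pairs],
                "v": [v for _, v in self.pairs],
                "cutoff": self.cutoff,
            }
        )

    def to_dict(self) -> dict:
        return {
            "pairs": [[int(n), float(v)] for n, v in self.pairs],
            "cutoff": float(self.cutoff),
            "optimal_n": self.optimal_n,
            "advisory": self.advisory,
        }


@dataclass
class NormfinderResult:
    """NormFinder stability values (rho, lower = more stable).

    ``variance`` holds the clipped per-gene variance estimates; in grouped
    mode ``group_bias`` holds the shrunken gene-by-group differences d-tilde
    and ``clipped`` lists genes whose raw variance estimate was negative.
    """

    stability: pd.Series
    variance: pd.Series
    grouped: bool = False
    group_bias: Optional[pd.DataFrame] = None
    clipped: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"stability": self.stability, "variance": self.variance}
        )
        df.index.name = "gene_id"
        return df.reset_index()


@dataclass
class ConsensusReport:
    """Agreement between two stability rankings (e.g. geNorm vs NormFinder)."""

    sample_set: str
    genorm_ranking: list[str]
    normfinder_ranking: list[str]
    k: int
    top_k_overlap: frozenset[str]
    least_stable_agreement: frozenset[str]
    normfinder_best_in_genorm_top_k: bool
    boundary_tie: bool = False

    @property
    def top_k_overlap_size(self) -> int:
        return len(self.top_k_overlap)

    def to_dict(self) -> dict:
        return {
            "sample_set": self.sample_set,
            "genorm_ranking": list(self.genorm_ranking),
            "normfinder_ranking": list(self.normfinder_ranking),
            "k": self.k,
            "top_k_overlap": sorted(self.top_k_overlap),
            "top_k_overlap_size": self.top_k_overlap_size,
            "least_stable_agreement": sorted(self.least_stable_agreement),
            "normfinder_best_in_genorm_top_k": self.normfinder_best_in_genorm_top_k,
            "boundary_tie": self.boundary_tie,
        }


@dataclass
class RelExpressionTable:
    """Relative expression of a target gene under one normalizer choice.

    ``values`` maps sample -> expression relative to the calibrator (which is
    scaled to 1); ``aggregated`` holds mean +/- SD per condition over
    biological replicates when condition labels were supplied.
    """

    target_gene: str
    normalizer: tuple[str, ...]
    calibrator: str
    values: pd.Series
    aggregated: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.values.index,
                "relative_expression": self.values.to_numpy(),
            }
        )
        df["target_gene"] = self.target_gene
        df["normalizer"] = "+".join(self.normalizer)
        df["calibrator"] = self.calibrator
        return df


@dataclass
class SetBundle:
    """All per-sample-set outputs of the batch driver."""

    name: str
    n_samples: int = 0
    genorm: Optional[StabilityReport] = None
    normfinder: Optional[NormfinderResult] = None
    normfinder_ranking: Optional[list[str]] = None
    vcurve: Optional[VCurve] = None
    consensus: Optional[ConsensusReport] = None
    error: Optional[str] = None
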