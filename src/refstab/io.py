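"""Reading, validating, aggregating, and subsetting Cq data.

Cq (quantification cycle, also called Cp) values arrive either in long
format — one row per ``(sample_id, gene_id, replicate)`` — or as a wide
gene x sample.replicate table.  Both readers produce the same
:class:`CqDataset`; technical replicates are then collapsed into a complete
gene x sample :class:`CqMatrix`, which is what the stability algorithms
consume.  Missing values are never imputed: samples left incomplete after
aggregation are dropped and recorded in the :class:`QCReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError

LONG_COLUMNS = ("sample_id", "gene_id", "replicate", "cq")

#: Tokens treated as a missing Cq on input (case-insensitive).
NA_TOKENS = frozenset({"", "na", "nan", "n/a", "null", "none", "-", "undetermined"})

#: Default replicate-SD QC threshold, in cycles.
DEFAULT_MAX_REPLICATE_SD = 0.5

#: Default tolerated fraction of samples missing a given gene.
DEFAULT_MAX_MISSING_FRACTION = 0.2


@dataclass
class CqDataset:
    """Replicate-level Cq records with optional sample/assay metadata.

    ``records`` has columns ``sample_id, gene_id, replicate, cq`` (cq is
    float, NaN for missing).  ``meta`` is indexed by sample_id, ``assays``
    by gene_id.
    """

    records: pd.DataFrame
    meta: Optional[pd.DataFrame] = None
    assays: Optional[pd.DataFrame] = None

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.records["gene_id"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class QCReport:
    """Report-only quality control summary; never mutates the data."""

    missing_cells: list[tuple[str, str]] = field(default_factory=list)
    replicate_sd_flags: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)
    dropped_genes: list[str] = field(default_factory=list)


@dataclass
class CqMatrix:
    """Complete replicate-aggregated gene x sample Cq table.

    ``cq`` is indexed by gene_id with sample_id columns; orders are
    deterministic (lexicographic unless an explicit order was supplied).
    """

    cq: pd.DataFrame
    meta: Optional[pd.DataFrame] = None
    assays: Optional[pd.DataFrame] = None
    qc: Optional[QCReport] = None

    @property
    def genes(self) -> list[str]:
        return list(self.cq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.cq.columns)

    @property
    def n_genes(self) -> int:
        return self.cq.shape[0]

    @property
    def n_samples(self) -> int:
        return self.cq.shape[1]


def _parse_cq_column(raw: pd.Series) -> pd.Series:
    """Parse a string Cq column, mapping NA tokens to NaN.

    Raises :class:`FormatError` naming the 1-based data row of the first
    non-numeric, non-NA cell.
    """
    out = np.empty(len(raw), dtype=float)
    for i, v in enumerate(raw.astype(str).str.strip()):
        if v.lower() in NA_TOKENS:
            out[i] = np.nan
            continue
        try:
            out[i] = float(v)
        except ValueError:
            raise FormatError(
                f"non-numeric Cq value {v!r} at data row {i + 1}"
            ) from None
    return pd.Series(out, index=raw.index)


def _finalize_records(df: pd.DataFrame) -> pd.DataFrame:
    dup = df.duplicated(subset=["sample_id", "gene_id", "replicate"])
    if dup.any():
        first = df.loc[dup, ["sample_id", "gene_id", "replicate"]].iloc[0]
        raise FormatError(
            "duplicate (sample_id, gene_id, replicate) record: "
            f"({first.sample_id}, {first.gene_id}, {first.replicate})"
        )
    neg = df["cq"].notna() & (df["cq"] <= 0)
    if neg.any():
        raise FormatError(
            f"Cq values must be positive; found {df.loc[neg, 'cq'].iloc[0]!r}"
        )
    return df.reset_index(drop=True)


def read_cq_long(source, sep: Optional[str] = None) -> CqDataset:
    """Read long-format Cq data (columns sample_id, gene_id, replicate, cq).

    ``source`` is a path or open text stream; the delimiter is sniffed when
    ``sep`` is None.  NA-like Cq cells become missing values (flagged later
    by :func:`validate_dataset`), non-numeric cells raise
    :class:`FormatError` with the offending row.
    """
    df = pd.read_csv(
        source, sep=sep, engine="python", dtype=str, keep_default_na=False
    )
    df.columns = [str(c).strip() for c in df.columns]
    for col in LONG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if df.empty:
        records = pd.DataFrame(
            {
                "sample_id": pd.Series(dtype=str),
                "gene_id": pd.Series(dtype=str),
                "replicate": pd.Series(dtype=int),
                "cq": pd.Series(dtype=float),
            }
        )
        return CqDataset(records=records)
    try:
        replicate = df["replicate"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer replicate index: {exc}") from None
    records = pd.DataFrame(
        {
            "sample_id": df["sample_id"].str.strip(),
            "gene_id": df["gene_id"].str.strip(),
            "replicate": replicate,
            "cq": _parse_cq_column(df["cq"]),
        }
    )
    return CqDataset(records=_finalize_records(records))


def read_cq_wide(source, sep: Optional[str] = None) -> CqDataset:
    """Read a wide gene x sample.replicate table.

    First column is ``gene_id``; every other column label must be of the
    form ``<sample_id>.<replicate>``.  Duplicate column labels are a format
    error.  Content-equivalent to the long reader on the same data.
    """
    raw = pd.read_csv(
        source, sep=sep, engine="python", header=None, dtype=str,
        keep_default_na=False,
    )
    if raw.empty:
        raise FormatError("empty wide-format file (no header row)")
    header = [str(c).strip() for c in raw.iloc[0]]
    if len(set(header)) != len(header):
        seen: set[str] = set()
        dup = next(c for c in header if c in seen or seen.add(c))  # type: ignore[func-returns-value]
        raise FormatError(f"duplicate column label {dup!r} in wide table")
    body = raw.iloc[1:].reset_index(drop=True)
    rows = []
    for label in header[1:]:
        if "." not in label:
            raise FormatError(
                f"wide column {label!r} is not of the form sample.replicate"
            )
        sample_id, rep_str = label.rsplit(".", 1)
        try:
            rep = int(rep_str)
        except ValueError:
            raise FormatError(
                f"wide column {label!r} has non-integer replicate suffix"
            ) from None
        rows.append((sample_id, rep))
    records = []
    for _, r in body.iterrows():
        gene = str(r.iloc[0]).strip()
        for j, (sample_id, rep) in enumerate(rows, start=1):
            records.append((sample_id, gene, rep, str(r.iloc[j])))
    df = pd.DataFrame(
        records, columns=["sample_id", "gene_id", "replicate", "cq"]
    )
    df["cq"] = _parse_cq_column(df["cq"])
    return CqDataset(records=_finalize_records(df))


def write_cq_long(ds: CqDataset, path) -> None:
    """Write a dataset back to long-format CSV (numeric content reproducible)."""
    out = ds.records.copy()
    out["cq"] = out["cq"].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, index=False)


def write_cq_wide(ds: CqDataset, path) -> None:
    """Write a dataset as a wide gene x sample.replicate CSV."""
    df = ds.records.copy()
    df["col"] = df["sample_id"] + "." + df["replicate"].astype(str)
    wide = df.pivot(index="gene_id", columns="col", values="cq")
    wide = wide.sort_index().sort_index(axis=1)
    wide.index.name = "gene_id"
    wide.map(lambda v: "" if pd.isna(v) else f"{v:.6f}").to_csv(path)


def read_sample_meta(source, sep: Optional[str] = None) -> pd.DataFrame:
    """Read a sample-metadata CSV keyed by ``sample_id``."""
    meta = pd.read_csv(source, sep=sep, engine="python", dtype=str)
    if "sample_id" not in meta.columns:
        raise FormatError("metadata file missing required column 'sample_id'")
    if meta["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in metadata")
    return meta.set_index("sample_id")


def read_assays(source, sep: Optional[str] = None) -> pd.DataFrame:
    """Read an assay table keyed by ``gene_id`` (efficiency, amplicon_length, tm)."""
    assays = pd.read_csv(source, sep=sep, engine="python")
    if "gene_id" not in assays.columns:
        raise FormatError("assay file missing required column 'gene_id'")
    assays = assays.set_index("gene_id")
    if "efficiency" in assays.columns:
        eff = assays["efficiency"].astype(float)
        bad = eff[(eff <= 1) | (eff > 2.5)]
        if not bad.empty:
            raise DataError(
                f"amplification efficiency out of range (1, 2.5] for "
                f"{bad.index[0]!r}: {bad.iloc[0]}"
            )
    return assays


def validate_dataset(
    ds: CqDataset,
    max_replicate_sd: float = DEFAULT_MAX_REPLICATE_SD,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
) -> QCReport:
    """Flag noisy replicate groups and gene x sample cells with no usable Cq.

    Report-only: flags replicate groups whose sample SD (n-1 denominator)
    exceeds ``max_replicate_sd`` cycles and cells where every replicate is
    missing.  ``max_missing_fraction`` is echoed to callers via
    :func:`aggregate_replicates`, which enforces it.
    """
    if ds.records.empty:
        raise DataError("cannot validate an empty dataset")
    report = QCReport()
    grouped = ds.records.groupby(["gene_id", "sample_id"])["cq"]
    counts = grouped.count()
    for (gene, sample), n_ok in counts.items():
        if n_ok == 0:
            report.missing_cells.append((gene, sample))
    sds = grouped.std(ddof=1)
    for (gene, sample), sd in sds.items():
        if pd.notna(sd) and sd > max_replicate_sd:
            report.replicate_sd_flags.append((gene, sample, float(sd)))
    return report


def aggregate_replicates(
    ds: CqDataset,
    method: str = "mean",
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
    qc: Optional[QCReport] = None,
    gene_order: Optional[Sequence[str]] = None,
    sample_order: Optional[Sequence[str]] = None,
) -> CqMatrix:
    """Collapse technical replicates to one Cq per gene x sample.

    ``method`` is "mean" (qPCR convention) or "median".  Samples still
    missing any gene after aggregation are dropped (recorded in the QC
    report) so the result is complete.  A gene absent from more than
    ``max_missing_fraction`` of samples is a hard error advising its
    removal rather than silently discarding most of the dataset.
    """
    if ds.records.empty:
        raise DataError("cannot aggregate an empty dataset")
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    agg = ds.records.groupby(["gene_id", "sample_id"])["cq"].agg(method)
    matrix = agg.unstack("sample_id")

    genes = list(gene_order) if gene_order is not None else sorted(matrix.index)
    samples = (
        list(sample_order) if sample_order is not None else sorted(matrix.columns)
    )
    matrix = matrix.reindex(index=genes, columns=samples)

    qc = qc if qc is not None else QCReport()
    missing_frac = matrix.isna().mean(axis=1)
    bad_genes = missing_frac[missing_frac > max_missing_fraction]
    if not bad_genes.empty:
        worst = bad_genes.idxmax()
        raise DataError(
            f"gene {worst!r} is missing in {bad_genes.max():.0%} of samples "
            f"(> {max_missing_fraction:.0%}); remove it from the candidate "
            "panel and re-aggregate"
        )
    incomplete = matrix.columns[matrix.isna().any(axis=0)]
    if len(incomplete):
        qc.dropped_samples.extend(incomplete)
        matrix = matrix.drop(columns=incomplete)
    if matrix.shape[1] == 0:
        raise DataError("no complete samples remain after aggregation")

    meta = None
    if ds.meta is not None:
        meta = ds.meta.loc[ds.meta.index.intersection(matrix.columns)]
        meta = meta.reindex(matrix.columns)
    return CqMatrix(cq=matrix, meta=meta, assays=ds.assays, qc=qc)


Selector = Union[Callable[[pd.DataFrame], "pd.Series"], Mapping[str, object]]


def _selector_mask(meta: pd.DataFrame, selector: Selector) -> pd.Series:
    if callable(selector):
        mask = selector(meta)
        return pd.Series(np.asarray(mask, dtype=bool), index=meta.index)
    mask = pd.Series(True, index=meta.index)
    for col, wanted in selector.items():
        if col not in meta.columns:
            raise DataError(f"metadata has no column {col!r}")
        if isinstance(wanted, (list, tuple, set, frozenset)):
            mask &= meta[col].isin(list(wanted))
        else:
            mask &= meta[col] == wanted
    return mask


def subset_by_experiment(m: CqMatrix, selector: Selector) -> CqMatrix:
    """Restrict a matrix to the samples matching a metadata predicate.

    ``selector`` is either a dict of ``column -> value`` (or list of
    values) matched conjunctively, or a callable returning a boolean mask
    over the metadata.  Gene order is preserved; fewer than two selected
    samples is an error because stability is undefined there.
    """
    if m.meta is None:
        raise DataError("matrix has no sample metadata to subset on")
    mask = _selector_mask(m.meta, selector)
    keep = [s for s in m.samples if bool(mask.get(s, False))]
    if len(keep) < 2:
        raise DataError(
            f"selector matched {len(keep)} sample(s); at least 2 required "
            "for stability analysis"
        )
    return CqMatrix(
        cq=m.cq[keep],
        meta=m.meta.loc[keep],
        assays=m.assays,
        qc=m.qc,
    )
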