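import io as _io
import math
import statistics

import numpy as np
import pandas as pd
import pytest

from refstab.io import CqMatrix
from refstab.transform import QuantityMatrix


def make_qm(arr, genes=None, samples=None) -> QuantityMatrix:
    """Wrap a positive array as a QuantityMatrix (no rescaling applied)."""
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i+1:02d}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j+1:03d}" for j in range(arr.shape[1])]
    q = pd.DataFrame(arr, index=genes, columns=samples)
    return QuantityMatrix(
        q=q,
        efficiency_mode="fixed_base",
        efficiencies=pd.Series(2.0, index=genes),
    )


def make_cq_matrix(arr, genes=None, samples=None, meta=None) -> CqMatrix:
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i+1:02d}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j+1:03d}" for j in range(arr.shape[1])]
    return CqMatrix(cq=pd.DataFrame(arr, index=genes, columns=samples), meta=meta)


def naive_m_values(q: pd.DataFrame) -> pd.Series:
    """Independent geNorm oracle: double loop, statistics.stdev of log2 ratios."""
    genes = list(q.index)
    vals = q.to_numpy(dtype=float)
    n = vals.shape[1]
    out = {}
    for j, gj in enumerate(genes):
        sds = []
        for k, _ in enumerate(genes):
            if k == j:
                continue
            ratios = [math.log2(vals[j, s] / vals[k, s]) for s in range(n)]
            sds.append(statistics.stdev(ratios))
        out[gj] = sum(sds) / len(sds)
    return pd.Series(out)


def naive_stepwise_order(q: pd.DataFrame) -> list:
    """Exclusion order recomputed from scratch with the naive M oracle."""
    order_index = {g: i for i, g in enumerate(q.index)}
    remaining = list(q.index)
    excluded = []
    while len(remaining) > 2:
        m = naive_m_values(q.loc[remaining])
        max_m = m.max()
        tied = [g for g in remaining if m[g] == max_m]
        worst = max(tied, key=lambda g: order_index[g])
        excluded.append(worst)
        remaining.remove(worst)
    return excluded


def long_csv(text: str) -> _io.StringIO:
    """Dedent-and-stream helper for inline CSV fixtures."""
    lines = [ln.strip() for ln in text.strip().splitlines()]
    return _io.StringIO("\n".join(lines))


@pytest.fixture(scope="session")
def study_dataset():
    from refstab.simulate import study_design

    return study_design(seed=11)


@pytest.fixture(scope="session")
def study_matrix(study_dataset):
    from refstab.io import aggregate_replicates, validate_dataset

    ds, _ = study_dataset
    qc = validate_dataset(ds)
    return aggregate_replicates(ds, qc=qc)
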