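"""Synthetic Cq data with known ground truth.

The generative model works on the Cq scale, where technical variation is
approximately homoscedastic::

    Cq[g, s, r] = baseline[g] + sample_effect[s] + group_shift[g, group(s)]
                  + gene_noise[g, s] + tech_noise[g, s, r]

* ``baseline`` sets each gene's abundance (lower Cq = more template);
* ``sample_effect`` is the shared loading/RT offset that normalization is
  meant to remove — it cancels in all stability statistics;
* ``group_shift`` models condition-responsive (unsuitable) reference genes;
* ``gene_noise`` is the per-gene instability the stability algorithms must
  recover — its SD ordering defines the ground-truth stability ranking;
* ``tech_noise`` is replicate-level pipetting/instrument scatter.

All noise is independent zero-mean normal with the configured SDs, drawn
from a single seeded generator, so a dataset is fully reproducible from its
:class:`SimConfig`.  ``study_design`` instantiates a 12-gene x 150-sample
candidate-reference-gene study across nine experimental sets (varieties,
developmental stages, organs, three hormone stimuli, bagging, storage
temperature, girdling with defoliation), the classic design for validating
reference genes in fruit tissues.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import DataError
from .io import CqDataset

#: Candidate panel of twelve housekeeping assays typical for fruit-tree
#: RT-qPCR validation, with measured amplification efficiencies
#: (fold/cycle), amplicon lengths (bp) and melting temperatures (degC).
STUDY_ASSAYS = pd.DataFrame(
    {
        "gene_id": [
            "CYP", "RPL", "GAPDH", "TUA", "TUB", "Fe-SOD",
            "Mn-SOD", "Cu/Zn-SOD", "18SrRNA", "Actin", "HistoneH3", "EF-1a",
        ],
        "efficiency": [
            2.072, 1.914, 1.962, 1.986, 1.977, 1.917,
            1.949, 1.992, 1.931, 1.984, 2.002, 2.072,
        ],
        "amplicon_length": [213, 246, 204, 175, 86, 114, 184, 207, 171, 93, 155, 129],
        "tm": [
            83.37, 80.87, 81.79, 81.09, 83.43, 80.80,
            81.44, 82.46, 83.93, 81.77, 85.71, 84.57,
        ],
    }
).set_index("gene_id")

#: Mean abundance per assay on the Cq scale (18SrRNA most abundant,
#: Fe-SOD least), spanning the range seen in fruit-tissue panels.
STUDY_BASELINES = {
    "CYP": 24.0, "RPL": 23.0, "GAPDH": 21.0, "TUA": 25.0, "TUB": 26.0,
    "Fe-SOD": 29.0, "Mn-SOD": 27.0, "Cu/Zn-SOD": 28.0, "18SrRNA": 17.4,
    "Actin": 22.0, "HistoneH3": 24.5, "EF-1a": 20.0,
}

#: Ground-truth instability (cycles) per assay: GAPDH/Fe-SOD/EF-1a stable,
#: the tubulins condition-responsive, the rest graded in between.
STUDY_GENE_NOISE = {
    "GAPDH": 0.12, "EF-1a": 0.15, "Fe-SOD": 0.15, "Mn-SOD": 0.18,
    "18SrRNA": 0.25, "Actin": 0.30, "HistoneH3": 0.30, "CYP": 0.35,
    "Cu/Zn-SOD": 0.40, "RPL": 0.45, "TUB": 0.70, "TUA": 0.75,
}


@dataclass
class SimConfig:
    """Configuration for one synthetic Cq dataset.

    ``gene_noise_sd`` may be a scalar (shared) or one SD per gene;
    ``group_shift`` maps (gene_id, group label) -> Cq cycles added to that
    gene in that group.  Zero-padded default identifiers keep lexicographic
    ordering equal to generation order.
    """

    n_genes: int = 12
    n_samples: int = 36
    n_tech_replicates: int = 3
    baseline_cq: Optional[Sequence[float]] = None
    sample_effect_sd: float = 0.8
    gene_noise_sd: Union[float, Sequence[float]] = 0.2
    group_labels: Optional[Sequence[str]] = None
    group_shift: Optional[Mapping[tuple[str, str], float]] = None
    replicate_sd: float = 0.15
    seed: int = 0
    gene_ids: Optional[Sequence[str]] = None
    sample_ids: Optional[Sequence[str]] = None

    def resolved_gene_ids(self) -> list[str]:
        if self.gene_ids is not None:
            return list(self.gene_ids)
        width = max(2, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def resolved_sample_ids(self) -> list[str]:
        if self.sample_ids is not None:
            return list(self.sample_ids)
        width = max(3, len(str(self.n_samples)))
        return [f"S{i + 1:0{width}d}" for i in range(self.n_samples)]

    def resolved_baselines(self) -> np.ndarray:
        if self.baseline_cq is not None:
            base = np.asarray(self.baseline_cq, dtype=float)
        else:
            # spread baselines across the typical qPCR working range
            base = np.linspace(18.0, 30.0, self.n_genes)
        if base.shape != (self.n_genes,):
            raise DataError(
                f"baseline_cq must have length n_genes={self.n_genes}"
            )
        return base

    def resolved_gene_noise(self) -> np.ndarray:
        if np.isscalar(self.gene_noise_sd):
            sds = np.full(self.n_genes, float(self.gene_noise_sd))
        else:
            sds = np.asarray(self.gene_noise_sd, dtype=float)
        if sds.shape != (self.n_genes,):
            raise DataError(
                f"gene_noise_sd must be scalar or length n_genes={self.n_genes}"
            )
        if (sds < 0).any():
            raise DataError("noise SDs must be >= 0")
        return sds

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1 or self.n_tech_replicates < 1:
            raise DataError("n_genes, n_samples, n_tech_replicates must be >= 1")
        if self.sample_effect_sd < 0 or self.replicate_sd < 0:
            raise DataError("noise SDs must be >= 0")
        self.resolved_baselines()
        self.resolved_gene_noise()
        if self.group_labels is not None and len(self.group_labels) != self.n_samples:
            raise DataError("group_labels must have length n_samples")
        if self.group_shift and self.group_labels is None:
            raise DataError("group_shift requires group_labels")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset: enough to recompute it from seed."""

    config: SimConfig
    sample_effects: pd.Series
    true_order: list[str]
    target: Optional[dict] = None

    def to_dict(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        for key in ("baseline_cq", "gene_noise_sd", "group_labels",
                    "gene_ids", "sample_ids"):
            v = cfg[key]
            if v is not None and not np.isscalar(v):
                cfg[key] = list(np.asarray(v).tolist())
        if cfg["group_shift"] is not None:
            cfg["group_shift"] = {
                f"{g}|{grp}": float(s) for (g, grp), s in cfg["group_shift"].items()
            }
        return {
            "config": cfg,
            "sample_effects": {
                s: float(v) for s, v in self.sample_effects.items()
            },
            "true_order": list(self.true_order),
            "target": self.target,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _simulate_arrays(cfg: SimConfig, rng: np.random.Generator):
    genes = cfg.resolved_gene_ids()
    samples = cfg.resolved_sample_ids()
    base = cfg.resolved_baselines()
    gene_sds = cfg.resolved_gene_noise()
    g, n, r = cfg.n_genes, cfg.n_samples, cfg.n_tech_replicates

    sample_effect = rng.normal(0.0, cfg.sample_effect_sd, size=n)
    shift = np.zeros((g, n))
    if cfg.group_shift:
        labels = list(cfg.group_labels)  # validated non-None
        gene_index = {gid: i for i, gid in enumerate(genes)}
        for (gid, grp), delta in cfg.group_shift.items():
            if gid not in gene_index:
                raise DataError(f"group_shift names unknown gene {gid!r}")
            mask = np.array([lab == grp for lab in labels])
            shift[gene_index[gid], mask] += float(delta)
    gene_noise = rng.normal(0.0, 1.0, size=(g, n)) * gene_sds[:, None]
    tech_noise = rng.normal(0.0, cfg.replicate_sd, size=(g, n, r))
    cq = (
        base[:, None, None]
        + sample_effect[None, :, None]
        + shift[:, :, None]
        + gene_noise[:, :, None]
        + tech_noise
    )
    return genes, samples, sample_effect, cq


def _records_from_cq(genes, samples, cq: np.ndarray) -> pd.DataFrame:
    g, n, r = cq.shape
    gene_col = np.repeat(genes, n * r)
    sample_col = np.tile(np.repeat(samples, r), g)
    rep_col = np.tile(np.arange(1, r + 1), g * n)
    return pd.DataFrame(
        {
            "sample_id": sample_col,
            "gene_id": gene_col,
            "replicate": rep_col,
            "cq": cq.ravel(),
        }
    )


def _true_order(cfg: SimConfig) -> list[str]:
    genes = cfg.resolved_gene_ids()
    sds = cfg.resolved_gene_noise()
    return [g for _, _, g in sorted(zip(sds, range(len(genes)), genes))]


def simulate_cq(
    cfg: SimConfig, meta: Optional[pd.DataFrame] = None
) -> tuple[CqDataset, SyntheticTruth]:
    """Draw one replicate-level Cq dataset; deterministic given the seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, samples, sample_effect, cq = _simulate_arrays(cfg, rng)
    records = _records_from_cq(genes, samples, cq)
    if meta is None:
        meta = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
        if cfg.group_labels is not None:
            meta["group"] = list(cfg.group_labels)
    ds = CqDataset(records=records, meta=meta)
    truth = SyntheticTruth(
        config=cfg,
        sample_effects=pd.Series(sample_effect, index=samples, name="sample_effect"),
        true_order=_true_order(cfg),
    )
    return ds, truth


def spike_target(
    cfg: SimConfig,
    fold_profile: Mapping[str, float],
    target_gene: str = "DlACO",
    target_baseline: float = 24.0,
    target_efficiency: float = 2.0,
    target_noise_sd: float = 0.05,
) -> tuple[CqDataset, SyntheticTruth]:
    """Simulate the reference panel plus a target gene with known fold changes.

    ``fold_profile`` maps each condition (the config's group labels) to the
    target's true expression fold relative to baseline; a fold F at
    efficiency E shifts the target's Cq by ``-log(F)/log(E)`` cycles there.
    The target shares the per-sample loading effects with the panel.
    """
    cfg.validate()
    if cfg.group_labels is None:
        raise DataError("spike_target requires group_labels (conditions)")
    folds = {k: float(v) for k, v in fold_profile.items()}
    if any(f <= 0 for f in folds.values()):
        raise DataError("fold_profile entries must be positive")
    missing = sorted(set(cfg.group_labels) - set(folds))
    if missing:
        raise DataError(f"fold_profile missing condition {missing[0]!r}")

    rng = np.random.default_rng(cfg.seed)
    genes, samples, sample_effect, cq = _simulate_arrays(cfg, rng)

    shift = np.array(
        [-np.log(folds[lab]) / np.log(target_efficiency) for lab in cfg.group_labels]
    )
    n, r = cfg.n_samples, cfg.n_tech_replicates
    t_noise = rng.normal(0.0, target_noise_sd, size=n)
    t_tech = rng.normal(0.0, cfg.replicate_sd, size=(n, r))
    t_cq = (
        target_baseline + sample_effect[:, None] + shift[:, None]
        + t_noise[:, None] + t_tech
    )

    records = pd.concat(
        [
            _records_from_cq(genes, samples, cq),
            _records_from_cq([target_gene], samples, t_cq[None, :, :]),
        ],
        ignore_index=True,
    )
    meta = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    meta["group"] = list(cfg.group_labels)
    ds = CqDataset(records=records, meta=meta)
    truth = SyntheticTruth(
        config=cfg,
        sample_effects=pd.Series(sample_effect, index=samples, name="sample_effect"),
        true_order=_true_order(cfg),
        target={
            "gene": target_gene,
            "fold_profile": folds,
            "baseline_cq": float(target_baseline),
            "efficiency": float(target_efficiency),
            "noise_sd": float(target_noise_sd),
        },
    )
    return ds, truth


def _study_meta() -> pd.DataFrame:
    """Sample book-keeping of the emulated study: 150 samples, nine sets."""
    cultivars = ["Shixia", "Chuliang", "Linglong", "Gushan", "Caopushi", "Benzhan"]
    stages = ["62DAA", "76DAA", "83DAA", "89DAA", "103DAA", "110DAA"]
    organs = ["root", "shoot", "leaf", "flower", "fruitlets", "seed"]
    rows = []

    def add(set_name, tissue, cultivar, treatment, timepoint, rep, tag):
        rows.append(
            {
                "sample_id": tag,
                "experimental_set": set_name,
                "tissue": tissue,
                "cultivar": cultivar,
                "treatment": treatment,
                "timepoint": timepoint,
                "biological_replicate": rep,
                "group": "",
            }
        )

    for tissue in ("pericarp", "aril"):
        for ci, cv in enumerate(cultivars, 1):
            for rep in (1, 2, 3):
                add("different_varieties", tissue, cv, "none", "110DAA", rep,
                    f"VAR-{tissue[:4]}-c{ci}-r{rep}")
    for tissue in ("pericarp", "aril"):
        for si, st in enumerate(stages, 1):
            for rep in (1, 2, 3):
                add("developmental_stages", tissue, "Shixia", "none", st, rep,
                    f"DEV-{tissue[:4]}-t{si}-r{rep}")
    for oi, organ in enumerate(organs, 1):
        tp = "40DAA" if organ == "fruitlets" else "110DAA"
        for rep in (1, 2, 3):
            add("different_organs", organ, "Shixia", "none", tp, rep,
                f"ORG-o{oi}-r{rep}")
    for set_name, code in (
        ("NAA", "NAA"), ("2,4-D", "D24"), ("ethephon", "ETH"), ("bagging", "BAG"),
    ):
        for ti, tp in enumerate(("0DAT", "2DAT", "3DAT"), 1):
            for rep in (1, 2, 3):
                add(set_name, "pericarp", "Shixia", set_name, tp, rep,
                    f"{code}-t{ti}-r{rep}")
    for temp in ("4°C", "22°C"):
        code = "T04" if temp == "4°C" else "T22"
        for ti, tp in enumerate(("2DAT", "3DAT"), 1):
            for rep in (1, 2, 3):
                add("temperature", "aril", "Shixia", temp, tp, rep,
                    f"{code}-t{ti}-r{rep}")
    for tissue, code in (("fruitlets", "frui"), ("abscission_zone", "absz")):
        for ti, tp in enumerate(("4DAT", "5DAT"), 1):
            for rep in (1, 2, 3):
                add("girdling_defoliation", tissue, "Shixia",
                    "girdling+defoliation", tp, rep, f"GIR-{code}-t{ti}-r{rep}")
    meta = pd.DataFrame(rows).set_index("sample_id")
    assert len(meta) == 150
    return meta


#: The thirteen per-set analysis panels (tissue splits included), keyed by
#: metadata selectors understood by :func:`refstab.io.subset_by_experiment`.
STUDY_PANELS: list[tuple[str, dict]] = [
    ("varieties_pericarp", {"experimental_set": "different_varieties", "tissue": "pericarp"}),
    ("varieties_aril", {"experimental_set": "different_varieties", "tissue": "aril"}),
    ("stages_pericarp", {"experimental_set": "developmental_stages", "tissue": "pericarp"}),
    ("stages_aril", {"experimental_set": "developmental_stages", "tissue": "aril"}),
    ("different_organs", {"experimental_set": "different_organs"}),
    ("NAA", {"experimental_set": "NAA"}),
    ("2,4-D", {"experimental_set": "2,4-D"}),
    ("ethephon", {"experimental_set": "ethephon"}),
    ("bagging", {"experimental_set": "bagging"}),
    ("cold_4C", {"experimental_set": "temperature", "treatment": "4°C"}),
    ("room_22C", {"experimental_set": "temperature", "treatment": "22°C"}),
    ("girdling_abscission_zone", {"experimental_set": "girdling_defoliation", "tissue": "abscission_zone"}),
    ("girdling_fruitlets", {"experimental_set": "girdling_defoliation", "tissue": "fruitlets"}),
]


def study_design(
    seed: int = 0,
    sample_effect_sd: float = 0.8,
    replicate_sd: float = 0.15,
    gene_noise_sd: Optional[Mapping[str, float]] = None,
    group_shift: Optional[Mapping[tuple[str, str], float]] = None,
) -> tuple[CqDataset, SyntheticTruth]:
    """Simulate the full 12-gene x 150-sample candidate-gene study.

    Sample book-keeping follows the emulated design exactly: nine
    experimental sets of 36+36+18+9+9+9+9+12+12 samples, three technical
    replicates each, with tissue/cultivar/treatment/timepoint metadata.
    Assay metadata (measured efficiencies) is attached for per-gene
    efficiency correction.
    """
    meta = _study_meta()
    genes = list(STUDY_ASSAYS.index)
    noise = dict(STUDY_GENE_NOISE)
    if gene_noise_sd:
        noise.update(gene_noise_sd)
    group_labels = list(meta["experimental_set"]) if group_shift else None
    cfg = SimConfig(
        n_genes=len(genes),
        n_samples=len(meta),
        n_tech_replicates=3,
        baseline_cq=[STUDY_BASELINES[g] for g in genes],
        sample_effect_sd=sample_effect_sd,
        gene_noise_sd=[noise[g] for g in genes],
        group_labels=group_labels,
        group_shift=dict(group_shift) if group_shift else None,
        replicate_sd=replicate_sd,
        seed=seed,
        gene_ids=genes,
        sample_ids=list(meta.index),
    )
    ds, truth = simulate_cq(cfg, meta=meta)
    ds.assays = STUDY_ASSAYS.copy()
    return ds, truth
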