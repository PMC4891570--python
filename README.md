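# refstab

Reference-gene stability analysis for RT-qPCR experiments.

Quantitative PCR measures a target transcript relative to one or more
*reference* ("housekeeping") genes, and the whole measurement is only as
good as the assumption that those references are stably expressed across
the samples being compared. `refstab` implements the standard workflow for
validating a panel of candidate reference genes — the kind of study run
before any expression profiling in a new tissue, treatment, or species —
from raw quantification-cycle (Cq) values to a final recommendation, plus
a synthetic Cq generator with known ground truth so that every stage of
the pipeline can be tested without instrument data.

## What it computes

Starting from replicate-level Cq values, each gene's measurements are
collapsed (mean of technical replicates) and rescaled to relative
quantities

```
Q = E^(minCq − Cq)
```

where `E` is the amplification efficiency (2 = perfect doubling; per-gene
efficiencies can come from dilution-series standard curves via
`E = 10^(−1/slope)`). Two complementary stability algorithms then rank the
candidates:

* **geNorm** — a gene's stability value `M` is the mean, over all other
  candidates, of the standard deviation across samples of the pairwise
  log2 ratio. Stepwise exclusion of the highest-M gene yields a ranking
  whose final pair is jointly best. The pairwise-variation curve
  `V(n/n+1) = SD[log2(NF_n / NF_{n+1})]`, where `NF_n` is the geometric
  mean of the top-n genes' quantities, decides how many references are
  needed: the smallest `n` with `V < 0.15` (cutoff configurable), or a
  "none adequate" sentinel when no combination qualifies.
* **NormFinder** — fits the additive model `y_ij = α_i + β_j + ε_ij` to
  log quantities and estimates each gene's residual variance with an
  unbiased variance-decomposition estimator; stability
  `ρ = sqrt(σ̂²)` (lower = more stable). A grouped mode additionally
  estimates shrunken between-group biases, flagging genes that respond to
  the experimental condition itself.
* **Consensus** — overlap of the two top-k sets, agreement on the
  least-stable pair, and whether NormFinder's best gene sits in geNorm's
  top k.
* **Relative quantification** — efficiency-corrected, Pfaffl-style
  target-gene expression against any chosen reference set and calibrator
  (reducing to classic 2^−ΔΔCq for a single reference at E = 2), including
  side-by-side comparison of normalizer choices to expose the distortion
  an unstable reference introduces.

## Worked example

The built-in study design simulates a 12-gene candidate panel over 150
samples in nine experimental sets (varieties, developmental stages,
organs, three hormone stimuli, bagging, storage temperature, girdling)
with graded, known per-gene instability:

```python
from refstab import simulate, io, transform, genorm, normfinder

ds, truth = simulate.study_design(seed=1)
matrix = io.aggregate_replicates(ds, qc=io.validate_dataset(ds))
sub = io.subset_by_experiment(
    matrix, {"experimental_set": "different_varieties", "tissue": "pericarp"})
qm = transform.relative_quantities(sub)          # Q = 2^(minCq − Cq)

report = genorm.stepwise_exclusion(qm)
print("geNorm best pair:", report.tied_best,
      "M =", round(report.per_gene_value[report.ranking[0]], 3))
print("least stable:", report.ranking[-2:])
v = genorm.pairwise_variation_curve(qm, report.ranking)
print("V2/3 =", round(v.pairs[0][1], 3), "-> optimal n =", v.optimal_n)

nf = normfinder.stability_single_group(transform.log_quantities(qm))
best = normfinder.rank_by_stability(nf)[0]
print("NormFinder best:", best, "rho =", round(nf.stability[best], 3))
```

prints

```
geNorm best pair: ('EF-1a', 'GAPDH') M = 0.227
least stable: ['TUB', 'TUA']
V2/3 = 0.08 -> optimal n = 2
NormFinder best: GAPDH rho = 0.177
```

i.e. both algorithms recover the genes simulated as most stable
(GAPDH/EF-1a), agree that the tubulins are the least stable, and the
V-curve says two reference genes suffice for this sample set (V2/3 = 0.08
< 0.15). The shared M of 0.227 is the best pair's average pairwise-ratio
SD in log2 cycles; ρ = 0.177 is NormFinder's estimate of GAPDH's own
expression SD on the same scale.

The same pipeline is scriptable from a shell:

```sh
refstab simulate --out data --seed 1 --study-design
refstab rank --cq data/cq.csv --meta data/meta.csv --study-sets --out ranks
refstab relquant --cq data/cq.csv --meta data/meta.csv \
    --target GAPDH --refs "EF-1a,Fe-SOD" --calibrator 110DAA \
    --condition-col timepoint --out rq
```

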