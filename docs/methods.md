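# Methods

## Data model and preprocessing

The unit of input is a replicate-level Cq record `(sample, gene, technical
replicate, Cq)`; Cp and Cq are treated as synonyms. Long and wide readers
are content-equivalent by construction, which the test suite checks by
round-tripping random datasets through both writers and readers. Missing
Cq values (NA tokens or blank cells) are carried as NaN and never imputed:
both stability algorithms require complete gene × sample matrices, and
imputing a quantification cycle would invent exactly the signal the
analysis is trying to measure. After technical replicates are collapsed,
any sample still missing a gene is dropped and recorded in the QC report;
a gene absent from more than a configurable fraction of samples (default
20 %) is a hard error with advice to remove the gene, since silently
dropping most samples would be worse.

Technical replicates are collapsed by the arithmetic mean of Cq (the
de-facto qPCR convention; median is offered for robustness against a
single aberrant well). The replicate-SD QC flag defaults to 0.5 cycles, a
common laboratory heuristic — flags are advisory only. Gene and sample
orders are lexicographic unless an explicit order is supplied, so every
downstream output is deterministic.

## Relative quantities

Stability analysis operates on `Q = E^(minCq − Cq)` per gene, so the
sample with the most template has Q = 1 and every additional cycle divides
Q by the efficiency E. The default is the fixed base E = 2 for all genes,
matching the conventional input to both algorithms; per-gene measured
efficiencies (from standard curves, `E = 10^(−1/slope)` with OLS of Cq on
log10 dilution) are available as a sensitivity analysis and for
efficiency-corrected target quantification. `minCq` is taken within the
analysed subset, not globally; this is the geNorm convention, and it is
inconsequential for stability because per-gene rescaling of Q cancels in
every statistic (asserted as a property test: shifting one gene's Cq by a
constant leaves its Q vector unchanged).

## geNorm

`M_j` is the mean over partners k of the sample SD (n−1 denominator,
matching the original implementation's variance convention) of
`log2(Q_j/Q_k)`. Stepwise exclusion recomputes M on the remaining set,
removes the argmax, and stops at two genes, which share the final pair's
M — a pair has a single ratio, so their M values are equal by identity.
Ties at the argmax are broken toward the gene latest in the deterministic
gene ordering; the final pair's display order also follows the gene
ordering. The exclusion trace stores, per round, the full M vector of the
remaining set, the excluded gene, and the average M after exclusion, so
either flavour of "average expression stability" curve can be regenerated.

The V curve uses the exclusion ranking to define nested sets:
`V_n = SD[log2(NF_n/NF_{n+1})]` with `NF_n` the geometric mean of the
top-n genes' quantities. The optimal count is the smallest n with
`V_n < 0.15`; the cutoff is a config default, explicitly overridable,
because it is a community convention rather than a statistical threshold.
When no n qualifies the result is a `None` sentinel plus an advisory
recommending at least the three most stable genes — reporting a number
here would overstate what the data support.

## NormFinder

Log2 quantities are modelled as `y_ij = α_i + β_j + ε_ij` with
`Var(ε_ij) = σ²_i`. With `r_ij` the double-centered residuals and
`z_i = Σ_j r²_ij/(n−1)`, the estimator

```
σ̂²_i = max(0, (g/(g−2)) · (z_i − Σ_k z_k / (g(g−1))))
```

is unbiased for σ²_i before clipping (the correction removes the leakage
of all genes' noise into the shared sample means); clipping events are
recorded on the result. Stability is `ρ_i = σ̂_i`. The estimator needs
g ≥ 3 — for g ≤ 2 the gene-specific variance is not identifiable — and
this is enforced with a clear error. Monte-Carlo tests validate the
estimator rather than any copied constants: the replicate-averaged
variance recovers true σ within 10 % per gene, and the regression of
estimated on true σ over a grid has slope within [0.9, 1.1]. For genes
whose σ is far below their co-candidates', the per-replicate ρ is
noticeably noisy (the shared term dominates); this is inherent to the
decomposition, which is why the validation targets the variance scale and
the regression slope.

Grouped mode estimates per-group variances the same way (groups of two
samples fall back to the plain residual mean square), takes the raw
gene-by-group interaction `d_gi` as the group mean of the full-matrix
residuals, and shrinks it by the empirical-Bayes factor
`var_d/(var_d + σ̂²_gi/n_g)`, where `var_d = max(0, Σ_i d²_gi/(g−1) −
mean_i(σ̂²_gi)/n_g)` is the spread of the observed d with its sampling
contribution removed; a non-positive `var_d` means the observed
differences are indistinguishable from noise and all d̃ are set to 0.
Stability is the group-mean of `|d̃_gi| + sqrt(σ̂²_gi/n_g)`. Single-group
mode is the default: a candidate study reports one stability value per
gene per sample set, and group labels are often unavailable. A direct
−Cq input path (`stability_from_cq`) is exposed and tested to give
identical values — it differs from log quantities only by per-gene
constants, to which the estimator is invariant.

## Consensus and batch driver

`compare_rankings` defaults k to half the panel. The least-stable
comparison takes the bottom two of each ranking; when stability values
are supplied and the boundary value is tied, all tied genes are included
and the report is flagged, so a "TUB/RPL"-style near-tie is visible
rather than resolved arbitrarily. `run_all_sets` collects per-set
failures into the bundle instead of aborting — in a 13-panel batch one
degenerate subset should not cost the other twelve results.

## Relative quantification

The target ratio is `E_t^(minCq−Cq) / NF`, rescaled so the calibrator
sample (or condition mean) equals 1; aggregation over biological
replicates reports mean ± SD per condition. With all efficiencies at 2
and a single reference this is algebraically 2^−ΔΔCq, asserted as a
property test. The distortion demonstration normalizes a spiked target
once by stable references (recovering the true fold within 10 % on
average) and once by a reference whose quantity drifts downward over the
time course, which inflates the apparent fold by the drift — the
qualitative failure mode that motivates stability validation in the
first place.

## Synthetic data

`Cq[g,s,r] = baseline_g + sample_effect_s + group_shift_{g,group(s)} +
gene_noise_{g,s} + tech_noise_{g,s,r}`, all terms independent zero-mean
normal on the Cq scale (log-scale fluorescence-cycle space, where
technical variation is approximately homoscedastic). One integer seed
drives a single generator stream, so datasets are reproducible bytewise.
The per-gene `gene_noise_sd` ordering *is* the ground-truth stability
ranking that the algorithms must recover; `sample_effect` emulates
loading/RT variation and cancels in both algorithms (asserted by
simulation: doubling it leaves rankings unchanged); `group_shift` models
condition-responsive genes for grouped-NormFinder tests and the
drifting-normalizer demonstration.

`study_design` instantiates a 12-assay, 150-sample validation study:
nine experimental sets of 36 + 36 + 18 + 9 + 9 + 9 + 9 + 12 + 12 samples
(varieties, developmental stages, organs, NAA, 2,4-D, ethephon, bagging,
temperature, girdling with defoliation), three technical replicates, and
thirteen analysis panels after the tissue splits. Defaults were chosen
once as field-realistic conditions: baselines spread 17.4–29.0 Cq
(rRNA most abundant, Fe-SOD least), sample-effect SD 0.8 cycles,
technical-replicate SD 0.15 cycles, and graded per-gene instability
0.12–0.75 cycles with GAPDH/EF-1a/Fe-SOD most stable and the tubulins
least — mirroring the common outcome that tubulins respond to treatment.
The attached assay table carries measured efficiencies (1.914–2.072),
amplicon lengths and Tm values for the twelve assays.

What the generator does **not** emulate: plate/position effects,
inter-run calibration drift, amplification-curve shape, non-normal
outliers (failed wells), correlated instability between co-regulated
genes, and tissue-specific baseline shifts beyond the shared sample
effect. Passing tests therefore demonstrate correctness of the
statistics and recovery under an additive-normal noise model, not
robustness to every instrument artefact real data can contain.

## Problem sizes and numerical choices

The simulation-based checks use 100–500 replicates at the panel sizes
above (12 × 36 for ranking recovery, 6 × 500 for estimator recovery,
2 × 20 per group for spike detection), sizes at which the Monte-Carlo
standard errors are comfortably below the asserted margins. Oracle
agreement is asserted at 1e−12 (double-precision identity up to summation
order); zero-noise limits at 1e−10. Degenerate inputs — fewer than two
samples after subsetting, fewer than three genes for exclusion or
NormFinder, non-positive quantities, non-negative standard-curve slopes,
empty reference sets, self-normalization — all raise typed errors with
actionable messages rather than propagating NaN.

## Known limitations

geNorm's M is biased toward co-regulated gene pairs (a correlated pair
can look artificially stable); NormFinder's variance decomposition
assumes at least a moderate panel (g ≥ 3, ideally ≥ 5) and additive
effects on the log scale. Neither limitation is corrected here — they are
properties of the published algorithms this package implements — but the
consensus report is the practical mitigation: disagreement between the
two rankings is itself diagnostic. Confidence intervals on M and ρ are
out of scope, as is RefFinder-style meta-ranking across more than two
algorithms.
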