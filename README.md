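# devochron

Timing and conservation of developmental gene expression.

`devochron` analyses high-density qPCR time courses of regulatory genes in
early embryos. It answers two questions a developmental biologist asks of
such data:

1. **How tightly is the timing of gene activation controlled within a
   species?** Absolute mRNA time courses from several biological repeats
   (offspring of different parent pairs) are compared in two modes of
   variation — maximal mRNA level and gene initiation time — and the two
   modes are tested for coupling.
2. **How conserved are expression dynamics between related species that
   develop at different rates?** A constant developmental rate ratio is
   estimated from matched initiation times, one species' time axis is
   rescaled by it, profiles are normalized to percent-of-maximum, and the
   conservation of relative dynamics is scored against a random-gene-pair
   null.

## The model

Absolute quantification anchors Ct values to a known spike-in quantity:

```
copies = spike_copies × E^(Ct_spike − Ct_gene),   E = 1.9 (pooled efficiency)
```

Zygotic activation of each gene is modelled on the log10 scale as a
four-parameter sigmoid

```
log10(mRNA(t)) = a − b / (1 + exp(c (t − t0)))
```

where `a` is log10 of the maximal level, `a − b` the basal (maternal)
level, `c` the rise rate (h⁻¹) and `t0` the time of half-rise in hours
post fertilization — the operational **gene initiation time**. The model
is fit by multi-start nonlinear least squares; `t0` gets a 95% confidence
interval from the NLS covariance (t-distribution, n − 4 df).

Between species, matched initiation times are related by a zero-intercept
regression `t0_B = ρ · t0_A`; the slope ρ is the developmental rate
ratio. Profiles aligned with ρ and normalized to their in-window maximum
are compared by Pearson correlation, per orthologue pair and against the
exhaustive non-orthologous pair baseline.

A synthetic two-species generator (`devochron.simulate`) produces
datasets with known ground truth — sigmoid parameters, rate ratio,
lognormal repeat jitter on timing (CV 8%) and level (CV 29%), maternal
genes, multiplicative measurement noise — so every stage of the pipeline
is verifiable without external data.

## Worked example

```python
import devochron as dc
from devochron.io import frame_to_profiles

cfg = dc.SimConfig(seed=11)                 # 25 genes, 3 repeats, ratio 1.3
df_a, df_b, truth = dc.generate_dataset(cfg)
summary = dc.run_pipeline(dc.PipelineConfig(
    profiles_a=frame_to_profiles(df_a),
    profiles_b=frame_to_profiles(df_b),
    seed=11,
))
```

which prints (selected keys):

```
n_genes: 25
n_zygotic: 20
mean_cv_t0_percent: 7.57
mean_cv_max_percent: 29.87
mean_pairwise_fold: 1.518
variation_coupling: -0.01956
rate_ratio: 1.284
rate_ratio_r2: 0.9595
matched_mean_correlation: 0.8465
random_pair_baseline: 0.6287
min_fit_r2: 0.9334
```

Reading the output: initiation times vary by ~7.6% between repeats while
maximal levels vary by ~30% (a mean 1.5-fold difference between
individuals), and the two variation modes are uncoupled — timing is
controlled much more tightly than level. The rate ratio 1.28 recovers the
generating ρ = 1.3 within sampling error, and matched orthologues
correlate far better (0.85) than random cross-species gene pairs (0.63)
after scaling and normalization.

The same stages are available from the shell:

```
devochron simulate --seed 11 --out sim/
devochron run --species-a sim/species_A.csv --species-b sim/species_B.csv \
              --seed 11 --out results/
devochron quantify --ct ct.csv --spike-copies 2.6e8 --out profiles.csv
```

Input formats: tidy long CSV/TSV (`gene_id,time,level[,repeat_id]`), wide
gene × time tables, or an XLSX workbook with one wide sheet per
biological repeat; Ct tables are tidy CSV with spike-in rows marked
`gene_id=SPIKE`. See `docs/methods.md` for the model, parameter defaults
and limitations.

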