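# exoquality

Consistency scoring for extracellular-vesicle (EV) isolation methods from
replicated multi-assay characterization data.

## The problem

EVs are membrane-bound nanoparticles carried in biofluids and a mainstay of
liquid-biopsy research, but no single assay defines the purity or quality of
an EV isolate. Laboratories characterize the same isolate with several
MISEV-style measurements — mean particle size (nm), particle concentration
(particles/mL), total protein, total RNA, and a particle dispersity index
(PDI) — on different scales and units, which makes isolation methods hard to
compare. `exoquality` implements a rank-based index that turns the
*replicate-to-replicate reproducibility* of a method, across all assays at
once, into a single interpretable percentage, together with a synthetic
study simulator for validating the metric without laboratory data.

## The metric

For each assay, all measurements (every method, sample and replicate pooled)
are quantile-transformed through the assay's empirical CDF onto a common
equal-likelihood scale, using mid-rank plotting positions
u = (r − ½)/N with averaged ranks for ties, so every transformed value lies
strictly in (0, 1) and a difference of 0.1 means "one tenth of the pooled
distribution" for every assay alike.

For method *m* and sample *s*, with n assays and transformed replicate
values x<sub>i,r</sub> for assay i, the **EV Inconsistency value** is

> EVI(m, s) = (1/n) Σ<sub>i=1..n</sub> √ Var<sub>r</sub>[ x<sub>i,r</sub> ]

— the per-assay across-replicate standard deviation on the uniform scale,
averaged over assays (the literal sum over assays is available via
`aggregation="sum"`). An EVI of 0.2 reads as an expected 20% deviation of
the isolate on re-isolation. The per-method **ExoQuality Index** is

> EQI(m) = 1 − mean<sub>s</sub> EVI(m, s),

reported as a percentage: the expected likelihood of obtaining a consistent
EV population when the isolation is repeated. Because the transform depends
only on ranks, EVI and EQI are invariant under any strictly increasing
rescaling of an assay — the property that makes sizes in nm, yields in
particles/mL and dimensionless indices commensurable.

The PDI of an NTA size profile is max(NTA)/σ(NTA): the largest particle
size present divided by the standard deviation of the profile.

## Worked example

Simulate the default study — 11 plasma samples (6 tumor, 5 healthy) x 4
isolation methods x 5 assays x 4 replicates, with method replicate CVs of
0.08 / 0.12 / 0.15 / 0.25 — and score it:

```python
import exoquality as eq

dataset, _ = eq.simulate_study(eq.default_config(seed=1))
transformed = eq.transform_dataset(dataset)
result = eq.compute_eqi(eq.evi_matrix(transformed))
print(result.table.to_string(index=False))
```

```
             method  mean_evi      eqi  eqi_percent  n_samples
    capture_release  0.059252 0.940748        94.07         11
  membrane_affinity  0.087090 0.912910        91.29         11
        ps_affinity  0.135347 0.864653        86.47         11
ultracentrifugation  0.082550 0.917450        91.74         11
```

The tight capture-release method (CV 0.08) scores the highest expected
consistency (94.07%), the noisy phosphatidylserine-affinity method
(CV 0.25) the lowest (86.47%); the two intermediate methods land in
between, in CV order. A ranking-recovery experiment repeats the whole
pipeline on fresh studies and scores how often the EQI ordering inverts the
known noise ordering — with three well-separated methods (CVs
0.02 / 0.10 / 0.30) it recovers the ranking in 100/100 runs:

```python
methods = (
    eq.MethodSpec("low_noise",  bias=1.0, replicate_cv=0.02),
    eq.MethodSpec("mid_noise",  bias=0.8, replicate_cv=0.10),
    eq.MethodSpec("high_noise", bias=1.2, replicate_cv=0.30),
)
summary = eq.recovery_experiment(eq.default_config(seed=1, methods=methods), n_runs=100)
print(summary.recovery_fraction)        # 1.0
print(summary.per_method.to_string(index=False))
```

```
    method  replicate_cv  mean_eqi   sd_eqi  mean_evi
 low_noise          0.02  0.976690 0.001877  0.023310
 mid_noise          0.10  0.931368 0.005580  0.068632
high_noise          0.30  0.828394 0.013270  0.171606
```

The same pipeline is available from the shell:

```sh
exoquality simulate --seed 1 -o study/
exoquality compute study/measurements.csv -o report/ --sweep --figures
```

which writes `raw_summaries.csv`, `transformed.csv`, `evi_matrix.csv`,
`eqi.csv`, a settings + input-digest manifest, the EQI under every
convention combination (`--sweep`), and heatmap/pairplot/bar figures.
`exoquality nta` derives size / PDI / concentration measurements from NTA
profile CSVs, and `exoquality recover` runs the ranking experiment from a
YAML config.

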