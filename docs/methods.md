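# Methods

## The model

An EV isolation-method comparison is a fully crossed design: samples
*s* = 1..S (with a group label such as tumor / healthy), isolation methods
*m* = 1..M, characterization assays *i* = 1..n, and technical replicates
*r* = 1..R, one non-negative measurement per cell. The canonical assay
panel is mean particle size (nm), particle concentration (particles/mL),
total protein, total RNA and the particle dispersity index, but the
vocabulary is open: any assay label is accepted and the metric generalizes
to any panel.

The core assumption is that, after the rank-based rescaling described
below, the spread of a cell's replicate values reflects random error of the
*isolation method*, not the unit, scale or technical bias of the assay.
Under that reading, the across-replicate standard deviation on the uniform
scale is a dimensionless reproducibility measure that can be averaged over
assays and samples.

## Quantile transformation

Each assay's values — pooled over all methods, samples and replicates by
default — are mapped through their empirical CDF. The plotting position is
the mid-rank (r − ½)/N with averaged ranks for ties; consequences:

- every transformed value is strictly inside (0, 1), never saturating;
- ties in raw values map to identical transformed values;
- the map is monotone, so any strictly increasing rescaling of a raw assay
  (unit changes, log transforms, calibration curves) leaves the output
  bit-identical — the invariance that makes assays commensurable;
- the marginal of the transformed values is uniform by construction (KS
  statistic ~ 1/(2N)).

A Weibull position r/(N+1) and per-group / per-method pooling scopes are
exposed for sensitivity analysis. Out-of-reference queries (applying a
fitted map to held-out values) interpolate linearly between reference
positions and clamp to [½N⁻¹, 1 − ½N⁻¹], so no query maps to exactly 0
or 1. The mid-rank default was chosen because it is symmetric, avoids the
boundary exactly, and is the common convention of rank-based quantile
transforms.

## EVI and EQI

For cell (m, s), each assay with at least 2 replicates contributes the
standard deviation of its transformed replicate values; assays with fewer
replicates are dropped with a warning and the assay count n reduced —
imputing them would manufacture consistency. The per-assay standard
deviations aggregate to the EV Inconsistency value

EVI(m, s) = (1/n) Σᵢ sdᵣ(xᵢᵣ)   (default), or  Σᵢ sdᵣ(xᵢᵣ)  (`aggregation="sum"`).

The mean is the default on interpretability grounds: it keeps EVI inside
[0, √(R/(R−1))·½] — at R = 4 replicates at most √⅓ ≈ 0.577 — so that an EVI
of 0.2 genuinely reads as "20% expected deviation on re-isolation" and
1 − mean(EVI) lands on a percentage scale, whichever the number of assays.
A literal sum grows with the panel size and can exceed 1, breaking that
reading; it is kept behind a flag for comparison. The standard deviation
uses the sample (n−1) estimator by default — the small-sample convention at
4 replicates — with the population estimator behind `sd_mode="population"`.

The per-method index is EQI(m) = 1 − mean over samples of EVI(m, s),
averaged over samples only (the assays are already aggregated per cell),
reported as a fraction and as a percentage rounded to 2 decimals.

## PDI

For a size profile, PDI = max(NTA)/σ(NTA). `max(NTA)` is read as the
largest particle size present in the profile (largest bin center with
positive concentration for binned data), because a size divided by the
size standard deviation is dimensionless, matching an index; a mode-based
numerator is exposed via `max_def="mode_size"`. Per-particle profiles use
the unbiased (n−1) standard deviation; binned profiles use the
concentration-weighted population form, with bin concentrations treated as
per-bin counts (summed, not integrated) for the total concentration, the
convention of ZetaView-style exports. A monodisperse profile (σ = 0)
raises a degenerate-profile error rather than returning infinity; when
deriving measurement records from a batch of profiles, such a replicate
keeps its size record and only its PDI record is omitted, with a warning.

## Synthetic studies

The generator draws, per sample and assay, a lognormal true value
T(s, i) ~ LogNormal(μᵢ, σᵢ); each method multiplies it by a fixed bias
b(m, i) > 0 and each replicate by lognormal noise ε with E[ε] = 1 and a
method-specific coefficient of variation (σ_log = √log(1 + CV²)).
Lognormal truths and multiplicative noise were chosen because particle
counts and protein/RNA masses are positive and right-skewed. A method's
ground-truth quality in this model is exactly its replicate CV, which is
what the EVI estimates on the rank scale.

Defaults (scenario choices, fixed once):

| parameter | default | note |
|---|---|---|
| samples | 11 (6 tumor / 5 healthy) | typical pilot-cohort size |
| methods | 4 | CVs 0.08 / 0.12 / 0.15 / 0.25, biases 1.0 / 0.9 / 0.7 / 1.3 |
| assays | 5 | size ~120 nm (σ_log 0.15), concentration ~1e10/mL (0.8), protein ~150 (0.5), RNA ~20 (0.6), PDI ~4 (0.2) |
| replicates | 4 | minimum for a stable sd |
| NTA profiles | off | 500 particles/replicate, lognormal mixture 0.7·LN(log 95, 0.25) + 0.3·LN(log 170, 0.20) when on |

When NTA output is on, size, PDI and concentration records are derived
from the simulated profiles through the summary path (the profile is
scaled so its mean tracks the same truth x bias x noise draw); the finite
particle count makes max- and sd-based summaries vary naturally across
replicates. Repeated-run experiments spawn child seeds from the master
seed via `numpy.random.SeedSequence`, so runs are independent and the
whole experiment reproducible; no function uses hidden global randomness.

### What the generator does and does not emulate

It reproduces the design (crossed layout, replicate counts, positive
right-skewed marginals, method-specific location bias and replicate noise)
but not: assay detection limits or censoring, day/operator batch effects,
correlated errors between assays measured on the same aliquot, instrument
drift within an NTA run, or any mechanistic vesicle biophysics. Passing
the simulation-based tests therefore shows that the metric recovers known
noise orderings under a clean multiplicative error model — not that any
particular laboratory workflow satisfies that model.

### Measured behaviour worth knowing

- With three methods at CVs 0.02 / 0.10 / 0.30 (11 samples, 4 replicates),
  the EQI ranking inverts the noise ranking in ≥ 95 of 100 runs; adjacent
  CVs such as 0.12 vs 0.15 are at the resolution limit of an 11-sample
  study and swap rankings frequently.
- Because the transform pools all methods, a method-level location bias
  changes where that method's values sit in the pooled distribution and
  thus couples weakly into EVI (a 2x bias moves EQI by a few percentage
  points — well below the noise-driven separation between methods, and
  without disturbing the noise ranking). Per-method pooling removes the
  coupling but also removes cross-method comparability; the pooled default
  is retained and the coupling quantified in the test suite.

## Numerical and degenerate-input choices

- All-equal assay values transform to exactly 0.5; zero replicate noise
  yields EVI exactly 0 and EQI exactly 100% (no floating-point slack).
- Cells with < 2 replicates cannot contribute a variance and are dropped
  (logged); a cell with no usable assay raises an undefined-EVI error.
- Row order of input CSVs never affects results: datasets are
  canonicalized (sorted by sample, method, assay, replicate) on
  construction, and duplicate (sample, method, assay, replicate) keys are
  rejected.
- Measurement CSVs are written at full `repr` precision and parsed with
  correctly-rounded float conversion, so write → read is the identity.
- The report pipeline builds outputs in a temporary directory and moves
  them in place only on success; the manifest (settings + SHA-256 input
  digests, no timestamps) makes reruns byte-identical and reproducible
  from the manifest alone.

## Validation problem sizes

The test suite exercises: 100 random small designs (≤ 3 methods x ≤ 3
assays x ≤ 3 replicates) against a first-principles EVI loop at 1e−12;
50 random datasets for bit-exact monotone invariance; a 2,000-point
uniformity check; 100-run ranking recovery at the default study size; and
200-run symmetry checks for identical-CV methods. These sizes keep the
whole suite in the tens of seconds while leaving the Monte-Carlo claims
well-powered.

## Known limitations

- EQI measures *consistency*, not correctness: a method that reproducibly
  co-purifies the same contaminant scores high. Orthogonal purity evidence
  (e.g. albumin/lipoprotein assays) remains necessary.
- The index depends on the set of methods pooled into the transform;
  adding or removing a method changes every method's EVI slightly.
- No significance testing between methods' EQI values is provided; the
  Monte-Carlo recovery experiment is the supported way to judge whether a
  difference is resolvable at a given design size.
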