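"""Synthetic multi-method EV characterization studies with known noise.

The generator emulates a crossed isolation-method comparison: for each
sample s and assay a a true value T(s, a) is drawn lognormal (particle
counts, protein and RNA masses are positive and right-skewed); each
isolation method m distorts it by a fixed multiplicative bias b(m, a) and
each technical replicate adds multiplicative lognormal noise with a
method-specific coefficient of variation:

    value(s, m, a, r) = T(s, a) * b(m, a) * eps,   eps ~ LogNormal, CV = cv(m, a),

with E[eps] = 1.  Because the EVI is a replicate-variance metric on the
rank scale, a method's ground-truth quality in this model is exactly its
replicate CV: recovery experiments check that EQI ranks methods inversely
to their CVs while being insensitive to their biases.

Optionally, per-replicate NTA size profiles are drawn from a lognormal
mixture (small-EV and large-EV modes) and the size / PDI / concentration
records are derived through :mod:`exoquality.nta` rather than from the
direct model, so the NTA summary path is exercised end to end.

All randomness flows from one integer seed; repeated runs use
counter-based child seeds spawned from it.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import ConfigError, NTAProfile, StudyDataset
from .eqi import compute_eqi, evi_matrix
from .nta import CONC_ASSAY, PDI_ASSAY, SIZE_ASSAY, derive_measurements
from .transform import transform_dataset


@dataclass(frozen=True)
class MethodSpec:
    """One simulated isolation method.

    ``bias`` and ``replicate_cv`` may be scalars (shared across assays) or
    per-assay mappings; CV is the standard deviation of replicate noise
    relative to its mean.
    """

    label: str
    bias: float | Mapping[str, float] = 1.0
    replicate_cv: float | Mapping[str, float] = 0.1

    def bias_for(self, assay: str) -> float:
        if isinstance(self.bias, Mapping):
            return float(self.bias.get(assay, 1.0))
        return float(self.bias)

    def cv_for(self, assay: str) -> float:
        if isinstance(self.replicate_cv, Mapping):
            return float(self.replicate_cv.get(assay, 0.0))
        return float(self.replicate_cv)


@dataclass(frozen=True)
class AssaySpec:
    """Lognormal model for one assay's sample-level true values:
    ``T ~ LogNormal(log_mean, log_sd)`` on the natural-log scale."""

    label: str
    log_mean: float
    log_sd: float


@dataclass(frozen=True)
class LognormalComponent:
    """One mode of the NTA size mixture (sizes in nm, log scale)."""

    weight: float
    log_mean: float
    log_sd: float


@dataclass(frozen=True)
class NTAConfig:
    """Per-replicate size-profile generation.

    ``n_particles`` tracked particles are drawn from the mixture and scaled
    so the profile's expected mean size follows the same
    truth x bias x noise model as the direct size assay.  Finite particle
    counts make max- and sd-based summaries (hence PDI) vary naturally
    across replicates.
    """

    n_particles: int = 500
    components: tuple[LognormalComponent, ...] = (
        LognormalComponent(weight=0.7, log_mean=math.log(95.0), log_sd=0.25),
        LognormalComponent(weight=0.3, log_mean=math.log(170.0), log_sd=0.20),
    )

    @property
    def mixture_mean(self) -> float:
        return sum(
            c.weight * math.exp(c.log_mean + 0.5 * c.log_sd**2)
            for c in self.components
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic study."""

    methods: tuple[MethodSpec, ...]
    assays: tuple[AssaySpec, ...]
    n_samples: int = 11
    groups: Mapping[str, int] = field(
        default_factory=lambda: {"tumor": 6, "healthy": 5}
    )
    n_replicates: int = 4
    nta: NTAConfig | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2 (a variance is needed)")
        if not self.methods or not self.assays:
            raise ConfigError("methods and assays must be non-empty")
        labels = [m.label for m in self.methods]
        if len(set(labels)) != len(labels):
            raise ConfigError("method labels must be unique")
        if sum(self.groups.values()) != self.n_samples:
            raise ConfigError(
                f"group sizes {dict(self.groups)} must sum to n_samples="
                f"{self.n_samples}"
            )
        for m in self.methods:
            for a in self.assays:
                if m.cv_for(a.label) < 0:
                    raise ConfigError(f"negative replicate_cv for {m.label}/{a.label}")
                if m.bias_for(a.label) <= 0:
                    raise ConfigError(f"non-positive bias for {m.label}/{a.label}")
        for a in self.assays:
            if a.log_sd <= 0:
                raise ConfigError(f"assay {a.label}: log_sd must be > 0")
        if self.nta is not None:
            if self.nta.n_particles < 2:
                raise ConfigError("nta.n_particles must be >= 2")
            w = sum(c.weight for c in self.nta.components)
            if not math.isclose(w, 1.0, rel_tol=1e-9):
                raise ConfigError(f"NTA mixture weights sum to {w}, expected 1")
            if any(c.log_sd <= 0 or c.weight <= 0 for c in self.nta.components):
                raise ConfigError("NTA mixture components need positive weight/log_sd")
            present = {a.label for a in self.assays}
            if SIZE_ASSAY not in present:
                raise ConfigError(f"NTA output requires the {SIZE_ASSAY!r} assay")


def default_assays() -> tuple[AssaySpec, ...]:
    """The five-assay MISEV-style panel with realistic plasma-EV scales:
    ~120 nm mean size, ~1e10 particles/mL, ~150 ug protein, ~20 ng RNA,
    PDI around 4."""
    return (
        AssaySpec("size_mean_nm", math.log(120.0), 0.15),
        AssaySpec("particle_concentration_per_mL", math.log(1.0e10), 0.8),
        AssaySpec("protein_total", math.log(150.0), 0.5),
        AssaySpec("rna_total", math.log(20.0), 0.6),
        AssaySpec("pdi", math.log(4.0), 0.2),
    )


def default_methods() -> tuple[MethodSpec, ...]:
    """Four isolation methods spanning a realistic reproducibility range:
    capture-release beads (tight), ultracentrifugation, membrane-affinity
    column, phosphatidylserine-affinity beads (loose), with distinct yield
    biases."""
    return (
        MethodSpec("capture_release", bias=1.0, replicate_cv=0.08),
        MethodSpec("ultracentrifugation", bias=0.9, replicate_cv=0.12),
        MethodSpec("membrane_affinity", bias=0.7, replicate_cv=0.15),
        MethodSpec("ps_affinity", bias=1.3, replicate_cv=0.25),
    )


def default_config(seed: int = 0, *, nta: bool = False, **overrides) -> SimulationConfig:
    """The default study: 11 samples (6 tumor / 5 healthy), 4 methods,
    5 assays, 4 replicates."""
    cfg = SimulationConfig(
        methods=default_methods(),
        assays=default_assays(),
        nta=NTAConfig() if nta else None,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _sample_ids(config: SimulationConfig) -> list[tuple[str, str]]:
    ids = []
    for group in sorted(config.groups):
        for i in range(config.groups[group]):
            ids.append((f"{group}_{i + 1:02d}", group))
    return ids


def _cv_to_log_sd(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def simulate_study(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[StudyDataset, list[NTAProfile] | None]:
    """Draw one synthetic study from the configured model.

    Returns the measurement dataset and, when ``config.nta`` is set, the
    per-replicate size profiles (in which case the size / PDI /
    concentration records come from the profiles via the NTA summary path,
    and the remaining assays from the direct model).  Fully deterministic
    given ``config.seed`` (or an explicit ``rng``).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    samples = _sample_ids(config)
    assay_labels = [a.label for a in config.assays]
    S, M, A, R = (
        len(samples), len(config.methods), len(config.assays), config.n_replicates,
    )

    log_mu = np.array([a.log_mean for a in config.assays])
    log_sd = np.array([a.log_sd for a in config.assays])
    truths = rng.lognormal(mean=log_mu, sigma=log_sd, size=(S, A))  # (S, A)

    bias = np.array(
        [[m.bias_for(a) for a in assay_labels] for m in config.methods]
    )  # (M, A)
    noise_sd = np.array(
        [[_cv_to_log_sd(m.cv_for(a)) for a in assay_labels] for m in config.methods]
    )  # (M, A)
    z = rng.standard_normal(size=(S, M, A, R))
    sig = noise_sd[None, :, :, None]
    eps = np.exp(sig * z - 0.5 * sig**2)  # E[eps] = 1; exact 1 when cv = 0
    values = truths[:, None, :, None] * bias[None, :, :, None] * eps

    nta_assays = {SIZE_ASSAY, PDI_ASSAY, CONC_ASSAY} if config.nta else set()
    rows = []
    for si, (sample_id, group) in enumerate(samples):
        for mi, m in enumerate(config.methods):
            for ai, assay in enumerate(assay_labels):
                if assay in nta_assays:
                    continue
                for r in range(R):
                    rows.append(
                        (sample_id, group, m.label, assay, r + 1,
                         values[si, mi, ai, r])
                    )
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "method", "assay", "replicate", "value"],
    )

    profiles: list[NTAProfile] | None = None
    if config.nta is not None:
        nta = config.nta
        size_ai = assay_labels.index(SIZE_ASSAY)
        weights = np.array([c.weight for c in nta.components])
        comp_mu = np.array([c.log_mean for c in nta.components])
        comp_sd = np.array([c.log_sd for c in nta.components])
        mix_mean = nta.mixture_mean
        profiles = []
        conc_map = {}
        for si, (sample_id, group) in enumerate(samples):
            for mi, m in enumerate(config.methods):
                for r in range(R):
                    comp = rng.choice(len(weights), size=nta.n_particles, p=weights)
                    sizes = rng.lognormal(comp_mu[comp], comp_sd[comp])
                    # scale so the profile mean tracks truth x bias x noise
                    factor = values[si, mi, size_ai, r] / mix_mean
                    profiles.append(
                        NTAProfile(
                            sample_id=sample_id, method=m.label, replicate=r + 1,
                            sizes=sizes * factor, group=group,
                        )
                    )
                    if CONC_ASSAY in assay_labels:
                        ci = assay_labels.index(CONC_ASSAY)
                        conc_map[(sample_id, m.label, r + 1)] = values[si, mi, ci, r]
        derived = derive_measurements(profiles, concentrations=conc_map or None)
        df = pd.concat(
            [df, pd.DataFrame([r.__dict__ for r in derived])], ignore_index=True
        )

    return StudyDataset(df), profiles


@dataclass
class RecoverySummary:
    """Outcome of a repeated-pipeline ranking experiment.

    ``recovery_fraction`` is the share of runs whose EQI ordering (best
    first) exactly inverts the configured replicate-CV ordering (lowest CV
    first).  ``per_method`` holds mean/sd of EQI (fraction) and mean EVI
    per method over runs; ``runs`` the per-run EQI values.
    """

    n_runs: int
    recovery_fraction: float
    per_method: pd.DataFrame
    runs: pd.DataFrame


def recovery_experiment(
    config: SimulationConfig,
    n_runs: int,
    *,
    aggregation: str = "mean",
    sd_mode: str = "sample",
    scope: str = "all",
    rank_convention: str = "midrank",
) -> RecoverySummary:
    """Run simulate -> transform -> EVI -> EQI ``n_runs`` times and score
    how often the EQI ranking recovers the (inverse) noise ranking.

    Requires at least 2 methods with strictly ordered scalar replicate CVs
    shared across assays.  Child seeds are spawned from ``config.seed`` so
    runs are independent and the whole experiment is reproducible.
    """
    config.validate()
    if len(config.methods) < 2:
        raise ConfigError("recovery experiment needs at least 2 methods")
    if n_runs < 1:
        raise ConfigError("n_runs must be >= 1")
    for m in config.methods:
        if isinstance(m.replicate_cv, Mapping):
            raise ConfigError(
                "recovery experiment needs scalar replicate_cv shared across assays"
            )
    cvs = {m.label: float(m.replicate_cv) for m in config.methods}
    truth_order = [label for label, _ in sorted(cvs.items(), key=lambda kv: kv[1])]

    children = np.random.SeedSequence(config.seed).spawn(n_runs)
    rows = []
    hits = 0
    for run, child in enumerate(children):
        rng = np.random.default_rng(child)
        dataset, _ = simulate_study(config, rng=rng)
        transformed = transform_dataset(
            dataset, scope=scope, rank_convention=rank_convention
        )
        matrix = evi_matrix(transformed, aggregation=aggregation, sd_mode=sd_mode)
        result = compute_eqi(matrix)
        ranked = (
            result.table.sort_values(["eqi", "method"], ascending=[False, True])
            ["method"].tolist()
        )
        hit = ranked == truth_order
        hits += hit
        for row in result.table.itertuples(index=False):
            rows.append(
                (run, row.method, cvs[row.method], row.eqi, row.mean_evi, hit)
            )
    runs = pd.DataFrame(
        rows, columns=["run", "method", "replicate_cv", "eqi", "mean_evi", "hit"]
    )
    per_method = (
        runs.groupby("method", sort=True)
        .agg(
            replicate_cv=("replicate_cv", "first"),
            mean_eqi=("eqi", "mean"),
            sd_eqi=("eqi", "std"),
            mean_evi=("mean_evi", "mean"),
        )
        .reset_index()
        .sort_values("replicate_cv", kind="mergesort")
        .reset_index(drop=True)
    )
    return RecoverySummary(
        n_runs=n_runs,
        recovery_fraction=hits / n_runs,
        per_method=per_method,
        runs=runs,
    )
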