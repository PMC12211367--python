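"""Scalar summaries of NTA size profiles: mean size, concentration and PDI.

The particle dispersity index (PDI) summarizes the heterogeneity of a size
profile as ``max(NTA) / sigma(NTA)``: the largest particle size present
divided by the standard deviation of the profile.  Both numerator and
denominator are lengths in nm, so the index is dimensionless and invariant
under a rescaling of all sizes.

For per-particle profiles the sample (n-1) standard deviation is used; for
binned profiles the concentration-weighted population form is used, with bin
concentrations treated as per-bin counts (summed, not integrated) for the
total concentration — the convention of ZetaView-style exports.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    DegenerateProfileError,
    MeasurementRecord,
    NTAProfile,
    ValidationError,
    warn,
)

#: Assay labels emitted by :func:`derive_measurements`.
SIZE_ASSAY = "size_mean_nm"
CONC_ASSAY = "particle_concentration_per_mL"
PDI_ASSAY = "pdi"


@dataclass(frozen=True)
class ProfileSummary:
    """Scalar statistics of one size profile.

    ``pdi = max_size / sd_size`` whenever ``sd_size > 0``; for a
    monodisperse profile ``pdi`` is ``nan`` here and :func:`compute_pdi`
    raises instead of returning infinity.
    """

    mean_size: float
    sd_size: float
    max_size: float
    mode_size: float
    total_concentration: float | None
    pdi: float


def summarize_profile(
    profile: NTAProfile, *, total_concentration: float | None = None
) -> ProfileSummary:
    """Compute mean/sd/max/mode size, total concentration and PDI.

    Per-particle profiles use sample statistics (sd with ddof=1; 0 for a
    single particle) and take ``total_concentration`` from the keyword if
    supplied.  Binned profiles use concentration-weighted statistics over
    bin centers: ``max_size`` is the largest bin center with strictly
    positive concentration, ``mode_size`` the bin center of maximal
    concentration (smallest on ties), and the total concentration the sum
    of bin concentrations.
    """
    if profile.is_binned:
        b = profile.bin_sizes
        c = profile.bin_concentrations
        w = c / c.sum()
        mean = float(np.sum(w * b))
        sd = float(math.sqrt(np.sum(w * (b - mean) ** 2)))
        max_size = float(b[c > 0].max())
        mode_size = float(b[np.argmax(c)])
        total = float(c.sum())
    else:
        s = profile.sizes
        mean = float(s.mean())
        sd = float(s.std(ddof=1)) if s.size > 1 else 0.0
        max_size = float(s.max())
        vals, counts = np.unique(s, return_counts=True)
        mode_size = float(vals[np.argmax(counts)])
        total = total_concentration
    pdi = max_size / sd if sd > 0 else float("nan")
    return ProfileSummary(
        mean_size=mean,
        sd_size=sd,
        max_size=max_size,
        mode_size=mode_size,
        total_concentration=total,
        pdi=pdi,
    )


def compute_pdi(profile: NTAProfile, *, max_def: str = "max_size") -> float:
    """Particle dispersity index of a profile: ``max(NTA) / sigma(NTA)``.

    Parameters
    ----------
    profile
        A valid size profile.
    max_def
        Which size statistic forms the numerator: ``"max_size"`` (default,
        the largest particle size present) or ``"mode_size"`` (the modal
        size) — exposed because either reading keeps the index
        dimensionless.

    Raises
    ------
    DegenerateProfileError
        If the profile is monodisperse (zero size spread); the index is
        undefined there and is never reported as infinity.
    """
    summary = summarize_profile(profile)
    if summary.sd_size == 0:
        raise DegenerateProfileError(
            f"profile {profile.key}: zero size spread, PDI undefined"
        )
    if max_def == "max_size":
        return summary.max_size / summary.sd_size
    if max_def == "mode_size":
        return summary.mode_size / summary.sd_size
    raise ValidationError(f"unknown max_def {max_def!r}")


def derive_measurements(
    profiles: Sequence[NTAProfile],
    *,
    concentrations: Mapping[tuple[str, str, int], float] | None = None,
    groups: Mapping[str, str] | None = None,
    max_def: str = "max_size",
) -> list[MeasurementRecord]:
    """Turn size profiles into measurement records ready for a StudyDataset.

    Emits one ``size_mean_nm`` and one ``pdi`` record per profile, plus a
    ``particle_concentration_per_mL`` record when a total concentration is
    available (from binned profiles or the ``concentrations`` map keyed by
    ``(sample_id, method, replicate)``).  A monodisperse replicate keeps its
    size record but its PDI record is omitted with a warning.

    Raises
    ------
    ValidationError
        If two profiles share a (sample_id, method, replicate) key.
    """
    seen: set[tuple[str, str, int]] = set()
    records: list[MeasurementRecord] = []
    for p in profiles:
        if p.key in seen:
            raise ValidationError(f"duplicate profile key {p.key}")
        seen.add(p.key)
        conc = None
        if concentrations is not None and p.key in concentrations:
            conc = float(concentrations[p.key])
        summary = summarize_profile(p, total_concentration=conc)
        group = p.group or (groups or {}).get(p.sample_id, "")
        base = dict(
            sample_id=p.sample_id, group=group, method=p.method,
            replicate=int(p.replicate),
        )
        records.append(
            MeasurementRecord(assay=SIZE_ASSAY, value=summary.mean_size, **base)
        )
        if summary.total_concentration is not None:
            records.append(
                MeasurementRecord(
                    assay=CONC_ASSAY, value=summary.total_concentration, **base
                )
            )
        try:
            pdi = compute_pdi(p, max_def=max_def)
        except DegenerateProfileError:
            warn(
                f"profile {p.key}: monodisperse replicate, PDI record omitted"
            )
        else:
            records.append(MeasurementRecord(assay=PDI_ASSAY, value=pdi, **base))
    return records
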