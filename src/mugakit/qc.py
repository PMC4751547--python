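"""Array-level quality control and probe quality-tier assignment.

Three checks are applied to each array before analysis:

1. *Hybridization intensity.*  The per-probe statistic
   ``d = sqrt(x^2 + y^2)`` summarizes total intensity (its companion
   ``R = x + y`` overestimates intensity in heterozygous samples by the
   triangle inequality).  Arrays whose distribution of ``d`` departs from
   the reference Normal(0.97, 0.42) by a Kolmogorov-Smirnov statistic
   K > 0.1 are flagged.
2. *Call rate.*  Group-specific bounds on missing calls (> 15,000 for
   Mus musculus samples, > 45,000 for other Mus species) and on
   heterozygous calls for classical inbred strains (> 2000).
3. *Sex concordance.*  Good (nonmissing, nonheterozygous) calls at
   Y-linked markers separate the sexes; the ambiguous band (more than 33
   but fewer than 42 good Y calls) is resolved by mean X-chromosome
   intensity, which is higher in females.

Count thresholds are calibrated to a full-size array (143,259 markers)
and scaled proportionally when only a subset of markers is present.

Probes are also classified into four mutually exclusive quality tiers
based on the genotype states they exhibit across a reference panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import (
    Call,
    GenotypeMatrix,
    IntensityMatrix,
    MarkerAnnotation,
    SampleGroup,
    SampleInfo,
)

__all__ = [
    "QCConfig",
    "ArrayQCReport",
    "compute_d",
    "ks_flag",
    "callrate_flags",
    "sex_check",
    "assign_tiers",
    "run_qc",
    "FULL_ARRAY_MARKERS",
]

FULL_ARRAY_MARKERS = 143_259


@dataclass
class QCConfig:
    ref_mean: float = 0.97
    ref_sd: float = 0.42
    k_threshold: float = 0.1
    max_missing_musculus: int = 15_000
    max_missing_other_mus: int = 45_000
    max_het_classical: int = 2_000
    female_max_y_calls: int = 33
    male_min_y_calls: int = 42
    tier_nocall_rate: float = 0.10
    #: count thresholds assume this many markers; subsets scale them
    full_array_markers: int = FULL_ARRAY_MARKERS

    def __post_init__(self) -> None:
        if self.female_max_y_calls >= self.male_min_y_calls:
            raise ValueError("female_max_y_calls must be < male_min_y_calls")
        for name in ("ref_sd", "k_threshold", "max_missing_musculus",
                     "max_missing_other_mus", "max_het_classical",
                     "tier_nocall_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scale(self, n_markers: int) -> float:
        """Proportional adjustment of count thresholds for subsetted arrays."""
        return n_markers / self.full_array_markers


@dataclass
class ArrayQCReport:
    sample_id: str
    d_mean: float
    d_sd: float
    K: float
    n_missing: int
    n_het: int
    y_good_calls: int
    x_mean_d: float
    inferred_sex: str  # F, M, ambiguous
    flags: set[str] = field(default_factory=set)

    @property
    def status(self) -> str:
        return "FAIL" if self.flags else "PASS"


def compute_d(x, y):
    """Total-intensity statistic d = ||(x, y)||_2 for nonnegative channels."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("intensities must be nonnegative")
    out = np.hypot(x, y)
    return float(out) if out.ndim == 0 else out


def ks_flag(d_values, config: QCConfig | None = None) -> tuple[float, bool]:
    """Two-sided KS statistic of d against the reference normal, with flag.

    K is the supremum over d of |empirical CDF - Normal(ref_mean, ref_sd)
    CDF| using the right-continuous ECDF convention; the array is flagged
    when K exceeds ``k_threshold``.  Requires at least 100 values.
    """
    config = config or QCConfig()
    d = np.asarray(d_values, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < 100:
        raise ValueError(f"need >= 100 d values for a stable K, got {d.size}")
    k = stats.kstest(d, stats.norm(config.ref_mean, config.ref_sd).cdf).statistic
    return float(k), bool(k > config.k_threshold)


_MUSCULUS_GROUPS = {
    SampleGroup.CLASSICAL_INBRED, SampleGroup.WILD_DERIVED, SampleGroup.F1,
    SampleGroup.CC_F1, SampleGroup.DO, SampleGroup.WILD_MUSCULUS,
}


def callrate_flags(
    genotypes: GenotypeMatrix,
    samples: list[SampleInfo],
    config: QCConfig | None = None,
) -> dict[str, set[str]]:
    """Missing-call and heterozygosity flags with group-specific thresholds.

    Mus musculus samples are flagged above ``max_missing_musculus`` missing
    calls, other Mus species above ``max_missing_other_mus``; the
    heterozygosity bound applies only to classical inbred strains.  All
    bounds are strict inequalities, scaled to the number of markers
    present.
    """
    config = config or QCConfig()
    scale = config.scale(len(genotypes.markers))
    out: dict[str, set[str]] = {}
    for info in samples:
        calls = genotypes.sample_calls(info.sample_id)
        n_missing = int((calls == Call.N).sum())
        n_het = int((calls == Call.AB).sum())
        flags: set[str] = set()
        if info.group in _MUSCULUS_GROUPS:
            bound = config.max_missing_musculus * scale
        elif info.group is SampleGroup.OTHER_MUS:
            bound = config.max_missing_other_mus * scale
        else:  # pragma: no cover - SampleGroup is exhaustive
            raise ValueError(f"unknown sample group {info.group}")
        if n_missing > bound:
            flags.add("missing_fail")
        if info.group is SampleGroup.CLASSICAL_INBRED:
            if n_het > config.max_het_classical * scale:
                flags.add("het_fail")
        out[info.sample_id] = flags
    return out


def sex_check(
    genotypes: GenotypeMatrix,
    intensities: IntensityMatrix,
    manifest: list[MarkerAnnotation],
    samples: list[SampleInfo],
    config: QCConfig | None = None,
) -> dict[str, tuple[str, bool]]:
    """Infer sample sex from Y-linked calls, resolving the ambiguous band
    by X-chromosome intensity.

    Good Y calls are nonmissing and nonheterozygous.  At most
    ``female_max_y_calls`` (scaled) good calls infers F, at least
    ``male_min_y_calls`` infers M.  Samples in between are resolved by
    comparing mean d over X markers against the midpoint of the batch's
    known-female and known-male means (below the midpoint -> M).  The
    mismatch flag is set when the resolved sex contradicts a known sex.
    """
    config = config or QCConfig()
    marker_idx = {m: i for i, m in enumerate(genotypes.markers)}
    y_rows = [marker_idx[m.marker_id] for m in manifest
              if m.chromosome == "Y" and m.marker_id in marker_idx]
    x_rows = [marker_idx[m.marker_id] for m in manifest
              if m.chromosome == "X" and m.marker_id in marker_idx]
    if not y_rows:
        raise ValueError("manifest contains no Y-chromosome markers")
    y_scale = len(y_rows) / 83.0  # thresholds quoted for an 83-probe Y panel
    female_max = config.female_max_y_calls * y_scale
    male_min = config.male_min_y_calls * y_scale

    d = intensities.d()
    x_mean_d = {
        s: float(np.nanmean(d[x_rows, intensities.sample_column(s)]))
        if x_rows else math.nan
        for s in genotypes.samples
    }
    known = {info.sample_id: info.known_sex for info in samples}
    f_means = [x_mean_d[s] for s, sex in known.items() if sex == "F"]
    m_means = [x_mean_d[s] for s, sex in known.items() if sex == "M"]
    midpoint = (
        (float(np.mean(f_means)) + float(np.mean(m_means))) / 2.0
        if f_means and m_means else None
    )

    out: dict[str, tuple[str, bool]] = {}
    for info in samples:
        calls = genotypes.sample_calls(info.sample_id)[y_rows]
        good = int(((calls == Call.AA) | (calls == Call.BB)).sum())
        if good <= female_max:
            sex = "F"
        elif good >= male_min:
            sex = "M"
        elif midpoint is not None:
            sex = "M" if x_mean_d[info.sample_id] < midpoint else "F"
        else:
            sex = "ambiguous"
        mismatch = (
            sex in ("F", "M")
            and info.known_sex != "unknown"
            and sex != info.known_sex
        )
        out[info.sample_id] = (sex, mismatch)
    return out


def assign_tiers(
    genotypes: GenotypeMatrix, config: QCConfig | None = None
) -> dict[str, int]:
    """Assign each marker to a quality tier from reference-panel calls.

    Tier 1: at least one sample called each of AA, BB and AB, with
    no-call rate strictly below 10%.  Tier 2: not Tier 1, both homozygous
    states seen, no-call rate < 10%.  Tier 3: neither, no-call rate
    < 10%.  Tier 4: all remaining probes.  Tiers are mutually exclusive
    and exhaustive.
    """
    config = config or QCConfig()
    calls = genotypes.calls
    n = calls.shape[1]
    if n == 0:
        raise ValueError("reference panel is empty")
    has_aa = (calls == Call.AA).any(axis=1)
    has_bb = (calls == Call.BB).any(axis=1)
    has_ab = (calls == Call.AB).any(axis=1)
    nocall_ok = (calls == Call.N).sum(axis=1) / n < config.tier_nocall_rate
    tier = np.full(len(genotypes.markers), 4, dtype=int)
    tier[nocall_ok] = 3
    tier[nocall_ok & has_aa & has_bb] = 2
    tier[nocall_ok & has_aa & has_bb & has_ab] = 1
    return dict(zip(genotypes.markers, (int(t) for t in tier)))


def run_qc(
    genotypes: GenotypeMatrix,
    intensities: IntensityMatrix,
    manifest: list[MarkerAnnotation],
    samples: list[SampleInfo],
    config: QCConfig | None = None,
) -> list[ArrayQCReport]:
    """Full per-sample QC: intensity, call-rate and sex checks combined."""
    config = config or QCConfig()
    d = intensities.d()
    crate = callrate_flags(genotypes, samples, config)
    sexes = sex_check(genotypes, intensities, manifest, samples, config)
    marker_idx = {m: i for i, m in enumerate(genotypes.markers)}
    y_rows = [marker_idx[m.marker_id] for m in manifest
              if m.chromosome == "Y" and m.marker_id in marker_idx]
    x_rows = [marker_idx[m.marker_id] for m in manifest
              if m.chromosome == "X" and m.marker_id in marker_idx]
    reports = []
    for info in samples:
        j = intensities.sample_column(info.sample_id)
        dj = d[:, j]
        K, intensity_fail = ks_flag(dj, config)
        calls = genotypes.sample_calls(info.sample_id)
        sex, mismatch = sexes[info.sample_id]
        flags = set(crate[info.sample_id])
        if intensity_fail:
            flags.add("intensity_fail")
        if mismatch:
            flags.add("sex_mismatch")
        ycalls = calls[y_rows]
        reports.append(ArrayQCReport(
            sample_id=info.sample_id,
            d_mean=float(np.nanmean(dj)),
            d_sd=float(np.nanstd(dj, ddof=1)),
            K=K,
            n_missing=int((calls == Call.N).sum()),
            n_het=int((calls == Call.AB).sum()),
            y_good_calls=int(((ycalls == Call.AA) | (ycalls == Call.BB)).sum()),
            x_mean_d=float(np.nanmean(dj[x_rows])) if x_rows else math.nan,
            inferred_sex=sex,
            flags=flags,
        ))
    return reports
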