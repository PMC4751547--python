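"""Core containers and file I/O for genotyping-array data.

The central objects are a marker manifest (:class:`MarkerAnnotation`),
a markers x samples matrix of discrete genotype calls
(:class:`GenotypeMatrix`), the paired two-channel hybridization
intensities (:class:`IntensityMatrix`), a genetic map supporting
bp -> cM interpolation (:class:`GeneticMap`), and the allele codes of a
set of founder haplotypes (:class:`FounderHaplotypeSet`).

Coordinates are 1-based and inclusive throughout; BED output converts to
0-based half-open on write.  Chromosome labels are normalized to
``{"1".."19", "X", "Y", "M"}`` with any leading ``chr`` prefix stripped.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Call",
    "ProbeType",
    "MarkerAnnotation",
    "GenotypeMatrix",
    "IntensityMatrix",
    "SampleInfo",
    "GeneticMap",
    "FounderHaplotypeSet",
    "normalize_chromosome",
    "read_manifest",
    "write_manifest",
    "read_genetic_map",
    "read_finalreport",
    "write_finalreport",
    "write_bed",
    "write_phylip_matrix",
    "read_phylip_matrix",
    "write_fasta",
]

CHROMOSOMES = tuple(str(i) for i in range(1, 20)) + ("X", "Y", "M")
AUTOSOMES = tuple(str(i) for i in range(1, 20))

#: Tokens accepted as a missing allele in genotype input.
MISSING_ALLELE_TOKENS = {"-", "N", "", "0"}


class Call(enum.IntEnum):
    """Discrete genotype call.

    AA is homozygous for the reference allele, BB homozygous for the
    alternate, AB heterozygous and N a no-call.
    """

    N = 0
    AA = 1
    AB = 2
    BB = 3


class ProbeType(str, enum.Enum):
    HAPLOTYPE_DISCRIMINATION = "haplotype_discrimination"
    RECOMBINATION_HOTSPOT = "recombination_hotspot"
    WILD_ALLELES = "wild_alleles"
    OTHER_EXISTING = "other_existing"
    ICR_NOVEL = "icr_novel"
    CNV_SD = "cnv_sd"
    # "sanger_known" appears only in the tier census, not the probe-type
    # census; both labels are accepted and kept distinct.
    SANGER_KNOWN = "sanger_known"
    SISTER_STRAINS = "sister_strains"
    TARGET_LOCUS = "target_locus"
    TRANSGENE = "transgene"


def normalize_chromosome(label: str) -> str:
    """Normalize a chromosome label to ``1..19, X, Y, M``."""
    lab = str(label).strip()
    if lab.lower().startswith("chr"):
        lab = lab[3:]
    if lab.upper() in {"MT", "M"}:
        return "M"
    lab = lab.upper() if lab.upper() in {"X", "Y"} else lab
    if lab not in CHROMOSOMES:
        raise ValueError(f"unknown chromosome label: {label!r}")
    return lab


@dataclass
class MarkerAnnotation:
    """One array probe: locus, alleles, design class and quality tier."""

    marker_id: str
    chromosome: str
    position_bp: int
    allele_ref: str
    allele_alt: str
    probe_type: ProbeType = ProbeType.HAPLOTYPE_DISCRIMINATION
    position_cM: float | None = None
    tier: int | None = None
    diagnostic_for: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.chromosome = normalize_chromosome(self.chromosome)
        self.position_bp = int(self.position_bp)
        if self.position_bp < 1:
            raise ValueError(
                f"{self.marker_id}: position_bp must be >= 1, got {self.position_bp}"
            )
        self.probe_type = ProbeType(self.probe_type)
        if self.tier is not None and self.tier not in (1, 2, 3, 4):
            raise ValueError(f"tier must be 1-4 or None, got {self.tier}")
        if not self.diagnostic_for <= {"dom", "mus", "cas"}:
            raise ValueError(f"bad diagnostic_for: {self.diagnostic_for}")
        is_snp = self.probe_type not in (ProbeType.CNV_SD, ProbeType.TRANSGENE)
        if is_snp and self.allele_ref == self.allele_alt:
            raise ValueError(f"{self.marker_id}: SNP probe alleles must differ")


@dataclass
class GenotypeMatrix:
    """Markers x samples matrix of calls in {AA, AB, BB, N}."""

    markers: list[str]
    samples: list[str]
    calls: np.ndarray  # int8, values from Call

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} inconsistent with "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        if not np.isin(self.calls, [int(c) for c in Call]).all():
            raise ValueError("calls must be in the 4-state {AA, AB, BB, N} alphabet")
        self._marker_index = {m: i for i, m in enumerate(self.markers)}
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    def sample_calls(self, sample_id: str) -> np.ndarray:
        return self.calls[:, self._sample_index[sample_id]]

    def marker_calls(self, marker_id: str) -> np.ndarray:
        return self.calls[self._marker_index[marker_id], :]


@dataclass
class IntensityMatrix:
    """Markers x samples paired channel intensities, raw and normalized."""

    markers: list[str]
    samples: list[str]
    x_raw: np.ndarray
    y_raw: np.ndarray
    x_norm: np.ndarray
    y_norm: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.markers), len(self.samples))
        for name in ("x_raw", "y_raw", "x_norm", "y_norm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if np.nanmin(arr, initial=0.0) < 0:
                raise ValueError(f"{name} contains negative intensities")
            setattr(self, name, arr)
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    def d(self, normalized: bool = True) -> np.ndarray:
        """Per-probe total-intensity statistic d = ||(x, y)||_2."""
        x = self.x_norm if normalized else self.x_raw
        y = self.y_norm if normalized else self.y_raw
        return np.hypot(x, y)

    def R(self, normalized: bool = True) -> np.ndarray:
        """Per-probe channel-sum intensity R = x + y."""
        x = self.x_norm if normalized else self.x_raw
        y = self.y_norm if normalized else self.y_raw
        return x + y

    def sample_column(self, sample_id: str) -> int:
        return self._sample_index[sample_id]


class SampleGroup(str, enum.Enum):
    CLASSICAL_INBRED = "classical_inbred"
    WILD_DERIVED = "wild_derived"
    F1 = "f1"
    CC_F1 = "cc_f1"
    DO = "do"
    WILD_MUSCULUS = "wild_musculus"
    OTHER_MUS = "other_mus"


@dataclass
class SampleInfo:
    sample_id: str
    group: SampleGroup
    known_sex: str = "unknown"  # F, M, unknown
    strain_or_parents: tuple[str, ...] = ()
    qc_status: str = "unset"  # PASS, FAIL, unset

    def __post_init__(self) -> None:
        self.group = SampleGroup(self.group)
        if self.known_sex not in ("F", "M", "unknown"):
            raise ValueError(f"known_sex must be F/M/unknown, got {self.known_sex}")
        self.strain_or_parents = tuple(self.strain_or_parents)
        if self.group in (SampleGroup.F1, SampleGroup.CC_F1):
            if len(self.strain_or_parents) != 2:
                raise ValueError(
                    f"{self.sample_id}: F1 samples need exactly two parent labels"
                )


class GeneticMap:
    """Per-chromosome anchors (position_bp, position_cM) with interpolation.

    Anchors must be strictly increasing in bp and nondecreasing in cM.
    Queries between anchors are linearly interpolated; queries outside the
    anchor range are extrapolated with the slope of the nearest segment and
    floored at 0 cM.
    """

    def __init__(self, anchors: dict[str, list[tuple[int, float]]]) -> None:
        self._bp: dict[str, np.ndarray] = {}
        self._cm: dict[str, np.ndarray] = {}
        for chrom, pts in anchors.items():
            chrom = normalize_chromosome(chrom)
            pts = sorted(pts)
            bp = np.array([p[0] for p in pts], dtype=float)
            cm = np.array([p[1] for p in pts], dtype=float)
            if len(bp) < 2:
                raise ValueError(f"chromosome {chrom}: need >= 2 map anchors")
            if not (np.diff(bp) > 0).all():
                raise ValueError(f"chromosome {chrom}: anchor bp must strictly increase")
            if not (np.diff(cm) >= 0).all():
                raise ValueError(f"chromosome {chrom}: anchor cM must be nondecreasing")
            self._bp[chrom] = bp
            self._cm[chrom] = cm

    @property
    def chromosomes(self) -> list[str]:
        return list(self._bp)

    def interpolate_cM(self, position_bp, chromosome: str):
        """Map bp position(s) to cM by piecewise-linear interpolation.

        Outside the anchor range the terminal segment's slope is extended;
        results are floored at 0 cM.  Scalar in, scalar out.
        """
        chrom = normalize_chromosome(chromosome)
        if chrom not in self._bp:
            raise KeyError(f"chromosome {chrom} not in genetic map")
        bp, cm = self._bp[chrom], self._cm[chrom]
        pos = np.asarray(position_bp, dtype=float)
        out = np.interp(pos, bp, cm)
        # np.interp clamps outside the range; extend terminal slopes instead
        lo_slope = (cm[1] - cm[0]) / (bp[1] - bp[0])
        hi_slope = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
        out = np.where(pos < bp[0], cm[0] + (pos - bp[0]) * lo_slope, out)
        out = np.where(pos > bp[-1], cm[-1] + (pos - bp[-1]) * hi_slope, out)
        out = np.maximum(out, 0.0)
        return float(out) if np.isscalar(position_bp) else out


@dataclass
class FounderHaplotypeSet:
    """Allele codes (0 = A, 1 = B, -1 = missing) for F founder strains.

    ``alleles`` is an (n_markers, n_founders) int8 array aligned to
    ``markers``.
    """

    founders: list[str]
    markers: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if len(self.founders) < 2:
            raise ValueError("need at least 2 founders")
        if self.alleles.shape != (len(self.markers), len(self.founders)):
            raise ValueError("allele matrix shape inconsistent with markers x founders")
        if not np.isin(self.alleles, [-1, 0, 1]).all():
            raise ValueError("founder alleles must be 0 (A), 1 (B) or -1 (missing)")
        if (self.alleles == -1).all(axis=0).any():
            raise ValueError("a founder has no observed alleles")

    @property
    def n_founders(self) -> int:
        return len(self.founders)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = [
    "marker_id", "chromosome", "position_bp", "allele_ref", "allele_alt",
    "probe_type", "position_cM", "tier", "diagnostic_for",
]


def read_manifest(path) -> list[MarkerAnnotation]:
    """Read a marker manifest CSV into a list of annotations."""
    df = pd.read_csv(path, dtype={"chromosome": str, "marker_id": str})
    df.columns = [c.strip().lower() for c in df.columns]
    out = []
    for row in df.itertuples(index=False):
        tier = getattr(row, "tier", None)
        tier = None if tier is None or pd.isna(tier) else int(tier)
        cm = getattr(row, "position_cm", None)
        cm = None if cm is None or pd.isna(cm) else float(cm)
        diag = getattr(row, "diagnostic_for", "")
        diag = frozenset() if pd.isna(diag) or not diag else frozenset(str(diag).split(";"))
        out.append(MarkerAnnotation(
            marker_id=row.marker_id,
            chromosome=row.chromosome,
            position_bp=int(row.position_bp),
            allele_ref=row.allele_ref,
            allele_alt=row.allele_alt,
            probe_type=getattr(row, "probe_type", "haplotype_discrimination"),
            position_cM=cm,
            tier=tier,
            diagnostic_for=diag,
        ))
    return out


def write_manifest(manifest: list[MarkerAnnotation], path) -> None:
    rows = []
    for m in manifest:
        rows.append({
            "marker_id": m.marker_id,
            "chromosome": m.chromosome,
            "position_bp": m.position_bp,
            "allele_ref": m.allele_ref,
            "allele_alt": m.allele_alt,
            "probe_type": m.probe_type.value,
            "position_cM": m.position_cM,
            "tier": m.tier,
            "diagnostic_for": ";".join(sorted(m.diagnostic_for)),
        })
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, index=False)


def read_genetic_map(path) -> GeneticMap:
    """Read a genetic map TSV with columns chromosome, position_bp, position_cM."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = [c.strip().lower() for c in df.columns]
    anchors: dict[str, list[tuple[int, float]]] = {}
    for row in df.itertuples(index=False):
        anchors.setdefault(str(row.chromosome), []).append(
            (int(row.position_bp), float(row.position_cm))
        )
    return GeneticMap(anchors)


class FinalReportParseError(ValueError):
    """Raised on a malformed genotype-report row, carrying the line number."""


def _recode_call(a1: str, a2: str, ref: str, alt: str) -> tuple[Call, bool]:
    """Recode an unordered allele pair against manifest alleles.

    Returns (call, mismatched) where ``mismatched`` marks an allele not in
    {ref, alt, missing-token}.
    """
    a1, a2 = a1.strip().upper(), a2.strip().upper()
    if a1 in MISSING_ALLELE_TOKENS or a2 in MISSING_ALLELE_TOKENS:
        return Call.N, False
    pair = frozenset((a1, a2))
    if not pair <= {ref, alt}:
        return Call.N, True
    if pair == {ref}:
        return Call.AA, False
    if pair == {alt}:
        return Call.BB, False
    return Call.AB, False


def read_finalreport(
    path, manifest: list[MarkerAnnotation]
) -> tuple[GenotypeMatrix, IntensityMatrix]:
    """Read a genotyping-service report TSV into call and intensity matrices.

    The expected dialect is tab-separated with one row per (sample, marker)
    and a header naming at least the sample id, marker id, the two allele
    calls, and the raw and normalized channel intensities.  Column names are
    matched case-insensitively.  Calls are recoded to {AA, AB, BB, N}
    against the manifest alleles; an allele pair not matching the manifest
    becomes N and is counted; markers absent from the manifest are rejected
    with a warning giving the count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {c.strip().lower().replace(" ", "_"): c for c in df.columns}

    def col(*names):
        for n in names:
            if n in colmap:
                return colmap[n]
        raise FinalReportParseError(
            f"missing required column (one of {names}); found {list(df.columns)}"
        )

    c_sample = col("sample_id", "sample")
    c_marker = col("marker_id", "snp_name", "marker")
    c_a1 = col("allele1", "allele1_-_forward", "allele_1")
    c_a2 = col("allele2", "allele2_-_forward", "allele_2")
    c_x0 = col("x_raw", "x0")
    c_y0 = col("y_raw", "y0")
    c_x = col("x", "x_norm")
    c_y = col("y", "y_norm")

    by_id = {m.marker_id: m for m in manifest}
    markers = [m.marker_id for m in manifest]
    marker_pos = {m: i for i, m in enumerate(markers)}
    samples = list(dict.fromkeys(df[c_sample]))
    sample_pos = {s: j for j, s in enumerate(samples)}

    shape = (len(markers), len(samples))
    calls = np.zeros(shape, dtype=np.int8)
    layers = {k: np.zeros(shape) for k in ("x_raw", "y_raw", "x_norm", "y_norm")}
    n_unknown_marker = 0
    n_allele_mismatch = 0

    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        vals = dict(zip(df.columns, row))
        marker = vals[c_marker]
        if marker not in by_id:
            n_unknown_marker += 1
            continue
        ann = by_id[marker]
        i, j = marker_pos[marker], sample_pos[vals[c_sample]]
        call, mismatched = _recode_call(
            vals[c_a1], vals[c_a2], ann.allele_ref, ann.allele_alt
        )
        n_allele_mismatch += mismatched
        calls[i, j] = call
        try:
            layers["x_raw"][i, j] = float(vals[c_x0])
            layers["y_raw"][i, j] = float(vals[c_y0])
            layers["x_norm"][i, j] = float(vals[c_x])
            layers["y_norm"][i, j] = float(vals[c_y])
        except ValueError as exc:
            raise FinalReportParseError(f"line {lineno}: bad intensity value: {exc}")

    if n_unknown_marker:
        warnings.warn(
            f"{n_unknown_marker} rows referenced markers absent from the manifest "
            "and were skipped",
            stacklevel=2,
        )
    if n_allele_mismatch:
        warnings.warn(
            f"{n_allele_mismatch} calls had alleles not matching the manifest "
            "and were set to N",
            stacklevel=2,
        )
    geno = GenotypeMatrix(markers=markers, samples=samples, calls=calls)
    inten = IntensityMatrix(markers=markers, samples=samples, **layers)
    return geno, inten


_CALL_TO_ALLELES = {
    Call.AA: lambda r, a: (r, r),
    Call.BB: lambda r, a: (a, a),
    Call.AB: lambda r, a: (r, a),
    Call.N: lambda r, a: ("-", "-"),
}


def write_finalreport(
    geno: GenotypeMatrix,
    inten: IntensityMatrix,
    manifest: list[MarkerAnnotation],
    path,
) -> None:
    """Write calls + intensities back to the report TSV dialect."""
    by_id = {m.marker_id: m for m in manifest}
    rows = []
    for j, s in enumerate(geno.samples):
        for i, m in enumerate(geno.markers):
            ann = by_id[m]
            a1, a2 = _CALL_TO_ALLELES[Call(geno.calls[i, j])](
                ann.allele_ref, ann.allele_alt
            )
            rows.append((
                s, m, a1, a2,
                inten.x_raw[i, j], inten.y_raw[i, j],
                inten.x_norm[i, j], inten.y_norm[i, j],
            ))
    out = pd.DataFrame(
        rows,
        columns=["sample_id", "marker_id", "allele1", "allele2",
                 "x_raw", "y_raw", "x", "y"],
    )
    out.to_csv(path, sep="\t", index=False)


def write_bed(regions, path) -> None:
    """Write (chromosome, start_bp, end_bp[, name]) regions as BED.

    Input coordinates are 1-based inclusive; output is 0-based half-open.
    """
    with open(path, "w") as fh:
        for region in regions:
            chrom, start, end = region[0], int(region[1]), int(region[2])
            name = region[3] if len(region) > 3 else "."
            fh.write(f"{normalize_chromosome(chrom)}\t{start - 1}\t{end}\t{name}\n")


def write_phylip_matrix(chars: dict[str, str], path) -> None:
    """Write per-sample character sequences as relaxed PHYLIP."""
    if not chars:
        raise ValueError("no sequences to write")
    lengths = {len(s) for s in chars.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged sequence lengths: {sorted(lengths)}")
    (n_chars,) = lengths
    if not all(set(s) <= set("ACGT") for s in chars.values()):
        raise ValueError("sequences must be over the {A, C, G, T} alphabet")
    with open(path, "w") as fh:
        fh.write(f"{len(chars)} {n_chars}\n")
        for name, seq in chars.items():
            fh.write(f"{name}  {seq}\n")


def read_phylip_matrix(path) -> dict[str, str]:
    """Read a relaxed PHYLIP character matrix written by this package."""
    with open(path) as fh:
        header = fh.readline().split()
        n_taxa, n_chars = int(header[0]), int(header[1])
        out: dict[str, str] = {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            out[name] = seq.strip()
    if len(out) != n_taxa or any(len(s) != n_chars for s in out.values()):
        raise ValueError("PHYLIP header inconsistent with body")
    return out


def write_fasta(chars: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in chars.items():
            fh.write(f">{name}\n{seq}\n")
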