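"""Core domain types shared across all pipeline stages.

The atom of every stage is :class:`AnnotatedVariant`: one somatic or germline
call with its functional annotations and per-region read support.  Sampling
structure (regions within patients within a cohort) is carried by
:class:`RegionSample`, :class:`Patient` and :class:`Cohort`.  Copy-number and
allele-loss evidence live in :class:`CNVSegment` and :class:`LOHCall`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
CLINVAR_STATES = ("pathogenic", "likely_pathogenic", "other", "none")
PREDICTORS = ("PROVEAN", "SIFT", "PolyPhen")
PREDICTOR_STATES = ("damaging", "benign", "missing")


@dataclass(eq=False)
class AnnotatedVariant:
    """One variant call with annotations and per-region read support.

    Coordinates are 1-based throughout (VCF convention).  ``per_region_support``
    maps a region/sample identifier to ``(alt_reads, total_reads)``.  Missing
    annotations (CADD, caller quality, population AF) are ``None``; missing
    predictor calls are simply absent from ``predictor_calls``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    impact: str = "MODIFIER"
    cadd: Optional[float] = None
    qss: Optional[float] = None
    pop_af: Optional[float] = None
    clinvar: str = "none"
    pfam_domain: bool = False
    predictor_calls: dict[str, str] = field(default_factory=dict)
    per_region_support: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (got {self.pos})")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.impact not in IMPACTS:
            raise ValueError(f"unknown impact {self.impact!r}")
        if self.clinvar not in CLINVAR_STATES:
            raise ValueError(f"unknown ClinVar state {self.clinvar!r}")
        for name, call in self.predictor_calls.items():
            if name not in PREDICTORS:
                raise ValueError(f"unknown predictor {name!r}")
            if call not in PREDICTOR_STATES:
                raise ValueError(f"unknown predictor call {call!r}")
        for region, (alt_reads, total_reads) in self.per_region_support.items():
            if alt_reads < 0 or total_reads < 0:
                raise ValueError(f"negative read counts for region {region!r}")
            if alt_reads > total_reads:
                raise ValueError(
                    f"alt reads exceed total reads for region {region!r} "
                    f"({alt_reads} > {total_reads})"
                )

    @property
    def vtype(self) -> str:
        """``"SNV"`` iff both alleles are single bases, else ``"indel"``."""
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def is_snv(self) -> bool:
        return self.vtype == "SNV"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def vaf(self, region: str) -> Optional[float]:
        """Variant allele frequency in one region; None if depth is zero."""
        alt_reads, total_reads = self.per_region_support[region]
        return alt_reads / total_reads if total_reads > 0 else None


@dataclass(frozen=True)
class RegionSample:
    """One sampled tumor region: label plus inferred tumor cellularity."""

    region_id: str
    cellularity: float

    def __post_init__(self) -> None:
        if not 0.0 < self.cellularity <= 1.0:
            raise ValueError(f"cellularity must be in (0, 1] (got {self.cellularity})")


@dataclass
class Patient:
    """All per-patient data: regions, variants, CNV profiles, metadata."""

    patient_id: str
    regions: list[RegionSample]
    histotype: str = "LUAD"
    smoking_status: str = "ever"
    pack_years: Optional[float] = None
    somatic: list[AnnotatedVariant] = field(default_factory=list)
    germline: list[AnnotatedVariant] = field(default_factory=list)
    germline_hets: list[AnnotatedVariant] = field(default_factory=list)
    cnv: dict[str, list["CNVSegment"]] = field(default_factory=dict)

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def cellularities(self) -> dict[str, float]:
        return {r.region_id: r.cellularity for r in self.regions}


@dataclass
class Cohort:
    patients: list[Patient] = field(default_factory=list)

    def __iter__(self):
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)


@dataclass(frozen=True)
class CNVSegment:
    """A copy-number segment with 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    copy_number: int
    minor_cn: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start ({self.end} < {self.start})")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if self.minor_cn is not None:
            if self.minor_cn < 0 or self.minor_cn > self.copy_number:
                raise ValueError("minor_cn must satisfy 0 <= minor_cn <= copy_number")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class LOHCall:
    """Allele-loss decision for one germline-het site (or segment).

    ``status`` is ``"LOH"`` only when the log-likelihood ratio of the best
    loss model over the retained-het model exceeds the caller's threshold.
    """

    key: tuple
    status: str  # "LOH" | "retained" | "indeterminate"
    log_likelihood_ratio: float
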