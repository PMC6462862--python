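"""Variant filtration cascades and mutation-burden classification.

Three cascades mirror the study design for treatment-naive lung cancer WGS:

1. somatic driver filter — known driver genes, caller quality QSS/QSI > 15,
   population AF < 1%, CADD scaled score > 2 (when available), HIGH or
   MODERATE impact;
2. somatic LOF+LOH filter — all genes queried, same quality/AF/CADD rules,
   HIGH impact only, plus evidence of somatic loss of heterozygosity;
3. germline DNA-repair filter — repair-gene list, population AF < 2%, and
   for missense variants the three-way rule: ClinVar (likely) pathogenic,
   OR in a Pfam domain and damaging by at least one of PROVEAN/SIFT/PolyPhen,
   OR damaging by at least two of the three predictors.

Missing CADD or population AF pass their rules ("if available" semantics:
absence of evidence is not exclusion); missing predictor calls count as
not-damaging.  All numeric thresholds are strict inequalities and
configurable keyword arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .types import AnnotatedVariant

DAMAGING = "damaging"


@dataclass
class FilterDecision:
    variant: AnnotatedVariant
    passed: bool
    failed_rules: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (not self.failed_rules):
            raise ValueError("passed must be equivalent to failed_rules being empty")


def _decide(variant: AnnotatedVariant, failed: list[str]) -> FilterDecision:
    return FilterDecision(variant, passed=not failed, failed_rules=failed)


def _quality_af_cadd_rules(
    v: AnnotatedVariant, qss_min: float, af_max: float, cadd_min: float
) -> list[str]:
    failed = []
    if v.qss is None or not v.qss > qss_min:
        failed.append("qss")
    if v.pop_af is not None and not v.pop_af < af_max:
        failed.append("pop_af")
    if v.cadd is not None and not v.cadd > cadd_min:
        failed.append("cadd")
    return failed


def somatic_driver_filter(
    variants: Sequence[AnnotatedVariant],
    driver_genes: Iterable[str],
    qss_min: float = 15.0,
    af_max: float = 0.01,
    cadd_min: float = 2.0,
) -> list[FilterDecision]:
    """Candidate driver events: driver-gene hit plus quality/AF/CADD/impact rules."""
    driver_genes = set(driver_genes)
    if not driver_genes:
        raise ValueError("driver gene list must be non-empty")
    decisions = []
    for v in variants:
        failed = []
        if v.gene not in driver_genes:
            failed.append("gene")
        failed += _quality_af_cadd_rules(v, qss_min, af_max, cadd_min)
        if v.impact not in ("HIGH", "MODERATE"):
            failed.append("impact")
        decisions.append(_decide(v, failed))
    return decisions


def somatic_lof_loh_filter(
    variants: Sequence[AnnotatedVariant],
    loh_flags: Mapping[AnnotatedVariant, bool] | Mapping[tuple, bool],
    qss_min: float = 15.0,
    af_max: float = 0.01,
    cadd_min: float = 2.0,
) -> list[FilterDecision]:
    """Loss-of-function candidates across all genes, requiring somatic LOH.

    ``loh_flags`` may be keyed by variant object or by ``variant.key``;
    variants absent from the map count as no LOH evidence.
    """
    decisions = []
    for v in variants:
        failed = _quality_af_cadd_rules(v, qss_min, af_max, cadd_min)
        if v.impact != "HIGH":
            failed.append("impact")
        flag = loh_flags.get(v)
        if flag is None:
            flag = loh_flags.get(v.key, False)
        if not flag:
            failed.append("loh")
        decisions.append(_decide(v, failed))
    return decisions


def _missense_damage_evidence(v: AnnotatedVariant) -> bool:
    if v.clinvar in ("pathogenic", "likely_pathogenic"):
        return True
    n_damaging = sum(
        1 for call in v.predictor_calls.values() if call == DAMAGING
    )
    if v.pfam_domain and n_damaging >= 1:
        return True
    return n_damaging >= 2


def germline_repair_filter(
    variants: Sequence[AnnotatedVariant],
    repair_genes: Iterable[str],
    af_max: float = 0.02,
) -> list[FilterDecision]:
    """Potentially significant germline variants in DNA-repair genes.

    HIGH-impact variants pass on the gene and AF rules alone; missense
    (MODERATE) variants additionally need the three-way damage-evidence rule.
    """
    repair_genes = set(repair_genes)
    if not repair_genes:
        raise ValueError("repair gene list must be non-empty")
    decisions = []
    for v in variants:
        failed = []
        if v.gene not in repair_genes:
            failed.append("gene")
        if v.pop_af is not None and not v.pop_af < af_max:
            failed.append("pop_af")
        if v.impact == "HIGH":
            pass
        elif v.impact == "MODERATE":
            if not _missense_damage_evidence(v):
                failed.append("damage_evidence")
        else:
            failed.append("impact")
        decisions.append(_decide(v, failed))
    return decisions


def mutation_burden(n_variants: int, callable_mb: float) -> float:
    """Somatic burden in variants per megabase of callable genome."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    if n_variants < 0:
        raise ValueError("n_variants must be non-negative")
    return n_variants / callable_mb


def classify_hypermutated(burden: float, threshold: float = 10.0) -> bool:
    """Hypermutated iff burden strictly exceeds the threshold (variants/Mb)."""
    return burden > threshold


def decisions_to_rows(decisions: Sequence[FilterDecision]) -> list[dict]:
    """Flatten decisions for a TSV export (failed rules semicolon-joined)."""
    rows = []
    for d in decisions:
        v = d.variant
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "passed": d.passed,
                "failed_rules": ";".join(d.failed_rules),
            }
        )
    return rows
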