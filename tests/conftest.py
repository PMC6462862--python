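"""Shared fixtures: a session reference sequence, the bundled catalog, and a
hand-evaluated truth table for the three filtration cascades.

Every truth-table row was evaluated by hand against the filter rules
(strict QSS > 15, somatic AF < 1% / germline AF < 2%, CADD > 2 when
available, impact classes, LOH requirement, and the germline three-way
damage-evidence rule), including the boundary values QSS = 15,
pop_af = 0.01 / 0.02 and CADD = 2.
"""

from dataclasses import dataclass

import pytest

from tumorhet.synthetic import generate_reference
from tumorhet.types import AnnotatedVariant
from tumorhet.vcfio import default_catalog

DRIVERS = {"TP53", "KRAS"}
REPAIR = {"NEIL1", "MUTYH"}


@pytest.fixture(scope="session")
def reference():
    return generate_reference(100_000, 0.41, seed=7)


@pytest.fixture(scope="session")
def refmap(reference):
    return {"chr1": reference}


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@dataclass
class TruthRow:
    label: str
    variant: AnnotatedVariant
    loh: bool
    driver_pass: bool
    lof_pass: bool
    germline_pass: bool


def _v(pos, **kw):
    base = dict(chrom="chr1", pos=pos, ref="C", alt="A")
    base.update(kw)
    return AnnotatedVariant(**base)


def filter_truth_table() -> list[TruthRow]:
    rows = []

    def add(label, variant, loh, d, l, g):
        rows.append(TruthRow(label, variant, loh, d, l, g))

    # --- somatic driver cascade, incl. boundary values ---
    add("d_all_pass", _v(100, gene="TP53", impact="MODERATE", qss=20.0,
                         pop_af=0.001, cadd=15.0), False, True, False, False)
    add("d_qss_boundary", _v(101, gene="TP53", impact="MODERATE", qss=15.0,
                             pop_af=0.001, cadd=15.0), False, False, False, False)
    add("d_qss_above", _v(102, gene="TP53", impact="MODERATE", qss=15.1,
                          pop_af=0.001, cadd=15.0), False, True, False, False)
    add("d_af_boundary", _v(103, gene="TP53", impact="MODERATE", qss=20.0,
                            pop_af=0.01, cadd=15.0), False, False, False, False)
    add("d_af_below", _v(104, gene="TP53", impact="MODERATE", qss=20.0,
                         pop_af=0.0099, cadd=15.0), False, True, False, False)
    add("d_cadd_boundary", _v(105, gene="TP53", impact="MODERATE", qss=20.0,
                              pop_af=0.001, cadd=2.0), False, False, False, False)
    add("d_cadd_above", _v(106, gene="TP53", impact="MODERATE", qss=20.0,
                           pop_af=0.001, cadd=2.1), False, True, False, False)
    add("d_cadd_missing", _v(107, gene="TP53", impact="MODERATE", qss=20.0,
                             pop_af=0.001, cadd=None), False, True, False, False)
    add("d_af_missing", _v(108, gene="TP53", impact="MODERATE", qss=20.0,
                           pop_af=None, cadd=15.0), False, True, False, False)
    add("d_impact_low", _v(109, gene="TP53", impact="LOW", qss=20.0,
                           pop_af=0.001, cadd=15.0), False, False, False, False)
    add("d_impact_modifier", _v(110, gene="TP53", impact="MODIFIER", qss=20.0,
                                pop_af=0.001, cadd=15.0), False, False, False, False)
    add("d_gene_not_list", _v(111, gene="GENEX", impact="MODERATE", qss=20.0,
                              pop_af=0.001, cadd=15.0), False, False, False, False)
    add("d_indel_qsi", _v(112, gene="TP53", ref="A", alt="AT", impact="MODERATE",
                          qss=16.0), False, True, False, False)
    add("d_qss_missing", _v(113, gene="TP53", impact="MODERATE", qss=None,
                            pop_af=0.001, cadd=15.0), False, False, False, False)

    # --- somatic LOF + LOH cascade (all genes queried) ---
    add("l_all_pass", _v(200, gene="GENEX", impact="HIGH", qss=30.0),
        True, False, True, False)
    add("l_no_loh", _v(201, gene="GENEX", impact="HIGH", qss=30.0),
        False, False, False, False)
    add("l_moderate_impact", _v(202, gene="GENEX", impact="MODERATE", qss=30.0),
        True, False, False, False)
    add("l_qss_boundary", _v(203, gene="GENEX", impact="HIGH", qss=15.0),
        True, False, False, False)
    add("l_af_boundary", _v(204, gene="GENEX", impact="HIGH", qss=30.0,
                            pop_af=0.02), True, False, False, False)
    add("l_cadd_low", _v(205, gene="GENEX", impact="HIGH", qss=30.0,
                         cadd=1.5), True, False, False, False)
    add("l_driver_gene_high", _v(206, gene="TP53", impact="HIGH", qss=30.0,
                                 pop_af=0.001, cadd=10.0), True, True, True, False)

    # --- germline DNA-repair cascade (three-way damage rule) ---
    add("g_clinvar_pathogenic", _v(300, gene="NEIL1", impact="MODERATE",
                                   pop_af=0.001, clinvar="pathogenic",
                                   predictor_calls={"SIFT": "benign", "PROVEAN": "benign"}),
        False, False, False, True)
    add("g_clinvar_likely", _v(301, gene="NEIL1", impact="MODERATE",
                               pop_af=0.001, clinvar="likely_pathogenic"),
        False, False, False, True)
    add("g_pfam_one_damaging", _v(302, gene="NEIL1", impact="MODERATE",
                                  pop_af=0.001, clinvar="other", pfam_domain=True,
                                  predictor_calls={"SIFT": "damaging"}),
        False, False, False, True)
    add("g_no_pfam_one_damaging", _v(303, gene="NEIL1", impact="MODERATE",
                                     pop_af=0.001, pfam_domain=False,
                                     predictor_calls={"SIFT": "damaging"}),
        False, False, False, False)
    add("g_two_damaging", _v(304, gene="NEIL1", impact="MODERATE", pop_af=0.001,
                             predictor_calls={"PROVEAN": "damaging", "PolyPhen": "damaging"}),
        False, False, False, True)
    add("g_af_boundary", _v(305, gene="NEIL1", impact="MODERATE", pop_af=0.02,
                            predictor_calls={"PROVEAN": "damaging", "PolyPhen": "damaging"}),
        False, False, False, False)
    add("g_af_below", _v(306, gene="NEIL1", impact="MODERATE", pop_af=0.0199,
                         predictor_calls={"PROVEAN": "damaging", "PolyPhen": "damaging"}),
        False, False, False, True)
    add("g_af_high_clinvar", _v(307, gene="NEIL1", impact="MODERATE", pop_af=0.05,
                                clinvar="pathogenic"),
        False, False, False, False)
    add("g_wrong_gene", _v(308, gene="GENEX", impact="MODERATE", pop_af=0.001,
                           clinvar="pathogenic"),
        False, False, False, False)
    add("g_high_impact", _v(309, gene="NEIL1", impact="HIGH", pop_af=0.001),
        False, False, False, True)
    add("g_low_impact", _v(310, gene="NEIL1", impact="LOW", pop_af=0.001,
                           clinvar="pathogenic"),
        False, False, False, False)
    add("g_pfam_missing_predictors", _v(311, gene="NEIL1", impact="MODERATE",
                                        pop_af=0.001, pfam_domain=True),
        False, False, False, False)
    add("g_one_damaging_one_missing", _v(312, gene="NEIL1", impact="MODERATE",
                                         pop_af=0.001,
                                         predictor_calls={"SIFT": "damaging"}),
        False, False, False, False)
    add("g_af_missing_two_damaging", _v(313, gene="NEIL1", impact="MODERATE",
                                        pop_af=None,
                                        predictor_calls={"SIFT": "damaging",
                                                         "PROVEAN": "damaging"}),
        False, False, False, True)
    return rows
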