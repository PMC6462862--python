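"""96-channel spectra, NNLS exposure fitting, branch attribution, smoking metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from tumorhet.clonal import Assignment, build_tree
from tumorhet.exceptions import UndefinedFitError
from tumorhet.signatures import (
    CHANNELS,
    MutationSpectrum,
    SignatureCatalog,
    branch_signatures,
    build_spectrum,
    channel_name,
    fit_exposures,
    make_synthetic_catalog,
    smoking_metrics,
    trinucleotide_context,
)
from tumorhet.synthetic import draw_mutations
from tumorhet.types import AnnotatedVariant

_COMP = str.maketrans("ACGT", "TGCA")


def test_channel_order_is_canonical():
    assert CHANNELS[0] == "A[C>A]A"
    assert CHANNELS[1] == "A[C>A]C"
    assert CHANNELS[16] == "A[C>G]A"
    assert CHANNELS[95] == "T[T>G]T"
    assert len(set(CHANNELS)) == 96


def test_context_pyrimidine_reference():
    ref = {"chr1": "TCA"}
    idx = trinucleotide_context(ref, "chr1", 2, "C", "T")
    assert CHANNELS[idx] == "T[C>T]A"


def test_context_purine_reverse_complemented():
    # A G A with G>A maps to the reverse complement T C T, channel T[C>T]T
    ref = {"chr1": "AGA"}
    idx = trinucleotide_context(ref, "chr1", 2, "G", "A")
    assert CHANNELS[idx] == "T[C>T]T"


def test_context_edge_positions_and_indels_excluded():
    ref = {"chr1": "ACGTA"}
    assert trinucleotide_context(ref, "chr1", 1, "A", "T") is None
    assert trinucleotide_context(ref, "chr1", 5, "A", "T") is None
    assert trinucleotide_context(ref, "chr1", 3, "G", "GA") is None


def test_context_reference_mismatch_raises():
    ref = {"chr1": "ACGTA"}
    with pytest.raises(ValueError, match="mismatch"):
        trinucleotide_context(ref, "chr1", 3, "T", "A")


@settings(derandomize=True, max_examples=100)
@given(
    five=st.sampled_from("ACGT"),
    three=st.sampled_from("ACGT"),
    sub=st.sampled_from([("C", "A"), ("C", "G"), ("C", "T"),
                         ("T", "A"), ("T", "C"), ("T", "G"),
                         ("G", "T"), ("G", "C"), ("G", "A"),
                         ("A", "T"), ("A", "G"), ("A", "C")]),
)
def test_channel_is_strand_symmetric(five, three, sub):
    """Complementing the strand (and swapping flanks) leaves the channel fixed."""
    ref, alt = sub
    direct = channel_name(five, ref, alt, three)
    flipped = channel_name(
        three.translate(_COMP), ref.translate(_COMP), alt.translate(_COMP),
        five.translate(_COMP),
    )
    assert direct == flipped
    assert direct in CHANNELS


def test_build_spectrum_counts_snvs_and_skips_indels(refmap):
    seq = refmap["chr1"]
    pos = 500
    while seq[pos - 1] not in "CT":
        pos += 1
    snv = AnnotatedVariant("chr1", pos, seq[pos - 1], "A" if seq[pos - 1] != "A" else "G")
    indel = AnnotatedVariant("chr1", 600, seq[599], seq[599] + "T")
    spectrum = build_spectrum([snv, indel], refmap)
    assert spectrum.total == 1
    assert spectrum.n_excluded == 1
    assert spectrum.counts.max() == 1


def test_empty_spectrum_is_zero_vector(refmap):
    spectrum = build_spectrum([], refmap)
    assert spectrum.total == 0 and spectrum.n_excluded == 0


def test_fit_disjoint_support_forces_split():
    matrix = np.zeros((2, 96))
    matrix[0, :16] = 1 / 16  # pure C>A signature
    matrix[1, 32:48] = 1 / 16  # pure C>T signature
    cat = SignatureCatalog(["tobacco-like", "clock-like"], matrix)
    counts = np.zeros(96)
    counts[:16] = 70  # 1120 mutations on sig-1 channels
    counts[32:48] = 30  # 480 on sig-2 channels: a 70/30 split
    fit = fit_exposures(MutationSpectrum(counts.astype(int)), cat)
    assert fit.fractions == pytest.approx([0.7, 0.3], abs=1e-9)


def test_fit_exact_catalog_row_recovers_unit_fraction(catalog):
    row = catalog.matrix[2]
    counts = np.round(row * 100000).astype(int)
    fit = fit_exposures(MutationSpectrum(counts), catalog)
    assert fit.fractions[2] == pytest.approx(1.0, abs=1e-4)
    assert fit.residual_norm < 1e-3


def test_fit_recovers_noiseless_mixture_to_1e6(catalog):
    """Exact mixture of four catalog rows: NNLS returns the generating weights."""
    weights = np.array([0.4, 0.3, 0.2, 0.1])
    sub = catalog.subset(["tobacco-like", "clock-like", "apobec-like", "hrd-like"])
    assert np.linalg.matrix_rank(sub.matrix) == 4
    target = weights @ sub.matrix
    spectrum = MutationSpectrum((target * 1e9).astype(np.int64))
    fit = fit_exposures(spectrum, sub)
    assert np.max(np.abs(fit.fractions - weights)) < 1e-6


def test_fit_residual_nonincreasing_in_catalog_size(catalog, refmap):
    """Nested-model property: adding signatures never worsens the NNLS residual."""
    variants = draw_mutations(
        2000, [0.5, 0.5, 0, 0, 0, 0], catalog, refmap["chr1"], seed=3
    )
    spectrum = build_spectrum(variants, refmap)
    small = catalog.subset(["tobacco-like", "clock-like"])
    res_small = fit_exposures(spectrum, small).residual_norm
    res_full = fit_exposures(spectrum, catalog).residual_norm
    assert res_full <= res_small + 1e-12


def test_fit_empty_spectrum_is_undefined(catalog):
    with pytest.raises(UndefinedFitError):
        fit_exposures(MutationSpectrum(np.zeros(96, dtype=int)), catalog)


def test_drawn_spectrum_passes_multinomial_goodness_of_fit(catalog, refmap):
    """10,000 drawn SNVs: chi-square GOF vs catalog^T.exposures not rejected."""
    exposures = np.array([0.5, 0.3, 0.1, 0.0, 0.0, 0.1])
    variants = draw_mutations(10000, exposures, catalog, refmap["chr1"], seed=11)
    spectrum = build_spectrum(variants, refmap)
    expected = exposures @ catalog.matrix * spectrum.total
    mask = expected > 0
    stat, p = chisquare(spectrum.counts[mask], expected[mask] * spectrum.counts[mask].sum() / expected[mask].sum())
    assert p > 0.01


def _toy_tree(trunk_variants, private_variants, regions=("R1", "R2")):
    variants = trunk_variants + private_variants
    assignments = [Assignment("truncal", frozenset(regions))] * len(trunk_variants)
    assignments += [Assignment("private", frozenset([regions[0]]))] * len(private_variants)
    return build_tree(variants, assignments, list(regions))


def test_branch_signatures_trunk_only_matches_global_fit(catalog, refmap):
    variants = draw_mutations(500, [0.6, 0.2, 0.1, 0, 0, 0.1], catalog,
                              refmap["chr1"], seed=5)
    tree = _toy_tree(variants, [])
    fits = branch_signatures(tree, refmap, catalog)
    global_fit = fit_exposures(build_spectrum(variants, refmap), catalog)
    assert fits["truncal"].fractions == pytest.approx(global_fit.fractions, abs=1e-12)
    assert fits["R1"] is None and fits["R2"] is None  # empty leaves: undefined fit


def test_branch_signatures_flags_small_branches(catalog, refmap):
    trunk = draw_mutations(200, [1, 0, 0, 0, 0, 0], catalog, refmap["chr1"], seed=6)
    private = draw_mutations(10, [0, 1, 0, 0, 0, 0], catalog, refmap["chr1"], seed=7)
    fits = branch_signatures(_toy_tree(trunk, private), refmap, catalog)
    assert not fits["truncal"].low_confidence
    assert fits["R1"].low_confidence


@pytest.mark.parametrize(
    "fraction, n, py, count, per_py",
    [
        (0.5, 40000, 20.0, 20000, 1000.0),
        (0.0, 500, 10.0, 0, 0.0),
    ],
)
def test_smoking_metrics_arithmetic(fraction, n, py, count, per_py):
    fit = _fit_with_fraction(fraction, n)
    metrics = smoking_metrics(fit, py)
    assert metrics.smoking_variant_count == count
    assert metrics.smoking_variants_per_py == pytest.approx(per_py)


def _fit_with_fraction(fraction, n):
    from tumorhet.signatures import ExposureFit

    fractions = np.array([fraction, 1 - fraction])
    return ExposureFit(
        signature_names=["tobacco-like", "clock-like"],
        exposures=fractions * n,
        fractions=fractions,
        residual_norm=0.0,
        n_mutations=n,
    )


def test_smoking_metrics_never_smoker_rate_undefined():
    metrics = smoking_metrics(_fit_with_fraction(0.4, 1000), 0)
    assert metrics.smoking_fraction == pytest.approx(0.4)
    assert metrics.smoking_variants_per_py is None
    with pytest.raises(ValueError):
        smoking_metrics(_fit_with_fraction(0.4, 1000), -5)


def test_bundled_catalog_matches_in_code_builder(catalog):
    built = make_synthetic_catalog()
    assert built.names == catalog.names
    assert np.abs(built.matrix - catalog.matrix).max() < 1e-7
    assert catalog.names[catalog.tobacco_index] == "tobacco-like"
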