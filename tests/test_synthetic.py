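"""Synthetic cohort generator: determinism, ground-truth conservation,
read-count model, reference/context machinery."""

import numpy as np
import pytest

from tumorhet.exceptions import ConfigError
from tumorhet.signatures import CHANNELS, build_spectrum
from tumorhet.synthetic import (
    GermlineConfig,
    SimConfig,
    assign_read_counts,
    draw_mutations,
    generate_reference,
    simulate_cohort,
    truncal_private_split,
    write_cohort,
)


def test_reference_length_and_determinism():
    ref_a = generate_reference(100_000, 0.41, seed=7)
    ref_b = generate_reference(100_000, 0.41, seed=7)
    assert len(ref_a) == 100_000
    assert ref_a == ref_b
    assert generate_reference(1000, 0.41, seed=8) != generate_reference(1000, 0.41, seed=9)


def test_reference_gc_boundary_and_min_length():
    assert set(generate_reference(5000, 1.0, seed=1)) == {"G", "C"}
    assert set(generate_reference(5000, 0.0, seed=1)) == {"A", "T"}
    with pytest.raises(ValueError):
        generate_reference(2, 0.5, seed=1)


def test_draw_mutations_empty_and_determinism(catalog, reference):
    assert draw_mutations(0, np.ones(6) / 6, catalog, reference, seed=1) == []
    a = draw_mutations(50, np.ones(6) / 6, catalog, reference, seed=5)
    b = draw_mutations(50, np.ones(6) / 6, catalog, reference, seed=5)
    assert [v.key for v in a] == [v.key for v in b]


def test_draw_mutations_one_hot_tobacco_is_all_c_to_a(catalog, reference, refmap):
    """The tobacco-like signature lives on C>A channels only, so every drawn
    variant must be C>A (or G>T on the purine strand)."""
    exposures = np.zeros(6)
    exposures[catalog.names.index("tobacco-like")] = 1.0
    variants = draw_mutations(300, exposures, catalog, reference, seed=9)
    assert len(variants) == 300
    for v in variants:
        assert (v.ref, v.alt) in {("C", "A"), ("G", "T")}
    spectrum = build_spectrum(variants, refmap)
    channel_classes = {CHANNELS[i][2:5] for i in np.nonzero(spectrum.counts)[0]}
    assert channel_classes == {"C>A"}
    assert spectrum.total == 300


def test_draw_mutations_contexts_match_reference(catalog, reference, refmap):
    """Every emitted variant sits on a reference trinucleotide compatible with
    its channel: rebuilding the spectrum raises no reference mismatch."""
    variants = draw_mutations(500, np.ones(6) / 6, catalog, reference, seed=3)
    spectrum = build_spectrum(variants, refmap)  # would raise on any mismatch
    assert spectrum.total == 500
    positions = [v.pos for v in variants]
    assert len(set(positions)) == len(positions)  # sampled without replacement


def test_assign_read_counts_no_signal_and_degenerate_depth():
    assert assign_read_counts(False, 100, 0.8, 1, 2, error_rate=0.0, seed=1)[0] == 0
    assert assign_read_counts(True, 0, 0.8, 1, 2, error_rate=0.0, seed=1) == (0, 0)
    with pytest.raises(ValueError):
        assign_read_counts(True, -5, 0.8, 1, 2, 0.0, seed=1)


def test_assign_read_counts_het_diploid_mean_vaf_is_half():
    rng = np.random.default_rng(11)
    vafs = []
    for _ in range(10_000):
        alt, total = assign_read_counts(
            True, 150, 1.0, 1, 2, error_rate=0.0, rng=rng
        )
        if total:
            vafs.append(alt / total)
    assert np.mean(vafs) == pytest.approx(0.5, abs=0.01)


@pytest.mark.parametrize(
    "n, fraction, regions, expected",
    [
        (100, 0.8, ["R1", "R2", "R3"], {"truncal": 80, "R1": 7, "R2": 7, "R3": 6}),
        (10, 1.0, ["R1", "R2"], {"truncal": 10, "R1": 0, "R2": 0}),
        (7, 0.5, ["R1", "R2"], {"truncal": 4, "R1": 2, "R2": 1}),  # half-up rounding
        (100, 0.3, ["R1"], {"truncal": 100}),  # single region: all truncal
    ],
)
def test_truncal_private_split_is_exact(n, fraction, regions, expected):
    assert truncal_private_split(n, fraction, regions) == expected


def _small_config(**kw):
    base = dict(n_patients=2, n_somatic=120, reference_length=50_000,
                n_germline_hets=20, seed=21)
    base.update(kw)
    return SimConfig(**base)


def test_cohort_truth_conservation_and_truncal_fraction():
    config = _small_config()
    cohort, truth, _ = simulate_cohort(config)
    for patient in cohort:
        rows = truth.variants[truth.variants["patient_id"] == patient.patient_id]
        assert len(rows) == config.n_somatic
        realized = (rows["branch"] == "truncal").mean()
        assert abs(realized - config.truncal_fraction) <= 1.0 / config.n_somatic
        assert len(patient.somatic) == config.n_somatic


def test_cohort_truncal_fraction_one_present_everywhere():
    cohort, truth, _ = simulate_cohort(_small_config(truncal_fraction=1.0))
    assert (truth.variants["branch"] == "truncal").all()


def test_cohort_single_region_all_truncal():
    cohort, truth, _ = simulate_cohort(_small_config(regions_per_patient=1))
    assert (truth.variants["branch"] == "truncal").all()


def test_cohort_serialization_is_byte_identical_under_fixed_seed(tmp_path):
    config = _small_config()
    for run in ("a", "b"):
        cohort, truth, refmap = simulate_cohort(config)
        write_cohort(cohort, truth, refmap, config, tmp_path / run)
    for rel in ("patients/P01/somatic.vcf", "patients/P01/germline.vcf",
                "metadata.tsv", "truth/truth_variants.tsv", "reference.fa"):
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes(), rel


def test_germline_injection_follows_probability_and_effect():
    config = _small_config(
        n_patients=6,
        germline=GermlineConfig(p_mutant=1.0, tobacco_fraction_mutant=0.6,
                                tobacco_fraction_wt=0.1, tobacco_fraction_sd=0.01),
    )
    cohort, truth, _ = simulate_cohort(config)
    assert truth.patients["germline_mutant"].all()
    assert (truth.patients["tobacco_fraction"] > 0.5).all()
    for patient in cohort:
        assert any(v.gene for v in patient.germline)  # repair variant injected

    config_wt = _small_config(n_patients=4, germline=GermlineConfig(p_mutant=0.0))
    _, truth_wt, _ = simulate_cohort(config_wt)
    assert not truth_wt.patients["germline_mutant"].any()


def test_branch_exposures_label_validation():
    with pytest.raises(ConfigError, match="labels"):
        SimConfig(
            n_patients=1,
            regions_per_patient=2,
            branch_exposures={"truncal": {"tobacco-like": 1.0}},
        )
    with pytest.raises(ConfigError, match="sum"):
        SimConfig(
            n_patients=1,
            regions_per_patient=1,
            branch_exposures={
                "truncal": {"tobacco-like": 0.5},
                "R1": {"apobec-like": 1.0},
            },
        )


def test_invalid_config_values_rejected():
    for kw in (
        {"truncal_fraction": 1.2},
        {"mean_depth": 0},
        {"cellularity": (0.0, 0.5)},
        {"regions_per_patient": 0},
        {"reference_length": 2},
    ):
        with pytest.raises(ConfigError):
            SimConfig(**kw)


def test_config_yaml_round_trip(tmp_path):
    config = _small_config(cellularity=(0.5, 0.7))
    path = tmp_path / "config.yaml"
    config.to_yaml(path)
    back = SimConfig.from_yaml(path)
    assert back.to_dict() == config.to_dict()
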