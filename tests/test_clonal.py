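"""Presence calling, truncal/shared/private partition, clone trees."""

import itertools

import pytest

from tumorhet.clonal import (
    ABSENT,
    PRESENT,
    TRUNCAL,
    UNKNOWN,
    Assignment,
    branch_mutation_counts,
    build_tree,
    call_presence,
    classify_pattern,
    partition_variants,
    to_newick,
)
from tumorhet.types import AnnotatedVariant


@pytest.mark.parametrize(
    "alt_reads, total_reads, expected",
    [
        (0, 150, ABSENT),
        (2, 150, ABSENT),   # below alt-read floor
        (8, 150, PRESENT),
        (7, 150, ABSENT),   # 7/150 < 5% VAF
        (8, 160, PRESENT),  # exactly 5% VAF counts as present
        (1, 5, UNKNOWN),    # below depth floor
        (0, 0, UNKNOWN),
    ],
)
def test_call_presence_rule(alt_reads, total_reads, expected):
    assert call_presence(alt_reads, total_reads) == expected


def test_call_presence_rejects_negative_counts():
    with pytest.raises(ValueError):
        call_presence(-1, 10)


def _expected_assignment(states, regions):
    """Independent statement of the partition rule for the oracle below."""
    present = [r for r, s in zip(regions, states) if s == PRESENT]
    absent = [r for r, s in zip(regions, states) if s == ABSENT]
    if not present:
        return None
    if not absent:
        return Assignment(TRUNCAL, frozenset(regions))
    if len(present) == 1:
        return Assignment("private", frozenset(present))
    return Assignment("shared", frozenset(present))


def test_partition_matches_exhaustive_three_region_enumeration():
    """All 27 presence/absence/unknown patterns over 3 regions classify as the
    stated rule demands (unknowns tolerated for truncal, precedence order)."""
    regions = ["R1", "R2", "R3"]
    for states in itertools.product([PRESENT, ABSENT, UNKNOWN], repeat=3):
        pattern = dict(zip(regions, states))
        assert classify_pattern(pattern, regions) == _expected_assignment(states, regions)


def _variant(pos, support):
    return AnnotatedVariant("chr1", pos, "C", "A", per_region_support=support)


def test_partition_variants_drops_absent_everywhere():
    regions = ["R1", "R2"]
    variants = [
        _variant(10, {"R1": (50, 100), "R2": (40, 100)}),
        _variant(20, {"R1": (0, 100), "R2": (0, 100)}),
    ]
    assignments, n_dropped = partition_variants(variants, regions)
    assert assignments[0].category == TRUNCAL
    assert assignments[1] is None
    assert n_dropped == 1


def _make_tree(subset_counts, regions):
    variants, assignments = [], []
    pos = 1
    all_regions = frozenset(regions)
    for subset, count in subset_counts.items():
        category = (
            TRUNCAL if subset == all_regions
            else "private" if len(subset) == 1
            else "shared"
        )
        for _ in range(count):
            variants.append(_variant(pos, {}))
            assignments.append(Assignment(category, subset))
            pos += 1
    return build_tree(variants, assignments, regions)


def test_star_tree_from_truncal_plus_privates():
    regions = ["R1", "R2", "R3"]
    tree = _make_tree(
        {
            frozenset(regions): 100,
            frozenset(["R1"]): 10,
            frozenset(["R2"]): 8,
            frozenset(["R3"]): 6,
        },
        regions,
    )
    assert tree.trunk.count == 100
    assert {c.label for c in tree.trunk.children} == {"R1", "R2", "R3"}
    counts = branch_mutation_counts(tree)
    assert sum(counts.values()) == 124


def test_nested_subsets_form_a_chain():
    regions = ["R1", "R2", "R3"]
    tree = _make_tree(
        {
            frozenset(regions): 50,
            frozenset(["R1", "R2"]): 20,
            frozenset(["R1"]): 5,
        },
        regions,
    )
    shared = tree.find("R1+R2")
    assert shared is not None
    assert {c.label for c in tree.trunk.children} == {"R1+R2", "R3"}
    # both private leaves nest inside the shared clade, not the trunk
    assert {c.label for c in shared.children} == {"R1", "R2"}


def test_conflicting_subsets_keep_higher_count_as_clade():
    """Overlapping non-nested patterns: the larger one stays a clade, the
    smaller attaches to the trunk (hand application of the greedy rule)."""
    regions = ["R1", "R2", "R3"]
    tree = _make_tree(
        {
            frozenset(regions): 50,
            frozenset(["R1", "R2"]): 50,
            frozenset(["R2", "R3"]): 10,
        },
        regions,
    )
    clade = tree.find("R1+R2")
    conflicted = tree.find("R2+R3")
    assert clade in tree.trunk.children
    assert conflicted in tree.trunk.children  # demoted to trunk attachment
    # R1 and R2 leaves nest under the kept clade; R3's under the trunk
    assert {c.label for c in clade.children} == {"R1", "R2"}
    counts = branch_mutation_counts(tree)
    assert sum(counts.values()) == 110


def test_empty_private_branches_reported_as_zero():
    regions = ["R1", "R2"]
    tree = _make_tree({frozenset(regions): 30}, regions)
    counts = branch_mutation_counts(tree)
    assert counts["R1"] == 0 and counts["R2"] == 0
    assert counts[TRUNCAL] == 30


def test_region_permutation_changes_labels_not_counts():
    base = {
        frozenset(["R1", "R2", "R3"]): 40,
        frozenset(["R1", "R2"]): 12,
        frozenset(["R3"]): 7,
    }
    counts_a = branch_mutation_counts(_make_tree(base, ["R1", "R2", "R3"]))
    counts_b = branch_mutation_counts(_make_tree(base, ["R3", "R2", "R1"]))
    assert sorted(counts_a.values()) == sorted(counts_b.values())


def test_newick_export_contains_all_branches_with_counts():
    regions = ["R1", "R2"]
    tree = _make_tree(
        {frozenset(regions): 10, frozenset(["R1"]): 3, frozenset(["R2"]): 2}, regions
    )
    newick = to_newick(tree)
    assert newick.endswith(";")
    assert "truncal:10" in newick
    assert "R1:3" in newick and "R2:2" in newick


def test_single_region_patient_is_all_truncal():
    regions = ["R1"]
    variants = [_variant(i + 1, {"R1": (40, 100)}) for i in range(5)]
    assignments, n_dropped = partition_variants(variants, regions)
    assert n_dropped == 0
    assert all(a.category == TRUNCAL for a in assignments)
    tree = build_tree(variants, assignments, regions)
    assert tree.trunk.count == 5
    assert tree.trunk.children == []
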