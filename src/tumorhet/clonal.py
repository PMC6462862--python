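"""Truncal/shared/private partition and clone-tree reconstruction.

Each somatic variant gets a per-region presence pattern from its read
support.  Variants present in every region (absences forbidden, unknowns
tolerated) are truncal and define the last common ancestor; variants present
in exactly one region are private; the rest are shared by a region subset.
Distinct presence subsets are assembled into a perfect phylogeny: every
subset attaches to its smallest observed strict superset (the trunk carries
the all-regions set).  Incompatible subset pairs — overlapping but
non-nested, which a perfect phylogeny cannot host — are resolved greedily:
the higher-count pattern is kept as a clade and the other attaches directly
to the trunk.

Clustering is by presence pattern only; VAF is not used for subclonal
deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .types import AnnotatedVariant

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"

TRUNCAL = "truncal"
SHARED = "shared"
PRIVATE = "private"


def call_presence(
    alt_reads: int,
    total_reads: int,
    min_depth: int = 10,
    min_alt: int = 3,
    min_vaf: float = 0.05,
) -> str:
    """Presence call for one variant in one region.

    Unknown below the depth floor; present when both the alt-read count and
    the VAF clear their thresholds; absent otherwise.  Defaults are
    conservative for ~150x coverage.
    """
    if alt_reads < 0 or total_reads < 0:
        raise ValueError("read counts must be non-negative")
    if alt_reads > total_reads:
        raise ValueError("alt reads exceed total reads")
    if total_reads < min_depth:
        return UNKNOWN
    if alt_reads >= min_alt and alt_reads / total_reads >= min_vaf:
        return PRESENT
    return ABSENT


@dataclass(frozen=True)
class Assignment:
    category: str  # truncal | shared | private
    regions: frozenset[str]  # regions whose branch carries the variant


def presence_pattern(
    variant: AnnotatedVariant, region_ids: Sequence[str], **thresholds
) -> dict[str, str]:
    """Per-region presence states for one variant (missing support = unknown)."""
    pattern = {}
    for region in region_ids:
        support = variant.per_region_support.get(region)
        if support is None:
            pattern[region] = UNKNOWN
        else:
            pattern[region] = call_presence(*support, **thresholds)
    return pattern


def classify_pattern(pattern: dict[str, str], region_ids: Sequence[str]) -> Optional[Assignment]:
    """Apply the truncal/private/shared rule to one presence pattern.

    Returns None when the variant is present nowhere (dropped).  Rule order
    matters: truncal (no absences, at least one presence) takes precedence,
    then private (exactly one presence), then shared.
    """
    present = [r for r in region_ids if pattern[r] == PRESENT]
    absent = [r for r in region_ids if pattern[r] == ABSENT]
    if not present:
        return None
    if not absent:
        return Assignment(TRUNCAL, frozenset(region_ids))
    if len(present) == 1:
        return Assignment(PRIVATE, frozenset(present))
    return Assignment(SHARED, frozenset(present))


def partition_variants(
    variants: Sequence[AnnotatedVariant],
    region_ids: Sequence[str],
    **thresholds,
) -> tuple[list[Optional[Assignment]], int]:
    """Classify every variant; returns (assignments, n_dropped).

    ``assignments`` is parallel to ``variants``; entries are None for
    variants present in no region (these are dropped downstream and only
    counted).
    """
    if not region_ids:
        raise ValueError("at least one region is required")
    assignments: list[Optional[Assignment]] = []
    n_dropped = 0
    for v in variants:
        assignment = classify_pattern(presence_pattern(v, region_ids, **thresholds), region_ids)
        if assignment is None:
            n_dropped += 1
        assignments.append(assignment)
    return assignments, n_dropped


# ---------------------------------------------------------------------------
# Clone tree
# ---------------------------------------------------------------------------

@dataclass
class CladeNode:
    label: str
    regions: frozenset[str]
    variants: list[AnnotatedVariant] = field(default_factory=list)
    children: list["CladeNode"] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.variants)


@dataclass
class CladeTree:
    """Root (germline, zero mutations) -> trunk (last common ancestor) -> clades."""

    root: CladeNode
    region_ids: list[str]

    @property
    def trunk(self) -> CladeNode:
        return self.root.children[0]

    def iter_nodes(self) -> Iterator[CladeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def find(self, label: str) -> Optional[CladeNode]:
        for node in self.iter_nodes():
            if node.label == label:
                return node
        return None


def _subset_label(regions: frozenset[str], all_regions: frozenset[str]) -> str:
    if regions == all_regions:
        return TRUNCAL
    return "+".join(sorted(regions))


def build_tree(
    variants: Sequence[AnnotatedVariant],
    assignments: Sequence[Optional[Assignment]],
    region_ids: Sequence[str],
) -> CladeTree:
    """Perfect phylogeny over the observed presence subsets.

    Subsets are admitted in decreasing mutation count (ties broken by the
    lexicographic sorted-region label) and attach to the smallest accepted
    strict superset, defaulting to the trunk.  A subset that overlaps an
    accepted clade without nesting attaches directly to the trunk and is not
    used as a parent for later subsets.  Every region gets a private leaf,
    reported with count 0 when no private variant was observed.
    """
    all_regions = frozenset(region_ids)
    groups: dict[frozenset[str], list[AnnotatedVariant]] = {}
    for v, a in zip(variants, assignments):
        if a is None:
            continue
        groups.setdefault(a.regions, []).append(v)

    trunk = CladeNode(TRUNCAL, all_regions, groups.pop(all_regions, []))
    root = CladeNode("germline", frozenset())
    root.children.append(trunk)

    order = sorted(
        groups,
        key=lambda s: (-len(groups[s]), sorted(s)),
    )
    accepted: list[CladeNode] = [trunk]
    nodes: dict[frozenset[str], CladeNode] = {all_regions: trunk}
    for subset in order:
        node = CladeNode(_subset_label(subset, all_regions), subset, groups[subset])
        conflicts = [
            a for a in accepted
            if (subset & a.regions) and not (subset <= a.regions or a.regions <= subset)
        ]
        if conflicts:
            trunk.children.append(node)
        else:
            supersets = [a for a in accepted if subset < a.regions]
            parent = min(supersets, key=lambda a: (len(a.regions), sorted(a.regions)))
            parent.children.append(node)
            accepted.append(node)
        nodes[subset] = node

    # guarantee a private leaf per region, count 0 when unobserved
    for region in region_ids:
        singleton = frozenset([region])
        if singleton not in nodes:
            supersets = [a for a in accepted if singleton < a.regions]
            parent = min(supersets, key=lambda a: (len(a.regions), sorted(a.regions)))
            leaf = CladeNode(region, singleton)
            parent.children.append(leaf)
            nodes[singleton] = leaf

    for node in nodes.values():
        node.children.sort(key=lambda n: (len(n.regions), sorted(n.regions)))
    return CladeTree(root=root, region_ids=list(region_ids))


def branch_mutation_counts(tree: CladeTree) -> dict[str, int]:
    """Mutation count per branch (root excluded); empty branches report 0."""
    return {
        node.label: node.count
        for node in tree.iter_nodes()
        if node.label != "germline"
    }


def to_newick(tree: CladeTree) -> str:
    """Newick export with branch lengths equal to mutation counts."""

    def render(node: CladeNode) -> str:
        if not node.children:
            return f"{node.label}:{node.count}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){node.label}:{node.count}"

    return render(tree.root) + ";"


def to_edge_rows(tree: CladeTree) -> list[dict]:
    """Edge list (parent, child, mutation count, region subset) for TSV export."""
    rows = []

    def walk(node: CladeNode) -> None:
        for child in node.children:
            rows.append(
                {
                    "parent": node.label,
                    "child": child.label,
                    "mutations": child.count,
                    "regions": ",".join(sorted(child.regions)),
                }
            )
            walk(child)

    walk(tree.root)
    return rows
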