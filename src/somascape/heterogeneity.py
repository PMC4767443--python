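"""Multi-region intra-tumor heterogeneity: presence matrix, common/shared/private
classification, Venn counts and a clonal-ordering tree.

A mutation detected in every sampled region of a tumor is "common" (trunk), one
detected in a proper subset of two or more regions is "shared", and one seen in
exactly one region is "private".  Clonal ordering places each region-subset's
mutation set on a tree nested by subset inclusion, trunk first; subsets that are
neither nested nor disjoint cannot coexist on a tree and are reported as
conflicts (resolved greedily by descending mutation count, ties by subset
label), never fatally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

VariantKey = tuple[str, int, str, str]


def build_presence(
    region_calls: dict[str, pd.DataFrame],
    evidence: dict[str, pd.DataFrame] | None = None,
    rescue_alt: int = 0,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Mutations x regions boolean presence matrix from per-region call sets.

    Rows are the union of accepted calls over regions, keyed by
    (chrom, pos, ref, alt).  A mutation is present in a region if it was called
    there, or — when ``rescue_alt`` > 0 and per-region ``evidence`` tables
    (t_alt, depth columns alongside the key) are supplied — if the region shows
    at least ``rescue_alt`` supporting reads at depth >= ``min_depth``; the
    rescue guards against depth-driven false privacy and is off by default.
    """
    if len(region_calls) < 2:
        raise ValueError("need call sets from at least 2 regions")
    keys_by_region: dict[str, set[VariantKey]] = {}
    for region, calls in region_calls.items():
        keys = list(zip(calls["chrom"], calls["pos"], calls["ref"], calls["alt"]))
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate variant keys within region {region}")
        keys_by_region[region] = set(keys)
    all_keys = sorted(set().union(*keys_by_region.values()))
    regions = sorted(region_calls)
    rescue: dict[str, set[VariantKey]] = {r: set() for r in regions}
    if rescue_alt > 0 and evidence:
        for region, ev in evidence.items():
            for _, row in ev.iterrows():
                depth = row["t_alt"] + row.get("t_ref", 0)
                if "depth" in ev.columns:
                    depth = row["depth"]
                if row["t_alt"] >= rescue_alt and depth >= min_depth:
                    rescue[region].add((row["chrom"], row["pos"], row["ref"], row["alt"]))
    data = {
        region: [k in keys_by_region[region] or k in rescue.get(region, set()) for k in all_keys]
        for region in regions
    }
    idx = pd.MultiIndex.from_tuples(all_keys, names=["chrom", "pos", "ref", "alt"])
    return pd.DataFrame(data, index=idx)


def classify(matrix: pd.DataFrame) -> tuple[pd.Series, dict[str, int]]:
    """Label each mutation common/shared/private; return labels and counts."""
    _check_matrix(matrix)
    n_regions = matrix.shape[1]
    row_sums = matrix.sum(axis=1)
    labels = pd.Series("shared", index=matrix.index, name="label")
    labels[row_sums == n_regions] = "common"
    labels[row_sums == 1] = "private"
    counts = {
        "common": int((labels == "common").sum()),
        "shared": int((labels == "shared").sum()),
        "private": int((labels == "private").sum()),
    }
    assert sum(counts.values()) == len(matrix)
    return labels, counts


def percent_common(matrix: pd.DataFrame) -> int:
    """Whole-percent share of mutations present in all regions."""
    _, counts = classify(matrix)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty presence matrix")
    return round(100.0 * counts["common"] / total)


def venn_counts(matrix: pd.DataFrame) -> dict[frozenset, int]:
    """Mutation count per nonempty region subset (all 2^R - 1 cells)."""
    _check_matrix(matrix)
    regions = list(matrix.columns)
    counts = {}
    for r in range(1, len(regions) + 1):
        for combo in combinations(regions, r):
            counts[frozenset(combo)] = 0
    for _, row in matrix.iterrows():
        present = frozenset(c for c in regions if row[c])
        counts[present] += 1
    assert sum(counts.values()) == len(matrix)
    return counts


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[1] < 2:
        raise ValueError("presence matrix needs >= 2 regions")
    if len(matrix) and not matrix.any(axis=1).all():
        raise ValueError("presence matrix has an all-false row")


@dataclass
class CladeNode:
    """One branch of the clonal-ordering tree: a region subset and its mutations."""

    regions: frozenset
    count: int
    children: list["CladeNode"] = field(default_factory=list)


@dataclass
class CladeTree:
    """Clonal-ordering tree; the root branch is the trunk (common mutations)."""

    root: CladeNode
    conflicts: list[tuple[frozenset, frozenset]]

    def branch_lengths(self) -> dict[frozenset, int]:
        out = {}

        def walk(node: CladeNode) -> None:
            out[node.regions] = node.count
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def total_mutations(self) -> int:
        return sum(self.branch_lengths().values())

    def newick(self) -> str:
        def render(node: CladeNode) -> str:
            if not node.children:
                name = "|".join(sorted(node.regions)) if len(node.regions) == 1 else ""
                return f"{name}:{node.count}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}):{node.count}"

        return render(self.root) + ";"


def clonal_ordering_tree(matrix: pd.DataFrame) -> CladeTree:
    """Perfect-phylogeny-style clonal ordering of a presence matrix.

    The trunk holds the common mutations; every observed proper subset with at
    least one mutation becomes a branch nested by subset inclusion under the
    deepest placed superset.  Each region gets a terminal branch (length zero
    when it has no private mutations), so the leaf set equals the region set
    and branch lengths sum to the mutation total.  Subset pairs that overlap
    without nesting are recorded as conflicts; placement is greedy by
    descending count, ties broken by sorted subset label.
    """
    _check_matrix(matrix)
    regions = list(matrix.columns)
    full = frozenset(regions)
    subset_counts: dict[frozenset, int] = {}
    for _, row in matrix.iterrows():
        present = frozenset(c for c in regions if row[c])
        subset_counts[present] = subset_counts.get(present, 0) + 1
    root = CladeNode(full, subset_counts.get(full, 0))
    placed: list[CladeNode] = [root]
    conflicts: list[tuple[frozenset, frozenset]] = []
    for region in regions:  # every region ends as a leaf, even with no privates
        subset_counts.setdefault(frozenset([region]), 0)
    proper = [s for s in subset_counts if s != full]
    # supersets first so nesting is available; among equal sizes the greedy
    # priority is descending mutation count, ties by sorted subset label
    proper.sort(key=lambda s: (-len(s), -subset_counts[s], sorted(s)))
    for s in proper:
        supersets = [n for n in placed if s < n.regions]
        parent = min(supersets, key=lambda n: (len(n.regions), sorted(n.regions)))
        for sib in parent.children:
            inter = s & sib.regions
            if inter and not (s <= sib.regions or sib.regions <= s):
                conflicts.append((sib.regions, s))
        node = CladeNode(s, subset_counts[s])
        parent.children.append(node)
        placed.append(node)
    return CladeTree(root, conflicts)
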