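"""Topology agreement across bootstrapped gene trees and between symbiont and
host phylogenies.

Sister-pair tallies follow the cherry semantics: an unordered leaf pair is a
supported sister pair in a tree when an internal node with bootstrap support
strictly above the threshold subtends exactly those two leaves; larger
clades never create pairs.  Group monophyly likewise requires a supported
node whose leaf set equals the group (as the trees are written).
Symbiont/host congruence is the unrooted Robinson-Foulds distance after
mapping host leaves onto symbiont leaves.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from .core_io import get_support

__all__ = [
    "SisterSupportTally",
    "MonophylyReport",
    "CongruenceResult",
    "supported_sister_pairs",
    "tally_sister_support",
    "monophyly_support",
    "host_congruence",
    "tally_to_dot",
]

Pair = frozenset


@dataclass
class SisterSupportTally:
    """Counts of supported sister pairs across a set of gene trees."""

    taxa: list[str]
    counts: pd.DataFrame  # symmetric taxa x taxa integer matrix
    n_trees: int
    rare_pairs: list[tuple[str, str]]  # 0 < count < rare_fraction * n_trees
    effective_n: pd.DataFrame  # trees containing both taxa of a pair
    threshold: float
    rare_fraction: float


@dataclass
class MonophylyReport:
    groups: dict[str, set[str]]
    per_tree: pd.DataFrame  # one boolean column per group + "all_groups"
    n_support: int
    n_trees: int
    threshold: float


@dataclass
class CongruenceResult:
    shared_bipartitions: int
    rf_distance: int
    normalized_rf: float
    n_shared_leaves: int
    leaf_mapping: pd.DataFrame


def _supported_clades(
    tree: dendropy.Tree, threshold: float
) -> list[frozenset]:
    """Leaf sets of internal nodes with support strictly above threshold."""
    out = []
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        support = get_support(node)
        if support is None or not support > threshold:
            continue
        out.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out


def supported_sister_pairs(
    tree: dendropy.Tree, threshold: float = 95.0
) -> set[Pair]:
    """Unordered leaf pairs forming supported cherries.

    A pair qualifies when an internal node with support strictly above
    ``threshold`` subtends exactly those two leaves; larger clades do not
    create pairs and missing supports never qualify.
    """
    return {
        Pair(clade)
        for clade in _supported_clades(tree, threshold)
        if len(clade) == 2
    }


def tally_sister_support(
    treeset: Sequence[dendropy.Tree],
    threshold: float = 95.0,
    rare_fraction: float = 0.01,
    taxa: Sequence[str] | None = None,
) -> SisterSupportTally:
    """Count, over all trees, how often each pair is a supported cherry.

    The denominator stays the full number of trees; ``effective_n`` records
    for each pair how many trees contained both taxa.
    """
    trees = list(treeset)
    if not trees:
        raise ValueError("empty tree set")
    pair_counts: Counter = Counter()
    cooccur: Counter = Counter()
    seen: set[str] = set()
    for tree in trees:
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        seen |= leaves
        leaf_list = sorted(leaves)
        for i, a in enumerate(leaf_list):
            for b in leaf_list[i + 1:]:
                cooccur[Pair((a, b))] += 1
        for pair in supported_sister_pairs(tree, threshold):
            pair_counts[pair] += 1
    taxa_list = sorted(taxa) if taxa is not None else sorted(seen)
    counts = pd.DataFrame(0, index=taxa_list, columns=taxa_list, dtype=int)
    eff = pd.DataFrame(0, index=taxa_list, columns=taxa_list, dtype=int)
    for pair, n in pair_counts.items():
        a, b = sorted(pair)
        counts.loc[a, b] = counts.loc[b, a] = n
    for pair, n in cooccur.items():
        a, b = sorted(pair)
        eff.loc[a, b] = eff.loc[b, a] = n
    n_trees = len(trees)
    rare = sorted(
        tuple(sorted(p))
        for p, n in pair_counts.items()
        if 0 < n < rare_fraction * n_trees
    )
    return SisterSupportTally(
        taxa=taxa_list,
        counts=counts,
        n_trees=n_trees,
        rare_pairs=rare,
        effective_n=eff,
        threshold=threshold,
        rare_fraction=rare_fraction,
    )


def monophyly_support(
    treeset: Sequence[dendropy.Tree],
    groups: Mapping[str, set[str]],
    threshold: float = 95.0,
) -> MonophylyReport:
    """Per tree: does every group form a supported clade?

    A group with >= 2 members present in a tree must be the exact leaf set of
    an internal node with support strictly above the threshold; groups with
    <= 1 present member are vacuously monophyletic.  Overlapping groups are
    an error.
    """
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap = groups[a] & groups[b]
            if overlap:
                raise ValueError(
                    f"groups {a!r} and {b!r} overlap: {sorted(overlap)}"
                )
    trees = list(treeset)
    if not trees:
        raise ValueError("empty tree set")
    rows = []
    for tree in trees:
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        supported_sets = set(_supported_clades(tree, threshold))
        row = {}
        for name in names:
            present = frozenset(groups[name] & leaves)
            row[name] = len(present) <= 1 or present in supported_sets
        row["all_groups"] = all(row[name] for name in names)
        rows.append(row)
    per_tree = pd.DataFrame(rows)
    return MonophylyReport(
        groups={k: set(v) for k, v in groups.items()},
        per_tree=per_tree,
        n_support=int(per_tree["all_groups"].sum()),
        n_trees=len(trees),
        threshold=threshold,
    )


def _nontrivial_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    bips = set()
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(side) <= len(all_leaves) - 2:
            bips.add(min(side, all_leaves - side, key=sorted))
    return bips


def host_congruence(
    bact_tree: dendropy.Tree,
    host_tree: dendropy.Tree,
    mapping: Mapping[str, str],
) -> CongruenceResult:
    """Unrooted Robinson-Foulds congruence between symbiont and host trees.

    ``mapping`` sends bacterial leaf labels to host leaf labels and must be
    injective on the shared leaves.  Both trees are restricted to the mapped
    leaves; the RF distance is normalised by 2(n-3), its maximum for n
    shared leaves.
    """
    bact_leaves = {lf.taxon.label for lf in bact_tree.leaf_node_iter()}
    host_leaves = {lf.taxon.label for lf in host_tree.leaf_node_iter()}
    usable = {
        b: h for b, h in mapping.items() if b in bact_leaves and h in host_leaves
    }
    if len(set(usable.values())) != len(usable):
        raise ValueError("mapping is not injective on shared leaves")
    if len(usable) < 4:
        raise ValueError(f"need >= 4 mapped leaves, got {len(usable)}")

    inverse = {h: b for b, h in usable.items()}
    bact = bact_tree.extract_tree_with_taxa_labels(list(usable))
    host = host_tree.extract_tree_with_taxa_labels(list(usable.values()))
    for leaf in host.leaf_node_iter():
        leaf.taxon.label = inverse[leaf.taxon.label]

    bip_a = _nontrivial_bipartitions(bact)
    bip_b = _nontrivial_bipartitions(host)
    shared = len(bip_a & bip_b)
    rf = len(bip_a - bip_b) + len(bip_b - bip_a)
    n = len(usable)
    max_rf = 2 * (n - 3)
    return CongruenceResult(
        shared_bipartitions=shared,
        rf_distance=rf,
        normalized_rf=rf / max_rf if max_rf > 0 else 0.0,
        n_shared_leaves=n,
        leaf_mapping=pd.DataFrame(
            sorted(usable.items()), columns=["bacterial_leaf", "host_leaf"]
        ),
    )


def tally_to_dot(tally: SisterSupportTally) -> str:
    """Graphviz DOT rendering of the pair-support graph (dotted = rare)."""
    lines = ["graph sister_pairs {"]
    rare = {tuple(sorted(p)) for p in tally.rare_pairs}
    for i, a in enumerate(tally.taxa):
        for b in tally.taxa[i + 1:]:
            n = int(tally.counts.loc[a, b])
            if n == 0:
                continue
            style = "dotted" if (a, b) in rare else "solid"
            lines.append(f'  "{a}" -- "{b}" [label="{n}", style={style}];')
    lines.append("}")
    return "\n".join(lines)
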