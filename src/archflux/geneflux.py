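"""Ancestral gene-content flux by generalized (Sankoff) parsimony.

Given a rooted species tree and a families x taxa ortholog copy-number
matrix, each family's ancestral copy number is reconstructed by dynamic
programming over the states {0..max_copies} under an asymmetric event-cost
scheme: acquiring an ortholog is expensive (default 10), losing it cheaper
(5), the first duplication costs 1 and every further copy-number step 0.2.
The asymmetry makes independent losses cheaper to infer than independent
gains, the standard assumption for reductive genome evolution.

By default the root state is free, as in standard ancestral-state parsimony:
a family present on both sides of the root is simply ancestral.  The
alternative convention that charges presence at the root as an acquisition
on a root stem (``charge_root=True``) is available, but note that under the
default costs it makes a clade-wide loss (origination 10 + loss 5) dearer
than an independent re-gain in the sister clade (10), which systematically
relabels reductive flux as parallel gains — keep it off when quantifying
genome reduction.  Among co-optimal state assignments a deterministic
rootward tie-break is applied:
a child keeps its parent's state whenever that is co-optimal, remaining ties
resolve to the higher copy number (at the root likewise), which places
changes as early as possible without sacrificing optimality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .core_io import OrthologMatrix

__all__ = [
    "CostScheme",
    "EventReconstruction",
    "FluxSummary",
    "transition_cost",
    "cost_matrix",
    "node_id_map",
    "sankoff_reconstruct",
    "flux_summary",
    "clade_unique_families",
]

_EPS = 1e-9


@dataclass(frozen=True)
class CostScheme:
    """Event costs for gene-content transitions along one branch."""

    gain: float = 10.0
    loss: float = 5.0
    first_dup: float = 1.0
    copy_step: float = 0.2
    max_copies: int = 8

    def __post_init__(self) -> None:
        if min(self.gain, self.loss, self.first_dup, self.copy_step) < 0:
            raise ValueError("costs must be non-negative")
        if self.max_copies < 1:
            raise ValueError("max_copies must be >= 1")


def transition_cost(a: int, b: int, costs: CostScheme = CostScheme()) -> float:
    """Cost of the composite copy-number change a -> b along one branch.

    c(a,a) = 0; a gain from absence costs ``gain`` plus the expansion from one
    copy (first_dup + (b-2)*copy_step for b >= 2); any loss to absence costs
    the flat ``loss``; 1 -> b>=2 costs first_dup + (b-2)*copy_step; all other
    copy-number variations cost copy_step per copy changed (contractions
    included, symmetric).
    """
    K = costs.max_copies
    if not (0 <= a <= K and 0 <= b <= K):
        raise ValueError(f"states must lie in [0, {K}]")
    if a == b:
        return 0.0
    if a == 0:  # acquisition, then expansion from a single copy
        return costs.gain + (0.0 if b == 1 else costs.first_dup + (b - 2) * costs.copy_step)
    if b == 0:
        return costs.loss
    if a == 1 and b >= 2:  # the first duplication, then per-copy steps
        return costs.first_dup + (b - 2) * costs.copy_step
    return abs(a - b) * costs.copy_step


def cost_matrix(costs: CostScheme, presence_absence: bool = False) -> np.ndarray:
    """(K+1) x (K+1) transition-cost table; K=1 in presence/absence mode."""
    K = 1 if presence_absence else costs.max_copies
    C = np.zeros((K + 1, K + 1))
    for a in range(K + 1):
        for b in range(K + 1):
            if presence_absence:
                C[a, b] = 0.0 if a == b else (costs.gain if a == 0 else costs.loss)
            else:
                C[a, b] = transition_cost(a, b, costs)
    return C


@dataclass
class EventReconstruction:
    """Ancestral states and per-branch events for every family.

    ``states`` is a families x nodes DataFrame of copy numbers; ``events``
    lists one row per (branch, family) change with the event type and copy
    delta; ``totals`` aggregates gains/losses/expansions/contractions and the
    family count at the branch's child node.  Branches are identified by
    their child node (leaves by taxon label, internal nodes by a
    deterministic preorder id, the root stem by the root's id).
    """

    tree: dendropy.Tree
    states: pd.DataFrame
    events: pd.DataFrame
    totals: pd.DataFrame
    total_cost: float
    per_family_cost: pd.Series
    mode: str = "copy_number"
    root_id: str = "N0"


@dataclass
class FluxSummary:
    """Per-branch flux with branch-length-normalised loss rates."""

    per_branch: pd.DataFrame
    focal_branch: str | None = None
    fold_vs_background: tuple[float, float] | None = None  # (vs max, vs min)
    warnings: list[str] = field(default_factory=list)


def node_id_map(tree: dendropy.Tree) -> dict[dendropy.Node, str]:
    """Stable node ids: leaf = taxon label, internal = preorder N0, N1, ...

    Branches are named after their child node throughout the package, so the
    same convention lets simulated event logs and reconstructions be joined.
    """
    counter = 0
    ids: dict[dendropy.Node, str] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        else:
            ids[node] = f"N{counter}"
            counter += 1
    return ids


def _index_tree(tree: dendropy.Tree) -> tuple[list[dendropy.Node], dict]:
    ids = {id(n): label for n, label in node_id_map(tree).items()}
    post = list(tree.postorder_node_iter())
    return post, ids


def sankoff_reconstruct(
    matrix: OrthologMatrix,
    tree: dendropy.Tree,
    costs: CostScheme = CostScheme(),
    presence_absence: bool = False,
    charge_root: bool = False,
) -> EventReconstruction:
    """Minimum-cost ancestral copy numbers for every family on a rooted tree.

    Bottom-up Sankoff dynamic program over states {0..max_copies} with
    :func:`transition_cost`, followed by a top-down back-pass with the
    rootward tie-break.  ``presence_absence=True`` collapses counts to {0,1}
    and uses gain/loss costs only.  ``charge_root=True`` adds the origination
    cost c(0, root_state) and reports it as a gain on the root stem.
    """
    root = tree.seed_node
    if len(root.child_nodes()) != 2:
        raise ValueError(
            "tree looks unrooted: the root must have exactly 2 children"
        )
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(matrix.taxa) - leaf_labels
    if missing:
        raise ValueError(f"matrix taxa absent from tree: {sorted(missing)}")
    absent_leaves = leaf_labels - set(matrix.taxa)
    if absent_leaves:
        warnings.warn(
            f"tree leaves without matrix counts treated as 0 copies: "
            f"{sorted(absent_leaves)}",
            stacklevel=2,
        )

    families = sorted(matrix.families)
    F = len(families)
    C = cost_matrix(costs, presence_absence)
    K = C.shape[0] - 1

    counts = matrix.counts.loc[families]
    if (counts.to_numpy() > K).any():
        warnings.warn(f"copy counts above {K} clipped", stacklevel=2)
    leaf_state = {
        taxon: np.minimum(counts[taxon].to_numpy(), K) for taxon in matrix.taxa
    }
    for taxon in absent_leaves:
        leaf_state[taxon] = np.zeros(F, dtype=int)
    if presence_absence:
        leaf_state = {t: (s > 0).astype(int) for t, s in leaf_state.items()}

    post, ids = _index_tree(tree)

    # bottom-up: per-node (F, K+1) cost tables
    node_cost: dict[int, np.ndarray] = {}
    for node in post:
        if node.is_leaf():
            table = np.full((F, K + 1), np.inf)
            table[np.arange(F), leaf_state[node.taxon.label]] = 0.0
        else:
            table = np.zeros((F, K + 1))
            for child in node.child_nodes():
                # min over child state s' of child_cost[f, s'] + C[s, s']
                table += (node_cost[id(child)][:, None, :] + C[None, :, :]).min(axis=2)
        node_cost[id(node)] = table

    root_table = node_cost[id(root)]
    if charge_root:
        root_table = root_table + C[0][None, :]
    per_family_cost = root_table.min(axis=1)

    def _pick(cand: np.ndarray, prefer: np.ndarray | None) -> np.ndarray:
        """Argmin per row; prefer the given state if co-optimal, else the
        highest co-optimal state."""
        best = cand.min(axis=1)
        highest = K - np.argmin(cand[:, ::-1], axis=1)  # last (highest) argmin
        if prefer is None:
            return highest
        keep = cand[np.arange(len(cand)), prefer] <= best + _EPS
        return np.where(keep, prefer, highest)

    # top-down back-pass
    state_of: dict[int, np.ndarray] = {}
    state_of[id(root)] = _pick(root_table, None)
    for node in tree.preorder_node_iter():
        p_state = state_of[id(node)]
        for child in node.child_nodes():
            cand = node_cost[id(child)] + C[p_state, :]
            state_of[id(child)] = _pick(cand, p_state)

    states = pd.DataFrame(
        {ids[id(node)]: state_of[id(node)] for node in tree.preorder_node_iter()},
        index=pd.Index(families, name="family"),
    )

    # events per branch (branch = its child node; root stem = root id)
    event_rows: list[dict] = []
    totals_rows: list[dict] = []

    def _emit(branch_id: str, parent: np.ndarray, child: np.ndarray,
              branch_length: float | None, is_internal: bool) -> None:
        delta = child.astype(int) - parent.astype(int)
        gains = (parent == 0) & (child > 0)
        losses = (parent > 0) & (child == 0)
        expans = (parent > 0) & (child > parent)
        contr = (parent > child) & (child > 0)
        for mask, etype in ((gains, "gain"), (losses, "loss"),
                            (expans, "expansion"), (contr, "contraction")):
            for f_idx in np.nonzero(mask)[0]:
                event_rows.append(
                    {
                        "branch": branch_id,
                        "family": families[f_idx],
                        "type": etype,
                        "delta": int(delta[f_idx]),
                    }
                )
        totals_rows.append(
            {
                "branch": branch_id,
                "gains": int(gains.sum()),
                "losses": int(losses.sum()),
                "expansions": int(expans.sum()),
                "contractions": int(contr.sum()),
                "families_at_child": int((child > 0).sum()),
                "branch_length": np.nan if branch_length is None else branch_length,
                "is_internal": is_internal,
            }
        )

    root_state = state_of[id(root)]
    if charge_root:
        _emit(ids[id(root)], np.zeros(F, dtype=int), root_state, None, True)
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            _emit(
                ids[id(child)],
                state_of[id(node)],
                state_of[id(child)],
                child.edge.length,
                not child.is_leaf(),
            )

    events = pd.DataFrame(event_rows, columns=["branch", "family", "type", "delta"])
    totals = pd.DataFrame(
        totals_rows,
        columns=["branch", "gains", "losses", "expansions", "contractions",
                 "families_at_child", "branch_length", "is_internal"],
    ).set_index("branch")

    return EventReconstruction(
        tree=tree,
        states=states,
        events=events,
        totals=totals,
        total_cost=float(per_family_cost.sum()),
        per_family_cost=pd.Series(per_family_cost, index=states.index),
        mode="presence_absence" if presence_absence else "copy_number",
        root_id=ids[id(root)],
    )


def flux_summary(
    recon: EventReconstruction,
    focal_branch: str | None = None,
) -> FluxSummary:
    """Per-branch gains/losses/family totals with loss rates per unit length.

    ``loss_rate = losses / branch_length`` where a length is present.  For a
    designated focal branch the loss-rate excess over the other *internal*
    branches is reported as a (fold vs max background, fold vs min background)
    range.
    """
    per_branch = recon.totals.copy()
    notes: list[str] = []
    has_len = per_branch["branch_length"].notna() & (per_branch["branch_length"] > 0)
    if not has_len.all():
        notes.append(
            "branches without positive lengths have no loss_rate: "
            + ", ".join(per_branch.index[~has_len])
        )
    per_branch["loss_rate"] = np.where(
        has_len, per_branch["losses"] / per_branch["branch_length"], np.nan
    )

    fold = None
    if focal_branch is not None:
        if focal_branch not in per_branch.index:
            raise KeyError(f"unknown branch {focal_branch!r}")
        focal_rate = per_branch.loc[focal_branch, "loss_rate"]
        bg = per_branch[
            per_branch["is_internal"]
            & (per_branch.index != focal_branch)
            & per_branch["loss_rate"].notna()
        ]["loss_rate"]
        if np.isnan(focal_rate) or bg.empty:
            notes.append("fold_vs_background undefined (missing rates)")
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                fold = (float(focal_rate / bg.max()), float(focal_rate / bg.min()))
            if any(np.isnan(f) for f in fold):
                fold = None
                notes.append("fold_vs_background undefined (0/0 loss rates)")
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return FluxSummary(
        per_branch=per_branch,
        focal_branch=focal_branch,
        fold_vs_background=fold,
        warnings=notes,
    )


def clade_unique_families(
    matrix: OrthologMatrix,
    clade: set[str],
    mode: str = "strict",
) -> list[str]:
    """Families confined to a clade.

    ``strict``: present (>= 1 copy) in *every* clade member and absent from
    every non-member.  ``relaxed``: present in at least one clade member and
    absent outside.
    """
    if not clade:
        raise ValueError("empty clade")
    unknown = clade - set(matrix.taxa)
    if unknown:
        raise ValueError(f"clade taxa absent from matrix: {sorted(unknown)}")
    if mode not in {"strict", "relaxed"}:
        raise ValueError(f"unknown mode {mode!r}")
    inside = matrix.counts[sorted(clade)]
    outside_taxa = [t for t in matrix.taxa if t not in clade]
    out_ok = (
        (matrix.counts[outside_taxa] == 0).all(axis=1)
        if outside_taxa
        else pd.Series(True, index=matrix.counts.index)
    )
    if mode == "strict":
        in_ok = (inside >= 1).all(axis=1)
    else:
        in_ok = (inside >= 1).any(axis=1)
    return sorted(matrix.counts.index[in_ok & out_ok])
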