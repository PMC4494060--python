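"""Alignment-level recombination screen built around the pairwise homoplasy
(Phi) statistic, plus pairwise identity arithmetic and the all-tests-positive
screen summary.

For two aligned sites the refined incompatibility is

    inc(i, j) = l(i, j) - (s_i - 1) - (s_j - 1)

where s_k is the number of character states at site k and l(i, j) the minimum
number of state changes required to explain the joint site pattern on *some*
tree.  l is computed exactly from the partition-intersection (state) graph,
whose vertices are the states of the two sites and whose edges are the
observed joint patterns:
l = (#distinct joint patterns) + (#connected components) - 2.  For two
binary sites this reduces to the four-gamete test.  Phi is the mean incompatibility
over pairs of parsimony-informative sites whose separation in informative-site
rank is at most a window; its null distribution comes from permuting the
order of the informative sites, which breaks the spatial signal that
recombination creates while preserving the per-pair incompatibilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Alignment

__all__ = [
    "IdentityResult",
    "PhiResult",
    "ScreenSummary",
    "pairwise_identity",
    "informative_sites",
    "site_pair_incompatibility",
    "incompatibility_matrix",
    "phi_test",
    "recombination_screen",
]

_MISSING = {"-", "N"}


@dataclass
class IdentityResult:
    aligned_length: int
    n_mismatches: int
    identity_percent: float  # 100*(1 - mism/len), reported to 1 decimal


@dataclass
class PhiResult:
    gene_id: str
    phi_observed: float | None
    p_value: float | None
    n_informative_sites: int
    window_w: int
    n_permutations: int
    seed: int
    status: str = "ok"  # or "untestable"


@dataclass
class ScreenSummary:
    n_tested: int
    n_positive: int
    fraction_percent: float  # rounded half away from zero to 1 decimal
    alpha: float


def _round1(x: float) -> float:
    """Round to 1 decimal, half away from zero."""
    return np.floor(abs(x) * 10.0 + 0.5) / 10.0 * (1 if x >= 0 else -1)


def pairwise_identity(
    aln: Alignment,
    seq_a: str,
    seq_b: str,
    gap_mode: str = "exclude_gap_columns",
) -> IdentityResult:
    """Percent identity between two rows of an alignment.

    ``exclude_gap_columns`` drops every column where either sequence has a
    gap or N before counting; ``count_gaps`` keeps all columns and counts a
    base-vs-gap column as a mismatch (gap-vs-gap matches).
    """
    a = aln.row(seq_a)
    b = aln.row(seq_b)
    if gap_mode == "exclude_gap_columns":
        pairs = [
            (x, y) for x, y in zip(a, b)
            if x not in _MISSING and y not in _MISSING
        ]
    elif gap_mode == "count_gaps":
        pairs = list(zip(a, b))
    else:
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    length = len(pairs)
    if length == 0:
        raise ValueError("no comparable columns")
    mism = sum(1 for x, y in pairs if x != y)
    return IdentityResult(
        aligned_length=length,
        n_mismatches=mism,
        identity_percent=_round1(100.0 * (1.0 - mism / length)),
    )


def _column_states(aln: Alignment, j: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for row in aln.rows:
        ch = row[j]
        if ch in _MISSING:
            continue
        counts[ch] = counts.get(ch, 0) + 1
    return counts


def informative_sites(aln: Alignment, min_nonmissing: int = 4) -> list[int]:
    """Columns that are parsimony-informative.

    A column qualifies when at least two states are each carried by at least
    two sequences; gaps and N are missing; columns with fewer than
    ``min_nonmissing`` non-missing sequences are excluded.
    """
    out = []
    for j in range(aln.n_sites):
        counts = _column_states(aln, j)
        if sum(counts.values()) < min_nonmissing:
            continue
        if sum(1 for n in counts.values() if n >= 2) >= 2:
            out.append(j)
    return out


def _pair_incompatibility_codes(col_i: list, col_j: list) -> int:
    """Refined incompatibility from two columns of per-sequence state codes
    (None = missing)."""
    joint = set()
    for x, y in zip(col_i, col_j):
        if x is None or y is None:
            continue
        joint.add((x, y))
    if not joint:
        return 0
    states_i = {x for x, _ in joint}
    states_j = {y for _, y in joint}
    # connected components of the bipartite state graph (union-find)
    nodes = [("i", x) for x in states_i] + [("j", y) for y in states_j]
    parent = {n: n for n in nodes}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    for x, y in joint:
        a, b = find(("i", x)), find(("j", y))
        if a != b:
            parent[a] = b
    components = len({find(n) for n in nodes})
    # minimum joint changes on the best common tree: every distinct joint
    # pattern beyond the first in its component needs one change, plus one
    # change to join each extra component
    l_min = len(joint) + components - 2
    return l_min - (len(states_i) - 1) - (len(states_j) - 1)


def site_pair_incompatibility(aln: Alignment, site_i: int, site_j: int) -> int:
    """Refined incompatibility of two informative sites (0 = compatible).

    Computed over the sequences non-missing at both sites; state counts are
    taken over that joint sample.  For two binary sites this is the
    four-gamete test (1 iff all four gametes present).
    """
    info = set(informative_sites(aln))
    if site_i not in info or site_j not in info:
        raise ValueError("both sites must be parsimony-informative")
    cols_i = [None if r[site_i] in _MISSING else r[site_i] for r in aln.rows]
    cols_j = [None if r[site_j] in _MISSING else r[site_j] for r in aln.rows]
    return _pair_incompatibility_codes(cols_i, cols_j)


def incompatibility_matrix(aln: Alignment, sites: list[int]) -> np.ndarray:
    """Symmetric matrix of refined incompatibilities among the given sites."""
    cols = [
        [None if r[j] in _MISSING else r[j] for r in aln.rows] for j in sites
    ]
    k = len(sites)
    M = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            M[a, b] = M[b, a] = _pair_incompatibility_codes(cols[a], cols[b])
    return M


def _window_pairs(k: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j), 0 < j - i <= w, over k ranked positions."""
    ii = []
    jj = []
    for d in range(1, min(w, k - 1) + 1):
        ii.append(np.arange(0, k - d))
        jj.append(np.arange(d, k))
    return np.concatenate(ii), np.concatenate(jj)


def _windowed_mean(M: np.ndarray, order: np.ndarray, w: int) -> float:
    """Mean of M[order[i], order[j]] over pairs with 0 < j - i <= w."""
    k = len(order)
    if k < 2:
        return 0.0
    ii, jj = _window_pairs(k, w)
    return float(M[order[ii], order[jj]].mean())


def phi_test(
    aln: Alignment,
    window_w: int = 100,
    n_permutations: int = 1000,
    seed: int = 0,
    gene_id: str = "",
) -> PhiResult:
    """Permutation Phi test for recombination within one alignment.

    ``phi_observed`` is the mean refined incompatibility over informative-site
    pairs separated by at most ``window_w`` in informative-site rank.  The
    null distribution permutes the informative-site order ``n_permutations``
    times (seeded); ``p = (1 + #{phi_perm <= phi_obs}) / (n_permutations+1)``,
    so recombination (locally depressed incompatibility) gives small p.
    Alignments with < 2 informative sites are reported as untestable, never
    with a p-value.
    """
    if n_permutations < 99:
        raise ValueError("need n_permutations >= 99")
    sites = informative_sites(aln)
    k = len(sites)
    if k < 2:
        return PhiResult(gene_id, None, None, k, window_w, n_permutations,
                         seed, status="untestable")
    M = incompatibility_matrix(aln, sites)
    ii, jj = _window_pairs(k, window_w)
    observed = float(M[ii, jj].mean())
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(n_permutations):
        perm = rng.permutation(k)
        if float(M[perm[ii], perm[jj]].mean()) <= observed + 1e-12:
            n_le += 1
    p = (1 + n_le) / (n_permutations + 1)
    return PhiResult(gene_id, float(observed), float(p), k, window_w,
                     n_permutations, seed)


def recombination_screen(
    results: list[PhiResult],
    external: pd.DataFrame | None = None,
    alpha: float = 0.01,
) -> tuple[ScreenSummary, pd.DataFrame]:
    """Summarise per-gene verdicts under the all-tests-positive rule.

    A gene is positive iff every available test p-value (Phi plus any columns
    of the ``external`` table, indexed by gene id) is strictly below
    ``alpha``.  Untestable genes are excluded from the denominator.  Returns
    the summary and a per-gene verdict table.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    ids = [r.gene_id for r in results]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids: {dup}")
    rows = []
    for r in results:
        if r.status != "ok":
            rows.append({"gene_id": r.gene_id, "phi_p": np.nan,
                         "status": "untestable", "positive": False})
            continue
        ps = [r.p_value]
        if external is not None and r.gene_id in external.index:
            ps.extend(float(v) for v in external.loc[r.gene_id].dropna())
        rows.append({
            "gene_id": r.gene_id,
            "phi_p": r.p_value,
            "status": "tested",
            "positive": all(p < alpha for p in ps),
        })
    verdicts = pd.DataFrame(rows, columns=["gene_id", "phi_p", "status", "positive"])
    tested = verdicts[verdicts["status"] == "tested"]
    if tested.empty:
        raise ValueError("no testable genes in the screen")
    n_tested = len(tested)
    n_positive = int(tested["positive"].sum())
    return (
        ScreenSummary(
            n_tested=n_tested,
            n_positive=n_positive,
            fraction_percent=_round1(100.0 * n_positive / n_tested),
            alpha=alpha,
        ),
        verdicts,
    )
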