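"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and an explicit seed
(one :class:`numpy.random.Generator` per call, no global state) and returns a
:class:`SimulationTruth` sidecar recording the planted parameters, so every
downstream operation can be tested as a recovery problem.

The default integration scenario (:func:`kunkeei_like`) mirrors a small
fructophilic-lactobacillus species complex: a 1.5 Mb circular chromosome,
~1,300 genes with origin- and terminus-biased functional categories, 13 taxa
in four microclusters of 2-3 strains evolving gene content under loss-heavy
rates with one focal reduction branch, 790 bootstrapped gene trees drawn from
a topology mixture, clonal and recombinant alignments, and OD growth curves
with a 55-minute doubling time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Alignment, CircularGenome, GeneRecord, OrthologMatrix
from .geneflux import node_id_map

__all__ = [
    "SimulationTruth",
    "simulate_genome",
    "simulate_gene_positions",
    "simulate_gene_content_evolution",
    "simulate_gene_trees",
    "simulate_alignment",
    "simulate_growth_curve",
    "default_species_tree",
    "swap_leaf_labels",
    "kunkeei_like",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationTruth:
    """Planted parameters of one generated dataset."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"scenario": self.scenario, "seed": self.seed,
                 "params": self.params},
                fh, indent=2, sort_keys=True, default=str,
            )


# ---------------------------------------------------------------------------
# genomes


def simulate_genome(
    length: int,
    ori: int,
    ter: int,
    skew_amp: float,
    seed: int,
    genome_id: str = "simgenome",
) -> tuple[CircularGenome, SimulationTruth]:
    """Circular genome with a planted GC-skew signal.

    On the ori -> ter arc P(G) = 0.25(1+skew_amp) and P(C) = 0.25(1-skew_amp);
    the complementary arc is mirrored; A and T stay at 0.25.  The expected
    window skew is therefore +skew_amp on the first replichore and -skew_amp
    on the second.
    """
    if not 0 <= skew_amp <= 1:
        raise ValueError("skew_amp must lie in [0, 1]")
    ori %= length
    ter %= length
    if ori == ter:
        raise ValueError("ori and ter must differ")
    rng = np.random.default_rng(seed)
    a = skew_amp
    p_lead = [0.25, 0.25 * (1 - a), 0.25 * (1 + a), 0.25]  # A C G T
    p_lag = [0.25, 0.25 * (1 + a), 0.25 * (1 - a), 0.25]
    arc1 = (ter - ori) % length
    codes = np.empty(length, dtype=np.int64)
    idx1 = (ori + np.arange(arc1)) % length
    idx2 = (ter + np.arange(length - arc1)) % length
    codes[idx1] = rng.choice(4, size=arc1, p=p_lead)
    codes[idx2] = rng.choice(4, size=length - arc1, p=p_lag)
    sequence = _BASES[codes].tobytes().decode("ascii")
    genome = CircularGenome(id=genome_id, length=length, ori=ori, ter=ter,
                            sequence=sequence)
    truth = SimulationTruth(
        "genome", seed,
        {"length": length, "ori": ori, "ter": ter, "skew_amp": skew_amp},
    )
    return genome, truth


# ---------------------------------------------------------------------------
# gene positions

_BIASES = {"ori_proximal", "ter_proximal", "uniform"}


def simulate_gene_positions(
    n_genes: int,
    categories: Sequence[tuple[str, str]],
    genome: CircularGenome,
    seed: int,
    gene_length: int = 900,
    flags_for: dict[str, set[str]] | None = None,
) -> tuple[list[GeneRecord], SimulationTruth]:
    """Genes whose distance to ori follows a per-category bias model.

    ``categories`` is a sequence of (name, bias) with bias in
    {ori_proximal, ter_proximal, uniform}; genes are split as evenly as
    possible across categories.  ori_proximal distances follow a triangular
    distribution peaked at 0 on [0, L/2], ter_proximal one peaked at L/2,
    uniform is uniform on [0, L/2]; each gene lands on a random side of ori.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for name, bias in categories:
        if bias not in _BIASES:
            raise ValueError(f"unknown bias spec {bias!r} for category {name!r}")
    rng = np.random.default_rng(seed)
    L = genome.length
    half = L / 2.0
    per_cat = [n_genes // len(categories)] * len(categories)
    for i in range(n_genes % len(categories)):
        per_cat[i] += 1
    genes: list[GeneRecord] = []
    counter = 0
    for (name, bias), n_cat in zip(categories, per_cat):
        if bias == "ori_proximal":
            dist = rng.triangular(0.0, 0.0, half, size=n_cat)
        elif bias == "ter_proximal":
            dist = rng.triangular(0.0, half, half, size=n_cat)
        else:
            dist = rng.uniform(0.0, half, size=n_cat)
        side = rng.choice([-1, 1], size=n_cat)
        strands = rng.choice(["+", "-"], size=n_cat)
        mids = (genome.ori + side * dist.astype(np.int64)) % L
        for mid, strand in zip(mids, strands):
            start = int((mid - gene_length // 2) % L)
            end = int((start + gene_length) % L)
            flags = set((flags_for or {}).get(name, set()))
            genes.append(
                GeneRecord(f"{name}_{counter:05d}", genome.id, start, end,
                           str(strand), category=name, flags=flags)
            )
            counter += 1
    truth = SimulationTruth(
        "gene_positions", seed,
        {"n_genes": n_genes, "categories": list(map(list, categories)),
         "gene_length": gene_length, "genome": genome.id},
    )
    return genes, truth


# ---------------------------------------------------------------------------
# gene-content evolution


def _gillespie_branch(
    rng: np.random.Generator,
    state: int,
    length: float,
    gain: float,
    loss: float,
    dup: float,
) -> tuple[int, list[tuple[float, str, int]]]:
    """Continuous-time gain/loss/duplication events along one branch."""
    t = 0.0
    events: list[tuple[float, str, int]] = []
    while True:
        rate = gain if state == 0 else loss + dup
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= length:
            break
        if state == 0:
            state = 1
            events.append((t, "gain", state))
        elif rng.random() < loss / (loss + dup):
            state = 0
            events.append((t, "loss", state))
        else:
            state += 1
            events.append((t, "duplication", state))
    return state, events


def simulate_gene_content_evolution(
    tree: dendropy.Tree,
    root_families: int,
    gain_rate: float,
    loss_rate: float,
    dup_rate: float,
    seed: int,
    focal_branch: str | None = None,
    loss_multiplier: float = 1.0,
    novel_families: int = 0,
) -> tuple[OrthologMatrix, SimulationTruth]:
    """Gene-family evolution on a tree with a complete true event log.

    Families present at the root start with one copy; ``novel_families``
    additional families start absent and can only be gained.  Along each
    branch, events are sampled in continuous time: gains (rate ``gain_rate``)
    only while absent, whole-family losses (``loss_rate``) and duplications
    (``dup_rate``) only while present.  The branch named ``focal_branch``
    (child-node id, see :func:`archflux.geneflux.node_id_map`) has its loss
    rate multiplied by ``loss_multiplier`` to plant a genome-reduction
    signature.  Leaf copy numbers become the ortholog matrix; families absent
    from every leaf are dropped from the matrix but kept in the log.
    """
    if min(gain_rate, loss_rate, dup_rate) < 0:
        raise ValueError("rates must be non-negative")
    if root_families + novel_families == 0 or (
        root_families == 0 and gain_rate == 0
    ):
        raise ValueError("nothing can ever be present: no root families and "
                         "no gains possible")
    rng = np.random.default_rng(seed)
    ids = node_id_map(tree)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("tree must have branch lengths")

    families = [f"F{i:05d}" for i in range(root_families + novel_families)]
    root_state = {
        fam: (1 if i < root_families else 0) for i, fam in enumerate(families)
    }
    states: dict[str, dict[str, int]] = {ids[tree.seed_node]: dict(root_state)}
    log_rows: list[dict] = []
    true_losses: dict[str, int] = {}
    true_gains: dict[str, int] = {}

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        branch = ids[node]
        parent_states = states[ids[node.parent_node]]
        here: dict[str, int] = {}
        mult = loss_multiplier if branch == focal_branch else 1.0
        n_loss = n_gain = 0
        for fam in families:
            end_state, events = _gillespie_branch(
                rng, parent_states[fam], node.edge.length,
                gain_rate, loss_rate * mult, dup_rate,
            )
            here[fam] = end_state
            for t, etype, new_copies in events:
                log_rows.append(
                    {"branch": branch, "family": fam, "type": etype,
                     "time": t, "copies_after": new_copies}
                )
                if etype == "loss":
                    n_loss += 1
                elif etype == "gain":
                    n_gain += 1
        states[branch] = here
        true_losses[branch] = n_loss
        true_gains[branch] = n_gain

    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    counts = pd.DataFrame(
        {leaf: [states[leaf][fam] for fam in families] for leaf in leaves},
        index=pd.Index(families, name="family"),
    )
    present = counts.to_numpy().sum(axis=1) > 0
    matrix = OrthologMatrix(counts[present])
    truth = SimulationTruth(
        "gene_content", seed,
        {
            "root_families": root_families,
            "novel_families": novel_families,
            "gain_rate": gain_rate,
            "loss_rate": loss_rate,
            "dup_rate": dup_rate,
            "focal_branch": focal_branch,
            "loss_multiplier": loss_multiplier,
            "event_log": log_rows,
            "true_losses_per_branch": true_losses,
            "true_gains_per_branch": true_gains,
            "root_states": root_state,
            "node_states": states,
            "families_in_matrix": list(matrix.families),
        },
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# gene trees


def simulate_gene_trees(
    species_tree: dendropy.Tree,
    n_trees: int,
    seed: int,
    alt_topologies: Sequence[tuple[dendropy.Tree, float]] = (),
    support_model: tuple[float, float] = (99.0, 2.0),
) -> tuple[dendropy.TreeList, SimulationTruth]:
    """Gene trees drawn from a topology mixture with bootstrap-like supports.

    The species tree receives weight 1 - sum(alternative weights); each gene
    tree is a clone of the drawn topology whose internal nodes get supports
    from a normal(mean, sd) truncated to [0, 100].
    """
    weights = [w for _, w in alt_topologies]
    w_species = 1.0 - sum(weights)
    if w_species < -1e-9 or any(w < 0 for w in weights):
        raise ValueError("mixture weights must be non-negative and sum to <= 1")
    topologies = [species_tree] + [t for t, _ in alt_topologies]
    probs = np.array([w_species] + weights, dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    mean, sd = support_model
    a, b = (0.0 - mean) / sd, (100.0 - mean) / sd

    namespace = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(taxon_namespace=namespace)
    choices = rng.choice(len(topologies), size=n_trees, p=probs)
    for which in choices:
        newick = topologies[which].as_string(schema="newick").strip()
        tree = dendropy.Tree.get(
            data=newick, schema="newick", taxon_namespace=namespace,
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
        for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
            node.support = float(
                stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
            )
        tree.seed_node.support = None
        trees.append(tree)
    truth = SimulationTruth(
        "gene_trees", seed,
        {"n_trees": n_trees, "weights": probs.tolist(),
         "chosen": choices.tolist(), "support_model": list(support_model)},
    )
    return trees, truth


# ---------------------------------------------------------------------------
# alignments


def _evolve_on_tree(
    tree: dendropy.Tree,
    n_sites: int,
    subst_rate: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Equal-rate (Jukes-Cantor) evolution of one segment; leaf code arrays."""
    root_seq = rng.integers(0, 4, size=n_sites)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            t = node.edge.length
            if t is None:
                raise ValueError("alignment simulation needs branch lengths")
            parent = seqs[id(node.parent_node)]
            p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * subst_rate * t))
            mask = rng.random(n_sites) < p_change
            seq = parent.copy()
            if mask.any():
                seq[mask] = (seq[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
            seqs[id(node)] = seq
        if node.is_leaf():
            out[node.taxon.label] = seqs[id(node)]
    return out


def simulate_alignment(
    tree_segments: Sequence[tuple[dendropy.Tree, int]],
    subst_rate: float,
    seed: int,
) -> tuple[Alignment, SimulationTruth]:
    """Concatenated alignment evolved segment-by-segment on given trees.

    Each segment evolves independently under an equal-rate substitution model
    from a uniform random root sequence; a single segment yields clonal data,
    several segments with different topologies yield recombinant-like data.
    Breakpoint positions (0-based start of every segment after the first) are
    recorded in the truth sidecar.
    """
    if not tree_segments:
        raise ValueError("need at least one (tree, n_sites) segment")
    if subst_rate <= 0:
        raise ValueError("subst_rate must be positive")
    rng = np.random.default_rng(seed)
    leaf_sets = [
        frozenset(lf.taxon.label for lf in t.leaf_node_iter())
        for t, _ in tree_segments
    ]
    if len(set(leaf_sets)) != 1:
        raise ValueError("all segment trees must share the same leaf set")
    labels = sorted(leaf_sets[0])
    pieces: dict[str, list[np.ndarray]] = {l: [] for l in labels}
    breakpoints: list[int] = []
    offset = 0
    for tree, n_sites in tree_segments:
        if n_sites <= 0:
            raise ValueError("zero-length segment")
        if offset > 0:
            breakpoints.append(offset)
        leaf_seqs = _evolve_on_tree(tree, n_sites, subst_rate, rng)
        for l in labels:
            pieces[l].append(leaf_seqs[l])
        offset += n_sites
    rows = [
        _BASES[np.concatenate(pieces[l])].tobytes().decode("ascii")
        for l in labels
    ]
    aln = Alignment(ids=labels, rows=rows)
    truth = SimulationTruth(
        "alignment", seed,
        {"segments": [n for _, n in tree_segments],
         "breakpoints": breakpoints, "subst_rate": subst_rate},
    )
    return aln, truth


# ---------------------------------------------------------------------------
# growth curves


def simulate_growth_curve(
    doubling: float,
    t_max: float,
    interval: float,
    noise_sd: float,
    seed: int,
    od0: float = 0.05,
    lag_min: float = 0.0,
    plateau_od: float | None = None,
) -> tuple[np.ndarray, np.ndarray, SimulationTruth]:
    """OD time series with exponential growth and multiplicative noise.

    OD(t) = od0 * 2^((t - lag)/doubling) (flat during the lag, capped at the
    plateau), multiplied by exp(eps) with eps ~ Normal(0, noise_sd).
    """
    if min(doubling, t_max, interval) <= 0 or noise_sd < 0:
        raise ValueError("doubling, t_max and interval must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + 1e-9, interval)
    effective = np.maximum(times - lag_min, 0.0)
    od = od0 * np.power(2.0, effective / doubling)
    if plateau_od is not None:
        od = np.minimum(od, plateau_od)
    if noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, noise_sd, size=len(times)))
    truth = SimulationTruth(
        "growth_curve", seed,
        {"doubling": doubling, "t_max": t_max, "interval": interval,
         "noise_sd": noise_sd, "od0": od0, "lag_min": lag_min,
         "plateau_od": plateau_od},
    )
    return times, od, truth


# ---------------------------------------------------------------------------
# the integration scenario

KUNKEEI_LIKE_NEWICK = (
    "((((((A1:0.02,A2:0.02):0.03,A3:0.04):0.10,"
    "((B1:0.02,B2:0.02):0.03,B3:0.04):0.10):0.05,"
    "((C1:0.04,C2:0.04):0.10,(D1:0.03,D2:0.03):0.11):0.05):0.08,"
    "E1:0.30):0.06,(F1:0.25,OUT:0.45):0.08):0.0;"
)


def default_species_tree() -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=KUNKEEI_LIKE_NEWICK, schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )
    for node in tree:
        node.support = None
    return tree


def swap_leaf_labels(tree: dendropy.Tree, a: str, b: str) -> dendropy.Tree:
    clone = dendropy.Tree.get(
        data=tree.as_string(schema="newick"), schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )
    for leaf in clone.leaf_node_iter():
        if leaf.taxon.label == a:
            leaf.taxon.label = b
        elif leaf.taxon.label == b:
            leaf.taxon.label = a
    return clone


def kunkeei_like(seed: int, n_recomb_genes: int = 24) -> dict:
    """Generate the full default scenario; returns objects plus truths.

    13 taxa in four microclusters (A1-3, B1-3, C1-2, D1-2) plus two
    early-diverging strains (E1, F1) and an outgroup; a 1.5 Mb circular
    genome with planted skew; 1,300 category-biased genes; 500 root gene
    families evolving loss-heavily with a focal reduction branch (the stem
    of the ingroup, N2); 790 gene trees mixing three resolutions of the A
    microcluster (0.6/0.25/0.15); clonal and recombinant gene alignments;
    and a 55-minute growth curve.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    species = default_species_tree()
    genome, genome_truth = simulate_genome(
        length=1_500_000, ori=0, ter=750_000, skew_amp=0.08, seed=sub(),
        genome_id="A1_chromosome",
    )
    genes, genes_truth = simulate_gene_positions(
        n_genes=1300,
        categories=[
            ("E", "ori_proximal"), ("G", "ori_proximal"),
            ("J", "ter_proximal"), ("L", "ter_proximal"),
            ("R", "uniform"), ("S", "uniform"),
        ],
        genome=genome,
        seed=sub(),
        flags_for={"E": {"secreted"}},
    )
    matrix, flux_truth = simulate_gene_content_evolution(
        species, root_families=500, gain_rate=0.05, loss_rate=0.6,
        dup_rate=0.05, seed=sub(), focal_branch="N2", loss_multiplier=8.0,
        novel_families=80,
    )
    alt1 = swap_leaf_labels(species, "A2", "A3")  # (A1,A3) cherry
    alt2 = swap_leaf_labels(species, "A1", "A3")  # (A3,A2) cherry
    gene_trees, trees_truth = simulate_gene_trees(
        species, n_trees=790, seed=sub(),
        alt_topologies=[(alt1, 0.25), (alt2, 0.15)],
        support_model=(98.0, 2.0),
    )
    four_taxa = dendropy.Tree.get(
        data="((A1:0.4,B1:0.4):0.3,(C1:0.4,D1:0.4):0.3):0.0;",
        schema="newick", suppress_internal_node_taxa=True,
    )
    four_alt = dendropy.Tree.get(
        data="((A1:0.4,C1:0.4):0.3,(B1:0.4,D1:0.4):0.3):0.0;",
        schema="newick", suppress_internal_node_taxa=True,
    )
    alignments = {}
    aln_truths = {}
    n_clonal = max(n_recomb_genes - 4, 0)
    for i in range(n_clonal):
        aln, t = simulate_alignment([(four_taxa, 1000)], subst_rate=0.3,
                                    seed=sub())
        alignments[f"clonal{i:03d}"] = aln
        aln_truths[f"clonal{i:03d}"] = t
    for i in range(n_recomb_genes - n_clonal):
        aln, t = simulate_alignment(
            [(four_taxa, 500), (four_alt, 500)], subst_rate=0.3, seed=sub()
        )
        alignments[f"recomb{i:03d}"] = aln
        aln_truths[f"recomb{i:03d}"] = t
    times, od, growth_truth = simulate_growth_curve(
        doubling=55.0, t_max=600.0, interval=30.0, noise_sd=0.02, seed=sub(),
        lag_min=60.0, plateau_od=1.2,
    )
    return {
        "species_tree": species,
        "genome": genome,
        "genes": genes,
        "matrix": matrix,
        "gene_trees": gene_trees,
        "alignments": alignments,
        "growth": (times, od),
        "truths": {
            "genome": genome_truth,
            "genes": genes_truth,
            "flux": flux_truth,
            "gene_trees": trees_truth,
            "alignments": aln_truths,
            "growth": growth_truth,
        },
        "seed": seed,
    }
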