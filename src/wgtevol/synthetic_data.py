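"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs: (a) ordered pillar tables
produced by subgenome-biased loss along a species tree, with hidden
track->subgenome permutations persisting between syntenic neighbours;
(b) class-labeled interaction networks with tunable same-class edge
enrichment; (c) expression matrices with planted coexpression blocks.
All randomness flows through one seeded generator per call and the planted
truth is returned alongside every dataset.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .loss_model import (
    N_STATES, STATES, STATE_INDEX, SUBGENOMES, LossModelSpec, Variant,
    build_generator, root_chain,
)
from .pillar_hmm import PERMS, N_PERMS, SLOT_SUBSETS, HmmSpec, PillarSet
from .trees import SpeciesTree, default_study_tree


def default_loss_spec() -> LossModelSpec:
    """Biased-fractionation generating model used as the study condition:
    three distinguishable subgenomes, LF losing least, MF2 the baseline."""
    return LossModelSpec.g3(sigma=0.8, fT=(0.6, 0.8, 1.0), fD=(0.5, 0.7, 1.0))


def default_hmm_spec() -> HmmSpec:
    return HmmSpec(theta=0.05)


@dataclass
class SimulationTruth:
    """Ground truth of one pillar simulation."""

    perms: np.ndarray          # (n_pillars, G) permutation index per genome
    redraws: np.ndarray        # (n_pillars, G) where the permutation chain redrew
    node_states: np.ndarray    # (n_pillars, n_nodes) copy-number state at node
    events: pd.DataFrame       # pillar, branch, kind, subgenome, pre_arrival
    spec: LossModelSpec
    hmm: HmmSpec
    tree: SpeciesTree
    seed: int

    def loss_counts(self) -> pd.DataFrame:
        ev = self.events[self.events["kind"] == "loss"]
        return (ev.groupby(["branch", "subgenome"]).size()
                .rename("losses").reset_index())


def _simulate_branch(state: int, Q: np.ndarray, nu: float, rng) -> tuple[int, list]:
    """Exact CTMC simulation (competing exponentials) of one branch.

    Returns the end state and the list of jumps ``(from, to)``.
    """
    jumps = []
    t = 0.0
    while True:
        rates = Q[state].copy()
        rates[state] = 0.0
        total = rates.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > nu:
            break
        nxt = rng.choice(len(rates), p=rates / total)
        jumps.append((state, int(nxt)))
        state = int(nxt)
    return state, jumps


def simulate_pillars(tree: SpeciesTree | None = None,
                     spec: LossModelSpec | None = None,
                     hmm: HmmSpec | None = None,
                     n_pillars: int = 1000, seed: int = 0,
                     flag_breaks: bool = True) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate an ordered pillar table under the loss model.

    Per pillar, the copy-number state evolves by exact stochastic simulation
    down the tree from the variant's start state; hidden permutations follow
    the persistence chain with parameter ``theta`` and, when ``flag_breaks``,
    redraw events are annotated as synteny breaks.  Returns the pillar table
    (the on-disk TSV schema) and the full :class:`SimulationTruth`.
    """
    tree = tree if tree is not None else default_study_tree()
    spec = spec if spec is not None else default_loss_spec()
    hmm = hmm if hmm is not None else default_hmm_spec()
    if n_pillars < 1:
        raise ValueError("n_pillars must be >= 1")
    rng = np.random.default_rng(seed)
    G = tree.n_tips
    theta = hmm.theta_vector(G)
    last = spec.last_subgenome

    # hidden permutation chain
    perms = np.empty((n_pillars, G), dtype=np.int64)
    redraws = np.zeros((n_pillars, G), dtype=bool)
    perms[0] = rng.integers(0, N_PERMS, size=G)
    for i in range(1, n_pillars):
        redraw = rng.random(G) < theta
        redraws[i] = redraw
        perms[i] = np.where(redraw, rng.integers(0, N_PERMS, size=G), perms[i - 1])

    Q_non = build_generator(spec, "non_root")
    chain = root_chain(spec)
    node_states = np.empty((n_pillars, tree.n_nodes), dtype=np.int64)
    ev_rows: list[tuple] = []
    names = tree.edge_names()
    preorder = list(reversed(tree.postorder))
    for i in range(n_pillars):
        for node in preorder:
            if node == 0:
                # root branch runs on the (possibly augmented) root chain so
                # the last subgenome can arrive at most once
                end, jumps = _simulate_branch(chain.start, chain.Q,
                                              float(tree.lengths[0]), rng)
                sets, pre_flags = chain.state_sets, chain.pre_arrival
                node_states[i, 0] = chain.projection[end]
            else:
                start = node_states[i, tree.parent[node]]
                end, jumps = _simulate_branch(int(start), Q_non,
                                              float(tree.lengths[node]), rng)
                sets, pre_flags = STATES, np.zeros(N_STATES, dtype=bool)
                node_states[i, node] = end
            for (u, v) in jumps:
                su, sv = sets[u], sets[v]
                pre = bool(pre_flags[u])
                for m in su - sv:
                    ev_rows.append((i, names[node], "loss", m, pre))
                for m in sv - su:
                    ev_rows.append((i, names[node], "arrival", m, pre))
    events = pd.DataFrame(ev_rows,
                          columns=["pillar", "branch", "kind", "subgenome", "pre_arrival"])

    # observed slot patterns through the true permutations
    patterns = np.empty((n_pillars, G), dtype=np.int64)
    for g_i in range(G):
        tip_node = tree.tips[g_i]
        for i in range(n_pillars):
            surviving = STATES[node_states[i, tip_node]]
            slots = frozenset(k + 1 for k in range(3)
                              if PERMS[perms[i, g_i]][k] in surviving)
            patterns[i, g_i] = STATE_INDEX[slots]
    breaks = redraws if flag_breaks else np.zeros_like(redraws)
    pillars = PillarSet(patterns, breaks, tree.genomes,
                        ids=[f"p{i:05d}" for i in range(n_pillars)],
                        anchors=[f"At_{i:05d}" for i in range(n_pillars)])
    truth = SimulationTruth(perms=perms, redraws=redraws, node_states=node_states,
                            events=events, spec=spec, hmm=hmm, tree=tree, seed=seed)
    return pillars.to_dataframe(), truth


def simulate_labeled_network(n_nodes: int = 300, degree_param: float = 6.0,
                             class_sizes: dict | None = None,
                             enrichment: float = 1.0, seed: int = 0) -> nx.Graph:
    """Random class-labeled graph with tunable same-class edge enrichment.

    Edge probabilities follow a G(n, p)-style model in which same-class pairs
    are ``enrichment``-fold more likely to be joined; ``enrichment = 1`` is
    the label-exchangeable null.  Node attributes: ``subgenome`` (class
    label or ``unassigned``) and ``copy_status``.
    """
    if enrichment < 0:
        raise ValueError("enrichment must be >= 0")
    class_sizes = class_sizes if class_sizes is not None else {
        "LF": n_nodes // 3, "MF1": n_nodes // 3, "MF2": n_nodes // 3}
    if sum(class_sizes.values()) > n_nodes:
        raise ValueError("class sizes exceed node count")
    rng = np.random.default_rng(seed)
    labels = []
    for cls, size in class_sizes.items():
        labels.extend([cls] * size)
    labels.extend(["unassigned"] * (n_nodes - len(labels)))
    labels = np.array(labels)
    rng.shuffle(labels)
    iu, ju = np.triu_indices(n_nodes, k=1)
    same = (labels[iu] == labels[ju]) & (labels[iu] != "unassigned")
    mult = np.where(same, enrichment, 1.0)
    base = degree_param / (max(n_nodes - 1, 1) * mult.mean())
    p = np.clip(base * mult, 0.0, 1.0)
    keep = rng.random(p.shape) < p
    g = nx.Graph()
    for i in range(n_nodes):
        g.add_node(i, subgenome=str(labels[i]), copy_status="single")
    g.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    return g


def simulate_expression(n_genes: int = 200, n_conditions: int = 32,
                        n_blocks: int = 4, within_block_corr: float = 0.8,
                        missing_rate: float = 0.0, seed: int = 0,
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Expression matrix with planted coexpression blocks.

    Genes in a block share a latent condition factor with correlation
    ``within_block_corr``; values are exponentiated to a nonnegative
    RPKM-like scale (rank correlations are unaffected).  Entries are dropped
    at ``missing_rate``.  Returns the genes x conditions table and the
    planted block membership (-1 for background genes).
    """
    if not 0.0 <= within_block_corr <= 1.0:
        raise ValueError("within_block_corr must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    blocks = np.full(n_genes, -1, dtype=int)
    if n_blocks > 0:
        per = n_genes // (2 * n_blocks)  # half the genes in blocks by default
        for b in range(n_blocks):
            blocks[b * per:(b + 1) * per] = b
    rho = within_block_corr
    noise = rng.normal(size=(n_genes, n_conditions))
    if n_blocks > 0:
        factors = rng.normal(size=(n_blocks, n_conditions))
        shared = np.sqrt(rho) * factors[np.clip(blocks, 0, None)] + \
            np.sqrt(1.0 - rho) * noise
        latent = np.where(blocks[:, None] >= 0, shared, noise)
    else:
        latent = noise
    values = np.exp(latent + 2.0)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = np.where(mask, np.nan, values)
    df = pd.DataFrame(values,
                      index=[f"gene{i:04d}" for i in range(n_genes)],
                      columns=[f"lib{j:02d}" for j in range(n_conditions)])
    return df, pd.Series(blocks, index=df.index, name="block")
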