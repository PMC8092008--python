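"""Subgenome-label statistics on interaction and coexpression networks.

Nodes carry a parental-subgenome label (LF/MF1/MF2/unassigned, applied by the
caller only when assignment confidence is high enough) and a copy status.
Enrichment of same-subgenome edges is assessed against two nulls: shuffling
labels over a fixed topology (permutation test) and degree-preserving edge
rewiring with the labels fixed.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

SUBGENOME_LABELS = ("LF", "MF1", "MF2")


def count_class_edges(net: nx.Graph, predicate) -> Counter:
    """Count edges by the key a predicate assigns to each endpoint pair.

    ``predicate(attrs_u, attrs_v)`` returns a hashable key (e.g. a label
    pair) or None to skip the edge.
    """
    counts: Counter = Counter()
    for u, v in net.edges():
        key = predicate(net.nodes[u], net.nodes[v])
        if key is not None:
            counts[key] += 1
    return counts


def same_subgenome_single_copy(attrs_u, attrs_v):
    """Both endpoints single-copy genes from the same subgenome -> that label."""
    if (attrs_u.get("copy_status") == "single" and attrs_v.get("copy_status") == "single"
            and attrs_u.get("subgenome") == attrs_v.get("subgenome")
            and attrs_u.get("subgenome") in SUBGENOME_LABELS):
        return attrs_u["subgenome"]
    return None


def both_triplicated(attrs_u, attrs_v):
    if attrs_u.get("copy_status") == "triplicated" and attrs_v.get("copy_status") == "triplicated":
        return "triplet"
    return None


def subgenome_pair(attrs_u, attrs_v):
    """Unordered subgenome label pair of the endpoints (labeled nodes only)."""
    a, b = attrs_u.get("subgenome"), attrs_v.get("subgenome")
    if a in SUBGENOME_LABELS and b in SUBGENOME_LABELS:
        return tuple(sorted((a, b)))
    return None


@dataclass(frozen=True)
class PermutationTestResult:
    observed: float
    p_upper: float
    p_lower: float
    n_perm: int
    null_mean: float
    null_sd: float


def label_permutation_test(net: nx.Graph, statistic, n_perm: int = 1000,
                           frozen_nodes=None, seed: int = 0,
                           label_attr: str = "subgenome") -> PermutationTestResult:
    """Permutation test shuffling node labels over a fixed topology.

    ``statistic(net)`` maps the labeled network to a scalar.  Labels of
    ``frozen_nodes`` are held fixed (e.g. retained-triplet rows); the label
    multiset of the remaining nodes is shuffled.  Empirical p-values use the
    add-one convention p = (r + 1) / (n_perm + 1); both tails are reported.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    frozen = set(frozen_nodes or ())
    free = [n for n in net.nodes() if n not in frozen]
    if not free:
        raise ValueError("all nodes are frozen; nothing to permute")
    rng = np.random.default_rng(seed)
    observed = float(statistic(net))
    labels = [net.nodes[n].get(label_attr) for n in free]
    work = net.copy()
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(free))
        for i, n in enumerate(free):
            work.nodes[n][label_attr] = labels[perm[i]]
        null[b] = statistic(work)
    ge = int(np.sum(null >= observed))
    le = int(np.sum(null <= observed))
    return PermutationTestResult(
        observed=observed,
        p_upper=(ge + 1) / (n_perm + 1),
        p_lower=(le + 1) / (n_perm + 1),
        n_perm=n_perm,
        null_mean=float(null.mean()), null_sd=float(null.std()))


def metabolic_edge_stat(reaction_net: nx.Graph, reaction_genes: dict,
                        gene_labels: dict) -> Counter:
    """Same-subgenome single-copy edge counts on a reaction network.

    Nodes are biochemical reactions (edges join reactions sharing a
    metabolite); ``reaction_genes`` maps each reaction to its catalyzing
    genes and ``gene_labels`` maps gene -> (subgenome, copy_status).  An edge
    counts for a subgenome when the two reactions carry a pair of distinct
    single-copy genes from it.
    """
    counts: Counter = Counter({s: 0 for s in SUBGENOME_LABELS})
    for r1, r2 in reaction_net.edges():
        for sub in SUBGENOME_LABELS:
            g1 = {g for g in reaction_genes.get(r1, ())
                  if gene_labels.get(g) == (sub, "single")}
            g2 = {g for g in reaction_genes.get(r2, ())
                  if gene_labels.get(g) == (sub, "single")}
            # a shared gene catalyzing both reactions is not a pair
            if g1 and g2 and len(g1 | g2) >= 2:
                counts[sub] += 1
    return counts


def build_coexpression(expr: pd.DataFrame, max_missing: int = 1,
                       threshold: float = 0.9,
                       labels: pd.DataFrame | None = None) -> nx.Graph:
    """Spearman coexpression network from a genes x conditions matrix.

    Genes missing more than ``max_missing`` condition values are excluded;
    Spearman rho is computed on pairwise-complete observations with average
    ranks for ties, and an edge joins any pair with rho >= threshold or
    rho <= -threshold.  Constant-expression genes are skipped with a warning.
    Optional ``labels`` (index gene, columns subgenome/copy_status) are
    attached as node attributes.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 conditions")
    keep = expr.isna().sum(axis=1) <= max_missing
    expr = expr.loc[keep]
    constant = expr.nunique(axis=1, dropna=True) <= 1
    if constant.any():
        warnings.warn(
            f"skipping {int(constant.sum())} constant-expression genes "
            "(Spearman rho undefined)", RuntimeWarning)
        expr = expr.loc[~constant]
    net = nx.Graph()
    for gene in expr.index:
        attrs = {}
        if labels is not None and gene in labels.index:
            attrs = labels.loc[gene].to_dict()
        net.add_node(gene, **attrs)
    if len(expr) >= 2:
        corr = expr.T.corr(method="spearman", min_periods=3)
        genes = corr.index.to_list()
        mat = corr.to_numpy()
        iu, ju = np.triu_indices(len(genes), k=1)
        hits = np.abs(mat[iu, ju]) >= threshold
        for i, j in zip(iu[hits], ju[hits]):
            net.add_edge(genes[i], genes[j], rho=float(mat[i, j]))
    return net


@dataclass(frozen=True)
class RewireTestResult:
    observed: dict
    p_upper: dict
    p_lower: dict
    null_counts: pd.DataFrame
    n_rewire: int


def rewire_test(net: nx.Graph, n_rewire: int = 100, seed: int = 0,
                label_attr: str = "subgenome") -> RewireTestResult:
    """Degree-preserving rewiring null for subgenome-pair edge counts.

    The network is randomized by repeated double-edge swaps that keep every
    node's degree fixed (labels travel with the nodes); per randomized
    network the six subgenome-pair edge counts are tallied and empirical
    add-one p-values reported per pair.  Networks with no valid swap (e.g. a
    star) are left unchanged.
    """
    if net.number_of_edges() < 2:
        raise ValueError("network too small to rewire")
    pairs = [tuple(sorted(p)) for p in
             [(a, b) for i, a in enumerate(SUBGENOME_LABELS)
              for b in SUBGENOME_LABELS[i:]]]
    observed = Counter({p: 0 for p in pairs})
    observed.update(count_class_edges(net, subgenome_pair))
    rng = np.random.default_rng(seed)
    rows = []
    m = net.number_of_edges()
    for b in range(n_rewire):
        h = net.copy()
        try:
            nx.double_edge_swap(h, nswap=5 * m, max_tries=100 * m,
                                seed=int(rng.integers(2 ** 31)))
        except nx.NetworkXException:
            pass  # no swappable edge pair (e.g. a star): keep the topology
        counts = Counter({p: 0 for p in pairs})
        counts.update(count_class_edges(h, subgenome_pair))
        rows.append({str(p): counts[p] for p in pairs})
    null = pd.DataFrame(rows)
    p_upper, p_lower = {}, {}
    for p in pairs:
        col = null[str(p)].to_numpy()
        p_upper[p] = (int(np.sum(col >= observed[p])) + 1) / (n_rewire + 1)
        p_lower[p] = (int(np.sum(col <= observed[p])) + 1) / (n_rewire + 1)
    return RewireTestResult(observed=dict(observed), p_upper=p_upper,
                            p_lower=p_lower, null_counts=null, n_rewire=n_rewire)


@dataclass(frozen=True)
class SweepAssociation:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame
    expected: pd.DataFrame
    std_residuals: pd.DataFrame


def sweep_association(genes: pd.DataFrame, label_col: str = "subgenome",
                      flag_col: str = "sweep") -> SweepAssociation:
    """Pearson chi-square association between subgenome of origin and
    selective-sweep status, with per-cell standardized residuals.

    ``genes`` has one row per gene with a subgenome label column and a
    boolean/0-1 sweep flag.  No continuity correction is applied.
    """
    table = pd.crosstab(genes[label_col], genes[flag_col].astype(int))
    if table.shape[0] < 2 or table.shape[1] < 2 or \
            (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("contingency table has an empty row or column")
    res = scipy.stats.chi2_contingency(table.to_numpy(), correction=False)
    expected = pd.DataFrame(res.expected_freq, index=table.index, columns=table.columns)
    n = table.to_numpy().sum()
    row_frac = table.sum(axis=1).to_numpy()[:, None] / n
    col_frac = table.sum(axis=0).to_numpy()[None, :] / n
    denom = np.sqrt(expected.to_numpy() * (1 - row_frac) * (1 - col_frac))
    std_res = (table.to_numpy() - expected.to_numpy()) / denom
    return SweepAssociation(
        statistic=float(res.statistic), df=int(res.dof), p_value=float(res.pvalue),
        table=table, expected=expected,
        std_residuals=pd.DataFrame(std_res, index=table.index, columns=table.columns))
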