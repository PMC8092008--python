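"""Ancestral gene-order reconstruction by maximum-weight matching.

Homology sets (one candidate ancestral gene each) are linearized from the
gene adjacencies observed in the extant genomes: each set contributes a head
and a tail endpoint, observed adjacencies become weighted candidate edges
between endpoints, and a maximum-weight matching selects a consistent subset
that chains the sets into linear contigs.  Contigs are filtered on size and
chromosome-of-origin purity, and a second matching round orders the
surviving contigs into chromosome-scale sequences.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AdjacencyCandidate:
    """Candidate ancestral adjacency between two homology-set endpoints."""

    set_a: str
    end_a: str  # "head" | "tail"
    set_b: str
    end_b: str
    weight: int


def build_homology_sets(homolog_pairs: pd.DataFrame, genome_caps: dict,
                        ) -> pd.DataFrame:
    """Fallback homology-set construction from pairwise homologies.

    Sets are connected components of the homology graph, split greedily
    (largest component first, highest-degree gene removed) until every
    genome's membership respects its cap (1 for diploid outgroups, 3 for
    triplicated genomes).  Columns in/out: set_id, genome, gene_id.
    """
    g = nx.Graph()
    gene_genome = {}
    for r in homolog_pairs.itertuples():
        g.add_edge(r.gene1, r.gene2)
        gene_genome[r.gene1] = r.genome1
        gene_genome[r.gene2] = r.genome2
    rows = []
    sid = 0
    comps = [set(c) for c in nx.connected_components(g)]
    while comps:
        comp = comps.pop()
        counts = Counter(gene_genome[x] for x in comp)
        over = [gnm for gnm, c in counts.items() if c > genome_caps.get(gnm, 1)]
        if over:
            sub = g.subgraph(comp).copy()
            worst = max((x for x in comp if gene_genome[x] in over),
                        key=lambda x: sub.degree(x))
            sub.remove_node(worst)
            comps.extend(set(c) for c in nx.connected_components(sub))
            comps.append({worst})
            continue
        for gene in sorted(comp):
            rows.append({"set_id": f"hs{sid:05d}", "genome": gene_genome[gene],
                         "gene_id": gene})
        sid += 1
    return pd.DataFrame(rows)


def max_set_size(genome_caps: dict) -> int:
    """Largest possible homology set: the sum of the per-genome caps."""
    return int(sum(genome_caps.values()))


def collect_adjacencies(gene_orders: pd.DataFrame, sets: pd.DataFrame,
                        ) -> list[AdjacencyCandidate]:
    """Weighted candidate adjacencies between homology sets.

    ``gene_orders`` columns: genome, chrom, pos, gene_id; ``sets`` columns:
    set_id, genome, gene_id.  For every pair of genes at consecutive
    positions on a chromosome whose sets differ, one observation is recorded;
    observations aggregate into the candidate's weight.  Orientation: the
    majority observed direction A-before-B maps to (A, tail)-(B, head), ties
    broken toward the lexicographically smaller set id.
    """
    gene_set = {}
    for r in sets.itertuples():
        if r.gene_id in gene_set:
            raise ValueError(f"gene {r.gene_id} belongs to multiple homology sets")
        gene_set[r.gene_id] = r.set_id
    directed: Counter = Counter()
    for (_genome, _chrom), sub in gene_orders.groupby(["genome", "chrom"]):
        ordered = sub.sort_values("pos")["gene_id"].tolist()
        for a, b in zip(ordered[:-1], ordered[1:]):
            sa, sb = gene_set.get(a), gene_set.get(b)
            if sa is None or sb is None or sa == sb:
                continue
            directed[(sa, sb)] += 1
    pair_weight: Counter = Counter()
    for (sa, sb), cnt in directed.items():
        pair_weight[tuple(sorted((sa, sb)))] += cnt
    out = []
    for (sa, sb), weight in sorted(pair_weight.items()):
        fwd = directed.get((sa, sb), 0)
        rev = directed.get((sb, sa), 0)
        if fwd > rev or (fwd == rev):  # ties toward the sorted (lexicographic) order
            a, b = sa, sb
        else:
            a, b = sb, sa
        out.append(AdjacencyCandidate(a, "tail", b, "head", int(weight)))
    return out


def _endpoint(set_id, end):
    return (set_id, end)


def mwm_linearize(candidates: list[AdjacencyCandidate],
                  all_sets=None) -> tuple[list[list[tuple]], list[AdjacencyCandidate]]:
    """Select a maximum-weight endpoint matching and chain sets into contigs.

    Each set contributes a head and a tail node; a matching uses each at most
    once, so the selected adjacencies form simple paths and cycles over sets.
    Cycles are broken at their lowest-weight selected edge (returned for the
    record).  Returns ``(contigs, dropped_edges)`` where each contig is an
    ordered list of ``(set_id, orientation)`` with orientation ``+1``
    (head-to-tail) or ``-1`` (flipped); unmatched sets become singletons.
    """
    g = nx.Graph()
    for c in candidates:
        u, v = _endpoint(c.set_a, c.end_a), _endpoint(c.set_b, c.end_b)
        if g.has_edge(u, v):
            if g[u][v]["weight"] >= c.weight:
                continue
        g.add_edge(u, v, weight=c.weight)
    matching = nx.max_weight_matching(g, maxcardinality=False)
    sets = set(all_sets) if all_sets is not None else set()
    for c in candidates:
        sets.add(c.set_a)
        sets.add(c.set_b)
    # set-level graph: internal head-tail edge per set plus matched adjacencies
    sg = nx.MultiGraph()
    for s in sets:
        sg.add_edge(_endpoint(s, "head"), _endpoint(s, "tail"), kind="internal",
                    weight=np.inf)
    selected = []
    for u, v in matching:
        w = g[u][v]["weight"]
        sg.add_edge(u, v, kind="adjacency", weight=w)
        selected.append((u, v, w))
    dropped: list[AdjacencyCandidate] = []
    # break cycles at the lowest-weight adjacency edge
    for comp in list(nx.connected_components(sg)):
        sub = sg.subgraph(comp)
        if all(d == 2 for _, d in sub.degree()) and sub.number_of_edges() > 1:
            adj_edges = [(u, v, k, d) for u, v, k, d in sub.edges(keys=True, data=True)
                         if d["kind"] == "adjacency"]
            if not adj_edges:
                continue
            u, v, k, d = min(adj_edges, key=lambda e: e[3]["weight"])
            sg.remove_edge(u, v, key=k)
            dropped.append(AdjacencyCandidate(u[0], u[1], v[0], v[1], int(d["weight"])))
    contigs = []
    for comp in nx.connected_components(sg):
        sub = sg.subgraph(comp)
        endpoints = [n for n, d in sub.degree() if d == 1]
        start = min(endpoints) if endpoints else min(comp)
        # walk the path endpoint to endpoint
        path_nodes = [start]
        prev = None
        cur = start
        while True:
            nbrs = [n for n in sub.neighbors(cur) if n != prev]
            if not nbrs:
                break
            prev, cur = cur, nbrs[0]
            path_nodes.append(cur)
            if cur == start:
                break
        contig = []
        for i in range(0, len(path_nodes) - 1, 2):
            s, end = path_nodes[i]
            contig.append((s, +1 if end == "head" else -1))
        contigs.append(contig)
    contigs.sort(key=lambda c: c[0][0])
    return contigs, dropped


def matching_weight(candidates: list[AdjacencyCandidate],
                    contigs: list[list[tuple]]) -> int:
    """Total weight of the candidate adjacencies realized by the contigs."""
    lookup = {}
    for c in candidates:
        lookup[frozenset([(c.set_a, c.end_a), (c.set_b, c.end_b)])] = c.weight
    total = 0
    for contig in contigs:
        for (s1, o1), (s2, o2) in zip(contig[:-1], contig[1:]):
            e1 = (s1, "tail" if o1 > 0 else "head")
            e2 = (s2, "head" if o2 > 0 else "tail")
            total += lookup.get(frozenset([e1, e2]), 0)
    return total


def filter_contigs(contigs: list[list[tuple]], sets: pd.DataFrame,
                   required_genome: str, min_genes: int = 4,
                   chromosome_labels: dict | None = None,
                   majority: float = 0.8) -> list[list[tuple]]:
    """Drop small and mixed-origin contigs.

    A contig is dropped when it holds ``min_genes`` or fewer genes from
    ``required_genome``, or - when per-set chromosome-of-origin labels are
    supplied - when no single label reaches the ``majority`` fraction of its
    members (a contig mixing two or more ancient chromosomes).
    """
    genes_per_set = sets[sets["genome"] == required_genome].groupby("set_id").size()
    kept = []
    for contig in contigs:
        n_genes = int(sum(genes_per_set.get(s, 0) for s, _ in contig))
        if n_genes <= min_genes:
            continue
        if chromosome_labels is not None:
            labels = [chromosome_labels[s] for s, _ in contig if s in chromosome_labels]
            if labels:
                top = Counter(labels).most_common(1)[0][1]
                if top / len(labels) < majority:
                    continue
        kept.append(contig)
    return kept


def order_contigs(contigs: list[list[tuple]], gene_orders: pd.DataFrame,
                  sets: pd.DataFrame) -> list[list[tuple]]:
    """Second matching round: order the contigs themselves.

    Contig-level adjacency candidates are collected from gene neighbours that
    span a contig boundary, then matched exactly as in
    :func:`mwm_linearize`.  Returns reconstructed chromosomes as ordered
    lists of ``(set_id, orientation)``.
    """
    if not contigs:
        raise ValueError("need at least one contig")
    set_contig = {}
    for idx, contig in enumerate(contigs):
        for s, _ in contig:
            set_contig[s] = f"c{idx:04d}"
    gene_set = dict(zip(sets["gene_id"], sets["set_id"]))
    directed: Counter = Counter()
    for (_genome, _chrom), sub in gene_orders.groupby(["genome", "chrom"]):
        ordered = sub.sort_values("pos")["gene_id"].tolist()
        for a, b in zip(ordered[:-1], ordered[1:]):
            sa, sb = gene_set.get(a), gene_set.get(b)
            if sa is None or sb is None:
                continue
            ca, cb = set_contig.get(sa), set_contig.get(sb)
            if ca is None or cb is None or ca == cb:
                continue
            directed[(ca, cb)] += 1
    pair_weight: Counter = Counter()
    for (ca, cb), cnt in directed.items():
        pair_weight[tuple(sorted((ca, cb)))] += cnt
    cands = []
    for (ca, cb), weight in sorted(pair_weight.items()):
        fwd = directed.get((ca, cb), 0)
        rev = directed.get((cb, ca), 0)
        a, b = (ca, cb) if fwd >= rev else (cb, ca)
        cands.append(AdjacencyCandidate(a, "tail", b, "head", int(weight)))
    contig_ids = [f"c{idx:04d}" for idx in range(len(contigs))]
    chains, _ = mwm_linearize(cands, all_sets=contig_ids)
    by_id = {f"c{idx:04d}": contig for idx, contig in enumerate(contigs)}
    chromosomes = []
    for chain in chains:
        chrom: list[tuple] = []
        for cid, orient in chain:
            piece = by_id[cid]
            if orient < 0:
                piece = [(s, -o) for s, o in reversed(piece)]
            chrom.extend(piece)
        chromosomes.append(chrom)
    return chromosomes


def ancestral_order_frame(chromosomes: list[list[tuple]]) -> pd.DataFrame:
    rows = []
    for ci, chrom in enumerate(chromosomes):
        for pos, (set_id, orient) in enumerate(chrom):
            rows.append({"chrom": f"anc{ci + 1}", "pos": pos,
                         "set_id": set_id, "orientation": orient})
    return pd.DataFrame(rows)
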