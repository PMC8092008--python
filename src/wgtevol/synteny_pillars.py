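"""Building pillars of triple-conserved synteny from homology and gene order.

A pillar anchors up to three gene copies per polyploid genome to one outgroup
gene (or tandem group).  Pillar construction is a combinatorial optimization:
assign homologs to pillars and order the pillars so that gene neighbours in
the extant genomes stay neighbours along the pillar sequence (the
triple-conserved-synteny score), using simulated annealing.  Per-genome
layouts are then merged on their shared outgroup anchors and a global order
is sought that minimizes synteny breaks across all genomes.
"""
from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


def filter_homologs(pairs: pd.DataFrame, min_identity: float = 0.70,
                    min_length_ratio: float = 0.80) -> pd.DataFrame:
    """Retain homolog pairs with amino-acid identity >= 70% whose shorter
    sequence is at least 80% of the longer (both thresholds inclusive).

    ``pairs`` columns: outgroup_gene, poly_gene, identity, length_ratio
    (both ratios on [0, 1]).
    """
    for col in ("identity", "length_ratio"):
        vals = pairs[col].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError(f"{col} must lie in [0, 1]")
    keep = (pairs["identity"] >= min_identity) & (pairs["length_ratio"] >= min_length_ratio)
    return pairs.loc[keep].reset_index(drop=True)


def collapse_tandems(outgroup_genes: pd.DataFrame, intra_pairs: pd.DataFrame,
                     max_gap: int = 1) -> pd.DataFrame:
    """Merge runs of homologous outgroup neighbours into single anchors.

    ``outgroup_genes`` columns: chrom, pos, gene (ordered positions);
    ``intra_pairs`` columns: gene1, gene2 (within-outgroup homolog pairs).
    Homologous genes within ``max_gap`` positions on the same chromosome are
    joined; anchors are the connected components (transitive closure), named
    after their first member.  Returns columns gene, anchor.
    """
    pos = {r.gene: (r.chrom, int(r.pos)) for r in outgroup_genes.itertuples()}
    g = nx.Graph()
    g.add_nodes_from(pos)
    for r in intra_pairs.itertuples():
        if r.gene1 in pos and r.gene2 in pos:
            c1, p1 = pos[r.gene1]
            c2, p2 = pos[r.gene2]
            if c1 == c2 and abs(p1 - p2) <= max_gap:
                g.add_edge(r.gene1, r.gene2)
    rows = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda x: pos[x])
        anchor = members[0]
        for gene in members:
            rows.append({"gene": gene, "anchor": anchor})
    return pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)


@dataclass
class PillarLayout:
    """Pillar gene assignments plus a pillar order for one or more genomes."""

    order: list  # anchors in pillar order
    slots: dict  # (anchor, genome) -> [gene or None] * 3
    genomes: tuple

    def copy(self) -> "PillarLayout":
        return PillarLayout(list(self.order),
                            {k: list(v) for k, v in self.slots.items()},
                            tuple(self.genomes))

    def genes_of(self, anchor, genome):
        return self.slots.get((anchor, genome), [None, None, None])

    def validate(self):
        seen = set()
        for (anchor, genome), genes in self.slots.items():
            if len(genes) != 3:
                raise ValueError("each pillar genome holds exactly 3 track slots")
            for gene in genes:
                if gene is None:
                    continue
                if gene in seen:
                    raise ValueError(f"gene {gene} assigned twice")
                seen.add(gene)


def tcs_objective(layout: PillarLayout, gene_pos: dict, w: int = 1) -> tuple[int, int]:
    """Triple-conserved-synteny score and break count of a layout.

    Scores each (genome, track) pair of genes in adjacent pillars: +1 when
    both genes sit on the same chromosome within ``w`` order positions
    (conserved adjacency), else it counts as a synteny break.  Pairs with an
    empty slot on either side are not counted.
    """
    score = 0
    breaks = 0
    for a, b in zip(layout.order[:-1], layout.order[1:]):
        for genome in layout.genomes:
            ga = layout.genes_of(a, genome)
            gb = layout.genes_of(b, genome)
            for k in range(3):
                if ga[k] is None or gb[k] is None:
                    continue
                ca, pa = gene_pos[ga[k]]
                cb, pb = gene_pos[gb[k]]
                if ca == cb and abs(pa - pb) <= w:
                    score += 1
                else:
                    breaks += 1
    return score, breaks


def initial_layout(anchors, homolog_candidates: dict, genome: str,
                   gene_pos: dict) -> PillarLayout:
    """Greedy starting layout for one polyploid genome.

    ``anchors`` is the ordered anchor list; ``homolog_candidates`` maps each
    polyploid gene to a list of ``(anchor, identity)`` candidates.  Genes are
    assigned to their highest-identity anchor with a free track slot (at most
    three per pillar).
    """
    order = list(anchors)
    slots = {(a, genome): [None, None, None] for a in order}
    ranked = sorted(
        ((gene, cand) for gene, cands in homolog_candidates.items() for cand in cands),
        key=lambda x: -x[1][1])
    placed = set()
    for gene, (anchor, _ident) in ranked:
        if gene in placed or (anchor, genome) not in slots:
            continue
        row = slots[(anchor, genome)]
        for k in range(3):
            if row[k] is None:
                row[k] = gene
                placed.add(gene)
                break
    return PillarLayout(order, slots, (genome,))


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule with a stall-based stop."""

    t0: float = 1.0
    cooling: float = 0.995
    patience: int = 200        # sweeps without improvement before stopping
    max_sweeps: int = 4000
    moves_per_sweep: int | None = None


def _propose(layout: PillarLayout, rng, candidate_anchors: dict | None,
             allow_assignment_moves: bool):
    """One random move: relocate a pillar block, swap tracks, or move a gene
    between pillars that share a homologous anchor."""
    new = layout.copy()
    n = len(new.order)
    kinds = ["block"]
    if n >= 1:
        kinds.append("swap_tracks")
    if allow_assignment_moves and candidate_anchors:
        kinds.append("move_gene")
    kind = kinds[rng.integers(len(kinds))]
    if kind == "block" and n >= 2:
        length = int(rng.integers(1, min(3, n) + 1))
        i = int(rng.integers(0, n - length + 1))
        block = new.order[i:i + length]
        rest = new.order[:i] + new.order[i + length:]
        if rng.random() < 0.5:
            block = block[::-1]
        j = int(rng.integers(0, len(rest) + 1))
        new.order = rest[:j] + block + rest[j:]
    elif kind == "swap_tracks":
        a = new.order[rng.integers(n)]
        genome = new.genomes[rng.integers(len(new.genomes))]
        row = list(new.genes_of(a, genome))
        k1, k2 = rng.choice(3, size=2, replace=False)
        row[k1], row[k2] = row[k2], row[k1]
        new.slots[(a, genome)] = row
    else:  # move_gene
        genes = list(candidate_anchors)
        gene = genes[rng.integers(len(genes))]
        anchors = candidate_anchors[gene]
        if len(anchors) < 2:
            return new
        genome = None
        src = None
        for (a, g), row in new.slots.items():
            if gene in row:
                genome, src = g, a
                break
        if genome is None:
            return new
        targets = [a for a in anchors if a != src and (a, genome) in new.slots
                   and None in new.slots[(a, genome)]]
        if not targets:
            return new
        dst = targets[rng.integers(len(targets))]
        srow = new.slots[(src, genome)]
        srow[srow.index(gene)] = None
        drow = new.slots[(dst, genome)]
        drow[drow.index(None)] = gene
    return new


def _polish_order(layout: PillarLayout, gene_pos: dict, w: int,
                  max_block: int = 3, max_passes: int = 30) -> PillarLayout:
    """Greedy local search over single block relocations (with reversal)."""
    best = layout.copy()
    best_score, _ = tcs_objective(best, gene_pos, w)
    n = len(best.order)
    for _ in range(max_passes):
        improved = False
        for length in range(1, min(max_block, n) + 1):
            for i in range(n - length + 1):
                block = best.order[i:i + length]
                rest = best.order[:i] + best.order[i + length:]
                for rev in (False, True):
                    blk = block[::-1] if rev else block
                    for j in range(len(rest) + 1):
                        if not rev and j == i:
                            continue
                        cand = PillarLayout(rest[:j] + blk + rest[j:],
                                            best.slots, best.genomes)
                        score, _ = tcs_objective(cand, gene_pos, w)
                        if score > best_score:
                            best, best_score = cand.copy(), score
                            improved = True
        if not improved:
            break
    return best


def anneal_layout(layout: PillarLayout, gene_pos: dict,
                  schedule: AnnealSchedule | None = None, seed: int = 0,
                  candidate_anchors: dict | None = None, w: int = 1,
                  allow_assignment_moves: bool = True) -> PillarLayout:
    """Simulated annealing over pillar orders and gene assignments.

    Maximizes the TCS score with Metropolis acceptance and geometric cooling,
    followed by a greedy block-relocation polish of the pillar order; always
    returns the best layout seen, so the result never scores below the input.
    Deterministic for a fixed seed.
    """
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    current = layout.copy()
    cur_score, _ = tcs_objective(current, gene_pos, w)
    best, best_score = current.copy(), cur_score
    temp = schedule.t0
    moves = schedule.moves_per_sweep or max(20, 2 * len(layout.order))
    stall = 0
    for _ in range(schedule.max_sweeps):
        improved = False
        for _ in range(moves):
            cand = _propose(current, rng, candidate_anchors, allow_assignment_moves)
            cand_score, _ = tcs_objective(cand, gene_pos, w)
            delta = cand_score - cur_score
            if delta >= 0 or rng.random() < np.exp(delta / max(temp, 1e-12)):
                current, cur_score = cand, cand_score
                if cur_score > best_score:
                    best, best_score = current.copy(), cur_score
                    improved = True
        temp *= schedule.cooling
        stall = 0 if improved else stall + 1
        if stall >= schedule.patience:
            break
    return _polish_order(best, gene_pos, w)


def merge_and_order(layouts: dict, gene_pos: dict, seed: int = 0,
                    schedule: AnnealSchedule | None = None, w: int = 1,
                    ) -> pd.DataFrame:
    """Merge per-genome layouts on shared anchors and order them globally.

    Only pillars with at least one surviving gene in *every* genome are
    retained.  The global order is annealed to maximize total conserved
    adjacencies (equivalently, minimize breaks); the result is emitted in the
    pillar TSV schema with per-genome break flags.
    """
    genomes = sorted(layouts)
    anchor_sets = [set(l.order) for l in layouts.values()]
    anchors = set.union(*anchor_sets) if anchor_sets else set()
    merged_slots = {}
    kept = []
    first_order = list(next(iter(layouts.values())).order)
    seen_rank = {a: i for i, a in enumerate(first_order)}
    for anchor in sorted(anchors, key=lambda a: (seen_rank.get(a, 1 << 30), str(a))):
        rows = {}
        ok = True
        for g in genomes:
            row = layouts[g].slots.get((anchor, g), [None, None, None])
            if not any(x is not None for x in row):
                ok = False
                break
            rows[g] = list(row)
        if ok:
            kept.append(anchor)
            for g in genomes:
                merged_slots[(anchor, g)] = rows[g]
    if not kept:
        raise ValueError("no pillar has a surviving gene in every genome")
    merged = PillarLayout(kept, merged_slots, tuple(genomes))
    merged = anneal_layout(merged, gene_pos, schedule=schedule, seed=seed,
                           candidate_anchors=None, w=w,
                           allow_assignment_moves=False)
    # emit pillar table with break flags
    cols: dict = {"pillar_id": [f"p{i:05d}" for i in range(len(merged.order))],
                  "order_index": list(range(len(merged.order))),
                  "anchor": list(merged.order)}
    for g in genomes:
        for k in range(3):
            cols[f"{g}.slot{k + 1}_gene"] = [
                merged.genes_of(a, g)[k] or "" for a in merged.order]
            cols[f"{g}.slot{k + 1}_present"] = [
                int(merged.genes_of(a, g)[k] is not None) for a in merged.order]
        brk = [0]
        for prev, cur in zip(merged.order[:-1], merged.order[1:]):
            cont = False
            for k in range(3):
                ga, gb = merged.genes_of(prev, g)[k], merged.genes_of(cur, g)[k]
                if ga is None or gb is None:
                    continue
                ca, pa = gene_pos[ga]
                cb, pb = gene_pos[gb]
                if ca == cb and abs(pa - pb) <= w:
                    cont = True
                    break
            brk.append(0 if cont else 1)
        cols[f"{g}.break"] = brk
    return pd.DataFrame(cols)


def build_pillars(homologs: pd.DataFrame, outgroup_genes: pd.DataFrame,
                  poly_genes: pd.DataFrame, intra_outgroup: pd.DataFrame | None = None,
                  seed: int = 0, schedule: AnnealSchedule | None = None,
                  w: int = 1, max_gap: int = 1) -> pd.DataFrame:
    """End-to-end pillar construction from raw tables.

    ``homologs``: outgroup_gene, poly_gene, identity, length_ratio (the
    70%/80% filter is applied here); ``outgroup_genes``: chrom, pos, gene;
    ``poly_genes``: genome, chrom, pos, gene.  Returns the merged, ordered
    pillar table.
    """
    kept = filter_homologs(homologs)
    intra = intra_outgroup if intra_outgroup is not None else \
        pd.DataFrame(columns=["gene1", "gene2"])
    anchor_map = collapse_tandems(outgroup_genes, intra, max_gap=max_gap)
    gene_anchor = dict(zip(anchor_map["gene"], anchor_map["anchor"]))
    anchors = list(dict.fromkeys(
        gene_anchor[g] for g in outgroup_genes.sort_values(["chrom", "pos"])["gene"]))
    gene_pos = {r.gene: (r.chrom, int(r.pos)) for r in poly_genes.itertuples()}
    layouts = {}
    rng = np.random.default_rng(seed)
    for genome, sub in poly_genes.groupby("genome"):
        cands: dict = {}
        mine = set(sub["gene"])
        for r in kept.itertuples():
            if r.poly_gene in mine and r.outgroup_gene in gene_anchor:
                cands.setdefault(r.poly_gene, []).append(
                    (gene_anchor[r.outgroup_gene], float(r.identity)))
        lay = initial_layout(anchors, cands, genome, gene_pos)
        layouts[genome] = anneal_layout(
            lay, gene_pos, schedule=schedule, seed=int(rng.integers(2 ** 31)),
            candidate_anchors={g: sorted({a for a, _ in c}) for g, c in cands.items()},
            w=w)
    return merge_and_order(layouts, gene_pos, seed=int(rng.integers(2 ** 31)),
                           schedule=schedule, w=w)
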