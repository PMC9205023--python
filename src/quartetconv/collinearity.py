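"""Chain homolog pairs into collinear blocks on gene-order coordinates.

A block is a chain of anchored pairs whose order indices are strictly
monotone on both chromosomes (ascending on one, ascending or descending on
the other), with adjacent anchors at most ``max_gap`` intervening genes
apart on both genomes.  Chains are extracted greedily by descending anchor
count (replacing a block-significance test with the minimum-length
threshold of 4 anchors), so every pair belongs to at most one block.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .models import CollinearBlock, GeneModel, HomologPair, PairStats


def filter_large_families(
    pairs: Sequence[HomologPair], family_size_cutoff: int = 50
) -> list[HomologPair]:
    """Drop pairs touching a homology-graph connected component (gene
    family) with >= ``family_size_cutoff`` members."""
    graph = nx.Graph()
    for p in pairs:
        graph.add_edge(p.gene_a, p.gene_b)
    big = set()
    for comp in nx.connected_components(graph):
        if len(comp) >= family_size_cutoff:
            big.update(comp)
    return [p for p in pairs if p.gene_a not in big and p.gene_b not in big]


def apply_blast_filters(
    pairs: Sequence[HomologPair],
    max_evalue: float = 1e-5,
    min_score: float = 100.0,
) -> list[HomologPair]:
    """Apply similarity-search cutoffs where the pair table carries them;
    pairs without score/evalue columns pass through unchanged."""
    out = []
    for p in pairs:
        if p.evalue is not None and p.evalue >= max_evalue:
            continue
        if p.score is not None and p.score <= min_score:
            continue
        out.append(p)
    return out


def _gene_index(catalogs: Iterable[Sequence[GeneModel]]) -> dict[str, GeneModel]:
    index: dict[str, GeneModel] = {}
    for catalog in catalogs:
        for g in catalog:
            index[g.gene_id] = g
    return index


def _best_chain(
    points: list[tuple[int, int, int]], max_gap: int, orientation: int
) -> list[int]:
    """Longest gap-constrained monotone chain over (a_order, b_order, idx)
    points; among maximal chains, the lexicographically smallest anchor
    sequence is returned (indices into ``points``)."""
    pts = sorted(range(len(points)), key=lambda k: (points[k][0], orientation * points[k][1]))
    n = len(pts)
    if n == 0:
        return []
    # f[k] = longest chain starting at pts[k] (forward DP computed backwards)
    f = [1] * n
    for x in range(n - 1, -1, -1):
        ax, bx, _ = points[pts[x]]
        for y in range(x + 1, n):
            ay, by, _ = points[pts[y]]
            if ay <= ax or ay - ax > max_gap:
                if ay - ax > max_gap:
                    break
                continue
            if orientation * (by - bx) <= 0 or abs(by - bx) > max_gap:
                continue
            if 1 + f[y] > f[x]:
                f[x] = 1 + f[y]
    best_len = max(f)
    # greedy lexicographic reconstruction among maximum chains
    chain: list[int] = []
    need = best_len
    prev: Optional[tuple[int, int]] = None
    candidates = range(n)
    while need > 0:
        chosen = None
        for x in candidates:
            if f[x] != need:
                continue
            ax, bx, _ = points[pts[x]]
            if prev is not None:
                pa, pb = prev
                if ax <= pa or ax - pa > max_gap:
                    continue
                if orientation * (bx - pb) <= 0 or abs(bx - pb) > max_gap:
                    continue
            if chosen is None or (ax, bx) < chosen[:2]:
                chosen = (ax, bx, x)
        if chosen is None:
            break
        x = chosen[2]
        chain.append(pts[x])
        prev = (points[pts[x]][0], points[pts[x]][1])
        need -= 1
        candidates = range(x + 1, n)
    return chain


def chain_collinear_pairs(
    pairs: Sequence[HomologPair],
    catalogs: Sequence[Sequence[GeneModel]],
    max_gap: int = 50,
    min_block_len: int = 4,
) -> list[CollinearBlock]:
    """Greedy extraction of non-overlapping collinear blocks.

    Per chromosome pair and orientation, the longest remaining
    gap-constrained chain is found by dynamic programming; the globally best
    chain (most anchors, ties by starting order index) is emitted and its
    pairs removed, until no chain reaches ``min_block_len`` anchors.
    """
    genes = _gene_index(catalogs)

    grouped: dict[tuple, list[HomologPair]] = defaultdict(list)
    for p in pairs:
        ga, gb = genes.get(p.gene_a), genes.get(p.gene_b)
        if ga is None or gb is None:
            continue
        key_a = (ga.genome, ga.chromosome)
        key_b = (gb.genome, gb.chromosome)
        # orient the group key so side a is the lexicographically smaller key
        grouped[(key_a, key_b) if key_a <= key_b else (key_b, key_a)].append(p)

    # store per-group point lists: (a_order, b_order, pair)
    groups: dict[tuple, list[tuple[int, int, HomologPair]]] = {}
    for key, plist in grouped.items():
        (gen_a, chr_a), (gen_b, chr_b) = key
        pts = []
        for p in plist:
            ga, gb = genes[p.gene_a], genes[p.gene_b]
            if (ga.genome, ga.chromosome) == (gen_a, chr_a):
                pts.append((ga.order_index, gb.order_index, p))
            else:
                pts.append((gb.order_index, ga.order_index, p))
        groups[key] = pts

    blocks: list[CollinearBlock] = []
    counter = 0
    while True:
        best = None  # (length, start_order, key, orientation, chain indices)
        for key, pts in groups.items():
            if len(pts) < min_block_len:
                continue
            coords = [(a, b, i) for i, (a, b, _) in enumerate(pts)]
            for orientation in (1, -1):
                chain = _best_chain(coords, max_gap, orientation)
                if len(chain) < min_block_len:
                    continue
                coords_seq = tuple((pts[i][0], pts[i][1]) for i in chain)
                cand = (-len(chain), coords_seq, key, orientation, chain)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None:
            break
        _, _, key, orientation, chain = best
        pts = groups[key]
        (gen_a, chr_a), (gen_b, chr_b) = key
        anchor_pairs = [pts[i] for i in chain]
        anchors = []
        for a_ord, b_ord, p in anchor_pairs:
            ga = genes[p.gene_a]
            if (ga.genome, ga.chromosome) == (gen_a, chr_a) and ga.order_index == a_ord:
                anchors.append((p.gene_a, p.gene_b))
            else:
                anchors.append((p.gene_b, p.gene_a))
        counter += 1
        blocks.append(
            CollinearBlock(
                block_id=f"b{counter:04d}",
                genome_a=gen_a,
                genome_b=gen_b,
                chrom_a=chr_a,
                chrom_b=chr_b,
                anchors=anchors,
                orientation=orientation,
            )
        )
        used = {id(p) for _, _, p in anchor_pairs}
        groups[key] = [t for t in pts if id(t[2]) not in used]
    return blocks


def annotate_blocks_ks(
    blocks: Sequence[CollinearBlock], pairstats: dict[tuple[str, str], PairStats]
) -> None:
    """Attach the median anchor Ks to each block (saturated/missing anchors
    skipped; all-missing blocks stay UNASSIGNED with no median)."""
    for block in blocks:
        values = []
        for a, b in block.anchors:
            st = pairstats.get((a, b)) or pairstats.get((b, a))
            if st is not None and st.ks is not None:
                values.append(st.ks)
        block.median_ks = float(np.median(values)) if values else None


def label_blocks_by_event(
    blocks: Sequence[CollinearBlock], windows: dict[str, tuple[float, float]]
) -> None:
    """Label each block by which (disjoint) Ks window contains its median."""
    items = sorted(windows.items(), key=lambda kv: kv[1][0])
    for (la, (lo_a, hi_a)), (lb, (lo_b, _)) in zip(items, items[1:]):
        if hi_a > lo_b:
            raise ValueError(f"event windows {la} and {lb} overlap")
    for block in blocks:
        block.event_label = "UNASSIGNED"
        if block.median_ks is None:
            continue
        for label, (lo, hi) in items:
            if lo <= block.median_ks <= hi:
                block.event_label = label
                break
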