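"""Assemble homologous gene quartets from labeled collinear blocks.

A quartet joins an anchored paralog pair (P1, P2) from a tetraploidy-labeled
block in one genome with the respective orthologs (S1, S2) of the other
genome found through ortholog-labeled blocks.  Quartets are aligned four
ways, all six pairwise NG86 statistics computed, and unreliable quartets
(gap fraction > 50% or any pairwise amino-acid identity < 40%) are dropped.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .kaks import align_pair, align_quartet, ng86
from .models import CollinearBlock, CodonAlignment, GeneModel, Quartet

MAX_GAP_FRACTION = 0.5
MIN_AA_IDENTITY = 0.4

PAIR_LABELS = {
    "P1P2": (0, 1),
    "S1S2": (2, 3),
    "P1S1": (0, 2),
    "P2S2": (1, 3),
    "P1S2": (0, 3),
    "P2S1": (1, 2),
}


def _ortholog_lookup(
    ortholog_blocks: Sequence[CollinearBlock],
) -> dict[str, list[tuple[str, int, str]]]:
    """gene -> [(partner, block length, block id)] from ORTHOLOG blocks."""
    lookup: dict[str, list[tuple[str, int, str]]] = {}
    for block in ortholog_blocks:
        if block.event_label != "ORTHOLOG":
            continue
        for a, b in block.anchors:
            lookup.setdefault(a, []).append((b, block.n_anchors, block.block_id))
            lookup.setdefault(b, []).append((a, block.n_anchors, block.block_id))
    return lookup


def _best_partner(
    lookup: dict[str, list[tuple[str, int, str]]], gene: str
) -> Optional[tuple[str, str]]:
    """Partner in the longest ortholog block; ties by lexicographic id."""
    options = lookup.get(gene)
    if not options:
        return None
    best = sorted(options, key=lambda t: (-t[1], t[0]))[0]
    return best[0], best[2]


def build_quartets(
    paralog_blocks: Sequence[CollinearBlock],
    ortholog_blocks: Sequence[CollinearBlock],
    genome_a: str,
    genome_b: str,
    paralog_label: str = "SCT",
) -> list[Quartet]:
    """Quartet skeletons (no alignments yet) for every anchored paralog pair
    of genome A whose two orthologs in genome B both exist.

    Genome-B-side quartets are produced by calling this again with the roles
    swapped.
    """
    lookup = _ortholog_lookup(ortholog_blocks)
    quartets: list[Quartet] = []
    seen: set[tuple[str, str]] = set()
    k = 0
    for block in paralog_blocks:
        if block.event_label != paralog_label:
            continue
        if block.genome_a != genome_a or block.genome_b != genome_a:
            continue
        for p1, p2 in block.anchors:
            key = tuple(sorted((p1, p2)))
            if key in seen:
                continue
            seen.add(key)
            hit1 = _best_partner(lookup, p1)
            hit2 = _best_partner(lookup, p2)
            if hit1 is None or hit2 is None:
                continue
            s1, s2 = hit1[0], hit2[0]
            if s1 == s2:
                continue
            k += 1
            quartets.append(
                Quartet(
                    quartet_id=f"{genome_a}_q{k:05d}",
                    p1=p1, p2=p2, s1=s1, s2=s2,
                    genome_a=genome_a, genome_b=genome_b,
                    provenance={
                        "paralog_block": block.block_id,
                        "ortholog_block_s1": hit1[1],
                        "ortholog_block_s2": hit2[1],
                    },
                )
            )
    return quartets


def attach_alignment_and_stats(
    quartet: Quartet, cds_by_gene: dict[str, str]
) -> Quartet:
    """Compute the shared four-way alignment and the six pairwise NG86
    statistics (each from its own pairwise alignment)."""
    genes = quartet.gene_order
    seqs = [cds_by_gene[g] for g in genes]
    quartet.alignment = align_quartet(genes, seqs)
    for label, (i, j) in PAIR_LABELS.items():
        pair_aln = align_pair(seqs[i], seqs[j], genes[i], genes[j])
        quartet.stats[label] = ng86(pair_aln)
    return quartet


def quartet_from_sequences(
    quartet_id: str,
    cds: dict[str, str],
    genome_a: str = "A",
    genome_b: str = "B",
) -> Quartet:
    """Build a fully populated quartet directly from four CDSs keyed
    'P1', 'P2', 'S1', 'S2' (the simulator's output format)."""
    q = Quartet(
        quartet_id=quartet_id,
        p1=f"{quartet_id}_P1", p2=f"{quartet_id}_P2",
        s1=f"{quartet_id}_S1", s2=f"{quartet_id}_S2",
        genome_a=genome_a, genome_b=genome_b,
    )
    mapping = {q.p1: cds["P1"], q.p2: cds["P2"], q.s1: cds["S1"], q.s2: cds["S2"]}
    return attach_alignment_and_stats(q, mapping)


def filter_quartet(quartet: Quartet) -> Quartet:
    """Apply the reliability filters; sets filter_status/filter_reason.

    Drop when any pairwise gap fraction exceeds 50% of the alignment length
    or any pairwise amino-acid identity falls below 40%.  Idempotent.
    """
    if not quartet.stats:
        raise ValueError("quartet has no pairwise statistics")
    for label in sorted(quartet.stats):
        st = quartet.stats[label]
        if st.gap_fraction > MAX_GAP_FRACTION:
            quartet.filter_status = "drop"
            quartet.filter_reason = "gap>50%"
            return quartet
    for label in sorted(quartet.stats):
        st = quartet.stats[label]
        if st.aa_identity is not None and st.aa_identity < MIN_AA_IDENTITY:
            quartet.filter_status = "drop"
            quartet.filter_reason = "identity<40%"
            return quartet
    quartet.filter_status = "keep"
    quartet.filter_reason = ""
    return quartet
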