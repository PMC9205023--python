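"""End-to-end orchestration: pairs -> blocks -> Ks -> quartets -> calls -> stats.

This is the library-level pipeline used by the command-line subcommands; it
operates on in-memory objects so synthetic studies and tests can run it
without touching disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import collinearity, conversion, ksdist, quartets as quartets_mod
from .config import PipelineConfig
from .kaks import align_pair, ng86
from .models import (
    CollinearBlock,
    ConversionCall,
    GeneModel,
    HomologPair,
    PairStats,
    Quartet,
)
from .simulate import GenomePairResult


def compute_pairstats(
    pairs: Sequence[HomologPair], cds_by_gene: dict[str, str]
) -> dict[tuple[str, str], PairStats]:
    """Pairwise codon alignment + NG86 for every pair with both CDSs known."""
    out: dict[tuple[str, str], PairStats] = {}
    for p in pairs:
        a, b = p.gene_a, p.gene_b
        if a not in cds_by_gene or b not in cds_by_gene:
            continue
        aln = align_pair(cds_by_gene[a], cds_by_gene[b], a, b)
        out[(a, b)] = ng86(aln)
    return out


def build_blocks(
    pairs: Sequence[HomologPair],
    catalogs: Sequence[Sequence[GeneModel]],
    cfg: PipelineConfig,
) -> list[CollinearBlock]:
    """Input filters (similarity cutoffs where present, large families) then
    collinear chaining."""
    filtered = collinearity.apply_blast_filters(pairs)
    filtered = collinearity.filter_large_families(filtered, cfg.family_size_cutoff)
    return collinearity.chain_collinear_pairs(
        filtered, catalogs, max_gap=cfg.max_gap, min_block_len=cfg.min_block_len
    )


def fit_event_windows(
    blocks: Sequence[CollinearBlock],
    pairstats: dict[tuple[str, str], PairStats],
    events: Sequence[str],
    cfg: PipelineConfig,
) -> tuple[dict[str, tuple[float, float]], ksdist.KsMixtureFit]:
    """Fit the anchor-Ks distribution and derive labeling windows."""
    values = []
    for b in blocks:
        for a, g in b.anchors:
            st = pairstats.get((a, g)) or pairstats.get((g, a))
            if st is not None and st.ks is not None:
                values.append(st.ks)
    grid, dens = ksdist.kde_ks(values, bandwidth=cfg.kde_bandwidth)
    fit = ksdist.fit_min_gaussians(grid, dens, r2_threshold=cfg.r2_threshold,
                                   bandwidth=cfg.kde_bandwidth)
    windows = ksdist.peaks_to_event_windows(fit, events)
    return windows, fit


@dataclass
class ScanResult:
    quartets: list[Quartet]
    calls: list[ConversionCall]
    status_by_quartet: dict[str, dict[str, str]] = field(default_factory=dict)
    n_dropped: int = 0

    def status_counts(self, genome: str) -> dict[str, int]:
        counts = {"nonconverted": 0, "WCV": 0, "PCV": 0}
        for statuses in self.status_by_quartet.values():
            counts[statuses[genome]] += 1
        return counts

    def converted_genes(self) -> set[str]:
        out = set()
        for c in self.calls:
            out.update([c.acceptor, c.donor])
        return out


def scan_quartets(
    quartet_list: Sequence[Quartet],
    cfg: PipelineConfig,
    seed: int = 0,
) -> ScanResult:
    """WCV + PCV detection on both paralog pairs of every kept quartet."""
    rng = np.random.default_rng(seed)
    calls: list[ConversionCall] = []
    status: dict[str, dict[str, str]] = {}
    kept = []
    n_dropped = 0
    for q in quartet_list:
        quartets_mod.filter_quartet(q)
        if q.filter_status != "keep":
            n_dropped += 1
            continue
        kept.append(q)
        q_calls: list[ConversionCall] = []
        for focus in ("A", "B"):
            wcv = conversion.detect_wcv(q, cfg, seed=rng, focus=focus)
            if wcv is not None:
                q_calls.append(wcv)
            q_calls.extend(conversion.detect_pcv(q, cfg, seed=rng, focus=focus))
        calls.extend(q_calls)
        status[q.quartet_id] = conversion.classify_quartet(q_calls, q)
    return ScanResult(quartets=kept, calls=calls, status_by_quartet=status,
                      n_dropped=n_dropped)


@dataclass
class SyntheticRunResult:
    blocks_a: list[CollinearBlock]
    blocks_b: list[CollinearBlock]
    blocks_orth: list[CollinearBlock]
    windows_intra: dict[str, tuple[float, float]]
    windows_orth: dict[str, tuple[float, float]]
    scan: ScanResult
    pairstats: dict[tuple[str, str], PairStats]


def run_synthetic_pipeline(
    sim: GenomePairResult,
    cfg: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> SyntheticRunResult:
    """Full pipeline on a simulated genome pair."""
    cfg = cfg or PipelineConfig()
    genomes = sorted(sim.catalogs)
    genome_a, genome_b = genomes[0], genomes[1]
    cds = {g.gene_id: g.cds for cat in sim.catalogs.values() for g in cat}

    blocks_a = build_blocks(sim.paralog_pairs[genome_a], [sim.catalogs[genome_a]], cfg)
    blocks_b = build_blocks(sim.paralog_pairs[genome_b], [sim.catalogs[genome_b]], cfg)
    blocks_orth = build_blocks(
        sim.ortholog_pairs, [sim.catalogs[genome_a], sim.catalogs[genome_b]], cfg
    )

    all_pairs = (list(sim.paralog_pairs[genome_a]) + list(sim.paralog_pairs[genome_b])
                 + list(sim.ortholog_pairs))
    pairstats = compute_pairstats(all_pairs, cds)

    for blocks in (blocks_a, blocks_b, blocks_orth):
        collinearity.annotate_blocks_ks(blocks, pairstats)

    intra_blocks = blocks_a + blocks_b
    windows_intra, _ = fit_event_windows(intra_blocks, pairstats, ["SCT"], cfg)
    windows_orth, _ = fit_event_windows(blocks_orth, pairstats, ["ORTHOLOG"], cfg)
    collinearity.label_blocks_by_event(blocks_a, windows_intra)
    collinearity.label_blocks_by_event(blocks_b, windows_intra)
    collinearity.label_blocks_by_event(blocks_orth, windows_orth)

    qs = quartets_mod.build_quartets(blocks_a, blocks_orth, genome_a, genome_b)
    seen = {frozenset(q.gene_order) for q in qs}
    for q in quartets_mod.build_quartets(blocks_b, blocks_orth, genome_b, genome_a):
        if frozenset(q.gene_order) not in seen:
            qs.append(q)
    for q in qs:
        quartets_mod.attach_alignment_and_stats(q, cds)

    scan = scan_quartets(qs, cfg, seed=seed)
    return SyntheticRunResult(
        blocks_a=blocks_a, blocks_b=blocks_b, blocks_orth=blocks_orth,
        windows_intra=windows_intra, windows_orth=windows_orth,
        scan=scan, pairstats=pairstats,
    )
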