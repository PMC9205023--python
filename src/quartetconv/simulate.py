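"""Synthetic quartets, genome layouts and expression tables with ground truth.

The quartet simulator evolves codon sequences on the topology
((P1,S1),(P2,S2)) rooted at the whole-genome duplication.  Substitutions are
proposed uniformly per nucleotide site (Jukes–Cantor style); synonymous
proposals are always accepted, nonsynonymous ones with probability equal to
the Ka/Ks ratio, and proposals creating stop codons are rejected.  With this
acceptance scheme the expected NG86 Ks between two tips equals the sum of
their branch lengths, so the generator's divergence targets are recovered by
the estimator without further calibration.

Gene conversion is implanted by overwriting the acceptor's tract with the
donor's current sequence at a configurable time point between speciation
(time_fraction 0) and the present (time_fraction 1), after which both copies
continue to evolve independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .codontables import AA_BY_CODON_INDEX, IS_STOP, NUCS, SENSE_CODONS
from .models import (
    ConversionCall,
    GeneModel,
    HomologPair,
    SimTruth,
    SimTruthEvent,
)

_GENE_NAMES = ("P1", "P2", "S1", "S2")


@dataclass(frozen=True)
class ConversionSpec:
    """One conversion event to implant: whole-gene or a nucleotide tract."""

    kind: str  # 'whole' | 'tract'
    acceptor: str  # one of P1, P2, S1, S2
    donor: str
    tract_start: int = 1  # 1-based inclusive nt, ignored for 'whole'
    tract_end: int = -1
    time_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in {"whole", "tract"}:
            raise ValueError(f"unknown conversion kind {self.kind!r}")
        if self.acceptor not in _GENE_NAMES or self.donor not in _GENE_NAMES:
            raise ValueError("acceptor/donor must be one of P1, P2, S1, S2")
        if {self.acceptor, self.donor} not in ({"P1", "P2"}, {"S1", "S2"}):
            raise ValueError("conversion must act within one genome's paralog pair")
        if not (0.0 <= self.time_fraction <= 1.0):
            raise ValueError("time_fraction must lie in [0, 1]")


@dataclass
class QuartetSimConfig:
    n_codons: int = 500
    k_par: float = 0.25
    k_orth: float = 0.12
    ka_ks_ratio: float = 0.3
    conversion: Union[ConversionSpec, Sequence[ConversionSpec], None] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.k_orth < self.k_par or self.k_par == self.k_orth == 0.0):
            raise ValueError("require 0 <= k_orth < k_par (or both zero)")
        for k in (self.k_par, self.k_orth):
            p = 0.75 * (1.0 - math.exp(-4.0 * k / 3.0))
            if p > 0.74:
                raise ValueError(f"divergence {k} is too close to JC saturation")
        for ev in self.events:
            if ev.kind == "tract":
                if not (1 <= ev.tract_start <= ev.tract_end <= 3 * self.n_codons):
                    raise ValueError("tract outside the alignment")

    @property
    def events(self) -> list[ConversionSpec]:
        if self.conversion is None:
            return []
        if isinstance(self.conversion, ConversionSpec):
            return [self.conversion]
        return list(self.conversion)


def _random_ancestor(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    codons = rng.choice(SENSE_CODONS, size=n_codons)
    nt = np.empty(3 * n_codons, dtype=np.int8)
    nt[0::3] = codons >> 4
    nt[1::3] = (codons >> 2) & 3
    nt[2::3] = codons & 3
    return nt


def _evolve(seq: np.ndarray, branch_ks: float, omega: float, rng: np.random.Generator) -> None:
    """Evolve ``seq`` in place along a branch of expected synonymous length
    ``branch_ks`` substitutions per synonymous site."""
    if branch_ks <= 0:
        return
    n_nt = seq.size
    n_events = rng.poisson(branch_ks * n_nt)
    positions = rng.integers(0, n_nt, size=n_events)
    offsets = rng.integers(1, 4, size=n_events)
    accept_draws = rng.random(size=n_events)
    for pos, off, u in zip(positions, offsets, accept_draws):
        cod_start = 3 * (pos // 3)
        old_codon = (seq[cod_start] << 4) | (seq[cod_start + 1] << 2) | seq[cod_start + 2]
        new_nt = (seq[pos] + off) % 4
        shift = (2 - (pos - cod_start)) * 2
        new_codon = (old_codon & ~(3 << shift)) | (int(new_nt) << shift)
        if IS_STOP[new_codon]:
            continue
        if AA_BY_CODON_INDEX[new_codon] != AA_BY_CODON_INDEX[old_codon] and u >= omega:
            continue
        seq[pos] = new_nt


def _to_string(seq: np.ndarray) -> str:
    return "".join(NUCS[b] for b in seq)


def simulate_quartet(
    cfg: QuartetSimConfig, seed: Union[int, np.random.Generator]
) -> tuple[dict[str, str], SimTruth, ]:
    """Simulate one quartet; returns ({'P1':..., 'P2':..., 'S1':..., 'S2':...},
    SimTruth)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cfg.n_codons
    omega = cfg.ka_ks_ratio
    t_pre = 0.5 * (cfg.k_par - cfg.k_orth)  # WGD -> speciation, per branch
    t_post = 0.5 * cfg.k_orth  # speciation -> present, per branch

    ancestor = _random_ancestor(n, rng)
    copy1 = ancestor.copy()
    copy2 = ancestor.copy()
    _evolve(copy1, t_pre, omega, rng)
    _evolve(copy2, t_pre, omega, rng)

    tips = {"P1": copy1.copy(), "S1": copy1, "P2": copy2.copy(), "S2": copy2}

    events = sorted(cfg.events, key=lambda e: e.time_fraction)
    truth = SimTruth(quartet_id="q0", events=[])
    t_done = 0.0
    for ev in events:
        dt = (ev.time_fraction - t_done) * t_post
        for s in tips.values():
            _evolve(s, dt, omega, rng)
        t_done = ev.time_fraction
        if ev.kind == "whole":
            lo, hi = 1, 3 * n
        else:
            lo, hi = ev.tract_start, ev.tract_end
        tips[ev.acceptor][lo - 1 : hi] = tips[ev.donor][lo - 1 : hi]
        truth.events.append(
            SimTruthEvent(
                event_type="WCV" if ev.kind == "whole" else "PCV",
                acceptor=ev.acceptor,
                donor=ev.donor,
                tract_start=lo,
                tract_end=hi,
                time_fraction=ev.time_fraction,
            )
        )
    dt = (1.0 - t_done) * t_post
    for s in tips.values():
        _evolve(s, dt, omega, rng)

    return {name: _to_string(tips[name]) for name in _GENE_NAMES}, truth


@dataclass
class QuartetSetResult:
    sequences: dict[str, dict[str, str]]  # quartet_id -> gene role -> CDS
    truths: list[SimTruth]


def simulate_quartet_set(
    n: int,
    pcv_fraction: float,
    wcv_fraction: float,
    cfg: Optional[QuartetSimConfig] = None,
    seed: int = 0,
    tract_len_range: tuple[int, int] = (30, 120),
) -> QuartetSetResult:
    """Simulate ``n`` quartets; event types assigned by the given fractions,
    PCV tract lengths drawn uniformly from ``tract_len_range`` (nt)."""
    if pcv_fraction + wcv_fraction > 1.0 + 1e-12:
        raise ValueError("pcv_fraction + wcv_fraction must not exceed 1")
    cfg = cfg or QuartetSimConfig()
    rng = np.random.default_rng(seed)
    n_pcv = int(round(n * pcv_fraction))
    n_wcv = int(round(n * wcv_fraction))
    kinds = ["tract"] * n_pcv + ["whole"] * n_wcv + [None] * (n - n_pcv - n_wcv)
    rng.shuffle(kinds)

    sequences: dict[str, dict[str, str]] = {}
    truths: list[SimTruth] = []
    for k, kind in enumerate(kinds):
        qid = f"q{k:05d}"
        conv: Optional[ConversionSpec] = None
        if kind == "whole":
            conv = ConversionSpec(kind="whole", acceptor="P2", donor="P1",
                                  time_fraction=cfg.events[0].time_fraction if cfg.events else 1.0)
        elif kind == "tract":
            tl = int(rng.integers(tract_len_range[0], tract_len_range[1] + 1))
            start = int(rng.integers(1, 3 * cfg.n_codons - tl + 2))
            conv = ConversionSpec(kind="tract", acceptor="P2", donor="P1",
                                  tract_start=start, tract_end=start + tl - 1,
                                  time_fraction=cfg.events[0].time_fraction if cfg.events else 1.0)
        qcfg = replace(cfg, conversion=conv)
        seqs, truth = simulate_quartet(qcfg, rng)
        truth.quartet_id = qid
        sequences[qid] = seqs
        truths.append(truth)
    return QuartetSetResult(sequences=sequences, truths=truths)


# ---------------------------------------------------------------------------
# genome-pair simulation
# ---------------------------------------------------------------------------


def _as_profile(p: Union[float, Callable[[float], float]]) -> Callable[[float], float]:
    if callable(p):
        return p
    value = float(p)
    return lambda _t: value


@dataclass
class GenomePairResult:
    catalogs: dict[str, list[GeneModel]]  # genome label -> genes
    paralog_pairs: dict[str, list[HomologPair]]  # per genome
    ortholog_pairs: list[HomologPair]
    truth_calls: list[SimTruthEvent]
    converted_genes: set[str] = field(default_factory=set)
    duplicate_genes: set[str] = field(default_factory=set)
    quartet_gene_sets: list[tuple[str, str, str, str]] = field(default_factory=list)


def simulate_genome_pair(
    n_chrom: int = 2,
    genes_per_chrom: int = 200,
    duplicate_density_profile: Union[float, Callable[[float], float]] = 0.4,
    converted_rate_profile: Union[float, Callable[[float], float]] = 0.1,
    seed: int = 0,
    n_codons: int = 200,
    wcv_fraction_of_converted: float = 0.15,
    genome_a: str = "P",
    genome_b: str = "S",
    k_par: float = 0.25,
    k_orth: float = 0.12,
    ka_ks_ratio: float = 0.3,
    gene_spacing_bp: int = 5000,
    tract_len_range: tuple[int, int] = (30, 120),
    with_sequences: bool = True,
) -> GenomePairResult:
    """Simulate two genomes with homoeologous chromosome pairs.

    Each ancestral chromosome yields two homoeologs per genome ('a' and 'b'
    copies from the shared tetraploidization).  An ancestral gene is retained
    as a duplicate pair (on both copies, in both genomes, forming a full
    quartet) with probability ``duplicate_density_profile(t)`` where t is the
    relative position along the chromosome; otherwise it survives as a single
    copy on one homoeolog with its ortholog in the other genome.  Duplicates
    are converted with probability ``converted_rate_profile(t)`` (conversion
    implanted in genome A's paralog pair).
    """
    density = _as_profile(duplicate_density_profile)
    conv_rate = _as_profile(converted_rate_profile)
    rng = np.random.default_rng(seed)

    catalogs: dict[str, list[GeneModel]] = {genome_a: [], genome_b: []}
    paralog_pairs: dict[str, list[HomologPair]] = {genome_a: [], genome_b: []}
    ortholog_pairs: list[HomologPair] = []
    truth_calls: list[SimTruthEvent] = []
    converted: set[str] = set()
    duplicates: set[str] = set()
    quartet_sets: list[tuple[str, str, str, str]] = []

    gene_len = 3 * n_codons

    for ci in range(1, n_chrom + 1):
        # per-homoeolog running placement state: next order index and bp offset
        chrom_names = {
            (genome_a, "a"): f"{genome_a}{ci}a",
            (genome_a, "b"): f"{genome_a}{ci}b",
            (genome_b, "a"): f"{genome_b}{ci}a",
            (genome_b, "b"): f"{genome_b}{ci}b",
        }
        placed: dict[tuple[str, str], int] = {k: 0 for k in chrom_names}

        def place(genome: str, copy: str, gene_id: str, cds: str) -> None:
            k = (genome, copy)
            rank = placed[k]
            start = 1 + rank * gene_spacing_bp
            catalogs[genome].append(
                GeneModel(
                    gene_id=gene_id,
                    genome=genome,
                    chromosome=chrom_names[k],
                    start_bp=start,
                    end_bp=start + gene_len - 1,
                    strand="+",
                    order_index=rank,
                    cds=cds,
                )
            )
            placed[k] += 1

        for j in range(genes_per_chrom):
            t = j / max(genes_per_chrom - 1, 1)
            d = density(t)
            c = conv_rate(t)
            if not (0.0 <= d <= 1.0) or not (0.0 <= c <= 1.0):
                raise ValueError("profiles must take values in [0, 1]")
            is_dup = rng.random() < d
            tag = f"{ci}g{j:04d}"

            if is_dup:
                is_conv = rng.random() < c
                conv_spec: Optional[ConversionSpec] = None
                if is_conv:
                    if rng.random() < wcv_fraction_of_converted:
                        conv_spec = ConversionSpec(kind="whole", acceptor="P2", donor="P1")
                    else:
                        tl = int(rng.integers(tract_len_range[0], tract_len_range[1] + 1))
                        start = int(rng.integers(1, gene_len - tl + 2))
                        conv_spec = ConversionSpec(kind="tract", acceptor="P2", donor="P1",
                                                   tract_start=start, tract_end=start + tl - 1)
                if with_sequences:
                    cfg = QuartetSimConfig(n_codons=n_codons, k_par=k_par, k_orth=k_orth,
                                           ka_ks_ratio=ka_ks_ratio, conversion=conv_spec)
                    seqs, truth = simulate_quartet(cfg, rng)
                else:
                    seqs = {g: "" for g in _GENE_NAMES}
                    truth = SimTruth(quartet_id="", events=[])
                    if conv_spec is not None:
                        lo, hi = ((1, gene_len) if conv_spec.kind == "whole"
                                  else (conv_spec.tract_start, conv_spec.tract_end))
                        truth.events.append(SimTruthEvent(
                            event_type="WCV" if conv_spec.kind == "whole" else "PCV",
                            acceptor="P2", donor="P1", tract_start=lo, tract_end=hi,
                            time_fraction=conv_spec.time_fraction))

                ids = {
                    "P1": f"{genome_a}{ci}a_{tag}",
                    "P2": f"{genome_a}{ci}b_{tag}",
                    "S1": f"{genome_b}{ci}a_{tag}",
                    "S2": f"{genome_b}{ci}b_{tag}",
                }
                place(genome_a, "a", ids["P1"], seqs["P1"])
                place(genome_a, "b", ids["P2"], seqs["P2"])
                place(genome_b, "a", ids["S1"], seqs["S1"])
                place(genome_b, "b", ids["S2"], seqs["S2"])
                duplicates.update(ids.values())
                quartet_sets.append((ids["P1"], ids["P2"], ids["S1"], ids["S2"]))
                paralog_pairs[genome_a].append(HomologPair(ids["P1"], ids["P2"]))
                paralog_pairs[genome_b].append(HomologPair(ids["S1"], ids["S2"]))
                ortholog_pairs.append(HomologPair(ids["P1"], ids["S1"]))
                ortholog_pairs.append(HomologPair(ids["P2"], ids["S2"]))
                for ev in truth.events:
                    converted.update([ids[ev.acceptor], ids[ev.donor]])
                    truth_calls.append(SimTruthEvent(
                        event_type=ev.event_type,
                        acceptor=ids[ev.acceptor],
                        donor=ids[ev.donor],
                        tract_start=ev.tract_start,
                        tract_end=ev.tract_end,
                        time_fraction=ev.time_fraction,
                    ))
            else:
                copy = "a" if rng.random() < 0.5 else "b"
                if with_sequences:
                    cfg = QuartetSimConfig(n_codons=n_codons, k_par=k_par, k_orth=k_orth,
                                           ka_ks_ratio=ka_ks_ratio)
                    seqs, _ = simulate_quartet(cfg, rng)
                else:
                    seqs = {g: "" for g in _GENE_NAMES}
                id_a = f"{genome_a}{ci}{copy}_{tag}"
                id_b = f"{genome_b}{ci}{copy}_{tag}"
                place(genome_a, copy, id_a, seqs["P1"])
                place(genome_b, copy, id_b, seqs["S1"])
                ortholog_pairs.append(HomologPair(id_a, id_b))

    return GenomePairResult(
        catalogs=catalogs,
        paralog_pairs=paralog_pairs,
        ortholog_pairs=ortholog_pairs,
        truth_calls=truth_calls,
        converted_genes=converted,
        duplicate_genes=duplicates,
        quartet_gene_sets=quartet_sets,
    )


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


@dataclass
class ExpressionEffectConfig:
    """Log-normal TPM model for duplicate pairs.

    ``spread_*`` are the standard deviations (log2 scale) of the between-copy
    fold change for converted / nonconverted pairs; the pair mean TPM is
    log-normal with the given log-scale mean and sd.
    """

    spread_converted: float = 1.42
    spread_nonconverted: float = 1.67
    log_tpm_mean: float = 3.0
    log_tpm_sd: float = 1.0
    mean_shift_converted: float = -0.25  # converted pairs slightly less expressed

    def __post_init__(self) -> None:
        if self.spread_converted < 0 or self.spread_nonconverted < 0:
            raise ValueError("spreads must be non-negative")


def simulate_expression(
    pairs: Sequence[HomologPair],
    converted_flags: Sequence[bool],
    effect_cfg: Optional[ExpressionEffectConfig] = None,
    seed: int = 0,
) -> dict[str, float]:
    """TPM per gene for each duplicate pair; converted pairs are drawn with a
    smaller between-copy log-fold spread."""
    cfg = effect_cfg or ExpressionEffectConfig()
    rng = np.random.default_rng(seed)
    tpm: dict[str, float] = {}
    for pair, conv in zip(pairs, converted_flags):
        shift = cfg.mean_shift_converted if conv else 0.0
        mean_tpm = float(np.exp(rng.normal(cfg.log_tpm_mean + shift, cfg.log_tpm_sd)))
        spread = cfg.spread_converted if conv else cfg.spread_nonconverted
        delta = float(rng.normal(0.0, spread)) if spread > 0 else 0.0
        tpm[pair.gene_a] = mean_tpm * 2.0 ** (0.5 * delta)
        tpm[pair.gene_b] = mean_tpm * 2.0 ** (-0.5 * delta)
    return tpm
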