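"""Domain types for the quartet gene-conversion pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence


@dataclass
class GeneModel:
    """A gene with its genomic context and coding sequence.

    Coordinates are 1-based inclusive (GFF3 convention) on disk and in this
    object; ``order_index`` is the 0-based rank of the gene along its
    chromosome by ascending start.
    """

    gene_id: str
    genome: str
    chromosome: str
    start_bp: int
    end_bp: int
    strand: str = "+"
    order_index: int = -1
    cds: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.gene_id}: start_bp > end_bp")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)


@dataclass(frozen=True)
class HomologPair:
    """An unordered homologous gene pair (canonicalized lexicographically)."""

    gene_a: str
    gene_b: str
    score: Optional[float] = None
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class PairStats:
    """NG86 distances for one aligned gene pair.

    ``ka``/``ks`` are the Jukes–Cantor-corrected proper distances
    (substitutions per site); ``pn``/``ps`` are aliases for the same values
    under the notation used for JC-corrected rates in the output tables.
    """

    gene_a: str
    gene_b: str
    ka: Optional[float]
    ks: Optional[float]
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    aa_identity: Optional[float]
    gap_fraction: float
    saturated: bool = False
    reason: str = ""

    @property
    def pn(self) -> Optional[float]:
        return self.ka

    @property
    def ps(self) -> Optional[float]:
        return self.ks


@dataclass
class CodonAlignment:
    """A codon-aware alignment: aligned nucleotide strings with '-' gaps.

    Gaps occur in whole-codon units; removing them recovers each input CDS.
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("aligned sequences differ in length")
        if self.seqs and len(self.seqs[0]) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n_codon_columns(self) -> int:
        return self.length // 3

    def ungapped(self, i: int) -> str:
        return self.seqs[i].replace("-", "")

    def column_to_ungapped(self, i: int) -> list[int]:
        """For sequence i, map each alignment column to its 0-based ungapped
        position, or -1 for gap columns."""
        out = []
        pos = 0
        for ch in self.seqs[i]:
            if ch == "-":
                out.append(-1)
            else:
                out.append(pos)
                pos += 1
        return out


@dataclass
class CollinearBlock:
    """An ordered chain of anchored homolog pairs between two chromosomes."""

    block_id: str
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]
    orientation: int = 1  # +1 ascending, -1 descending in genome b
    median_ks: Optional[float] = None
    event_label: str = "UNASSIGNED"

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class KsMixtureFit:
    bandwidth: float
    grid: "list[float]"
    density: "list[float]"
    components: list[tuple[float, float, float]]  # (weight, mean, sd)
    r_squared: float
    n_components: int
    converged: bool = True


@dataclass
class Quartet:
    """Paralogs P1,P2 (genome A) with orthologs S1,S2 (genome B).

    ``alignment`` is the shared four-way codon alignment in order
    [P1, P2, S1, S2]; ``stats`` maps pair labels ('P1P2', 'S1S2', 'P1S1',
    'P2S2', 'P1S2', 'P2S1') to PairStats from pairwise alignments.
    """

    quartet_id: str
    p1: str
    p2: str
    s1: str
    s2: str
    genome_a: str = "A"
    genome_b: str = "B"
    alignment: Optional[CodonAlignment] = None
    stats: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    filter_status: str = "keep"
    filter_reason: str = ""

    @property
    def gene_order(self) -> list[str]:
        return [self.p1, self.p2, self.s1, self.s2]


@dataclass
class ConversionCall:
    """One whole- (WCV) or partial-gene (PCV) conversion event call."""

    quartet_id: str
    call_type: str  # 'WCV' | 'PCV'
    converted_genome: str
    acceptor: str
    donor: str
    tract_start: int  # 1-based inclusive, acceptor ungapped nt coordinates
    tract_end: int
    col_start: int  # 0-based alignment column span
    col_end: int
    score: float
    p_value: float
    direction_confidence: str = "resolved"  # resolved | ambiguous | both_copies

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


@dataclass
class SimTruthEvent:
    event_type: str  # 'WCV' | 'PCV'
    acceptor: str
    donor: str
    tract_start: int  # 1-based inclusive nt in the (gap-free) acceptor
    tract_end: int
    time_fraction: float


@dataclass
class SimTruth:
    quartet_id: str
    events: list[SimTruthEvent] = field(default_factory=list)


@dataclass
class RateRecord:
    label: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError(f"{self.label}: denominator must be positive")
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError(f"{self.label}: counts out of range")

    @property
    def percent(self) -> float:
        return round(100.0 * self.numerator / self.denominator, 2)


@dataclass
class WindowStat:
    chromosome: str
    window_index: int  # distance rank from the nearest chromosome terminus
    n_genes: int
    n_duplicates: int
    n_converted: int

    @property
    def duplicate_density(self) -> Optional[float]:
        return self.n_duplicates / self.n_genes if self.n_genes else None

    @property
    def conversion_rate(self) -> Optional[float]:
        return self.n_converted / self.n_duplicates if self.n_duplicates else None


Profile = Callable[[float], float]
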