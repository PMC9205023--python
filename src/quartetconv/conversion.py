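"""Whole- and partial-gene conversion calls within homologous quartets.

Partial-gene conversion (PCV) is detected from per-column mismatch profiles
on the shared four-way alignment: at each column the paralog mismatch state
is subtracted from the mean ortholog mismatch state, so runs of positive
score mark regions where the paralogs are locally *more* similar than each
copy is to its own ortholog — the signature of a conversion tract.  Candidate
tracts are the Ruzzo–Tompa maximal scoring segments (>= 10 informative
columns), tested by a column-resampling bootstrap and reported recursively
after masking, so multiple tracts per gene can be recovered.

Whole-gene conversion (WCV) is called when the paralog Ks drops below both
ortholog Ks values AND the four-taxon topology places the paralogs as
sisters with bootstrap support >= 0.95.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .kaks import jc_correct
from .models import CodonAlignment, ConversionCall, Quartet

_VALID_NT = frozenset("ACGT")

#: minimum bootstrap support for the paralogs-sister topology in a WCV call
WCV_SUPPORT = 0.95
#: ortholog-Ks ratio under which WCV direction is reported as both_copies
WCV_SYMMETRY_RATIO = 1.2


# ---------------------------------------------------------------------------
# site profiles and scores
# ---------------------------------------------------------------------------


def _char_matrix(alignment: CodonAlignment) -> np.ndarray:
    return np.array([np.frombuffer(s.encode(), dtype="S1") for s in alignment.seqs])


def site_profiles(quartet: Quartet, focus: str = "A") -> dict[str, np.ndarray]:
    """Mismatch profiles (0 match, 1 mismatch, NaN missing) over alignment
    columns for the scanned paralog pair and the two ortholog pairs.

    ``focus='A'`` scans paralogs (P1,P2); ``focus='B'`` scans (S1,S2).  A
    column where any of the four genes has a gap or ambiguous base is missing
    in all profiles.
    """
    aln = quartet.alignment
    if aln is None:
        raise ValueError("quartet has no alignment")
    chars = _char_matrix(aln).view(np.uint8)
    valid_char = np.zeros(256, dtype=bool)
    for c in "ACGTacgt":
        valid_char[ord(c)] = True
    ok = valid_char[chars]
    missing = ~ok.all(axis=0)

    # alignment row order is [P1, P2, S1, S2]
    def prof(i: int, j: int) -> np.ndarray:
        upper = chars | 0x20  # case-fold
        p = (upper[i] != upper[j]).astype(float)
        p[missing] = np.nan
        return p

    if focus == "A":
        return {"par": prof(0, 1), "orth1": prof(0, 2), "orth2": prof(1, 3)}
    if focus == "B":
        return {"par": prof(2, 3), "orth1": prof(0, 2), "orth2": prof(1, 3)}
    raise ValueError("focus must be 'A' or 'B'")


def conversion_score_array(
    par: np.ndarray, orth1: np.ndarray, orth2: np.ndarray
) -> np.ndarray:
    """Per-column score o(i) - p(i): mean ortholog mismatch minus paralog
    mismatch, missing-aware; columns with no usable comparison score 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        o = np.nanmean(np.vstack([orth1, orth2]), axis=0)
    score = o - par
    score[np.isnan(score)] = 0.0
    return score


# ---------------------------------------------------------------------------
# maximal scoring segments (Ruzzo–Tompa)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    start: int  # 0-based inclusive alignment column
    end: int  # 0-based inclusive
    score: float
    n_informative: int = 0  # non-missing columns within the span


def ruzzo_tompa(scores: np.ndarray) -> list[Segment]:
    """All maximal scoring segments with positive total score."""
    stack: list[list[float]] = []  # [start, end_exclusive, Lval, Rval]
    cum = 0.0
    for i, s in enumerate(scores):
        left = cum
        cum += float(s)
        if s <= 0:
            continue
        seg = [i, i + 1, left, cum]
        while True:
            j = len(stack) - 1
            while j >= 0 and stack[j][2] >= seg[2]:
                j -= 1
            if j < 0 or stack[j][3] >= seg[3]:
                stack.append(seg)
                break
            merged = [stack[j][0], seg[1], stack[j][2], seg[3]]
            del stack[j:]
            seg = merged
    return [
        Segment(start=int(a), end=int(b) - 1, score=r - l)
        for a, b, l, r in stack
    ]


def maximal_scoring_segments(
    scores: np.ndarray,
    min_tract_len: int = 10,
    missing: Optional[np.ndarray] = None,
) -> list[Segment]:
    """Ruzzo–Tompa segments spanning >= ``min_tract_len`` informative
    (non-missing) columns, sorted by descending score then start."""
    segs = []
    for seg in ruzzo_tompa(scores):
        if missing is None:
            n_inf = seg.end - seg.start + 1
        else:
            n_inf = int((~missing[seg.start : seg.end + 1]).sum())
        if n_inf >= min_tract_len:
            segs.append(Segment(seg.start, seg.end, seg.score, n_inf))
    segs.sort(key=lambda g: (-g.score, g.start))
    return segs


def _best_subarray_scores(samples: np.ndarray) -> np.ndarray:
    """Per-row best (maximum-sum) contiguous segment score; 0 if none positive."""
    b, n = samples.shape
    c = np.concatenate([np.zeros((b, 1)), np.cumsum(samples, axis=1)], axis=1)
    runmin = np.minimum.accumulate(c[:, :-1], axis=1)
    return np.maximum((c[:, 1:] - runmin).max(axis=1), 0.0)


def bootstrap_segment_p(
    scores: np.ndarray,
    segment: Segment,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Resampling p-value for a candidate segment.

    The null shuffles the score columns B times — in codon-sized blocks, so
    the strong first/second/third-position heterogeneity of the score
    distribution is preserved — and records each replicate's best segment
    score (the maximum-sum subarray, which equals the top Ruzzo–Tompa
    segment score).  Column permutation keeps the observed column multiset
    fixed, so under column exchangeability the p-value is exactly calibrated
    up to the discreteness of the half-integer scores; ties between null and
    observed are counted half (mid-p), with an add-one floor of 1/(B+1).
    """
    if B < 100:
        warnings.warn("resampling with B < 100 replicates is unreliable")
    if segment.score <= 0:
        return 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = scores.size
    if n % 3 == 0 and n >= 3:
        blocks = scores.reshape(n // 3, 3)
        perm = np.argsort(rng.random((B, blocks.shape[0])), axis=1)
        samples = blocks[perm].reshape(B, n)
    else:
        perm = np.argsort(rng.random((B, n)), axis=1)
        samples = scores[perm]
    null = _best_subarray_scores(samples)
    greater = int((null > segment.score + 1e-9).sum())
    ties = int((np.abs(null - segment.score) <= 1e-9).sum())
    return (1 + greater + 0.5 * ties) / (B + 1)


# ---------------------------------------------------------------------------
# PCV detection (recursive scan with masking)
# ---------------------------------------------------------------------------


def _map_span_to_gene(
    aln: CodonAlignment, row: int, col_start: int, col_end: int
) -> tuple[int, int]:
    """Alignment column span -> 1-based inclusive ungapped nt coordinates of
    the given row."""
    colmap = aln.column_to_ungapped(row)
    inside = [p for p in colmap[col_start : col_end + 1] if p >= 0]
    if not inside:
        return 0, -1
    return inside[0] + 1, inside[-1] + 1


def detect_pcv(
    quartet: Quartet,
    params: Optional[PipelineConfig] = None,
    seed: int | np.random.Generator = 0,
    focus: str = "A",
    max_rounds: int = 10,
) -> list[ConversionCall]:
    """Recursive partial-gene conversion scan of one paralog pair.

    Each round scores the alignment, takes the top qualifying maximal
    segment, bootstrap-tests it, emits a call if p <= alpha, masks its
    columns, and repeats (up to ``max_rounds`` rounds).
    """
    params = params or PipelineConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profiles = site_profiles(quartet, focus=focus)
    missing = np.isnan(profiles["par"])
    base_scores = conversion_score_array(profiles["par"], profiles["orth1"], profiles["orth2"])

    aln = quartet.alignment
    if focus == "A":
        gene_rows = {quartet.p1: 0, quartet.p2: 1}
        pair = (quartet.p1, quartet.p2)
        genome = quartet.genome_a
    else:
        gene_rows = {quartet.s1: 2, quartet.s2: 3}
        pair = (quartet.s1, quartet.s2)
        genome = quartet.genome_b

    calls: list[ConversionCall] = []
    mask = np.zeros(base_scores.size, dtype=bool)
    for _ in range(max_rounds):
        scores = base_scores.copy()
        scores[mask] = 0.0
        segments = maximal_scoring_segments(scores, params.min_tract_len, missing | mask)
        if not segments:
            break
        best = segments[0]
        p = bootstrap_segment_p(scores, best, B=params.bootstrap_B, seed=rng)
        if p > params.alpha:
            break

        span = slice(best.start, best.end + 1)
        m1 = np.nansum(profiles["orth1"][span][~mask[span]])
        m2 = np.nansum(profiles["orth2"][span][~mask[span]])
        if m1 > m2:
            acceptor, donor = pair[0], pair[1]
            confidence = "resolved"
        elif m2 > m1:
            acceptor, donor = pair[1], pair[0]
            confidence = "resolved"
        else:
            acceptor, donor = sorted(pair)
            confidence = "ambiguous"

        t_start, t_end = _map_span_to_gene(aln, gene_rows[acceptor], best.start, best.end)
        calls.append(
            ConversionCall(
                quartet_id=quartet.quartet_id,
                call_type="PCV",
                converted_genome=genome,
                acceptor=acceptor,
                donor=donor,
                tract_start=t_start,
                tract_end=t_end,
                col_start=best.start,
                col_end=best.end,
                score=best.score,
                p_value=p,
                direction_confidence=confidence,
            )
        )
        mask[span] = True
    return calls


# ---------------------------------------------------------------------------
# topology and WCV
# ---------------------------------------------------------------------------

_PAIRINGS = {
    frozenset({0, 1}): "paralogs_sister",
    frozenset({2, 3}): "paralogs_sister",
    frozenset({0, 2}): "expected",
    frozenset({1, 3}): "expected",
    frozenset({0, 3}): "mixed",
    frozenset({1, 2}): "mixed",
}


def topology_from_matrix(d: np.ndarray) -> str:
    """Four-taxon topology by the neighbor-joining Q criterion on a 4x4
    distance matrix ordered [P1, P2, S1, S2]."""
    if not np.all(np.isfinite(d)):
        return "undetermined"
    totals = d.sum(axis=1)
    best = None
    for i in range(4):
        for j in range(i + 1, 4):
            q = 2.0 * d[i, j] - totals[i] - totals[j]
            if best is None or q < best[0] - 1e-12:
                best = (q, (i, j))
    return _PAIRINGS[frozenset(best[1])]


def quartet_topology(quartet: Quartet) -> str:
    """Topology from the six pairwise Ks distances (NJ on the 4x4 matrix)."""
    order = quartet.gene_order
    labels = {
        (0, 1): "P1P2", (2, 3): "S1S2", (0, 2): "P1S1",
        (1, 3): "P2S2", (0, 3): "P1S2", (1, 2): "P2S1",
    }
    d = np.zeros((4, 4))
    for (i, j), lab in labels.items():
        st = quartet.stats.get(lab)
        if st is None or st.ks is None:
            return "undetermined"
        d[i, j] = d[j, i] = st.ks
    return topology_from_matrix(d)


def _codon_diff_counts(aln: CodonAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per codon column: pairwise nt mismatch counts (6 x n_codons) and valid
    nt counts, for pairs in order (01, 02, 03, 12, 13, 23)."""
    chars = _char_matrix(aln).view(np.uint8)
    valid_char = np.zeros(256, dtype=bool)
    for c in "ACGTacgt":
        valid_char[ord(c)] = True
    ok = valid_char[chars]
    upper = chars | 0x20
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    n_cod = aln.n_codon_columns
    diffs = np.zeros((6, n_cod))
    valids = np.zeros((6, n_cod))
    for k, (i, j) in enumerate(pairs):
        both = ok[i] & ok[j]
        mism = (upper[i] != upper[j]) & both
        diffs[k] = mism.reshape(n_cod, 3).sum(axis=1)
        valids[k] = both.reshape(n_cod, 3).sum(axis=1)
    return diffs, valids


def _matrix_from_counts(diff_sums: np.ndarray, valid_sums: np.ndarray) -> np.ndarray:
    d = np.full((4, 4), np.nan)
    np.fill_diagonal(d, 0.0)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for k, (i, j) in enumerate(pairs):
        if valid_sums[k] <= 0:
            return np.full((4, 4), np.nan)
        p = diff_sums[k] / valid_sums[k]
        dist = jc_correct(min(p, 0.7499)) if p < 0.75 else None
        if dist is None:
            return np.full((4, 4), np.nan)
        d[i, j] = d[j, i] = dist
    return d


def topology_bootstrap_support(
    aln: CodonAlignment,
    topology: str,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Fraction of codon-column bootstrap replicates whose NJ topology (on
    JC nucleotide distances) equals ``topology``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diffs, valids = _codon_diff_counts(aln)
    n_cod = diffs.shape[1]
    support = 0
    idx = rng.integers(0, n_cod, size=(B, n_cod))
    d_sum = diffs[:, idx].sum(axis=2)  # 6 x B
    v_sum = valids[:, idx].sum(axis=2)
    for b in range(B):
        d = _matrix_from_counts(d_sum[:, b], v_sum[:, b])
        if np.all(np.isfinite(d)) and topology_from_matrix(d) == topology:
            support += 1
    return support / B


def detect_wcv(
    quartet: Quartet,
    params: Optional[PipelineConfig] = None,
    seed: int | np.random.Generator = 0,
    focus: str = "A",
) -> Optional[ConversionCall]:
    """Whole-gene conversion call for one paralog pair, or None.

    Requires Ks(paralogs) < min(Ks of both ortholog pairs), a
    paralogs-sister NJ topology, and codon-bootstrap support >= 0.95.
    """
    params = params or PipelineConfig()
    if focus == "A":
        par_lab, pair, genome = "P1P2", (quartet.p1, quartet.p2), quartet.genome_a
        rows = (0, 1)
    else:
        par_lab, pair, genome = "S1S2", (quartet.s1, quartet.s2), quartet.genome_b
        rows = (2, 3)
    st_par = quartet.stats.get(par_lab)
    st_o1 = quartet.stats.get("P1S1")
    st_o2 = quartet.stats.get("P2S2")
    if any(s is None or s.ks is None for s in (st_par, st_o1, st_o2)):
        return None
    if st_par.ks >= min(st_o1.ks, st_o2.ks):
        return None
    if quartet_topology(quartet) != "paralogs_sister":
        return None
    support = topology_bootstrap_support(
        quartet.alignment, "paralogs_sister", B=params.bootstrap_B, seed=seed
    )
    if support < WCV_SUPPORT:
        return None

    # the converted copy is the one whose ortholog comparison was stretched
    ks1, ks2 = st_o1.ks, st_o2.ks
    if focus == "A":
        acceptor, donor = (pair[0], pair[1]) if ks1 > ks2 else (pair[1], pair[0])
    else:
        # for the S-side pair, S1 pairs with ortholog stats P1S1 and so on
        acceptor, donor = (pair[0], pair[1]) if ks1 > ks2 else (pair[1], pair[0])
    lo, hi = max(ks1, ks2), min(ks1, ks2)
    confidence = "both_copies" if hi > 0 and lo / hi <= WCV_SYMMETRY_RATIO else "resolved"

    aln = quartet.alignment
    row = rows[0] if acceptor == pair[0] else rows[1]
    gene_len = len(aln.ungapped(row))
    return ConversionCall(
        quartet_id=quartet.quartet_id,
        call_type="WCV",
        converted_genome=genome,
        acceptor=acceptor,
        donor=donor,
        tract_start=1,
        tract_end=gene_len,
        col_start=0,
        col_end=aln.length - 1,
        score=float("nan"),
        p_value=1.0 - support,
        direction_confidence=confidence,
    )


def classify_quartet(calls: list[ConversionCall], quartet: Quartet) -> dict[str, str]:
    """Per-genome conversion status; WCV takes precedence over PCV."""
    status = {quartet.genome_a: "nonconverted", quartet.genome_b: "nonconverted"}
    rank = {"nonconverted": 0, "PCV": 1, "WCV": 2}
    for call in calls:
        g = call.converted_genome
        if rank[call.call_type] > rank[status[g]]:
            status[g] = call.call_type
    return status
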