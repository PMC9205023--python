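"""Protein-guided codon alignment and Nei–Gojobori (NG86) distances.

The estimator follows the classic NG86 recipe: fractional synonymous site
counts averaged over the two sequences, observed differences averaged over
all minimal mutational pathways for multi-difference codons (stop-containing
pathways excluded), and a Jukes–Cantor correction of the raw proportions.
Raw proportions at or beyond 0.745 are flagged as saturated and the
corresponding distance is reported as missing.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .codontables import (
    AA_BY_CODON_INDEX,
    IS_STOP,
    NUC_INDEX,
    SENSE_RANK,
    pathway_difference_tables,
    synonymous_site_fractions,
)
from .models import CodonAlignment, PairStats

#: raw proportions at/above this are treated as JC-saturated
SATURATION_P = 0.745

_GAP_OPEN = -10.0
_GAP_EXTEND = -0.5


def jc_correct(p: float) -> Optional[float]:
    """Jukes–Cantor distance d = -(3/4) ln(1 - 4p/3); None at saturation."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def translate(cds: str, name: str = "sequence") -> str:
    """Translate a CDS; internal stops are an error, a terminal stop is kept
    as '*', codons containing non-ACGT characters become 'X'."""
    if len(cds) % 3 != 0:
        raise ValueError(f"{name}: CDS length not divisible by 3")
    aas = []
    n = len(cds) // 3
    for k in range(n):
        codon = cds[3 * k : 3 * k + 3].upper()
        try:
            idx = 16 * NUC_INDEX[codon[0]] + 4 * NUC_INDEX[codon[1]] + NUC_INDEX[codon[2]]
        except KeyError:
            aas.append("X")
            continue
        aa = str(AA_BY_CODON_INDEX[idx])
        if aa == "*" and k < n - 1:
            raise ValueError(f"{name}: internal stop codon at codon {k + 1}")
        aas.append(aa)
    return "".join(aas)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = _GAP_OPEN
    aligner.extend_gap_score = _GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def _backtranslate(cds: str, aligned_protein: str) -> str:
    out = []
    pos = 0
    for aa in aligned_protein:
        if aa == "-":
            out.append("---")
        else:
            out.append(cds[3 * pos : 3 * pos + 3])
            pos += 1
    return "".join(out)


def align_pair(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b") -> CodonAlignment:
    """Global protein alignment (BLOSUM62, affine gaps open 10 / extend 0.5)
    of the two translations, back-translated to a codon alignment."""
    prot_a = translate(cds_a, id_a)
    prot_b = translate(cds_b, id_b)
    alignment = next(iter(_ALIGNER.align(prot_a, prot_b)))
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    return CodonAlignment(
        ids=[id_a, id_b],
        seqs=[_backtranslate(cds_a, aligned_a), _backtranslate(cds_b, aligned_b)],
    )


def aligned_codon_indices(aligned_seq: str) -> np.ndarray:
    """Codon index per codon column of an aligned (gapped) sequence.

    -1 marks columns unusable for NG86: containing a gap character or any
    non-ACGT base.
    """
    lut = np.full(256, -1, dtype=np.int64)
    for c, i in NUC_INDEX.items():
        lut[ord(c)] = i
        lut[ord(c.lower())] = i
    arr = lut[np.frombuffer(aligned_seq.encode(), dtype=np.uint8)]
    cod = arr.reshape(-1, 3)
    idx = cod[:, 0] * 16 + cod[:, 1] * 4 + cod[:, 2]
    idx[(cod < 0).any(axis=1)] = -1
    return idx


def ng86(alignment: CodonAlignment, i: int = 0, j: int = 1) -> PairStats:
    """NG86 distances between rows i and j of a codon alignment."""
    idx_a = aligned_codon_indices(alignment.seqs[i])
    idx_b = aligned_codon_indices(alignment.seqs[j])
    rank_a = np.where(idx_a >= 0, SENSE_RANK[idx_a], -1)
    rank_b = np.where(idx_b >= 0, SENSE_RANK[idx_b], -1)
    valid = (rank_a >= 0) & (rank_b >= 0)
    n_valid = int(valid.sum())

    aa_identity, gap_fraction = aa_identity_and_gaps(alignment, i, j)
    base = dict(
        gene_a=alignment.ids[i],
        gene_b=alignment.ids[j],
        aa_identity=aa_identity,
        gap_fraction=gap_fraction,
    )
    if n_valid == 0:
        return PairStats(ka=None, ks=None, n_sites=0.0, s_sites=0.0, nd=0.0, sd=0.0,
                         reason="no comparable codon columns", **base)

    sfrac = synonymous_site_fractions()
    s_sites = 0.5 * float(sfrac[idx_a[valid]].sum() + sfrac[idx_b[valid]].sum())
    n_sites = 3.0 * n_valid - s_sites

    sd_tab, nd_tab = pathway_difference_tables()
    ra, rb = rank_a[valid], rank_b[valid]
    sd = float(sd_tab[ra, rb].sum())
    nd = float(nd_tab[ra, rb].sum())

    ks: Optional[float]
    ka: Optional[float]
    saturated = False
    reason = ""
    if s_sites <= 0:
        ks, reason = None, "zero synonymous sites"
    else:
        ps_raw = sd / s_sites
        if ps_raw >= SATURATION_P:
            ks, saturated, reason = None, True, "synonymous saturation"
        else:
            ks = jc_correct(ps_raw)
    if n_sites <= 0:
        ka = None
        reason = (reason + "; " if reason else "") + "zero nonsynonymous sites"
    else:
        pn_raw = nd / n_sites
        if pn_raw >= SATURATION_P:
            ka, saturated = None, True
            reason = (reason + "; " if reason else "") + "nonsynonymous saturation"
        else:
            ka = jc_correct(pn_raw)

    return PairStats(ka=ka, ks=ks, n_sites=n_sites, s_sites=s_sites, nd=nd, sd=sd,
                     saturated=saturated, reason=reason, **base)


def aa_identity_and_gaps(
    alignment: CodonAlignment, i: int = 0, j: int = 1
) -> tuple[Optional[float], float]:
    """Amino-acid identity over columns where both rows have residues, and
    the fraction of codon columns containing a gap in either row."""
    sa, sb = alignment.seqs[i], alignment.seqs[j]
    n_cols = alignment.n_codon_columns
    if n_cols == 0:
        return None, 0.0
    gaps = 0
    both = 0
    same = 0
    for k in range(n_cols):
        ca = sa[3 * k : 3 * k + 3]
        cb = sb[3 * k : 3 * k + 3]
        ga, gb = "-" in ca, "-" in cb
        if ga or gb:
            gaps += 1
            continue
        both += 1
        aa_a = _translate_one(ca)
        aa_b = _translate_one(cb)
        if aa_a == aa_b:
            same += 1
    identity = (same / both) if both else None
    return identity, gaps / n_cols


def _translate_one(codon: str) -> str:
    try:
        idx = 16 * NUC_INDEX[codon[0]] + 4 * NUC_INDEX[codon[1]] + NUC_INDEX[codon[2]]
    except KeyError:
        return "X"
    return str(AA_BY_CODON_INDEX[idx])


# ---------------------------------------------------------------------------
# four-way union alignment (progressive: (P1,S1) + (P2,S2), then profiles)
# ---------------------------------------------------------------------------

_B62 = substitution_matrices.load("BLOSUM62")
_B62_ALPHABET = _B62.alphabet
_B62_INDEX = {c: k for k, c in enumerate(_B62_ALPHABET)}
_B62_MATRIX = np.array(_B62)


def _protein_rows(codon_alignment: CodonAlignment) -> list[str]:
    rows = []
    for s in codon_alignment.seqs:
        aas = []
        for k in range(len(s) // 3):
            codon = s[3 * k : 3 * k + 3]
            aas.append("-" if "-" in codon else _translate_one(codon))
        rows.append("".join(aas))
    return rows


def _profile_encoding(rows: list[str]) -> np.ndarray:
    length = len(rows[0])
    enc = np.zeros((length, len(_B62_ALPHABET)))
    for row in rows:
        for pos, aa in enumerate(row):
            if aa != "-":
                enc[pos, _B62_INDEX.get(aa, _B62_INDEX["X"])] += 1
    return enc


def _profile_align_columns(rows_a: list[str], rows_b: list[str]) -> list[tuple[int, int]]:
    """Gotoh global alignment of two protein profiles; returns merged column
    pairs as (ia, ib) with -1 for a gap column on that side."""
    enc_a = _profile_encoding(rows_a)
    enc_b = _profile_encoding(rows_b)
    la, lb = enc_a.shape[0], enc_b.shape[0]
    denom = max(len(rows_a) * len(rows_b), 1)
    score = (enc_a @ _B62_MATRIX @ enc_b.T) / denom

    neg = -math.inf
    m = np.full((la + 1, lb + 1), neg)
    x = np.full((la + 1, lb + 1), neg)  # gap in B (A column vs gap)
    y = np.full((la + 1, lb + 1), neg)  # gap in A
    m[0, 0] = 0.0
    for i in range(1, la + 1):
        x[i, 0] = _GAP_OPEN + _GAP_EXTEND * (i - 1)
    for j in range(1, lb + 1):
        y[0, j] = _GAP_OPEN + _GAP_EXTEND * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = score[i - 1, j - 1]
            m[i, j] = s + max(m[i - 1, j - 1], x[i - 1, j - 1], y[i - 1, j - 1])
            x[i, j] = max(m[i - 1, j] + _GAP_OPEN, x[i - 1, j] + _GAP_EXTEND,
                          y[i - 1, j] + _GAP_OPEN)
            y[i, j] = max(m[i, j - 1] + _GAP_OPEN, y[i, j - 1] + _GAP_EXTEND,
                          x[i, j - 1] + _GAP_OPEN)

    cols: list[tuple[int, int]] = []
    i, j = la, lb
    state = max(("m", m[i, j]), ("x", x[i, j]), ("y", y[i, j]), key=lambda t: t[1])[0]
    while i > 0 or j > 0:
        if state == "m" and i > 0 and j > 0:
            cols.append((i - 1, j - 1))
            s = score[i - 1, j - 1]
            prev = m[i, j] - s
            i, j = i - 1, j - 1
            state = _pick_state(prev, m[i, j], x[i, j], y[i, j])
        elif state == "x" and i > 0:
            cols.append((i - 1, -1))
            val = x[i, j]
            if math.isclose(val, x[i - 1, j] + _GAP_EXTEND, abs_tol=1e-9):
                state = "x"
            elif math.isclose(val, m[i - 1, j] + _GAP_OPEN, abs_tol=1e-9):
                state = "m"
            else:
                state = "y"
            i -= 1
        else:
            cols.append((-1, j - 1))
            val = y[i, j]
            if math.isclose(val, y[i, j - 1] + _GAP_EXTEND, abs_tol=1e-9):
                state = "y"
            elif math.isclose(val, m[i, j - 1] + _GAP_OPEN, abs_tol=1e-9):
                state = "m"
            else:
                state = "x"
            j -= 1
    cols.reverse()
    return cols


def _pick_state(target: float, m_val: float, x_val: float, y_val: float) -> str:
    for name, val in (("m", m_val), ("x", x_val), ("y", y_val)):
        if math.isclose(val, target, rel_tol=1e-9, abs_tol=1e-9):
            return name
    return "m"


def align_quartet(ids: list[str], seqs: list[str]) -> CodonAlignment:
    """Shared codon alignment of four CDSs [P1, P2, S1, S2].

    The two ortholog pairs (P1,S1) and (P2,S2) are aligned pairwise first and
    then merged by profile–profile alignment, so that all six pairs share
    alignment columns.  When both guide alignments are gap-free and of equal
    length (the typical indel-free case) the merge is the identity.
    """
    if len(ids) != 4 or len(seqs) != 4:
        raise ValueError("a quartet needs exactly four sequences")
    p1, p2, s1, s2 = seqs
    aln1 = align_pair(p1, s1, ids[0], ids[2])
    aln2 = align_pair(p2, s2, ids[1], ids[3])

    gapfree = "-" not in "".join(aln1.seqs) and "-" not in "".join(aln2.seqs)
    if gapfree and aln1.length == aln2.length:
        return CodonAlignment(
            ids=[ids[0], ids[1], ids[2], ids[3]],
            seqs=[aln1.seqs[0], aln2.seqs[0], aln1.seqs[1], aln2.seqs[1]],
        )

    rows_a = _protein_rows(aln1)  # [P1, S1]
    rows_b = _protein_rows(aln2)  # [P2, S2]
    cols = _profile_align_columns(rows_a, rows_b)

    def codon_at(aln: CodonAlignment, row: int, col: int) -> str:
        return aln.seqs[row][3 * col : 3 * col + 3] if col >= 0 else "---"

    out = {k: [] for k in range(4)}
    for ia, ib in cols:
        out[0].append(codon_at(aln1, 0, ia))
        out[2].append(codon_at(aln1, 1, ia))
        out[1].append(codon_at(aln2, 0, ib))
        out[3].append(codon_at(aln2, 1, ib))
    return CodonAlignment(
        ids=[ids[0], ids[1], ids[2], ids[3]],
        seqs=["".join(out[k]) for k in range(4)],
    )
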