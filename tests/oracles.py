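"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and written without reference to the
package's implementation: straightforward loops, itertools enumeration and
Biopython translation, so the two routes only agree if both are right.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


@lru_cache(maxsize=None)
def naive_syn_sites(codon: str) -> float:
    """Fraction-of-3 synonymous site count; stop neighbors are nonsynonymous."""
    if codon in STOPS:
        return 0.0
    syn = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOPS and _aa(alt) == _aa(codon):
                syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def naive_pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over minimal pathways, excluding
    pathways through stop codons (all pathways if every one is blocked)."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    all_paths = []
    for order in itertools.permutations(diff):
        cur = c1
        blocked = False
        syn = nonsyn = 0
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOPS and nxt != c2:
                blocked = True
            if cur not in STOPS and nxt not in STOPS and _aa(cur) == _aa(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        all_paths.append((blocked, syn, nonsyn))
    ok = [(s, n) for b, s, n in all_paths if not b]
    if not ok:
        ok = [(s, n) for _, s, n in all_paths]
    return (sum(s for s, _ in ok) / len(ok), sum(n for _, n in ok) / len(ok))


def naive_ng86(seq_a: str, seq_b: str):
    """NG86 ka/ks on two equal-length gap-free CDSs; None at saturation."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    s_sites_a = s_sites_b = 0.0
    sd = nd = 0.0
    n_codons = 0
    for k in range(len(seq_a) // 3):
        ca = seq_a[3 * k : 3 * k + 3]
        cb = seq_b[3 * k : 3 * k + 3]
        if set(ca + cb) - set(BASES) or ca in STOPS or cb in STOPS:
            continue
        n_codons += 1
        s_sites_a += naive_syn_sites(ca)
        s_sites_b += naive_syn_sites(cb)
        s, n = naive_pathway_counts(ca, cb)
        sd += s
        nd += n
    s_sites = 0.5 * (s_sites_a + s_sites_b)
    n_sites = 3.0 * n_codons - s_sites
    ks = _naive_jc(sd / s_sites) if s_sites > 0 else None
    ka = _naive_jc(nd / n_sites) if n_sites > 0 else None
    return dict(ka=ka, ks=ks, s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd)


def _naive_jc(p: float):
    if p >= 0.745:
        return None
    return -3.0 / 4.0 * math.log(1.0 - 4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# global alignment score by exhaustive enumeration (affine gaps)
# ---------------------------------------------------------------------------


def brute_force_alignment_score(a: str, b: str, sub, gap_open: float,
                                gap_extend: float) -> float:
    """Best global alignment score over ALL alignments, enumerated
    recursively; affine cost: a gap of length L costs open + extend*(L-1)."""
    best = -math.inf

    def rec(i: int, j: int, score: float, state: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub[a[i]][b[j]], "m")
        if i < len(a):
            cost = gap_extend if state == "x" else gap_open
            rec(i + 1, j, score - cost, "x")
        if j < len(b):
            cost = gap_extend if state == "y" else gap_open
            rec(i, j + 1, score - cost, "y")

    rec(0, 0, 0.0, "m")
    return best


# ---------------------------------------------------------------------------
# maximal scoring segments by recursive exhaustive max-subarray search
# ---------------------------------------------------------------------------


def exhaustive_max_segments(scores) -> list[tuple[int, int, float]]:
    """All maximal scoring segments: repeatedly take the best-sum subarray
    (shortest, then leftmost, among ties) and recurse on both flanks."""
    scores = list(scores)

    def best_subarray(lo: int, hi: int):
        best = None
        for i in range(lo, hi):
            total = 0.0
            for j in range(i, hi):
                total += scores[j]
                if total > 1e-12:
                    cand = (total, j - i, i)
                    if best is None or (-cand[0], cand[1], cand[2]) < (-best[0], best[1], best[2]):
                        best = cand
        return best

    out: list[tuple[int, int, float]] = []

    def rec(lo: int, hi: int) -> None:
        if lo >= hi:
            return
        found = best_subarray(lo, hi)
        if found is None:
            return
        total, length, start = found
        end = start + length
        out.append((start, end, total))
        rec(lo, start)
        rec(end + 1, hi)

    rec(0, len(scores))
    return sorted(out)


# ---------------------------------------------------------------------------
# four-taxon topology by exhaustive least-squares branch fitting
# ---------------------------------------------------------------------------


def least_squares_topology(d: np.ndarray) -> str:
    """Best of the three unrooted 4-taxon topologies by non-negative
    least-squares fit of the 5 branch lengths to the 6 distances."""
    from scipy.optimize import nnls

    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    y = np.array([d[i, j] for i, j in pairs])
    topologies = {
        "paralogs_sister": ({0, 1}, {2, 3}),
        "expected": ({0, 2}, {1, 3}),
        "mixed": ({0, 3}, {1, 2}),
    }
    best = None
    for name, (left, _right) in topologies.items():
        # columns: 4 external branches + 1 internal branch
        X = np.zeros((6, 5))
        for r, (i, j) in enumerate(pairs):
            X[r, i] = 1.0
            X[r, j] = 1.0
            split = ({i} <= left) != ({j} <= left)
            if split:
                X[r, 4] = 1.0
        coef, _ = nnls(X, y)
        sse = float(((X @ coef - y) ** 2).sum())
        if best is None or sse < best[0] - 1e-12:
            best = (sse, name)
    return best[1]
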