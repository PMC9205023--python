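"""Genetic-code lookup tables shared by the simulator and the Ka/Ks estimator.

Everything here is a fixed property of the standard nuclear genetic code:
codon indexing, amino-acid translation, per-position synonymous site
fractions, and the pathway-averaged synonymous/nonsynonymous difference
counts for every pair of sense codons (Nei & Gojobori's convention:
multi-difference codons are averaged over all minimal mutational pathways,
pathways passing through a stop codon excluded).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

NUCS = "ACGT"
NUC_INDEX = {c: i for i, c in enumerate(NUCS)}

# standard genetic code, indexed by 16*n1 + 4*n2 + n3 with A,C,G,T = 0..3
_CODE = (
    "KNKNTTTTRSRSIIMIQHQHPPPPRRRRLLLL"
    "EDEDAAAAGGGGVVVV*Y*YSSSS*CWCLFLF"
)

AA_BY_CODON_INDEX = np.frombuffer(_CODE.encode(), dtype="S1").astype("U1")
IS_STOP = AA_BY_CODON_INDEX == "*"

#: indices of the 61 sense codons, and the inverse map (64-long, -1 for stops)
SENSE_CODONS = np.flatnonzero(~IS_STOP)
SENSE_RANK = np.full(64, -1, dtype=np.int64)
SENSE_RANK[SENSE_CODONS] = np.arange(len(SENSE_CODONS))


def codon_index(codon: str) -> int:
    """Index of a codon in 0..63, or -1 if it contains a non-ACGT character."""
    try:
        return 16 * NUC_INDEX[codon[0]] + 4 * NUC_INDEX[codon[1]] + NUC_INDEX[codon[2]]
    except KeyError:
        return -1


def index_codon(idx: int) -> str:
    return NUCS[idx >> 4] + NUCS[(idx >> 2) & 3] + NUCS[idx & 3]


def translate_codon(codon: str) -> str:
    idx = codon_index(codon)
    return "X" if idx < 0 else str(AA_BY_CODON_INDEX[idx])


def _neighbors(idx: int, pos: int):
    """The three codons differing from idx at position pos (0..2)."""
    shift = (2 - pos) * 2
    cur = (idx >> shift) & 3
    base = idx & ~(3 << shift)
    return [base | (n << shift) for n in range(4) if n != cur]


@lru_cache(maxsize=1)
def synonymous_site_fractions() -> np.ndarray:
    """Per-codon NG86 synonymous site counts, shape (64,).

    Each position contributes exactly 1 site split as (syn changes)/3
    synonymous and the rest nonsynonymous; changes producing a stop codon
    count as nonsynonymous, so s + n always sums to 3 per codon.
    """
    s = np.zeros(64)
    for idx in range(64):
        if IS_STOP[idx]:
            continue
        aa = AA_BY_CODON_INDEX[idx]
        syn = 0
        for pos in range(3):
            for nb in _neighbors(idx, pos):
                if not IS_STOP[nb] and AA_BY_CODON_INDEX[nb] == aa:
                    syn += 1
        s[idx] = syn / 3.0
    return s


@lru_cache(maxsize=1)
def pathway_difference_tables() -> tuple[np.ndarray, np.ndarray]:
    """(sd, nd) tables over sense-codon rank pairs, shape (61, 61).

    sd[i, j] / nd[i, j] are the synonymous / nonsynonymous difference counts
    between sense codons of rank i and j, averaged over minimal mutational
    pathways.  Pathways whose intermediate codons are stops are excluded;
    in the degenerate case where every pathway is blocked, all pathways are
    used (stop intermediates counted as nonsynonymous steps).
    """
    n = len(SENSE_CODONS)
    sd = np.zeros((n, n))
    nd = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if j <= i:
                continue
            s, d = _pathway_average(int(ci), int(cj))
            sd[i, j] = sd[j, i] = s
            nd[i, j] = nd[j, i] = d
    return sd, nd


def _pathway_average(ci: int, cj: int) -> tuple[float, float]:
    diff_pos = [p for p in range(3) if ((ci >> ((2 - p) * 2)) & 3) != ((cj >> ((2 - p) * 2)) & 3)]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = ci
        steps = []
        blocked = False
        for p in order:
            shift = (2 - p) * 2
            nxt = (cur & ~(3 << shift)) | (cj & (3 << shift))
            if IS_STOP[nxt] and nxt != cj:
                blocked = True
            syn = (not IS_STOP[cur]) and (not IS_STOP[nxt]) and (
                AA_BY_CODON_INDEX[cur] == AA_BY_CODON_INDEX[nxt]
            )
            steps.append(syn)
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    s = float(np.mean([sum(st) for st in usable]))
    return s, len(diff_pos) - s


def seq_to_codon_indices(seq: str) -> np.ndarray:
    """Codon index array for an ungapped CDS string; -1 where any base is not ACGT."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for c, i in NUC_INDEX.items():
        lut[ord(c)] = i
    nt = lut[arr]
    cod = nt.reshape(-1, 3)
    bad = (cod < 0).any(axis=1)
    idx = cod[:, 0] * 16 + cod[:, 1] * 4 + cod[:, 2]
    idx[bad] = -1
    return idx
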