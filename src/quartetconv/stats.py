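"""Genome-scale summaries of conversion calls.

Rates with exact counts, positional (decile and 1-Mb window) analyses of
converted duplicates, duplicate-density/conversion-rate correlations, the
converted-vs-nonconverted group comparisons (Pn, Ps, Pn/Ps; pooled-variance
t-tests), expression-divergence proportions from TPM tables, and per-GO-term
Pearson chi-square enrichment.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .models import GeneModel, HomologPair, RateRecord, WindowStat


def rate(numerator: int, denominator: int, label: str = "") -> RateRecord:
    """Exact percentage record; percent = round(100 n/d, 2)."""
    return RateRecord(label=label, numerator=numerator, denominator=denominator)


# ---------------------------------------------------------------------------
# positional analyses
# ---------------------------------------------------------------------------


def _chromosome_lengths(catalog: Sequence[GeneModel]) -> dict[str, int]:
    lengths: dict[str, int] = defaultdict(int)
    for g in catalog:
        lengths[g.chromosome] = max(lengths[g.chromosome], g.end_bp)
    return dict(lengths)


@dataclass
class DecileReport:
    first_decile: RateRecord
    last_decile: RateRecord
    middle: RateRecord
    per_decile: list[RateRecord]
    anova_F: Optional[float]
    anova_p: Optional[float]


def decile_conversion_rates(
    catalog: Sequence[GeneModel],
    duplicate_genes: Iterable[str],
    converted_genes: Iterable[str],
) -> DecileReport:
    """Converted-duplicate rates in the first 10%, last 10% and middle 80%
    of each chromosome's length, pooled over chromosomes, plus a one-way
    ANOVA across the three positional groups using per-chromosome group
    rates as observations."""
    duplicates = set(duplicate_genes)
    converted = set(converted_genes)
    lengths = _chromosome_lengths(catalog)

    dup_counts = defaultdict(lambda: np.zeros(10, dtype=int))
    conv_counts = defaultdict(lambda: np.zeros(10, dtype=int))
    for g in catalog:
        if g.gene_id not in duplicates:
            continue
        decile = min(int(10 * g.midpoint_bp / lengths[g.chromosome]), 9)
        dup_counts[g.chromosome][decile] += 1
        if g.gene_id in converted:
            conv_counts[g.chromosome][decile] += 1

    total_dup = np.zeros(10, dtype=int)
    total_conv = np.zeros(10, dtype=int)
    for chrom in dup_counts:
        total_dup += dup_counts[chrom]
        total_conv += conv_counts[chrom]

    def group_record(label: str, deciles: slice) -> RateRecord:
        d = int(total_dup[deciles].sum())
        c = int(total_conv[deciles].sum())
        return rate(c, max(d, 1), label) if d == 0 else rate(c, d, label)

    per_decile = [
        rate(int(total_conv[i]), int(total_dup[i]), f"decile{i + 1}")
        if total_dup[i] else RateRecord(f"decile{i + 1}", 0, 1)
        for i in range(10)
    ]

    groups: list[list[float]] = [[], [], []]
    for chrom in dup_counts:
        d, c = dup_counts[chrom], conv_counts[chrom]
        for gi, sl in enumerate((slice(0, 1), slice(9, 10), slice(1, 9))):
            nd = d[sl].sum()
            if nd > 0:
                groups[gi].append(float(c[sl].sum() / nd))
    anova_F = anova_p = None
    if all(len(g) >= 2 for g in groups):
        anova_F, anova_p = map(float, sps.f_oneway(*groups))

    return DecileReport(
        first_decile=group_record("first_decile", slice(0, 1)),
        last_decile=group_record("last_decile", slice(9, 10)),
        middle=group_record("middle", slice(1, 9)),
        per_decile=per_decile,
        anova_F=anova_F,
        anova_p=anova_p,
    )


def window_stats(
    catalog: Sequence[GeneModel],
    duplicate_genes: Iterable[str],
    converted_genes: Iterable[str],
    window_bp: int = 1_000_000,
) -> dict[str, list[WindowStat]]:
    """Per-chromosome tiling windows (window index measured as distance rank
    from the nearest terminus, mirroring both ends toward the center)."""
    duplicates = set(duplicate_genes)
    converted = set(converted_genes)
    lengths = _chromosome_lengths(catalog)
    per_chrom: dict[str, list[WindowStat]] = {}
    counts: dict[str, np.ndarray] = {}
    for chrom, length in lengths.items():
        n_win = max(1, int(np.ceil(length / window_bp)))
        counts[chrom] = np.zeros((n_win, 3), dtype=int)  # genes, dups, conv
    for g in catalog:
        w = min(int((g.midpoint_bp - 1) // window_bp), counts[g.chromosome].shape[0] - 1)
        counts[g.chromosome][w, 0] += 1
        if g.gene_id in duplicates:
            counts[g.chromosome][w, 1] += 1
            if g.gene_id in converted:
                counts[g.chromosome][w, 2] += 1
    for chrom, arr in counts.items():
        n_win = arr.shape[0]
        per_chrom[chrom] = [
            WindowStat(
                chromosome=chrom,
                window_index=min(w, n_win - 1 - w),
                n_genes=int(arr[w, 0]),
                n_duplicates=int(arr[w, 1]),
                n_converted=int(arr[w, 2]),
            )
            for w in range(n_win)
        ]
    return per_chrom


def window_density_correlation(
    catalog: Sequence[GeneModel],
    duplicate_genes: Iterable[str],
    converted_genes: Iterable[str],
    window_bp: int = 1_000_000,
) -> dict[str, tuple[Optional[float], Optional[float]]]:
    """Pearson r (and p) between duplicate density and conversion rate over
    each chromosome's windows; windows with no duplicates are excluded
    pairwise; chromosomes with < 3 usable windows or zero variance are
    flagged with (None, None)."""
    out: dict[str, tuple[Optional[float], Optional[float]]] = {}
    for chrom, wins in window_stats(catalog, duplicate_genes, converted_genes, window_bp).items():
        xs, ys = [], []
        for w in wins:
            if w.duplicate_density is None or w.conversion_rate is None:
                continue
            xs.append(w.duplicate_density)
            ys.append(w.conversion_rate)
        if len(xs) < 3 or np.std(xs) == 0 or np.std(ys) == 0:
            out[chrom] = (None, None)
            continue
        r, p = sps.pearsonr(xs, ys)
        out[chrom] = (float(r), float(p))
    return out


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    *more: Sequence[float],
    test: str = "t",
) -> tuple[Optional[float], Optional[float]]:
    """Two-sided pooled-variance t-test ('t') or one-way ANOVA ('anova')."""
    groups = [np.asarray([v for v in g if np.isfinite(v)], dtype=float)
              for g in (values_a, values_b, *more)]
    if test == "t":
        if len(groups) != 2:
            raise ValueError("t-test needs exactly two groups")
        a, b = groups
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs >= 2 finite values")
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
            return 0.0, 1.0
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        if not np.isfinite(stat):
            return None, None
        return float(stat), float(p)
    if test == "anova":
        if len(groups) < 2:
            raise ValueError("ANOVA needs >= 2 groups")
        stat, p = sps.f_oneway(*groups)
        if not np.isfinite(stat):
            return None, None
        return float(stat), float(p)
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# expression divergence
# ---------------------------------------------------------------------------


@dataclass
class ExpressionReport:
    divergent_converted: RateRecord
    divergent_nonconverted: RateRecord
    mean_tpm_converted: float
    mean_tpm_nonconverted: float
    t_statistic: Optional[float]
    t_p_value: Optional[float]
    n_pairs_dropped: int


def expression_divergence(
    tpm: dict[str, float],
    pairs: Sequence[HomologPair],
    converted_flags: Sequence[bool],
    fold_cutoff: float = 2.0,
    pseudocount: float = 0.1,
) -> ExpressionReport:
    """Proportion of duplicate pairs with a fold change >= ``fold_cutoff``,
    per conversion group, plus a mean-TPM comparison.

    Genes with zero (or missing) TPM are removed first; a pair is evaluated
    only when both members remain.  Fold change uses a pseudocount:
    (max + c) / (min + c).
    """
    expressed = {g: v for g, v in tpm.items() if v and v > 0}
    div = {True: 0, False: 0}
    tot = {True: 0, False: 0}
    tpm_vals: dict[bool, list[float]] = {True: [], False: []}
    dropped = 0
    for pair, conv in zip(pairs, converted_flags):
        a = expressed.get(pair.gene_a)
        b = expressed.get(pair.gene_b)
        if a is None or b is None:
            dropped += 1
            continue
        tot[conv] += 1
        tpm_vals[conv].extend([a, b])
        fold = (max(a, b) + pseudocount) / (min(a, b) + pseudocount)
        if fold >= fold_cutoff:
            div[conv] += 1
    if tot[True] == 0 or tot[False] == 0:
        raise ValueError("empty conversion group after expression filtering")
    t_stat = t_p = None
    if len(tpm_vals[True]) >= 2 and len(tpm_vals[False]) >= 2:
        t_stat, t_p = compare_groups(tpm_vals[True], tpm_vals[False], test="t")
    return ExpressionReport(
        divergent_converted=rate(div[True], tot[True], "converted_divergent"),
        divergent_nonconverted=rate(div[False], tot[False], "nonconverted_divergent"),
        mean_tpm_converted=float(np.mean(tpm_vals[True])),
        mean_tpm_nonconverted=float(np.mean(tpm_vals[False])),
        t_statistic=t_stat,
        t_p_value=t_p,
        n_pairs_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------


@dataclass
class GoTermResult:
    term: str
    n_converted_in_term: int
    n_converted: int
    n_universe_in_term: int
    n_universe: int
    pct_converted: float
    pct_universe: float
    chi2: Optional[float]
    p_value: Optional[float]
    q_value: Optional[float] = None
    low_count: bool = False


def go_enrichment(
    go_map: dict[str, set[str]],
    converted: set[str],
    universe: set[str],
) -> list[GoTermResult]:
    """Per-term Pearson chi-square (no continuity correction) on the 2x2
    table converted/not x in-term/not, over the duplicate-gene universe.

    Reports the proportion of converted genes and of all duplicates carrying
    each term; raw p plus a Benjamini–Hochberg q column.
    """
    if not converted <= universe:
        raise ValueError("every converted gene must be in the universe")
    n_conv = len(converted)
    n_uni = len(universe)
    genes_by_term: dict[str, set[str]] = defaultdict(set)
    for gene, terms in go_map.items():
        if gene in universe:
            for t in terms:
                genes_by_term[t].add(gene)

    results: list[GoTermResult] = []
    for term in sorted(genes_by_term):
        in_term = genes_by_term[term]
        a = len(in_term & converted)
        b = n_conv - a
        c = len(in_term) - a
        d = (n_uni - n_conv) - c
        table = np.array([[a, b], [c, d]], dtype=float)
        chi2 = p = None
        low = False
        if table.sum() > 0 and (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
            low = bool((expected < 1).any())
            chi2_v, p_v, _, _ = sps.chi2_contingency(table, correction=False)
            chi2, p = float(chi2_v), float(p_v)
        results.append(
            GoTermResult(
                term=term,
                n_converted_in_term=a,
                n_converted=n_conv,
                n_universe_in_term=len(in_term),
                n_universe=n_uni,
                pct_converted=100.0 * a / n_conv if n_conv else float("nan"),
                pct_universe=100.0 * len(in_term) / n_uni if n_uni else float("nan"),
                chi2=chi2,
                p_value=p,
                low_count=low,
            )
        )
    ps = [r.p_value for r in results if r.p_value is not None]
    if ps:
        _, qs, _, _ = multipletests(ps, method="fdr_bh")
        it = iter(qs)
        for r in results:
            if r.p_value is not None:
                r.q_value = float(next(it))
    return results
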