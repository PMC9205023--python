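"""Family filtering, collinear chaining, Ks annotation and event labels."""

import itertools

import numpy as np
import pytest

from quartetconv.collinearity import (
    annotate_blocks_ks,
    apply_blast_filters,
    chain_collinear_pairs,
    filter_large_families,
    label_blocks_by_event,
)
from quartetconv.models import CollinearBlock, GeneModel, HomologPair, PairStats


def _gene(gid, chrom, order, genome="G"):
    return GeneModel(gene_id=gid, genome=genome, chromosome=chrom,
                     start_bp=1 + 1000 * order, end_bp=1000 * order + 500,
                     order_index=order)


def _catalog_pair(n=30):
    a = [_gene(f"a{i}", "c1", i, "A") for i in range(n)]
    b = [_gene(f"b{i}", "d1", i, "B") for i in range(n)]
    return a, b


class TestFamilyFilter:
    def test_hub_gene_family_removed(self):
        pairs = [HomologPair("hub", f"g{i}") for i in range(60)]
        pairs.append(HomologPair("x1", "x2"))
        kept = filter_large_families(pairs, family_size_cutoff=50)
        assert kept == [HomologPair("x1", "x2")]

    def test_small_families_untouched(self):
        pairs = [HomologPair(f"a{i}", f"b{i}") for i in range(20)]
        assert filter_large_families(pairs, 50) == pairs

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(120)]
        pairs = []
        seen = set()
        for _ in range(200):
            i, j = rng.integers(0, 120, size=2)
            if i == j or (min(i, j), max(i, j)) in seen:
                continue
            seen.add((min(i, j), max(i, j)))
            pairs.append(HomologPair(genes[i], genes[j]))
        cutoff = 10
        kept = filter_large_families(pairs, cutoff)

        # explicit union-find oracle
        parent = {g: g for g in genes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for p in pairs:
            parent[find(p.gene_a)] = find(p.gene_b)
        sizes = {}
        for g in genes:
            sizes[find(g)] = sizes.get(find(g), 0) + 1
        expected = [p for p in pairs
                    if sizes[find(p.gene_a)] < cutoff and sizes[find(p.gene_b)] < cutoff]
        assert kept == expected


class TestBlastFilters:
    def test_thresholds_applied_when_present(self):
        pairs = [
            HomologPair("a", "b", score=500.0, evalue=1e-30),
            HomologPair("c", "d", score=50.0, evalue=1e-30),
            HomologPair("e", "f", score=500.0, evalue=1e-3),
            HomologPair("g", "h"),  # no columns: passes through
        ]
        kept = apply_blast_filters(pairs)
        assert [p.gene_a for p in kept] == ["a", "g"]


class TestChaining:
    def test_perfect_diagonal_single_block(self):
        a, b = _catalog_pair(10)
        pairs = [HomologPair(f"a{i}", f"b{i}") for i in range(2, 7)]
        blocks = chain_collinear_pairs(pairs, [a, b], max_gap=50, min_block_len=4)
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 5
        assert blocks[0].orientation == 1

    def test_short_diagonal_below_threshold(self):
        a, b = _catalog_pair(10)
        pairs = [HomologPair(f"a{i}", f"b{i}") for i in range(3)]
        assert chain_collinear_pairs(pairs, [a, b], 50, 4) == []

    def test_antidiagonal_found_with_negative_orientation(self):
        a, b = _catalog_pair(10)
        pairs = [HomologPair(f"a{i}", f"b{9 - i}") for i in range(6)]
        blocks = chain_collinear_pairs(pairs, [a, b], 50, 4)
        assert len(blocks) == 1 and blocks[0].orientation == -1
        assert blocks[0].n_anchors == 6

    def test_gap_constraint_splits_chain(self):
        a = [_gene(f"a{i}", "c1", i, "A") for i in range(200)]
        b = [_gene(f"b{i}", "d1", i, "B") for i in range(200)]
        idxs = [0, 1, 2, 3, 100, 101, 102, 103]  # gap of 97 > max_gap 50
        pairs = [HomologPair(f"a{i}", f"b{i}") for i in idxs]
        blocks = chain_collinear_pairs(pairs, [a, b], max_gap=50, min_block_len=4)
        assert len(blocks) == 2
        assert all(blk.n_anchors == 4 for blk in blocks)

    def test_emitted_blocks_satisfy_constraints_and_disjointness(self):
        rng = np.random.default_rng(1)
        a = [_gene(f"a{i}", "c1", i, "A") for i in range(60)]
        b = [_gene(f"b{i}", "d1", i, "B") for i in range(60)]
        pairs = [HomologPair(f"a{int(i)}", f"b{int(j)}")
                 for i, j in rng.integers(0, 60, size=(80, 2))]
        pairs = list({p.key: p for p in pairs}.values())
        blocks = chain_collinear_pairs(pairs, [a, b], max_gap=10, min_block_len=3)
        seen = set()
        lookup = {g.gene_id: g for g in a + b}
        for blk in blocks:
            assert blk.n_anchors >= 3
            coords = [(lookup[x].order_index, lookup[y].order_index)
                      for x, y in blk.anchors]
            for (a1, b1), (a2, b2) in zip(coords, coords[1:]):
                assert 0 < a2 - a1 <= 10
                assert 0 < blk.orientation * (b2 - b1) <= 10 or \
                    abs(b2 - b1) <= 10
            for anchor in blk.anchors:
                assert anchor not in seen
                seen.add(anchor)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_chain_oracle(self, seed):
        """On tiny instances the greedy chain extraction equals exhaustive
        enumeration of gap-constrained monotone chains."""
        rng = np.random.default_rng(seed)
        n = 8
        a = [_gene(f"a{i}", "c1", i, "A") for i in range(n)]
        b = [_gene(f"b{i}", "d1", i, "B") for i in range(n)]
        coords = set()
        while len(coords) < 10:
            coords.add(tuple(rng.integers(0, n, size=2)))
        coords = sorted(coords)
        pairs = [HomologPair(f"a{i}", f"b{j}") for i, j in coords]
        max_gap, min_len = 3, 2
        blocks = chain_collinear_pairs(pairs, [a, b], max_gap, min_len)

        # oracle: repeatedly take the best chain among ALL subsets forming
        # valid chains (enumerated exhaustively), same tie-breaks
        remaining = list(coords)

        def all_chains(points):
            best = None
            for r in range(len(points), 0, -1):
                for combo in itertools.combinations(sorted(points), r):
                    for orient in (1, -1):
                        ok = True
                        for (a1, b1), (a2, b2) in zip(combo, combo[1:]):
                            if not (0 < a2 - a1 <= max_gap):
                                ok = False
                                break
                            if not (0 < orient * (b2 - b1) <= max_gap):
                                ok = False
                                break
                        if ok:
                            combo_py = tuple((int(x), int(y)) for x, y in combo)
                            cand = (-len(combo_py), combo_py)
                            if best is None or cand < best:
                                best = cand
                if best is not None:
                    break
            return best

        expected_blocks = []
        while True:
            best = all_chains(remaining)
            if best is None or -best[0] < min_len:
                break
            expected_blocks.append(best[1])
            for pt in best[1]:
                remaining.remove(pt)
        got = [
            tuple((int(x[1:]), int(y[1:])) for x, y in blk.anchors)
            for blk in blocks
        ]
        assert got == expected_blocks


class TestAnnotateAndLabel:
    def _block(self, anchors):
        return CollinearBlock(block_id="b1", genome_a="A", genome_b="A",
                              chrom_a="c1", chrom_b="c2", anchors=anchors)

    def _stats(self, a, b, ks):
        return PairStats(gene_a=a, gene_b=b, ka=0.1, ks=ks, n_sites=100,
                         s_sites=50, nd=1, sd=1, aa_identity=0.9, gap_fraction=0.0)

    def test_median_odd(self):
        blk = self._block([("a", "b"), ("c", "d"), ("e", "f")])
        table = {("a", "b"): self._stats("a", "b", 0.1),
                 ("c", "d"): self._stats("c", "d", 0.2),
                 ("e", "f"): self._stats("e", "f", 0.3)}
        annotate_blocks_ks([blk], table)
        assert blk.median_ks == pytest.approx(0.2)

    def test_median_single_and_even(self):
        blk = self._block([("a", "b")])
        annotate_blocks_ks([blk], {("a", "b"): self._stats("a", "b", 0.12)})
        assert blk.median_ks == pytest.approx(0.12)
        blk2 = self._block([("a", "b"), ("c", "d")])
        annotate_blocks_ks([blk2], {("a", "b"): self._stats("a", "b", 0.1),
                                    ("c", "d"): self._stats("c", "d", 0.2)})
        assert blk2.median_ks == pytest.approx(0.15)

    def test_all_saturated_block_unassigned(self):
        blk = self._block([("a", "b")])
        st = self._stats("a", "b", 0.2)
        st.ks = None
        st.saturated = True
        annotate_blocks_ks([blk], {("a", "b"): st})
        assert blk.median_ks is None
        label_blocks_by_event([blk], {"SCT": (0.1, 0.6)})
        assert blk.event_label == "UNASSIGNED"

    def test_labels_by_window(self):
        young = self._block([("a", "b")])
        young.median_ks = 0.25
        old = self._block([("c", "d")])
        old.median_ks = 1.30
        stray = self._block([("e", "f")])
        stray.median_ks = 0.8
        windows = {"SCT": (0.1, 0.6), "ECH": (1.0, 1.6)}
        label_blocks_by_event([young, old, stray], windows)
        assert young.event_label == "SCT"
        assert old.event_label == "ECH"
        assert stray.event_label == "UNASSIGNED"

    def test_overlapping_windows_rejected(self):
        blk = self._block([("a", "b")])
        blk.median_ks = 0.3
        with pytest.raises(ValueError, match="overlap"):
            label_blocks_by_event([blk], {"SCT": (0.1, 0.6), "ECH": (0.5, 1.2)})

    def test_clean_simulated_diagonals_fully_recovered(self):
        from quartetconv.simulate import simulate_genome_pair

        sim = simulate_genome_pair(n_chrom=2, genes_per_chrom=60,
                                   duplicate_density_profile=0.5,
                                   converted_rate_profile=0.0, seed=4,
                                   with_sequences=False)
        blocks = chain_collinear_pairs(sim.paralog_pairs["P"],
                                       [sim.catalogs["P"]], 50, 4)
        anchored = {frozenset(anchor) for blk in blocks for anchor in blk.anchors}
        expected = {frozenset((p.gene_a, p.gene_b)) for p in sim.paralog_pairs["P"]}
        assert anchored == expected
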