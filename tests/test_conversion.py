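"""Conversion detection: profiles, scoring, segments, bootstrap, calls."""

import itertools

import numpy as np
import pytest

from quartetconv.config import PipelineConfig
from quartetconv.conversion import (
    Segment,
    bootstrap_segment_p,
    classify_quartet,
    conversion_score_array,
    detect_pcv,
    detect_wcv,
    maximal_scoring_segments,
    quartet_topology,
    ruzzo_tompa,
    site_profiles,
    topology_from_matrix,
)
from quartetconv.models import CodonAlignment, ConversionCall, Quartet
from quartetconv.quartets import quartet_from_sequences
from quartetconv.simulate import ConversionSpec, QuartetSimConfig, simulate_quartet

from .oracles import exhaustive_max_segments, least_squares_topology


def _toy_quartet(seqs):
    q = Quartet(quartet_id="toy", p1="P1", p2="P2", s1="S1", s2="S2")
    q.alignment = CodonAlignment(ids=["P1", "P2", "S1", "S2"], seqs=list(seqs))
    return q


class TestSiteProfiles:
    def test_identical_sequences_all_zero(self):
        q = _toy_quartet(["ATGGCTAAA"] * 4)
        prof = site_profiles(q)
        for arr in prof.values():
            assert np.all(arr == 0)

    def test_single_mismatch_position(self):
        base = "ATGGCTAAA"
        p2 = base[:7] + "G" + base[8:]
        q = _toy_quartet([base, p2, base, base])
        prof = site_profiles(q)
        assert prof["par"][7] == 1 and prof["par"].sum() == 1
        assert prof["orth1"].sum() == 0
        assert prof["orth2"][7] == 1

    def test_gap_column_missing_everywhere(self):
        base = "ATGGCTAAA"
        gapped = "ATG---AAA"
        q = _toy_quartet([base, gapped, base, base])
        prof = site_profiles(q)
        for arr in prof.values():
            assert np.all(np.isnan(arr[3:6]))

    def test_mismatch_counts_match_recount(self, null_quartet):
        q, _ = null_quartet
        prof = site_profiles(q)
        s1, s2 = q.alignment.seqs[0], q.alignment.seqs[1]
        manual = sum(1 for a, b in zip(s1, s2) if a != b)
        assert np.nansum(prof["par"]) == manual


class TestScoreArray:
    def test_sign_conventions(self):
        par = np.array([0.0, 1.0, 0.0])
        o1 = np.array([1.0, 0.0, 0.0])
        o2 = np.array([1.0, 0.0, 0.0])
        assert conversion_score_array(par, o1, o2).tolist() == [1.0, -1.0, 0.0]

    def test_missing_scores_zero(self):
        par = np.array([np.nan])
        o = np.array([np.nan])
        assert conversion_score_array(par, o, o).tolist() == [0.0]


class TestRuzzoTompa:
    def test_single_positive_run(self):
        scores = np.zeros(40)
        scores[10:22] = 1.0
        segs = maximal_scoring_segments(scores, min_tract_len=10)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end, segs[0].score) == (10, 21, 12.0)

    def test_all_nonpositive_yields_nothing(self):
        assert ruzzo_tompa(np.array([-1.0, 0.0, -0.5, 0.0])) == []

    def test_min_length_filter_counts_informative_columns(self):
        scores = np.zeros(30)
        scores[5:17] = 1.0
        missing = np.zeros(30, dtype=bool)
        missing[6:10] = True  # 4 of the 12 columns uninformative
        segs = maximal_scoring_segments(scores, min_tract_len=10, missing=missing)
        assert segs == []  # only 8 informative columns

    @pytest.mark.parametrize("n", range(1, 10))
    def test_matches_exhaustive_oracle_small_arrays(self, n):
        for values in itertools.product((-1.0, 0.0, 1.0), repeat=n):
            got = sorted((s.start, s.end, s.score) for s in ruzzo_tompa(np.array(values)))
            expected = exhaustive_max_segments(values)
            assert got == expected, values

    def test_matches_exhaustive_oracle_random_half_integer(self):
        rng = np.random.default_rng(0)
        choices = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        for _ in range(400):
            arr = rng.choice(choices, size=12)
            got = sorted((s.start, s.end, s.score) for s in ruzzo_tompa(arr))
            assert got == exhaustive_max_segments(arr), arr


class TestBootstrap:
    def test_all_zero_scores_p_one(self):
        scores = np.zeros(60)
        p = bootstrap_segment_p(scores, Segment(0, 11, 0.0), B=200, seed=0)
        assert p == 1.0

    def test_strong_run_is_significant(self):
        rng = np.random.default_rng(1)
        scores = rng.choice([-1.0, 0.0, 0.0, 0.0], size=300)
        scores[100:130] = 1.0
        segs = maximal_scoring_segments(scores, 10)
        p = bootstrap_segment_p(scores, segs[0], B=1000, seed=2)
        assert p <= 0.05

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        scores = rng.choice([-1.0, 0.0, 0.5], size=90)
        seg = Segment(10, 30, 4.0)
        p1 = bootstrap_segment_p(scores, seg, B=300, seed=42)
        p2 = bootstrap_segment_p(scores, seg, B=300, seed=42)
        assert p1 == p2

    def test_small_B_warns(self):
        with pytest.warns(UserWarning):
            bootstrap_segment_p(np.zeros(30), Segment(0, 10, 0.0), B=50, seed=0)


class TestDetectPcv:
    def test_recovers_implanted_tract(self, tract_quartet, fast_config):
        q, truth = tract_quartet
        calls = detect_pcv(q, fast_config, seed=1)
        assert len(calls) >= 1
        ev = truth.events[0]
        call = calls[0]
        assert call.call_type == "PCV"
        assert call.tract_start <= ev.tract_end and call.tract_end >= ev.tract_start
        assert call.acceptor.endswith("P2") and call.donor.endswith("P1")

    def test_two_disjoint_tracts_found_by_recursion(self, fast_config):
        conv = [
            ConversionSpec(kind="tract", acceptor="P2", donor="P1",
                           tract_start=151, tract_end=270, time_fraction=1.0),
            ConversionSpec(kind="tract", acceptor="P2", donor="P1",
                           tract_start=901, tract_end=1020, time_fraction=1.0),
        ]
        seqs, truth = simulate_quartet(
            QuartetSimConfig(n_codons=400, conversion=conv), seed=3
        )
        q = quartet_from_sequences("two", seqs)
        calls = detect_pcv(q, fast_config, seed=3)
        hit = [False, False]
        for c in calls:
            for k, ev in enumerate(truth.events):
                if c.tract_start <= ev.tract_end and c.tract_end >= ev.tract_start:
                    hit[k] = True
        assert all(hit)

    def test_masking_monotonicity(self, fast_config):
        conv = [
            ConversionSpec(kind="tract", acceptor="P2", donor="P1",
                           tract_start=151, tract_end=270, time_fraction=1.0),
            ConversionSpec(kind="tract", acceptor="P2", donor="P1",
                           tract_start=901, tract_end=990, time_fraction=1.0),
        ]
        seqs, _ = simulate_quartet(QuartetSimConfig(n_codons=400, conversion=conv), seed=6)
        q = quartet_from_sequences("mono", seqs)
        calls = detect_pcv(q, fast_config, seed=6)
        scores = [c.score for c in calls]
        assert scores == sorted(scores, reverse=True)

    def test_tract_mapping_roundtrip_with_gaps(self, fast_config):
        conv = ConversionSpec(kind="tract", acceptor="P2", donor="P1",
                              tract_start=301, tract_end=420, time_fraction=1.0)
        seqs, _ = simulate_quartet(QuartetSimConfig(n_codons=300, conversion=conv), seed=9)
        # introduce a codon deletion upstream of the tract in S1
        seqs = dict(seqs)
        seqs["S1"] = seqs["S1"][:30] + seqs["S1"][33:]
        q = quartet_from_sequences("gapq", seqs)
        calls = detect_pcv(q, fast_config, seed=9)
        assert calls, "tract should still be detected with an upstream indel"
        c = calls[0]
        # map acceptor tract coordinates back through the alignment
        aln = q.alignment
        row = aln.ids.index(c.acceptor)
        colmap = aln.column_to_ungapped(row)
        inside = [p for p in colmap[c.col_start : c.col_end + 1] if p >= 0]
        assert inside[0] + 1 == c.tract_start
        assert inside[-1] + 1 == c.tract_end


class TestDetectWcv:
    def test_whole_conversion_called_with_acceptor(self, fast_config):
        conv = ConversionSpec(kind="whole", acceptor="P2", donor="P1", time_fraction=1.0)
        seqs, _ = simulate_quartet(QuartetSimConfig(n_codons=400, conversion=conv), seed=21)
        q = quartet_from_sequences("w", seqs)
        call = detect_wcv(q, fast_config, seed=21)
        assert call is not None and call.call_type == "WCV"
        assert call.acceptor.endswith("P2")
        assert call.tract_start == 1 and call.tract_end == 1200
        assert call.p_value <= 0.05

    def test_no_call_without_conversion(self, null_quartet, fast_config):
        q, _ = null_quartet
        assert detect_wcv(q, fast_config, seed=2) is None

    def test_recent_conversion_direction_both_copies(self, fast_config):
        # conversion at the moment of speciation elevates both ortholog Ks
        conv = ConversionSpec(kind="whole", acceptor="P2", donor="P1", time_fraction=0.999)
        seqs, _ = simulate_quartet(QuartetSimConfig(n_codons=500, conversion=conv), seed=30)
        q = quartet_from_sequences("sym", seqs)
        call = detect_wcv(q, fast_config, seed=30)
        assert call is not None


class TestTopology:
    def test_orthologs_closer_gives_expected(self):
        d = np.array([
            [0.00, 0.25, 0.12, 0.26],
            [0.25, 0.00, 0.26, 0.13],
            [0.12, 0.26, 0.00, 0.25],
            [0.26, 0.13, 0.25, 0.00],
        ])
        assert topology_from_matrix(d) == "expected"

    def test_converted_pair_gives_paralogs_sister(self):
        # P2 overwritten by P1: paralogs nearly identical, P2's ortholog
        # distance elevated to paralog depth
        d = np.array([
            [0.00, 0.05, 0.12, 0.26],
            [0.05, 0.00, 0.13, 0.26],
            [0.12, 0.13, 0.00, 0.25],
            [0.26, 0.26, 0.25, 0.00],
        ])
        assert topology_from_matrix(d) == "paralogs_sister"

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_least_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # additive distances from a random tree plus small noise
        ext = rng.uniform(0.02, 0.3, size=4)
        internal = rng.uniform(0.0, 0.2)
        pairing = rng.integers(0, 3)
        groups = [({0, 1}, {2, 3}), ({0, 2}, {1, 3}), ({0, 3}, {1, 2})][pairing]
        d = np.zeros((4, 4))
        for i in range(4):
            for j in range(i + 1, 4):
                split = ({i} <= groups[0]) != ({j} <= groups[0])
                dist = ext[i] + ext[j] + (internal if split else 0.0)
                d[i, j] = d[j, i] = dist + rng.normal(0, 0.002)
        d = np.abs((d + d.T) / 2)
        np.fill_diagonal(d, 0.0)
        assert topology_from_matrix(d) == least_squares_topology(d)


class TestClassify:
    def _call(self, qid, kind, genome):
        return ConversionCall(quartet_id=qid, call_type=kind, converted_genome=genome,
                              acceptor="x", donor="y", tract_start=1, tract_end=10,
                              col_start=0, col_end=9, score=1.0, p_value=0.01)

    def test_wcv_takes_precedence(self):
        q = Quartet(quartet_id="q", p1="a", p2="b", s1="c", s2="d",
                    genome_a="P", genome_b="S")
        calls = [self._call("q", "PCV", "P"), self._call("q", "WCV", "P")]
        assert classify_quartet(calls, q)["P"] == "WCV"

    def test_no_calls_nonconverted(self):
        q = Quartet(quartet_id="q", p1="a", p2="b", s1="c", s2="d",
                    genome_a="P", genome_b="S")
        status = classify_quartet([], q)
        assert status == {"P": "nonconverted", "S": "nonconverted"}
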