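"""Nussinov folding and the hairpin-candidacy rules."""

import numpy as np
import pytest

from xenomir.novel import (
    CandidateWindow,
    HairpinThresholds,
    dinucleotide_shuffle,
    evaluate_hairpin_candidate,
    extract_candidate_windows,
    filter_known_transcripts,
    nussinov_fold,
)
from xenomir.simulate import generate_hairpin_reference, revcomp

BASES = "ACGT"
PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def enumerate_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Exhaustive recursion over all non-crossing structures (oracle)."""

    def best(i, j):
        if j - i <= min_loop:
            return 0
        # j unpaired, or j paired with some k
        top = best(i, j - 1)
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in PAIRS:
                top = max(top, best(i, k - 1) + 1 + best(k + 1, j - 1) if k > i
                          else 1 + best(k + 1, j - 1))
        return top

    return best(0, len(seq) - 1)


class TestNussinov:
    def test_perfect_triplet_stem(self):
        r = nussinov_fold("GGGAAACCC")
        assert (r.pair_count, r.structure, r.loop_count) == (3, "(((...)))", 1)

    def test_no_complementary_bases(self):
        assert nussinov_fold("AAAAAA").pair_count == 0

    def test_structure_is_valid_and_consistent(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            seq = "".join(BASES[b] for b in rng.integers(0, 4, 40))
            r = nussinov_fold(seq)
            assert len(r.pairs) == r.pair_count
            for i, j in r.pairs:
                assert (seq[i], seq[j]) in PAIRS
                assert j - i > 3
            # non-crossing
            for (i, j) in r.pairs:
                for (a, b) in r.pairs:
                    assert not (i < a < j < b)

    def test_dp_equals_exhaustive_enumeration_short_sequences(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            n = int(rng.integers(1, 13))
            seq = "".join(BASES[b] for b in rng.integers(0, 4, n))
            assert nussinov_fold(seq).pair_count == enumerate_max_pairs(seq)

    def test_long_sequence_rejected(self):
        with pytest.raises(ValueError):
            nussinov_fold("A" * 301)


class TestTranscriptFilter:
    def test_exact_substring_removed_no_hit_retained(self):
        tx = {"t1": "ACGTACGTACGTACGTACGTACGTACGT"}
        tags = ["ACGTACGTACGTACGTACGT", "TTTTTTTTTTTTTTTTTTTT"]
        assert filter_known_transcripts(tags, tx, 1) == [tags[1]]

    def test_matches_brute_force_hamming_oracle(self):
        rng = np.random.default_rng(4)
        tx = {f"t{i}": "".join(BASES[b] for b in rng.integers(0, 4, 60))
              for i in range(5)}
        tags = ["".join(BASES[b] for b in rng.integers(0, 4, 18))
                for _ in range(10)]
        tags += [tx["t0"][5:25], tx["t3"][10:28]]

        def hits(tag):
            for seq in tx.values():
                for s in range(len(seq) - len(tag) + 1):
                    if sum(a != b for a, b in zip(tag, seq[s:s + len(tag)])) <= 1:
                        return True
            return False

        expected = [t for t in tags if not hits(t)]
        assert filter_known_transcripts(tags, tx, 1) == expected


class TestWindows:
    def test_forward_hit_arithmetic(self):
        rng = np.random.default_rng(1)
        genome = {"c": "".join(BASES[b] for b in rng.integers(0, 4, 2000))}
        tag = genome["c"][1000:1022]
        if genome["c"].find(tag) != 1000 or genome["c"].find(revcomp(tag)) != -1:
            pytest.skip("tag not unique in random genome draw")
        (w,) = extract_candidate_windows(tag, genome, flank=70)
        assert (w.offset, w.offset + len(w.sequence)) == (930, 1092)
        assert w.sequence[w.tag_start:w.tag_end] == tag

    def test_reverse_strand_window_reads_sense(self):
        rng = np.random.default_rng(6)
        genome = {"c": "".join(BASES[b] for b in rng.integers(0, 4, 500))}
        tag = revcomp(genome["c"][200:222])
        windows = [w for w in extract_candidate_windows(tag, genome, flank=30)
                   if w.strand == "-"]
        assert windows
        w = windows[0]
        assert w.sequence[w.tag_start:w.tag_end] == tag

    def test_absent_tag_empty(self):
        assert extract_candidate_windows("A" * 22, {"c": "CGCG" * 50}) == []


def planted_window(seed=0, flank=70):
    sim = generate_hairpin_reference(1, seed=seed, n_novel=1)
    nid = "sim-novel-000"
    arm5 = sim.novel[nid]["arm5"]
    # a perfect stem matches on both strands (the 3' arm is the exact
    # reverse complement of the tag); use the forward 5'-arm locus
    windows = extract_candidate_windows(arm5, sim.genome, flank=flank)
    (w,) = [x for x in windows if x.strand == "+"]
    return sim, w


class TestEvaluate:
    def test_planted_perfect_hairpin_passes(self):
        _, w = planted_window(seed=21)
        cand = evaluate_hairpin_candidate(w)
        assert cand.verdict == "pass", cand.reasons
        assert cand.loop_count == 1
        assert cand.pair_count >= 18
        assert cand.paired_fraction_of_tag >= 0.6

    def test_tag_on_loop_fails_with_loop_overlap(self):
        sim, _ = planted_window(seed=22)
        hp = sim.novel["sim-novel-000"]["sequence"]
        # a pseudo-tag centered on the terminal loop of the planted hairpin
        centre = len(hp) // 2
        tag_lo, tag_hi = centre - 9, centre + 9
        w = CandidateWindow(
            tag=hp[tag_lo:tag_hi], contig="c", strand="+", offset=0,
            sequence=hp, tag_start=tag_lo, tag_end=tag_hi)
        cand = evaluate_hairpin_candidate(w)
        assert cand.verdict == "fail"
        assert "loop_overlap" in cand.reasons

    def test_unstructured_window_fails_few_pairs(self):
        seq = "A" * 60 + "C" * 60
        w = CandidateWindow("A" * 22, "c", "+", 0, seq, 10, 32)
        cand = evaluate_hairpin_candidate(w)
        assert cand.verdict == "fail"
        assert "few_pairs" in cand.reasons

    def test_dinucleotide_shuffle_null_pass_rate_low(self):
        _, w = planted_window(seed=23)
        rng = np.random.default_rng(99)
        passes = 0
        n = 60
        for _ in range(n):
            shuffled = dinucleotide_shuffle(w.sequence, rng)
            sw = CandidateWindow(
                tag=shuffled[w.tag_start:w.tag_end], contig="c", strand="+",
                offset=0, sequence=shuffled,
                tag_start=w.tag_start, tag_end=w.tag_end)
            if evaluate_hairpin_candidate(sw).verdict == "pass":
                passes += 1
        assert passes / n <= 0.10


def test_shuffle_preserves_dinucleotide_composition():
    from collections import Counter

    rng = np.random.default_rng(12)
    seq = "".join(BASES[b] for b in rng.integers(0, 4, 120))
    for _ in range(5):
        s = dinucleotide_shuffle(seq, rng)
        assert Counter(zip(s, s[1:])) == Counter(zip(seq, seq[1:]))
        assert s[0] == seq[0] and s[-1] == seq[-1]
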