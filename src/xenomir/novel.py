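"""Novel-hairpin candidate screening.

Tags that map to no reference hairpin are first filtered against known
transcripts (rRNA/tRNA/mRNA degradation products), then located in the
genome; each hit is expanded to a +/-70-nt window and judged for hairpin
candidacy with an explicit, fully computable rule set built on a Nussinov
maximum-base-pairing fold: a single terminal loop, at least 18 base
pairs, at least 60% of the tag paired across the loop, and no more than
4 nt of tag/terminal-loop overlap. The rules are this package's own
testable criterion for pre-miRNA-like structure; thermodynamic folding
and learned classifiers are deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import EncodedReference, encode
from .io import HairpinReference
from .simulate import revcomp

logger = logging.getLogger(__name__)

MIN_LOOP = 3

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
# allowed pairs: AU/AT, GC and the GU/GT wobble
_PAIR = np.zeros((5, 5), dtype=np.uint8)
for _x, _y in (("A", "T"), ("G", "C"), ("G", "T")):
    _PAIR[_CODE[_x], _CODE[_y]] = 1
    _PAIR[_CODE[_y], _CODE[_x]] = 1


def _encode_codes(seq: str) -> np.ndarray:
    return np.array([_CODE.get(ch, 4) for ch in seq.upper()], dtype=np.int64)


def _fill_py(codes: np.ndarray, pair: np.ndarray, min_loop: int) -> np.ndarray:
    n = codes.size
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = 0
            if pair[codes[i], codes[j]] and span > min_loop:
                best = dp[i + 1, j - 1] + 1
            for k in range(i, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return dp


try:  # jit-compile the O(n^3) fill; the pure-Python fill is the fallback
    from numba import njit

    _fill = njit(_fill_py)
except Exception:  # pragma: no cover - numba present in supported envs
    _fill = _fill_py


@dataclass
class FoldResult:
    sequence: str
    pairs: list[tuple[int, int]]
    structure: str
    pair_count: int
    loop_count: int

    def hairpin_loops(self) -> list[tuple[int, int]]:
        """Closing pairs that enclose no other pair (terminal loops)."""
        loops = []
        for (i, j) in self.pairs:
            if not any(i < a and b < j for (a, b) in self.pairs if (a, b) != (i, j)):
                loops.append((i, j))
        return loops


def nussinov_fold(sequence: str, min_loop: int = MIN_LOOP) -> FoldResult:
    """Maximum non-crossing {AU, GC, GU} pairing with hairpin loops >= min_loop.

    The traceback is deterministic: pairing (i, j) is preferred over a
    bifurcation, and bifurcations split at the leftmost optimal point.
    """
    if len(sequence) > 300:
        raise ValueError("nussinov_fold is limited to sequences of length <= 300")
    n = len(sequence)
    codes = _encode_codes(sequence)
    if n == 0:
        return FoldResult(sequence, [], "", 0, 0)
    dp = _fill(codes, _PAIR, min_loop)
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if dp[i, j] == 0:
            continue
        if _PAIR[codes[i], codes[j]] and dp[i, j] == dp[i + 1, j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            if dp[i, k] + dp[k + 1, j] == dp[i, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    pairs.sort()
    structure = ["."] * n
    for i, j in pairs:
        structure[i], structure[j] = "(", ")"
    result = FoldResult(sequence, pairs, "".join(structure), len(pairs), 0)
    result.loop_count = len(result.hairpin_loops())
    return result


# ---------------------------------------------------------------------------
# transcript filter


def filter_known_transcripts(
    tags: Sequence[str],
    transcripts: Mapping[str, str],
    max_mismatches: int = 1,
) -> list[str]:
    """Drop tags that align ungapped to any known transcript.

    A tag matching some transcript offset with <= max_mismatches is
    removed; survivors are returned in input order with removal counts
    logged per transcript.
    """
    ref = EncodedReference(HairpinReference(records=dict(transcripts)))
    survivors = []
    removed: dict[str, int] = {}
    for tag in tags:
        tag_arr = encode(tag)
        hit = None
        for tid in ref.ids:
            windows = ref.windows(tid, tag_arr.size)
            if windows is None:
                continue
            mism = np.count_nonzero(windows != tag_arr, axis=1)
            if (mism <= max_mismatches).any():
                hit = tid
                break
        if hit is None:
            survivors.append(tag)
        else:
            removed[hit] = removed.get(hit, 0) + 1
    logger.info(
        "filter_known_transcripts: %d/%d removed %s",
        sum(removed.values()), len(tags), removed,
    )
    return survivors


# ---------------------------------------------------------------------------
# window extraction and evaluation


@dataclass(frozen=True)
class CandidateWindow:
    tag: str
    contig: str
    strand: str               # '+' or '-'
    offset: int               # window start on the forward strand
    sequence: str             # window sequence in tag orientation
    tag_start: int            # tag span within `sequence`
    tag_end: int


def extract_candidate_windows(
    tag: str, genome: Mapping[str, str], flank: int = 70
) -> list[CandidateWindow]:
    """Exact-match loci of the tag (either strand) expanded by +/-flank.

    Minus-strand hits return the reverse-complemented context so the tag
    always reads sense within the window; windows are clipped at contig
    ends. A tag absent from the genome yields an empty list.
    """
    windows = []
    rc = revcomp(tag)
    L = len(tag)
    for contig in sorted(genome):
        seq = genome[contig]
        for strand, needle in (("+", tag), ("-", rc)):
            pos = seq.find(needle)
            while pos != -1:
                s0 = max(0, pos - flank)
                s1 = min(len(seq), pos + L + flank)
                chunk = seq[s0:s1]
                if strand == "+":
                    windows.append(CandidateWindow(
                        tag, contig, "+", s0, chunk, pos - s0, pos - s0 + L))
                else:
                    windows.append(CandidateWindow(
                        tag, contig, "-", s0, revcomp(chunk),
                        s1 - (pos + L), s1 - pos))
                pos = seq.find(needle, pos + 1)
    if not windows:
        logger.debug("extract_candidate_windows: %s not found in genome", tag)
    return windows


@dataclass
class HairpinThresholds:
    """Config-exposed pass rules for hairpin candidacy."""

    min_pairs: int = 18
    min_paired_fraction: float = 0.6
    max_loop_overlap: int = 4
    min_window: int = 50
    max_window: int = 150
    span_pad: int = 3


@dataclass
class NovelCandidate:
    tag: str
    window_sequence: str
    window_offset: int        # offset of the scored subwindow within the source
    pair_count: int
    paired_fraction_of_tag: float
    loop_count: int
    verdict: str              # pass | fail
    reasons: list[str] = field(default_factory=list)
    fold: FoldResult | None = None
    arm_complementarity: float = 0.0


def _tag_outside_pairs(fold: FoldResult, tag_lo: int, tag_hi: int) -> int:
    n = 0
    for i, j in fold.pairs:
        if tag_lo <= i < tag_hi and not (tag_lo <= j < tag_hi):
            n += 1
        elif tag_lo <= j < tag_hi and not (tag_lo <= i < tag_hi):
            n += 1
    return n


#: maximum tag-to-partner gap considered during localization; pre-miRNA
#: terminal loops rarely exceed ~40 nt
MAX_LOOP_SPAN = 48


def _complementarity(tag: str, segment: str) -> int:
    """Antiparallel Watson-Crick match count of the tag vs a segment.

    Localization deliberately ignores GU wobble: real hairpin arms are
    predominantly WC-paired, and counting wobble here would let random
    sequence (6/16 pairable dinucleotides instead of 4/16) masquerade as
    an opposite arm. The fold itself still awards wobble pairs.
    """
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    L = len(tag)
    return sum((tag[k], segment[L - 1 - k]) in wc for k in range(L))


def _best_partner_span(seq: str, tag_lo: int, tag_hi: int) -> tuple[int, int] | None:
    """Locate the window segment most WC-complementary to the tag.

    Candidate placements never overlap the tag (a hairpin's opposite arm
    cannot) and stay within a terminal-loop distance of it; ties resolve
    toward the placement nearest the tag. Returns (start, score) or None
    when the window leaves no room.
    """
    L = tag_hi - tag_lo
    tag = seq[tag_lo:tag_hi]
    best = None
    for s in range(0, len(seq) - L + 1):
        if s < tag_hi and s + L > tag_lo:
            continue
        gap = s - tag_hi if s >= tag_hi else tag_lo - (s + L)
        if gap > MAX_LOOP_SPAN:
            continue
        score = _complementarity(tag, seq[s:s + L])
        distance = abs(s - tag_lo)
        key = (-score, distance, s)
        if best is None or key < best[0]:
            best = (key, s, score)
    if best is None:
        return None
    return best[1], best[2]


def _apply_rules(fold: FoldResult, tag_lo: int, tag_hi: int,
                 th: HairpinThresholds) -> tuple[list[str], float]:
    tag_len = tag_hi - tag_lo
    reasons: list[str] = []
    loops = fold.hairpin_loops()
    if fold.loop_count != 1:
        reasons.append("no_hairpin" if fold.loop_count == 0 else "multiple_loops")
        paired_fraction = _tag_outside_pairs(fold, tag_lo, tag_hi) / tag_len
    else:
        a, b = loops[0]
        loop_lo, loop_hi = a + 1, b  # positions strictly inside the closing pair
        across = 0
        for i, j in fold.pairs:
            for p, q in ((i, j), (j, i)):
                if tag_lo <= p < tag_hi and (
                    (p <= a and q >= b) or (p >= b and q <= a)
                ):
                    across += 1
        paired_fraction = across / tag_len
        if paired_fraction < th.min_paired_fraction:
            reasons.append("low_tag_pairing")
        overlap = max(0, min(tag_hi, loop_hi) - max(tag_lo, loop_lo))
        if overlap > th.max_loop_overlap:
            reasons.append("loop_overlap")
    if fold.pair_count < th.min_pairs:
        reasons.append("few_pairs")
    return reasons, paired_fraction


def evaluate_hairpin_candidate(
    window: CandidateWindow,
    thresholds: HairpinThresholds | None = None,
    min_loop: int = MIN_LOOP,
) -> NovelCandidate:
    """Judge one extracted window for pre-miRNA-like structure.

    The putative hairpin is localized by complementarity, not by folding:
    the window segment most complementary (antiparallel) to the tag marks
    the opposite arm, and the padded span enclosing tag and partner is
    folded and judged by the pass rules. When the whole window is short
    enough it is judged as well (covering tags sitting mid-hairpin, e.g.
    on the terminal loop). Localization is necessary because the
    maximum-pairing structure of a hairpin embedded in long random flanks
    never keeps a single terminal loop; judging a single
    complementarity-chosen span keeps the rules unbiased — no candidate
    is selected by how close it comes to passing.
    """
    th = thresholds or HairpinThresholds()
    seq = window.sequence
    n = len(seq)
    tag_lo, tag_hi = window.tag_start, window.tag_end
    L = tag_hi - tag_lo

    spans: list[tuple[int, int]] = []
    partner = _best_partner_span(seq, tag_lo, tag_hi)
    arm_fraction = 0.0
    if partner is not None:
        s, score = partner
        arm_fraction = score / L
        lo = max(0, min(tag_lo, s) - th.span_pad)
        hi = min(n, max(tag_hi, s + L) + th.span_pad)
        spans.append((lo, hi))
    if n <= th.max_window and (not spans or spans[0] != (0, n)):
        spans.append((0, n))
    if not spans:
        spans.append((0, min(n, th.max_window)))

    # the tag must be WC-complementary, in antiparallel register, to its
    # putative opposite arm: bulgy chance stems reach 18 fold pairs in a
    # ~60-nt span surprisingly often, but a >=60% contiguous-register
    # match is what a real arm provides and shuffled sequence does not
    arm_reasons = []
    if arm_fraction < th.min_paired_fraction:
        arm_reasons.append("weak_arm_complementarity")

    evaluated = []
    for lo, hi in spans:
        fold = nussinov_fold(seq[lo:hi], min_loop)
        reasons, frac = _apply_rules(fold, tag_lo - lo, tag_hi - lo, th)
        evaluated.append((lo, hi, fold, arm_reasons + reasons, frac))

    # report the passing span if any; otherwise the most hairpin-like
    # evaluation (single loop preferred, then more pairs)
    evaluated.sort(key=lambda e: (bool(e[3]), e[2].loop_count != 1, -e[2].pair_count))
    lo, hi, fold, reasons, paired_fraction = evaluated[0]

    return NovelCandidate(
        tag=window.tag,
        window_sequence=fold.sequence,
        window_offset=window.offset + (lo if window.strand == "+" else (n - hi)),
        pair_count=fold.pair_count,
        paired_fraction_of_tag=paired_fraction,
        loop_count=fold.loop_count,
        verdict="pass" if not reasons else "fail",
        reasons=reasons,
        fold=fold,
        arm_complementarity=arm_fraction,
    )


def screen_novel_tags(
    tags: Sequence[str],
    transcripts: Mapping[str, str],
    genome: Mapping[str, str],
    thresholds: HairpinThresholds | None = None,
    max_transcript_mismatches: int = 1,
    flank: int = 70,
) -> list[NovelCandidate]:
    """Full novel stage: transcript filter -> windows -> hairpin rules.

    A tag passes when any of its genomic windows passes; the reported
    candidate is its best window (pass preferred, then most pairs).
    """
    survivors = filter_known_transcripts(tags, transcripts, max_transcript_mismatches)
    out: list[NovelCandidate] = []
    for tag in survivors:
        windows = extract_candidate_windows(tag, genome, flank)
        if not windows:
            continue
        evaluated = [evaluate_hairpin_candidate(w, thresholds) for w in windows]
        evaluated.sort(key=lambda c: (c.verdict != "pass", -c.pair_count))
        out.append(evaluated[0])
    logger.info(
        "screen_novel_tags: %d tags in, %d with windows, %d pass",
        len(tags), len(out), sum(c.verdict == "pass" for c in out),
    )
    return out


# ---------------------------------------------------------------------------
# dinucleotide shuffle (null model for the hairpin rules)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle preserving dinucleotide composition."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    for _ in range(1000):
        # pick a candidate last-edge per non-terminal vertex; must form a
        # tree into the terminal vertex for an Eulerian walk to exist
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - tiny alphabets converge quickly
        return seq
    walk_edges = {}
    for v, succs in edges.items():
        rest = list(succs)
        if v in last_edge:
            rest.remove(last_edge[v])
        order = list(rng.permutation(len(rest)))
        shuffled = [rest[i] for i in order]
        if v in last_edge:
            shuffled.append(last_edge[v])
        walk_edges[v] = shuffled
    result = [seq[0]]
    idx = {v: 0 for v in edges}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = walk_edges[cur][idx[cur]]
        idx[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)
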