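"""Demultiplexing, 3' adapter trimming and tag collapsing.

Reads carry a 7-nt 5' library index followed by the small-RNA insert and
the 3' adapter. Demultiplexing requires an exact index match (the two
library indices differ at enough positions that no tolerance is needed);
trimming cuts at the leftmost occurrence of the adapter's first 7 bases
allowing one mismatch; collapsing aggregates identical inserts into unique
tags with per-library counts, then applies the 16-27 nt length filter and
the >=2-reads-in-at-least-one-library abundance filter.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .config import PipelineConfig

logger = logging.getLogger(__name__)

ADAPTER_SEED_LEN = 7
ADAPTER_SEED_MISMATCHES = 1


@dataclass
class TagRecord:
    """A unique trimmed insert with its per-library read counts."""

    sequence: str
    counts: dict[str, int]

    @property
    def length(self) -> int:
        return len(self.sequence)

    def count(self, library: str) -> int:
        return self.counts.get(library, 0)


@dataclass
class DemuxResult:
    by_library: dict[str, list[str]]
    unassigned: int = 0
    dropped_n: int = 0

    @property
    def assigned(self) -> int:
        return sum(len(v) for v in self.by_library.values())


def demultiplex(reads: Iterable[tuple[str, str]], index_map: Mapping[str, str]) -> DemuxResult:
    """Assign reads to libraries by exact 5' index match and strip the index.

    Reads containing N are dropped up front (they cannot collapse
    unambiguously); reads whose first k bases match no index are counted as
    unassigned and not emitted. assigned + unassigned + dropped_n equals the
    number of input reads.
    """
    lengths = {len(ix) for ix in index_map.values()}
    if len(lengths) != 1:
        raise ValueError("all library indices must share one length")
    k = lengths.pop()
    lookup = {ix.upper(): lib for lib, ix in index_map.items()}
    result = DemuxResult(by_library={lib: [] for lib in index_map})
    for _rid, seq in reads:
        if "N" in seq:
            result.dropped_n += 1
            continue
        lib = lookup.get(seq[:k])
        if lib is None:
            result.unassigned += 1
        else:
            result.by_library[lib].append(seq[k:])
    logger.info(
        "demultiplex: %d assigned, %d unassigned, %d dropped (N)",
        result.assigned, result.unassigned, result.dropped_n,
    )
    return result


def _seed_match(window: str, seed: str, max_mismatches: int) -> bool:
    mm = 0
    for a, b in zip(window, seed):
        if a != b:
            mm += 1
            if mm > max_mismatches:
                return False
    return True


def trim_adapter(sequence: str, adapter3: str) -> str | None:
    """Cut the insert before the leftmost 3' adapter occurrence.

    The adapter is located by its first 7 bases allowing <=1 mismatch; a
    read without any such occurrence is discarded (returns None). The match
    may start at position 0, yielding an empty insert that the length
    filter removes later.
    """
    if len(adapter3) < ADAPTER_SEED_LEN:
        raise ValueError("adapter3 must be at least 7 nt")
    seed = adapter3[:ADAPTER_SEED_LEN].upper()
    for pos in range(len(sequence) - ADAPTER_SEED_LEN + 1):
        if _seed_match(sequence[pos:pos + ADAPTER_SEED_LEN], seed, ADAPTER_SEED_MISMATCHES):
            return sequence[:pos]
    return None


@dataclass
class TrimStats:
    kept: dict[str, int] = field(default_factory=dict)
    no_adapter: dict[str, int] = field(default_factory=dict)


def trim_libraries(
    by_library: Mapping[str, list[str]], adapter3: str
) -> tuple[dict[str, list[str]], TrimStats]:
    """Apply :func:`trim_adapter` per library, counting discarded reads."""
    stats = TrimStats()
    trimmed: dict[str, list[str]] = {}
    for lib, seqs in by_library.items():
        kept: list[str] = []
        dropped = 0
        for seq in seqs:
            insert = trim_adapter(seq, adapter3)
            if insert is None:
                dropped += 1
            else:
                kept.append(insert)
        trimmed[lib] = kept
        stats.kept[lib] = len(kept)
        stats.no_adapter[lib] = dropped
        logger.info("trim[%s]: kept %d, no adapter %d", lib, len(kept), dropped)
    return trimmed, stats


def collapse_and_filter(
    trimmed: Mapping[str, list[str]], config: PipelineConfig
) -> list[TagRecord]:
    """Collapse identical inserts into tags; apply length and abundance filters.

    A tag survives iff its length is within [min_tag_len, max_tag_len] and
    its count reaches min_tag_count in at least one library. Surviving tags
    keep their exact counts from both libraries, including 0 and 1.
    Idempotent: re-collapsing collapsed output changes nothing.
    """
    counters = {lib: Counter(seqs) for lib, seqs in trimmed.items()}
    all_seqs = set()
    for counter in counters.values():
        all_seqs.update(counter)
    tags = []
    for seq in sorted(all_seqs):
        if not (config.min_tag_len <= len(seq) <= config.max_tag_len):
            continue
        counts = {lib: counters[lib].get(seq, 0) for lib in trimmed}
        if max(counts.values()) < config.min_tag_count:
            continue
        tags.append(TagRecord(sequence=seq, counts=counts))
    logger.info("collapse_and_filter: %d tags retained", len(tags))
    return tags


def length_filtered_totals(
    trimmed: Mapping[str, list[str]], config: PipelineConfig
) -> dict[str, int]:
    """Per-library read counts surviving trimming and the length filter.

    These equal the per-library sum of collapsed tag counts before the
    abundance filter (conservation check in the pipeline report).
    """
    return {
        lib: sum(1 for s in seqs if config.min_tag_len <= len(s) <= config.max_tag_len)
        for lib, seqs in trimmed.items()
    }


def run_preprocess(
    reads: Iterable[tuple[str, str]], config: PipelineConfig
) -> tuple[list[TagRecord], DemuxResult, TrimStats]:
    """demultiplex -> trim -> collapse in one call."""
    demux = demultiplex(reads, config.index_map)
    trimmed, trim_stats = trim_libraries(demux.by_library, config.adapter3)
    tags = collapse_and_filter(trimmed, config)
    return tags, demux, trim_stats
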