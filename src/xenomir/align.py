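"""Ungapped tag-to-hairpin alignment with a mismatch budget.

Each tag is scanned against every sense-strand offset of every hairpin and
all placements with Hamming distance <= max_mismatches are reported; no
gaps and no reverse-complement hits. Multi-mapping is resolved
conservatively: ties across hairpins that carry the same mature name
collapse to the first hairpin (paralogs), while ties that imply different
mature names mark the tag ambiguous and exclude it from counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import HairpinReference

logger = logging.getLogger(__name__)

_BASE_CODE = {ch: i for i, ch in enumerate("ACGTN")}


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class HairpinAlignment:
    tag: str
    hairpin_id: str
    start: int
    end: int
    mismatches: int


class EncodedReference:
    """Hairpin sequences pre-encoded as byte arrays, with sliding windows
    cached per (hairpin, tag length) for repeated scans."""

    def __init__(self, reference: HairpinReference):
        self.reference = reference
        self.ids: list[str] = sorted(reference.records)
        self.arrays = {hid: encode(reference.records[hid]) for hid in self.ids}
        self._windows: dict[tuple[str, int], np.ndarray] = {}

    def windows(self, hairpin_id: str, length: int) -> np.ndarray | None:
        key = (hairpin_id, length)
        if key not in self._windows:
            arr = self.arrays[hairpin_id]
            if length > arr.size:
                self._windows[key] = None
            else:
                self._windows[key] = np.lib.stride_tricks.sliding_window_view(arr, length)
        return self._windows[key]


def align_tag(
    tag: str,
    reference: HairpinReference | EncodedReference,
    max_mismatches: int,
) -> list[HairpinAlignment]:
    """All sense-strand placements of ``tag`` within the mismatch budget,
    sorted by (mismatches, hairpin_id, start)."""
    enc = reference if isinstance(reference, EncodedReference) else EncodedReference(reference)
    tag_arr = encode(tag)
    hits: list[HairpinAlignment] = []
    for hid in enc.ids:
        windows = enc.windows(hid, tag_arr.size)
        if windows is None:
            continue
        mism = np.count_nonzero(windows != tag_arr, axis=1)
        for start in np.flatnonzero(mism <= max_mismatches):
            hits.append(
                HairpinAlignment(
                    tag=tag,
                    hairpin_id=hid,
                    start=int(start),
                    end=int(start) + tag_arr.size,
                    mismatches=int(mism[start]),
                )
            )
    hits.sort(key=lambda a: (a.mismatches, a.hairpin_id, a.start))
    return hits


AMBIGUOUS = "ambiguous"
PARALOG_COLLAPSE = "paralog-collapse"
UNIQUE = "unique"
UNALIGNED = "unaligned"


def _implied_name(alignment: HairpinAlignment, reference: HairpinReference) -> str:
    """Mature name overlapped by the placement, or a hairpin-local label."""
    for ann in reference.matures_of(alignment.hairpin_id):
        if alignment.start < ann.end and alignment.end > ann.start:
            return ann.name
    return f"{alignment.hairpin_id}:unannotated"


def resolve_alignment(
    alignments: Sequence[HairpinAlignment], reference: HairpinReference
) -> tuple[HairpinAlignment | None, str]:
    """Pick one placement among the best-mismatch hits.

    Returns (alignment, status): unique for a single best hit,
    paralog-collapse when multiple best hits imply one mature name (first
    by (hairpin_id, start) wins), ambiguous (alignment None) when best hits
    imply different mature names, unaligned for an empty input.
    """
    if not alignments:
        return None, UNALIGNED
    best_mm = min(a.mismatches for a in alignments)
    best = sorted(
        (a for a in alignments if a.mismatches == best_mm),
        key=lambda a: (a.hairpin_id, a.start),
    )
    if len(best) == 1:
        return best[0], UNIQUE
    names = {_implied_name(a, reference) for a in best}
    if len(names) == 1:
        logger.debug("paralog-collapse: %s -> %s", best[0].tag, best[0].hairpin_id)
        return best[0], PARALOG_COLLAPSE
    return None, AMBIGUOUS


def align_and_resolve(
    tags: Iterable[str],
    reference: HairpinReference,
    max_mismatches: int,
) -> dict[str, tuple[HairpinAlignment | None, str]]:
    """Align and resolve many tags; result is independent of input order."""
    enc = EncodedReference(reference)
    out: dict[str, tuple[HairpinAlignment | None, str]] = {}
    for tag in tags:
        hits = align_tag(tag, enc, max_mismatches)
        out[tag] = resolve_alignment(hits, reference)
    n_status: dict[str, int] = {}
    for _, status in out.values():
        n_status[status] = n_status.get(status, 0) + 1
    logger.info("align_and_resolve: %s", n_status)
    return out
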