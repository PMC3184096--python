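"""Positional annotation of aligned tags and isomiR quantification.

Resolved alignments are classified into the four positional groups used
for stem-loop references — known mature miRNA/miRNA* (within a +/-2 nt
isomiR tolerance at both ends), putative miRNA* (opposite arm of a
single-mature hairpin), loop reads, and loop reads on hairpins with no
annotated mature — plus an arm_variant catch-all for arm reads outside
the isomiR tolerance. Tags of one feature are clustered by start
position; the most abundant start (combined over both libraries) is the
representative form compared between libraries, with the annotated-start
form kept as an extra row when it differs. Counts are normalized per
million hairpin-mapped tags.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import HairpinAlignment
from .config import PipelineConfig, METASTATIC, NON_METASTATIC
from .io import (
    FIVE_PRIME,
    ExpressionTable,
    HairpinReference,
    MatureAnnotation,
)
from .preprocess import TagRecord

logger = logging.getLogger(__name__)

KNOWN_MATURE = "known_mature"
PUTATIVE_STAR = "putative_star"
LOOP = "loop"
LOOP_NO_MATURE = "loop_no_mature"
ARM_VARIANT = "arm_variant"

DE_CATEGORIES = (KNOWN_MATURE, PUTATIVE_STAR)


def infer_loop_interval(
    hairpin_length: int, matures: Sequence[MatureAnnotation]
) -> tuple[int, int]:
    """Terminal-loop interval of a hairpin, 0-based half-open.

    Two matures: strictly between them. One mature: between the mature and
    its mirror image reflected about the hairpin midpoint. None: the
    central third. A degenerate (empty) interval collapses to length 0 at
    the midpoint.
    """
    L = hairpin_length
    if len(matures) >= 2:
        spans = sorted((m.start, m.end) for m in matures)
        lo, hi = spans[0][1], spans[1][0]
    elif len(matures) == 1:
        m = matures[0]
        mirror = (L - m.end, L - m.start)
        first, second = sorted([(m.start, m.end), mirror])
        lo, hi = first[1], second[0]
    else:
        lo, hi = L // 3, (2 * L) // 3
    if lo >= hi:
        mid = L // 2
        logger.debug("degenerate loop interval on hairpin of length %d", L)
        return (mid, mid)
    return (lo, hi)


@dataclass(frozen=True)
class Classification:
    category: str
    feature: str
    mature: MatureAnnotation | None
    start_shift: int | None


def classify_alignment(
    alignment: HairpinAlignment,
    reference: HairpinReference,
    isomir_shift: int,
) -> Classification:
    """Assign one positional category to a resolved alignment."""
    hid = alignment.hairpin_id
    matures = reference.matures_of(hid)
    hp_len = len(reference.records[hid])
    loop_lo, loop_hi = infer_loop_interval(hp_len, matures)

    for m in matures:
        if (
            abs(alignment.start - m.start) <= isomir_shift
            and abs(alignment.end - m.end) <= isomir_shift
        ):
            return Classification(KNOWN_MATURE, m.name, m, alignment.start - m.start)

    if len(matures) == 1:
        m = matures[0]
        midpoint = (alignment.start + alignment.end) / 2
        on_opposite = midpoint >= loop_hi if m.arm == FIVE_PRIME else midpoint < loop_lo
        if on_opposite:
            return Classification(PUTATIVE_STAR, f"{m.name}*", m, None)

    within_loop = alignment.start >= loop_lo and alignment.end <= loop_hi
    if within_loop and matures:
        return Classification(LOOP, f"{hid}:loop", None, None)
    if within_loop and not matures:
        return Classification(LOOP_NO_MATURE, f"{hid}:loop", None, None)

    # overlaps an arm but violates the isomiR tolerance (or straddles arm/loop)
    return Classification(ARM_VARIANT, f"{hid}:variant", None, None)


@dataclass
class AnnotatedGroup:
    """A (feature, start-position) cluster of tags with per-library counts."""

    feature: str
    category: str
    hairpin_id: str
    group_start: int
    start_shift: int | None
    counts: dict[str, int] = field(default_factory=dict)
    seq_counts: Counter = field(default_factory=Counter)
    is_representative: bool = False

    def combined(self) -> int:
        return sum(self.counts.values())

    def top_sequence(self) -> str:
        # most abundant tag sequence of the cluster, ties by sequence
        return min(self.seq_counts, key=lambda s: (-self.seq_counts[s], s))


def cluster_isomirs(groups: Sequence[AnnotatedGroup]) -> list[AnnotatedGroup]:
    """Pick the representative start-position group of one feature.

    Largest combined two-library count wins; ties break toward the smaller
    |start_shift|, then the upstream (smaller) start. The annotated-start
    (zero-shift) group is additionally emitted whenever it exists and is
    not itself the representative.
    """
    if not groups:
        return []

    def key(g: AnnotatedGroup):
        shift = abs(g.start_shift) if g.start_shift is not None else 0
        return (-g.combined(), shift, g.group_start)

    ordered = sorted(groups, key=key)
    rep = ordered[0]
    rep.is_representative = True
    out = [rep]
    for g in groups:
        if g is not rep and g.start_shift == 0:
            out.append(g)
    return out


def normalize_counts(raw: float, total: float, norm_scale: float) -> float:
    """Counts per ``norm_scale`` (per-million by default) hairpin-mapped tags."""
    if total <= 0:
        raise ValueError("normalization total must be positive")
    return raw / total * norm_scale


@dataclass
class AnnotationResult:
    groups: list[AnnotatedGroup]
    table: ExpressionTable
    de_rows: list[dict]
    ambiguous_tags: int
    unaligned_tags: int


def annotate_tags(
    tags: Sequence[TagRecord],
    resolved: Mapping[str, tuple[HairpinAlignment | None, str]],
    reference: HairpinReference,
    config: PipelineConfig,
) -> AnnotationResult:
    """Classify and cluster all resolved tags; build the expression table.

    Library totals are the per-library sums over ALL tags with a resolved
    hairpin alignment (every category), so normalized values per library
    sum exactly to norm_scale.
    """
    libraries = config.libraries
    clusters: dict[tuple, AnnotatedGroup] = {}
    ambiguous = unaligned = 0

    for tag in tags:
        alignment, status = resolved[tag.sequence]
        if alignment is None:
            if status == "ambiguous":
                ambiguous += 1
            else:
                unaligned += 1
            continue
        cls = classify_alignment(alignment, reference, config.isomir_shift)
        key = (cls.feature, cls.category, alignment.hairpin_id, alignment.start)
        group = clusters.get(key)
        if group is None:
            group = clusters[key] = AnnotatedGroup(
                feature=cls.feature,
                category=cls.category,
                hairpin_id=alignment.hairpin_id,
                group_start=alignment.start,
                start_shift=cls.start_shift,
            )
        for lib in libraries:
            group.counts[lib] = group.counts.get(lib, 0) + tag.count(lib)
        group.seq_counts[tag.sequence] += sum(tag.count(lib) for lib in libraries)

    groups = sorted(
        clusters.values(), key=lambda g: (g.feature, g.category, g.hairpin_id, g.group_start)
    )

    totals = {
        lib: sum(g.counts.get(lib, 0) for g in groups) for lib in libraries
    }
    for lib, total in totals.items():
        if total <= 0:
            raise ValueError(f"library {lib!r}: no hairpin-mapped tags to normalize against")

    # representative selection per feature (known matures and putative stars)
    by_feature: dict[tuple[str, str], list[AnnotatedGroup]] = {}
    for g in groups:
        by_feature.setdefault((g.feature, g.category), []).append(g)

    de_groups: list[AnnotatedGroup] = []
    for (_feature, category), feat_groups in sorted(by_feature.items()):
        if category in DE_CATEGORIES:
            de_groups.extend(cluster_isomirs(feat_groups))

    def row_of(g: AnnotatedGroup) -> dict:
        row = {
            "feature": g.feature,
            "category": g.category,
            "hairpin_id": g.hairpin_id,
            "group_start": g.group_start,
            "start_shift": g.start_shift,
            "is_representative": g.is_representative,
            "sequence": g.top_sequence(),
        }
        for lib in libraries:
            raw = g.counts.get(lib, 0)
            row[f"raw_{lib}"] = raw
            row[f"norm_{lib}"] = normalize_counts(raw, totals[lib], config.norm_scale)
        return row

    rows = [row_of(g) for g in groups]
    de_rows = [row_of(g) for g in de_groups]
    table = ExpressionTable(rows=rows, library_totals=totals)
    logger.info(
        "annotate_tags: %d groups, totals %s, %d DE rows, %d ambiguous, %d unaligned",
        len(groups), totals, len(de_rows), ambiguous, unaligned,
    )
    return AnnotationResult(
        groups=groups,
        table=table,
        de_rows=de_rows,
        ambiguous_tags=ambiguous,
        unaligned_tags=unaligned,
    )


def star_ratio_report(
    result: AnnotationResult, reference: HairpinReference
) -> list[dict]:
    """Pair each miRNA with its opposite-arm counterpart per hairpin.

    Reports representative normalized values of both arms per library and
    flags hairpins whose dominant arm differs between the two libraries
    (arm-dominance switch); equal values are noted as ties, not switches.
    """
    rep = {
        (r["hairpin_id"], r["feature"]): r
        for r in result.de_rows
        if r["is_representative"]
    }
    out = []
    for hid in sorted(reference.records):
        matures = reference.matures_of(hid)
        if len(matures) != 2:
            continue
        m5, m3 = sorted(matures, key=lambda m: m.start)
        rows = [rep.get((hid, m.name)) for m in (m5, m3)]
        vals = {}
        for m, r in zip((m5, m3), rows):
            for lib in (METASTATIC, NON_METASTATIC):
                vals[(m.name, lib)] = r[f"norm_{lib}"] if r else 0.0
        entry = {"hairpin_id": hid, "arm_5p": m5.name, "arm_3p": m3.name}
        dominant = {}
        for lib in (METASTATIC, NON_METASTATIC):
            a, b = vals[(m5.name, lib)], vals[(m3.name, lib)]
            entry[f"{lib}_5p"] = a
            entry[f"{lib}_3p"] = b
            dominant[lib] = "tie" if a == b else ("5p" if a > b else "3p")
        entry["dominance_switch"] = (
            dominant[METASTATIC] != dominant[NON_METASTATIC]
            and "tie" not in dominant.values()
        )
        entry["note"] = "tie" if "tie" in dominant.values() else ""
        out.append(entry)
    return out


def putative_star_report(
    result: AnnotationResult, reference: HairpinReference
) -> list[dict]:
    """Putative-miRNA* rows pairing each star cluster with its mature."""
    rep_mature = {
        (r["hairpin_id"], r["category"] == KNOWN_MATURE and r["feature"]): r
        for r in result.de_rows
        if r["is_representative"]
    }
    out = []
    for r in result.de_rows:
        if r["category"] != PUTATIVE_STAR or not r["is_representative"]:
            continue
        mature_name = r["feature"][:-1]  # strip trailing '*'
        mate = rep_mature.get((r["hairpin_id"], mature_name))
        out.append(
            {
                "feature": r["feature"],
                "sequence": r["sequence"],
                "hairpin_id": r["hairpin_id"],
                "group_start": r["group_start"],
                "norm_metastatic": r[f"norm_{METASTATIC}"],
                "norm_non_metastatic": r[f"norm_{NON_METASTATIC}"],
                "mature_norm_metastatic": mate[f"norm_{METASTATIC}"] if mate else 0.0,
                "mature_norm_non_metastatic": mate[f"norm_{NON_METASTATIC}"] if mate else 0.0,
            }
        )
    return out
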