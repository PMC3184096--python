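"""Domain types and on-disk formats.

The pipeline's shared containers live here: mature-arm annotations on
stem-loop (hairpin) precursors, the hairpin reference itself, and the
normalized expression table. File handling covers FASTA/FASTQ reads, the
GFF3 mature-annotation file and the TSV result tables.

Internally all coordinates are 0-based half-open; GFF3 input/output uses
that format's native 1-based closed convention. RNA (U) and DNA (T)
alphabets are collapsed to DNA at load time so reads and reference always
compare in one alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

_RNA_TO_DNA = str.maketrans("Uu", "Tt")


def normalize_alphabet(seq: str) -> str:
    """Upper-case and map RNA U onto DNA T."""
    return seq.translate(_RNA_TO_DNA).upper()


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA (or miRNA*) annotated on a hairpin.

    ``start``/``end`` are 0-based half-open offsets on the hairpin; ``arm``
    says which side of the terminal loop the mature sits on.
    """

    name: str
    hairpin_id: str
    start: int
    end: int
    arm: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"mature {self.name!r} on {self.hairpin_id!r}: bad span "
                f"[{self.start}, {self.end})"
            )
        if self.arm not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"mature {self.name!r}: unknown arm {self.arm!r}")


@dataclass
class HairpinReference:
    """Stem-loop sequences plus their mature-arm annotations.

    Emulates a miRBase-style reference: each hairpin carries at most two
    annotated matures (the predominantly expressed miRNA and, when known,
    the opposite-arm miRNA*).
    """

    records: dict[str, str]
    matures: dict[str, list[MatureAnnotation]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = {hid: normalize_alphabet(s) for hid, s in self.records.items()}
        for hid in self.matures:
            if hid not in self.records:
                raise ValueError(f"mature annotations reference unknown hairpin {hid!r}")
        for hid, anns in self.matures.items():
            if len(anns) > 2:
                raise ValueError(
                    f"hairpin {hid!r} carries {len(anns)} mature annotations (max 2)"
                )
            hp_len = len(self.records[hid])
            for ann in anns:
                if ann.end > hp_len:
                    raise ValueError(
                        f"mature {ann.name!r} [{ann.start}, {ann.end}) lies outside "
                        f"hairpin {hid!r} of length {hp_len}"
                    )

    def matures_of(self, hairpin_id: str) -> list[MatureAnnotation]:
        return self.matures.get(hairpin_id, [])

    @property
    def min_hairpin_length(self) -> int:
        return min(len(s) for s in self.records.values())

    # -- serialization -----------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for hid, seq in self.records.items():
                fh.write(f">{hid}\n{seq}\n")

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for hid in self.records:
                for ann in self.matures_of(hid):
                    attrs = f"Name={ann.name};arm={ann.arm}"
                    fh.write(
                        f"{hid}\txenomir\tmiRNA\t{ann.start + 1}\t{ann.end}\t.\t+\t.\t{attrs}\n"
                    )


def load_hairpin_reference(fasta_path: str | Path, gff_path: str | Path) -> HairpinReference:
    """Load hairpin FASTA plus GFF3 mature annotations.

    GFF3 features of type ``miRNA`` with a ``Name`` attribute become
    :class:`MatureAnnotation`; 1-based closed coordinates are converted to
    0-based half-open. A mature outside its hairpin, a duplicate hairpin id
    or more than two matures on one hairpin is rejected.
    """
    import gffutils

    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate hairpin id {rec.id!r} in {fasta_path}")
        records[rec.id] = normalize_alphabet(str(rec.seq))

    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique")
    matures: dict[str, list[MatureAnnotation]] = {}
    for feat in db.features_of_type("miRNA"):
        names = feat.attributes.get("Name")
        if not names:
            raise ValueError(f"miRNA feature without Name attribute: {feat}")
        name = names[0]
        if feat.seqid not in records:
            raise ValueError(
                f"mature {name!r} references hairpin {feat.seqid!r} absent from FASTA"
            )
        start0, end0 = feat.start - 1, feat.end
        hp_len = len(records[feat.seqid])
        if not (0 <= start0 < end0 <= hp_len):
            raise ValueError(
                f"mature {name!r} [{feat.start}..{feat.end}] outside hairpin "
                f"{feat.seqid!r} (length {hp_len})"
            )
        arm = (feat.attributes.get("arm") or [None])[0]
        if arm not in (FIVE_PRIME, THREE_PRIME):
            midpoint = (start0 + end0) / 2
            arm = FIVE_PRIME if midpoint < hp_len / 2 else THREE_PRIME
        matures.setdefault(feat.seqid, []).append(
            MatureAnnotation(name=name, hairpin_id=feat.seqid,
                             start=start0, end=end0, arm=arm)
        )

    return HairpinReference(records=records, matures=matures)


# -- reads -----------------------------------------------------------------


def read_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream (read_id, sequence) from FASTQ or FASTA, autodetected.

    Sequences are upper-cased (U mapped to T); input order is preserved.
    A truncated FASTQ record raises with the approximate byte offset.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == "":
            logger.warning("read_reads: %s is empty", path)
            return
        if first == "@":
            fmt = "fastq"
        elif first == ">":
            fmt = "fasta"
        else:
            raise ValueError(f"{path}: cannot autodetect format from first character {first!r}")
        n = 0
        parser = SeqIO.parse(fh, fmt)
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                offset = fh.tell()
                raise ValueError(
                    f"{path}: truncated/malformed {fmt.upper()} record near byte {offset}: {exc}"
                ) from exc
            n += 1
            yield rec.id, normalize_alphabet(str(rec.seq))
        logger.info("read_reads: yielded %d reads from %s", n, path)


# -- result tables ---------------------------------------------------------

#: Column layouts of the TSV outputs, keyed by schema name.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "expression": [
        "feature", "category", "hairpin_id", "group_start", "start_shift",
        "raw_metastatic", "raw_non_metastatic",
        "norm_metastatic", "norm_non_metastatic",
    ],
    "de": [
        "feature", "norm_metastatic", "norm_non_metastatic", "fold",
        "p_raw", "p_adj", "direction", "significant",
    ],
    "putative_star": [
        "feature", "sequence", "hairpin_id", "group_start",
        "norm_metastatic", "norm_non_metastatic",
        "mature_norm_metastatic", "mature_norm_non_metastatic",
    ],
    "novel": [
        "feature", "sequence", "window_start", "window_end", "pair_count",
        "paired_fraction", "loop_count", "verdict", "reasons",
    ],
    "integration": [
        "feature", "direction", "z_ratio", "supporting_mirnas", "site_classes",
    ],
}

_TWO_DP = {
    "norm_metastatic", "norm_non_metastatic", "fold",
    "mature_norm_metastatic", "mature_norm_non_metastatic",
    "paired_fraction", "z_ratio",
}


def format_cell(column: str, value) -> str:
    if value is None:
        return "N/A"
    if column in _TWO_DP:
        return f"{float(value):.2f}"
    if column in ("p_raw", "p_adj"):
        return f"{float(value):.6g}"
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def _sort_key(row: Mapping[str, object]):
    start = row.get("group_start", row.get("window_start", 0))
    return (str(row.get("feature", "")), start if isinstance(start, int) else 0)


def write_table(rows: Iterable[Mapping[str, object]], path: str | Path, schema: str) -> None:
    """Write rows as a TSV under a named schema.

    Output is deterministic: rows are stably sorted by (feature, start),
    normalized counts and fold changes print with 2 decimals and an
    undefined fold change prints as ``N/A``.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}; known: {sorted(TABLE_SCHEMAS)}")
    columns = TABLE_SCHEMAS[schema]
    ordered = sorted(rows, key=_sort_key)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in ordered:
            fh.write("\t".join(format_cell(c, row.get(c)) for c in columns) + "\n")


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read back a TSV written by :func:`write_table` (cells as strings)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:]]


@dataclass
class ExpressionTable:
    """Per-feature raw and normalized counts for the two libraries.

    ``library_totals`` holds the per-library total of hairpin-mapped tag
    counts used as the normalization denominator; every normalized cell
    equals raw / total * norm_scale.
    """

    rows: list[dict]
    library_totals: dict[str, int]

    def __post_init__(self) -> None:
        for lib, total in self.library_totals.items():
            if total <= 0:
                raise ValueError(f"library {lib!r} has non-positive total {total}")

    def rows_of_category(self, *categories: str) -> list[dict]:
        return [r for r in self.rows if r["category"] in categories]
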