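"""Pipeline configuration.

Every analysis constant used across the pipeline lives in
:class:`PipelineConfig`: index tags of the two sequencing libraries, the
3' adapter, tag length/abundance filters, the alignment mismatch budget,
the isomiR positional tolerance, the per-million normalization scale and
the significance thresholds for the Fisher and z-ratio calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

# Library labels used throughout: the metastatic (LTL-313H-like) library is
# tagged ACATCGA, the non-metastatic (LTL-313B-like) library CGTGATA.
METASTATIC = "metastatic"
NON_METASTATIC = "non_metastatic"

DEFAULT_INDEX_MAP = {METASTATIC: "ACATCGA", NON_METASTATIC: "CGTGATA"}

#: Classic Illumina small-RNA 3' adapter; overridable in config.
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"


@dataclass
class PipelineConfig:
    """All tunable constants of the profiling pipeline.

    Defaults follow small-RNA practice for a two-library comparison:
    16-27 nt tags, count >= 2 in at least one library, up to 3 mismatches
    against the stem-loop reference, +/-2 nt isomiR shift tolerance,
    counts-per-million normalization, Bonferroni-corrected Fisher p < 0.001
    with a 2-fold change requirement, and +/-1.96 z-ratio calls on the
    matching two-array expression data.
    """

    index_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_INDEX_MAP))
    adapter3: str = DEFAULT_ADAPTER3
    min_tag_len: int = 16
    max_tag_len: int = 27
    min_tag_count: int = 2
    max_mismatches: int = 3
    isomir_shift: int = 2
    norm_scale: float = 1_000_000.0
    p_threshold: float = 0.001
    fold_threshold: float = 2.0
    z_threshold: float = 1.96
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.index_map:
            raise ValueError("index_map must name at least one library")
        lengths = {len(s) for s in self.index_map.values()}
        if len(lengths) != 1:
            raise ValueError("index sequences must all have equal length")
        seqs = list(self.index_map.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("index sequences must be pairwise distinct")
        for name, s in self.index_map.items():
            if set(s.upper()) - set("ACGT"):
                raise ValueError(f"index for {name!r} is not a DNA string: {s!r}")
        if len(self.adapter3) < 7:
            raise ValueError("adapter3 must be at least 7 nt (trimming seed length)")
        if self.min_tag_len <= 0 or self.max_tag_len <= 0:
            raise ValueError("tag length bounds must be strictly positive")
        if self.min_tag_len > self.max_tag_len:
            raise ValueError(
                f"min_tag_len ({self.min_tag_len}) > max_tag_len ({self.max_tag_len})"
            )
        if self.min_tag_count < 1:
            raise ValueError("min_tag_count must be >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.isomir_shift < 0:
            raise ValueError("isomir_shift must be >= 0")
        for attr in ("norm_scale", "p_threshold", "fold_threshold", "z_threshold"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be strictly positive")

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416 - field names
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def libraries(self) -> list[str]:
        return list(self.index_map)
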