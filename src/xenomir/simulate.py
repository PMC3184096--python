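"""Synthetic study generator.

Produces every input the pipeline consumes, with recorded ground truth:
a hairpin reference with mature-arm annotations embedded in a decoy
genome, two multiplexed small-RNA libraries with isomiR start/end
scatter, opposite-arm (star) and loop reads, planted per-miRNA fold
changes and sequencing error, a known-transcript set absorbing
degradation reads, per-gene 3'UTRs with planted seed sites, and a
matching two-array expression table with planted z-ratio-detectable
genes.

Every generator is a pure function of its arguments including the seed;
the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import infer_loop_interval
from .config import PipelineConfig, METASTATIC, NON_METASTATIC
from .io import FIVE_PRIME, THREE_PRIME, HairpinReference, MatureAnnotation

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


#: isomiR start-offset law; end offsets follow the same law independently.
ISOMIR_OFFSET_LAW: dict[int, float] = {-2: 0.05, -1: 0.15, 0: 0.6, 1: 0.15, 2: 0.05}


# ---------------------------------------------------------------------------
# hairpin reference + genome


@dataclass
class HairpinSim:
    reference: HairpinReference
    genome: dict[str, str]
    hairpin_offsets: dict[str, int]
    novel: dict[str, dict]            # novel_id -> {offset, sequence, arm5}


def _contains_near_match(seq: str, motif: str, max_mismatches: int = 1) -> bool:
    k = len(motif)
    for i in range(len(seq) - k + 1):
        mm = sum(a != b for a, b in zip(seq[i:i + k], motif))
        if mm <= max_mismatches:
            return True
    return False


def _trimmable_motifs(seed: str, budget: int = 1) -> list[tuple[str, int]]:
    """Motifs whose occurrence makes an insert vulnerable to mistrimming.

    A read is insert + adapter, so the trimming seed can match spanning
    the boundary: k insert bases matching seed[:k] followed by the
    adapter's own first 7-k bases standing in for seed[k:]. The adapter
    contributes hamming(seed[:7-k], seed[k:]) mismatches on its own;
    whatever budget remains constrains the insert suffix. Returns
    (motif, allowed_mismatches) pairs including the full seed itself.
    """
    out = [(seed, budget)]
    for k in range(1, len(seed)):
        self_mm = sum(a != b for a, b in zip(seed[: len(seed) - k], seed[k:]))
        if self_mm <= budget:
            out.append((seed[:k], budget - self_mm))
    return out


def _trimmable(seq: str, seed: str) -> bool:
    return any(_contains_near_match(seq, motif, mm)
               for motif, mm in _trimmable_motifs(seed))


def _make_hairpin(rng: np.random.Generator, arm_len: int, loop_len: int,
                  mutation_rate: float, forbidden_motif: str | None = None) -> str:
    """One stem-loop; redrawn until free of ``forbidden_motif`` look-alikes.

    Terminal loops use a two-letter non-self-pairing alphabet (no A-T,
    G-C or G-T pair possible within the loop), mimicking the unstructured
    loop of real pre-miRNAs: the max-pairing structure of a clean hairpin
    then keeps exactly one terminal loop by construction. The forbidden
    motif is the 3'-adapter seed — a read whose insert resembles it is
    destroyed by adapter trimming under any protocol using that adapter,
    so such hairpins are never emitted.
    """
    for _ in range(200):
        arm5 = _random_seq(rng, arm_len)
        loop = "".join("AC"[i] for i in rng.integers(0, 2, size=loop_len))
        arm3 = list(revcomp(arm5))
        for i in range(len(arm3)):
            if rng.random() < mutation_rate:
                arm3[i] = BASES[rng.integers(0, 4)]
        hairpin = arm5 + loop + "".join(arm3)
        if forbidden_motif is None or not _trimmable(hairpin, forbidden_motif):
            return hairpin
    raise RuntimeError("could not sample a hairpin free of the adapter seed")


def generate_hairpin_reference(
    n_hairpins: int,
    arm_len: int = 22,
    loop_len: int = 18,
    frac_single_mature: float = 0.3,
    seed: int = 0,
    mutation_rate: float = 0.05,
    n_novel: int = 0,
    novel_arm_len: int = 24,
    genome_gap: int = 60,
    adapter3: str = None,
) -> HairpinSim:
    """Hairpins = 5' arm + loop + (mutated) reverse-complement arm.

    Each hairpin carries two mature annotations (both arms) or, with
    probability frac_single_mature, only one — the driver of putative-star
    discovery downstream. All hairpins, plus n_novel perfect-stem hairpins
    deliberately left out of the reference, are embedded at recorded
    offsets in a random decoy genome.
    """
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    from .config import DEFAULT_ADAPTER3
    seed_motif = (adapter3 or DEFAULT_ADAPTER3)[:7]
    rng = np.random.default_rng(seed)
    records: dict[str, str] = {}
    matures: dict[str, list[MatureAnnotation]] = {}
    for i in range(n_hairpins):
        hid = f"sim-mir-{i:03d}"
        seq = _make_hairpin(rng, arm_len, loop_len, mutation_rate, seed_motif)
        records[hid] = seq
        total = len(seq)
        base = f"sim-miR-{i:03d}"
        m5 = MatureAnnotation(base, hid, 0, arm_len, FIVE_PRIME)
        m3 = MatureAnnotation(f"{base}*", hid, total - arm_len, total, THREE_PRIME)
        single = rng.random() < frac_single_mature
        if single:
            # annotate one arm only; name it as the mature
            if rng.random() < 0.5:
                matures[hid] = [m5]
            else:
                matures[hid] = [MatureAnnotation(base, hid, total - arm_len, total, THREE_PRIME)]
        else:
            matures[hid] = [m5, m3]
    reference = HairpinReference(records=records, matures=matures)

    novel: dict[str, dict] = {}
    novel_seqs: dict[str, str] = {}
    for i in range(n_novel):
        nid = f"sim-novel-{i:03d}"
        seq = _make_hairpin(rng, novel_arm_len, loop_len, 0.0, seed_motif)
        novel_seqs[nid] = seq
        novel[nid] = {"sequence": seq, "arm5": seq[:novel_arm_len]}

    genome_parts: list[str] = []
    offsets: dict[str, int] = {}
    pos = 0
    for hid, seq in list(records.items()) + list(novel_seqs.items()):
        gap = _random_seq(rng, genome_gap)
        genome_parts.append(gap)
        pos += genome_gap
        genome_parts.append(seq)
        offsets[hid] = pos
        pos += len(seq)
    genome_parts.append(_random_seq(rng, genome_gap))
    genome = {"chr_sim": "".join(genome_parts)}
    for nid in novel:
        novel[nid]["offset"] = offsets[nid]
    hairpin_offsets = {hid: offsets[hid] for hid in records}
    return HairpinSim(reference=reference, genome=genome,
                      hairpin_offsets=hairpin_offsets, novel=novel)


# ---------------------------------------------------------------------------
# ground truth and read simulation


@dataclass
class EmissionUnit:
    """One source of reads: a span of a hairpin, genome or transcript."""

    name: str
    kind: str                 # mature | star | loop | novel | degradation
    source_seq: str
    start: int
    end: int
    isomir_scatter: bool


@dataclass
class SimTruth:
    """Ground truth sufficient to score every downstream stage."""

    abundance: dict[str, float]
    fold_changes: dict[str, float]
    star_fractions: dict[str, float]
    loop_fraction: float
    degradation_fraction: float
    novel_ids: list[str]
    de_genes: dict[str, str] = field(default_factory=dict)
    rng_seed: int = 0
    units: dict[str, EmissionUnit] = field(default_factory=dict)

    def planted_up(self) -> set[str]:
        return {f for f, x in self.fold_changes.items() if x > 1}

    def planted_down(self) -> set[str]:
        return {f for f, x in self.fold_changes.items() if x < 1}


def _seed_patterns(mirna_seq: str) -> set[str]:
    return {revcomp(mirna_seq[1:8]), revcomp(mirna_seq[1:7]) + "A"}


def _seeds_conflict(seq_a: str, seq_b: str) -> bool:
    """True when one miRNA's 8mer site necessarily contains a
    7mer-or-better site of the other (no exclusive planting possible)."""
    site_a = revcomp(seq_a[1:8]) + "A"
    site_b = revcomp(seq_b[1:8]) + "A"
    return any(p in site_a for p in _seed_patterns(seq_b)) or any(
        p in site_b for p in _seed_patterns(seq_a)
    )


def build_sim_truth(
    sim: HairpinSim,
    seed: int = 0,
    abundance_sigma: float = 1.5,
    star_fraction: float = 0.05,
    loop_fraction: float = 0.01,
    degradation_fraction: float = 0.02,
    novel_fraction: float = 0.01,
    n_fold_up: int = 5,
    n_fold_down: int = 5,
    planted_fold: float = 10.0,
    min_planted_abundance: float = 1e-3,
    max_planted_abundance: float = 1e-2,
    transcripts: Mapping[str, str] | None = None,
) -> SimTruth:
    """Baseline abundances (log-normal across mature features), planted
    fold changes (``planted_fold`` up, ``1/planted_fold`` down), and
    star/loop/novel/degradation mass. Abundances over all emission units
    sum to 1.

    Folds are planted inside a moderate-abundance band: high enough that
    the feature is well measured at typical depth, low enough that the
    compositional renormalization of the folded library leaves every null
    feature's proportion shift far below the 2-fold call line (counts are
    proportions of a fixed per-library depth, so a planted increase
    necessarily deflates everything else a little).
    """
    rng = np.random.default_rng(seed)
    reference = sim.reference
    units: dict[str, EmissionUnit] = {}
    mature_names: list[str] = []
    star_fractions: dict[str, float] = {}

    for hid in sorted(reference.records):
        seq = reference.records[hid]
        anns = reference.matures_of(hid)
        for ann in anns:
            units[ann.name] = EmissionUnit(
                ann.name, "mature", seq, ann.start, ann.end, True
            )
            mature_names.append(ann.name)
        if len(anns) == 1:
            # unannotated opposite arm feeds putative-star discovery
            m = anns[0]
            L = len(seq)
            star_span = (L - m.end, L - m.start)
            name = f"{m.name}*"
            units[name] = EmissionUnit(
                name, "star", seq, star_span[0], star_span[1], False
            )
            star_fractions[hid] = star_fraction
        loop_lo, loop_hi = infer_loop_interval(len(seq), anns)
        if loop_hi - loop_lo >= 16:
            units[f"{hid}:loop"] = EmissionUnit(
                f"{hid}:loop", "loop", seq, loop_lo, loop_hi, False
            )

    weights = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=len(mature_names))
    weights /= weights.sum()
    mature_abundance = dict(zip(mature_names, weights))

    # reserve mass fractions for the side channels
    side = {}
    for hid, frac in star_fractions.items():
        m = reference.matures_of(hid)[0]
        side[f"{m.name}*"] = mature_abundance.get(m.name, 0.0) * frac
    loop_units = [n for n in units if units[n].kind == "loop"]
    for name in loop_units:
        side[name] = loop_fraction / max(len(loop_units), 1)

    for nid, info in sim.novel.items():
        name = f"novel:{nid}"
        units[name] = EmissionUnit(name, "novel", info["sequence"], 0,
                                   len(info["arm5"]), False)
        side[name] = novel_fraction / max(len(sim.novel), 1)

    if transcripts:
        for tid in sorted(transcripts):
            name = f"deg:{tid}"
            seq = transcripts[tid]
            units[name] = EmissionUnit(name, "degradation", seq, 0, len(seq), False)
            side[name] = degradation_fraction / len(transcripts)

    side_mass = sum(side.values())
    abundance = {n: w * (1.0 - side_mass) for n, w in mature_abundance.items()}
    abundance.update(side)

    # eligibility is judged on the unscaled mature simplex so the planted
    # set does not depend on how much side-channel (star/loop/novel/
    # degradation) mass this particular study reserves
    # least-abundant eligible features first: planting near the bottom of
    # the band keeps the total mass perturbation (hence the compositional
    # shift of every null feature) to a few percent
    eligible = sorted(
        (n for n in mature_names
         if min_planted_abundance <= mature_abundance[n] <= max_planted_abundance),
        key=lambda n: mature_abundance[n],
    )
    # planted features must have mutually non-overlapping seed patterns,
    # or no UTR could carry a site for one without a site for the other
    seqs = _mature_sequences(reference)
    picked: list[str] = []
    for name in eligible:
        if len(picked) == n_fold_up + n_fold_down:
            break
        if all(not _seeds_conflict(seqs[name], seqs[p]) for p in picked):
            picked.append(name)
    rng.shuffle(picked)
    fold_changes = {}
    for name in picked[:n_fold_up]:
        fold_changes[name] = planted_fold
    for name in picked[n_fold_up:n_fold_up + n_fold_down]:
        fold_changes[name] = 1.0 / planted_fold

    return SimTruth(
        abundance=abundance,
        fold_changes=fold_changes,
        star_fractions=star_fractions,
        loop_fraction=loop_fraction,
        degradation_fraction=degradation_fraction,
        novel_ids=sorted(sim.novel),
        rng_seed=seed,
        units=units,
    )


def _draw_offset(rng: np.random.Generator, law: Mapping[int, float]) -> int:
    keys = sorted(law)
    probs = np.array([law[k] for k in keys])
    return int(rng.choice(keys, p=probs / probs.sum()))


def simulate_libraries(
    reference: HairpinReference,
    truth: SimTruth,
    depth_per_library: int,
    error_rate: float,
    seed: int,
    config: PipelineConfig | None = None,
    offset_law: Mapping[int, float] | None = None,
) -> list[tuple[str, str]]:
    """Two multiplexed libraries as (read_id, sequence) pairs.

    Per library, feature counts are one multinomial draw of size
    ``depth_per_library`` over the truth abundances (metastatic weights
    multiplied by the planted fold changes and renormalized); each read is
    index + isomiR-scattered insert + 3' adapter, with independent
    per-base substitution errors. Reads from both libraries are
    interleaved by a seeded shuffle; the total read count equals
    2 * depth_per_library exactly.
    """
    config = config or PipelineConfig()
    law = dict(offset_law or ISOMIR_OFFSET_LAW)
    rng = np.random.default_rng(seed)
    names = sorted(truth.abundance)
    base_w = np.array([truth.abundance[n] for n in names], dtype=float)
    if not np.isfinite(base_w).all() or base_w.sum() <= 0 or (base_w < 0).any():
        raise ValueError("abundances are not normalizable")
    base_w = base_w / base_w.sum()

    reads: list[tuple[str, str]] = []
    for lib in (METASTATIC, NON_METASTATIC):
        w = base_w.copy()
        if lib == METASTATIC:
            for i, n in enumerate(names):
                w[i] *= truth.fold_changes.get(n, 1.0)
        w = w / w.sum()
        counts = rng.multinomial(depth_per_library, w)
        index = config.index_map[lib]
        serial = 0
        for name, count in zip(names, counts):
            unit = truth.units[name]
            src, lo, hi = unit.source_seq, unit.start, unit.end
            for _ in range(int(count)):
                if unit.kind == "degradation":
                    # random fragment of the transcript
                    frag_len = int(rng.integers(config.min_tag_len, config.max_tag_len + 1))
                    start = int(rng.integers(0, max(1, len(src) - frag_len + 1)))
                    insert = src[start:start + frag_len]
                elif unit.isomir_scatter:
                    so = _draw_offset(rng, law)
                    eo = _draw_offset(rng, law)
                    start = min(max(0, lo + so), len(src) - 1)
                    end = max(start + 1, min(len(src), hi + eo))
                    insert = src[start:end]
                else:
                    insert = src[lo:hi]
                if error_rate > 0:
                    chars = list(insert)
                    hits = np.flatnonzero(rng.random(len(chars)) < error_rate)
                    for pos in hits:
                        chars[pos] = BASES[(BASES.index(chars[pos]) +
                                            int(rng.integers(1, 4))) % 4]
                    insert = "".join(chars)
                reads.append((f"sim:{lib}:{name}:{serial}", index + insert + config.adapter3))
                serial += 1
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    logger.info("simulate_libraries: %d reads (%d per library)", len(reads), depth_per_library)
    return reads


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# microarray


def simulate_microarray(
    n_genes: int,
    n_de: int,
    effect_sd_units: float = 6.0,
    seed: int = 0,
    flag_fraction: float = 0.05,
    gene_sd: float = 1.0,
    noise_sd: float = 0.2,
    frac_up: float = 0.5,
    de_genes: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Two log-scale arrays with planted differential genes.

    Gene baselines spread with sd ``gene_sd``; each array adds independent
    noise of sd ``noise_sd``. Planted genes shift array 1 (metastatic) by
    effect_sd_units times the null sd of the array-1 minus array-2
    difference (sqrt(2) * noise_sd), so an effect of 3 units lands well
    past the 1.96 z-ratio call line. A flag column marks a random probe
    fraction absent per array.
    """
    if de_genes is None and n_de >= n_genes:
        raise ValueError("n_de must be smaller than n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"gene-{i:04d}" for i in range(n_genes)]
    mu = rng.normal(3.0, gene_sd, size=n_genes)
    x1 = mu + rng.normal(0.0, noise_sd, size=n_genes)
    x2 = mu + rng.normal(0.0, noise_sd, size=n_genes)
    if de_genes is None:
        chosen = rng.choice(n_genes, size=n_de, replace=False)
        n_up = int(round(len(chosen) * frac_up))
        de_genes = {}
        for j, gi in enumerate(sorted(chosen)):
            de_genes[genes[gi]] = "up" if j < n_up else "down"
    effect = effect_sd_units * np.sqrt(2.0) * noise_sd
    index = {g: i for i, g in enumerate(genes)}
    for gene, direction in de_genes.items():
        x1[index[gene]] += effect if direction == "up" else -effect
    flag1 = rng.random(n_genes) < flag_fraction
    flag2 = rng.random(n_genes) < flag_fraction
    df = pd.DataFrame(
        {
            "gene": genes,
            "array_metastatic": np.round(x1, 6),
            "array_non_metastatic": np.round(x2, 6),
            "flag_metastatic": flag1.astype(int),
            "flag_non_metastatic": flag2.astype(int),
        }
    )
    truth = {g: d for g, d in de_genes.items()
             if not flag1[index[g]] and not flag2[index[g]]}
    return df, truth


# ---------------------------------------------------------------------------
# transcripts and UTRs


def _mature_sequences(reference: HairpinReference) -> dict[str, str]:
    out = {}
    for hid, anns in reference.matures.items():
        seq = reference.records[hid]
        for ann in anns:
            out[ann.name] = seq[ann.start:ann.end]
    return out


def _site_for_class(mirna_seq: str, site_class: str) -> str:
    core7 = revcomp(mirna_seq[1:8])
    core6 = revcomp(mirna_seq[1:7])
    if site_class == "8mer":
        return core7 + "A"
    if site_class == "7mer-m8":
        return core7
    if site_class == "7mer-A1":
        return core6 + "A"
    if site_class == "6mer":
        return core6
    raise ValueError(f"unknown site class {site_class!r}")


def _has_7mer_or_better(utr: str, mirna_seq: str) -> bool:
    return (revcomp(mirna_seq[1:8]) in utr) or (revcomp(mirna_seq[1:7]) + "A") in utr


def generate_transcript_and_utr_sets(
    reference: HairpinReference,
    n_known_transcripts: int,
    n_genes: int,
    planted_sites: Mapping[tuple[str, str], str],
    seed: int = 0,
    transcript_len: int = 300,
    utr_len: int = 400,
    max_rejections: int = 200,
    mirna_names: Sequence[str] | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Known-transcript decoys and per-gene 3'UTRs with planted seed sites.

    Planted (miRNA, gene) pairs receive an exact site of the requested
    class; every unplanted pair is rejection-sampled to carry no
    7mer-or-better site. Returns (transcripts, utrs) as id -> sequence.
    """
    rng = np.random.default_rng(seed)
    mirnas = _mature_sequences(reference)
    if mirna_names is not None:
        mirnas = {n: mirnas[n] for n in mirna_names}
    transcripts = {f"tx-{i:03d}": _random_seq(rng, transcript_len)
                   for i in range(n_known_transcripts)}

    by_gene: dict[str, list[tuple[str, str]]] = {}
    for (mir, gene), cls in planted_sites.items():
        if mir not in mirnas:
            raise ValueError(f"planted site references unknown miRNA {mir!r}")
        by_gene.setdefault(gene, []).append((mir, cls))

    utrs: dict[str, str] = {}
    for i in range(n_genes):
        gene = f"gene-{i:04d}"
        planted = by_gene.get(gene, [])
        # a planted 6mer is deliberately below the prediction threshold, so
        # only stronger classes must register as 7mer-or-better sites
        strong_mirs = {m for m, cls in planted if cls != "6mer"}
        for attempt in range(max_rejections):
            utr = _random_seq(rng, utr_len)
            for mir, cls in planted:
                site = _site_for_class(mirnas[mir], cls)
                pos = int(rng.integers(1, utr_len - len(site) - 1))
                utr = utr[:pos] + site + utr[pos + len(site):]
            clean = all(
                _has_7mer_or_better(utr, seq) == (name in strong_mirs)
                for name, seq in mirnas.items()
            )
            if clean:
                utrs[gene] = utr
                break
        else:
            raise RuntimeError(
                f"could not sample a clean UTR for {gene} after {max_rejections} "
                "attempts; consider longer UTRs"
            )
    return transcripts, utrs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in seqs:
            fh.write(f">{sid}\n{seqs[sid]}\n")
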