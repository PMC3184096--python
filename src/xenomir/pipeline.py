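"""End-to-end orchestration with per-stage conservation reporting.

``run_pipeline`` chains simulation (optional) -> preprocessing ->
hairpin alignment -> annotation/quantification -> differential
expression -> novel-hairpin screening -> miRNA-mRNA integration, writes
every result TSV plus a machine-readable summary, and checks read/tag
conservation at each stage. On simulated input the summary also scores
every stage against the generator's ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import annotate, diffexp, integration, novel, preprocess, simulate
from .align import align_and_resolve
from .config import PipelineConfig, METASTATIC, NON_METASTATIC
from .io import HairpinReference, read_reads, write_table
from .reference_tables import recompute_fold_changes, count_strong_upregulated

logger = logging.getLogger(__name__)


@dataclass
class StageReport:
    stage: str
    n_in: int
    n_out: int
    dropped: dict[str, int] = field(default_factory=dict)

    def conserved(self) -> bool:
        return self.n_in == self.n_out + sum(self.dropped.values())


@dataclass
class SimulationOptions:
    """Study conditions of the default simulated experiment."""

    n_hairpins: int = 60
    n_novel: int = 6
    depth_per_library: int = 100_000
    error_rate: float = 0.001
    n_genes: int = 1000
    n_transcripts: int = 8
    genes_per_mirna: int = 2
    effect_sd_units: float = 6.0
    frac_single_mature: float = 0.3


def _build_simulation(config: PipelineConfig, opts: SimulationOptions, outdir: Path):
    """Generate reference, truth, reads, transcripts, UTRs and microarray."""
    seed = config.rng_seed
    sim = simulate.generate_hairpin_reference(
        n_hairpins=opts.n_hairpins,
        frac_single_mature=opts.frac_single_mature,
        seed=seed,
        n_novel=opts.n_novel,
    )
    truth = simulate.build_sim_truth(sim, seed=seed + 1)

    # integration truth: each planted DE miRNA regulates a few exclusive
    # genes whose mRNA moves opposite to the miRNA
    mature_names = sorted(truth.planted_up() | truth.planted_down())
    planted_sites: dict[tuple[str, str], str] = {}
    de_genes: dict[str, str] = {}
    gene_idx = 0
    for name in mature_names:
        mrna_dir = "up" if name in truth.planted_down() else "down"
        for _ in range(opts.genes_per_mirna):
            gene = f"gene-{gene_idx:04d}"
            planted_sites[(name, gene)] = "8mer"
            de_genes[gene] = mrna_dir
            gene_idx += 1
    transcripts, utrs = simulate.generate_transcript_and_utr_sets(
        sim.reference,
        n_known_transcripts=opts.n_transcripts,
        n_genes=opts.n_genes,
        planted_sites=planted_sites,
        seed=seed + 2,
        mirna_names=mature_names,
    )
    truth = simulate.build_sim_truth(sim, seed=seed + 1, transcripts=transcripts)
    array_df, array_truth = simulate.simulate_microarray(
        n_genes=opts.n_genes,
        n_de=0,
        effect_sd_units=opts.effect_sd_units,
        seed=seed + 3,
        de_genes=de_genes,
    )
    truth.de_genes = array_truth
    reads = simulate.simulate_libraries(
        sim.reference, truth, opts.depth_per_library, opts.error_rate,
        seed=seed + 4, config=config,
    )

    simulate.write_fastq(reads, outdir / "reads.fastq")
    sim.reference.to_fasta(outdir / "hairpins.fasta")
    sim.reference.to_gff3(outdir / "matures.gff3")
    simulate.write_fasta(sim.genome, outdir / "genome.fasta")
    simulate.write_fasta(transcripts, outdir / "transcripts.fasta")
    simulate.write_fasta(utrs, outdir / "utrs.fasta")
    array_df.to_csv(outdir / "microarray.tsv", sep="\t", index=False)
    truth_payload = {
        "fold_changes": truth.fold_changes,
        "novel_ids": truth.novel_ids,
        "de_genes": truth.de_genes,
        "planted_sites": {f"{m}|{g}": c for (m, g), c in sorted(planted_sites.items())},
        "rng_seed": seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth_payload, indent=1, sort_keys=True))
    return sim, truth, transcripts, utrs, array_df, reads


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    simulate_inputs: bool = True,
    sim_options: SimulationOptions | None = None,
    reads_path: str | Path | None = None,
    hairpin_fasta: str | Path | None = None,
    mature_gff: str | Path | None = None,
    genome_fasta: str | Path | None = None,
    transcripts_fasta: str | Path | None = None,
    utr_fasta: str | Path | None = None,
    microarray_tsv: str | Path | None = None,
) -> dict:
    """Run every stage; returns the summary dict (also written to disk).

    With ``simulate_inputs`` all inputs are generated under ``outdir``
    first; otherwise the given file paths are used. Raises on any stage
    conservation violation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports: list[StageReport] = []

    if simulate_inputs:
        opts = sim_options or SimulationOptions()
        sim, truth, transcripts, utrs, array_df, reads = _build_simulation(
            config, opts, outdir)
        reference = sim.reference
        genome = sim.genome
    else:
        truth = None
        from Bio import SeqIO

        from .io import load_hairpin_reference, normalize_alphabet

        reference = load_hairpin_reference(hairpin_fasta, mature_gff)
        reads = list(read_reads(reads_path))

        def _fasta_dict(path):
            return {r.id: normalize_alphabet(str(r.seq))
                    for r in SeqIO.parse(str(path), "fasta")}

        genome = _fasta_dict(genome_fasta) if genome_fasta else {}
        transcripts = _fasta_dict(transcripts_fasta) if transcripts_fasta else {}
        utrs = _fasta_dict(utr_fasta) if utr_fasta else {}
        array_df = (pd.read_csv(microarray_tsv, sep="\t")
                    if microarray_tsv else None)

    # preprocess ----------------------------------------------------------
    n_reads = len(reads)
    demux = preprocess.demultiplex(reads, config.index_map)
    reports.append(StageReport(
        "demultiplex", n_reads, demux.assigned,
        {"unassigned": demux.unassigned, "contains_N": demux.dropped_n},
    ))
    trimmed, trim_stats = preprocess.trim_libraries(demux.by_library, config.adapter3)
    reports.append(StageReport(
        "trim_adapter", demux.assigned, sum(trim_stats.kept.values()),
        {"no_adapter": sum(trim_stats.no_adapter.values())},
    ))
    tags = preprocess.collapse_and_filter(trimmed, config)
    surviving = preprocess.length_filtered_totals(trimmed, config)
    n_trimmed = sum(trim_stats.kept.values())
    n_len_ok = sum(surviving.values())
    reports.append(StageReport(
        "length_filter", n_trimmed, n_len_ok, {"bad_length": n_trimmed - n_len_ok}))
    write_table(
        [
            {
                "feature": t.sequence,
                "category": "tag",
                "group_start": 0,
                "raw_metastatic": t.count(METASTATIC),
                "raw_non_metastatic": t.count(NON_METASTATIC),
            }
            for t in tags
        ],
        outdir / "tags.tsv",
        "expression",
    )

    # align + annotate ----------------------------------------------------
    resolved = align_and_resolve(
        [t.sequence for t in tags], reference, config.max_mismatches)
    result = annotate.annotate_tags(tags, resolved, reference, config)
    n_aligned_tags = len(tags) - result.ambiguous_tags - result.unaligned_tags
    reports.append(StageReport(
        "align_resolve", len(tags), n_aligned_tags,
        {"ambiguous": result.ambiguous_tags, "unaligned": result.unaligned_tags},
    ))

    def expr_row(r: dict) -> dict:
        return {
            "feature": r["feature"],
            "category": r["category"],
            "hairpin_id": r["hairpin_id"],
            "group_start": r["group_start"],
            "start_shift": r["start_shift"],
            "raw_metastatic": r[f"raw_{METASTATIC}"],
            "raw_non_metastatic": r[f"raw_{NON_METASTATIC}"],
            "norm_metastatic": r[f"norm_{METASTATIC}"],
            "norm_non_metastatic": r[f"norm_{NON_METASTATIC}"],
        }

    write_table([expr_row(r) for r in result.table.rows],
                outdir / "expression.tsv", "expression")
    write_table(annotate.putative_star_report(result, reference),
                outdir / "putative_star.tsv", "putative_star")

    # differential expression --------------------------------------------
    de_results = diffexp.call_differential(
        result.de_rows, result.table.library_totals, config)
    write_table([r.as_row() for r in de_results], outdir / "diffexp.tsv", "de")
    significant = [r for r in de_results if r.significant]

    # novel candidates ----------------------------------------------------
    unaligned_tags = [
        t.sequence for t in tags if resolved[t.sequence][0] is None
        and resolved[t.sequence][1] == "unaligned"
    ]
    candidates = novel.screen_novel_tags(unaligned_tags, transcripts, genome)
    write_table(
        [
            {
                "feature": f"novel-{i:03d}",
                "sequence": c.tag,
                "window_start": c.window_offset,
                "window_end": c.window_offset + len(c.window_sequence),
                "pair_count": c.pair_count,
                "paired_fraction": c.paired_fraction_of_tag,
                "loop_count": c.loop_count,
                "verdict": c.verdict,
                "reasons": ";".join(c.reasons),
            }
            for i, c in enumerate(candidates)
        ],
        outdir / "novel_candidates.tsv",
        "novel",
    )

    # integration ---------------------------------------------------------
    list_a: list[dict] = []
    list_b: list[dict] = []
    if array_df is not None and utrs:
        seq_of = {r["feature"]: r["sequence"] for r in result.de_rows
                  if r["is_representative"]}
        up_targets = {}
        down_targets = {}
        for r in significant:
            seq = seq_of.get(r.feature)
            if seq is None or len(seq) < 8:
                continue
            preds = integration.predict_targets_seed({r.feature: seq}, utrs)
            genes = integration.predicted_target_genes(preds).get(r.feature, set())
            (up_targets if r.direction == diffexp.UP else down_targets)[r.feature] = genes
        z_records = integration.z_ratio(array_df, z_threshold=config.z_threshold)
        list_a, list_b = integration.integrate(up_targets, down_targets, z_records)
        write_table(list_a + list_b, outdir / "integration.tsv", "integration")

    # summary -------------------------------------------------------------
    summary: dict = {
        "config": {k: v for k, v in asdict(config).items()},
        "stages": [asdict(r) for r in reports],
        "n_tags": len(tags),
        "library_totals": result.table.library_totals,
        "n_de_rows": len(result.de_rows),
        "n_significant": len(significant),
        "n_novel_pass": sum(c.verdict == "pass" for c in candidates),
        "conservation_ok": all(r.conserved() for r in reports),
    }
    if truth is not None:
        summary["recovery"] = score_against_truth(
            truth, de_results, candidates, list_a, list_b)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    bad = [r.stage for r in reports if not r.conserved()]
    if bad:
        raise RuntimeError(f"conservation violated in stages: {bad}")
    return summary


def score_against_truth(
    truth: simulate.SimTruth,
    de_results: list[diffexp.DEResult],
    candidates: list[novel.NovelCandidate],
    list_a: list[dict],
    list_b: list[dict],
) -> dict:
    """Recovery metrics of every stage against the planted ground truth."""
    called = {r.feature: r.direction for r in de_results if r.significant}
    planted_up = truth.planted_up()
    planted_down = truth.planted_down()
    planted = planted_up | planted_down
    correct = {
        f for f in planted
        if called.get(f) == ("up" if f in planted_up else "down")
    }
    false_calls = {f for f in called if f not in planted}
    de_sensitivity = len(correct) / len(planted) if planted else 1.0
    de_fdp = len(false_calls) / len(called) if called else 0.0

    # novel: a planted hairpin is recovered when a passing candidate tag is
    # an exact substring of it; a passing candidate on no planted hairpin is
    # a false positive
    passing = [c for c in candidates if c.verdict == "pass"]
    novel_seqs = {
        nid: truth.units[f"novel:{nid}"].source_seq for nid in truth.novel_ids
        if f"novel:{nid}" in truth.units
    }
    recovered = {
        nid for nid, seq in novel_seqs.items()
        if any(c.tag in seq for c in passing)
    }
    tp = sum(any(c.tag in seq for seq in novel_seqs.values()) for c in passing)
    novel_recall = len(recovered) / len(novel_seqs) if novel_seqs else 1.0
    novel_precision = tp / len(passing) if passing else 1.0

    planted_a = {g for g, d in truth.de_genes.items() if d == "up"}
    planted_b = {g for g, d in truth.de_genes.items() if d == "down"}
    got_a = {r["feature"] for r in list_a}
    got_b = {r["feature"] for r in list_b}
    n_planted = len(planted_a) + len(planted_b)
    integration_sensitivity = (
        (len(planted_a & got_a) + len(planted_b & got_b)) / n_planted
        if n_planted else 1.0
    )
    return {
        "de_sensitivity": de_sensitivity,
        "de_false_discovery_proportion": de_fdp,
        "novel_recall": novel_recall,
        "novel_precision": novel_precision,
        "integration_sensitivity": integration_sensitivity,
        "n_planted_de": len(planted),
        "n_called_de": len(called),
    }


def verify_tables() -> dict:
    """Recompute the bundled reference table's fold changes.

    Returns per-row agreement with the printed values and the count of
    up-regulated rows exceeding 5-fold.
    """
    df = recompute_fold_changes()
    return {
        "n_rows": int(len(df)),
        "n_matching": int(df["matches_printed"].sum()),
        "mismatches": df.loc[~df["matches_printed"], "feature"].tolist(),
        "n_up_gt5": count_strong_upregulated(),
    }
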