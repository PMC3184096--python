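"""miRNA-target prediction and mRNA integration.

Targets of the differentially expressed miRNAs are predicted by
canonical seed matching: the 3'UTR is scanned for reverse complements of
miRNA positions 2-8, classified as 8mer / 7mer-m8 / 7mer-A1 / 6mer, and
a gene counts as a predicted target with at least one 7mer-or-better
site. The matching two-array expression table is reduced to per-gene
z-ratios (difference of per-array z-scores over the sd of those
differences) with calls at +/-1.96, flagged probes excluded throughout.
The final integration keeps genes regulated exclusively by one miRNA
direction and moving the opposite way at the mRNA level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import revcomp

logger = logging.getLogger(__name__)

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_PREDICTIVE = {"8mer", "7mer-m8", "7mer-A1"}  # 7mer-or-better rule


@dataclass(frozen=True)
class TargetPrediction:
    mirna: str
    gene: str
    site_class: str
    site_count: int

    @property
    def predictive(self) -> bool:
        return self.site_class in _PREDICTIVE


def _classify_sites(utr: str, mirna_seq: str) -> dict[str, int]:
    """Count canonical seed sites of each class in one UTR."""
    core6 = revcomp(mirna_seq[1:7])     # matches miRNA positions 2-7
    m8_base = revcomp(mirna_seq[7])     # position 8 complement
    counts = dict.fromkeys(SITE_CLASSES, 0)
    start = 0
    while True:
        pos = utr.find(core6, start)
        if pos == -1:
            break
        has_m8 = pos > 0 and utr[pos - 1] == m8_base
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            counts["8mer"] += 1
        elif has_m8:
            counts["7mer-m8"] += 1
        elif has_a1:
            counts["7mer-A1"] += 1
        else:
            counts["6mer"] += 1
        start = pos + 1
    return counts


def predict_targets_seed(
    mirna_seqs: Mapping[str, str], utrs: Mapping[str, str]
) -> list[TargetPrediction]:
    """All seed-site records per (miRNA, gene); one record per site class.

    Only records of class 7mer-m8/7mer-A1/8mer make a gene a predicted
    target; 6mer records are reported but below threshold.
    """
    out: list[TargetPrediction] = []
    for name in sorted(mirna_seqs):
        seq = mirna_seqs[name]
        if len(seq) < 8:
            raise ValueError(f"miRNA {name!r} shorter than 8 nt")
        for gene in sorted(utrs):
            for cls, n in _classify_sites(utrs[gene], seq).items():
                if n > 0:
                    out.append(TargetPrediction(name, gene, cls, n))
    return out


def predicted_target_genes(predictions: Sequence[TargetPrediction]) -> dict[str, set[str]]:
    """miRNA -> set of predicted target genes (7mer-or-better only)."""
    out: dict[str, set[str]] = {}
    for p in predictions:
        if p.predictive:
            out.setdefault(p.mirna, set()).add(p.gene)
    return out


# ---------------------------------------------------------------------------
# z-ratio calls


UP = "up"
DOWN = "down"
NONE = "none"
FLAGGED = "flagged"


@dataclass
class ZRatioRecord:
    gene: str
    z_met: float
    z_nonmet: float
    z_ratio: float
    status: str


def z_ratio(
    table: pd.DataFrame,
    z_threshold: float = 1.96,
    value_cols: tuple[str, str] = ("array_metastatic", "array_non_metastatic"),
    flag_cols: tuple[str, str] | None = ("flag_metastatic", "flag_non_metastatic"),
) -> list[ZRatioRecord]:
    """Per-gene z-ratio between two arrays of log-scale intensities.

    Per array, z = (x - mean) / sd over unflagged probes (sample sd); the
    z-ratio is the per-gene z difference divided by the sample sd of all
    unflagged differences. A probe flagged on either array carries no
    call and is excluded from every mean and sd.
    """
    x1 = table[value_cols[0]].to_numpy(dtype=float)
    x2 = table[value_cols[1]].to_numpy(dtype=float)
    if flag_cols is not None and all(c in table.columns for c in flag_cols):
        flagged = (table[flag_cols[0]].to_numpy(dtype=bool)
                   | table[flag_cols[1]].to_numpy(dtype=bool))
    else:
        flagged = np.zeros(len(table), dtype=bool)
    ok = ~flagged
    if ok.sum() < 3:
        raise ValueError("too few unflagged probes")
    z1 = np.full(len(table), np.nan)
    z2 = np.full(len(table), np.nan)
    for src, dst in ((x1, z1), (x2, z2)):
        mu = src[ok].mean()
        sd = src[ok].std(ddof=1)
        if sd == 0:
            raise ValueError("degenerate arrays: zero spread")
        dst[ok] = (src[ok] - mu) / sd
    diff = z1 - z2
    sd_diff = np.std(diff[ok], ddof=1)
    if sd_diff == 0:
        raise ValueError("degenerate arrays: all z differences equal")
    zr = diff / sd_diff

    records = []
    genes = table["gene"].tolist()
    for i, gene in enumerate(genes):
        if flagged[i]:
            records.append(ZRatioRecord(gene, np.nan, np.nan, np.nan, FLAGGED))
            continue
        status = UP if zr[i] > z_threshold else (DOWN if zr[i] < -z_threshold else NONE)
        records.append(ZRatioRecord(gene, z1[i], z2[i], zr[i], status))
    n_up = sum(r.status == UP for r in records)
    n_down = sum(r.status == DOWN for r in records)
    logger.info("z_ratio: %d up, %d down, %d flagged", n_up, n_down, int(flagged.sum()))
    return records


# ---------------------------------------------------------------------------
# exclusive sets and final integration


def exclusive_target_sets(
    targets_of_up: set[str], targets_of_down: set[str]
) -> tuple[set[str], set[str]]:
    """Genes targeted only by up-miRNAs vs only by down-miRNAs (disjoint)."""
    return targets_of_up - targets_of_down, targets_of_down - targets_of_up


def integrate(
    up_mirna_targets: Mapping[str, set[str]],
    down_mirna_targets: Mapping[str, set[str]],
    z_records: Sequence[ZRatioRecord],
) -> tuple[list[dict], list[dict]]:
    """Cross miRNA direction with mRNA direction.

    List A (candidate derepression): mRNAs up at the array level whose
    predicted regulators are exclusively down-regulated miRNAs. List B:
    mRNAs down at the array level targeted exclusively by up-regulated
    miRNAs.
    """
    up_targets = set().union(*up_mirna_targets.values()) if up_mirna_targets else set()
    down_targets = set().union(*down_mirna_targets.values()) if down_mirna_targets else set()
    up_only, down_only = exclusive_target_sets(up_targets, down_targets)

    status = {r.gene: r for r in z_records}

    def rows(genes: set[str], wanted_status: str,
             supporters: Mapping[str, set[str]]) -> list[dict]:
        out = []
        for gene in sorted(genes):
            rec = status.get(gene)
            if rec is None or rec.status != wanted_status:
                continue
            mirnas = sorted(m for m, gs in supporters.items() if gene in gs)
            out.append(
                {
                    "feature": gene,
                    "direction": wanted_status,
                    "z_ratio": rec.z_ratio,
                    "supporting_mirnas": ",".join(mirnas),
                    "site_classes": "",
                }
            )
        return out

    list_a = rows(down_only, UP, down_mirna_targets)
    list_b = rows(up_only, DOWN, up_mirna_targets)
    logger.info("integrate: %d derepression candidates, %d repression candidates",
                len(list_a), len(list_b))
    return list_a, list_b
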