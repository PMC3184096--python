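"""Differential expression between the two libraries.

Fold changes are signed ratios of normalized counts (negative when the
metastatic library is lower, ``N/A`` when exactly one side is zero).
Significance comes from a two-sided Fisher exact test on raw tag counts
against the library totals, Bonferroni-corrected over the number of
tested rows; a feature is called significant when the corrected p falls
below the p threshold and the fold change reaches the fold threshold (or
is undefined with signal on one side only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .config import PipelineConfig, METASTATIC, NON_METASTATIC

logger = logging.getLogger(__name__)

#: relative slack on the "probability <= observed" comparison of the
#: two-sided Fisher sum, absorbing float error in the log-pmf.
_FISHER_TOL = 1e-12

UP = "up"
DOWN = "down"
NONE = "none"


def fold_change(norm_met: float, norm_nonmet: float) -> float | None:
    """Signed fold change; None (printed N/A) when exactly one side is zero.

    Positive = higher in the metastatic library (ratio met/nonmet),
    negative = higher in the non-metastatic library (-(nonmet/met));
    equal positive values give +1.0. Antisymmetric under swapping the
    libraries. Both-zero inputs must be excluded upstream.
    """
    if norm_met < 0 or norm_nonmet < 0:
        raise ValueError("normalized counts must be non-negative")
    if norm_met == 0 and norm_nonmet == 0:
        raise ValueError("both-zero feature must be excluded before fold_change")
    if norm_met == 0 or norm_nonmet == 0:
        return None
    if norm_met >= norm_nonmet:
        return norm_met / norm_nonmet
    return -(norm_nonmet / norm_met)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability is <= that of the observed table (with a
    1e-12 relative slack on the comparison); computed in log space so
    library-scale totals are handled exactly as small tables are.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("Fisher table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    M = a + b + c + d
    r1 = a + b          # first-row margin
    n1 = a + c          # first-column margin
    if M == 0 or r1 == 0 or r1 == M or n1 == 0 or n1 == M:
        return 1.0
    k_min = max(0, n1 - (M - r1))
    k_max = min(n1, r1)
    ks = np.arange(k_min, k_max + 1)
    logp = hypergeom.logpmf(ks, M, r1, n1)
    log_obs = logp[a - k_min]
    keep = logp <= log_obs + _FISHER_TOL
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p: min(1, m * p)."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    return min(1.0, p * m)


@dataclass
class DEResult:
    feature: str
    group_start: int | None
    start_shift: int | None
    raw_met: int
    raw_nonmet: int
    norm_met: float
    norm_nonmet: float
    fold: float | None
    p_raw: float
    p_adj: float
    direction: str
    significant: bool

    def as_row(self) -> dict:
        return {
            "feature": self.feature,
            "norm_metastatic": self.norm_met,
            "norm_non_metastatic": self.norm_nonmet,
            "fold": self.fold,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "direction": self.direction,
            "significant": self.significant,
            "group_start": self.group_start if self.group_start is not None else 0,
        }


def call_differential(
    de_rows: Sequence[dict],
    library_totals: dict[str, int],
    config: PipelineConfig,
) -> list[DEResult]:
    """Fisher + Bonferroni differential calls over the tested rows.

    ``de_rows`` are the representative start-position groups (plus
    annotated-start extra rows, tested independently); m for the
    correction is the number of tested rows. Fold changes use normalized
    counts, the exact test uses raw counts against the library totals.
    An undefined fold takes the direction of the nonzero library.
    """
    total_met = library_totals[METASTATIC]
    total_nonmet = library_totals[NON_METASTATIC]
    tested = [
        r for r in de_rows
        if r[f"raw_{METASTATIC}"] + r[f"raw_{NON_METASTATIC}"] > 0
    ]
    m = len(tested)
    results = []
    for row in tested:
        raw_met = row[f"raw_{METASTATIC}"]
        raw_nonmet = row[f"raw_{NON_METASTATIC}"]
        norm_met = row[f"norm_{METASTATIC}"]
        norm_nonmet = row[f"norm_{NON_METASTATIC}"]
        fold = fold_change(norm_met, norm_nonmet)
        p_raw = fisher_exact_two_sided(
            raw_met, total_met - raw_met, raw_nonmet, total_nonmet - raw_nonmet
        )
        p_adj = bonferroni(p_raw, m)
        if fold is None:
            direction = UP if norm_met > 0 else DOWN
            fold_ok = True
        elif fold >= config.fold_threshold:
            direction, fold_ok = UP, True
        elif fold <= -config.fold_threshold:
            direction, fold_ok = DOWN, True
        else:
            direction = UP if fold > 1 else (DOWN if fold < -1 else NONE)
            fold_ok = False
        significant = fold_ok and p_adj < config.p_threshold
        results.append(
            DEResult(
                feature=row["feature"],
                group_start=row.get("group_start"),
                start_shift=row.get("start_shift"),
                raw_met=raw_met,
                raw_nonmet=raw_nonmet,
                norm_met=norm_met,
                norm_nonmet=norm_nonmet,
                fold=fold,
                p_raw=p_raw,
                p_adj=p_adj,
                direction=direction,
                significant=significant,
            )
        )
    n_sig = sum(r.significant for r in results)
    logger.info("call_differential: %d rows tested, %d significant", m, n_sig)
    return results
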