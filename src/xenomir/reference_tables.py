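"""Bundled reference comparison table.

The package ships the published normalized-count table of the metastatic
(LTL-313H) versus non-metastatic (LTL-313B) prostate-cancer xenograft
comparison: per miRNA, the counts-per-million values in each library,
the printed signed fold change (``N/A`` where one library had no reads)
and a marker for rows whose dominant isomiR started one base off the
annotated mature. It serves as a worked-example input for the
fold-change convention: re-deriving the printed fold changes from the
printed count pairs exercises the same code path the pipeline uses on
fresh data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .diffexp import fold_change


def load_reference_de_table() -> pd.DataFrame:
    with resources.files("xenomir.data").joinpath("xenograft_de_reference.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"printed_fold": str},
                         keep_default_na=False)
    return df


def recompute_fold_changes(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute each row's signed fold change from its count pair.

    Adds ``computed_fold`` (None where undefined), ``computed_str`` (2-dp
    string or N/A) and ``matches_printed``.
    """
    if df is None:
        df = load_reference_de_table()
    df = df.copy()
    computed = [
        fold_change(met, nonmet)
        for met, nonmet in zip(df["norm_metastatic"], df["norm_non_metastatic"])
    ]
    df["computed_fold"] = computed
    df["computed_str"] = ["N/A" if f is None else f"{f:.2f}" for f in computed]
    # the published folds were computed from unrounded counts; the printed
    # 2-dp counts carry +/-0.005 each, so agreement is judged within the
    # propagated interval |f| * (0.005/met + 0.005/nonmet) plus half an ULP
    matches = []
    for c, p, met, nonmet in zip(
        df["computed_str"], df["printed_fold"].str.replace("−", "-"),
        df["norm_metastatic"], df["norm_non_metastatic"],
    ):
        if c == "N/A" or p == "N/A":
            matches.append(c == p)
            continue
        cf, pf = float(c), float(p)
        tol = abs(cf) * (0.005 / max(met, 0.005) + 0.005 / max(nonmet, 0.005))
        matches.append(abs(cf - pf) <= tol + 0.005 + 1e-9)
    df["matches_printed"] = matches
    return df


def count_strong_upregulated(df: pd.DataFrame | None = None, threshold: float = 5.0) -> int:
    """Number of up-regulated rows whose recomputed fold exceeds ``threshold``."""
    df = recompute_fold_changes(df)
    up = df[df["regulation"] == "up"]
    return int(sum(f is not None and f > threshold for f in up["computed_fold"]))
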