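"""Promoter cis-element enrichment against a genome-wide background.

For a candidate promoter with X observed occurrences of a motif over W
scannable windows, the null model is X ~ Binomial(W, rate) with the
genome-wide per-window rate. Significance is a one-sided (upper-tail)
normal approximation with continuity correction:

    mu = W * rate,  sigma^2 = W * rate * (1 - rate)
    z  = (X - mu - 0.5) / sigma,   p = P(Z >= z)

and effect size is log2 fold change with a 0.5 pseudocount on both sides:

    log2FC = log2((X + 0.5) / (mu + 0.5))

so zero-count rows stay finite. The flag ``significant`` is p <= alpha on
the raw p-value (default alpha = 0.1, no multiple-testing correction); a
Benjamini-Hochberg column is reported for information only. An exact
binomial upper tail is provided as a validation oracle for the normal model.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from seedreg.motifs import BackgroundModel, Motif, count_occurrences
from seedreg.promoters import PromoterSet

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "gene_id", "motif_name", "observed", "windows", "expected",
    "log2fc", "z", "p", "bh_fdr", "significant",
]


def _check_args(observed: int, windows: int, rate: float) -> None:
    if windows <= 0:
        raise ValueError("windows must be > 0")
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if not 0 <= observed <= windows:
        raise ValueError(f"observed={observed} outside [0, windows={windows}]")


def enrichment_stat(
    observed: int, windows: int, rate: float
) -> tuple[float, float, float]:
    """(log2fc, z, p) for an observed count against the background rate."""
    _check_args(observed, windows, rate)
    mu = windows * rate
    var = windows * rate * (1.0 - rate)
    log2fc = math.log2((observed + 0.5) / (mu + 0.5))
    if var == 0.0:
        # degenerate null: rate 0 (or 1); any excess count is infinitely
        # surprising, no count is perfectly expected
        if observed == mu:
            return log2fc, float("-inf"), 1.0
        z = float("inf") if observed > mu else float("-inf")
        return log2fc, z, 0.0 if observed > mu else 1.0
    z = (observed - mu - 0.5) / math.sqrt(var)
    p = float(stats.norm.sf(z))
    return log2fc, z, p


def exact_binomial_tail(observed: int, windows: int, rate: float) -> float:
    """Exact upper tail P(Bin(windows, rate) >= observed); validation oracle."""
    _check_args(observed, windows, rate)
    if observed == 0:
        return 1.0
    return float(stats.binom.sf(observed - 1, windows, rate))


def enrich_all(
    candidates: PromoterSet,
    motifs: Sequence[Motif],
    background: Mapping[str, BackgroundModel],
    alpha: float = 0.1,
    both_strands: bool = False,
) -> pd.DataFrame:
    """One enrichment row per (candidate promoter, motif), sorted by p.

    The background must have been built genome-wide (the candidate set may
    be a subset of it). Each promoter is tested individually.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    missing = [m.name for m in motifs if m.name not in background]
    if missing:
        raise KeyError(f"no background model for motif(s): {missing}")
    rows = []
    for motif in motifs:
        rate = background[motif.name].rate
        counts = count_occurrences(candidates, motif, both_strands)
        for gene_id, x, w in counts.itertuples(index=False):
            if w == 0:
                logger.warning(
                    "%s shorter than motif %s; skipped", gene_id, motif.name
                )
                continue
            log2fc, z, p = enrichment_stat(int(x), int(w), rate)
            rows.append(
                {
                    "gene_id": gene_id,
                    "motif_name": motif.name,
                    "observed": int(x),
                    "windows": int(w),
                    "expected": w * rate,
                    "log2fc": log2fc,
                    "z": z,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS[:-2] + [])
    if table.empty:
        return pd.DataFrame(columns=REPORT_COLUMNS)
    table["bh_fdr"] = stats.false_discovery_control(table["p"], method="bh")
    table["significant"] = table["p"] <= alpha
    table = table.sort_values(
        ["p", "gene_id", "motif_name"], kind="stable"
    ).reset_index(drop=True)
    n_sig = int(table["significant"].sum())
    logger.info(
        "enrichment: %d test(s), %d significant at p <= %g", len(table), n_sig, alpha
    )
    return table[REPORT_COLUMNS]


def write_enrichment_report(table: pd.DataFrame, path, sig_path=None) -> None:
    """Write the full report TSV and a second file of significant rows only.

    Floats are written at full precision so a round-trip parse reproduces
    values exactly. ``sig_path`` defaults to ``<stem>.significant.tsv``.
    """
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    if sig_path is None:
        sig_path = path.with_suffix(".significant.tsv")
    if len(table):
        table[table["significant"]].to_csv(sig_path, sep="\t", index=False)
    else:
        table.to_csv(sig_path, sep="\t", index=False)


def read_enrichment_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
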