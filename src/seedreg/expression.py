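"""Expression-matrix and gene-role input handling, and abundance-based selection.

The expression matrix is a genes x samples :class:`pandas.DataFrame` of
numeric abundances (missing values allowed as NaN). The role table assigns
each gene a regulatory role: ``TF`` (with a family label such as bZIP or
MYB), ``SSP`` (with a storage-protein class: glutelin, prolamin, globulin or
albumin), or ``other``. Candidate selection keeps the top-N most abundant
transcripts and partitions them into TF and SSP sets for the co-expression
network.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ROLES = frozenset({"TF", "SSP", "other"})

ROLE_COLUMNS = ["gene_id", "role", "subclass", "display_name"]


class ExpressionParseError(ValueError):
    """A cell of the expression matrix could not be parsed as a number."""


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicate ids, bad role, ...)."""


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a tab-delimited genes x samples abundance matrix.

    First row holds sample ids, first column gene ids. Empty cells and the
    literal ``NA`` are treated as missing. Non-numeric cells raise
    :class:`ExpressionParseError` naming the offending gene and sample;
    duplicate gene ids raise :class:`ValidationError`.
    """
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValidationError(f"duplicate gene id(s): {', '.join(dupes)}")

    values = raw.where(~raw.isin(["", "NA"]))
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ExpressionParseError(
            f"non-numeric cell at gene {gene!r}, sample {sample!r}: "
            f"{values.loc[gene, sample]!r}"
        )
    if not np.isfinite(numeric.to_numpy(dtype=float)[~numeric.isna().to_numpy()]).all():
        raise ValidationError("expression matrix contains non-finite values")
    logger.info(
        "read expression matrix: %d genes x %d samples, %d missing cells",
        numeric.shape[0],
        numeric.shape[1],
        int(numeric.isna().to_numpy().sum()),
    )
    return numeric.astype(float)


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a matrix in the same TSV dialect read_expression_matrix accepts."""
    matrix.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


def read_role_table(path) -> pd.DataFrame:
    """Read the 4-column gene-role table (gene_id, role, subclass, display_name).

    Roles must be one of TF / SSP / other; the subclass (TF family or SSP
    class) must be non-empty unless the role is ``other``.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ROLE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"role table missing column(s): {missing_cols}")
    table = table[ROLE_COLUMNS]
    if table["gene_id"].duplicated().any():
        dupes = sorted(set(table.loc[table["gene_id"].duplicated(), "gene_id"]))
        raise ValidationError(f"duplicate gene id(s) in role table: {dupes}")
    unknown = sorted(set(table["role"]) - VALID_ROLES)
    if unknown:
        raise ValidationError(
            f"unknown role value(s) {unknown}; expected one of {sorted(VALID_ROLES)}"
        )
    blank_sub = table[(table["role"] != "other") & (table["subclass"] == "")]
    if len(blank_sub):
        raise ValidationError(
            "empty subclass for non-'other' gene(s): "
            + ", ".join(blank_sub["gene_id"])
        )
    logger.info("read role table: %d genes (%d TF, %d SSP)",
                len(table),
                int((table["role"] == "TF").sum()),
                int((table["role"] == "SSP").sum()))
    return table.set_index("gene_id", drop=False)


def select_top_abundant(
    matrix: pd.DataFrame,
    n: int,
    metric: str = "mean",
    max_missing_frac: float = 0.5,
    log2_transform: bool = False,
) -> list[str]:
    """Return the ids of the ``n`` most abundant genes, most abundant first.

    Abundance is summarised per gene over non-missing samples by ``metric``
    (mean, median or max; mean is the default reading of "most abundant"
    for a multi-sample compendium). Genes missing in more than
    ``max_missing_frac`` of samples are excluded before ranking. Ties are
    broken lexicographically by gene id so the ranking is deterministic.
    ``log2_transform`` applies log2(x + 1) before summarising (off by
    default; abundances are otherwise used as supplied).
    """
    if metric not in {"mean", "median", "max"}:
        raise ValueError(f"unknown metric {metric!r}")
    if n < 1:
        raise ValueError("n must be a positive integer")
    values = matrix
    if log2_transform:
        values = np.log2(values + 1.0)
    frac_missing = values.isna().mean(axis=1)
    usable = values.loc[frac_missing <= max_missing_frac]
    dropped = len(values) - len(usable)
    if dropped:
        logger.info("dropped %d gene(s) missing in > %.0f%% of samples",
                    dropped, 100 * max_missing_frac)
    if n > len(usable):
        raise ValueError(
            f"requested n={n} exceeds {len(usable)} usable genes"
        )
    score = getattr(usable, metric)(axis=1, skipna=True)
    # stable sort after a lexicographic pre-sort -> ties broken by gene id
    ranked = score.sort_index(kind="stable").sort_values(
        ascending=False, kind="stable"
    )
    return list(ranked.index[:n])


def partition_candidates(
    top: Sequence[str], roles: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Split a ranked gene list into (tf_ids, ssp_ids), preserving order.

    Genes absent from the role table default to role ``other``; all
    ``other`` genes are dropped (counted in the log).
    """
    role_of = roles["role"] if "role" in roles else pd.Series(dtype=str)
    tf_ids: list[str] = []
    ssp_ids: list[str] = []
    n_other = 0
    for gene in top:
        role = role_of.get(gene, "other")
        if role == "TF":
            tf_ids.append(gene)
        elif role == "SSP":
            ssp_ids.append(gene)
        else:
            n_other += 1
    logger.info(
        "partitioned %d genes: %d TF, %d SSP, %d other (dropped)",
        len(top), len(tf_ids), len(ssp_ids), n_other,
    )
    if top and not tf_ids and not ssp_ids:
        logger.warning("no TF or SSP genes among the %d selected", len(top))
    return tf_ids, ssp_ids
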