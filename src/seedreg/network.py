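"""Signed bipartite TF-SSP co-expression network from Pearson correlation.

Edges connect a transcription factor to a seed storage protein gene whenever
the absolute Pearson correlation of their expression profiles reaches the
cutoff (default |r| >= 0.7). The sign of r is kept on the edge (positive /
negative co-expression); hub analysis ranks TFs by degree and shared-target
analysis intersects the SSP target sets of a TF subset.

Correlations are computed over pairwise-complete samples with a minimum
number of complete pairs; pairs with a constant profile are undefined and
never become edges. No p-value is attached to edges: the procedure is a pure
|r| threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger(__name__)

EDGE_TSV_COLUMNS = ["tf_id", "ssp_id", "r", "sign", "n_used"]


@dataclass(frozen=True)
class CorrelationEdge:
    """A thresholded TF-SSP co-expression edge with its correlation value."""

    tf_id: str
    ssp_id: str
    r: float
    n_used: int

    @property
    def sign(self) -> str:
        return "positive" if self.r > 0 else "negative"


@dataclass
class CoexpressionNetwork:
    """Bipartite TF-SSP network; node metadata maps id -> (display_name, subclass)."""

    tf_nodes: dict[str, tuple[str, str]]
    ssp_nodes: dict[str, tuple[str, str]]
    edges: list[CorrelationEdge]
    cutoff: float = 0.7

    def targets_of(self, tf_id: str) -> set[str]:
        if tf_id not in self.tf_nodes:
            raise KeyError(f"unknown TF id {tf_id!r}")
        return {e.ssp_id for e in self.edges if e.tf_id == tf_id}


def pearson_r(
    x: Sequence[float], y: Sequence[float], min_pairs: int = 6
) -> float:
    """Sample Pearson correlation over pairwise-complete positions.

    Returns NaN (undefined) when fewer than ``min_pairs`` complete pairs
    remain or either vector is constant over the complete positions.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError(
            f"length mismatch: {xa.shape} vs {ya.shape} (need equal 1-d vectors)"
        )
    ok = ~(np.isnan(xa) | np.isnan(ya))
    if int(ok.sum()) < min_pairs:
        return float("nan")
    xs, ys = xa[ok], ya[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    return float((xc * yc).sum() / denom)


def _complete_pairs(xa: np.ndarray, ya: np.ndarray) -> int:
    return int((~(np.isnan(xa) | np.isnan(ya))).sum())


def build_network(
    matrix: pd.DataFrame,
    tf_ids: Sequence[str],
    ssp_ids: Sequence[str],
    cutoff: float = 0.7,
    min_pairs: int = 6,
    roles: pd.DataFrame | None = None,
) -> CoexpressionNetwork:
    """Threshold all TF x SSP Pearson correlations into a signed network.

    ``tf_ids`` and ``ssp_ids`` must be disjoint and present in the matrix.
    Pairs whose correlation is undefined (constant profile or too few
    complete samples) are skipped and counted in the log. When ``roles`` is
    given, display names and subclasses are attached to the nodes.
    """
    overlap = set(tf_ids) & set(ssp_ids)
    if overlap:
        raise ValueError(f"TF and SSP id lists overlap: {sorted(overlap)[:5]}")
    missing = [g for g in [*tf_ids, *ssp_ids] if g not in matrix.index]
    if missing:
        raise KeyError(f"gene id(s) not in matrix: {missing[:5]}")
    if not 0 < cutoff:
        raise ValueError("cutoff must be positive")

    tf_block = matrix.loc[list(tf_ids)].to_numpy(dtype=float)
    ssp_block = matrix.loc[list(ssp_ids)].to_numpy(dtype=float)
    n_samples = tf_block.shape[1]

    edges: list[CorrelationEdge] = []
    n_skipped = 0

    no_missing = not (np.isnan(tf_block).any() or np.isnan(ssp_block).any())
    if no_missing and n_samples >= min_pairs:
        # fast path: one matrix product for all pairs
        def _standardise(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            centred = block - block.mean(axis=1, keepdims=True)
            norms = np.sqrt((centred * centred).sum(axis=1))
            constant = norms == 0
            norms[constant] = 1.0
            return centred / norms[:, None], constant

        tf_std, tf_const = _standardise(tf_block)
        ssp_std, ssp_const = _standardise(ssp_block)
        rmat = tf_std @ ssp_std.T
        rmat[tf_const, :] = np.nan
        rmat[:, ssp_const] = np.nan
        n_skipped = int(np.isnan(rmat).sum())
        ii, jj = np.nonzero(np.abs(rmat) >= cutoff)
        for i, j in zip(ii.tolist(), jj.tolist()):
            edges.append(
                CorrelationEdge(tf_ids[i], ssp_ids[j], float(rmat[i, j]), n_samples)
            )
    else:
        for i, tf in enumerate(tf_ids):
            for j, ssp in enumerate(ssp_ids):
                r = pearson_r(tf_block[i], ssp_block[j], min_pairs=min_pairs)
                if np.isnan(r):
                    n_skipped += 1
                    continue
                if abs(r) >= cutoff:
                    edges.append(
                        CorrelationEdge(
                            tf, ssp, r, _complete_pairs(tf_block[i], ssp_block[j])
                        )
                    )

    if n_skipped:
        logger.warning(
            "skipped %d TF-SSP pair(s) with undefined correlation "
            "(constant profile or < %d complete samples)", n_skipped, min_pairs,
        )
    logger.info(
        "network: %d TF x %d SSP genes, %d edge(s) at |r| >= %g",
        len(tf_ids), len(ssp_ids), len(edges), cutoff,
    )

    def _meta(gene: str) -> tuple[str, str]:
        if roles is not None and gene in roles.index:
            row = roles.loc[gene]
            return str(row["display_name"]) or gene, str(row["subclass"])
        return gene, ""

    return CoexpressionNetwork(
        tf_nodes={g: _meta(g) for g in tf_ids},
        ssp_nodes={g: _meta(g) for g in ssp_ids},
        edges=sorted(edges, key=lambda e: (e.tf_id, e.ssp_id)),
        cutoff=cutoff,
    )


def degree_table(net: CoexpressionNetwork) -> pd.DataFrame:
    """Per-TF degree and target list, highest degree first (ties by gene id).

    Every TF node is listed, including isolated ones (degree 0). An optional
    downstream "hub" call is simply the head of this table.
    """
    targets: dict[str, list[str]] = {tf: [] for tf in net.tf_nodes}
    for e in net.edges:
        targets[e.tf_id].append(e.ssp_id)
    rows = [
        {
            "tf_id": tf,
            "degree": len(tgts),
            "targets": ",".join(sorted(tgts)),
        }
        for tf, tgts in targets.items()
    ]
    table = pd.DataFrame(rows, columns=["tf_id", "degree", "targets"])
    table = table.sort_values(
        ["degree", "tf_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return table


def shared_targets(
    net: CoexpressionNetwork, tf_subset: Iterable[str]
) -> set[str]:
    """SSP genes co-expressed with every TF in ``tf_subset`` (set intersection)."""
    tfs = list(tf_subset)
    if not tfs:
        return set()
    shared = net.targets_of(tfs[0])
    for tf in tfs[1:]:
        shared &= net.targets_of(tf)
    return shared


def to_networkx(net: CoexpressionNetwork) -> nx.Graph:
    """Materialise the network as a networkx graph with role/subclass attributes."""
    g = nx.Graph()
    for gene, (name, subclass) in net.tf_nodes.items():
        g.add_node(gene, role="TF", subclass=subclass, display_name=name)
    for gene, (name, subclass) in net.ssp_nodes.items():
        g.add_node(gene, role="SSP", subclass=subclass, display_name=name)
    for e in net.edges:
        g.add_edge(e.tf_id, e.ssp_id, r=e.r, sign=e.sign, n_used=e.n_used)
    return g


def export_network(net: CoexpressionNetwork, fmt: str, path) -> None:
    """Write the network for Cytoscape: 'edge-tsv', 'sif' or 'graphml'."""
    path = Path(path)
    if fmt == "edge-tsv":
        rows = [
            (e.tf_id, e.ssp_id, repr(e.r), e.sign, e.n_used) for e in net.edges
        ]
        pd.DataFrame(rows, columns=EDGE_TSV_COLUMNS).to_csv(
            path, sep="\t", index=False
        )
    elif fmt == "sif":
        with open(path, "w") as fh:
            for e in net.edges:
                rel = "coexpr_pos" if e.sign == "positive" else "coexpr_neg"
                fh.write(f"{e.tf_id}\t{rel}\t{e.ssp_id}\n")
    elif fmt == "graphml":
        nx.write_graphml(to_networkx(net), path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_edge_tsv(path) -> pd.DataFrame:
    """Read an edge-tsv export back into a DataFrame (full-precision r)."""
    table = pd.read_csv(
        path, sep="\t", dtype={"tf_id": str, "ssp_id": str},
        float_precision="round_trip",
    )
    table["r"] = table["r"].astype(float)
    return table
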