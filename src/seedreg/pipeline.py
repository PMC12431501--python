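"""End-to-end orchestration: select -> correlate -> network -> promoters -> scan -> enrich.

A single config drives the whole analysis. Outputs land in one run
directory: the selected-gene list, the signed co-expression network in
three formats, the TF degree (hub) table, the shared-target report for the
top hubs, the promoter FASTA (when extracting from a genome), the motif hit
table and the enrichment reports, plus a manifest recording the config and
SHA-256 checksums of all inputs. Each stage writes through a ``.partial``
file renamed on success, so an aborted run leaves its incomplete outputs
clearly marked.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import seedreg
from seedreg import enrichment as enrich_mod
from seedreg import expression as expr_mod
from seedreg import motifs as motif_mod
from seedreg import network as net_mod
from seedreg import promoters as prom_mod

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    expression: str = ""
    roles: str = ""
    genome: str = ""  # genome FASTA (with gff) ...
    gff: str = ""
    promoter_fasta: str = ""  # ... or a ready-made promoter FASTA
    motifs: str = ""
    outdir: str = "seedreg_run"
    top_n: int = 2000
    metric: str = "mean"
    r_cutoff: float = 0.7
    min_pairs: int = 6
    promoter_length: int = 2000
    alpha: float = 0.1
    both_strands: bool = False
    hub_top_k: int = 3
    candidate_ids: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.top_n < 1:
            problems.append("top_n must be >= 1")
        if not 0 < self.r_cutoff <= 1:
            problems.append("r_cutoff must be in (0, 1]")
        if not 0 < self.alpha < 1:
            problems.append("alpha must be in (0, 1)")
        if self.promoter_length < 1:
            problems.append("promoter_length must be >= 1")
        if self.metric not in {"mean", "median", "max"}:
            problems.append(f"unknown metric {self.metric!r}")
        if self.hub_top_k < 1:
            problems.append("hub_top_k must be >= 1")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))


def validate_config(path) -> PipelineConfig:
    """Load a YAML config file, apply defaults, report all violations at once."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageWriter:
    """Write stage outputs via .partial files, renamed on stage success."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self._pending: list[tuple[Path, Path]] = []

    def path(self, name: str) -> Path:
        final = self.outdir / name
        partial = self.outdir / (name + ".partial")
        self._pending.append((partial, final))
        return partial

    def commit(self) -> None:
        for partial, final in self._pending:
            if partial.exists():
                partial.replace(final)
        self._pending.clear()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full analysis; returns the run directory."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    writer = _StageWriter(outdir)
    inputs = {
        k: getattr(cfg, k)
        for k in ("expression", "roles", "genome", "gff", "promoter_fasta", "motifs")
        if getattr(cfg, k)
    }

    # --- selection ---------------------------------------------------------
    stage = "annotation_select"
    try:
        matrix = expr_mod.read_expression_matrix(cfg.expression)
        roles = expr_mod.read_role_table(cfg.roles)
        top_n = min(cfg.top_n, matrix.shape[0])
        top = expr_mod.select_top_abundant(matrix, top_n, metric=cfg.metric)
        tf_ids, ssp_ids = expr_mod.partition_candidates(top, roles)
        with open(writer.path("selected_genes.tsv"), "w") as fh:
            fh.write("gene_id\trole\n")
            for g in top:
                role = roles["role"].get(g, "other") if len(roles) else "other"
                fh.write(f"{g}\t{role}\n")
        writer.commit()
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- co-expression network --------------------------------------------
    stage = "coexpr_net"
    try:
        net = net_mod.build_network(
            matrix, tf_ids, ssp_ids,
            cutoff=cfg.r_cutoff, min_pairs=cfg.min_pairs, roles=roles,
        )
        if not net.edges:
            logger.warning("co-expression network is empty at |r| >= %g",
                           cfg.r_cutoff)
        net_mod.export_network(net, "edge-tsv", writer.path("edges.tsv"))
        net_mod.export_network(net, "sif", writer.path("edges.sif"))
        net_mod.export_network(net, "graphml", writer.path("edges.graphml"))
        degrees = net_mod.degree_table(net)
        degrees.to_csv(writer.path("degree_table.tsv"), sep="\t", index=False)
        head = degrees.head(cfg.hub_top_k)
        hubs = list(head.loc[head["degree"] > 0, "tf_id"])
        shared = net_mod.shared_targets(net, hubs) if hubs else set()
        with open(writer.path("shared_targets.tsv"), "w") as fh:
            fh.write("hub_tfs\tshared_ssp_targets\n")
            fh.write(",".join(hubs) + "\t" + ",".join(sorted(shared)) + "\n")
        writer.commit()
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- promoters ---------------------------------------------------------
    stage = "promoters"
    try:
        if cfg.promoter_fasta:
            promoters = prom_mod.read_promoters(
                cfg.promoter_fasta, requested_length=cfg.promoter_length
            )
        elif cfg.genome and cfg.gff:
            promoters = prom_mod.extract_promoters(
                cfg.genome, cfg.gff, length=cfg.promoter_length
            )
            prom_mod.write_promoters(promoters, writer.path("promoters.fa"))
        else:
            raise ValueError(
                "config must provide promoter_fasta or genome + gff"
            )
        writer.commit()
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- motif scan --------------------------------------------------------
    stage = "motif_scan"
    try:
        motifs = motif_mod.read_motif_library(cfg.motifs)
        background = motif_mod.build_background(
            promoters, motifs, both_strands=cfg.both_strands
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- enrichment on candidate promoters ---------------------------------
    stage = "cre_enrich"
    try:
        if cfg.candidate_ids:
            candidate_ids = list(cfg.candidate_ids)
        else:
            # default: every TF-role gene with a promoter in the set
            in_set = {r.gene_id for r in promoters}
            candidate_ids = [g for g in roles.index
                             if roles["role"].get(g) == "TF" and g in in_set]
        candidates = prom_mod.PromoterSet(
            records=[promoters.get(g) for g in candidate_ids],
            requested_length=cfg.promoter_length,
        )
        hits = motif_mod.scan_promoter_set(
            candidates, motifs, both_strands=cfg.both_strands
        )
        motif_mod.write_hits_bed(hits, motifs, writer.path("motif_hits.tsv"))
        table = enrich_mod.enrich_all(
            candidates, motifs, background,
            alpha=cfg.alpha, both_strands=cfg.both_strands,
        )
        enrich_mod.write_enrichment_report(
            table,
            writer.path("enrichment.tsv"),
            sig_path=writer.path("enrichment.significant.tsv"),
        )
        writer.commit()
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- manifest ----------------------------------------------------------
    manifest = {
        "seedreg_version": seedreg.__version__,
        "config": dataclasses.asdict(cfg),
        "inputs_sha256": {k: _sha256(Path(v)) for k, v in inputs.items()},
        "n_edges": len(net.edges),
        "n_candidates": len(candidate_ids),
        "n_significant": int(table["significant"].sum()) if len(table) else 0,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline run complete: %s", outdir)
    return outdir
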