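"""Synthetic data with planted ground truth for every pipeline stage.

Expression: a single-latent-factor-per-module model. Each module has one
standard-normal factor per sample; a member gene's value is

    offset + a * factor + Normal(0, sigma)

so two genes i, j in the same module have true correlation

    r_ij = (a_i * a_j) / sqrt((a_i^2 + sigma_i^2) * (a_j^2 + sigma_j^2))

Negative loadings plant negative edges. Background genes are independent
noise. The default of 48 samples matches the size of a seed transcriptome
compendium typical for this analysis.

Promoters: i.i.d. background bases at a chosen composition, with concrete
expansions of IUPAC consensus motifs inserted (overwriting the background)
at Poisson-sampled counts targeting a per-window rate; planted genes get
fold x the background rate. Insertions never overlap each other, keeping
the counting oracle unambiguous. Note the background sequence itself also
produces chance matches on top of insertions, at roughly the product of the
per-position base probabilities of the consensus.

All randomness flows from explicit seeds; identical spec + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from seedreg.expression import write_expression_matrix
from seedreg.motifs import Motif, iupac_matcher, load_place_motifs
from seedreg.promoters import PromoterRecord, PromoterSet, write_promoters

logger = logging.getLogger(__name__)


def _per_gene(value, genes: Sequence[str], what: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [g for g in genes if g not in value]
        if missing:
            raise ValueError(f"{what} missing for gene(s) {missing}")
        return {g: float(value[g]) for g in genes}
    return {g: float(value) for g in genes}


@dataclass
class ModuleSpec:
    """One latent-factor module: its TF and SSP members, loadings and noise."""

    tf_ids: list[str]
    ssp_ids: list[str]
    loading: Mapping[str, float] | float = 1.0
    noise_sd: Mapping[str, float] | float = 1.0

    @property
    def genes(self) -> list[str]:
        return [*self.tf_ids, *self.ssp_ids]


@dataclass
class ExpressionSimSpec:
    modules: list[ModuleSpec]
    n_samples: int = 48
    n_background_genes: int = 0
    background_prefix: str = "BG"
    offsets: Mapping[str, float] | float = 0.0
    seed: int = 0


@dataclass
class PromoterSimSpec:
    n_promoters: int
    length: int = 2000
    base_composition: Mapping[str, float] | None = None  # default uniform
    background_rate: Mapping[str, float] | float = 0.0  # per motif per window
    planted: list[tuple[str, str, float]] = field(default_factory=list)
    gene_ids: list[str] | None = None  # default PRO0001..
    seed: int = 0


@dataclass
class TruthTable:
    """Machine-readable ground truth of planted structure."""

    true_edges: list[tuple[str, str, float]] = field(default_factory=list)
    true_enrichments: list[tuple[str, str, float]] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "edges": [
                {"tf": t, "ssp": s, "true_r": r} for t, s, r in self.true_edges
            ],
            "enrichments": [
                {"gene": g, "motif": m, "fold": f}
                for g, m, f in self.true_enrichments
            ],
            "seeds": self.seeds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            true_edges=[
                (e["tf"], e["ssp"], e["true_r"]) for e in payload["edges"]
            ],
            true_enrichments=[
                (e["gene"], e["motif"], e["fold"])
                for e in payload["enrichments"]
            ],
            seeds={k: int(v) for k, v in payload["seeds"].items()},
        )


def true_correlation(a_i, sigma_i, a_j, sigma_j) -> float:
    """Closed-form pairwise correlation of the one-factor model."""
    return (a_i * a_j) / np.sqrt(
        (a_i**2 + sigma_i**2) * (a_j**2 + sigma_j**2)
    )


def simulate_expression(
    spec: ExpressionSimSpec,
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate a genes x samples matrix with planted TF-SSP correlations."""
    all_genes: list[str] = []
    for mod in spec.modules:
        all_genes.extend(mod.genes)
    bg_genes = [
        f"{spec.background_prefix}{i + 1:04d}"
        for i in range(spec.n_background_genes)
    ]
    all_genes.extend(bg_genes)
    if len(all_genes) != len(set(all_genes)):
        seen, dupes = set(), set()
        for g in all_genes:
            (dupes if g in seen else seen).add(g)
        raise ValueError(f"duplicate gene id(s) across modules: {sorted(dupes)}")

    offsets = _per_gene(spec.offsets, all_genes, "offset")
    rng = np.random.default_rng(spec.seed)
    rows: dict[str, np.ndarray] = {}
    truth = TruthTable(seeds={"expression": spec.seed})

    for mod in spec.modules:
        loadings = _per_gene(mod.loading, mod.genes, "loading")
        sds = _per_gene(mod.noise_sd, mod.genes, "noise_sd")
        for g, sd in sds.items():
            if sd < 0:
                raise ValueError(f"negative noise_sd for gene {g}")
        factor = rng.standard_normal(spec.n_samples)
        for g in mod.genes:
            noise = rng.normal(0.0, sds[g], spec.n_samples) if sds[g] > 0 else 0.0
            rows[g] = offsets[g] + loadings[g] * factor + noise
        for tf in mod.tf_ids:
            for ssp in mod.ssp_ids:
                r = float(
                    true_correlation(
                        loadings[tf], sds[tf], loadings[ssp], sds[ssp]
                    )
                )
                if r != 0.0:  # zero-loading members plant no edge
                    truth.true_edges.append((tf, ssp, r))
    for g in bg_genes:
        rows[g] = offsets[g] + rng.standard_normal(spec.n_samples)

    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix.index.name = "gene_id"
    matrix.columns = [f"S{j + 1:02d}" for j in range(spec.n_samples)]
    logger.info(
        "simulated expression: %d genes x %d samples, %d planted edge(s)",
        matrix.shape[0], matrix.shape[1], len(truth.true_edges),
    )
    return matrix, truth


def _random_seq(rng: np.random.Generator, length: int,
                bases: str, probs: np.ndarray) -> np.ndarray:
    return rng.choice(np.frombuffer(bases.encode(), dtype="S1"), size=length,
                      p=probs)


def _concrete_expansion(rng: np.random.Generator, consensus: str) -> str:
    return "".join(
        sorted(allowed)[rng.integers(len(allowed))]
        for allowed in iupac_matcher(consensus)
    )


def simulate_promoters(
    spec: PromoterSimSpec, motifs: Sequence[Motif]
) -> tuple[PromoterSet, TruthTable]:
    """Simulate promoters with motif instances planted at controlled rates."""
    motif_by_name = {m.name: m for m in motifs}
    rates = (
        {m.name: float(spec.background_rate) for m in motifs}
        if not isinstance(spec.background_rate, Mapping)
        else {m.name: float(spec.background_rate.get(m.name, 0.0)) for m in motifs}
    )
    fold_of: dict[tuple[str, str], float] = {}
    for gene, motif_name, fold in spec.planted:
        if motif_name not in motif_by_name:
            raise KeyError(f"planted motif {motif_name!r} not in library")
        if fold < 1:
            raise ValueError("planting fold must be >= 1")
        fold_of[(gene, motif_name)] = float(fold)

    gene_ids = spec.gene_ids or [
        f"PRO{i + 1:04d}" for i in range(spec.n_promoters)
    ]
    if len(gene_ids) != spec.n_promoters:
        raise ValueError("gene_ids length must equal n_promoters")

    comp = spec.base_composition or {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    bases = "".join(sorted(comp))
    probs = np.array([comp[b] for b in bases], dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(spec.seed)
    truth = TruthTable(
        true_enrichments=list(spec.planted), seeds={"promoters": spec.seed}
    )
    records = []
    for gene in gene_ids:
        arr = _random_seq(rng, spec.length, bases, probs)
        occupied: list[tuple[int, int]] = []  # half-open, kept disjoint
        for motif in motifs:
            m = len(motif)
            windows = max(0, spec.length - m + 1)
            if windows == 0:
                continue
            rate = rates[motif.name] * fold_of.get((gene, motif.name), 1.0)
            if rate == 0.0:
                continue
            if rate * windows > windows / (2 * m):
                raise ValueError(
                    f"over-dense planting for {motif.name} in {gene}: "
                    f"expected {rate * windows:.1f} insertions in {windows} windows"
                )
            n_insert = int(rng.poisson(rate * windows))
            placed = 0
            attempts = 0
            while placed < n_insert and attempts < 50 * (n_insert + 1):
                attempts += 1
                pos = int(rng.integers(windows))
                if any(pos < e and pos + m > s for s, e in occupied):
                    continue
                word = _concrete_expansion(rng, motif.consensus)
                arr[pos:pos + m] = np.frombuffer(word.encode(), dtype="S1")
                occupied.append((pos, pos + m))
                placed += 1
            if placed < n_insert:
                logger.warning(
                    "%s: placed only %d/%d %s insertions (overlap rejection)",
                    gene, placed, n_insert, motif.name,
                )
        records.append(
            PromoterRecord(
                gene_id=gene,
                seq=arr.tobytes().decode(),
                chrom="synth",
                start=1,
                end=spec.length,
                strand="+",
                truncated=False,
            )
        )
    logger.info(
        "simulated %d promoter(s) of %d bp, %d planted enrichment(s)",
        len(records), spec.length, len(spec.planted),
    )
    return PromoterSet(records=records, requested_length=spec.length), truth


# --- default end-to-end fixture --------------------------------------------

FIXTURE_FILES = (
    "expression.tsv", "roles.tsv", "promoters.fa", "motifs.tsv", "truth.json"
)

# true r = 1 / (1 + sigma^2) = 0.9 for unit loadings
_SIGMA_09 = 1.0 / 3.0

_FIXTURE_PLANTED = [
    ("TF0001", "RYREPEATGMGY2", 10.0),
    ("TF0002", "ABREZMRAB28", 10.0),
    ("TF0003", "AUXRETGA2GMGH3", 10.0),
]


def default_expression_spec(seed: int = 0) -> ExpressionSimSpec:
    """A small compendium-like matrix: 3 modules (TF degrees 5/3/1), one
    negative edge, idle TFs and SSPs, and background genes."""
    mod1 = ModuleSpec(
        tf_ids=["TF0001"],
        ssp_ids=[f"SSP{i:04d}" for i in range(1, 6)],
        loading={**{"TF0001": 1.0},
                 **{f"SSP{i:04d}": 1.0 for i in range(1, 5)},
                 "SSP0005": -1.0},
        noise_sd=_SIGMA_09,
    )
    mod2 = ModuleSpec(
        tf_ids=["TF0002"],
        ssp_ids=[f"SSP{i:04d}" for i in range(6, 9)],
        noise_sd=_SIGMA_09,
    )
    mod3 = ModuleSpec(tf_ids=["TF0003"], ssp_ids=["SSP0009"], noise_sd=_SIGMA_09)
    # idle candidates: modelled as 1-gene "modules" of pure noise
    idle = ModuleSpec(
        tf_ids=[f"TF{i:04d}" for i in range(4, 9)],
        ssp_ids=[f"SSP{i:04d}" for i in range(10, 13)],
        loading=0.0,
        noise_sd=1.0,
    )
    modules = [mod1, mod2, mod3, idle]
    # TF/SSP candidates sit well above the background baseline so that
    # top-abundance selection retains them all
    offsets = {g: 12.0 for mod in modules for g in mod.genes}
    offsets.update({f"BG{i + 1:04d}": 4.0 for i in range(60)})
    return ExpressionSimSpec(
        modules=modules,
        n_samples=48,
        n_background_genes=60,
        offsets=offsets,
        seed=seed,
    )


def default_roles() -> pd.DataFrame:
    """Role table matching the default expression spec."""
    tf_families = ["MYB", "C3H", "bHLH", "GATA", "ZF-HD", "bZIP", "S1Fa", "ZF-HD"]
    ssp_classes = ["glutelin"] * 5 + ["prolamin"] * 4 + [
        "glutelin", "prolamin", "globulin",
    ]
    rows = []
    for i, fam in enumerate(tf_families, start=1):
        rows.append((f"TF{i:04d}", "TF", fam, f"OsTF{i}"))
    for i, cls in enumerate(ssp_classes, start=1):
        rows.append((f"SSP{i:04d}", "SSP", cls, f"Ssp{i}"))
    for i in range(1, 61):
        rows.append((f"BG{i:04d}", "other", "", f"bg{i}"))
    table = pd.DataFrame(
        rows, columns=["gene_id", "role", "subclass", "display_name"]
    )
    return table.set_index("gene_id", drop=False)


def default_promoter_spec(seed: int = 0) -> PromoterSimSpec:
    """Genome-wide-like promoter set: all fixture genes plus anonymous
    background promoters, with three 10x planted enrichments in TF promoters."""
    genes = (
        [f"TF{i:04d}" for i in range(1, 9)]
        + [f"SSP{i:04d}" for i in range(1, 13)]
        + [f"PRO{i:04d}" for i in range(1, 181)]
    )
    return PromoterSimSpec(
        n_promoters=len(genes),
        length=2000,
        background_rate=5e-4,
        planted=list(_FIXTURE_PLANTED),
        gene_ids=genes,
        seed=seed,
    )


def make_fixture(outdir, seed: int = 0) -> dict[str, Path]:
    """Write a complete small fixture: expression TSV, role TSV, promoter
    FASTA, motif TSV and truth JSON. Deterministic per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    motifs = load_place_motifs()

    expr_seed = seed
    prom_seed = seed + 10_000
    matrix, expr_truth = simulate_expression(default_expression_spec(expr_seed))
    promoters, prom_truth = simulate_promoters(
        default_promoter_spec(prom_seed), motifs
    )

    paths = {name: outdir / name for name in FIXTURE_FILES}
    write_expression_matrix(matrix, paths["expression.tsv"])
    default_roles().to_csv(paths["roles.tsv"], sep="\t", index=False)
    write_promoters(promoters, paths["promoters.fa"])
    pd.DataFrame(
        [(m.name, m.consensus, m.description) for m in motifs],
        columns=["name", "consensus", "description"],
    ).to_csv(paths["motifs.tsv"], sep="\t", index=False)

    truth = TruthTable(
        true_edges=expr_truth.true_edges,
        true_enrichments=prom_truth.true_enrichments,
        seeds={"expression": expr_seed, "promoters": prom_seed},
    )
    truth.to_json(paths["truth.json"])
    logger.info("fixture written to %s", outdir)
    return paths
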