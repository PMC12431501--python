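"""Shared fixtures: the packaged motif library, a synthetic end-to-end
fixture directory, and a completed pipeline run over it."""

import itertools

import pytest

from seedreg.motifs import iupac_matcher, load_place_motifs
from seedreg.pipeline import PipelineConfig, run_pipeline
from seedreg.simulate import make_fixture

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def place_motifs():
    return load_place_motifs()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return make_fixture(outdir, seed=FIXTURE_SEED)


def pipeline_config(paths, outdir) -> PipelineConfig:
    return PipelineConfig(
        expression=str(paths["expression.tsv"]),
        roles=str(paths["roles.tsv"]),
        promoter_fasta=str(paths["promoters.fa"]),
        motifs=str(paths["motifs.tsv"]),
        outdir=str(outdir),
        top_n=40,
    )


@pytest.fixture(scope="session")
def pipeline_run(fixture_dir, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    return run_pipeline(pipeline_config(fixture_dir, outdir))


# --- independent oracles ----------------------------------------------------

def expand_consensus(consensus: str) -> list[str]:
    """All concrete words matching an IUPAC consensus (N expands to ACGTN)."""
    sets = []
    for code, allowed in zip(consensus.upper(), iupac_matcher(consensus)):
        chars = sorted(allowed) + (["N"] if code == "N" else [])
        sets.append(chars)
    return ["".join(w) for w in itertools.product(*sets)]


def brute_force_offsets(seq: str, consensus: str) -> list[int]:
    """Overlapping match offsets by expanding the consensus and comparing
    every window; independent of the scanner's regex machinery."""
    seq = seq.upper()
    words = set(expand_consensus(consensus))
    m = len(consensus)
    return [i for i in range(len(seq) - m + 1) if seq[i:i + m] in words]


def definitional_pearson(x, y):
    """Pearson r via the raw sum formula, no numpy vectorisation tricks."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    ) ** 0.5
    return num / den if den else float("nan")
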