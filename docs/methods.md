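# Methods

`seedreg` implements a two-part procedure for nominating transcription
factors (TFs) that may regulate seed storage protein (SSP) genes in rice:
(1) a signed Pearson co-expression network between TF and SSP expression
profiles over a seed transcriptome compendium, with bipartite hub and
shared-target analysis, and (2) genome-wide enrichment of plant
cis-regulatory elements (CREs) in fixed-length promoter windows of the
candidate TFs. This note records the models, defaults, numerical choices
and limitations.

## Co-expression network

**Model.** For every (TF, SSP) gene pair the sample Pearson correlation r
is computed over pairwise-complete samples and thresholded at |r| ≥ 0.7
(the conventional "strong co-expression" cutoff for seed compendia of this
size). Edges keep r at full precision and a sign attribute (positive /
negative co-expression). No p-value or multiple-testing control is applied
to edges — the procedure is a pure correlation threshold, and the cutoff is
exposed as configuration for users who want a different operating point.

**Candidate selection.** "Most abundant" transcripts are ranked by the mean
abundance over non-missing samples (median and max are available); for a
multi-sample compendium the mean is the conventional summary, and the
choice matters little for strongly seed-expressed genes. Ties are broken
lexicographically by gene id so rankings are reproducible. Genes missing in
more than half the samples are excluded from ranking (configurable).
Abundances are used as supplied — no internal normalisation or log
transform (an optional log2(x+1) flag exists, off by default), because the
compendium is assumed to be already normalised upstream.

**Missing data.** Correlations use pairwise-complete observations with a
minimum of 6 complete pairs (configurable); pairs with a constant profile
over the complete positions are undefined and never become edges. Both
situations are counted and logged, not errors.

**Hubs and shared targets.** Hubness is reported as a ranked degree table
(every TF listed, ties lexicographic) rather than a hard label; the
pipeline's hub report takes the top 3 TFs by degree (configurable) and
intersects their SSP target sets. This mirrors the common practice of
calling the few highest-degree regulators "hubs" without committing to a
degree threshold.

## Promoter extraction

The promoter is the window of `length` bases (default 2000) immediately
upstream of the translation start codon — the first CDS base of the
representative mRNA (+ strand) or the last CDS base (− strand). The
representative mRNA is the first child mRNA by ID order; annotations
without an mRNA level but with CDS directly under the gene are accepted,
and genes without any CDS are skipped with a warning. Minus-strand windows
are reverse-complemented so the returned sequence reads 5′→3′ into the
start codon. Windows are clipped at chromosome boundaries and flagged
`truncated`; overlap with neighbouring genes is not masked. Soft-masked
(lowercase) bases are uppercased and scanned normally; any non-ACGT
character becomes N. Coordinates are GFF3-style 1-based inclusive
throughout, including FASTA headers (`gene chrom:start-end(strand)`).

## Motif scanning

CREs are named IUPAC consensus strings (the ten-element PLACE library used
for seed promoters ships with the package). Matching is binary — a window
matches when every base falls in the allowed set of the corresponding
IUPAC code — with all overlapping occurrences counted, matching the
behaviour of occurrence-counting scans with consensus patterns. No PWM or
match score is computed: the downstream statistic consumes counts only.
Scanning is single-strand (the consensus orientation) by default, since
PLACE elements are defined 5′→3′ on their reported strand; `both_strands`
additionally scans the reverse-complemented consensus and doubles the
window count. A sequence N satisfies only the consensus code N, so
hard-masked runs cannot inflate counts.

## Enrichment statistic

With X observed occurrences over W = L − m + 1 scannable windows in a
candidate promoter and a genome-wide per-window rate ρ (total occurrences
over total windows in the full promoter set), the null is X ~ Binomial(W, ρ).
Significance is the one-sided upper tail of the continuity-corrected
normal approximation,

    μ = Wρ,  σ² = Wρ(1 − ρ),  z = (X − μ − 0.5)/σ,  p = Φ̄(z),

and the effect size is log2FC = log2((X + 0.5)/(μ + 0.5)); the 0.5
pseudocounts keep zero-count rows finite while p is computed on raw
counts. Promoters are tested individually and flagged at raw p ≤ 0.1 (no
multiple-testing correction, since the procedure reports element-level
candidates, not a controlled discovery set); a Benjamini–Hochberg column is
included for information. When σ = 0 (ρ = 0 or 1), the test degenerates:
p = 1 when X equals its expectation and 0 when it exceeds it.

An exact binomial upper tail is provided as an independent oracle. The
continuity-corrected normal is accurate but not exact in the skewed
small-rate regime: its worst absolute error against the exact tail is
about 0.021 at μ = 10, decaying roughly as 1/√μ (≈ 0.011 at μ = 40,
< 0.01 from μ ≈ 60), as the characterisation test in the suite measures.
Significance calls at p ≤ 0.1 are nevertheless stable because the gap
concentrates near the distribution centre (p ≈ 0.5), far from the decision
boundary. Under the null the discrete test is conservative (sub-uniform),
so empirical flag rates at α = 0.1 sit at or below ~0.1.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated; its defaults are fixed, not tuning knobs.

**Expression.** One standard-normal latent factor per module per sample;
gene values are offset + a·factor + N(0, σ). Two genes in one module have
true correlation (aᵢaⱼ)/√((aᵢ²+σᵢ²)(aⱼ²+σⱼ²)); negative loadings plant
negative edges. Defaults: 48 samples (a seed-compendium-sized design);
planted edges use unit loadings with σ = 1/3, i.e. true r = 0.9 — strong
co-expression comfortably above the 0.7 cutoff, as expected for SSP genes
under shared developmental control. The default fixture plants TF hub
degrees 5/3/1, one negative edge, five idle TFs and three idle SSPs
(zero loading), and 60 background genes; planted genes sit at a higher
baseline (offset 12 vs 4) so abundance selection retains them, emulating
the strong seed-specific expression of SSP and seed TF genes.

**Promoters.** I.i.d. uniform-composition background bases; motif
instances (uniformly chosen concrete expansions of the consensus) are
inserted at Poisson counts targeting a per-window rate, overwriting the
background and rejecting overlaps so the counting oracle is unambiguous.
The default genome-wide rate is 5·10⁻⁴ per window (the order of magnitude
of a specific 7–10 bp element in real promoter sets); planted genes get
10× that rate, a strong but realistic promoter-level enrichment. Because
background bases are random, chance matches occur on top of insertions at
roughly ∏ᵢ P(base ∈ allowedᵢ) per window (6·10⁻⁵ for a 7-mer at uniform
composition); recovery tests compare against planted + chance, the correct
expectation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: microarray noise models (intensity-dependent
variance, probe effects, batch structure), non-uniform promoter base
composition and CpG/TA islands, positional clustering of elements near the
TATA region, overlap between neighbouring genes' promoters, and
correlation structure richer than one factor per module (e.g. overlapping
regulons). Results on real compendia depend on upstream normalisation,
which this package deliberately leaves to the user.

**Determinism.** All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical spec + seed reproduces outputs
byte-for-byte, and the pipeline manifest records input SHA-256 checksums.

## Problem sizes used in validation

The validation battery (tests and `scripts/acceptance.py`) runs at sizes
chosen to make the statistical assertions sharp while keeping the whole
battery in the order of seconds: 1000 random sequences (50–2000 bp) × 10
elements for scanner-oracle equivalence; 2000 planted pairs (and ~4M null
pairs) at n = 48 for correlation recovery; 2000 null and 200 planted
2000-bp promoters against a 2000-promoter background for enrichment
calibration and power; a (W, ρ, X) grid with μ ≥ 10 for the
normal-vs-exact gap; and a 200-promoter end-to-end fixture for
determinism.

## Known limitations

- The |r| ≥ 0.7 cutoff has no error control; with many TF–SSP pairs some
  null edges are expected at smaller n (at n = 48 the null rate is
  negligible, ~3·10⁻⁹ per pair).
- The enrichment null treats windows as independent Bernoulli trials;
  overlapping windows are positively dependent for self-overlapping
  motifs, making the variance slightly optimistic for such elements.
- Per-promoter tests across many promoters and elements are reported at
  raw p; users scanning large candidate sets should consult the BH column.
- Promoter extraction trusts the annotation's first mRNA; for genes whose
  canonical isoform differs, the window may shift.
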