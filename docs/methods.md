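# Methods

## Scope and model

`mitoscreen` implements an in-silico screen for transcription factors that
regulate an organelle's biogenesis program — the setting it targets is the
identification of transcriptional repressors of mitochondrial biogenesis in
lysosomal storage disease models, where candidates must survive two
independent arms of evidence:

1. **Promoter arm.** The promoters of a focus gene set (e.g. respiratory
   chain / OXPHOS subunits) are scanned for TF binding sites; TF families
   whose sites are unusually prevalent are retained, then individual family
   members with broad coverage.
2. **Activity arm.** A per-gene differential signature (condition vs
   control) is tested for over-representation of each TF's known targets.

The candidate list is the intersection of the two TF lists after motif-name
to gene-symbol translation. Each stage is an importable function; the
orchestrator `run_pipeline` wires them together and writes every
intermediate table plus a manifest.

### Organelle set score

The input is a normalized genes×samples intensity matrix (RMA-style log2
values are unlogged first; normalization itself is out of scope and assumed
done). Each gene is divided by the mean of its control samples, so the
control mean is exactly 1 and per-gene scale factors cancel (the score is
invariant to rescaling any gene's raw values). The per-sample score of an
organelle list is the mean ratio over the list's genes; the reported change
is `mean(condition scores)/mean(control scores) − 1`, printed as a signed
percent (0.75× control → −25%). Significance is a Welch (unequal-variance)
t-test on the per-sample scores, followed by a Bonferroni correction whose
default multiplier is the list's gene count — the reading motivated by the
lists having hundreds of genes. Because the set-level test admits a second
reading (per-gene tests corrected over the list), that alternate statistic
is exposed as `per_gene_significant_fraction`; the per-sample mode is
primary. A per-list Bonferroni mode is also available.

### Differential signature

Two groups are compared per gene with the Welch t-test, three or more with
one-way ANOVA; the signature is genes at raw p < 0.05 with fold change =
condition mean / control mean on intensity scale. No multiple-testing
correction and no fold-change cutoff are applied — this reproduces the
protocol's filter deliberately. Genes with zero variance in every group get
p = 1 and a flag rather than an exception. The Welch statistic is written
out in `stats.welch_t_test` (Welch–Satterthwaite degrees of freedom) and is
cross-checked against `scipy.stats.ttest_ind(equal_var=False)` in the test
suite; ANOVA delegates to `scipy.stats.f_oneway`.

### Promoters

Windows span −`upstream`..−1 and +1..+`downstream` with the TSS at +1 and
no position 0 — with the defaults (500/100) a 600 bp window. Coordinates
are BED-style 0-based half-open externally, 1-based in error messages.
Minus-strand windows are reverse-complemented so every sequence reads
promoter-sense. Windows crossing a contig edge are N-padded to full length
and flagged rather than dropped, keeping promoter counts equal to gene
counts so coverage fractions stay interpretable. Genes with several
annotated TSS must designate one via `transcript_id`; unresolved duplicates
are an error listing the gene.

### PWM scanning

Count matrices are smoothed with a pseudocount of 0.01 per base before
column normalization (avoids log 0 and zero-frequency vetoes). Each
position carries a conservation value
`ci(i) = (100/ln 4)(Σ_b f(i,b) ln f(i,b) + ln 4)` — 0 for a uniform column,
100 for a fully conserved one — and a window scores
`Σ ci·f(i, w_i) / Σ ci·max_b f(i,b)`, so the consensus scores exactly 1.
The core similarity is the same ratio over the 4 consecutive positions with
the largest total conservation (leftmost on ties). Hits require matrix
similarity ≥ 0.85 and core similarity ≥ 0.75; both strands are scanned at
every offset, windows containing N never hit, and hit order is
deterministic (promoter, offset, strand, matrix). These are published-style
conventions for this scorer family; the proprietary tool they stand in for
uses unpublished per-matrix thresholds and family definitions, so family
membership here is taken from the motif file's `FAMILY/NAME` tags and
absolute enrichment p-values are not comparable to that tool's output.

### Family enrichment and member selection

Enrichment counts promoters, not hits: `a` = target promoters with ≥ 1 hit
from any family member, against a user-supplied background promoter set
(the proprietary genome-wide background is unavailable — a documented
deviation affecting absolute p-values). The test is the one-sided (greater)
Fisher exact test on the 2×2 promoter table; a family is enriched only if
p < 0.05 **and** it covers ≥ 85% of target promoters. Within enriched
families, individual matrices are retained at ≥ 50% coverage on their own.

### Regulator over-representation and activation z

For each TF in a signed TF→target network, the one-sided Fisher test asks
whether its targets are over-represented in the signature, with the
universe = genes measured on the platform (the signature's sampling frame),
significant at p < 0.01. The optional activation score
`z = Σ sign(edge)·sign(log FC) / √N` (N = signed edges whose targets are in
the signature; undefined below 3) summarises directional consistency. Sign
convention: an engaged repressor — negative edges, down-regulated targets —
scores **positive** z, because its regulatory program agrees with the data;
z is antisymmetric under a global fold-change flip. This heuristic is a
clearly-labelled simplification of commercial upstream-regulator scoring,
whose internals are unpublished; only the Fisher filter gates candidates by
default, and a direction filter (require z > 0) is available behind a flag
and off by default, since the protocol does not state one.

### Intersection

Motif matrix names are translated to gene symbols through an explicit
two-column map; matching is case-insensitive but never fuzzy, and unmapped
promoter TFs are reported, not dropped. Candidates are ordered by family
then name. Tightening any threshold can only shrink the candidate list
(tested as a monotonicity property).

## Synthetic data: what it emulates and what it does not

The generator produces a planted-truth version of the study design the
screen targets: 6 control vs 6 condition samples; 1000 genes of which a
200-gene "mitochondria" list is repressed to 0.75× control (plus two null
organelle lists of 120 and 80 genes); log-normal baselines
(log2 intensities ~ N(7, 1.5²)) with i.i.d. multiplicative noise
exp(N(0, 0.1²)), matching intensity-scale microarray behaviour; 100 target
and 300 background promoters of 600 bp with a sharp 10-bp motif consensus
embedded in exactly 90% / 10% of them (uniform base composition by default,
to isolate scorer correctness from composition effects; a GC parameter
exists); and a planted repressor with 30 signed targets drawn from the
down-regulated genes at 0.9 sign consistency, next to 5 decoy TFs with
random targets and a decoy motif family. Every generator is a pure
function of (spec, seed) and returns its ground truth.

What it does **not** emulate: probe-level artifacts and normalization,
correlated gene-gene noise, genomic GC/dinucleotide structure, soft or
degenerate motif instances (sites are planted as consensus), overlapping
organelle lists, batch effects. Passing the recovery tests therefore shows
the statistics and bookkeeping are correct under the stated model, not that
real microarray data of this design would give the same power.

## Numerical choices

- Fisher one-sided p via `scipy.stats.fisher_exact(alternative="greater")`;
  validated against exact integer hypergeometric-tail enumeration for all
  2×2 tables with total ≤ 30 (agreement ≲ 1e-15).
- Bonferroni: `min(1, p·m)`.
- Welch p from the t distribution with Welch–Satterthwaite df; both-groups
  zero variance → NaN → mapped to p = 1 (set test and signature filter).
- PWM scan vectorised per promoter via stride tricks; N encoded as a fifth
  row with a large negative weight, clamped so N-containing windows can
  never reach a positive threshold. Scalar and vectorised scorers are
  cross-checked by brute-force enumeration in the tests.
- Core window ties resolved leftmost; consensus ties resolved by base order
  A < C < G < T (deterministic, and "unique maxima" is the tested case).
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from explicit spec/seed values; output tables are byte-identical
  across reruns with the same config and seed (similarities rounded to 6
  decimals in the hits table only for file size, full precision in memory).

## Problem sizes

The test suite and the acceptance report run at the generator's default
scale (1000 genes, 6v6, 100/300 promoters): 20 seeds for score recovery,
200 simulated tests for null calibration, 50 seeds for enrichment and
end-to-end recovery in the suite (20 in the report script), 1000 sign
permutations for z calibration, and full enumeration for the discrete
oracles. These sizes give binomial error bars comfortably inside the
asserted bands while keeping a full run under a minute apiece.

## Known limitations

- Absolute promoter-enrichment p-values depend on the chosen background
  promoter set; only the relative screen logic is portable.
- The Bonferroni family for the set score (genes vs lists) is genuinely
  ambiguous in the protocol; both modes are provided and the per-gene
  multiplier is the default.
- Alias resolution and motif-name translation are frozen input tables, not
  live database lookups, by design (reproducibility).
- No moderated/empirical-Bayes differential testing; fidelity to the raw
  p < 0.05 filter is the point.
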