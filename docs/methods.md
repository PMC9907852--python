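# Methods

## Community model

A virtual microbiome is an `C × S` matrix of relative abundances
(communities × species) plus a three-rank taxonomy. Generation follows
the macroecological laws reported for real microbial communities:

1. **MAD** — per-species mean abundances are lognormal draws
   `Lognormal(mu_mad, sigma_mad)` normalized to sum 1.
2. **AFD** — each species' across-community fluctuation profile is a
   gamma draw `Gamma(shape_afd, scale_afd)` normalized to sum 1. Because
   the profile is normalized, the gamma scale cancels; only the shape
   matters (coefficient of variation `1/sqrt(shape)`).
3. Column `i` of the matrix is `mad_i * afd_i * C`, which makes the mean
   of every column exactly `mad_i` — the column-mean identity that unit
   tests assert to 1e-12.
4. **Taylor's law filter** — the matrix is accepted only if the Pearson
   correlation between `log10` per-species mean and `log10` per-species
   variance (sample variance, ddof = 1, species with zero variance
   excluded) reaches `taylor_r_min = 0.95`. Correlation is computed in
   log–log space because the law is a power law; in linear space the
   largest species would dominate. The filter is applied to the raw
   matrix of step 3; accepted matrices are then row-renormalized to
   relative abundances for all downstream use. With fewer than three
   communities variance is meaningless; the filter is skipped and flagged.
5. **Goodness of fit** — one-sample Kolmogorov–Smirnov tests compare the
   raw (pre-normalization) lognormal and gamma draws against their
   generating laws at `alpha = 0.01`; a rejection triggers a redraw. The
   rejection loop is bounded (`max_attempts = 1000`, configurable) and
   reports the failed criterion on exhaustion. Since the draws really do
   come from the tested laws, the loop rejects ~2–4% of attempts (two
   1%-level tests plus Taylor), so the expected attempt count is ~1.03.

Species are grouped into genera, and genera into families, by drawing
lognormal weights per parent, converting them to integer group sizes with
largest-remainder rounding, and repairing empty groups by moving one child
from the currently largest group. Largest-remainder ties go to the lower
index (stable sort) — every such tie-break in the package is deterministic
for reproducibility.

Diversity summaries: Shannon index `H = −Σ p ln p` (nats) per community;
beta diversity is the mean pairwise Bray–Curtis dissimilarity (scipy
`pdist`); a microbiome is classed high-diversity when its mean `H`
exceeds `ln(S)/2`, a configurable midpoint convention.

**Parameter defaults.** `n_species = 300` and `n_families = 8` are the
study conditions the benchmark is designed around. The remaining shape
parameters are modelling choices: `n_genera = 40` gives realistic
multi-species genera under lognormal grouping; `mu_mad = 0` (location is
irrelevant after normalization); `sigma_mad = 1.5` spreads mean abundances
over ~3 orders of magnitude, typical of moderately uneven communities and
wide enough that the Taylor correlation is comfortably above the filter
(~0.99); `shape_afd = 2` gives fluctuation CV ≈ 0.71; `n_communities =
20` balances variance estimation against run time.

**Paired communities.** `perturb_abundances` multiplies a chosen fraction
of species (count rounded half-up) by `2^(±effect_log2)` with random
signs, renormalizes, and records each species' pre-normalization trend
(up/down/unchanged). The recorded trends are the ground truth for
trend-detection scoring; renormalization means other species' *observed*
relative abundances shift too, which is exactly the compositional
confound real studies face.

## Reference universe

Real reference databases cannot ship with a test suite, so the package
synthesizes a complete universe with controlled structure: one random
root 16S sequence (default 1,500 bp), family ancestors mutated from it,
genus ancestors from those, species sequences from those — independent
per-site substitutions at rates 0.25 / 0.10 / 0.02 per step. No indels
are introduced, keeping primer offsets and amplicon coordinates exact.
The rates were chosen so that 31-mers separate species while same-family
sequences stay similar enough to produce cross-matches once a species is
deleted from the database — the mechanism by which incomplete references
generate false positives. Genome records (default 100 kb) embed the
species' 16S gene in uniform-random flanking sequence.

Primer sites (one concrete realization of the degenerate V3–V4 pair,
shared by the whole universe) are masked from divergence mutations,
mirroring conserved priming regions. A fraction `primer_fail_prob = 0.10`
of species instead carries three substitutions at non-degenerate forward
primer positions, guaranteeing amplification failure at any mismatch
tolerance below 3 — this emulates the non-trivial primer failure rate of
real degenerate primers.

What the universe does *not* emulate: phylogenetically realistic
evolution (no substitution-rate matrices, no rate heterogeneity, no
indels), horizontal transfer, intra-genomic 16S copy variation, or real
database redundancy (`records_per_species` defaults to 1). Passing tests
therefore demonstrate correctness of the benchmark machinery and the
directional effects of database incompleteness, not quantitative accuracy
for any real clade.

## Read simulation

Allocation is largest-remainder on `abundance × total_reads` — exact,
deterministic conservation of the requested depth, which is counted in
read *pairs*. A multinomial option models sampling noise and is used for
the dominated-community sampling-loss experiment.

In-silico PCR honours IUPAC degeneracy on the primer side only: a
sequence base matches iff it is a member of the primer symbol's base set
(so `N` in the sequence matches only a primer `N`). The 5'-most forward
hit and the nearest downstream reverse-complemented reverse hit bracket
the amplicon (0-based, half-open, primers included). Mismatch tolerance
defaults to 0 and is exposed because the failure rate depends on it.
Reads of species with no amplifiable record are redistributed over
amplifiable species proportionally to abundance (largest-remainder),
conserving total depth.

Fragments: insert length `Normal(mean, sd)` clamped to
`[read_length, region_length]` (clamping rather than resampling —
deterministic and simple); start uniform; strand fixed forward when
unidirectional. Mate 1 is the fragment's 5' end, mate 2 the reverse
complement of its 3' end, so a 550 bp insert with 300 bp reads overlaps
by exactly 50 bp and a 400 bp insert with 150 bp reads leaves a 100 bp
inner gap.

The error model applies per-position error probability
`p(i) = (a + b·i⁴)/100` at 1-based cycle `i`, clamped to [0, 1], with
`a = 3e-3`, `b = 3.3e-8` — the coefficients are conventionally quoted as
percentages, which is how they are interpreted here (read literally as
probabilities the polynomial saturates by cycle ~74 of a 300 bp read).
Even in percent the tail of a 300 bp read is heavily degraded (~113
expected errors per read), an intentional feature of extrapolating a
100 bp-era polynomial to 300 bp reads. Errors are substitutions /
insertions / deletions at 80/10/10 (configurable); substituted and
inserted bases get quality Q10, everything else Q30; reads are re-trimmed
or padded with random Q10 bases to the configured length after indels.
FASTQ output is Phred+33 with truth labels carried in read IDs
(`pair#####|species|record`), so truth survives a round trip through
files.

## Classification

The built-in classifier indexes canonical k-mers (lexicographic minimum
of k-mer and reverse complement, k = 31 by default) of every record and
assigns each pair to the species with the most distinct k-mer hits over
both mates, requiring `min_hits = 10` and a strict lead over the
runner-up; ties collapse to the lowest common ancestor (genus, then
family, then unclassified). It is deliberately naive — the benchmark's
claims concern the harness, not any particular profiler — and external
profiler outputs can be imported instead (generic TSV or kraken2-style
reports, direct counts at species/genus/family). Imported profiles are
normalized over classified rows and otherwise trusted as-is.

Profiles at genus/family rank include reads assigned at that rank plus
reads assigned deeper (union semantics); shallower assignments cannot be
placed and are skipped.

## Metrics

Denominators are deliberately different and never mixed: unsampled and
true positives are fractions of the *truth* set, unidentified of the
*sampled* set, false positives of the *detected* set. "Below the
detection threshold" is operationalized as zero allocated reads
(`min_reads` configurable). A detected taxon counts as a true positive by
set membership even if its supporting reads came from another taxon —
the definitions are set-based, not provenance-based.

The abundance error `D = (1/N) Σ (ã−a)/a` is evaluated over taxa that are
both detected and truly present: false positives have `a = 0` and the
formula is undefined on them, so the evaluated set is `detected ∩ truth`
with `N` its size (`None` when empty, never a fake zero). Trend
comparison aligns taxon universes on their union (absent = 0), calls a
change when the after/before ratio exceeds `min_fold` (default 1.0 — any
change counts, magnitude ignored), and reports the share of true changes
recovered with the right sign and the share of reported changes that are
spurious. Method overlap uses the union of the two detected sets as
denominator (the alternative single-method denominators are available via
a flag) and separately reports how much of the intersection is absent
from the truth.

Under the oracle condition — complete database, zero-error reads,
mutually distinguishable references — every sampled taxon and nothing
else is detected, so unidentified = 0, FP = 0, TP = 100 − unsampled
exactly, and D is read-rounding noise. With the default universe's 10%
primer-failure rate, amplicon redistribution concentrates reads on
amplifiable species, so detected abundances are inflated relative to
truth and D is positive by construction; the D ≈ 0 identity therefore
holds on a failure-free universe.

## Orchestration and problem sizes

`run_benchmark` expands scenario names (complete; DB1/DB2/DB3 = half the
families/genera/species deleted; repr50/repr25 = family subsets retaining
~50%/25% of community abundance, 2 and 4 variants enumerated by subset
search) into databases per marker, simulates both modes at the configured
depths, classifies, scores, and writes per-cell JSON/TSV reports, a long
summary table, cross-mode overlap statistics, and a provenance record
(config hash + seed). One master seed spawns per-stage child seeds, so
any stage can be rerun in isolation and full reruns are byte-identical.

Default depths mirror the benchmark grid (amplicon 100,000/50,000 pairs,
WGS 60,000/20,000). The test suite and acceptance script run reduced
sizes chosen as this package's own verification scale — communities of
16–60 species, genomes of 2–20 kb, depths of 200–20,000 pairs (plus one
full 100,000-pair amplicon simulation) — because the pure-Python k-mer
classifier is the bottleneck and the properties under test are
scale-free: conservation laws, set identities, and distributional
statements hold at any size.

## Known limitations

- The classifier is exact-match k-mer voting; it under-detects at high
  error rates where real profilers use minimizers, spaced seeds or
  alignment. Comparative statements about real tools require importing
  their outputs.
- Abundance estimates are read-count fractions; no correction for genome
  length or 16S copy number is applied in WGS mode (uniform choice among
  a species' records; flagged rather than length-normalized).
- The universe's substitution-only divergence makes within-species
  records more homogeneous than real deposited sequences.
- Representation scenarios search family subsets exhaustively only up to
  20 families (greedy beyond); with few families the achievable fractions
  can sit far from the nominal 50%/25% targets, and the manifest records
  the achieved value.
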