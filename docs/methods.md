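# Methods

This note documents the models and procedures `linctools` implements, the
defaults it ships, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the underlying methods
left the choice open.

## Discovery cascade

The cascade is a fixed-order sequence of elimination filters over
assembled transcripts. Order matters only for the per-stage accounting;
the final retained *set* is invariant to reordering of the independent
predicates (the test suite asserts this for the coding-potential and
gene-proximity stages). The `FilterLedger` enforces two conservation
invariants — per stage, input = removed + retained; across stages, each
input equals the previous retained — so any bookkeeping error fails
loudly rather than silently shifting counts.

Parameters (all configurable; defaults are the standard thresholds for
this kind of survey):

| parameter | default | meaning |
|---|---|---|
| `min_length` | 200 nt | retain spliced length strictly > 200 (a 200-nt transcript is removed) |
| `max_orf` | 300 nt | retain longest ORF ≤ 300; ORF length counts the stop codon |
| `evalue_cutoff` | 1e-3 | protein and domain hits at e ≤ cutoff remove the transcript |
| `cpc_threshold` | 0 | coding-potential score > 0 removes; exactly 0 is retained |
| `flank_window` | 500 nt | genomic gap ≤ 500 to any coding gene removes; overlap counts as gap 0; strand-agnostic |

ORF scanning: an ORF is ATG…first in-frame stop; open-ended stretches
(no stop before the transcript end) are not counted by default
(configurable), which keeps the statistic deterministic and conservative.
Codons containing `N` never match ATG or a stop. Transcripts with known
strand are scanned in 3 sense frames; unstranded transcripts (common for
single-exon intergenic assemblies) in all 6, so an antisense ORF cannot
leak through. Ties among equal-length ORFs resolve to the sense strand,
then the 5′-most start.

Homology, domain and coding-potential evidence are consumed as
tab-delimited tables rather than by invoking the upstream search tools;
this keeps the cascade deterministic and lets the same code run on any
organism's evidence. Missing protein/domain entries mean "no hit"; a
missing coding-potential score is an error (the score is defined for
every transcript, unlike a hit).

Survivor identifiers (`Ca_linc_0001`…) are assigned in (chromosome,
start, transcript id) order — the ordering is not semantically meaningful,
only reproducible.

## Tissue-specificity index

TSI (tau) = Σᵢ(1 − xᵢ/x_max)/(N−1) over N ≥ 2 tissues. It is
scale-invariant, lies in [0,1], and is monotone non-increasing in any
non-maximal component. An all-zero vector leaves tau undefined; such rows
are flagged and excluded from specificity calls rather than treated as
specific or housekeeping. Ties for the maximal tissue resolve to the
first column. The specificity call threshold is TSI ≥ 0.9; stage-specific
calls use on ≥ 3 FPKM within the target tissues and ≤ 0.1 FPKM
everywhere else.

The five expression classes are bounded by 2 and 20 FPKM at the extremes;
the interior boundaries (5, 10) follow conventional FPKM binning and are
configurable, since only the outer bounds are fixed by the class scheme.
"Expressed in a tissue" uses FPKM ≥ 1 by default; the cutoff is exposed
because per-tissue expressed counts are meaningless without it.

Spearman co-expression uses average ranks (tie-corrected), equivalent to
Pearson on ranks; zero-variance rows yield undefined ρ, which is reported
as 0 with the row id flagged — auditable, never silently dropped.

## Bicolor network and propagation

Candidate pairs for the co-expression percentile cut are lincRNA–mRNA and
mRNA–mRNA pairs (lincRNA–lincRNA pairs excluded by default; configurable).
The threshold is the (100 − p)-th percentile of |ρ| with p = 0.5 at study
scale; kept edges are weighted |ρ|. PPI scores are min–max normalized to
[0,1] on load; where a pair carries both a co-expression and a PPI weight
the maximum is used (mean available as an option) so weights stay in
[0,1]. PPI edges touching a lincRNA node are rejected as input errors.

Propagation iterates F ← αW′F + (1−α)Y from F = Y with
W′ = D^(−1/2)WD^(−1/2) (isolated nodes get zero rows). Symmetric degree
normalization bounds the spectral radius of αW′ below 1 for α < 1, so
convergence is guaranteed; the implementation still caps at 1000
iterations and reports a convergence flag rather than failing silently.
Defaults: α = 0.8 (standard for diffusion methods of this family — the
method itself does not pin a value), L1 tolerance 1e−6. The iterative
solution equals the closed form (1−α)(I−αW′)⁻¹Y; the test suite checks
this equivalence on every network ≤ 200 nodes.

Per GO term, lincRNAs are ranked by score (ties by node id) and the top
100 with strictly positive score inherit the term. The positivity guard
is a deliberate choice: without it, disconnected lincRNAs could be
"annotated" purely by rank padding. First-degree neighbour annotation
(union of adjacent mRNAs' terms) is recorded separately as the seed-level
annotation.

Enrichment: hypergeometric upper tail P(X ≥ k) with parameters
(N population, K term carriers, n study size), BH-adjusted, significance
threshold 1e−10 (the conventional reading of the "e−10" shorthand).

## miRNA target scoring

The expectation score is the additive penalty of the best antiparallel
miRNA–target alignment: match 0, G:U wobble 0.5, mismatch 1.0, bulge 2.0,
all doubled at miRNA positions 2–13 from the 5′ end (the seed). These
constants follow the plant target-prediction convention of the commonly
used web scorer; only the reporting cutoffs (expectation ≤ 3, UPE ≤ 25)
are fixed by the workflow itself, so all constants are configurable. At
most one single-nucleotide bulge per duplex, on either strand — this
bounds the scan at O(miRNA length × transcript length) per pair and
matches the near-perfect complementarity regime plant miRNAs operate in.
The whole-transcript scanner is a vectorized anti-diagonal formulation
of the same arithmetic; a test asserts exact equality against per-window
scoring at every placement. Target-site accessibility (UPE) requires RNA
folding and is therefore consumed from an optional precomputed table;
when absent the filter is skipped with a logged notice.

Overlapping hits of one (lincRNA, miRNA) pair are collapsed: lowest
expectation wins (then the 5′-most site); non-overlapping extra sites are
kept as secondary records but the interaction network counts distinct
pairs only. Component patterns are classified in the miRNA → lincRNA
direction (one miRNA, many lincRNAs = one-to-many).

## Synthetic data: what it does and does not show

The generator emulates, at desk scale, the structure of a multi-tissue
plant lincRNA study: a two-chromosome genome with 40 coding genes; 85
assembled transcripts covering every cascade category (30 clean lincRNAs
with AU-rich composition and mean length ≈ 615 nt, single-exon biased with
mean exon count ≈ 1.2; 10 short; 10 with planted exact-length ORFs > 300;
6 + 2 with homology evidence; 5 scored coding; 7 placed within 500 nt of
a gene; 15 gene-overlapping non-`u`); an 11-tissue FPKM matrix with
planted tissue-specific, housekeeping, co-regulated-module and very-low
background profiles under multiplicative lognormal noise (CV 20%); three
GO modules with dense intra-module PPI; and 21-nt miRNAs with binding
sites built by exact penalty arithmetic at designed expectations
(0, 0, 0.5, 2.0, 3.0, 3.5) — construction is verified by re-scoring, so
recovery tests are exact rather than stochastic.

Two thresholds are scaled to fixture size, because their study-scale
values are meaningless on 30 lincRNAs: the co-expression percentile cut
(5% instead of 0.5%; the fixture pair universe is ~4×10³ pairs against
~10⁷ at study scale) and the per-term annotation rank cutoff
(min(100, ⌈0.05·n⌉)). The production defaults are unchanged.

What passing these tests shows: the filters, scores and rankings compute
exactly what they claim, with correct boundary behaviour, and the
workflow recovers planted structure under calibrated noise. What it does
not show: robustness to assembly artifacts, fragmented transcripts,
mis-mapped multi-reads, batch effects between libraries, or GO-annotation
incompleteness — none of which the generator simulates.

## Numerical choices and degenerate inputs

- Min–max normalization of a constant vector maps to all zeros (not NaN).
- Percentile edge selection with all-equal |ρ| keeps every pair (the
  threshold equals the common value); fewer than 200 candidate pairs
  triggers an instability warning but still computes.
- BH-adjusted p-values are clamped to be ≥ the raw p (guards a 1-ulp
  float artifact of the running-minimum formulation).
- Hypergeometric null calibration is checked one-sidedly (no excess of
  small p): discrete p-values are super-uniform by construction, so a
  two-sided uniformity test would reject any exact discrete test.
- The dinucleotide shuffle used for negative controls is an Eulerian-walk
  shuffle with bounded retries; it preserves the exact dinucleotide
  composition of the input.
- Empty inputs: an empty transcript set produces an empty ledger (all
  stages zero); an empty study set for enrichment and an empty expression
  vector for tau are errors, not silent zeros.

## Known limitations

- The ORF filter's open-ended ORFs default to "not an ORF"; genuinely
  truncated assemblies with long partial ORFs therefore pass the ORF
  stage and must be caught by the homology/coding-potential stages.
- Propagation treats the GO terms independently (no DAG structure); a
  term's parents are neither propagated nor deduplicated.
- The bulge model allows one unpaired nucleotide per duplex; longer
  asymmetric loops found by full dynamic-programming aligners are out of
  scope.
- FPKM is taken as given; no normalization across libraries is performed.
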