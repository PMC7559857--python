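# Methods

## The problem and the model

Metagenomic annotation of assembled virome contigs is a two-dimensional
judgement, not a yes/no lookup. Every retained database hit carries a
percent identity (matching positions over aligned columns) and a query
coverage (aligned query span over contig length). Confidently annotated
taxa sit in the high-coverage, high-identity corner of that plane;
largely novel genomes that merely contain a conserved protein-coding
stretch appear with high *local* identity but low coverage. `virofit`
operationalises that judgement as a strict coverage boundary (default
60%): a taxon cluster is `high_confidence` iff its mean query coverage
exceeds the boundary, otherwise `novel`. The strictness makes ">60%" and
"0–60%" an exact partition; the boundary is configurable
(`coverage_boundary`).

The pipeline around it follows standard virome practice: per-contig hit
lists are filtered (e-value ≤ `evalue_max` = 1e-5; top `top_hits` = 25
per query by bitscore, ties broken by subject id; contigs ≥
`min_contig_len` = 500 nt; subjects significant in a no-template control
removed), assigned to a taxon by best hit (bitscore → e-value → tax id
tie-break) or by the lowest common ancestor of all hits scoring within
`lca_score_window` = 10% of the top bitscore, then clustered by taxon id
with unweighted mean identity/coverage. Abundance is RPKM per contig and
the unweighted mean of member-contig RPKMs per taxon; the depth
denominator is the per-sample total of reads mapped to any contig
(raw-read totals are not available to the pipeline and would differ only
by a per-sample constant).

Two deliberate rule choices are worth flagging:

* **Control-hit exclusion is applied to the *filtered* control table.**
  A no-template control's raw search output contains the same weak,
  insignificant matches as any other query's; excluding every subject it
  merely touches would blacklist genuine reference sequences. Only
  control hits passing the standard e-value/top-N filter define
  contaminant subjects.
* **Broad-category taxa** ("uncultured virus" and kin) are flagged, not
  dropped, at clustering time: richness summaries exclude them by
  default, while the confidence analysis retains them — a low-coverage
  hit to an uncultured virus still carries similarity information.

## Enrichment testing

Whether the novel class is enriched in a taxon set (CRESS-DNA families
in the motivating study) is a 2×2 Pearson chi-square test of
independence, df = 1, no continuity correction by default (Yates
available as an option). The statistic is Σ(O−E)²/E with expectations
from the margins; the p-value is the df-1 survival function. Class
fractions are reported both per taxon and RPKM-weighted, because "the
fraction of CRESS hits" is ambiguous between the two and they can
disagree.

## Calibration (mutation drift)

A model sequence of known taxon is mutated at each rate r in a grid
(default 0.1–0.5), `reps` = 30 independent replicates per rate, and
searched against a labelled database. The mutation operator substitutes
exactly `round(r·L)` distinct positions with a different base, so the
position-wise identity to the source is 100·(1−r) *by construction* —
this is reported as `mean_source_identity`. The aligner's
`mean_best_identity` agrees with it at low rates but exceeds it beyond
r ≈ 0.25, because Smith–Waterman trims mismatch-rich ends and keeps the
best-scoring core. That divergence is not an artefact to be corrected:
it *is* the phenomenon the goodness-of-assignment analysis detects
(deceptively high identity over a shrinking fraction of the query).

A best hit is a misassignment when it shares no ancestor with the true
taxon at or below `related_rank` (default family; the motivating
observations were cross-kingdom, so family is conservative). A replicate
with no hit at all also counts as misassigned. On synthetic databases
the misassignment fraction rises with rate and misassigned hits have
lower median query coverage than correct ones; the rate at which drift
sets in depends on the database and is treated as qualitative, not as a
portable constant.

## Alignment engine

Local and global alignment run on `Bio.Align.PairwiseAligner` with
affine gaps; defaults are megablast-like (match +2, mismatch −3, gap
open −5, gap extend −2; `gap_open` is the score of the first gap column).
Identity counts matches over aligned columns including gaps; coverage is
the aligned query span over query length. Database search is exhaustive
by default — correct at desk scale — with an optional exact shared-k-mer
prescreen (BLAST-like seeding; the pool simulator uses k = 13) that
skips subjects sharing no word with the query. Bitscores and e-values
for generated hit tables come from a Karlin–Altschul-style transform of
the raw score with nominal blastn-like constants (λ = 0.625, K = 0.41);
only their ordering and rough scale matter downstream. Because traceback
among co-optimal global alignments is direction-dependent, genome
identity canonicalises the argument order, making it symmetric exactly.

## Genome-level procedures

* **Circularity**: the longest k < L/2 with prefix(k) = suffix(k),
  exact match only (the motivating observation was an *identical*
  terminal repeat); circular if k ≥ `min_terminal_repeat` = 20 nt, and
  the duplicated suffix is trimmed so re-appending prefix(k) reproduces
  the input. A mismatch-tolerant mode is deliberately not default.
* **Species demarcation**: identity < `demarcation_identity` = 75%
  (strict) ⇒ distinct species; at or above ⇒ variant. A genome at 78%
  identity to its reference is therefore a variant.
* **Circular genome identity**: the rotation register is fixed before
  global alignment by a shared 15-mer vote (each shared word votes for
  the offset superposing its occurrences; most votes wins, ties to the
  smaller offset). An exhaustive-rotation mode exists behind a flag for
  small genomes; the vote is the default because a full rotation scan is
  quadratic in genome length for no practical gain.
* **In-silico PCR**: exact primer matches only (the motivating assays
  were Sanger-validated; mismatch/degenerate binding is out of scope).
  Forward primer on the plus strand, reverse primer's reverse complement
  downstream within `max_amplicon`; product length runs 5'-to-5'
  inclusive; circular templates wrap across the origin, making the
  product set rotation-invariant.

## Synthetic data: what it emulates and what it does not

The generator's default design is a four-pool study shaped like the
motivating survey: pools AUT_01/AUT_02 (one environment) share 8 planted
taxa, BRB_ae/BRB_cp (another) share 4, one taxon bridges AUT_01 and
BRB_cp; 20 taxa per pool (union 67); host groups dominated by
mosquito-associated viruses with phage, bat, mammal, plant and other
groups in fixed proportions; ~45% of taxa novel-class; CRESS-like
families drawn with probability 0.65 for novel slots vs 0.35 for
high-confidence slots (the planted enrichment); 3 circular genomes with
exact terminal repeats of 50–200 nt; 3 contaminant subjects planted in
both sample and control tables; 2 broad-category taxa; 2 sub-500-nt
decoy contigs per pool.

Reference genomes (2–3 kb, uniform base composition) are related within
families: a family ancestor, genus ancestors at 12% divergence, species
at a further 8%, so congeners exist and best-hit vs LCA assignment is a
real decision. High-confidence contigs are long, mildly diverged
fragments (identity ~N(92, 3), coverage ~N(85, 7) clipped above 66);
novel contigs are a short mutated island (identity ~N(85, 4)) inside
random flanks (coverage ~N(28, 10) clipped below 52). Island mutations
are resampled at the same rate until a ≥20 nt conserved run survives —
real homologous islands are locally conserved, and this keeps every
planted contig discoverable by word-seeded search. Read counts are
negative binomial (mean 200, dispersion 2). Hit tables are produced by
genuinely searching each contig against the reference database, so they
contain congener hits, flank-extended alignments and spurious weak
matches, exactly like real tabular output.

The generator audits itself: each planted contig is re-aligned to its
source genome and its realized coverage checked against its planted
class.

What passing tests on these data do **not** show: behaviour under
assembly fragmentation or chimerism, sequencing error models,
amplification bias, real taxonomies (four ranks here, deep and ragged in
reality), protein-space search, or databases at NCBI-nt scale — in
particular, absolute drift thresholds measured on the synthetic database
do not transfer to real searches.

## Numerical and degenerate-input choices

Coverage uses the single best-hit HSP span (clustering operates on best
hits; multi-HSP union is a documented non-default). Ties are broken
deterministically everywhere (bitscore → e-value → tax id for best hit;
subject id in ranking; smallest offset in the rotation vote), so every
stage is byte-identical under a fixed seed. Empty hit lists yield an
`unassigned` sentinel, not an error; zero-scoring alignments return
empty results; a zero margin in the 2×2 table, zero mapped reads in a
sample, and infeasible designs (shared taxa exceeding pool size) raise
typed errors. Percentages are reported on [0, 100].

## Problem sizes

Default test and acceptance runs use the four-pool design above
(~100 contigs against ~90 genomes of 2–3 kb, word-seeded), a calibration
grid of six rates × 30 replicates of a 100-nt model against a 20-species
database (exhaustive search), 200 random pairs (≤80 nt) for the
alignment oracle, and 100 replicates for the enrichment power check —
sizes at which exhaustive dynamic programming and exact recovery checks
are comfortable on a single CPU.
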