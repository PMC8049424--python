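# Methods

This note documents the models, conventions and design choices behind
`jointprofiler`, in the spirit of a statistical-software methods appendix.

## Coordinate and format conventions

All internal intervals are 0-based half-open. SAM POS (1-based) and tabular
protein-alignment coordinates (1-based inclusive, amino acids) are converted
at the I/O boundary and nowhere else. FASTA sequences are uppercased and any
character outside {A,C,G,T,N} becomes N. SAM parsing goes through pysam;
unmapped, secondary (0x100) and supplementary (0x800) records are discarded,
the reference-consumed interval is derived from the CIGAR (M/D/N/=/X), and a
CIGAR running past the @SQ length is a format error. The protein-alignment
dialect is the 12-column tabular format (qseqid sseqid pident length mismatch
gapopen qstart qend sstart send evalue bitscore) with the subject length
taken from an optional 13th `slen` column or a two-column side table; the
subject length is mandatory because the coverage filter is defined on it.

## Contig taxonomy

A contig inherits the taxon of its best assignment. Ambiguity is judged at
contig level on exact score ties: a contig is kept iff exactly one taxon
attains its maximum score (classifier scores are integers in practice, so
exact equality is the right tie test). Tied contigs are excluded by default;
`tie_policy="lca"` resolves them to the lowest common ancestor instead.
Contigs with no assignment at all are retained and labelled `unclassified`
at every rank, so their read mass still contributes to per-sample totals;
they can be dropped with `keep_unassigned=False`. Lineage labels at a
requested rank walk the parent chain of a 4-column taxonomy table
(taxon, parent, rank, name); a walk that reaches the root without meeting
the rank yields `unclassified`.

## Gene annotation

ORF detection scans all six frames with prokaryotic conventions: start
codons {ATG, GTG, TTG}, stops {TAA, TAG, TGA}, translation table 11,
`min_codons` 30 by default. Within each stop-bounded frame segment the first
start codon opens the (maximal) ORF. Assemblies truncate genes at contig
edges, so edge segments are also reported and flagged partial — but only
when anchored by at least one signal: a 5'-truncated ORF must end at a stop,
a 3'-truncated ORF must begin at a start codon. Frame segments with neither
signal are noise, not ORFs. Translation is vectorised over codon indices
with the code table taken from Biopython; any codon containing N translates
to X (partial ambiguity such as ACN is deliberately not resolved).

Protein alignments are filtered on *subject* coverage,
(send − sstart + 1) / subject_len ≥ 0.8 by default — the filter guards
against fragmentary hits to the database protein, so the database side is
the right denominator. Per ORF a single best alignment survives (bitscore,
then percent identity, then lexicographically smallest subject id for
determinism), and its query interval is projected to contig nucleotides
respecting strand: one gene per ORF, no per-domain multi-assignment.

## Abundance model

Let a joint feature be a (taxon label, gene id) pair within one sample, with
gene regions r₁…r_k on the taxon's contigs (one region per gene copy).
A fragment (read-pair template) counts toward a region if any of its mate
intervals overlaps it by ≥ 1 base; aligned bases are the per-base overlap of
all mates clipped to the region. Fragments overlapping two regions count for
both — the simplest rule consistent with counting reads located in genes.

- **mean depth** (default, "dosage"): Σᵢ basesᵢ/lenᵢ — the sum of per-copy
  depths. Under uniform c-fold coverage a k-copy gene scores c·k, which is
  what a true abundance defined as coverage × copy number requires, and what
  makes depth-per-genome equal copies per genome. The pooled alternative
  Σbases/Σlen estimates per-copy depth (≈ c regardless of k) and is exposed
  as `depth_mode="pooled"` for users who want coverage rather than dosage.
- **FPKM**: count × 10⁹ / (Σlen × total mapped fragments), with the total
  counted as distinct fragment ids passing the SAM filters.
- **depth per genome**: feature mean depth divided by the taxon's
  genome-wide mean depth (total aligned bases on its contigs / their total
  length). Undefined (reported absent) when the taxon has no aligned bases.

Zero-abundance features are emitted so tables align across samples
(`drop_zeros` disables this). Output order is deterministic (taxon, gene).
Rank aggregation operates on profile-level inputs because depth statistics
must be pooled from bases and lengths, not averaged from finished tables;
counts, bases, lengths, dosage depth and FPKM are all additive under
aggregation, and total fragment counts are conserved.

## Two-group comparison

log2 fold change uses a pseudocount of half the smallest positive table
value (fallback 1e-6) to stay finite at zeros. The default test is the
two-sided Wilcoxon rank-sum with normal approximation and tie correction —
robust for skewed, zero-inflated abundances; Welch's t is available. A
feature whose observations are all identical carries no evidence and is
assigned p = 1. Benjamini–Hochberg q-values are reported alongside raw
p-values. No compositional transform is applied; that is out of scope.

## Outcome prediction

A random forest with 500 trees (scikit-learn, fixed `random_state`)
evaluated by leave-one-out cross-validation; accuracy is the exact fraction
of correctly predicted held-out samples, and ties in the ensemble vote
resolve to the lower class label, keeping runs deterministic per seed.
Variable importances come from a full-data fit (impurity-based by default,
permutation importances optional), min–max rescaled to [0, 100] so the top
feature scores 100; features above 50 are reported as candidate biomarkers.
Known limitation: with very few samples (n ≈ 12) and many continuous noise
features, chance-separating noise features dilute the forest vote, and even
a perfectly separating feature may be predicted imperfectly; biomarker
screens at this n should keep feature sets small or pre-filter.

## Heatmap

One HTML table cell per (feature, sample); the cell colour interpolates
linearly between red `#d73027` (minimum) and green `#1a9850` (maximum) after
a log1p transform (abundances are right-skewed; `linear` available). An
all-equal matrix maps to the midpoint colour. The output is a single
self-contained HTML string built with the standard library — no external
assets, no JavaScript.

## Synthetic communities and what they do (not) show

The generator plants a shared pool of synthetic KO-style genes into random
ACGT genomes: each gene is one fixed 900-bp cassette (ATG + 298 stop-free
sense codons + TAA, identical across its copies), inserted at disjoint
positions on random strands with uniformly partitioned gaps. Each genome
carries every pool gene at a copy number drawn uniformly from the configured
range, giving an exact truth table: true abundance = coverage × copy number.
Default study conditions: 20 species × 300 kb genomes, 50 genes at 1–5
copies, paired 100-bp reads from fragments of size Normal(200, 50) clipped
to [read length, 3 × mean], at uniform 10X coverage, error-free, seed 42.

Fragments are emitted pre-aligned as SAM records carrying their true
coordinates, so no assembler or aligner runs anywhere in the test path and
every fixture is byte-reproducible from its seed. Fragment starts are
stratified-uniform (one uniform draw per equal-width bin): marginally
uniform, but with the low-discrepancy evenness that "uniform coverage"
denotes for an idealised error-free experiment. Substitution errors (when
enabled) alter read sequences, never positions. "Assembly" can be emulated
by splitting genomes into several contigs at breakpoints chosen inside
inter-gene gaps, so cassettes are never cut.

Annotation inputs are synthesized rather than computed by external tools:
every contig is assigned its true taxon at score 100 (a configurable
fraction receives a second tied row to exercise the ambiguity filter), and
each planted cassette yields one 13-column protein alignment at identity 100
and subject coverage 1.0, addressed to the ORF that hosts the cassette.

What passing tests therefore show: the counting, normalisation and
aggregation machinery is exact under known truth, and the downstream modules
produce correct statistics on well-formed tables. What they do not show:
robustness to assembly fragmentation through genes, chimeric contigs,
classifier error, homology-driven mis-annotation, non-uniform coverage
(GC bias, edge effects) or real error profiles — all properties of the
upstream tools this package deliberately does not run.

## Benchmark sizes and numerical choices

The headline benchmark (tests and `scripts/acceptance.py`) uses the default
community above: 1,000 (taxon, gene) pairs, ≈ 30 Mb of genome, ≈ 300k
fragments, completing in well under a minute on one CPU; the Pearson
correlation between truth and estimated mean depth rounds to 1.000, and
depth per genome recovers every planted copy number within ±0.2. Ties in
assignment scores are exact float comparisons; BH q-values use statsmodels;
forests use scikit-learn defaults apart from `n_estimators` and
`random_state`. TSV floats are written at 6 significant digits, which bounds
round-trip error at ~1e-6 relative.
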