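# Methods

## The problem this package models

Nested retrotransposon insertions leave a recognisable signature in repeat
annotations: an endogenous retrovirus (ERV) that inserted into, or
recombined with, a LINE produces a **trinomial recombination product** —
two fragments of one LINE family flanking an LTR of the ERV in immediate
succession (for the bovine lineage: RTE-BovB / BTLTR1 / RTE-BovB, often
called BovLTRBov). In a domesticated/wild species pair sharing a conserved
syntenic gene block, these products and the mature miRNAs they harbour can
be compared directly: detect the clusters in each species, measure their
identities, extract the conserved consensus of the homologous regions, scan
a mature-miRNA database against each species' consensus, and compare the
two hit sets.

The pipeline stages are: detect → genomic context → region extraction →
identity matrices → star MSA + conserved window (per species) → miRNA scan
(per species) → species comparison. Every number in the emitted reports is
re-derivable by calling the owning module directly; the orchestration layer
adds no arithmetic of its own.

## Conventions

* **Coordinates** are 1-based and inclusive on both ends everywhere
  (`length = end − start + 1`). BED12 input is converted at the boundary.
  The packaged tables of the 12-gene block (cattle bosTau7 and bison
  Bison_UMD1.0 coordinates) verify this convention: every start/end pair
  reproduces its printed length cell.
* **Strand** uses the RepeatMasker vocabulary `{+, C}`; `-`/`Complement`
  normalise to `C` on read.
* **Alphabet**: sequences are normalised to `{A,C,G,T,N}` at read time
  (U→T, other IUPAC codes→N), so DNA queries and RNA matures compare
  exactly. The miRNA database writer can re-emit the RNA alphabet.

## Trinomial detection

Candidates are triples of features consecutive among *non-ignored*
annotation rows (classes in `ignore_classes`, default
`{Simple_repeat, Low_complexity}`, are transparent and may sit inside the
gaps), with the configured LINE family on both flanks, the LTR family in
the middle, both inter-part gaps ≤ `max_gap`, and (by default) one common
strand. Two detection signals are offered because the underlying pattern is
exposed two ways by annotation pipelines:

* `adjacency` (default) — the purely positional pattern;
* `fragment_id` — additionally requires the flanking LINEs to share a
  RepeatMasker fragment-linkage ID, the split-LINE signature of a nested
  LTR insertion.

`max_gap` defaults to 100 bp: the parts of a nested insertion are
near-contiguous, and the tolerance mainly absorbs annotation imprecision at
fragment edges. Chains (LINE,LTR,LINE,LTR,LINE) resolve greedily left to
right, so each feature belongs to at most one cluster — the "product"
semantics of a single recombination event — and detection is deterministic
and permutation-invariant. Cluster names follow the `+<n>-<gene>` /
`c<n>-<gene>` convention: forward clusters numbered in genomic order with
prefix `+`, complement clusters with prefix `c`, host-gene suffix added by
the context stage (intergenic clusters keep `NA`).

## Genomic context

Closed-interval overlap (≥ 1 shared bp). A cluster fully inside a gene body
is `exonic` if it touches any exon of its host, otherwise `intronic`; a
cluster straddling a gene boundary is `mixed` rather than forced into the
gene; no gene overlap means `intergenic`. With overlapping genes the host
is the gene with the larger overlap, ties to the lexicographically smaller
gene id. The synteny check projects both species onto the shared gene set,
compares relative order (per `(chrom, start)` sorting, so scaffold-split
assemblies are meaningful per scaffold run only) and reports strand flips
and missing genes.

## Pairwise alignment and identity

Global alignment is a three-state Gotoh dynamic programme; local alignment
is Smith–Waterman with Waterman–Eggert cell masking for deterministic
suboptimal matches (`max_alternatives`, honouring the "alternative
matches" idiom of interactive alignment tools). A gap of length k costs
`gap_open + (k−1)·gap_extend`. Defaults: match +5, mismatch −4, gap open
12, gap extend 2 (EDNAFULL-like); all configurable. Traceback ties resolve
diagonal > up > left, and within gap states toward closing the gap, making
every alignment bit-reproducible across platforms.

**Percent identity** is the EMBOSS convention: 100 × identical columns /
total alignment columns, gap columns in the denominator. `N` never counts
as identical and scores as a mismatch by default (`n_policy`), which keeps
identity conservative on masked bases.

Identity matrices are computed once per unordered pair (symmetric by
construction, diagonal 100) with min/max off-diagonal summary and arg
pairs. Because the published regional identity tables mix within-species
and cross-species comparisons, the pipeline computes **both** explicitly:
an all-vs-all matrix per species, and per-cluster cross-species identities
with homologs paired by cluster name.

## Star MSA and the conserved window

The consensus stage replaces manual curation with a deterministic rule.
A star MSA is built around the sequence maximising summed pairwise global
identity (ties → lexicographically smallest label; a pipeline that already
computed the identity matrix passes its medoid and skips the recomputation),
merging pairwise alignments under "once a gap, always a gap" with per-slot
insertion padding.

The **conserved sequence** is then the longest contiguous column window in
which (a) every source row has ≥ `min_source_identity` percent identity to
the column consensus within the window (gaps count as non-identical), and
(b) every column has non-gap occupancy ≥ `min_occupancy` and a
residue-valued (non-gap-dominant) consensus call. Consensus ties break
alphabetically (A < C < G < T); equally long windows resolve to the
leftmost. Defaults `min_source_identity = 95`, `min_occupancy = 0.9`: the
published per-source identity floor of such a conserved block is just above
95%, so 95 is the natural round floor. Per-source identities over the
window are reported with the sequence (the Table-4-style report).

## miRNA scan

A deterministic seed-and-extend search replaces a web BLAST ranked by
E-value, which is not reproducible offline. Anchors are exact `seed_k`-mers
(default 7, the biological seed length of miRNA targeting) shared between a
mature and the query, forward and reverse complement; each anchor is placed
ungapped over the full mature extent (clipped only at query ends, which is
the only way coverage drops below 1), then refined by one banded gapped
pass (band ±2) that is kept only when it strictly improves the placement
score `2·matches − 3·mismatches − 5·gap_columns` — a gap is strictly worse
than a mismatch, so gaps appear only when an indel genuinely helps. One
best placement is kept per (miRNA, strand, non-overlapping locus). Hits are
filtered by `identity = 100·(aligned_length − mismatches − gaps) /
aligned_length ≥ min_identity` (default 85) and mature coverage ≥
`min_coverage` (default 0.9), then sorted by descending identity and name.

Completeness caveat: a placement with no exact `seed_k`-mer cannot be
anchored. At the default thresholds a passing hit has at most ~4 edits in
≥ 16 columns, which virtually always leaves an intact 7-mer; the synthetic
generator additionally keeps a protected central seed window intact in
planted homologs, so on generated data the seeded search is provably
equivalent to an exhaustive slide (and is tested against one).

Family grammar: names parse as `prefix-core[-arm]`; the family collapses
lettered paralogs and numeric sub-indices after a dash
(`bta-miR-30c-1-3p` → `miR-30`); unparseable names roll up as `unknown`.

## Species comparison

Hit sets compare on full mature names (species prefix included), matching
name-level counting in which homologs of one family contributed by
different database species count separately; `strip_prefix` switches this
off. Reports: common / A-only / B-only sets, per-family breakdown, the
dominant family of the A-only set with its share, species-prefix tallies
(the "different species" counts), and per-species cluster counts with
their ratio — the frequency contrast between the species is reported as
raw counts plus ratio because the natural denominator is ambiguous.

## Synthetic scenarios (the study conditions)

The generator emulates the study design end to end with no downloads. The
canonical configuration matches the study conditions: **30 clusters in
the 12-gene block** (kcne2 … jam2, with the canonical per-gene allocation
that induces exactly the labels `+1-gart` … `+20-jam2`, `c1-kcne2` …
`c10-jam2`), a **266 bp conserved core**, a per-source core identity floor
of **95%**, cluster flank divergence 8% per site (placing flank identities
in the low-to-mid 80s, the published lower range of such clusters), and
species divergence 3% per site (the published gene-level identity range is
91–99%).

Construction: one ancestral LINE–gap–LTR–gap–LINE element is drawn once;
every cluster copy descends from it by substitutions only, so realized
identities are exactly computable. Flanks mutate at `cluster_divergence`;
the core window of each copy carries at most
`⌊(1 − floor/100)·core_length⌋` substitutions, and one designated copy
carries exactly that cap so the realized minimum identity sits at the
configured floor (as in the published per-source table, whose floor is a
realized value). Clusters are planted only inside introns — hence the
all-intronic expectation downstream — with complement-orientation copies
inserted as reverse complements. Decoy repeat annotations (other LINE/SINE
/LTR families, plus transparent simple repeats inside two cluster gaps)
are spaced so no false trinomial pattern exists at realistic gap
tolerances.

Species B shares coordinates with species A (substitution-only
divergence): the genome mutates at `species_divergence` outside cores;
inside the core, a small fixed set of species-level substitutions
(`core_species_subs`, default 4 — a 3 bp block plus an isolated site,
echoing how two such conserved sequences typically differ) is shared by
every B copy, and each B core copy is an independent bounded-noise draw
around the resulting B reference. Species-specific planted miRNAs are
18-mers covering the 3 bp block: three cross-species differences push an
18-mer below the 85% identity threshold in exactly one species. All
planted miRNA loci sit ≥ 12 bp inside the core so conserved-window
boundary jitter (bounded to ≈ ±10 bp by the at-cap copy) cannot clip them.
The database mixes planted homologs (controlled mismatch counts outside a
protected seed window, both strands) with random decoys at 1:4.

The ground truth records, for **every** database record including decoys,
the expected hit flag per species, computed by the generator's own oracle:
an exhaustive ungapped slide plus a complete (unseeded, unbanded)
semiglobal dynamic programme against each species' core reference — a code
path fully independent of the pipeline's search.

What passing on this generator does **not** show about real data: no
indels between species or copies (an indel-planting mode is out of scope),
no fragmented or partially annotated elements, uniform base composition,
and a miRNA database far smaller than a real mature database — so absolute
hit counts are not comparable to published genome-scale counts, only the
set relationships and recovery behaviour are.

## Numerical and degenerate-input choices

* Window search is exact (prefix-sum scan over all windows inside valid
  column runs), tested against a quadratic brute force.
* Empty FASTA files warn and return empty; empty-bodied records are legal.
* Fewer than two detected clusters degrades gracefully: one region becomes
  its own consensus; zero regions yield an empty conserved sequence with a
  diagnostic, and the scan is skipped.
* No positive-scoring local alignment returns an empty list, not an error.
* All randomness flows from one integer seed through one generator; report
  files contain no timestamps, so reruns are byte-identical and each run
  writes to a fresh numbered directory.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the canonical scenario
(~240 kb genomes, 30 clusters, 12 genes, 80-record miRNA database), an
enumeration-oracle battery of 200 random pairs of length ≤ 8, a 500 bp ×
200-record scan-oracle comparison, and two full pipeline runs for the
determinism check. These sizes keep every stage exact or oracle-checked
while completing in minutes on one CPU.

## Known limitations

* The star MSA is not a full progressive aligner; with substantial indel
  structure a guide-tree MSA would outperform it. Under substitution-only
  divergence it is near-exact, which is the regime the generator models.
* Cross-species cluster pairing is by cluster name, which presumes the
  same detection order in both species; real scaffold-level assemblies
  would need coordinate lift-over or sequence-based pairing (out of
  scope).
* The scan does not model alignment statistics (no E-values); thresholds
  are explicit and exposed in configuration.
* A second species' conserved sequence derived elsewhere is treated as
  user input; the package does not reconstruct it.
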