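# Methods

## Spectrum and rank-based hashing

All 15-mers of the input reads are counted in a fixed array of 4¹⁵ = 2³⁰
two-byte saturating counters (cap 2¹⁵ − 1), so the spectrum costs ~2 GB
of address space regardless of input size (pages are only committed for
k-mers actually seen). Counting is **both-strand** by default: every
15-mer instance increments its own code and its reverse-complement code.
This keeps counts strand-symmetric — two reads from opposite strands of
a locus see the same counts — at the price of doubling both the counted
instances and the distinct-code set. `canonical=True` switches to
counting `min(code, rc)` once per instance. 15 is odd, so no k-mer is
its own reverse complement and no double-counting ambiguity arises.

The depth mode is found by scanning the count histogram upward from
x = 1 for the first strict rise (the valley separating the
sequencing-error peak) and taking the argmax beyond it; a monotonically
decreasing histogram (no second peak) falls back to mode 1 with a
warning flag. The assembly-size estimate divides total counted
instances by the **weighted mean count over the peak neighbourhood**
\[mode/2, 1.5·mode\] and by the number of counted strands. The weighted
mean is used instead of the integer argmax because the discrete bin is
noisy at realistic depths and read truncation at template ends biases
the instance total; on error-free 30× simulations this keeps the
estimate within a few percent of truth, where the raw argmax can miss by
~8 %.

A k-mer *b* (15 ≤ k ≤ 31, 2-bit encoded) is hashed from the count *x* of
its 15-mer suffix: `h(b) = cumBelow(2·|x − mode|) + b mod nextPrime(x)`,
with `cumBelow(r)` the number of distinct 15-mers of rank strictly below
r (distinct, not instances — the natural reading of "number of k-mers
with smaller ranking") and `nextPrime` precomputed by a sieve to
2¹⁵ + 100. The rank is symmetric around the mode; no sub-mode penalty is
applied. The mod-prime term spreads k-mers of equal rank
pseudo-randomly. Modal (single-copy) k-mers therefore win minimizer
elections; repeat k-mers lose priority but stay usable.

## Minimizers and overlap detection

Minimizers use the standard smallest-hash-per-window scheme (default
k = 25, w = 40 ≈ one minimizer per 20 bp; w is not dictated by the
method, this default balances sensitivity against table size). Both
orientations of every k-mer are hashed and the smaller hash (ties:
smaller code, then smaller position) is selected, making selection
strand-symmetric as the undirected graph requires. Windows fully inside
N-runs select nothing; k-mers touching an N never participate.

The minimizer table is keyed by the **selected code** rather than the
hash: selection already happened through the hash, equal k-mers have
equal selected codes, and code keys avoid spurious matches between
different k-mers that collide through the mod term. In reference-aligner
mode, codes occurring ≥ 1,000 times in the reference are purged.

Reads are processed longest-first; each read queries the table of longer
reads, so each candidate pair is examined once with the longer read as
subject. Hits are clustered per pair and orientation on the subject
start they predict for the query (forward: `spos − qpos`; reverse:
`spos − (qlen − qpos − k)`), seeding clusters at sorted-gap breaks
larger than δ = max(100 bp, 1 % of query length) and refining
assignments to nearest centroids for up to 10 k-means-style rounds;
values further than δ from their final centroid are dropped. Clusters
with fewer than 5 shared k-mers or a predicted overlap below
w + k − 1 (the minimizer sharing guarantee) are noise and discarded. Up
to two clusters survive per pair, the second only if it implies a
different of the four end configurations (start/end × start/end).
Cluster geometry yields the edge statistics without any base-level
alignment: predicted overlap (mean of per-hit inferences), CSK (union of
subject k-mer intervals), evidence span, and evidence proportion.
Containment (centroid ≥ 0 and centroid + qlen ≤ slen, with 2k bp slack)
removes the query from the graph as an embedded read, recorded against
its host.

## Layout

Safe edges are reciprocal best for both endpoint vertices in overlap
**and** CSK, with both vertex degrees below mean + 3 SD. Overlap and CSK
of the safe edges are fitted as normals (SD floored at 1.0 against
degenerate sets) and evidence proportion as a beta via method of moments
(values clipped to \[1e−6, 1 − 1e−6\]). Edge scores are the sum of log
**lower-tail** CDFs of the three features — the tail is a design choice
the source description leaves open; the lower tail makes larger
overlap/CSK/evidence more credible — floored at log(1e−300). With fewer
than 10 safe edges the model is not identifiable and edges are ranked
lexicographically by (overlap, CSK) instead.

Selection is greedy: safe edges first (by overlap/CSK, ties by name),
then remaining edges by descending score. An edge is taken iff neither
endpoint vertex already carries a selected edge (matching condition) and
its two reads are not already in the same path (disjoint-set over reads
with each read's two vertices pre-united — this forbids cycles). Paths
are read off from free ports; a path is canonicalized to start at the
lexicographically smaller terminal read, making output orientation
deterministic.

## Consensus and polishing

The consensus of a path starts as the first oriented read; each next
read's prefix is dovetail-aligned to the consensus suffix (search window
= predicted overlap + 500 bp). The dovetail DP (match +1,
mismatch/gap −2; free leading contig gaps, read anchored at its start,
contig end must be consumed) picks the overlap length, with a 64-bp
(w + k − 1) minimum so that vanishing alignments cannot pass; identity
is then recomputed exactly as end-anchored edit distance. Junctions
below 65 % identity split the path into two contigs. Only the read's
overhang is appended, so the consensus coordinate of every path read is
known; embedded reads inherit coordinates from their hosts.

Two contig-level repair passes follow. Contigs contained in a longer
contig (containments the minimizer evidence missed under sequencing
errors, typically singleton or short redundant paths) are absorbed: the
contig is mapped onto the longer ones (minimizer alignment, with a
direct edit-distance fallback for probes ≤ 5 kb) and its reads become
placements on the host. Contigs whose ends dovetail — greedy matching
can strand two paths when all connecting edges touch already-matched
vertices — are joined after the dovetail aligner confirms the end
overlap under the same identity and minimum-overlap rules as path
junctions. Neither pass runs on the final diploid contig set, where
1 %-divergent haplotype contigs must not absorb each other.

Polishing realigns every read inside a padded window around its layout
position (edlib infix alignment; alignments worse than 35 % of the read
length are discarded) and runs two passes, twice by default: (1)
per-column majority base, ties keeping the consensus; (2) indel calls
(≥ 2 supporting reads) are dilated by ±5 bp and merged into active
regions; read segments spanning the region ± 20 bp flanks feed a de
Bruijn graph (k = 15) and the heaviest anchored path (anchors: flank
15-mers present in ≥ 50 % of segments, searched over 8 positions)
replaces the region. Cyclic region graphs or unanchored regions are left
unchanged. Replacements apply right-to-left so coordinates stay valid.

Circularization, when origin sequences are supplied, maps each origin
with the reference aligner, reverse-complements the best contig if the
hit is on the reverse strand, and rotates it so the origin starts at
position 0.

## Diploid assembly

The haploid pipeline runs first; heterozygous SNVs are called from the
pileup (depth ≥ 5, minor-allele fraction in \[0.2, 0.8\] — thresholds
chosen as sensible defaults, configurable). Reads covering ≥ 2 het sites
become fragments; connected fragment blocks are bipartitioned by a
randomized max-cut-style heuristic (greedy agreement seeding plus random
restarts, single-fragment flips with incremental MEC updates, 32
restarts, fixed seed). Blocks are classified by cluster depth: both
clusters ≥ 25 % of the local total ⇒ phased; one cluster < 25 % of the
other ⇒ heterozygous deletion; het-free gaps longer than the mean read
length ⇒ homozygous (shorter gaps are absorbed to the midpoint so the
regions tile the contig). Edges joining reads of different clusters in
the same block, both inside phased regions, are removed from the
original graph, and layout + consensus re-run. Each re-laid-out contig
is tagged with the majority (block, cluster) of its reads, and its
consensus/polish uses only reads of that cluster or unassigned reads —
without this filter, 50/50 cross-haplotype pileups would randomize het
sites in the polished haplotype. Zero called het sites reduce the
pipeline to the haploid output.

## Read simulator

Templates are i.i.d. random genomes (given GC content). Per read:
haplotype ~ Bernoulli(0.5) for diploid templates, start uniform on the
template, length ~ Normal(mean, SD) truncated to \[200,
template end\], strand ~ Bernoulli(0.5), i.i.d. substitutions, and
indels at the indel rate split evenly between insertions and deletions
with length 1 + Geometric(0.5) (mean 2) — the split and the length law
are this package's choice. Defaults mirror a HiFi-like library: mean
20 kb, SD 5 kb, 0.5 % substitutions, 1 % indels. Read names carry
`template:start-end:strand:hap`, which the evaluation module parses
losslessly. One seeded NumPy generator drives everything; identical
seeds give identical outputs.

What the simulator does **not** emulate: platform-specific error
profiles (homopolymer-biased ONT errors), chimeric reads, coverage
biases (GC, origin-proximity), quality values, and structural variation
beyond SNV-derived haplotypes. Passing tests on these simulations
therefore demonstrate algorithmic correctness and calibration, not
performance on real instrument data; genome sizes in the test suite
(20–100 kb) are far below the repeat complexity of real genomes.

## Evaluation

Nx is the length of the contig at which the descending cumulative length
first reaches x % of the assembly total (of the genome size for NGx; 0
when never reached). Aligner accuracy counts aligned reads and the RMSE
of |aligned start − true start| over aligned reads. The switch-error
finder takes canonical k-mers (k = 21) present in exactly one parent,
assigns 20-kb windows (10-kb step) to the parent with more specific-kmer
hits (ambiguous when tied or both counts < 10), and counts
parent changes between consecutive assigned windows per contig;
ambiguous windows are skipped transparently. Canonical k-mers make the
count invariant under reverse-complementing the assembly.

## Problem sizes and numerical choices

The bundled studies use 50-kb haploid and 2 × 50-kb diploid templates at
30–40×, 2-kb mean reads, and 10,000-read calibration runs — sizes at
which every stage's behaviour (graph shape, safe-edge fits, phasing
block structure) matches the method's operating regime while a full run
stays in minutes on one CPU. Identity of a contig against its template
is measured semi-globally (contig fully aligned, free template end
gaps): simulated reads systematically under-cover the first and last
~(coverage gap) bases of a linear template and containment slack trims
path ends, so a strictly global alignment would conflate completeness —
checked separately via contig counts and lengths — with per-base
accuracy. Known limitations: no transitive reduction or repeat
resolution beyond edge prioritization; substitution-only error
correction; the reference aligner reports cluster-level placements, not
base-level CIGARs; DGS-style phasing and trio/Hi-C integration are out
of scope.
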