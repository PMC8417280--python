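# Methods

This note documents the models and procedures implemented in
`splicebayes`, the choices made where the design was genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## Splicing-graph construction

Reads are decomposed into k-mers (default k = 25) in a hash table. For
strand-specific libraries mate 2 is reverse-complemented first so both
mates count on the transcript strand; for unstranded libraries counts
accumulate on the canonical form (lexicographic minimum of a k-mer and
its reverse complement). Windows containing N are skipped.

**Error filtering.** A k-mer with count 1 is removed when some
single-substitution neighbour out-counts it at least 20-fold
(`min_dominance_ratio`, configurable), the signature of a sequencing
error hanging off a well-covered k-mer; an absolute `min_count` floor
(default 1, i.e. inactive) is also available. The filter is idempotent.
At moderate coverage this rule is deliberately conservative — a
neighbour of count 19 does not dominate — so two complementary
graph-level defences exist (below).

**Locus growth** proceeds in four phases:

1. *Seeding.* The most frequent unused k-mer with base-composition
   entropy H > 1.5 bits (log base 2, so the DNA maximum is 2.0) and
   count > 1; ties break lexicographically. Entropy excludes
   low-complexity anchors; the count rule excludes singletons.
2. *Greedy extension.* Repeatedly append (then prepend) the base whose
   continuation k-mer is the most frequent unused table entry; every
   consumed k-mer is marked used, which keeps loci disjoint.
3. *Paired-end rescue.* When extension stalls, fragments with one mate
   anchored (exact k-mer match) within 300 nt of the contig end and the
   far mate overlapping that end by ≥ 15 exact bases spell the
   continuation from real mate sequence (never with N). The most
   supported spelling wins; extensions re-entering used k-mer territory
   are rejected (no circularisation). Up to 8 rescue rounds per contig
   end bound the work on garbage ends. The 15-base minimum overlap has a
   ~4⁻¹⁵ chance of a spurious exact match on random sequence.
4. *Read-guided branching.* At every position admitting an alternative
   continuation k-mer, a branch opens only if (a) the alternative has
   been observed in more than one read (mirroring the seed rule — a
   singleton claim at moderate coverage is usually an error that escaped
   the dominance filter), and (b) some read containing it also shares a
   k-mer with the locus, or failing that, its mate is anchored on the
   locus. Chimeric k-mers with no anchored support never open branches.
   Branches extend by phases 2–3, recursively, up to a configurable cap
   of 20 openings per locus (bounds pathological repeats). A branch that
   stays within 2k+5 bases and parallels its parent segment at Hamming
   distance ≤ 2 is a *substitution bubble* — the footprint of a
   recurrent sequencing error; its k-mers are absorbed (so they neither
   reopen nor seed junk loci) but it contributes no sequence.

**Condensation.** The locus k-mers form a graph in which x → y (y equal
to x shifted by one base) is realised when the pair was spelled
consecutively within a collected segment *or* the junction-spanning
(k+1)-mer occurs in at least one read. Maximal unbranched chains become
unitig nodes; edges connect nodes over k−1 overlaps and carry the count
of reads spanning the junction. An adjacency that lands on a node
boundary without a read spanning it is dropped rather than turned into
an unwitnessed edge — every edge of every graph is read-witnessed by
construction. Finally, parallel bubbles that survived to this point
(same predecessors, same successors, sequences within a few
substitutions) are popped keeping the higher-coverage twin, and short
(≤ 2k+5) one-sided dangling tips are trimmed; both are standard de
Bruijn hygiene and only ever remove error artefacts at these sequence
lengths, because every real alternative exon in the simulations is
hundreds of bases long. A locus may condense into several weakly
connected components (e.g. when coverage gaps are unbridgeable); each
becomes its own graph.

The node convention is worth stating: a skip junction appears as a
junction-overlap node of length 2(k−1) between its flanks, so a
skipped-exon gene condenses to 4 nodes and 4 edges rather than the
3-node textbook cartoon. What is invariant — and what the tests assert —
is that the set of spelled source-to-sink paths equals the set of true
isoforms when every junction is covered.

## Candidate enumeration

Candidates are all source-to-sink paths (sources: in-degree 0; sinks:
out-degree 0 — the standard splicing-graph convention). While the count
exceeds `max_candidates` (default 100), the edge with minimum junction
support is removed and paths re-enumerated, one edge at a time; an edge
is only prunable when its tail keeps another out-edge and its head
another in-edge, so pruning never orphans a node. If no edge is
prunable, the highest-support paths are kept. Directed cycles are
rejected with an error naming the nodes involved; unrolling repeats is
out of scope. Path spelling removes the k−1 overlap at each junction;
effective length is length − mean fragment length + 1, floored at 1.

## Bayesian transcript calling

Per graph, with candidates *t* = 1..n and fragments *r* = 1..N:

* c_t ~ Bernoulli(π) iid, default π = 0.5 (the indifferent prior and the
  natural Bayes decision boundary for the 0.5 call threshold);
* e | c ~ Dirichlet(α = 1) restricted to the expressed set;
* z_r ~ Categorical(e); a fragment is observed from its transcript with
  probability L(r,t) = Σ over admissible placements of the
  fragment-length pmf at the implied length, divided by the effective
  length.

Placements are anchored by shared k-mers and then verified against the
full mate sequence with a 10% mismatch budget — generous for
substitution errors, far below the divergence of a mate overhanging a
splice junction the candidate lacks. Fragments incompatible with every
candidate are discarded with a logged count. The fragment-length
distribution is Gaussian with mean/SD estimated from unique placements
on single-node graphs (≥ 100 observations required), truncated at
[k, max observed]; otherwise the configured fallback (μ = 250, σ = 25).

**Sampling.** The sampler targets the abundance-marginalised joint
p(c, z): assignments are refreshed by data augmentation (draw e | c, z
from its Dirichlet conditional, then z | c, e row-wise, then discard e),
and each indicator is flipped by a Metropolis–Hastings birth/death move
whose proposal re-allocates every fragment compatible with the candidate
using count-based weights (α + n_s)·L(r,s) — deterministic functions of
the discrete state, so forward and reverse proposal densities are exact.
The acceptance ratio combines the Bernoulli prior, the
Dirichlet-multinomial marginal over abundances, and the likelihood of
the re-allocation, all in log space. Single-site "toggle only when the
count is zero" updates were tried first and mix far too slowly to remove
redundant candidates; the re-allocation move is essential. Candidates
owning a fragment no other candidate can explain can never die, so their
death moves are skipped; when more than 8 candidates remain movable, a
round-robin window of 8 toggles per sweep keeps a sweep
O(window · N · n). The sampler was validated against brute-force
posterior enumeration on small toys (agreement within ~0.01, well inside
Monte-Carlo error).

Defaults: 2000 sampling sweeps after 500 burn-in, thinning 1 — sized for
graphs of up to ~100 candidates and a few thousand fragments. A
transcript is called when the posterior mean of c_t reaches 0.5;
reported abundances are posterior means renormalised over the called
set. A single seeded generator is threaded through all graphs in
lexicographic order of their smallest k-mer, so identical inputs and
seed give byte-identical outputs. Transcripts shorter than 200 nt (a
conventional assembler floor, configurable) are not reported.

## Synthetic data

The generator emulates a multi-isoform benchmark without external data.
Genes draw 3–7 uniform-random exons of 300–800 nt; isoform counts follow
a configurable distribution, uniform over 1..5 by default (covering the
stratification range). Additional isoforms derive from an existing one
by a single event: internal exon skip, alternative 5'/3' splice site
(truncating an exon boundary that faces a junction — trimming a terminal
boundary would create an isoform that is an exact substring of its
parent, unidentifiable from short reads by any method), or intron
retention (two adjacent exons merged with a 100–300 nt intron). FPKM is
log-uniform over [2, 200] by default with 10% of isoforms set to 0
(structure present, no reads).

Reads: fragments multinomial with weights FPKM × length; the library
size is set so that mean coverage (total sequenced bases over total
expressed transcript bases) equals the requested depth (default 25×).
Fragment lengths are Gaussian (μ = 250, σ = 25) clamped to [read length,
isoform length]; mates read 100 nt off both fragment ends; substitution
errors are iid at the configured rate (indels are not modelled — the
assembler's error handling is k-mer-frequency based and substitutions
exercise it directly). Realised FPKM is reported on the requested scale
(expected value equals the request). Uniform-random exons put k-mer
entropy near 2 bits and make sequences effectively unique — which is
exactly what licenses the evaluation module's exact-match overlap
computation as a stand-in for alignment.

What the simulations do **not** emulate: positional/sequence-specific
coverage bias, PCR duplicates, quality-score structure, indels, genomic
repeats, or paralogous gene families. Passing results therefore
demonstrate the method's behaviour under its own model assumptions, not
performance on real libraries, where repeats and bias further reduce
accuracy.

## Evaluation

An assembled transcript is correct when ≥ 90% of its sequence overlaps
≥ 80% of an expressed reference transcript (expressed: realised
FPKM > 1). Overlap is the best co-linear chain of exact 25-mer matches,
tried on both strands — lossless for unique random sequence. Each
assembly matches at most one reference (best fractions; ties by
reference id); several assemblies may match one reference, and each
counts as correct for precision (consistent with the per-assembly
90/80 definition). Precision divides by all assemblies passing the
length floor; recall by the number of expressed references;
F-score = 2PR/(P+R), defined as 0 when P + R = 0. Strata recompute the
metrics per gene expressed-isoform-count bin {1,2,3,4,>4} and per FPKM
bin {(1,10], (10,50], (50,∞)}; stratum precision is computed over
assemblies whose best reference falls in the stratum; empty bins are
omitted.

## Known limitations

Two limits are intrinsic to short-fragment evidence and surface in the
20-gene benchmarks (mean depth 25×, FPKM log-uniform [2, 200]):

* **Coverage floor.** Isoforms at the low end of the FPKM range receive
  under ~5× coverage; k-mer gaps that no read or mate pair spans cannot
  be crossed by any method that refuses to invent sequence. Their
  recoverable pieces surface as partial transcripts (precision cost) or
  not at all (recall cost).
* **Crossover ambiguity.** An isoform whose every junction also occurs
  in some sibling has no uniquely supporting fragment at ~250-nt
  fragment length; the exact posterior genuinely splits between the
  true isoform and crossover combinations of its siblings, and the
  caller — correctly, given the evidence — reports neither with
  confidence. Longer fragments or long reads would resolve this.

Measured on the bundled 20-gene benchmarks across several generator
seeds: error-free precision 0.81–0.97 and recall 0.76–0.87; with 0.5%
substitution errors precision 0.84–0.86 and recall 0.75–0.78. On
single-splicing-choice toys with full junction coverage, graph recovery
is exact.

Cyclic splicing graphs (repeats) are rejected, not unrolled; single-end
data are not supported (paired-end information is integral to rescue and
branching); scaffolding across graphs and fusion transcripts are out of
scope.
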