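# Methods

This note documents the models and procedures implemented in `rumiphage`,
the defaults they use, the numerical choices behind them, and what the
synthetic-data generators do and do not emulate.

## Coverage-based ANI

The ANI used throughout is operationally a *coverage fraction*, not an
identity average: local alignment hits between a query genome and a subject
are filtered to identity >= 90% and length >= 500 bp (both inclusive), their
query spans are merged into a disjoint interval union, and

    ANI = 100 * covered_bp / query_length.

Two consequences worth keeping in mind: a genome fully covered by 90%-identity
hits scores ANI 100, and hits shorter than 500 bp contribute nothing. An
identity-weighted variant was considered and deliberately not made the
default — the coverage form is the definition the rest of the pipeline
(dereplication, novelty) is built on, and mixing definitions invites subtle
inconsistencies. Novelty calls use the *query* (catalog genome) as the
coverage denominator and take the maximum ANI over references, each reference
scored separately.

Internally all intervals are 0-based half-open; BLAST-tabular I/O converts
to/from 1-based inclusive coordinates at the boundary (minus-strand subject
spans, `s_start > s_end`, are normalised to ascending before merging). This
keeps the interval algebra free of off-by-one special cases, and the merge is
by construction idempotent and order-invariant.

## The built-in aligner

`local_align_pair` is a desk-scale blastn stand-in: exact 11-mer seeds select
candidate diagonals; an affine-gap Smith–Waterman (numba-jitted) runs in a
band of +/- 24 diagonals around each seeded diagonal cluster; both strands are
searched; after each reported HSP its query span is masked and the search
repeats, up to `max_hsps`. Scoring defaults are blastn-like (match +2,
mismatch -3, gap open 5, gap extend 2) and E-values use the Karlin–Altschul
form E = K·m·n·exp(-lambda·S) with ungapped constants lambda = 1.28, K = 0.46.
The constants are documented choices, not values fitted to BLAST output, and
no claim is made that E-values or HSP sets reproduce BLAST's exactly.

Limitations that follow from the design: alignments confined to the band
(fine for the substitution-dominated divergence the generator produces, and
for any pair whose indel offset stays within the band); sequence pairs with
no shared 11-mer return no hits, like a seeded aligner should. Unrelated
random sequences of a few kb typically do produce many short spurious HSPs —
these carry low bitscores and never pass the 90%/500 bp qualifying filter,
so they are harmless downstream; `max_hsps` caps the work spent on them.
HSP ties are broken deterministically (bitscore desc, query start asc,
subject id).

## Dereplication into viral populations

Greedy, longest-first (ties by id): each genome joins the first existing
population whose representative it covers at >= 95% ANI, computed with the
*member as query* — identity relative to the shorter sequence, so a fragment
fully contained in a longer representative joins it. Representatives are
therefore always the longest member, and the output is a deterministic
partition of the input.

A short-word prescreen accelerates the quadratic scan: a pair is aligned only
if the member shares at least 10% of its distinct 11-mer words with the
representative. Under roughly uniform substitution a true 95%-ANI pair shares
at least ~0.95 * 0.9^11 ≈ 30% of words, so the default threshold has a 3x
safety margin; it can be set to 0 when divergence may be strongly clustered
along the genome. This mirrors the word filters of classical greedy
clusterers.

Contig filtering keeps length >= 1500 bp and completeness strictly > 50%.
Reported percentages are rounded half-up at 2 decimals (`proportion`).

## Viral clusters and Markov clustering

Candidate pairs need >= 1 hit at E <= 1e-10; the edge test then merges
>= 90%-identity HSP regions per genome and requires coverage strictly
above 70% of the larger and 90% of the smaller genome. Edges are unweighted —
the filters are pass/fail and no principled weight is defined by them.

MCL runs on the dense column-stochastic matrix with self-loops of weight 1,
expansion = matrix square, inflation 6.0 (entrywise power + column
renormalisation), pruning of entries < 1e-8 (a fully pruned column retreats
to its self-loop), convergence when the largest entry change falls below
1e-6, capped at 100 iterations. Clusters are read from the limit matrix's
attractor structure; nodes attracted by several attractor systems are
assigned to the largest cluster (ties: smallest member id), unattracted nodes
become singletons, so the output is always a partition and is invariant to
node input order. The dense implementation is intended for the
desk-scale graphs the package targets (hundreds to a few thousand nodes),
not for 10^5-node catalogs.

Behavior worth knowing: at inflation 6.0 the granularity is aggressive. Two
cliques joined by a single bridge split at the bridge, and disconnected
cliques are recovered exactly; but when several cross edges touch one clique,
MCL may peel a member off as a singleton attractor. That is inherent to the
algorithm at high inflation, not an artifact of this implementation.

Both entry points — clustering dereplicated representatives (default) or all
contigs — are supported, since the choice is a judgment call upstream of this
package.

## Lifestyles

Score thresholds: temperate <= 0.3 < uncertain temperate < 0.5 <= uncertain
virulent <= 0.7 < virulent; lytic means score >= 0.5 (virulent plus uncertain
virulent). The 0.5 boundary goes to the lytic side and 0.3/0.7 to the lower
categories; the map is total and monotone on [0, 1].

`chi_square` is Pearson's test of independence without continuity
correction; the p-value is the upper chi-square tail via the regularized
incomplete gamma function Q(df/2, X²/2). Expected counts below 5 trigger a
warning but not an error. Against `scipy.stats.chi2_contingency`
(correction=False) the statistic and p agree to < 1e-9, and the empirical
type-I error at alpha = 0.05 over 10,000 simulated independent 2x2 tables
(n = 200) is 0.05 within +/- 0.01.

## Co-diversification

Patristic distances are computed by breadth-first path sums over the parsed
tree's node graph, so arbitrarily rooted Newick input is fine (the matrix is
root-invariant) and branch lengths must be non-negative. For a tree whose
tips span >= 3 animal hosts and contain >= 1 within-host pair, all C(T, 2)
tip-pair distances are pooled into within-host (W) and between-host (B) sets
and two exactly opposite one-tailed Wilcoxon rank-sum tests are run on them;
coevolved / not-coevolved verdicts use alpha = 0.05 (the conventional reading
of "significant").

The rank-sum p is exact by full enumeration of rank assignments when the
pooled sample has <= 12 observations without ties, otherwise a normal
approximation with midranks, tie-corrected variance and continuity
correction 1/2. Against brute-force enumeration on small samples it agrees
to < 1e-12; on iid continuous samples its rejection rate at alpha = 0.05 is
0.051 (2,000 trials).

A caveat is inherited from the procedure itself: pooled tip pairs share tree
paths and are not independent, so the nominal level holds only approximately
and depends on tree shape. On label-permuted trees generated under the
strong-separation condition (stems 10x the within-host branch scale) the
empirical false-positive rate is ~0.05; on trees with weak host separation
the blocked distance structure makes the pooled test *conservative*
(~0.02 at stem length 0). Verdicts are invariant to tip order and to uniform
rescaling of branch lengths.

## Host prediction

The exact-repeat CRISPR detector finds arrays of >= 3 identical repeat copies
(repeat length 23–47 bp) separated by spacers of 20–50 bp, preferring
candidate arrays with more units, then longer repeats, and suppressing
overlapping shadows — this resolves the ambiguity that arises when several
spacers share a prefix (which would otherwise extend the repeat and truncate
the array). Real detectors tolerate repeat degeneracy; this one requires
exact copies, which is the right trade-off for synthetic data. For real MAGs
the fidelity-preserving path is to supply spacers from a dedicated detector
directly.

Spacer matching is full-length ungapped scanning of each spacer (and its
reverse complement) along the phage genome with <= 1 Hamming mismatch. For
spacers of <= 50 bp the ">95% of spacer length" alignment-length rule forces
effectively full length, so full-length matching realizes it; matches with
1-bp terminal truncations are not searched (documented simplification).
Homology links require identity strictly > 90% over strictly > 500 bp.
Evidence is combined per (phage, MAG) pair — "both" requires the same pair in
both methods; genus-level agreement can be derived from the output when a
looser notion of consistency is wanted. Specialist/generalist is decided on
the set of distinct host *genera* per phage (suffixed GTDB genera are
distinct); the raw network keeps MAG resolution.

## Synthetic communities

The generators are pure functions of (parameters, seed) — outputs, including
serialized FASTA/TSV, are byte-identical across runs — and every planted
entity is recorded in a `SimTruth` object.

* **Genomes.** Species are independent uniform-random ancestors (pairwise
  divergence of random sequences concentrates near 75%, so any
  `between_div` <= 0.7 is guaranteed separable); members are the ancestor
  with substitution-only mutation at `within_div` (each site substituted
  independently, uniformly to one of the three other bases). No indels —
  realized identity then follows the binomial expectation exactly, which
  keeps the ANI oracles exact. Completeness is uniform on (50, 100] because
  catalog inputs are post-filter by construction. Defaults: within 2%,
  between 25%, genome length 5–50 kb (tests and the acceptance script use
  1–2 kb genomes to keep run times in seconds; the statistics do not depend
  on genome scale beyond binomial noise).
* **MAGs.** Each MAG is random background (20 kb) with one CRISPR array
  inserted: (repeat, spacer) x k with repeat 30 bp, spacers 32 bp, k >= 3,
  spacer sequences copied from phage genomes with 0, 1, or 3 mismatches —
  3-mismatch copies are decoys that a <= 1-mismatch matcher must never
  recover. Array geometry follows typical detector ranges. Genera are drawn
  from a pool mixing the six methanogen genera with common rumen genera.
* **Trees.** Per-host random binary subtrees with Exp(mean 1) branch
  lengths, joined pairwise by stem edges of length `coevolution_strength`.
  The null condition keeps the topology and randomly permutes tip -> host
  labels, which removes any label–distance association (within/between
  distance distributions are then marginally identical).
* **Lifestyle scores.** A two-component mixture: lytic scores
  0.5 + 0.5·Beta(2,2), temperate scores 0.5·Beta(2,2); component membership
  is binomial with the lytic weight. The default weight 0.596 matches the
  lytic share reported for ruminant GIT catalogs. The components are
  entirely above/below the 0.5 decision boundary, so generator truth and the
  classifier agree by construction.

What the generators do *not* emulate: read-level noise, assembly artifacts
and chimeras, indels, prophage boundaries, repeat-degenerate CRISPR arrays,
compositional biases, or realistic phylogenetic rate variation. Passing
tests therefore demonstrate correctness of the implemented statistics on
clean planted structure, not robustness to the full messiness of real
metagenome-derived genomes.

## Problem sizes

Defaults in tests and the acceptance script: dereplication on 100 seeded
communities of 5–50 species (2–3 members each, 1–1.5 kb genomes);
1,000 fuzz cases each for the interval/coverage and spacer-matching oracles;
500 label-permuted and 200 strongly co-evolved trees (3 hosts x 4 tips) for
calibration and power; 500 random tables for the chi-square oracle; 200-node
planted-clique graphs for MCL. The full suite runs in under two minutes and
the acceptance script in about half a minute on one CPU.
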