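# Methods

## The model

`compdist` measures the dissimilarity of two nucleotide sequences — or
two NGS samples of short reads — from compressed sizes alone.  Let
C(x) be the size in bytes of x after lossless compression, C(xy) the
size of the concatenation, and C(x|y) the size of x when the
compressor's model has first been informed by y.  Three measures are
provided:

* **CDM**  d_CDM(x, y) = C(xy) / (C(x) + C(y)).  Ranges from 1/2
  (identical inputs: compressing the second copy is nearly free) to 1
  (no shared information: concatenation saves nothing).
* **conditional distance**  d(x, y) = (C(x|y) + C(y|x)) / C(xy),
  in [0, 1].
* **NCD**  d_NCD(x, y) = max{C(x|y), C(y|x)} / max{C(x), C(y)}, a
  computable stand-in for the normalized information distance; a
  proper metric under an idealized compressor.

The measures are parameter-free from the user's point of view: no
k-mer length, no alignment, no assembly.  An NGS sample enters the
pipeline as the plain concatenation of its reads (no separator
symbol, because a separator would shift every size systematically);
the distances are empirically insensitive to the concatenation order,
and `sample_from_reads(reads, order_seed=...)` exposes the shuffle
used to verify that.

Pairwise distance matrices feed neighbor joining; reconstructed trees
are scored against a reference with the Robinson–Foulds symmetric
difference and against a true classification with a leaf-label
parsimony count (bottom-up: an internal node takes the intersection
of its children's label sets when nonempty, otherwise their union at
a penalty of one; a tree with every group monophyletic scores
groups − 1).

## The built-in coder

Any compressor can back the size primitives (gzip/bzip2/xz backends
are registered, with C(x|y) ≈ max(C(yx) − C(y), 0) since they cannot
be primed), but the package's reference backend is a fully specified
adaptive arithmetic coder designed for true conditional compression:

* alphabet {A, C, G, T, N}; N is a first-class symbol so real reads
  never hit an undefined probability;
* a fixed-order context model (default order 8, configurable) with
  one count row per context;
* additive smoothing with asymmetric priors — 1/4 for each of
  A, C, G, T and 1/16 for N, one unit per observation, held as
  integer counts scaled by 16.  A fresh context then costs
  ≈ log2(17/4) = 2.09 bits per base, near the 2-bit entropy floor of
  uniform DNA rather than the naive log2 5 = 2.32 of a symmetric
  5-letter prior, while a single prior observation of the correct
  symbol already drops the cost to ≈ 0.72 bits;
* a classic 32-bit integer arithmetic coder with underflow handling;
* bitstream = 8-byte big-endian symbol count + code bits, so
  `header_bytes = 8` and an empty payload costs exactly the header;
  sizes are ceil(bits/8) + 8.

Conditional compression is native: C(x|y) primes the model with one
full counting pass over y (no output), resets the rolling context,
and encodes x.  Decoding replays the identical model updates, so
`decode(encode(p)) == p` for every payload; clearly truncated streams
are detected (the decoder refuses to read far past the buffer).

**Why these defaults.**  The design space (context order, smoothing
strength, priming passes; also order-blended models of the
context-tree-weighting and PPM families, which were prototyped and
measured) trades three things: compression of untrained data, the
strength of one-shot conditioning, and noise from sparse contexts
observed once with an unrepresentative symbol.  Order 8 keeps the
table sparsely loaded for payloads up to tens of kilobases, which is
what makes the unit-scale size contracts hold simultaneously:
a 4 kb uniform payload compresses to within 10% of its entropy floor,
C(x|x) < 0.5 C(x), C(xx) < 1.5 C(x), and priming on an *unrelated*
sequence costs at most the header for payloads up to ~2 kb.  That
last bound degrades quadratically with length (two random 4 kb
sequences share ~40 of 5^8 contexts by chance, each collision
costing ~1 bit), which is why the conditional-consistency property is
stated and tested for payloads ≤ 2 kb.

## Operating range of the distances

The cross-sequence signal of a context-model coder on sequences
without internal repeat structure is exact sharing of (k+1)-grams,
which decays as (1 − q)^(k+1) in the per-site difference q.  In
practice the distances are highly informative for pairwise
divergences up to ~0.3–0.4 substitutions/site (the regime of the
data this method family is used on: within-genus bacterial genomes,
mammalian mtDNA) and saturate beyond that.  Consequences measured on
synthetic clades:

* in-regime (pairwise paths < ~0.5): NCD rank-correlates with true
  path lengths at Spearman ≈ 0.99 and NJ recovers topologies;
* deeply diverged clades (paths of 1–2.4, as produced by stacking
  per-edge lengths of 0.02–0.3 down a 10-leaf tree) saturate the
  distances, and short internal edges near the root become
  unrecoverable.  This is close to an information limit rather than a
  coder defect: NJ on the *exact* per-site difference matrix — the
  best any alignment-free estimate could do — reconstructs those
  instances only marginally (its binomial noise at 20 kb is already
  commensurate with the shortest internal edges).  The recovery test
  at those stated conditions fails honestly (RF 6 vs the required 2);
  the same pipeline on the same clade passes the genome/read
  consistency (Pearson ≥ 0.9, measured 0.9996) and
  concatenation-robustness (≥ 0.99, measured 0.99998) checks, which
  depend on the distances' stability rather than their deep-branch
  resolution.

## Synthetic data

The generator supplies every input the tests need, with explicit
seeds end to end:

* `random_genome(length, gc_fraction, seed)` — i.i.d. bases;
  P(G) = P(C) = gc/2.
* `random_tree(labels, seed, branch_length_range)` — rooted binary
  topology by uniform random joins of available subtrees; per-edge
  lengths uniform in the given range (expected substitutions/site).
* `evolve_along_tree(root, cfg)` — Jukes–Cantor site-independent
  substitution down each branch: p = (3/4)(1 − exp(−4d/3)), the
  substituted site drawing uniformly among the three other bases.
  No indels, so every leaf keeps the root's length.
* `simulate_reads(genome, cfg)` — shotgun sampling:
  round(depth · L / read_length) reads of fixed length (default
  100 bp), uniform start positions with replacement, forward strand
  by default (keeping the exact-model substring invariant testable;
  `random_strand=True` reverse-complements half).  Error models are
  parameterized uniform substitution: `exact` 0, `illumina_like`
  0.01, `sanger_like` and `ls454_like` 0.005 substitutions/base —
  transparent stand-ins for platform error profiles, not replicas of
  any particular simulator.

What the generator does *not* emulate: real genomes' repeat structure
and compositional heterogeneity (which real compressors exploit, so
synthetic results are conservative for C(x) but also lack the
mid-order statistical sharing real relatives exhibit), indels and
rearrangements, coverage bias, and quality-correlated errors.
Passing tests therefore demonstrate correctness of the pipeline and
its behavior under substitution-type divergence, not performance on
any particular real dataset.

## Numerical and procedural choices

* Joint payloads are always concatenated in sorted-label order, so
  distance matrices are exactly symmetric without doubling work; the
  matrix diagonal is stored as 0 (what NJ and the PHYLIP format
  expect) even though the raw self-CDM is ≈ 1/2.
* Matrix correlation concatenates full rows (diagonal and both
  triangles) by default; `include_diagonal=False` restricts to the
  upper triangle.
* NJ breaks Q-criterion ties by the lexicographically smallest pair
  of cluster representatives (smallest leaf label per cluster) and
  minimizes over the upper triangle only, because the two float
  evaluations of Q(i,j) and Q(j,i) can differ in the last ulp.
  Negative branch lengths are kept (an option clamps them at 0).
* Outgroup rooting places the root at the midpoint of the edge whose
  bipartition best separates the outgroup (exactly when possible,
  fewest-disagreements otherwise).
* Parsimony scoring accepts multifurcations (including the degree-3
  seed of an unrooted tree) by folding children in sequentially with
  the same intersection/union rule; the score is invariant to the
  rooting, which the tests verify exhaustively on small trees rather
  than assume.
* Newick output is deterministic: children ordered by their smallest
  descendant leaf label; underscores in labels are preserved, not
  converted to spaces.
* PHYLIP square matrices pad/truncate labels to 10 characters and
  refuse to write when truncation collides; the relaxed tab-separated
  dialect round-trips losslessly (`repr` of the float values).

## Problem sizes used by the test battery

Unit tests run on payloads of 0.3–10 kb.  The end-to-end battery
uses: topology recovery and genome/read consistency on one 10-leaf
clade with 20 kb genomes (branch lengths 0.02–0.3); read-order
robustness on a 6-leaf clade with 10 kb genomes at 5× depth and 10
shuffle orders; NJ consistency on 100 random additive matrices of
5–16 taxa; RF and parsimony oracle equivalence exhaustively on trees
of ≤ 7 leaves.  The whole suite completes in well under a minute
after JIT warm-up.

## Known limitations

* Distance saturation at deep divergence, as quantified above.
* The conditional-consistency byte bound holds for payloads up to a
  few kilobases at the default order; conditioning very long
  unrelated sequences can exceed it by a few bytes per megabase
  squared of chance context collisions.
* The coder's per-symbol cost bound assumes payloads under ~30 Mb
  (the 4 bytes/symbol output buffer); larger inputs should be
  processed in pieces.
* `C(x|y)` for the gzip/bzip2/xz backends is the subtraction
  approximation and is flagged as such; those backends also see the
  sequence as ASCII bytes, so their absolute sizes are ~4× the
  built-in coder's.
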