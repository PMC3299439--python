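# Methods

## The model

Sequences evolve on an unrooted binary tree `T` with leaf set `S` under the
Jukes–Cantor (JC) substitution model: the root state of each site is uniform
on {A,C,G,T}, each edge `e` carries a substitution probability `p(e)` with
`0 < p(e) < 3/4`, and a site that changes on an edge moves to one of the
other three nucleotides uniformly. Sites are i.i.d. The edge transition
matrix is

    M(p) = (1 - p) I + (p/3) (J - I),

which is linear in `p` — a fact the optimiser exploits (below). At
`p = 3/4` the matrix is exactly uniform (every entry 1/4); the model is
time-reversible with uniform stationary distribution, so the likelihood of
an unrooted tree does not depend on the rooting used for computation
(asserted as a test).

For a fixed topology the quantity of interest is the supremum likelihood

    ML_JC(A, T) = sup_theta P(A | T, theta),

the supremum taken over all edge-probability assignments. Because the open
parameter box `(0, 3/4)^|E|` is not closed, the supremum may not be attained
— it can be approached as some `p(e)` tend to 0 or 3/4. The likelihood is
continuous in `theta`, so the supremum over the open box equals the maximum
over its closure `[0, 3/4]^|E|`; we therefore optimise on the closure and
flag each edge whose optimum lies at a boundary (`boundary_flags`), keeping
the open/closed distinction visible without sacrificing exact arithmetic.

## Gap treatments

Alignments are matrices over {A,C,G,T,-}. Three treatments of `-` are
implemented:

* **missing data** (the default, and the one under study): a gapped leaf is
  marginalised — its partial-likelihood vector is all ones, equivalently the
  column likelihood is summed over the four nucleotides the leaf could have
  had.
* **strip gapped sites**: every column containing any gap is removed before
  analysis. This can empty an alignment entirely (the built-in 7-taxon
  example does); an empty alignment has likelihood 1 and is reported as
  degenerate with a warning rather than an error.
* **gap coding**: each column containing a gap becomes one binary
  presence/absence character. This is a recoding, not a likelihood
  treatment — requesting a nucleotide likelihood under it is an error; the
  coded characters feed the gap-signal estimator instead.

Only `-` is accepted as a gap. Ambiguity codes (`N`, `?`, IUPAC letters) are
rejected: the analyses concern indel gaps specifically, and silently mixing
in ambiguous base calls would change the question.

## The flat surface on monotypic alignments

An alignment is *monotypic* if every column's non-gap characters are a
single nucleotide type and no column is entirely gaps. For such an
alignment with `R` columns, treating gaps as missing data:

* the per-column likelihood at all `p(e) = 0` is exactly 1/4 — the
  probability of drawing the column's one nucleotide at the root, every
  non-gap leaf then inheriting it unchanged and every gapped leaf
  marginalising to 1;
* no parameter assignment can do better, so the supremum over the closure is
  `(1/4)^R` for *every* topology.

Consequently exhaustive ML returns the whole topology space as its tie set:
the data contain no likelihood information about the tree. Under an
evolutionary process that produces monotypic alignments with non-vanishing
probability — indels without substitutions being the extreme case — ML with
gaps as missing data therefore cannot converge on the true tree no matter
how long the sequences are.

The package checks this identity *bit-exactly*: `p = 0` is handled as an
exact identity transition, and the total log-likelihood is re-evaluated at
the optimum with `math.fsum` over uncompressed per-column logs, so the
supremum compares equal (in floating point) to `R * log(0.25)` rather than
merely close.

## Likelihood computation

Felsenstein pruning, vectorised across the alignment's unique site patterns
(patterns are compressed with multiplicities; for long simulated alignments
this is the dominant saving). Partial vectors are kept in linear space with
per-pattern rescaling when entries drop below 1e-250, the rescaling
constants re-applied in log space; trees here are small (n ≤ 8) but the
simulator can generate arbitrarily long alignments, and rescaling makes the
evaluator safe for them.

## Optimisation

Per-topology optimisation is multistart coordinate ascent over the closed
box. The key structural fact: because `M(p)` is linear in `p`, each
column's likelihood is linear in any single edge's parameter with the
others held fixed, so the coordinate objective is

    f(p) = sum_c w_c log(a_c + b_c p),

a concave function on [0, 3/4]. Its maximiser is a boundary point or the
unique root of `f'` (found by bracketed root-finding to 1e-14); each
coordinate update is therefore solved exactly rather than by generic scalar
search. Two consequences matter here: boundary optima are *landed on*
(`p = 0` exactly, giving the bit-exact flat-surface values), and
convergence on monotypic data takes a single sweep.

Coordinate ascent on a multimodal surface is a local method. The multistart
grid is five homogeneous starts (all edges at 0.01, 0.1, 0.3, 0.5, 0.7)
plus three random interior starts from a fixed-seed generator; the high
starts are load-bearing — short gapped alignments can have a
near-saturation optimum separated from the low-`p` basin by a genuine
likelihood barrier, and a dense-grid oracle test exercises exactly that
case. All starts are optimised in lock-step batches sharing each pruning
pass, so the widened grid costs little. Convergence tolerance is 1e-10 in
log-likelihood with a 200-sweep cap; per-edge ties break toward `p = 0` for
determinism.

The exhaustive search scores every unrooted topology (guarded to n ≤ 8,
(2n−5)!! ≤ 10395) and returns the full tie set at relative log-likelihood
tolerance 1e-9 (scaled by max(|best|, 1)). The tolerance is a convention —
no canonical tie threshold exists for "all trees attaining the maximum" —
and is surfaced as a parameter; flat-surface ties are bit-exact, so it only
absorbs optimiser noise on data with real signal.

## Gap-signal estimator

Each gapped column's presence/absence character is scored on a topology by
Fitch small parsimony (exact for binary characters on binary trees; the
tree is rooted on a pendant edge to keep every internal node binary), and
the estimator returns every topology minimising the total score — always
the full tie set, never an arbitrary representative. A constant character
costs 0; a character whose presence set is a side of a tree bipartition
costs 1; anything else costs ≥ 2. This demonstrates that topologies are
*separable* from the gap pattern of a monotypic alignment; it is a
signal-existence contrast, not a statistically consistent estimator, and
the package makes no consistency claim for it.

## Simulator

The synthetic-data generator evolves a uniform-random root sequence of
length `L` down the tree. Per edge, independently per surviving site:
deletion with probability `d(e)` first (a site deleted on an edge cannot
also substitute on it; some order had to be fixed for reproducibility, and
either order is a valid process), then JC substitution with probability
`p(e)`. Optional single-residue insertions occur per inter-site slot with
probability `i(e)` (default 0), creating new homology columns gapped in all
lineages outside the insertion subtree. Deletion is irreversible per column
per lineage, so positional homology holds by construction and the emitted
alignment is the *true* alignment — matching the setting in which the
flat-surface result already applies (tree estimation given a correct
alignment). With `p(e) = 0` everywhere, every column's residues are copies
of one ancestral nucleotide, so the output is always monotypic.

This is deliberately the simplest indel process that produces monotypic
alignments: single-residue events, no indel-length distribution, no
TKF-style birth–death machinery. Conclusions tied to a specific indel
mechanism are properties of this simulator, not general claims; what the
downstream analyses need from it is only (a) known true alignment and tree,
(b) a zero-substitution regime, and (c) calibrated per-edge event
probabilities (empirical substitution and deletion fractions are tested
against `p(e)`/`d(e)` at L = 10,000 within three standard errors).

Randomness: a single integer seed; each edge draws from a substream keyed
by a stable CRC32 hash of its leaf-label bipartition, so simulated data are
invariant to traversal order. Replicate seeds in the experiment drivers are
derived through `SeedSequence(entropy=seed, spawn_key=(condition, rep))`,
making reports order-invariant and byte-reproducible.

There is also a direct generator of random monotypic alignments (random
non-empty presence set and one random nucleotide per column) used to sample
the hypothesis class of the flat-surface identity independently of any
particular indel process.

## Experiment design and problem sizes

Defaults are sized for a single CPU while keeping every regime
non-degenerate:

* **Flat-surface verification**: the built-in 7-taxon, 3-site monotypic
  alignment, all 945 topologies, full numeric optimisation (~10 s); plus
  200 random monotypic alignments with n uniform on 4..7 and R uniform on
  1..10, each checked on its full topology space.
* **Indel-only regime**: 5-taxon tree `((a,b),(c,d),e)`, `p = 0`,
  `d = 0.15` per edge, `L = 200`, 20 replicates. `d = 0.15` keeps most
  columns partially occupied (expected ~28% single-edge loss from root to a
  leaf through 2–3 edges) while generating enough informative gap
  characters that the parsimony contrast is non-vacuous in every run.
* **Substitution-only control**: same tree, `p = 0.05` per edge, `d = 0`,
  `L ∈ {100, 500, 2000}`, 20 replicates per length; recovery of the true
  topology is checked to be ≥ 90% at L = 2000 and non-decreasing in L.
  With five taxa and moderate `p` this control saturates quickly; it is a
  sanity anchor, not a hard estimation problem.

## What the synthetic data do and do not show

The simulator emulates i.i.d. single-site evolution with exactly the
substitution model the likelihood assumes — model match is the *point*: the
inconsistency arises even when the assumed substitution model is correct
and the alignment is true. Real data differ in every generous direction
(multi-residue indels, rate heterogeneity, alignment error, non-reversible
processes); passing tests therefore show the structural result and the
correctness of the computations, not that any particular biological
alignment is monotypic-like. Conversely, the flat-surface identity itself
is distribution-free given monotypy, which is why it is tested on random
gap patterns, not only on simulator output.

## Numerical choices, degenerate inputs, limitations

* Exact `p = 0` identity transitions; `fsum` totals; flat-surface checks at
  equality, not tolerance.
* Empty alignments (R = 0, e.g. after stripping) return log-likelihood 0
  with a `DegenerateAlignmentWarning`; every topology trivially ties.
* Rows that are entirely gaps are legal (the built-in example has two);
  under missing data they contribute a factor 1 per column.
* Fully gapped columns are rejected by the monotypic predicate but coded
  literally (all-zero character) by the gap coder.
* Degree-2 roots in input Newick are suppressed with the two incident
  probabilities composed as a serial JC channel, `p∘q = p + q − 4pq/3`.
* Newick branch lengths are `p(e)` values in [0, 3/4], not
  expected-substitution branch lengths; out-of-range values are parse
  errors.
* Global optimality of the per-topology supremum is heuristic (multistart
  hill-climbing), backed by the dense-grid oracle test at n = 4; the
  exhaustive searches are exact over topology space but capped at n = 8.
* Site indices in all reports are 0-based.
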