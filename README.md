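# gapml

Jukes–Cantor maximum-likelihood phylogenetics on alignments with gaps —
and a demonstration of why treating those gaps as missing data can make
maximum likelihood statistically inconsistent.

## The problem

Most phylogenetic likelihood software treats a gap (`-`, an insertion or
deletion) as missing data: the likelihood of a column is summed over the
four nucleotides a gapped leaf could have carried. This package is built
around a sharp failure mode of that convention. Call an alignment
**monotypic** if every column's non-gap characters are a single nucleotide
type (all A, or all C, …) and no column is entirely gaps, e.g. the built-in
7-taxon example:

    s1  A - -        s5  - - -
    s2  - C -        s6  - - T
    s3  A - -        s7  A - -
    s4  - - -

For any topology `T` on these taxa, the supremum JC likelihood with gaps as
missing data is

    ML_JC(A, T) = sup_θ P(A | T, θ) = (1/4)^R,

where `R` is the number of columns: the supremum is approached as every
edge substitution probability `p(e) → 0`, where each column contributes
exactly the 1/4 root-prior probability of its one nucleotide. The value
does not depend on `T`, so **every** tree is an ML tree. Since evolution
with indels but no substitutions produces monotypic alignments with
probability bounded away from zero, ML with gaps-as-missing-data cannot
converge on the true tree under such a process no matter how long the
sequences are — it is statistically inconsistent, even given the true
alignment. Yet the same alignments are not uninformative: their gap
*pattern*, recoded as binary presence/absence characters, still separates
topologies.

`gapml` implements all the machinery to state and verify this executably:
exact JC pruning likelihoods with gap marginalisation, supremum search over
edge probabilities on the closed box [0, 3/4] with boundary flags,
exhaustive enumeration of the (2n−5)!! unrooted topologies, a seeded
substitution+indel simulator whose output is the true alignment, gap coding
with Fitch parsimony over topologies, and orchestrated experiments.

## Who it is for

Researchers and students in molecular phylogenetics who want a small, exact,
fully testable laboratory for gap-treatment questions on trees of up to 8
taxa — not a production tree-search tool for large datasets.

## Worked example

```python
from gapml import (printed_alignment_fixture, exhaustive_ml, gap_code,
                   estimate_tree_from_gaps)

aln = printed_alignment_fixture()          # the 7-taxon alignment above
search = exhaustive_ml(aln)                # optimises all 945 topologies
print(search.n_topologies, len(search.optimal), search.log_likelihood_spread)
# 945 945 0.0        <- every topology ties, bit-exactly, at 3*log(1/4)

gaps = estimate_tree_from_gaps(gap_code(aln))
print(gaps.n_topologies, len(gaps.optimal), gaps.best_score)
# 945 45 3           <- the gap pattern keeps only the 45 trees containing
#                       the {s1,s3,s7} bipartition
```

The analysis drivers narrate the full story and write tables under
`results/`:

```
python analysis/01_flat_surface_printed_alignment.py
# 945/945 topologies at exactly R*log(1/4) = -4.158883 (likelihood (1/4)^3 = 0.015625)
# log-likelihood spread across topologies: 0.0
python analysis/02_gap_signal_printed_alignment.py
# 45 of 945 topologies attain the minimum parsimony score 3
python analysis/03_indel_only_inconsistency.py
# [indel_only] monotypic: 1.00  ML surface flat: 1.00  gap-parsimony strict subset: 1.00
python analysis/04_substitution_only_consistency.py
# recovery of the true topology at L=2000: 100%
```

Script 03 simulates indel-only evolution (p = 0, per-edge deletion 0.15) on
a known 5-taxon tree: every replicate is monotypic and ML ties all 15
topologies, while gap-coded parsimony narrows the set (and contains the true
tree) in every replicate. Script 04 is the gap-free control where ML
behaves classically.

There is also a CLI (`gapml simulate|ml-search|gap-tree|experiment`); note
that Newick branch lengths throughout are JC substitution *probabilities*
p(e) ∈ [0, 3/4], not expected substitutions per site.

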