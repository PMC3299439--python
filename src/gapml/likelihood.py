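"""Jukes-Cantor likelihood of gapped alignments by Felsenstein pruning.

Gaps treated as missing data are marginalised: a gapped leaf contributes the
all-ones partial vector, i.e. the column likelihood is summed over the four
possible nucleotides at that leaf.  The root nucleotide is uniform over
{A,C,G,T}; because JC is reversible with a uniform stationary distribution,
the likelihood does not depend on where the (unrooted) tree is rooted.

The JC transition matrix is linear in the edge's substitution probability p:

    M(p) = (1-p) I + (p/3) (J - I),        0 <= p <= 3/4,

so applying it to a partial-likelihood vector v is the rank-one update
(1 - 4p/3) v + (p/3) (sum v).  This linearity is exploited heavily by the
optimiser in :mod:`gapml.mlsearch`.

Per-column partial vectors are kept in linear space with per-pattern
rescaling when entries become very small; rescaling constants are
re-applied in log space, so arbitrarily long alignments are safe.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .alignment import CODE, GAP, Alignment, GapTreatment, strip_gapped_sites
from .trees import PhyloTree, Split

__all__ = [
    "jc_edge_transition",
    "column_likelihood",
    "alignment_log_likelihood",
    "TreeLikelihood",
    "DegenerateAlignmentWarning",
]

_RESCALE_THRESHOLD = 1e-250


class DegenerateAlignmentWarning(UserWarning):
    """Emitted when a likelihood is requested for an empty (R = 0) alignment."""


def jc_edge_transition(p: float) -> np.ndarray:
    """4×4 JC transition matrix for an edge with substitution probability p.

    Diagonal = 1-p (no change); each off-diagonal = p/3 (the changed site
    picks one of the three other states uniformly).  Rows sum to 1.
    """
    p = float(p)
    if not (0.0 <= p <= 0.75):
        raise ValueError(f"substitution probability must lie in [0, 3/4], got {p}")
    m = np.full((4, 4), p / 3.0)
    np.fill_diagonal(m, 1.0 - p)
    return m


class TreeLikelihood:
    """Compiled pruning evaluator for one topology and a fixed set of columns.

    Site columns are compressed to unique patterns with multiplicities; all
    pruning passes are vectorised across patterns.  Edge parameters are
    addressed positionally in the (fixed, deterministic) order of
    ``self.splits``.
    """

    def __init__(
        self,
        tree: PhyloTree,
        codes: np.ndarray,
        weights: Optional[np.ndarray] = None,
        root: Optional[int] = None,
    ):
        if codes.ndim != 2 or codes.shape[0] != tree.n_leaves:
            raise ValueError("codes must be (n_taxa, n_sites) aligned to tree.taxa")
        self.tree = tree
        self.taxa = tree.taxa
        root, order = tree.postorder_edges(root=root)
        self.root = root
        self.order = order  # (child, parent, split), children before parents
        self.splits: List[Split] = [s for (_, _, s) in order]
        self.split_index: Dict[Split, int] = {s: i for i, s in enumerate(self.splits)}

        # compress columns to unique patterns
        if codes.shape[1] == 0:
            self.patterns = np.empty((0, tree.n_leaves), dtype=np.int8)
            self.weights = np.empty(0)
            self.pattern_of_site = np.empty(0, dtype=np.intp)
        else:
            pat, inv, cnt = np.unique(
                codes.T, axis=0, return_inverse=True, return_counts=True
            )
            self.patterns = pat.astype(np.int8)       # (k, n_taxa)
            self.pattern_of_site = inv.ravel()
            self.weights = (
                cnt.astype(float) if weights is None
                else np.bincount(inv.ravel(), weights=weights, minlength=len(pat))
            )

        # leaf partial vectors per pattern: indicator rows, ones for gaps
        k = self.patterns.shape[0]
        eye5 = np.vstack([np.eye(4), np.ones(4)])  # code 4 = gap -> all-ones
        self._leaf_partials: Dict[int, np.ndarray] = {}
        taxon_col = {t: j for j, t in enumerate(self.taxa)}
        for node in tree.nodes():
            if tree.is_leaf(node):
                col = taxon_col[tree.leaf_label(node)]
                self._leaf_partials[node] = eye5[self.patterns[:, col]]
        self.k = k

    @classmethod
    def from_alignment(
        cls,
        tree: PhyloTree,
        alignment: Alignment,
        treatment: GapTreatment = GapTreatment.MISSING_DATA,
    ) -> "TreeLikelihood":
        if set(alignment.taxa) != set(tree.taxa):
            raise ValueError(
                "alignment taxa and tree leaf set differ: "
                f"{sorted(set(alignment.taxa) ^ set(tree.taxa))}"
            )
        if treatment is GapTreatment.STRIP_GAPPED_SITES:
            alignment = strip_gapped_sites(alignment)
        elif treatment is GapTreatment.GAP_CODE:
            raise ValueError(
                "gap_code recodes columns as binary characters and has no "
                "nucleotide-likelihood semantics; use gapml.gapsignal instead"
            )
        codes = alignment.codes()
        # reorder rows to the tree's taxon order
        row_of = {t: j for j, t in enumerate(alignment.taxa)}
        codes = codes[[row_of[t] for t in tree.taxa]]
        return cls(tree, codes)

    def params_vector(self, params: Optional[Mapping[Split, float]] = None) -> np.ndarray:
        """Edge parameters as a vector in ``self.splits`` order."""
        src = self.tree.edge_params if params is None else params
        return np.array([src[s] for s in self.splits], dtype=float)

    # -- core pruning ---------------------------------------------------

    def _prune(self, params_groups: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Pruning pass for G parameter vectors sharing all but a few entries.

        params_groups: (G, n_edges).  Returns (likelihoods, log_scales),
        each (G, k): per-pattern linear likelihood and the log rescaling
        already factored out of it.
        """
        G, n_edges = params_groups.shape
        k = self.k
        partials: Dict[int, np.ndarray] = {}   # internal node -> (G, k, 4)
        log_scale = np.zeros((G, k))

        def message(child: int, edge_idx: int) -> np.ndarray:
            v = partials.pop(child, None)
            if v is None:
                v = np.broadcast_to(self._leaf_partials[child], (G, k, 4))
            ps = params_groups[:, edge_idx]
            if G == 1 or np.all(ps == ps[0]):
                p = ps[0]
                if p == 0.0:
                    return v
                s = v.sum(axis=2, keepdims=True)
                return (1.0 - 4.0 * p / 3.0) * v + (p / 3.0) * s
            s = v.sum(axis=2, keepdims=True)
            pcol = ps[:, None, None]
            return (1.0 - 4.0 * pcol / 3.0) * v + (pcol / 3.0) * s

        for idx, (child, parent, _split) in enumerate(self.order):
            msg = message(child, idx)
            acc = partials.get(parent)
            if acc is None:
                base = self._leaf_partials.get(parent)
                if base is not None:  # root can be a leaf (2-taxon tree)
                    msg = msg * base
                partials[parent] = np.ascontiguousarray(msg)
            else:
                acc = acc * msg
                m = acc.max(axis=2)
                small = m < _RESCALE_THRESHOLD
                if small.any():
                    safe = np.where((m > 0) & small, m, 1.0)
                    acc = acc / safe[:, :, None]
                    log_scale += np.log(np.where(safe > 0, safe, 1.0))
                partials[parent] = acc

        root_partial = partials[self.root]  # (G, k, 4)
        lik = 0.25 * root_partial.sum(axis=2)
        return lik, log_scale

    def pattern_log_likelihoods(self, params: np.ndarray) -> np.ndarray:
        """(k,) natural-log likelihood per unique site pattern."""
        lik, log_scale = self._prune(np.asarray(params, dtype=float)[None, :])
        with np.errstate(divide="ignore"):
            return np.log(lik[0]) + log_scale[0]

    def log_likelihood(self, params: np.ndarray) -> float:
        """Weighted total log-likelihood (fast path used by the optimiser)."""
        if self.k == 0:
            return 0.0
        return float(self.weights @ self.pattern_log_likelihoods(params))

    def site_log_likelihoods(self, params: np.ndarray) -> np.ndarray:
        """(R,) per-site log likelihoods in original column order."""
        return self.pattern_log_likelihoods(params)[self.pattern_of_site]

    def exact_log_likelihood(self, params: np.ndarray) -> float:
        """Total log-likelihood as an exact (correctly rounded) float sum.

        ``math.fsum`` over the uncompressed per-site logs makes identities
        like R·log(1/4) hold bit-exactly for monotypic alignments.
        """
        if self.k == 0:
            return 0.0
        return math.fsum(self.site_log_likelihoods(params))

    def edge_linear_coefficients(
        self, params: np.ndarray, edge_idx: int
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Per-pattern (a, b) with column likelihood = a + b·p on edge `edge_idx`.

        Exploits linearity of M(p) in p: two pruning passes (p = 0 and
        p = 3/4), run stacked, give intercept and slope exactly.
        """
        a, b = self.multi_edge_linear_coefficients(
            np.asarray(params, dtype=float)[None, :], edge_idx
        )
        return a[0], b[0]

    # -- batched variants (several parameter vectors in one pruning pass) ----

    def multi_log_likelihood(self, params_matrix: np.ndarray) -> np.ndarray:
        """(S,) weighted log-likelihood for S parameter vectors at once."""
        if self.k == 0:
            return np.zeros(len(params_matrix))
        lik, log_scale = self._prune(np.asarray(params_matrix, dtype=float))
        with np.errstate(divide="ignore"):
            return (np.log(lik) + log_scale) @ self.weights

    def multi_edge_linear_coefficients(
        self, params_matrix: np.ndarray, edge_idx: int
    ) -> Tuple[np.ndarray, np.ndarray]:
        """(a, b) of shape (S, k) for S parameter vectors sharing one pass."""
        pm = np.asarray(params_matrix, dtype=float)
        pg = np.repeat(pm, 2, axis=0)
        pg[0::2, edge_idx] = 0.0
        pg[1::2, edge_idx] = 0.75
        lik, log_scale = self._prune(pg)
        lik = lik * np.exp(log_scale)  # scales are 0 except for huge R
        a = lik[0::2]
        b = (lik[1::2] - a) / 0.75
        return a, b


def column_likelihood(
    tree: PhyloTree,
    column: Mapping[str, str],
    treatment: GapTreatment = GapTreatment.MISSING_DATA,
) -> float:
    """Likelihood of a single alignment column under the tree's edge p(e).

    With gaps as missing data a gapped leaf is marginalised over {A,C,G,T};
    a gap-free column is the standard JC pruning likelihood.
    """
    if treatment is not GapTreatment.MISSING_DATA:
        raise ValueError(
            "column_likelihood supports the missing-data treatment only; "
            "strip_gapped_sites is an alignment-level transform"
        )
    if set(column) != set(tree.taxa):
        raise ValueError(
            f"column taxa {sorted(column)} do not match tree leaves {list(tree.taxa)}"
        )
    aln = Alignment(tuple(tree.taxa), tuple(column[t].upper() for t in tree.taxa))
    tl = TreeLikelihood.from_alignment(tree, aln)
    return float(np.exp(tl.pattern_log_likelihoods(tl.params_vector())[tl.pattern_of_site[0]]))


def alignment_log_likelihood(
    tree: PhyloTree,
    alignment: Alignment,
    treatment: GapTreatment = GapTreatment.MISSING_DATA,
) -> float:
    """Total log-likelihood of an alignment (i.i.d. columns) at the tree's p(e).

    An alignment that is empty after treatment (R = 0, e.g. fully stripped)
    has likelihood 1: the function warns and returns 0.0.
    """
    tl = TreeLikelihood.from_alignment(tree, alignment, treatment)
    if tl.k == 0:
        warnings.warn(
            "alignment has no sites after gap treatment; log-likelihood is 0 "
            "(probability 1) and carries no information",
            DegenerateAlignmentWarning,
            stacklevel=2,
        )
        return 0.0
    return tl.exact_log_likelihood(tl.params_vector())
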