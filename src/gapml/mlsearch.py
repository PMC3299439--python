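"""Supremum JC likelihood per topology, and exhaustive ML over topologies.

The likelihood domain of the JC model is the open box (0, 3/4)^|E|, so the
supremum over edge substitution probabilities may sit on the boundary and
not be attained.  The likelihood is continuous in the edge parameters, so
the supremum over the open box equals the maximum over its closure
[0, 3/4]^|E|; the optimiser works on the closure and flags every edge whose
optimum lies at 0 or 3/4, preserving the distinction that the open-domain
supremum may only be approached.

Optimisation is multistart coordinate ascent.  The column likelihood is
linear in each single edge's p (see :mod:`gapml.likelihood`), so with the
other edges held fixed the objective is

    f(p) = sum_c w_c log(a_c + b_c p),

a concave function on [0, 3/4] whose maximiser is a boundary point or the
unique root of f'.  Each coordinate update is therefore solved exactly
(to root-finding precision), and boundary optima — including the all-zero
optimum of monotypic alignments — are landed on exactly rather than
approached numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .alignment import Alignment, GapTreatment
from .likelihood import DegenerateAlignmentWarning, TreeLikelihood
from .trees import PhyloTree, Split, enumerate_unrooted_topologies

__all__ = ["LikelihoodResult", "MLSearchResult", "optimize_edge_params", "exhaustive_ml"]

#: multistart grid: homogeneous starts spanning the box plus random interior
#: points; high starts matter — saturated optima (p near 3/4 on several
#: edges) are separated from the low-p basin by genuine likelihood barriers
_START_LEVELS = (0.01, 0.1, 0.3, 0.5, 0.7)
_N_RANDOM_STARTS = 3
_RANDOM_START_SEED = 20120313  # fixed so results are reproducible run-to-run
_P_HI = 0.75


@dataclass
class LikelihoodResult:
    """Supremum log-likelihood of one topology with its optimising parameters."""

    topology: PhyloTree
    sup_log_likelihood: float
    edge_params: Dict[Split, float]
    boundary_flags: Dict[Split, Optional[str]]  # 'lower' (p=0), 'upper' (p=3/4), None
    degenerate: bool = False

    @property
    def at_lower_boundary(self) -> bool:
        return all(f == "lower" for f in self.boundary_flags.values())


@dataclass
class MLSearchResult:
    """Exhaustive ML over all unrooted topologies on the alignment's taxa."""

    results: List[LikelihoodResult]
    tie_tol: float
    best_log_likelihood: float = field(init=False)
    optimal: List[LikelihoodResult] = field(init=False)

    def __post_init__(self):
        if not self.results:
            raise ValueError("no topologies searched")
        self.best_log_likelihood = max(r.sup_log_likelihood for r in self.results)
        scale = max(abs(self.best_log_likelihood), 1.0)
        self.optimal = [
            r
            for r in self.results
            if self.best_log_likelihood - r.sup_log_likelihood <= self.tie_tol * scale
        ]

    @property
    def n_topologies(self) -> int:
        return len(self.results)

    @property
    def optimal_topologies(self) -> List[PhyloTree]:
        return [r.topology for r in self.optimal]

    @property
    def log_likelihood_spread(self) -> float:
        """max − min supremum log-likelihood across all topologies."""
        vals = [r.sup_log_likelihood for r in self.results]
        return max(vals) - min(vals)


def _maximize_edge(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    """Exact maximiser of sum(w * log(a + b p)) over p in [0, 3/4].

    Concave in p; ties (flat objective) break toward 0 so that boundary
    suprema are represented exactly.
    """
    nz = b != 0.0
    if not nz.any():
        return 0.0  # flat in this edge
    a_nz, b_nz, w_nz = a[nz], b[nz], w[nz]

    def deriv(p: float) -> float:
        return float(np.sum(w_nz * b_nz / (a_nz + b_nz * p)))

    # derivative at the lower end: +inf if some pattern needs p > 0
    lo = 0.0
    if np.any((a_nz == 0.0) & (b_nz > 0.0)):
        d_lo = np.inf
    else:
        d_lo = deriv(0.0)
    if d_lo <= 0.0:
        return 0.0
    hi = _P_HI
    hi_vals = a_nz + b_nz * hi
    if np.any(hi_vals <= 0.0):
        # objective -> -inf at 3/4; shrink the bracket away from the pole
        hi = float(np.min(-a_nz[b_nz < 0.0] / b_nz[b_nz < 0.0])) * (1 - 1e-12)
        d_hi = deriv(hi)
    else:
        d_hi = deriv(hi)
        if d_hi >= 0.0:
            return _P_HI
    if d_hi >= 0.0:
        return hi
    if d_lo == np.inf:
        lo = 1e-300  # strictly inside; deriv finite there
        if deriv(lo) <= 0.0:
            return lo
    return float(brentq(deriv, lo, hi, xtol=1e-14))


def _ascend_multistart(
    tl: TreeLikelihood,
    starts: Sequence[np.ndarray],
    tol: float,
    max_sweeps: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Coordinate ascent on all starts jointly (shared pruning passes).

    Returns (params (S, E), objective (S,)).  All starts sweep in lockstep;
    the loop ends when no coordinate moved or no start improved by `tol`.
    """
    P = np.vstack(starts)
    S, E = P.shape
    w = tl.weights
    best = tl.multi_log_likelihood(P)
    obj = best.copy()
    for _ in range(max_sweeps):
        changed = False
        for e in range(E):
            a, b = tl.multi_edge_linear_coefficients(P, e)
            for s in range(S):
                p_new = _maximize_edge(a[s], b[s], w)
                if p_new != P[s, e]:
                    P[s, e] = p_new
                    changed = True
            if e == E - 1:
                # objective comes free from the last edge's linear coefficients
                with np.errstate(divide="ignore", invalid="ignore"):
                    vals = a + b * P[:, e][:, None]
                    obj = np.where(
                        (vals > 0).all(axis=1),
                        np.log(np.where(vals > 0, vals, 1.0)) @ w,
                        -np.inf,
                    )
        if not changed:
            break
        if np.max(obj - best) < tol:
            best = np.maximum(best, obj)
            break
        best = np.maximum(best, obj)
    return P, tl.multi_log_likelihood(P)


def optimize_edge_params(
    topology: PhyloTree,
    alignment: Alignment,
    treatment: GapTreatment = GapTreatment.MISSING_DATA,
    *,
    tol: float = 1e-10,
    max_sweeps: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> LikelihoodResult:
    """Maximise the JC log-likelihood over edge probabilities in [0, 3/4]^|E|.

    Multistart coordinate ascent (homogeneous starts across the box plus
    random interior starts); each coordinate subproblem is concave and solved
    exactly, so boundary optima are reported with exact 0 or 3/4 parameters
    and flagged in ``boundary_flags``.

    An alignment with no usable sites (e.g. fully stripped) yields a
    degenerate result with score 0.0 and a warning, not an exception.
    """
    tl = TreeLikelihood.from_alignment(topology, alignment, treatment)
    splits = tl.splits
    if tl.k == 0:
        warnings.warn(
            "no sites remain after gap treatment; every topology scores "
            "log-likelihood 0 (probability 1)",
            DegenerateAlignmentWarning,
            stacklevel=2,
        )
        zero = {s: 0.0 for s in splits}
        return LikelihoodResult(
            topology.with_edge_params(zero),
            0.0,
            zero,
            {s: "lower" for s in splits},
            degenerate=True,
        )

    if rng is None:
        rng = np.random.default_rng(_RANDOM_START_SEED)
    n_edges = len(splits)
    starts = [np.full(n_edges, lvl) for lvl in _START_LEVELS]
    starts.extend(rng.uniform(0.0, _P_HI, size=(_N_RANDOM_STARTS, n_edges)))

    all_params, scores = _ascend_multistart(tl, starts, tol, max_sweeps)
    best_params = all_params[int(np.argmax(scores))]

    sup = tl.exact_log_likelihood(best_params)
    edge_params = {s: float(p) for s, p in zip(splits, best_params)}
    flags = {
        s: ("lower" if p == 0.0 else "upper" if p == _P_HI else None)
        for s, p in edge_params.items()
    }
    return LikelihoodResult(
        topology.with_edge_params(edge_params), sup, edge_params, flags
    )


def exhaustive_ml(
    alignment: Alignment,
    treatment: GapTreatment = GapTreatment.MISSING_DATA,
    tie_tol: float = 1e-9,
    *,
    max_taxa: int = 8,
    tol: float = 1e-10,
) -> MLSearchResult:
    """Score every unrooted binary topology; return all within `tie_tol` of best.

    `tie_tol` is a relative log-likelihood tolerance (scaled by max(|best|, 1));
    monotypic-alignment ties are bit-exact, so it only absorbs optimiser noise
    on data with genuine signal.
    """
    n = alignment.n_taxa
    if n < 3 or n > max_taxa:
        raise ValueError(
            f"exhaustive search covers 3..{max_taxa} taxa, got {n}; "
            "heuristic search for larger trees is out of scope"
        )
    results = [
        optimize_edge_params(topo, alignment, treatment, tol=tol)
        for topo in enumerate_unrooted_topologies(alignment.taxa)
    ]
    return MLSearchResult(results, tie_tol)
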