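"""End-to-end demonstrations of the flat ML surface and the gap-signal contrast.

Three orchestrated experiments, all exact and fully seeded:

* :func:`verify_lemma1` — on a monotypic alignment, every unrooted topology's
  supremum JC likelihood (gaps as missing data) equals (1/4)^R, attained in
  the limit of all edge substitution probabilities -> 0.  Because all trees
  tie, ML carries no topological information: on data generated by an
  indel-only process it is statistically inconsistent no matter how long the
  sequences grow.
* :func:`run_inconsistency_experiment` — simulates the indel-only regime
  (and any other configured conditions), confirms the flat surface on every
  replicate, and contrasts it with gap-coded parsimony, which typically
  rejects most topologies on the same data.
* :func:`recovery_vs_length` — the substitution-only control: with gap-free
  data, exhaustive ML concentrates on the true topology as sequence length
  grows, the classical consistency behaviour the flat surface destroys.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment, GapTreatment, gap_code, is_monotypic
from .gapsignal import estimate_tree_from_gaps
from .mlsearch import exhaustive_ml
from .simulate import SimulationConfig, simulate_alignment
from .trees import PhyloTree, n_unrooted_topologies, rf_distance, write_newick

__all__ = [
    "Lemma1Record",
    "Lemma1Report",
    "verify_lemma1",
    "ExperimentCondition",
    "ExperimentReport",
    "run_inconsistency_experiment",
    "recovery_vs_length",
]

LOG_QUARTER = math.log(0.25)


# ---------------------------------------------------------------------------
# flat-surface verification
# ---------------------------------------------------------------------------


@dataclass
class Lemma1Record:
    newick: str
    sup_log_likelihood: float
    exact: bool                 # equals R*log(1/4) bit-exactly
    all_lower_boundary: bool    # optimiser put every edge at p = 0


@dataclass
class Lemma1Report:
    n_sites: int
    expected_log_likelihood: float
    records: List[Lemma1Record]

    @property
    def n_topologies(self) -> int:
        return len(self.records)

    @property
    def n_exact(self) -> int:
        return sum(r.exact for r in self.records)

    @property
    def all_exact(self) -> bool:
        return self.n_exact == self.n_topologies

    @property
    def log_likelihood_spread(self) -> float:
        vals = [r.sup_log_likelihood for r in self.records]
        return max(vals) - min(vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "topology": [r.newick for r in self.records],
                "sup_log_likelihood": [r.sup_log_likelihood for r in self.records],
                "exact_quarter_power": [r.exact for r in self.records],
                "all_edges_at_zero": [r.all_lower_boundary for r in self.records],
            }
        )


def verify_lemma1(alignment: Alignment) -> Lemma1Report:
    """Check the flat-surface identity sup-lik = (1/4)^R on every topology.

    Requires a monotypic alignment (that is the hypothesis of the identity);
    raises ``ValueError`` otherwise.  The check is bit-exact in log space:
    the optimiser must land on the all-zero boundary, where each column's
    likelihood is exactly the 1/4 probability of drawing its one nucleotide
    at the root.
    """
    if not is_monotypic(alignment):
        raise ValueError("verify_lemma1 requires a monotypic alignment")
    R = alignment.n_sites
    expected = R * LOG_QUARTER
    search = exhaustive_ml(alignment, GapTreatment.MISSING_DATA)
    records = [
        Lemma1Record(
            newick=write_newick(r.topology, include_params=False),
            sup_log_likelihood=r.sup_log_likelihood,
            exact=(r.sup_log_likelihood == expected),
            all_lower_boundary=r.at_lower_boundary,
        )
        for r in search.results
    ]
    return Lemma1Report(R, expected, records)


# ---------------------------------------------------------------------------
# simulation experiments
# ---------------------------------------------------------------------------


@dataclass
class ExperimentCondition:
    """One cell of the simulation grid."""

    label: str
    tree: PhyloTree
    subst_p: float = 0.0
    del_p: float = 0.0
    ins_p: float = 0.0
    root_length: int = 200


@dataclass
class ExperimentReport:
    records: pd.DataFrame           # one row per (condition, replicate)
    summary: Dict[str, Dict]        # per-condition aggregates
    seed: int

    def condition_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.summary).T


def _replicate_seed(base_seed: int, cond_idx: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(cond_idx, rep))
    return int(ss.generate_state(1)[0] % (2**31))


def run_inconsistency_experiment(
    conditions: Sequence[ExperimentCondition],
    replicates: int = 20,
    seed: int = 0,
) -> ExperimentReport:
    """Simulate each condition and measure what ML and the gap signal can see.

    Per replicate: simulate the true alignment, record whether it is
    monotypic, run exhaustive JC ML with gaps as missing data (optimal-set
    size and log-likelihood spread over topologies), and run gap-coded
    parsimony (optimal-set size and minimum RF distance of the optimal set
    to the true topology).  Aggregates are replicate-order invariant and
    the whole report is a pure function of (conditions, replicates, seed).
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rows = []
    for ci, cond in enumerate(conditions):
        n = cond.tree.n_leaves
        if n > 7:
            raise ValueError(
                f"condition {cond.label!r}: exhaustive search limited to 7 taxa, got {n}"
            )
        n_topos = n_unrooted_topologies(n)
        for rep in range(replicates):
            rep_seed = _replicate_seed(seed, ci, rep)
            t0 = time.perf_counter()
            sim = simulate_alignment(
                SimulationConfig(
                    tree=cond.tree,
                    subst_p=cond.subst_p,
                    del_p=cond.del_p,
                    ins_p=cond.ins_p,
                    root_length=cond.root_length,
                    seed=rep_seed,
                )
            )
            aln = sim.alignment
            mono = is_monotypic(aln)
            search = exhaustive_ml(aln, GapTreatment.MISSING_DATA)
            ml_rf_min = min(
                rf_distance(t, cond.tree) for t in search.optimal_topologies
            )
            gaps = gap_code(aln)
            if gaps.n_characters > 0:
                gap_result = estimate_tree_from_gaps(gaps)
                gap_opt = len(gap_result.optimal)
                gap_rf_min = min(
                    rf_distance(t, cond.tree) for t in gap_result.optimal
                )
            else:
                gap_opt = n_topos
                gap_rf_min = 0
            rows.append(
                {
                    "condition": cond.label,
                    "replicate": rep,
                    "seed": rep_seed,
                    "n_taxa": n,
                    "R": aln.n_sites,
                    "monotypic": mono,
                    "best_log_likelihood": search.best_log_likelihood,
                    "ml_log_likelihood_spread": search.log_likelihood_spread,
                    "ml_optimal_set_size": len(search.optimal),
                    "n_topologies": n_topos,
                    "ml_rf_min": ml_rf_min,
                    "n_gap_characters": gaps.n_characters,
                    "gap_optimal_set_size": gap_opt,
                    "gap_rf_min": gap_rf_min,
                    "runtime_s": time.perf_counter() - t0,
                }
            )
    records = pd.DataFrame(rows)
    summary: Dict[str, Dict] = {}
    for cond in conditions:
        sub = records[records["condition"] == cond.label]
        summary[cond.label] = {
            "replicates": int(len(sub)),
            "frac_monotypic": float(sub["monotypic"].mean()),
            "frac_ml_surface_flat": float(
                (sub["ml_optimal_set_size"] == sub["n_topologies"]).mean()
            ),
            "mean_ml_optimal_fraction": float(
                (sub["ml_optimal_set_size"] / sub["n_topologies"]).mean()
            ),
            "max_ml_log_likelihood_spread": float(
                sub["ml_log_likelihood_spread"].max()
            ),
            "frac_gap_strict_subset": float(
                (sub["gap_optimal_set_size"] < sub["n_topologies"]).mean()
            ),
            "mean_gap_optimal_fraction": float(
                (sub["gap_optimal_set_size"] / sub["n_topologies"]).mean()
            ),
            "frac_gap_set_contains_truth": float((sub["gap_rf_min"] == 0).mean()),
            "mean_R": float(sub["R"].mean()),
        }
    return ExperimentReport(records, summary, seed)


def recovery_vs_length(
    tree: PhyloTree,
    subst_p: float,
    lengths: Sequence[int],
    replicates: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of replicates where ML's optimal set is exactly the true tree.

    Substitution-only (gap-free) control: sequences of growing length L are
    simulated on `tree` with per-edge substitution probability `subst_p` and
    no indels; exhaustive JC ML is run on each.  Returns one row per L with
    the recovery fraction and the mean minimum RF distance to the truth.
    """
    rows = []
    for li, L in enumerate(lengths):
        recovered = 0
        rf_sum = 0
        for rep in range(replicates):
            rep_seed = _replicate_seed(seed, 1000 + li, rep)
            sim = simulate_alignment(
                SimulationConfig(
                    tree=tree, subst_p=subst_p, del_p=0.0, root_length=L, seed=rep_seed
                )
            )
            search = exhaustive_ml(sim.alignment, GapTreatment.MISSING_DATA)
            opt = search.optimal_topologies
            rf_min = min(rf_distance(t, tree) for t in opt)
            rf_sum += rf_min
            if len(opt) == 1 and rf_min == 0:
                recovered += 1
        rows.append(
            {
                "L": L,
                "replicates": replicates,
                "recovery_fraction": recovered / replicates,
                "mean_rf_min": rf_sum / replicates,
            }
        )
    return pd.DataFrame(rows)
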