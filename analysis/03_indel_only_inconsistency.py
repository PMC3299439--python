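"""Simulate the inconsistency regime: indels without substitutions.

Sequences evolve down a known 5-taxon tree with per-edge deletion
probability 0.15 and zero substitution probability, so every replicate's
true alignment is monotypic.  On each replicate we run exhaustive JC ML
with gaps as missing data (expected: all 15 topologies tie at (1/4)^R —
the estimator cannot converge on the true tree at any sequence length)
and, as the contrast, gap-coded Fitch parsimony (expected: a strict subset
of topologies, usually containing the truth).

A second exploratory condition adds a small substitution probability
(p = 0.01); its alignments are no longer monotypic and ML regains some
discrimination.  Writes results/indel_only.tsv and results/indel_only.json.
"""

import argparse
import json
from pathlib import Path

from gapml import parse_newick
from gapml.experiments import ExperimentCondition, run_inconsistency_experiment

TRUE_TREE = "((a,b),(c,d),e);"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", default="results", type=Path)
    parser.add_argument("--seed", default=0, type=int)
    parser.add_argument("--replicates", default=20, type=int)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    tree = parse_newick(TRUE_TREE)
    conditions = [
        ExperimentCondition("indel_only", tree, subst_p=0.0, del_p=0.15,
                            root_length=200),
        ExperimentCondition("low_subst", tree, subst_p=0.01, del_p=0.15,
                            root_length=200),
    ]
    report = run_inconsistency_experiment(conditions, replicates=args.replicates,
                                          seed=args.seed)
    report.records.to_csv(args.out_dir / "indel_only.tsv", sep="\t", index=False)
    payload = {"seed": args.seed, "true_tree": TRUE_TREE, "summary": report.summary}
    (args.out_dir / "indel_only.json").write_text(json.dumps(payload, indent=2))

    for label, s in report.summary.items():
        print(f"[{label}] monotypic: {s['frac_monotypic']:.2f}  "
              f"ML surface flat: {s['frac_ml_surface_flat']:.2f}  "
              f"gap-parsimony strict subset: {s['frac_gap_strict_subset']:.2f}  "
              f"gap set contains truth: {s['frac_gap_set_contains_truth']:.2f}")
    flat = report.summary["indel_only"]["frac_ml_surface_flat"]
    if flat == 1.0:
        print("indel-only regime: ML with gaps as missing data learned nothing "
              "about the tree in any replicate; the gap signal did.")


if __name__ == "__main__":
    main()
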