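"""Phylogenetic signal in the gap pattern of an alignment.

Monotypic alignments give a flat likelihood surface when gaps are treated as
missing data (see :mod:`gapml.mlsearch`), yet their gap pattern is not
informationless: coding each gapped column as a binary presence/absence
character and scoring topologies by small parsimony separates topologies
whenever some character is parsimony-informative.

This is a demonstration that signal EXISTS in the gaps — parsimony on gap
characters is not claimed to be a statistically consistent tree estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

from .alignment import GapCharacterMatrix
from .trees import PhyloTree, enumerate_unrooted_topologies

__all__ = ["gap_parsimony_scores", "GapTreeResult", "estimate_tree_from_gaps"]


def gap_parsimony_scores(matrix: GapCharacterMatrix, topology: PhyloTree) -> int:
    """Total Fitch small-parsimony score of the binary gap characters.

    Sum over characters of the minimum number of presence/absence state
    changes on the topology.  A constant character costs 0; a character
    whose presence set is one side of a bipartition of the tree costs 1.
    """
    if set(matrix.taxa) != set(topology.taxa):
        raise ValueError(
            "gap matrix taxa and topology leaf set differ: "
            f"{sorted(set(matrix.taxa) ^ set(topology.taxa))}"
        )
    if matrix.n_characters == 0:
        return 0

    # root on a pendant edge so every internal node is binary (Fitch is exact)
    root, order = topology.postorder_edges(
        root=next(n for n in topology.nodes() if topology.is_leaf(n))
    )
    col = {t: j for j, t in enumerate(matrix.taxa)}
    K = matrix.n_characters

    def leaf_masks(node: int) -> List[int]:
        row = matrix.characters[col[topology.leaf_label(node)]]
        return [1 << row[k] for k in range(K)]

    masks: Dict[int, List[int]] = {}
    changes = [0] * K
    for child, parent, _split in order:
        child_masks = masks.pop(child, None) or leaf_masks(child)
        acc = masks.get(parent)
        if acc is None:
            if topology.is_leaf(parent):  # the chosen root leaf
                own = leaf_masks(parent)
                for k in range(K):
                    if not (own[k] & child_masks[k]):
                        changes[k] += 1
                        child_masks[k] |= own[k]
            masks[parent] = child_masks
        else:
            for k in range(K):
                inter = acc[k] & child_masks[k]
                if inter:
                    acc[k] = inter
                else:
                    acc[k] = acc[k] | child_masks[k]
                    changes[k] += 1
    return sum(changes)


@dataclass
class GapTreeResult:
    """Exhaustive gap-parsimony scoring of all topologies."""

    topologies: List[PhyloTree]
    scores: List[int]
    best_score: int = field(init=False)
    optimal: List[PhyloTree] = field(init=False)

    def __post_init__(self):
        self.best_score = min(self.scores)
        self.optimal = [
            t for t, s in zip(self.topologies, self.scores) if s == self.best_score
        ]

    @property
    def n_topologies(self) -> int:
        return len(self.topologies)

    @property
    def is_strict_subset(self) -> bool:
        """True iff the gap signal rules out at least one topology."""
        return len(self.optimal) < len(self.topologies)


def estimate_tree_from_gaps(
    matrix: GapCharacterMatrix, *, max_taxa: int = 8
) -> GapTreeResult:
    """All topologies minimising the total gap-parsimony score (full tie set).

    With zero coded characters every topology ties; with at least one
    parsimony-informative character the optimal set is a strict subset of
    the (2n-5)!! topologies.
    """
    n = len(matrix.taxa)
    if n < 3 or n > max_taxa:
        raise ValueError(f"exhaustive gap-tree search covers 3..{max_taxa} taxa, got {n}")
    topologies = list(enumerate_unrooted_topologies(matrix.taxa))
    scores = [gap_parsimony_scores(matrix, t) for t in topologies]
    return GapTreeResult(topologies, scores)
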