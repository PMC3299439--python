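"""Seeded simulation of sequence evolution with substitutions and indels.

Sequences evolve down a binary tree from a uniform-random root sequence.
On each edge, independently per surviving site: the site is deleted with
probability d(e); a site that survives substitutes with probability p(e),
moving to one of the other three nucleotides uniformly (the JC rule).
Optionally, single-residue insertions occur independently in each of the
m+1 slots of the current m-residue sequence with probability i(e),
creating a brand-new homology column present only in lineages below the
insertion point.

Because every residue keeps a global homology-column identity, the TRUE
alignment is known by construction: each output column is one homology
class, deleted lineages showing '-'.  A deleted column never re-acquires a
residue in that lineage, so two residue-bearing leaves in a column imply
residues along the whole path between them (positional homology).

The zero-substitution regime (all p(e) = 0, some d(e) > 0) produces
monotypic alignments: every column's surviving characters are copies of a
single root or inserted nucleotide.

Randomness: one top-level seed; each edge draws from its own substream
keyed by a stable hash of the edge's leaf-label split, so results do not
depend on traversal order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .alignment import NUCS, Alignment
from .trees import PhyloTree, Split

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_alignment",
    "random_monotypic_alignment",
    "printed_alignment_fixture",
]

EdgeValue = Union[float, Dict[Split, float]]


def _edge_value(spec: EdgeValue, split: Split, name: str, lo: float, hi: float,
                closed_hi: bool = True) -> float:
    v = spec[split] if isinstance(spec, dict) else spec
    v = float(v)
    ok = lo <= v <= hi if closed_hi else lo <= v < hi
    if not ok:
        br = "]" if closed_hi else ")"
        raise ValueError(f"{name} must lie in [{lo}, {hi}{br}, got {v}")
    return v


@dataclass
class SimulationConfig:
    """Parameters of one simulated evolutionary history.

    ``subst_p``, ``del_p`` and ``ins_p`` may be scalars (applied to every
    edge) or dicts keyed by canonical edge split.
    """

    tree: PhyloTree
    subst_p: EdgeValue = 0.0        # JC substitution probability per edge, [0, 3/4]
    del_p: EdgeValue = 0.0          # per-site deletion probability per edge, [0, 1]
    ins_p: EdgeValue = 0.0          # per-slot insertion probability per edge, [0, 1)
    root_length: int = 100          # L, residues in the root sequence
    seed: int = 0

    def __post_init__(self):
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        for split in self.tree.edge_params:
            _edge_value(self.subst_p, split, "subst_p", 0.0, 0.75)
            _edge_value(self.del_p, split, "del_p", 0.0, 1.0)
            _edge_value(self.ins_p, split, "ins_p", 0.0, 1.0, closed_hi=False)


@dataclass
class SimulationResult:
    alignment: Alignment                       # the true alignment; columns = homology classes
    tree: PhyloTree
    event_counts: Dict[Split, Dict[str, int]]  # per-edge substitutions/deletions/insertions
    n_root_columns: int                        # root columns surviving in >= 1 leaf

    @property
    def n_sites(self) -> int:
        return self.alignment.n_sites


def _edge_rng(seed: int, split: Split) -> np.random.Generator:
    key = zlib.crc32(",".join(sorted(split)).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, key)))


def simulate_alignment(config: SimulationConfig) -> SimulationResult:
    """Run one evolutionary history; returns the true alignment and event log."""
    tree = config.tree
    root = tree._default_root()
    L = config.root_length

    root_rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    root_ids = np.arange(L, dtype=np.int64)
    root_codes = root_rng.integers(0, 4, size=L).astype(np.int8)

    master_order: List[int] = list(range(L))  # global left-to-right column order
    next_col_id = L
    leaf_states: Dict[str, Dict[int, int]] = {}
    event_counts: Dict[Split, Dict[str, int]] = {
        s: {"substitutions": 0, "deletions": 0, "insertions": 0}
        for s in tree.edge_params
    }
    splits = tree.edge_splits()

    # iterative preorder; children visited in sorted order for determinism
    stack: List[Tuple[int, int, np.ndarray, np.ndarray]] = [
        (root, -1, root_ids, root_codes)
    ]
    while stack:
        node, parent, ids, codes = stack.pop()
        if tree.is_leaf(node):
            leaf_states[tree.leaf_label(node)] = dict(
                zip(ids.tolist(), codes.tolist())
            )
        for child in sorted(tree.neighbors(node)):
            if child == parent:
                continue
            split = splits[(min(node, child), max(node, child))]
            p = _edge_value(config.subst_p, split, "subst_p", 0.0, 0.75)
            d = _edge_value(config.del_p, split, "del_p", 0.0, 1.0)
            ins = _edge_value(config.ins_p, split, "ins_p", 0.0, 1.0, False)
            rng = _edge_rng(config.seed, split)

            # deletion first: a deleted site cannot substitute on this edge
            keep = rng.random(len(ids)) >= d
            n_del = int(len(ids) - keep.sum())
            child_ids = ids[keep]
            child_codes = codes[keep].copy()

            sub_mask = rng.random(len(child_ids)) < p
            n_sub = int(sub_mask.sum())
            if n_sub:
                shift = rng.integers(1, 4, size=n_sub).astype(np.int8)
                child_codes[sub_mask] = (child_codes[sub_mask] + shift) % 4

            n_ins = 0
            if ins > 0.0:
                m = len(child_ids)
                slot_hits = np.flatnonzero(rng.random(m + 1) < ins)
                if len(slot_hits):
                    new_codes = rng.integers(0, 4, size=len(slot_hits)).astype(np.int8)
                    id_list = child_ids.tolist()
                    code_list = child_codes.tolist()
                    # insert right-to-left so earlier slot indices stay valid
                    for slot, code in zip(slot_hits[::-1], new_codes[::-1]):
                        cid = next_col_id
                        next_col_id += 1
                        id_list.insert(slot, cid)
                        code_list.insert(slot, int(code))
                        # place in the master order: immediately after the
                        # column left of the slot (or at the front)
                        if slot == 0:
                            pos = (
                                master_order.index(id_list[1])
                                if len(id_list) > 1
                                else 0
                            )
                        else:
                            pos = master_order.index(id_list[slot - 1]) + 1
                        master_order.insert(pos, cid)
                        n_ins += 1
                    child_ids = np.asarray(id_list, dtype=np.int64)
                    child_codes = np.asarray(code_list, dtype=np.int8)

            ec = event_counts[split]
            ec["deletions"] += n_del
            ec["substitutions"] += n_sub
            ec["insertions"] += n_ins
            stack.append((child, node, child_ids, child_codes))

    taxa = tree.taxa
    surviving = [
        cid
        for cid in master_order
        if any(cid in leaf_states[t] for t in taxa)
    ]
    rows = tuple(
        "".join(
            NUCS[leaf_states[t][cid]] if cid in leaf_states[t] else "-"
            for cid in surviving
        )
        for t in taxa
    )
    alignment = Alignment(tuple(taxa), rows)
    n_root_surviving = sum(1 for cid in surviving if cid < L)
    return SimulationResult(alignment, tree, event_counts, n_root_surviving)


def random_monotypic_alignment(
    n_taxa: int, n_sites: int, rng: np.random.Generator
) -> Alignment:
    """A random monotypic alignment: per column one nucleotide type spread
    over a random non-empty subset of taxa, gaps elsewhere.

    This samples the *hypothesis class* of the flat-surface identity directly
    (arbitrary gap patterns), independent of any particular indel process.
    """
    if n_taxa < 2 or n_sites < 1:
        raise ValueError("need >= 2 taxa and >= 1 site")
    taxa = tuple(f"t{i + 1}" for i in range(n_taxa))
    cols = []
    for _ in range(n_sites):
        nuc = NUCS[rng.integers(0, 4)]
        present = rng.random(n_taxa) < rng.uniform(0.2, 0.9)
        if not present.any():
            present[rng.integers(0, n_taxa)] = True
        cols.append(["-" if not p else nuc for p in present])
    rows = tuple("".join(col[j] for col in cols) for j in range(n_taxa))
    return Alignment(taxa, rows)


def printed_alignment_fixture() -> Alignment:
    """The built-in 7-taxon, 3-site monotypic alignment.

    Every column contains gaps (stripping gapped sites empties it), two rows
    are entirely gaps, and each column's residues are a single nucleotide
    type — yet the gap pattern still carries phylogenetic signal.
    """
    return Alignment.from_dict(
        {
            "s1": "A--",
            "s2": "-C-",
            "s3": "A--",
            "s4": "---",
            "s5": "---",
            "s6": "--T",
            "s7": "A--",
        }
    )
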