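"""Phylogenetic-association screening for candidate xylanolytic taxa.

Given a phylogeny whose leaves include species with experimentally confirmed
xylanolytic activity, unlabeled (often non-sequenced) taxa are ranked by
patristic proximity — the sum of branch lengths along the tree path — to the
labeled set.  Close relatives of strong xylan degraders are the most
promising candidates for wet-lab characterization.  Pairwise percent
identity of protein sequences is provided for follow-up comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import dendropy
from Bio import Align

__all__ = [
    "PhyloTree",
    "AssociationRanking",
    "read_newick",
    "patristic_distance",
    "rank_candidates",
    "pairwise_identity",
]


@dataclass
class PhyloTree:
    """A leaf-labeled tree with branch lengths (substitutions per site).

    Wraps a :class:`dendropy.Tree`; missing edge lengths default to 0 with a
    warning at load time.  Patristic distances are root-invariant, so
    unrooted input is accepted.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [l.taxon.label for l in self.tree.leaf_node_iter()]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
        missing = 0
        for edge in self.tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
                if edge.head_node is not self.tree.seed_node:
                    missing += 1
        if missing:
            warnings.warn(
                f"{missing} edges had no branch length; defaulted to 0",
                stacklevel=2,
            )
        self._pdm = None

    @property
    def leaf_labels(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]

    def _distance_matrix(self):
        if self._pdm is None:
            self._pdm = self.tree.phylogenetic_distance_matrix()
        return self._pdm

    def write_newick(self, path: str | Path) -> None:
        self.tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(source: str | Path) -> PhyloTree:
    """Read a Newick tree from a path (or a literal Newick string).

    Internal-node labels (bootstrap values) are tolerated and ignored for
    distance purposes.
    """
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    return PhyloTree(tree=tree)


def patristic_distance(tree: PhyloTree, a: str, b: str) -> float:
    """Sum of branch lengths along the unique path between leaves a and b."""
    if a == b:
        _require_leaf(tree, a)
        return 0.0
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    for label in (a, b):
        if label not in taxa or not _is_leaf_label(tree, label):
            raise KeyError(f"unknown leaf {label!r}")
    return float(tree._distance_matrix().patristic_distance(taxa[a], taxa[b]))


def _is_leaf_label(tree: PhyloTree, label: str) -> bool:
    return label in tree.leaf_labels


def _require_leaf(tree: PhyloTree, label: str) -> None:
    if not _is_leaf_label(tree, label):
        raise KeyError(f"unknown leaf {label!r}")


@dataclass(frozen=True)
class AssociationRanking:
    candidate: str
    statistic: float
    rank: int


def rank_candidates(
    tree: PhyloTree,
    labeled: set[str],
    candidates: set[str],
    statistic: Literal["min", "mean"] = "min",
) -> list[AssociationRanking]:
    """Rank candidate leaves by patristic proximity to the labeled set.

    ``statistic`` aggregates each candidate's distances to all labeled
    leaves (``min`` = distance to the closest confirmed xylanolytic
    species).  Smaller is more promising; ties break alphabetically.
    Returns the full ranking — no hard distance cutoff is imposed.
    """
    if not labeled:
        raise ValueError("labeled set must be non-empty")
    if labeled & candidates:
        raise ValueError(
            f"labeled and candidate sets overlap: {sorted(labeled & candidates)}"
        )
    for label in sorted(labeled | candidates):
        _require_leaf(tree, label)
    if not candidates:
        return []
    scored = []
    for cand in candidates:
        dists = [patristic_distance(tree, cand, lab) for lab in labeled]
        value = min(dists) if statistic == "min" else sum(dists) / len(dists)
        scored.append((value, cand))
    scored.sort()
    return [
        AssociationRanking(candidate=c, statistic=v, rank=i + 1)
        for i, (v, c) in enumerate(scored)
    ]


_IDENTITY_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=0.0,
    open_gap_score=-1.0,
    extend_gap_score=-1.0,
)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over a global alignment, counting gap columns.

    Alignment scoring: match +1, mismatch 0, linear gap -1.  Identity is
    100 * matches / alignment length (gap columns included), one of several
    conventions in use — absolute values depend on this choice.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    alignment = _IDENTITY_ALIGNER.align(seq_a, seq_b)[0]
    a_row, b_row = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    return 100.0 * matches / len(a_row)
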