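"""Phylogeny ingestion, patristic distances, and community diversity metrics.

The three community metrics implemented here are the workhorses of
community-phylogenetic analysis of plot data:

* ``community_pd`` — phylogenetic diversity as the sum of branch lengths of
  the minimal subtree spanning the community, rooted at the community's most
  recent common ancestor. Unlike Faith's PD, the path from the MRCA up to the
  tree root is *not* counted, so a monoculture has PD = 0.
* ``community_mnnd`` — mean nearest-neighbour distance: the mean, over
  community members, of the patristic distance to the closest other member.
  Small values indicate phylogenetic clustering.
* ``community_mpd`` — mean pairwise patristic distance over all unordered
  pairs of members.

All distances are in the branch-length units the tree carries (for a
maximum-likelihood tree, expected substitutions per site); no normalisation
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    NewickParseError,
    TreeValidationError,
    UndefinedStatisticError,
    UnknownSpeciesError,
)

__all__ = [
    "Phylogeny",
    "PatristicMatrix",
    "CommunityMetrics",
    "read_newick",
    "patristic_matrix",
    "community_pd",
    "community_mnnd",
    "community_mpd",
]


@dataclass(frozen=True)
class PatristicMatrix:
    """Symmetric matrix of tip-to-tip path-length sums, indexed by species.

    ``values[i, j]`` is the sum of branch lengths along the unique tree path
    between tips ``labels[i]`` and ``labels[j]``.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    _index: dict = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.labels)})
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("patristic matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("patristic matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("patristic distances must be non-negative")

    def loc(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:
            raise UnknownSpeciesError(str(exc)) from exc

    def indices(self, species: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[s] for s in sorted(species)], dtype=np.intp)
        except KeyError as exc:
            raise UnknownSpeciesError(f"species not in tree: {exc}") from exc

    def submatrix(self, species: Iterable[str]) -> np.ndarray:
        idx = self.indices(species)
        return self.values[np.ix_(idx, idx)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


class Phylogeny:
    """A rooted tree with branch lengths, unique tip labels and optional
    clade tags (``grass`` / ``legume`` / ``other``) per tip.

    Wraps a :class:`dendropy.Tree`; validation happens at construction and the
    wrapped tree is treated as immutable afterwards.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        clade_tags: Optional[Mapping[str, Iterable[str]]] = None,
    ):
        self._tree = tree
        labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
        if any(lab is None or lab == "" for lab in labels):
            raise TreeValidationError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        root = tree.seed_node
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise TreeValidationError(
                    f"missing branch length on edge above {_node_name(node)}"
                )
            if node.edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length ({node.edge.length}) above {_node_name(node)}"
                )
        self.tip_labels: tuple[str, ...] = tuple(sorted(labels))
        tags = {}
        if clade_tags:
            unknown = set(clade_tags) - set(self.tip_labels)
            if unknown:
                raise UnknownSpeciesError(f"clade tags for non-tip species: {sorted(unknown)}")
            tags = {sp: frozenset(t) for sp, t in clade_tags.items()}
        self.clade_tags: dict[str, frozenset[str]] = tags
        self._metrics: Optional[CommunityMetrics] = None

    # -- basic accessors -------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def __len__(self) -> int:
        return len(self.tip_labels)

    @property
    def total_branch_length(self) -> float:
        return float(
            sum(
                n.edge.length
                for n in self._tree.preorder_node_iter()
                if n is not self._tree.seed_node
            )
        )

    def tips_with_tag(self, tag: str) -> frozenset[str]:
        return frozenset(sp for sp, tags in self.clade_tags.items() if tag in tags)

    def validate_species(self, species: Iterable[str]) -> None:
        unknown = set(species) - set(self.tip_labels)
        if unknown:
            raise UnknownSpeciesError(f"species not in tree: {sorted(unknown)}")

    def with_clade_tags(self, clade_tags: Mapping[str, Iterable[str]]) -> "Phylogeny":
        return Phylogeny(self._tree, clade_tags)

    def prune(self, drop_labels: Iterable[str]) -> "Phylogeny":
        """A new phylogeny with the named tips removed (e.g. outgroups)."""
        drop = set(drop_labels)
        self.validate_species(drop)
        clone = self._tree.clone(depth=1)
        clone.prune_taxa_with_labels(drop)
        tags = {sp: t for sp, t in self.clade_tags.items() if sp not in drop}
        return Phylogeny(clone, tags)

    def write_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip() + "\n"

    # -- cached metric engine -------------------------------------------

    @property
    def metrics(self) -> "CommunityMetrics":
        if self._metrics is None:
            self._metrics = CommunityMetrics(self)
        return self._metrics


def _node_name(node) -> str:
    if node.taxon is not None:
        return f"tip '{node.taxon.label}'"
    return "an internal node"


def read_newick(
    text: str,
    *,
    missing_length: str = "error",
    prune: Optional[Iterable[str]] = None,
    clade_tags: Optional[Mapping[str, Iterable[str]]] = None,
) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`.

    Parameters
    ----------
    text:
        Newick with branch lengths on all non-root edges.
    missing_length:
        ``"error"`` (default) rejects trees with missing lengths; ``"zero"``
        imputes 0 instead.
    prune:
        Tip labels to drop after parsing (outgroups such as the early-diverging
        angiosperms used for rooting are typically removed before analysis).
    clade_tags:
        Mapping species -> tags, attached to the result.
    """
    if missing_length not in ("error", "zero"):
        raise ValueError("missing_length must be 'error' or 'zero'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    if missing_length == "zero":
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node and node.edge.length is None:
                node.edge.length = 0.0
    phy = Phylogeny(tree, clade_tags=None)
    if prune:
        phy = phy.prune(prune)
    if clade_tags:
        phy = phy.with_clade_tags(clade_tags)
    return phy


class CommunityMetrics:
    """Vectorised metric engine for one phylogeny.

    Precomputes, for every edge, the set of tips below it (a boolean
    incidence matrix), from which PD and the full patristic matrix follow by
    linear algebra. Batch variants evaluate a statistic over many equally
    sized communities at once; they are what makes 1000-fold randomization
    tests over dozens of plots cheap.
    """

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        self.labels = tree.tip_labels
        self.index = {s: i for i, s in enumerate(self.labels)}
        ntips = len(self.labels)

        dtree = tree.dendropy_tree
        edges_bl = []
        desc_rows = []
        # postorder: each node's tip set is the union of its children's
        tipsets: dict[int, np.ndarray] = {}
        for node in dtree.postorder_node_iter():
            if node.is_leaf():
                mask = np.zeros(ntips, dtype=bool)
                mask[self.index[node.taxon.label]] = True
            else:
                mask = np.zeros(ntips, dtype=bool)
                for child in node.child_nodes():
                    mask |= tipsets[id(child)]
            tipsets[id(node)] = mask
            if node is not dtree.seed_node:
                edges_bl.append(float(node.edge.length))
                desc_rows.append(mask)
        self.branch_lengths = np.asarray(edges_bl)  # (E,)
        self.edge_desc = np.asarray(desc_rows)      # (E, T) bool
        self._desc_f = self.edge_desc.astype(float)

        # patristic distances: an edge separates tips below it from tips above
        a = self._desc_f * self.branch_lengths[:, None]  # (E, T)
        b = 1.0 - self._desc_f
        dist = a.T @ b + b.T @ (self._desc_f * self.branch_lengths[:, None])
        np.fill_diagonal(dist, 0.0)
        self.dist = dist

    # -- index helpers ---------------------------------------------------

    def indices(self, community: Iterable[str]) -> np.ndarray:
        try:
            idx = np.array(sorted(self.index[s] for s in set(community)), dtype=np.intp)
        except KeyError as exc:
            raise UnknownSpeciesError(f"species not in tree: {exc}") from exc
        return idx

    def mask(self, community: Iterable[str]) -> np.ndarray:
        m = np.zeros(len(self.labels), dtype=bool)
        m[self.indices(community)] = True
        return m

    @property
    def patristic(self) -> PatristicMatrix:
        return PatristicMatrix(self.labels, self.dist)

    # -- single-community metrics ----------------------------------------

    def pd(self, community: Iterable[str]) -> float:
        idx = self.indices(community)
        if idx.size == 0:
            raise UndefinedStatisticError("PD of an empty community is undefined")
        mask = np.zeros(len(self.labels), dtype=bool)
        mask[idx] = True
        counts = self.edge_desc.astype(np.int64) @ mask.astype(np.int64)
        k = idx.size
        return float(self.branch_lengths[(counts >= 1) & (counts < k)].sum())

    def pd_batch(self, masks: np.ndarray) -> np.ndarray:
        """PD for each row of a (N, T) boolean membership matrix."""
        counts = self._desc_f @ masks.T.astype(float)  # (E, N)
        k = masks.sum(axis=1).astype(float)            # (N,)
        inner = (counts >= 1) & (counts < k[None, :])
        return self.branch_lengths @ inner

    def mnnd(self, community: Iterable[str]) -> float:
        idx = self.indices(community)
        _require_pair(idx.size, "MNND")
        sub = self.dist[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        return float(sub.min(axis=1).mean())

    def mnnd_batch(self, idx_matrix: np.ndarray) -> np.ndarray:
        """MNND for each row of a (N, k) index matrix, k >= 2."""
        sub = self.dist[idx_matrix[:, :, None], idx_matrix[:, None, :]]
        k = idx_matrix.shape[1]
        sub[:, np.arange(k), np.arange(k)] = np.inf
        return sub.min(axis=2).mean(axis=1)

    def mpd(self, community: Iterable[str]) -> float:
        idx = self.indices(community)
        _require_pair(idx.size, "MPD")
        sub = self.dist[np.ix_(idx, idx)]
        k = idx.size
        return float(sub.sum() / (k * (k - 1)))

    def mpd_batch(self, idx_matrix: np.ndarray) -> np.ndarray:
        sub = self.dist[idx_matrix[:, :, None], idx_matrix[:, None, :]]
        k = idx_matrix.shape[1]
        return sub.sum(axis=(1, 2)) / (k * (k - 1))

    # -- cross-group statistics ------------------------------------------

    def cross_mnnd(self, focal_idx: np.ndarray, ref_idx: np.ndarray) -> float:
        """Mean over focal tips of the min patristic distance to any reference tip."""
        return float(self.dist[np.ix_(focal_idx, ref_idx)].min(axis=1).mean())

    def cross_mnnd_batch(self, focal_matrix: np.ndarray, ref_idx: np.ndarray) -> np.ndarray:
        """Batch version: focal_matrix is (N, k); reference set shared across rows."""
        sub = self.dist[focal_matrix[:, :, None], ref_idx[None, None, :]]
        return sub.min(axis=2).mean(axis=1)


def _require_pair(n: int, name: str) -> None:
    if n < 2:
        raise UndefinedStatisticError(
            f"{name} is undefined for communities of fewer than 2 species (got {n})"
        )


# -- public functional API ------------------------------------------------


def patristic_matrix(tree: Phylogeny) -> PatristicMatrix:
    """Tip-to-tip path-length matrix of ``tree`` (branch-length units)."""
    return tree.metrics.patristic


def community_pd(tree: Phylogeny, community: Iterable[str]) -> float:
    """Phylogenetic diversity of ``community`` on ``tree``.

    Sum of branch lengths of the minimal spanning subtree connecting the
    community's tips, rooted at their MRCA; the MRCA-to-root path is excluded,
    so a single-species community has PD = 0.
    """
    community = set(community)
    if not community:
        raise UndefinedStatisticError("PD of an empty community is undefined")
    tree.validate_species(community)
    return tree.metrics.pd(community)


def community_mnnd(dist: PatristicMatrix, community: Iterable[str]) -> float:
    """Mean nearest-neighbour patristic distance within ``community`` (>= 2 species)."""
    idx = dist.indices(set(community))
    _require_pair(idx.size, "MNND")
    sub = dist.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def community_mpd(dist: PatristicMatrix, community: Iterable[str]) -> float:
    """Mean pairwise patristic distance within ``community`` (>= 2 species)."""
    idx = dist.indices(set(community))
    _require_pair(idx.size, "MPD")
    sub = dist.values[np.ix_(idx, idx)]
    k = idx.size
    return float(sub.sum() / (k * (k - 1)))
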