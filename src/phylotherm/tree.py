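"""Phylogeny handling: Newick I/O, pruning, patristic distances, trait covariance.

The tree is the backbone of every comparative statistic in this package: it
supplies the patristic distances binned into classes by the correlogram and
the among-species covariance structures (Brownian motion, Ornstein-Uhlenbeck,
identity) assumed by the generalized least squares models. Parsing is
delegated to dendropy; this module adds strict validation (unique tips,
non-negative branch lengths), deterministic tip ordering, and the covariance
constructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Literal

import dendropy
import numpy as np
import pandas as pd

from .errors import DegenerateStructureError, NewickFormatError, ValidationError

__all__ = [
    "Phylogeny",
    "DistanceMatrix",
    "CovarianceStructure",
    "read_newick",
    "write_newick",
    "prune",
    "patristic_distances",
    "covariance",
]

#: smallest eigenvalue below this is treated as non-positive-definite
PD_TOLERANCE = 1e-10


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of tip-to-tip path lengths (patristic distances)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValidationError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def submatrix(self, labels: Iterable[str]) -> "DistanceMatrix":
        labels = tuple(labels)
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class CovarianceStructure:
    """Among-species covariance/correlation matrix under an evolutionary model.

    kind="BM"       C_ij = shared root-to-MRCA path length (diagonal = depth)
    kind="OU"       C_ij = exp(-alpha * d_ij), unit diagonal (Martins-Hansen)
    kind="identity" C = I  (conventional, non-phylogenetic)
    """

    kind: Literal["BM", "OU", "identity"]
    labels: tuple[str, ...]
    C: np.ndarray
    alpha: float | None = None

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        object.__setattr__(self, "C", C)
        n = len(self.labels)
        if C.shape != (n, n):
            raise ValidationError("covariance shape does not match labels")
        smallest = float(np.linalg.eigvalsh(C)[0])
        if smallest <= PD_TOLERANCE:
            raise DegenerateStructureError(
                f"{self.kind} covariance is not positive definite "
                f"(smallest eigenvalue {smallest:.3e})"
            )


class Phylogeny:
    """A rooted tree with branch lengths; tips are unique species labels.

    Thin wrapper over a dendropy Tree that freezes the tip order (input
    encounter order) and enforces the package's validity rules: unique
    non-empty tip labels, all branch lengths >= 0 with at least one > 0.
    """

    def __init__(self, tree: dendropy.Tree, tip_order: Iterable[str] | None = None):
        self._tree = tree
        leaves = [lf.taxon.label.strip() if lf.taxon else "" for lf in tree.leaf_node_iter()]
        if tip_order is None:
            tip_order = leaves
        self.tips: tuple[str, ...] = tuple(str(t).strip() for t in tip_order)
        self._validate(leaves)

    def _validate(self, leaves: list[str]) -> None:
        if any(not t for t in self.tips):
            raise ValidationError("empty tip label in tree")
        if len(set(self.tips)) != len(self.tips):
            dupes = sorted({t for t in self.tips if self.tips.count(t) > 1})
            raise ValidationError(f"duplicate tip labels: {', '.join(dupes)}")
        if set(leaves) != set(self.tips):
            raise ValidationError("tip order does not match the tree's leaves")
        lengths = [e.length for e in self._tree.preorder_edge_iter() if e.head_node.parent_node]
        if any(l is None for l in lengths):
            raise ValidationError("tree has edges without branch lengths")
        if any(l < 0 for l in lengths):
            raise ValidationError("negative branch length in tree")
        if not any(l > 0 for l in lengths):
            raise ValidationError("all branch lengths are zero")

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        out = {}
        for leaf in self._tree.leaf_node_iter():
            out[leaf.taxon.label.strip()] = leaf.distance_from_root()
        return out

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1), self.tips)

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip() + ("" if s.strip().endswith(";") else ";")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phylogeny({self.n_tips} tips)"


def read_newick(source: str, default_branch_length: float | None = None) -> Phylogeny:
    """Parse a Newick string or file path into a validated Phylogeny.

    Branch lengths are required; a tree with missing lengths raises unless
    ``default_branch_length`` supplies one for every length-less edge.
    """
    import os

    text = source
    if os.path.exists(source) or "(" not in source:
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        pos = getattr(exc, "col_num", None)
        raise NewickFormatError(f"could not parse Newick: {exc}", position=pos) from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is None:
            continue
        if edge.length is None:
            if default_branch_length is None:
                raise ValidationError(
                    "tree has edges without branch lengths; pass default_branch_length"
                )
            edge.length = default_branch_length
    return Phylogeny(tree)


def write_newick(tree: Phylogeny, path: str | None = None) -> str:
    text = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def prune(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict the tree to ``keep``, collapsing unary nodes by summing lengths.

    Patristic distances among retained tips are unchanged — pruning removes
    lineages, it never rescales paths.
    """
    keep = [str(k).strip() for k in keep]
    if len(set(keep)) != len(keep):
        raise ValidationError("duplicate species in keep set")
    missing = sorted(set(keep) - set(tree.tips))
    if missing:
        raise ValidationError(f"species not in tree: {', '.join(missing)}")
    if len(keep) < 2:
        raise ValidationError("need at least 2 species to prune to")
    clone = tree._tree.clone(depth=1)
    clone.retain_taxa_with_labels(keep)
    # retain_taxa suppresses unifurcations, summing the merged branch lengths
    order = [t for t in tree.tips if t in set(keep)]
    return Phylogeny(clone, order)


def _tip_edge_incidence(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (n_tips x n_edges) matrix: tip i descends from edge j; plus lengths."""
    index = {t: i for i, t in enumerate(tree.tips)}
    n = tree.n_tips
    masks, lengths = [], []
    for node in tree._tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        below = np.zeros(n, dtype=bool)
        for leaf in node.leaf_iter():
            below[index[leaf.taxon.label.strip()]] = True
        masks.append(below)
        lengths.append(float(node.edge.length))
    return np.array(masks).T, np.array(lengths)


def patristic_distances(tree: Phylogeny) -> DistanceMatrix:
    """Tip-to-tip path lengths: d_ij = sum of branch lengths on the i..j path."""
    inc, lengths = _tip_edge_incidence(tree)
    # edge is on the i..j path iff exactly one of i, j descends from it
    on_path = inc[:, None, :] ^ inc[None, :, :]
    d = on_path @ lengths
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tree.tips, d)


def covariance(
    tree: Phylogeny,
    kind: Literal["BM", "OU", "identity"],
    alpha: float | None = None,
) -> CovarianceStructure:
    """Among-species covariance structure implied by an evolutionary model.

    BM: C_ij is the shared path length from the root to the MRCA of i and j
    (the classic Brownian-motion covariance, diagonal = root-to-tip depth).
    OU: C_ij = exp(-alpha d_ij) with unit diagonal — the Martins-Hansen
    correlation in which alpha, the selection strength, sets how fast
    similarity decays with patristic distance; alpha -> infinity gives the
    identity (phylogeny-free) structure.
    """
    if kind == "identity":
        return CovarianceStructure("identity", tree.tips, np.eye(tree.n_tips))
    if kind == "BM":
        inc, lengths = _tip_edge_incidence(tree)
        shared = inc[:, None, :] & inc[None, :, :]
        C = shared @ lengths
        return CovarianceStructure("BM", tree.tips, C)
    if kind == "OU":
        if alpha is None or alpha <= 0:
            raise ValidationError("OU structure requires alpha > 0")
        d = patristic_distances(tree).values
        return CovarianceStructure("OU", tree.tips, np.exp(-alpha * d), alpha=float(alpha))
    raise ValidationError(f"unknown covariance kind: {kind!r}")
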