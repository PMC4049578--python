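"""Neighbor joining in composition space.

Animal groups are compared not by sequence but by a variance-scaled trait
distance over group-mean composition variables (default TC and TSN, 5-set):

    D(i, j) = sum_v (v_i - v_j)**2 / sigma_v**2

where sigma_v is the standard deviation of variable v across the groups in
the table (population sigma, divide-by-n, by default; configurable).  The
resulting matrix feeds a from-scratch Saitou-Nei neighbor-joining
agglomeration, with deterministic lowest-index tie-breaking in the Q-matrix
minimization and negative branch lengths clamped to zero (warned).  Trees
are returned as unrooted :class:`skbio.TreeNode` objects; an optional
outgroup rooting is provided for display.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode


@dataclass(frozen=True)
class TraitDistanceSpec:
    variables: tuple[str, ...] = ("TC", "TSN")
    protein_set: str = "set5"
    population_sigma: bool = True


@dataclass
class TraitTree:
    labels: list[str]
    distances: np.ndarray
    tree: TreeNode
    clamped_edges: int = 0
    spec: TraitDistanceSpec | None = None

    def newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()

    def distance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.labels, columns=self.labels)


def trait_distance(
    group_df: pd.DataFrame, spec: TraitDistanceSpec = TraitDistanceSpec()
) -> tuple[np.ndarray, list[str]]:
    """Variance-scaled squared-difference distance between groups.

    ``group_df`` is a group-level composition table with a ``group`` column
    and the spec's variables.  Returns the symmetric matrix and group labels.
    """
    missing = [v for v in spec.variables if v not in group_df.columns]
    if missing:
        raise ValueError(f"missing variables {missing}")
    if len(group_df) < 3:
        raise ValueError("need >= 3 groups")
    labels = list(group_df["group"])
    X = group_df[list(spec.variables)].to_numpy(float)
    sigma = X.std(axis=0, ddof=0 if spec.population_sigma else 1)
    if (sigma == 0).any():
        bad = [v for v, s in zip(spec.variables, sigma) if s == 0]
        raise ValueError(f"zero standard deviation for {bad}")
    Z = X / sigma
    diff = Z[:, None, :] - Z[None, :, :]
    D = (diff**2).sum(axis=2)
    np.fill_diagonal(D, 0.0)
    return D, labels


def _check_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if D.shape[0] < 3:
        raise ValueError("need >= 3 taxa")
    if np.isnan(D).any():
        raise ValueError("NaN in distance matrix")
    if (D < 0).any():
        raise ValueError("negative distances")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("matrix not symmetric")
    if not np.all(np.diagonal(D) == 0):
        raise ValueError("nonzero diagonal")
    return D


def neighbor_joining(
    D: np.ndarray, labels: Sequence[str], clamp_negative: bool = True
) -> TraitTree:
    """Saitou-Nei neighbor joining on a symmetric zero-diagonal matrix.

    Agglomerates by minimizing Q(i,j) = (n-2)D(i,j) - r_i - r_j (ties broken
    toward the lexicographically lowest index pair), with the standard
    branch-length and distance-update formulas.  Returns an unrooted tree
    (trifurcating root) with n-2 internal nodes for n leaves.
    """
    D = _check_matrix(D).copy()
    D_original = D.copy()
    labels = list(labels)
    if len(labels) != D.shape[0]:
        raise ValueError("labels/matrix size mismatch")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in labels]
    clamped = 0

    def _length(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        # minimize over the upper triangle only; np.argmin scans row-major,
        # so the first minimum is the lowest-index pair (deterministic ties)
        iu = np.triu_indices(n, k=1)
        k = int(np.argmin(Q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        u = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length = _length(li)
        cj.length = _length(lj)
        u.extend([ci, cj])
        newdist = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = newdist[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [u]

    # final 3-node star: closed-form three-point branch lengths
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    root = TreeNode()
    for node, ln in zip(nodes, (la, lb, lc)):
        node.length = _length(ln)
        root.append(node)
    if clamped:
        warnings.warn(f"{clamped} negative branch length(s) clamped to 0")
    return TraitTree(labels=labels, distances=D_original, tree=root, clamped_edges=clamped)


def build_trait_tree(
    group_df: pd.DataFrame,
    spec: TraitDistanceSpec = TraitDistanceSpec(),
    outgroup: str | None = None,
) -> TraitTree:
    """Distance matrix + NJ tree from a group-level composition table.

    ``outgroup`` optionally reroots the (intrinsically unrooted) tree at a
    named leaf for display.
    """
    D, labels = trait_distance(group_df, spec)
    result = neighbor_joining(D, labels)
    result.distances = D
    result.spec = spec
    if outgroup is not None:
        node = result.tree.find(outgroup)
        result.tree = result.tree.root_at(node.parent, reset=True)
    return result


def write_distance_tsv(tt: TraitTree, path) -> None:
    tt.distance_frame().to_csv(path, sep="\t")


def write_newick(tt: TraitTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tt.newick() + "\n")
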