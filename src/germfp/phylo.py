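"""Distance-based dendrogram construction and SplitsTree-compatible export.

The distance between two fingerprints is ``1 - allele-match similarity``
(optionally the total-difference fraction).  Trees are built with classic
neighbor joining (Saitou & Nei Q-criterion) with a deterministic
lowest-index tie-break, negative branch lengths clamped to zero, and are
returned as :class:`skbio.TreeNode` objects so they compose with the wider
tree ecosystem.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .pairwise import SimilarityMatrix

logger = logging.getLogger(__name__)


def genetic_distance(sim: SimilarityMatrix, metric: str = "allele_match"
                     ) -> DistanceMatrix:
    """Distance matrix from pairwise statistics.

    ``metric="allele_match"`` gives ``1 - similarity``;
    ``metric="pct_total_diffs"`` gives the fraction of differing genotypes.
    Incomparable pairs (no shared markers) raise, naming the pair.
    """
    n = sim.n
    for i in range(n):
        for j in range(i + 1, n):
            if sim.n_shared[i, j] == 0:
                raise ValueError(
                    f"incomparable pair ({sim.names[i]}, {sim.names[j]}): "
                    "no markers genotyped in both"
                )
    if metric == "allele_match":
        d = 1.0 - sim.similarity
    elif metric == "pct_total_diffs":
        with np.errstate(invalid="ignore"):
            d = (sim.het_diffs + sim.hom_diffs) / np.maximum(sim.n_shared, 1)
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=sim.names)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining with deterministic tie-breaking.

    At each step the pair minimising Q = (r-2)d(i,j) - R_i - R_j is joined;
    ties resolve to the lexicographically lowest active index pair.  Branch
    lengths follow the standard formulas; negatives are clamped to zero with
    a warning.  The result is an unrooted tree represented with a trifurcating
    root, so a tree on n leaves has n-2 internal nodes and 2n-3 branches.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]

    def clamp(v: float, context: str) -> float:
        if v < 0:
            if v < -1e-12:
                logger.warning("negative branch length %.3g at %s clamped to 0",
                               v, context)
            return 0.0
        return v

    while len(nodes) > 3:
        r = len(nodes)
        rowsum = D.sum(axis=1)
        Q = (r - 2) * D - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin on the flattened matrix returns the first (row-major, i.e.
        # lexicographically lowest) index among tied minima
        flat = int(np.argmin(Q))
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        vi = clamp(0.5 * dij + (rowsum[i] - rowsum[j]) / (2 * (r - 2)),
                   f"join({nodes[i].name},{nodes[j].name})")
        vj = clamp(dij - vi, f"join({nodes[i].name},{nodes[j].name})")
        nodes[i].length = vi
        nodes[j].length = vj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        nodes[i] = parent
        del nodes[j]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    nodes[0].length = clamp(0.5 * (d01 + d02 - d12), "final star")
    nodes[1].length = clamp(0.5 * (d01 + d12 - d02), "final star")
    nodes[2].length = clamp(0.5 * (d02 + d12 - d01), "final star")
    return TreeNode(children=nodes)


_NEEDS_QUOTE = re.compile(r"[\s()\[\]:;,']")


def _newick_label(label: str) -> str:
    if label and _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick(node: TreeNode) -> str:
    if node.is_tip():
        s = _newick_label(node.name or "")
    else:
        s = "(" + ",".join(_newick(c) for c in node.children) + ")"
        if node.name:
            s += _newick_label(node.name)
    if node.length is not None:
        s += f":{node.length:.12g}"
    return s


def tree_to_newick(tree: TreeNode) -> str:
    """Serialise a tree to a Newick string (labels with spaces or other
    special characters are single-quoted)."""
    return _newick(tree) + ";"


def export_tree(tree: TreeNode, path, format: str = "newick") -> Path:
    """Write the tree as Newick or as a minimal NEXUS file with TAXA and
    TREES blocks (loadable by SplitsTree4)."""
    path = Path(path)
    nwk = tree_to_newick(tree)
    if format == "newick":
        path.write_text(nwk + "\n")
    elif format == "nexus":
        tips = [t.name or "" for t in tree.tips()]
        lines = ["#NEXUS", "", "BEGIN TAXA;",
                 f"    DIMENSIONS NTAX={len(tips)};",
                 "    TAXLABELS",
                 *[f"        {_newick_label(t)}" for t in tips],
                 "    ;", "END;", "", "BEGIN TREES;",
                 f"    TREE tree1 = [&U] {nwk}", "END;", ""]
        path.write_text("\n".join(lines))
    else:
        raise ValueError(f"unknown tree format: {format!r}")
    return path
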