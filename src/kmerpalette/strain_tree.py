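"""Strain-level trees from common k-mer matrices, with abundance placement.

The 30-mer and 50-mer similarity matrices are averaged, symmetrized and
flipped into a distance (d = 1 − similarity, so identical genomes sit at
distance 0), and a neighbor-joining tree is built over the reference
genomes.  Solved abundance mass is then painted onto this tree: reference
mass sits at its genome's leaf, and hypothetical mass (genome i, bin h,
partner j) attaches on the path between leaf i and the i–j most recent
common ancestor — at the ancestor when h matches A30[i, j] exactly, nearer
the leaf ("below" the ancestor) when h > A30[i, j], nearer the root
("above") when h < A30[i, j].  The tree is midpoint rooted purely to give
"above/below" a direction.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .kmer_core import CommonKmerMatrix
from .solver import AbundanceEntry
from .taxonomy import DEFAULT_DELTA, find_partner

__all__ = [
    "Placement",
    "StrainTree",
    "similarity_to_distance",
    "neighbor_joining",
    "place_hypotheticals",
    "write_newick",
    "plot_tree",
]

#: Fraction of the adjacent edge used to offset strictly-above/-below
#: placements from the ancestor node (display only).
EDGE_OFFSET = 0.25


@dataclass(frozen=True)
class Placement:
    """One parcel of abundance mass attached to the tree.

    ``side`` is "leaf" (reference mass), "node" (exactly at the i–j
    ancestor), "below" (between ancestor and leaf) or "above" (rootward
    of the ancestor).  ``node_path`` names the attachment node by the
    sorted leaves under it; ``offset`` is the along-edge distance from
    that node toward the leaf (negative = rootward).
    """

    genome_id: str
    partner_id: str | None
    bin: float
    mass: float
    side: str
    node_path: str
    offset: float


@dataclass
class StrainTree:
    """Midpoint-rooted NJ tree plus the abundance placements painted on it."""

    tree: TreeNode
    genome_ids: list[str]
    placements: list[Placement] = field(default_factory=list)

    @property
    def total_mass(self) -> float:
        return sum(p.mass for p in self.placements)

    def placements_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "genome_id\tpartner_id\tbin\tmass\tside\tnode_path\toffset\n"
            )
            for p in self.placements:
                fh.write(
                    f"{p.genome_id}\t{p.partner_id or '-'}\t{p.bin:g}\t"
                    f"{p.mass:.10g}\t{p.side}\t{p.node_path}\t{p.offset:.6g}\n"
                )


def similarity_to_distance(
    A30: CommonKmerMatrix, A50: CommonKmerMatrix
) -> np.ndarray:
    """Distance matrix from the average of the two common k-mer matrices.

    S = (A30 + A50)/2 averaged over k, then symmetrized over (i, j) and
    mapped through d = 1 − s.  Zero diagonal, symmetric by construction.
    """
    if A30.genome_ids != A50.genome_ids:
        raise ValueError("matrices cover different genome orderings")
    if A30.values.shape != A50.values.shape:
        raise ValueError("matrix shape mismatch")
    S = (A30.values + A50.values) / 2.0
    D = 1.0 - (S + S.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def neighbor_joining(D: np.ndarray, ids: list[str]) -> TreeNode:
    """Saitou–Nei neighbor joining; exact on additive distance matrices.

    Deterministic (lowest-index tie-break); negative branch length
    estimates are clamped to zero.  n = 1 and n = 2 degenerate into a
    single leaf / a single edge split at its midpoint.
    """
    D = np.asarray(D, dtype=float)
    n = len(ids)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    if n == 1:
        return TreeNode(name=ids[0], length=0.0)
    if n == 2:
        half = D[0, 1] / 2.0
        root = TreeNode()
        root.extend(
            [TreeNode(name=ids[0], length=half), TreeNode(name=ids[1], length=half)]
        )
        return root
    return nj(DistanceMatrix(D, ids), neg_as_zero=True)


def _node_path(node: TreeNode) -> str:
    if node.is_tip():
        return node.name
    return ",".join(sorted(t.name for t in node.tips()))


def place_hypotheticals(
    tree: TreeNode,
    abundances: list[AbundanceEntry],
    A30: CommonKmerMatrix,
    delta: float = DEFAULT_DELTA,
) -> StrainTree:
    """Paint solved abundance mass onto a midpoint-rooted copy of the tree.

    Total placed mass equals total input mass.  For a fixed (i, j) pair,
    lowering the bin h only ever moves mass rootward (below → node →
    above), mirroring "less similar means deeper divergence".
    """
    ids = list(A30.genome_ids)
    if len(ids) >= 3:
        rooted = tree.root_at_midpoint()
    else:
        rooted = tree.copy()
    leaves = {t.name: t for t in ([rooted] if rooted.is_tip() else rooted.tips())}
    missing = [g for g in ids if g not in leaves]
    if missing:
        raise ValueError(f"tree lacks leaves for genomes: {missing}")
    placements: list[Placement] = []
    for e in abundances:
        gid = ids[e.genome_index]
        leaf = leaves[gid]
        if e.bin >= 1.0:
            placements.append(
                Placement(
                    genome_id=gid,
                    partner_id=None,
                    bin=1.0,
                    mass=e.abundance,
                    side="leaf",
                    node_path=gid,
                    offset=0.0,
                )
            )
            continue
        j = find_partner(e.genome_index, e.bin, A30, delta=delta)
        if j is None:
            # single-genome tree: everything hangs off the lone leaf
            placements.append(
                Placement(
                    genome_id=gid,
                    partner_id=None,
                    bin=e.bin,
                    mass=e.abundance,
                    side="node",
                    node_path=gid,
                    offset=0.0,
                )
            )
            continue
        pid = ids[j]
        anc = rooted.lca([leaves[gid], leaves[pid]])
        a_ij = float(A30.values[e.genome_index, j])
        if abs(e.bin - a_ij) < 1e-9:
            side, node, offset = "node", anc, 0.0
        elif e.bin > a_ij:
            # more similar than the partner: below the ancestor, toward leaf i
            child = leaf
            while child.parent is not anc:
                child = child.parent
            side, node = "below", anc
            offset = EDGE_OFFSET * (child.length or 0.0)
        else:
            # less similar: above the ancestor, toward the root
            side, node = "above", anc
            offset = -EDGE_OFFSET * (anc.length or 0.0)
        placements.append(
            Placement(
                genome_id=gid,
                partner_id=pid,
                bin=e.bin,
                mass=e.abundance,
                side=side,
                node_path=_node_path(node),
                offset=offset,
            )
        )
    return StrainTree(tree=rooted, genome_ids=ids, placements=placements)


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialize to Newick (branch lengths kept); returns the string."""
    buf = _io.StringIO()
    tree.write(buf)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def plot_tree(strain_tree: StrainTree, path, figsize=(8, 6)) -> None:
    """Static plot: leaves on a line, placements as scaled markers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tree = strain_tree.tree
    tips = list(tree.tips()) if not tree.is_tip() else [tree]
    ypos = {t.name: i for i, t in enumerate(tips)}
    xpos = {t.name: tree.distance(t) if not tree.is_tip() else 0.0 for t in tips}
    fig, ax = plt.subplots(figsize=figsize)
    for name in ypos:
        ax.plot([0, xpos[name]], [ypos[name]] * 2, color="0.7", lw=1)
        ax.text(xpos[name], ypos[name], " " + name, va="center", fontsize=8)
    for p in strain_tree.placements:
        y = ypos.get(p.genome_id, 0)
        x = xpos.get(p.genome_id, 0.0)
        if p.side != "leaf":
            x *= max(p.bin, 0.05)
        ax.scatter(
            [x], [y], s=2000 * p.mass, alpha=0.5,
            color="tab:red" if p.side != "leaf" else "tab:blue",
        )
    ax.set_yticks([])
    ax.set_xlabel("distance from root")
    ax.set_title("strain tree with placed abundance mass")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
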