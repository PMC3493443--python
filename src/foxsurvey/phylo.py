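"""Distance estimation, neighbor joining, bootstrap support and clade queries.

The tree stage of the ortholog survey: evolutionary distances from a
multiple alignment (p-distance or Poisson-corrected), the Saitou–Nei
neighbor-joining algorithm, nonparametric bootstrap of alignment columns
with bipartition-matched support values, and the clade query that decides
whether a candidate "groups with" the target-subfamily references.

Trees are held as :class:`skbio.TreeNode` objects (rooted representation of
an unrooted tree, trifurcating root) wrapped in :class:`PhyloTree`;
bootstrap supports are attached to internal nodes and serialized as
internal newick labels.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import TreeNode

logger = logging.getLogger(__name__)

_GAP = ord("-")


class SaturationError(ValueError):
    """Poisson correction undefined: observed p-distance >= 1."""


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labeled taxa."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate taxon ids")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if np.any(self.d < 0):
            raise ValueError("negative distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("non-zero diagonal")

    def write_phylip(self, path: str | Path) -> None:
        """Write in PHYLIP square format."""
        with Path(path).open("w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for name, row in zip(self.ids, self.d):
                fh.write(name + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths and optional bootstrap supports.

    ``root`` is an skbio TreeNode; internal nodes may carry a ``support``
    attribute in [0, 100], serialized as internal node labels in newick.
    """

    root: TreeNode
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = [t.name for t in self.root.tips()]

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Map each internal-edge bipartition to its defining (child) node.

        A bipartition is canonicalized as the frozenset of leaf names on the
        side *not* containing the lexicographically smallest leaf.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}
        for node in self.root.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            key = side if anchor not in side else all_leaves - side
            out[key] = node
        return out

    def clades(self) -> dict[frozenset, TreeNode]:
        """Map subtree leaf sets to nodes, for every internal node."""
        return {
            frozenset(t.name for t in node.tips()): node
            for node in self.root.non_tips(include_self=False)
        }

    def to_newick(self) -> str:
        # skbio serializes the node ``support`` attribute as internal labels
        buf = io.StringIO()
        self.root.write(buf, format="newick")
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        root = TreeNode.read(io.StringIO(text), format="newick")
        root.assign_supports()  # numeric internal labels -> node.support
        return cls(root=root)


def _encode_rows(rows: list[str]) -> np.ndarray:
    return np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(
        len(rows), -1
    )


def _pair_p_distance(
    enc: np.ndarray, i: int, j: int, cols: np.ndarray | None = None
) -> float:
    ri, rj = enc[i], enc[j]
    if cols is not None:
        ri, rj = ri[cols], rj[cols]
    comparable = (ri != _GAP) & (rj != _GAP)
    n = int(comparable.sum())
    if n == 0:
        return np.nan
    return float((ri[comparable] != rj[comparable]).sum()) / n


def distances(
    msa, model: str = "p", gap_rule: str = "pairwise"
) -> DistanceMatrix:
    """Pairwise distances from a multiple alignment.

    ``model="p"`` gives the raw proportion of differing residues among
    comparable columns; ``model="poisson"`` applies the multiple-hit
    correction ``−ln(1 − p)``.  Under the default pairwise-deletion gap
    rule, a column is compared for a pair only if neither row is gapped;
    ``gap_rule="complete"`` drops columns gapped in *any* row.
    """
    ids, rows = list(msa.ids), list(msa.rows)
    if len(rows) < 2:
        raise ValueError("need at least two aligned sequences")
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    enc = _encode_rows(rows)
    cols = None
    if gap_rule == "complete":
        cols = np.where(np.all(enc != _GAP, axis=0))[0]
    elif gap_rule != "pairwise":
        raise ValueError(f"unknown gap rule {gap_rule!r}")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _pair_p_distance(enc, i, j, cols)
            if np.isnan(p):
                raise ValueError(
                    f"no comparable columns for pair ({ids[i]!r}, {ids[j]!r})"
                )
            if model == "poisson":
                if p >= 1.0:
                    raise SaturationError(
                        f"saturated pair ({ids[i]!r}, {ids[j]!r}): p = {p}"
                    )
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids=ids, d=d)


def _clamp(length: float, context: str, warn: bool = True) -> float:
    if length < 0:
        if warn:
            logger.warning("clamping negative branch length %.4f (%s)", length, context)
        return 0.0
    return length


def neighbor_joining(dm: DistanceMatrix, warn_clamp: bool = True) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Agglomerates the pair minimizing the Q criterion until three nodes
    remain, then resolves the central node in closed form.  Ties on Q are
    broken by the lexicographically smallest index pair, making the result
    deterministic; negative branch-length estimates are clamped to zero.
    Two taxa yield the trivial single-edge tree.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("neighbor joining needs at least two taxa")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    if n == 2:
        a, b = nodes
        a.length = dm.d[0, 1] / 2.0
        b.length = dm.d[0, 1] / 2.0
        return PhyloTree(root=TreeNode(children=[a, b]), ids=list(dm.ids))

    d = dm.d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lexicographically smallest (i, j) among minimizers
        flat = np.flatnonzero(q == q.min())
        i_loc, j_loc = divmod(int(flat[0]), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = _clamp(li, f"join {i_loc},{j_loc}", warn_clamp)
        nodes[j].length = _clamp(lj, f"join {i_loc},{j_loc}", warn_clamp)
        new_node = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(new_node)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    nodes[i].length = _clamp(0.5 * (dij + dik - djk), "final", warn_clamp)
    nodes[j].length = _clamp(0.5 * (dij + djk - dik), "final", warn_clamp)
    nodes[k].length = _clamp(0.5 * (dik + djk - dij), "final", warn_clamp)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root=root, ids=list(dm.ids))


def bootstrap_support(
    msa,
    model: str = "p",
    n_replicates: int = 100,
    seed: int | np.random.Generator = 0,
    gap_rule: str = "pairwise",
) -> PhyloTree:
    """Point-estimate NJ tree with bootstrap bipartition supports.

    Columns of the alignment are resampled with replacement
    ``n_replicates`` times; each resample is rebuilt with NJ, and the
    support of every internal bipartition of the point-estimate tree is
    the percentage of replicates whose tree contains it.  Replicates in
    which some pair has no comparable column (or is saturated) are skipped
    with a warning and excluded from the denominator.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    point = neighbor_joining(distances(msa, model=model, gap_rule=gap_rule))
    target = point.bipartitions()
    counts = {key: 0 for key in target}
    n_cols = len(msa.rows[0])

    class _Resampled:
        def __init__(self, cols: np.ndarray) -> None:
            enc = _encode_rows(list(msa.rows))[:, cols]
            self.ids = list(msa.ids)
            self.rows = ["".join(map(chr, row)) for row in enc]

    n_used = 0
    for rep in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        try:
            rep_tree = neighbor_joining(
                distances(_Resampled(cols), model=model, gap_rule=gap_rule),
                warn_clamp=False,
            )
        except (ValueError, SaturationError) as exc:
            logger.warning("skipping bootstrap replicate %d: %s", rep, exc)
            continue
        n_used += 1
        rep_bips = rep_tree.bipartitions().keys()
        for key in counts:
            if key in rep_bips:
                counts[key] += 1
    if n_used == 0:
        raise ValueError("all bootstrap replicates failed")
    for key, node in target.items():
        node.support = 100.0 * counts[key] / n_used
    return point


def clade_support(
    tree: PhyloTree,
    query_id: str,
    reference_ids: set[str],
    other_reference_ids: set[str] = frozenset(),
) -> tuple[bool, float | None]:
    """Does the query group with the target-subfamily references?

    ``grouped`` is true iff some internal edge separates the query together
    with at least one target reference from every reference of a different
    subfamily (``other_reference_ids``); among qualifying edges the
    smallest such clade is reported.  ``support`` is that edge's bootstrap
    value (``None`` if supports were not computed).
    """
    leaves = set(tree.leaf_names())
    if query_id not in leaves:
        raise ValueError(f"query {query_id!r} is not a leaf of the tree")
    missing = set(reference_ids) - leaves
    if missing:
        raise ValueError(f"reference leaves missing from tree: {sorted(missing)}")
    all_leaves = frozenset(leaves)
    best: tuple[int, frozenset] | None = None
    bips = tree.bipartitions()
    for key, node in bips.items():
        for side in (key, all_leaves - key):
            if (
                query_id in side
                and side & reference_ids
                and not side & other_reference_ids
            ):
                if best is None or len(side) < best[0]:
                    best = (len(side), key)
    if best is None:
        return False, None
    node = bips[best[1]]
    return True, getattr(node, "support", None)
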