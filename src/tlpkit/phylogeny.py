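"""Distance-based phylogenetics over TLP protein families.

Pairwise distances are computed from a protein multiple sequence alignment
(gapped columns dropped pairwise), either as raw p-distances or with the
Poisson multiple-hit correction d = -ln(1 - p).  Trees are built with the
Saitou–Nei neighbor-joining algorithm, internal-edge confidence is
estimated by bootstrap resampling of alignment columns, and clades are cut
into k groups by removing the longest edges.

Alignment construction itself (e.g. MUSCLE) is upstream of this module;
an MSA is consumed as input.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from skbio.tree import TreeNode

from .io_formats import logger


@dataclasses.dataclass(frozen=True)
class Alignment:
    """A protein MSA: taxon names plus equal-length gapped rows."""

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxon names")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: columns drawn with replacement."""
        idx = rng.integers(0, self.n_columns, size=self.n_columns)
        return Alignment(
            self.names,
            tuple("".join(row[i] for i in idx) for row in self.rows),
        )


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])


def distance_matrix(alignment: Alignment,
                    model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances from an MSA under p-distance or Poisson model.

    Columns where either sequence of a pair has a gap are excluded for
    that pair (pairwise deletion); p = mismatches / compared sites;
    the Poisson correction is d = -ln(1 - p).

    Raises
    ------
    ValueError
        If a pair shares no comparable sites, or p = 1 under the Poisson
        model (infinite distance); the offending pair is named.
    """
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if alignment.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    arrays = [np.frombuffer(r.encode(), dtype="S1") for r in alignment.rows]
    gap = np.bytes_(b"-")
    n = alignment.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = (arrays[i] != gap) & (arrays[j] != gap)
            n_sites = int(usable.sum())
            if n_sites == 0:
                raise ValueError(
                    f"no comparable sites for pair "
                    f"({alignment.names[i]}, {alignment.names[j]})")
            p = float((arrays[i][usable] != arrays[j][usable]).mean())
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair ({alignment.names[i]}, "
                        f"{alignment.names[j]}): p = 1 has infinite "
                        "Poisson distance")
                dist = -np.log1p(-p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(alignment.names), d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

Bipartition = frozenset


@dataclasses.dataclass
class PhyloTree:
    """An unrooted phylogeny, stored rooted at a trifurcating basal node.

    supports maps non-trivial bipartitions (the tip-name set on one side,
    canonicalized to exclude the alphabetically first taxon) to bootstrap
    percentages in [0, 100].
    """

    root: TreeNode
    taxa: tuple[str, ...]
    supports: dict[Bipartition, float] = dataclasses.field(
        default_factory=dict)

    def to_newick(self) -> str:
        tree = self.root.copy()
        if self.supports:
            ref = min(self.taxa)
            full = frozenset(self.taxa)
            for node in tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                key = side if ref not in side else full - side
                if key in self.supports:
                    node.name = f"{self.supports[key]:.0f}"
        return str(tree).strip()

    def path_length(self, a: str, b: str) -> float:
        return float(self.root.find(a).distance(self.root.find(b)))


def bipartitions(tree: PhyloTree) -> set[Bipartition]:
    """Non-trivial bipartitions of the unrooted tree, each canonicalized
    as the tip-name side excluding the alphabetically first taxon."""
    ref = min(tree.taxa)
    full = frozenset(tree.taxa)
    out = set()
    for node in tree.root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(full) - 1:
            out.add(side if ref not in side else full - side)
    return out


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Branch lengths follow the standard formulas; negative estimates are
    clamped to zero with a warning.  The pair with the smallest Q is
    joined, ties broken by smallest index pair in current matrix order,
    so the result is deterministic for a given taxon order.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    active = list(range(n))
    clamped = False

    def _edge(child: TreeNode, length: float) -> TreeNode:
        nonlocal clamped
        if length < 0:
            clamped = True
            length = 0.0
        child.length = float(length)
        return child

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) in current order
        i_m, j_m = divmod(int(np.argmin(q)), m)
        if i_m > j_m:
            i_m, j_m = j_m, i_m
        i, j = active[i_m], active[j_m]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_m] - r[j_m]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        parent.append(_edge(nodes[i], li))
        parent.append(_edge(nodes[j], lj))
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    # closed-form basal trifurcation
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode()
    root.append(_edge(nodes[a], la))
    root.append(_edge(nodes[b], lb))
    root.append(_edge(nodes[c], lc))
    if clamped:
        logger.warning("negative NJ branch length(s) clamped to zero")
    return PhyloTree(root=root, taxa=tuple(sorted(dm.taxa)))


def bootstrap_support(alignment: Alignment, n_reps: int, seed: int,
                      model: str = "poisson") -> PhyloTree:
    """NJ tree with bootstrap supports on its internal edges.

    Alignment columns are resampled with replacement ``n_reps`` times
    (replicate r uses seed + r); the support of each internal edge of the
    tree built from the full alignment is the percentage of replicate
    trees containing the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("need at least one bootstrap replicate")
    tree = nj_tree(distance_matrix(alignment, model))
    observed = bipartitions(tree)
    counts = {bp: 0 for bp in observed}
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        rep = alignment.resample_columns(rng)
        try:
            rep_tree = nj_tree(distance_matrix(rep, model))
        except ValueError:
            continue  # saturated or degenerate replicate contributes no split
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    tree.supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return tree


# ---------------------------------------------------------------------------
# group extraction
# ---------------------------------------------------------------------------

def extract_groups(tree: PhyloTree, k: int) -> dict[str, int]:
    """Cut the tree into k groups by removing its k-1 longest edges.

    Edge-length ties are broken by the lexicographically smallest leaf
    label beneath the edge.  Groups are numbered 1..k in order of their
    smallest member label, and every taxon is assigned exactly once.
    """
    n = len(tree.taxa)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    edges = []  # (length, tie-break label, node)
    for node in tree.root.traverse(include_self=False):
        below = min(t.name for t in node.tips()) if not node.is_tip() \
            else node.name
        edges.append((-(node.length or 0.0), below, node))
    edges.sort(key=lambda e: (e[0], e[1]))

    def _grouping(cut_ids: set[int]) -> dict:
        comp: dict[int | None, list[str]] = {}
        for tip in tree.root.tips():
            anc_key = None
            node = tip
            while node is not None:
                if id(node) in cut_ids:
                    anc_key = id(node)  # deepest cut ancestor
                    break
                node = node.parent
            comp.setdefault(anc_key, []).append(tip.name)
        return comp

    # greedy: keep a cut only if it increases the component count (a cut
    # nested under earlier cuts can otherwise empty a component)
    cut_nodes: set[int] = set()
    groups = _grouping(cut_nodes)
    for _, _, node in edges:
        if len(groups) == k:
            break
        trial = cut_nodes | {id(node)}
        trial_groups = _grouping(trial)
        if len(trial_groups) > len(groups):
            cut_nodes = trial
            groups = trial_groups

    ordered = sorted(groups.values(), key=min)
    assignment: dict[str, int] = {}
    for idx, members in enumerate(ordered, 1):
        for taxon in members:
            assignment[taxon] = idx
    return assignment


def write_group_table(assignment: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tgroup\n")
        for taxon in sorted(assignment):
            fh.write(f"{taxon}\t{assignment[taxon]}\n")
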