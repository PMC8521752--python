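"""Distance-based trees and clade placement.

Neighbor-joining on p-distances is the in-package phylogenetic route for
associating a sequence with a clade, and doubles as a cross-check on the
diagnostic-substitution route.  Clade support is reported as bootstrap
proportions over resampled alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .refcoord import DELETED, NucSequence, ReferenceFrame, state_at

_NT_OK = set("ACGT")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal not zero")
        if (self.d < 0).any():
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


def _states_matrix(
    panel: dict[str, tuple[NucSequence, ReferenceFrame]], level: str
) -> tuple[list[str], list[list[str]]]:
    ids = list(panel)
    ref_length = next(iter(panel.values()))[1].ref_length
    if level == "aa":
        positions = [3 * c - 2 for c in range(1, ref_length // 3 + 1)]
    else:
        positions = list(range(1, ref_length + 1))
    rows = [
        [state_at(frame, seq, pos, level) for pos in positions]
        for seq, frame in panel.values()
    ]
    return ids, rows


def _usable(state: str, level: str) -> bool:
    if state == DELETED:
        return False
    return state != "X" if level == "aa" else state in _NT_OK


def pdistance(
    panel: dict[str, tuple[NucSequence, ReferenceFrame]],
    level: str = "nt",
) -> DistanceMatrix:
    """Proportion of differing sites per pair, over positions where neither
    sequence is deleted or ambiguous."""
    if len(panel) < 2:
        raise ValueError("need at least two sequences")
    ids, rows = _states_matrix(panel, level)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = diffs = 0
            for a, b in zip(rows[i], rows[j]):
                if _usable(a, level) and _usable(b, level):
                    comparable += 1
                    if a != b:
                        diffs += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            d[i, j] = d[j, i] = diffs / comparable
    return DistanceMatrix(ids, d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree with deterministic tie-breaking by label order.

    Negative branch-length estimates are clamped to zero.  The returned tree
    is unrooted (dendropy trifurcation at the seed node for n >= 3).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False

    nodes: list[dendropy.Node] = []
    for label in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    reps = list(dm.ids)  # smallest descendant label per cluster
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node
        dnew = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            dnew[k] = (d[i, k] + d[j, k] - d[i, j]) / 2
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(dnew) - 1] = dnew[:-1]
        d[: len(dnew) - 1, -1] = dnew[:-1]
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2
    root = tree.seed_node
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.edge.length = max(length, 0.0)
        root.add_child(node)
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


def is_monophyletic(
    tree: dendropy.Tree, tips: set[str] | list[str], outgroup: str
) -> bool:
    """True iff ``tips`` form a clade on the tree rooted at ``outgroup``."""
    tips = set(tips)
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = (tips | {outgroup}) - labels
    if unknown:
        raise ValueError(f"unknown tips: {sorted(unknown)}")
    work = tree.clone(depth=1)
    og = work.find_node_with_taxon_label(outgroup)
    work.reroot_at_edge(og.edge, update_bipartitions=True)
    mrca = work.mrca(taxon_labels=list(tips))
    clade_leaves = {
        leaf.taxon.label for leaf in mrca.leaf_iter()
    }
    return clade_leaves == tips


def place_query(
    panel: dict[str, tuple[NucSequence, ReferenceFrame]],
    clade_labels: dict[str, str],
    query_id: str,
    level: str = "nt",
) -> tuple[str, float]:
    """Nearest-clade placement by mean p-distance.

    ``panel`` must contain the query; ``clade_labels`` labels the remaining
    members.  Returns (clade, margin) where margin is the runner-up mean
    minus the best mean."""
    members = {sid for sid in panel if sid != query_id and clade_labels.get(sid)}
    if not members:
        raise ValueError("empty labelled panel")
    dm = pdistance(panel, level)
    means: dict[str, list[float]] = {}
    for sid in members:
        means.setdefault(clade_labels[sid], []).append(dm.get(query_id, sid))
    ranked = sorted(
        ((float(np.mean(v)), k) for k, v in means.items())
    )
    best_mean, best = ranked[0]
    margin = (ranked[1][0] - best_mean) if len(ranked) > 1 else float("inf")
    return best, margin


def bootstrap_clade_support(
    panel: dict[str, tuple[NucSequence, ReferenceFrame]],
    clades: dict[str, set[str]],
    outgroup: str,
    level: str = "nt",
    n_reps: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Proportion of column-resampled NJ replicates in which each named clade
    is monophyletic (rooted at the outgroup)."""
    ids, rows = _states_matrix(panel, level)
    rng = np.random.default_rng(seed)
    n_cols = len(rows[0])
    hits = {name: 0 for name in clades}
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                comparable = diffs = 0
                for c in cols:
                    a, b = rows[i][c], rows[j][c]
                    if _usable(a, level) and _usable(b, level):
                        comparable += 1
                        if a != b:
                            diffs += 1
                d[i, j] = d[j, i] = diffs / comparable if comparable else 0.0
        tree = nj_tree(DistanceMatrix(ids, d))
        for name, tips in clades.items():
            if is_monophyletic(tree, tips, outgroup):
                hits[name] += 1
    return {name: hits[name] / n_reps for name in clades}


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
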