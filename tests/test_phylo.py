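"""Distance matrices, neighbor joining, monophyly, and placement."""

import numpy as np
import pytest

import cannoxclass as cx
from cannoxclass.phylo import DistanceMatrix, bootstrap_clade_support
from cannoxclass.refcoord import NucSequence, align_global, build_frame


def _mini_panel(seqs):
    ref = seqs[0]
    return {s.id: (s, build_frame(align_global(ref, s))) for s in seqs}


# --- independent additive-tree machinery for the NJ oracle -----------------

def random_binary_tree(labels, rng):
    """Nested-tuple random topology ((left, bl), (right, br)) with branch
    lengths in [0.5, 2]; leaves are label strings."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(((a, float(rng.uniform(0.5, 2.0))),
                      (b, float(rng.uniform(0.5, 2.0)))))
    return nodes[0]


def tree_distances(tree):
    """Pairwise path lengths between leaves of the nested-tuple tree."""
    def walk(node):
        # returns {leaf: distance-to-this-node}, and fills pair distances
        if isinstance(node, str):
            return {node: 0.0}
        (lchild, lb), (rchild, rb) = node
        left = {k: v + lb for k, v in walk(lchild).items()}
        right = {k: v + rb for k, v in walk(rchild).items()}
        for a, da in left.items():
            for b, db in right.items():
                dist[(a, b)] = dist[(b, a)] = da + db
        left.update(right)
        return left

    dist = {}
    walk(tree)
    return dist


def tree_splits(tree, all_labels):
    """Non-trivial unrooted splits of the nested-tuple tree, canonicalized."""
    splits = set()

    def leaves(node):
        if isinstance(node, str):
            return {node}
        (l, _), (r, _) = node
        return leaves(l) | leaves(r)

    def walk(node):
        if isinstance(node, str):
            return
        for child, _bl in node:
            below = leaves(child)
            if 1 < len(below) < len(all_labels) - 1:
                splits.add(canonical_split(below, all_labels))
            walk(child)

    walk(tree)
    return splits


def canonical_split(side, all_labels):
    side = frozenset(side)
    anchor = min(all_labels)
    return side if anchor not in side else frozenset(all_labels) - side


def dendropy_splits(tree, all_labels):
    splits = set()
    for node in tree.preorder_internal_node_iter():
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if 1 < len(below) < len(all_labels) - 1:
            splits.add(canonical_split(below, all_labels))
    return splits


class TestPDistance:
    def test_identical_pair_zero(self):
        a = NucSequence("a", "ATGAAACCC")
        b = NucSequence("b", "ATGAAACCC")
        dm = cx.pdistance(_mini_panel([a, b]), "nt")
        assert dm.get("a", "b") == 0.0

    def test_all_sites_differ(self):
        # column-homologous comparison of complementary 4-mers: identity map
        from cannoxclass.refcoord import ReferenceFrame
        a = NucSequence("a", "ACGT")
        b = NucSequence("b", "TGCA")
        ident = {i: i for i in range(1, 5)}
        panel = {
            "a": (a, ReferenceFrame("a", "a", 4, ident, frozenset())),
            "b": (b, ReferenceFrame("a", "b", 4, ident, frozenset())),
        }
        dm = cx.pdistance(panel, "nt")
        assert dm.get("a", "b") == 1.0

    def test_matches_naive_recount(self, panel_frames):
        ids = list(panel_frames)[:6]
        sub = {i: panel_frames[i] for i in ids}
        dm = cx.pdistance(sub, "nt")
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                si, fi = sub[ids[i]]
                sj, fj = sub[ids[j]]
                comparable = diffs = 0
                for pos in range(1, fi.ref_length + 1):
                    a = cx.state_at(fi, si, pos, "nt")
                    b = cx.state_at(fj, sj, pos, "nt")
                    if a in "ACGT" and b in "ACGT":
                        comparable += 1
                        diffs += a != b
                assert dm.get(ids[i], ids[j]) == pytest.approx(
                    diffs / comparable
                )

    def test_symmetry_and_diagonal_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.1], [0.2, 0.0]]))


class TestNeighborJoining:
    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            cx.nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_four_taxon_additive_recovery(self):
        # ((a,b),(c,d)) with internal edge 1.0
        labels = ["a", "b", "c", "d"]
        d = np.array([
            [0.0, 2.0, 4.0, 4.0],
            [2.0, 0.0, 4.0, 4.0],
            [4.0, 4.0, 0.0, 2.0],
            [4.0, 4.0, 2.0, 0.0],
        ])
        tree = cx.nj_tree(DistanceMatrix(labels, d))
        splits = dendropy_splits(tree, set(labels))
        assert canonical_split({"a", "b"}, set(labels)) in splits

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(17)
        for trial in range(10):
            n = int(rng.integers(4, 11))
            labels = [f"t{i}" for i in range(n)]
            gen = random_binary_tree(labels, rng)
            dist = tree_distances(gen)
            d = np.zeros((n, n))
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i != j:
                        d[i, j] = dist[(a, b)]
            tree = cx.nj_tree(DistanceMatrix(labels, d))
            assert dendropy_splits(tree, set(labels)) == \
                tree_splits(gen, set(labels)), trial

    def test_leaf_set_matches_ids(self, panel_frames):
        ids = list(panel_frames)[:8]
        dm = cx.pdistance({i: panel_frames[i] for i in ids}, "nt")
        tree = cx.nj_tree(dm)
        assert {l.taxon.label for l in tree.leaf_node_iter()} == set(ids)

    def test_newick_roundtrip(self, tmp_path, panel_frames):
        ids = list(panel_frames)[:8]
        dm = cx.pdistance({i: panel_frames[i] for i in ids}, "nt")
        tree = cx.nj_tree(dm)
        path = tmp_path / "t.nwk"
        from cannoxclass.phylo import read_newick, write_newick
        write_newick(tree, path)
        back = read_newick(path)
        assert dendropy_splits(back, set(ids)) == dendropy_splits(
            tree, set(ids)
        )
        orig_len = sum(e.length or 0 for e in tree.edges())
        back_len = sum(e.length or 0 for e in back.edges())
        assert back_len == pytest.approx(orig_len, abs=1e-6)


class TestMonophyly:
    def _tree(self, panel_frames, ids):
        dm = cx.pdistance({i: panel_frames[i] for i in ids}, "nt")
        return cx.nj_tree(dm)

    def test_all_minus_outgroup_trivially_monophyletic(self, panel_frames,
                                                       panel_bundle):
        _p, labels, real = panel_bundle
        og = real.outgroup.id
        tree = self._tree(panel_frames, list(panel_frames))
        tips = set(panel_frames) - {og}
        assert cx.is_monophyletic(tree, tips, og)

    def test_clades_monophyletic_on_panel_tree(self, panel_frames,
                                               panel_bundle):
        _p, labels, real = panel_bundle
        og = real.outgroup.id
        tree = self._tree(panel_frames, list(panel_frames))
        for clade in ("A", "B", "C"):
            tips = {sid for sid, l in labels.items() if l["clade"] == clade}
            assert cx.is_monophyletic(tree, tips, og), clade
        mixed = {sid for sid, l in labels.items()
                 if l["subclade"] in ("A1_THCAS", "B1_CBDAS")}
        assert not cx.is_monophyletic(tree, mixed, og)

    def test_unknown_tip_rejected(self, panel_frames, panel_bundle):
        _p, _l, real = panel_bundle
        tree = self._tree(panel_frames, list(panel_frames))
        with pytest.raises(ValueError):
            cx.is_monophyletic(tree, {"nope"}, real.outgroup.id)


class TestPlacement:
    def test_identical_to_panel_member(self, panel_frames, panel_bundle):
        _p, labels, _real = panel_bundle
        clade_labels = {
            sid: lab["clade"] for sid, lab in labels.items()
            if lab["clade"] != "outgroup"
        }
        query = "proto_B2-1"
        best, margin = cx.place_query(panel_frames, clade_labels, query)
        assert best == "B" and margin > 0

    def test_concordance_with_diagnostic_route(self, panel_frames,
                                               panel_bundle, scheme):
        _p, labels, _real = panel_bundle
        clade_labels = {}
        agree = n = 0
        for sid, lab in labels.items():
            if lab["clade"] != "outgroup":
                clade_labels[sid] = lab["clade"]
        for sid, (seq, frame) in panel_frames.items():
            if labels[sid]["clade"] == "outgroup":
                continue
            held_out = dict(clade_labels)
            held_out.pop(sid)
            placed, _m = cx.place_query(panel_frames, held_out, sid)
            res = cx.classify_sequence(seq, scheme, frame)
            n += 1
            agree += placed == res.clade
        assert agree / n >= 0.95

    def test_bootstrap_support_high_for_true_clades(self, panel_frames,
                                                    panel_bundle):
        _p, labels, real = panel_bundle
        ids = [sid for sid, l in labels.items()
               if l["subclade"] in ("B1_CBDAS", "B2", "C")
               or l["clade"] == "outgroup"]
        sub = {i: panel_frames[i] for i in ids}
        clades = {
            "B": {sid for sid in ids if labels[sid]["clade"] == "B"},
            "C": {sid for sid in ids if labels[sid]["clade"] == "C"},
        }
        support = bootstrap_clade_support(
            sub, clades, real.outgroup.id, n_reps=20, seed=1
        )
        assert support["B"] >= 0.9 and support["C"] >= 0.9
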