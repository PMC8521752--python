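"""Diagnostic discovery, scheme construction, and hierarchical assignment."""

import math

import numpy as np
import pytest

import cannoxclass as cx
from cannoxclass.refcoord import (
    DELETED,
    NucSequence,
    align_global,
    build_frame,
    state_at,
)


def brute_force_diagnostics(panel, partition, level="aa"):
    """Independent per-column scan: for each label, states constant within
    and absent outside."""
    ref_length = next(iter(panel.values()))[1].ref_length
    if level == "aa":
        positions = [3 * c - 2 for c in range(1, ref_length // 3 + 1)]
    else:
        positions = list(range(1, ref_length + 1))
    labels = sorted({l for l in partition.values() if l is not None})
    out = {l: [] for l in labels}
    for pos in positions:
        col = {
            sid: state_at(frame, seq, pos, level)
            for sid, (seq, frame) in panel.items()
        }
        for label in labels:
            inside = [col[s] for s in col if partition.get(s) == label]
            outside = [col[s] for s in col if partition.get(s) != label]
            st = inside[0]
            if st == DELETED or (st == "X" if level == "aa"
                                 else st not in "ACGT"):
                continue
            if all(x == st for x in inside) and st not in outside:
                out[label].append((pos, st))
    return out


class TestDiscovery:
    def test_identical_sequences_no_diagnostics(self):
        s = NucSequence("a", "ATGAAACCCGGGTTTTAA")
        t = NucSequence("b", s.seq)
        panel = {
            x.id: (x, build_frame(align_global(s, x))) for x in (s, t)
        }
        disc = cx.discover_diagnostics(panel, {"a": "L1", "b": "L2"}, "nt")
        assert disc == {"L1": [], "L2": []}

    def test_counts_on_default_panel(self, panel_frames, panel_bundle):
        """The discovered per-(sub)clade site counts equal the scheme's
        published counts, with no extras."""
        _panel, labels, _real = panel_bundle
        part = {sid: lab["subclade"] for sid, lab in labels.items()}
        disc = cx.discover_diagnostics(panel_frames, part, "aa")
        subs = {k: [s for s in v if s.kind == "sub"] for k, v in disc.items()}
        assert len(subs["A2_CBCAS"]) == 12
        assert len(subs["A3"]) == 13
        assert len(subs["B1_CBDAS"]) == 14
        assert len(subs["B2"]) == 2
        assert len(subs["C"]) == 19
        # A4: 14 aa replacements plus the 4 shared premature stops
        a4 = subs["A4"]
        assert len([s for s in a4 if s.state != "*"]) == 14
        assert len([s for s in a4 if s.state == "*"]) == 4
        # subclade-specific indels ride along as indel-type sites
        assert [(s.ref_pos, s.indel_length) for s in disc["B1_CBDAS"]
                if s.kind == "indel"] == [(755, -3)]
        assert [(s.ref_pos, s.indel_length) for s in disc["B2"]
                if s.kind == "indel"] == [(153, -4)]
        assert [(s.ref_pos, s.indel_length) for s in disc["A3"]
                if s.kind == "indel"] == [(9, 3)]

    def test_clade_union_counts(self, panel_frames, panel_bundle):
        _panel, labels, _real = panel_bundle
        part = {sid: lab["clade"] for sid, lab in labels.items()}
        disc = cx.discover_diagnostics(panel_frames, part, "aa")
        counts = {k: len([s for s in disc[k] if s.kind == "sub"])
                  for k in ("A", "B", "C")}
        assert counts == {"A": 3, "B": 16, "C": 19}

    def test_matches_brute_force_oracle_on_random_panels(self):
        rng = np.random.default_rng(11)
        for trial in range(5):
            n_codons = 20
            ref = "ATG" + "".join(
                rng.choice(["GCT", "AAA", "CCT", "GGA", "TTT"],
                           n_codons - 2).tolist()
            ) + "TAA"
            refseq = NucSequence("ref", ref)
            panel = {}
            partition = {}
            for li, label in enumerate(["L1", "L2", "L3"]):
                for mi in range(3):
                    chars = list(ref)
                    # label-shared mutation + member-private noise
                    shared = 3 * (2 + 2 * li)
                    chars[shared] = "T" if chars[shared] != "T" else "G"
                    priv = 3 * int(rng.integers(2, n_codons - 1))
                    chars[priv] = "C" if chars[priv] != "C" else "A"
                    sid = f"{label}_{mi}"
                    seq = NucSequence(sid, "".join(chars))
                    panel[sid] = (seq, build_frame(align_global(refseq, seq)))
                    partition[sid] = label
            disc = cx.discover_diagnostics(panel, partition, "aa")
            expect = brute_force_diagnostics(panel, partition, "aa")
            for label in expect:
                got = [(s.ref_pos, s.state) for s in disc[label]
                       if s.kind == "sub"]
                assert got == expect[label], (trial, label)

    def test_disjoint_labels_share_no_states(self, panel_frames, panel_bundle):
        _panel, labels, _real = panel_bundle
        part = {sid: lab["subclade"] for sid, lab in labels.items()}
        disc = cx.discover_diagnostics(panel_frames, part, "aa")
        seen = set()
        for label, sites in disc.items():
            for s in sites:
                key = (s.ref_pos, s.level, s.state, s.kind)
                assert key not in seen, (label, key)
                seen.add(key)

    def test_empty_label_rejected(self, panel_frames):
        part = {sid: "L1" for sid in panel_frames}
        with pytest.raises(ValueError):
            cx.discover_diagnostics(panel_frames, part, "aa")


class TestSchemeStructure:
    def test_hierarchy_counts(self, scheme):
        assert sorted(c.name for c in scheme.clades) == ["A", "B", "C"]
        subclades = [n.name for n in scheme.nodes.values()
                     if n.kind == "subclade"]
        # clade C acts as its own subclade: 7 (sub)clades in total
        assert len(subclades) + 1 == 7
        assert len(scheme.types_under("A1_THCAS")) == 18
        assert len(scheme.types_under("C")) == 7
        assert len(scheme.types_under("B2")) == 3

    def test_aliases_present(self, scheme):
        assert scheme.nodes["1/1"].alias == "B_T"
        assert scheme.nodes["1/3"].alias == "B_T0"
        assert scheme.nodes["1/3"].defective
        assert "B_D" in scheme.nodes["B1-2"].alias

    def test_sibling_diagnostics_not_contradictory(self, scheme):
        scheme.validate()  # raises on conflict


class TestClassifySequence:
    def test_reference_is_type_1_1(self, panel_bundle, scheme):
        _p, _l, real = panel_bundle
        res = cx.classify_sequence(real.prototypes["1/1"].seq, scheme)
        assert (res.clade, res.subclade, res.group, res.type) == \
            ("A", "A1_THCAS", "1", "1/1")

    @pytest.mark.parametrize("proto,want_type", [
        ("1/3", "1/3"),   # 706 C (Gln), the defective B_T0 allele
        ("1/4", "1/4"),   # 749 A (Asp)
        ("1/5", "1/5"),   # 998 G (Arg)
        ("6", "6"),       # 998 G + 1064 A
        ("7", "7"),       # 749 A + 1018 G
    ])
    def test_printed_type_sites(self, panel_bundle, scheme, proto, want_type):
        _p, _l, real = panel_bundle
        res = cx.classify_sequence(real.prototypes[proto].seq, scheme)
        assert res.type == want_type

    def test_single_point_mutant_of_reference(self, panel_bundle, scheme):
        """Planting 706->C on the reference yields the defective-type call."""
        _p, _l, real = panel_bundle
        ref = real.prototypes["1/1"].seq
        mutant = NucSequence("m706", ref.seq[:705] + "C" + ref.seq[706:])
        res = cx.classify_sequence(mutant, scheme)
        assert res.type == "1/3"
        res749 = cx.classify_sequence(
            NucSequence("m749", ref.seq[:748] + "A" + ref.seq[749:]), scheme
        )
        assert res749.type == "1/4"

    def test_random_sequence_is_novel(self, scheme):
        rng = np.random.default_rng(5)
        rand = NucSequence("rand", "".join(rng.choice(list("ACGT"), 1638)))
        res = cx.classify_sequence(rand, scheme)
        assert res.clade == "novel"
        clade_fracs = [res.fractions[c] for c in ("A", "B", "C")]
        assert all(f < scheme.threshold for f in clade_fracs)

    def test_roundtrip_rate_zero_perfect(self, cfg, scheme_factory):
        """Every simulator output at rate 0 classifies to its generating
        labels with full diagnostic match (panels and whole simulated
        genomes, >= 200 sequences)."""
        n = ok = 0
        for seed in (1, 2, 3, 4):
            sch = scheme_factory(seed)
            panel, labels, _real = cx.default_panel(cfg, seed)
            for seq in panel:
                lab = labels[seq.id]
                if lab["clade"] == "outgroup":
                    continue
                res = cx.classify_sequence(seq, sch)
                n += 1
                if (res.clade, res.subclade) == (lab["clade"], lab["subclade"]) \
                        and res.type == (lab["type"] or "n/a") \
                        and res.fractions[res.subclade] == 1.0:
                    ok += 1
        for seed, profile in ((1, "Jamaican Lion (Mother)"),
                              (2, "Jamaican Lion (Mother)"),
                              (1, "Purple Kush"), (2, "Finola")):
            sch = scheme_factory(seed)
            genome = cx.simulate_genome(
                cfg, cx.SimConfig(seed=seed, profile=profile)
            )
            truth = genome.truth.set_index("seq_id")
            for seq in genome.loci:
                res = cx.classify_sequence(seq, sch)
                n += 1
                ok += res.subclade == truth.loc[seq.id, "subclade"]
        assert n >= 200 and ok == n

    def test_roundtrip_masked_background(self, cfg, scheme_factory):
        """0.5% background with diagnostic columns masked: subclade-level
        accuracy stays 100%."""
        sch = scheme_factory(2)
        panel, labels, _real = cx.default_panel(
            cfg, seed=2, rate=0.005, mask_diagnostics=True
        )
        for seq in panel:
            lab = labels[seq.id]
            if lab["clade"] == "outgroup":
                continue
            res = cx.classify_sequence(seq, sch)
            assert res.subclade == lab["subclade"], seq.id

    def test_roundtrip_unmasked_background(self, cfg, scheme_factory):
        """0.5% unmasked background: subclade accuracy at least 95%."""
        n = ok = 0
        for seed in (2, 3):
            sch = scheme_factory(seed)
            panel, labels, _real = cx.default_panel(
                cfg, seed, rate=0.005, mask_diagnostics=False
            )
            for seq in panel:
                lab = labels[seq.id]
                if lab["clade"] == "outgroup":
                    continue
                n += 1
                res = cx.classify_sequence(seq, sch)
                if res.subclade == lab["subclade"]:
                    ok += 1
        assert ok / n >= 0.95

    def test_fragment_partial_classification(self, panel_bundle, scheme):
        _p, _l, real = panel_bundle
        frag = NucSequence("frag", real.prototypes["A2_CBCAS"].seq.seq[200:900])
        res = cx.classify_sequence(frag, scheme)
        assert res.partial


class TestClassifyBatch:
    def test_empty_input(self, scheme):
        results, matrix = cx.classify_batch([], scheme)
        assert results == []
        assert matrix.drop(index="Sums").to_numpy().sum() == 0

    def test_cbdrx_total(self, cfg, scheme):
        genome = cx.simulate_genome(cfg, cx.SimConfig(seed=1, profile="CBDRx"))
        results, matrix = cx.classify_batch(genome.loci, scheme)
        assert len(results) == 13
        assert int(matrix.loc["Sums", "total"]) == 13
        assert (int(matrix.loc["C", "cd"]), int(matrix.loc["C", "nf"])) == (1, 4)

    def test_jilong_b2_row(self, cfg, scheme):
        genome = cx.simulate_genome(cfg, cx.SimConfig(seed=1, profile="Jilong"))
        _results, matrix = cx.classify_batch(genome.loci, scheme)
        assert (int(matrix.loc["B2", "cd"]), int(matrix.loc["B2", "nf"])) == (0, 5)
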