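"""Synthetic cannabinoid oxidocyclase gene families.

This module realizes the gene-family evolutionary model as a simulator: a
single ancestral group-10 BBE-like ORF neofunctionalizes in the *Cannabis*
lineage and diversifies through duplication and divergence into three clades
(A, B, C) and seven subclades, each carrying planted clade-constant,
panel-unique substitutions; subclade-specific indels (the 3-bp CBDAS deletion
at position 755, the 4-bp B2 frameshift at 153, the A3 codon-3 TAC
duplication) and nonsense mutations; tandem arrays in two syntenic blocks
with conserved flanking marker genes; and per-cultivar copy numbers matching
the published assembly counts.

Every printed diagnostic position of the classification scheme is planted
verbatim.  Diagnostic substitutions that the scheme only counts are realized
at deterministic placeholder positions drawn once from a fixed stream, so the
packaged scheme is stable across runs; everything else (ancestral sequence,
outgroup divergence, genome layout) flows from the caller's seed.
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .refcoord import NucSequence, STOP_CODONS, translate_codon
from .synteny import AnnotatedContig, Gene

#: Fixed stream for placeholder-site assignment: part of the packaged scheme,
#: independent of simulation seeds.
_PLACEHOLDER_SEED = 20210608

_BASES = "ACGT"
_ALL_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_CODING_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]

# ancestral codons at printed diagnostic positions, chosen so that applying
# the printed single-nucleotide change yields the printed amino acid
# (e.g. 706 C: AAA(Lys) -> CAA(Gln) at codon 236)
_ANCESTOR_CODONS = {
    63: "ATT",   # 187 C -> CTT (Leu)
    125: "ATT",  # 373 C -> CTT (Leu)
    236: "AAA",  # 706 C -> CAA (Gln)
    250: "GGT",  # 749 A -> GAT (Asp)
    265: "GAT",  # 794 G -> GGT (Gly)
    284: "GCA",  # 851 T -> GTA (Val)
    295: "ACA",  # 883 C -> CCA (Pro)
    333: "AAA",  # 998 G -> AGA (Arg)
    340: "TCT",  # 1018 G -> GCT (Ala)
    355: "ACT",  # 1064 A -> AAT (Asn)
    410: "GGA",  # 1229 A -> GAA (Glu)
    475: "GAA",  # 1423 A -> AAA (Lys)
}

# codons with a single-nucleotide synonymous neighbour (fourfold third base)
_FOURFOLD = ["GCT", "GGT", "CCT", "ACT", "GTT", "TCT", "CGT", "CTT"]
# codons one substitution away from a stop
_PRESTOP = ["TAT", "TGT", "TCA", "CAA", "GAA", "AAA"]
# codons one substitution away from a serine codon
_PRESER = ["GCT", "ACT", "CCT"]

_INDEL_WINDOW_CODONS = {50, 51, 52, 53, 251, 252, 253, 254}


class SchemeConfigError(ValueError):
    """Inconsistent or unrealizable scheme configuration."""


@dataclass
class DiagnosticSite:
    """One realized clade/type-diagnostic character in reference coordinates."""

    ref_pos: int
    level: str          # "nt" | "aa"
    state: str          # nucleotide, amino acid (with '*' = stop), or indel tag
    owner: str
    kind: str = "sub"   # "sub" | "indel"
    indel_length: int = 0
    alt_lengths: tuple[int, ...] = ()
    #: site carried over from another type's definition (e.g. a type that
    #: differs from its sibling only by synonymous changes shares the
    #: sibling's nonsynonymous profile); exempt from sibling-uniqueness
    inherited: bool = False


@dataclass
class SchemeNode:
    name: str
    kind: str           # clade | subclade | group | type
    parent: str
    explicit_sites: list[dict] = field(default_factory=list)
    aa_subs: int = 0
    syn_subs: int = 0
    nonsense_subs: int = 0
    forced_aa: str | None = None
    inherit_sites: str | None = None
    indels: list[dict] = field(default_factory=list)
    alias: str | None = None
    defective: bool = False
    secondary: bool = False
    orf_length: int | None = None
    children: list[str] = field(default_factory=list)
    # realized placeholder codon indices (1-based), filled at load time
    aa_codons: list[int] = field(default_factory=list)
    syn_codons: list[int] = field(default_factory=list)
    nonsense_codons: list[int] = field(default_factory=list)


@dataclass
class SchemeConfig:
    reference_length: int
    nodes: dict[str, SchemeNode]
    order: list[str]
    profiles: dict[str, dict]

    @property
    def n_codons(self) -> int:
        return self.reference_length // 3

    def children_of(self, name: str) -> list[SchemeNode]:
        return [self.nodes[c] for c in self.nodes[name].children]

    def subclade_of(self, name: str) -> str:
        node = self.nodes[name]
        while node.kind not in ("subclade", "clade"):
            node = self.nodes[node.parent]
        return node.name

    def lineage(self, name: str) -> list[SchemeNode]:
        """Nodes from clade down to ``name`` (inclusive)."""
        out = []
        node = self.nodes[name]
        while node.name != "root":
            out.append(node)
            if node.parent == "root":
                break
            node = self.nodes[node.parent]
        return list(reversed(out))

    def leaves(self) -> list[str]:
        """Panel leaves: types where defined, else the subclade itself."""
        out = []
        for name in self.order:
            node = self.nodes[name]
            if node.kind == "type":
                out.append(name)
            elif node.kind == "subclade" and not _has_type_descendant(self, node):
                out.append(name)
        return out

    def diagnostic_codons(self) -> set[int]:
        """All codon indices carrying any planted substitution."""
        codons: set[int] = set()
        for node in self.nodes.values():
            for s in node.explicit_sites:
                codons.add(math.ceil(s["pos"] / 3))
            codons.update(node.aa_codons)
            codons.update(node.syn_codons)
            codons.update(node.nonsense_codons)
        return codons


def _has_type_descendant(cfg: SchemeConfig, node: SchemeNode) -> bool:
    stack = list(node.children)
    while stack:
        child = cfg.nodes[stack.pop()]
        if child.kind == "type":
            return True
        stack.extend(child.children)
    return False


def _load_yaml() -> dict:
    ref = importlib.resources.files("cannoxclass.data").joinpath("scheme.yaml")
    return yaml.safe_load(ref.read_text())


def default_scheme_config() -> SchemeConfig:
    """The packaged scheme: printed sites verbatim, placeholder positions
    drawn deterministically from a fixed stream."""
    raw = _load_yaml()
    nodes: dict[str, SchemeNode] = {}
    order: list[str] = []
    for entry in raw["nodes"]:
        node = SchemeNode(
            name=str(entry["name"]),
            kind=entry["kind"],
            parent=str(entry["parent"]),
            explicit_sites=entry.get("sites", []),
            aa_subs=entry.get("aa_subs", 0),
            syn_subs=entry.get("syn_subs", 0),
            nonsense_subs=entry.get("nonsense_subs", 0),
            forced_aa=entry.get("forced_aa"),
            inherit_sites=(
                str(entry["inherit_sites"]) if "inherit_sites" in entry else None
            ),
            indels=entry.get("indels", []),
            alias=entry.get("alias"),
            defective=entry.get("defective", False),
            secondary=entry.get("secondary", False),
            orf_length=entry.get("orf_length"),
        )
        if node.name in nodes:
            raise SchemeConfigError(f"duplicate node name {node.name!r}")
        nodes[node.name] = node
        order.append(node.name)
    for node in nodes.values():
        if node.parent != "root":
            if node.parent not in nodes:
                raise SchemeConfigError(
                    f"node {node.name!r} has unknown parent {node.parent!r}"
                )
            nodes[node.parent].children.append(node.name)

    cfg = SchemeConfig(
        reference_length=raw["reference_length"],
        nodes=nodes,
        order=order,
        profiles=raw["profiles"],
    )
    _assign_placeholders(cfg)
    _validate(cfg)
    return cfg


def _assign_placeholders(cfg: SchemeConfig) -> None:
    rng = np.random.default_rng(_PLACEHOLDER_SEED)
    printed = {math.ceil(s["pos"] / 3) for n in cfg.nodes.values()
               for s in n.explicit_sites}
    pool = [
        c
        for c in range(5, cfg.n_codons - 1)
        if c not in printed and c not in _INDEL_WINDOW_CODONS
    ]
    pool = list(rng.permutation(pool))

    def take(n: int, min_codon: int = 0) -> list[int]:
        out: list[int] = []
        kept: list[int] = []
        while len(out) < n:
            if not pool:
                raise SchemeConfigError("placeholder pool exhausted")
            c = int(pool.pop())
            (out if c > min_codon else kept).append(c)
        pool.extend(kept)
        return out

    for name in cfg.order:
        node = cfg.nodes[name]
        # "secondary" mutations sit downstream of the subclade frameshift
        floor = 53 if node.secondary else 0
        node.aa_codons = sorted(take(node.aa_subs, floor))
        node.syn_codons = sorted(take(node.syn_subs, floor))
        node.nonsense_codons = sorted(take(node.nonsense_subs, floor))


def _validate(cfg: SchemeConfig) -> None:
    seen: dict[int, str] = {}
    for node in cfg.nodes.values():
        codons = (
            [math.ceil(s["pos"] / 3) for s in node.explicit_sites]
            + node.aa_codons
            + node.syn_codons
            + node.nonsense_codons
        )
        for c in codons:
            if c < 1 or c > cfg.n_codons:
                raise SchemeConfigError(
                    f"{node.name}: codon {c} outside reference"
                )
            owner = seen.get(c)
            # printed positions may be shared between types (e.g. 998G in
            # types 1/5 and 6); placeholder positions may not collide
            if owner and owner != node.name and c not in {
                math.ceil(s["pos"] / 3)
                for n in cfg.nodes.values()
                for s in n.explicit_sites
            }:
                raise SchemeConfigError(
                    f"placeholder collision at codon {c}: {owner} vs {node.name}"
                )
            seen[c] = node.name
        for ind in node.indels:
            if not 1 <= ind["pos"] <= cfg.reference_length:
                raise SchemeConfigError(
                    f"{node.name}: indel position {ind['pos']} out of range"
                )


# ---------------------------------------------------------------------------
# Prototype generation
# ---------------------------------------------------------------------------

def _hamming_neighbors(codon: str):
    for i in range(3):
        for b in _BASES:
            if b != codon[i]:
                yield codon[:i] + b + codon[i + 1 :]


def _mutate_codon(codon: str, want: str | None = None, stop: bool = False) -> str:
    """Deterministic single-substitution mutant of ``codon``.

    ``want``: required target amino acid; ``stop``: target a stop codon.
    Falls back to two substitutions when one does not suffice.
    """
    orig_aa = translate_codon(codon)
    candidates = list(_hamming_neighbors(codon))
    candidates += [
        c2 for c1 in _hamming_neighbors(codon) for c2 in _hamming_neighbors(c1)
        if c2 != codon
    ]
    candidates += [c for c in _ALL_CODONS if c != codon]  # last resort
    for cand in candidates:
        aa = translate_codon(cand)
        if stop:
            if aa == "*":
                return cand
        elif want is not None:
            if aa == want and cand != codon:
                return cand
        else:
            if aa not in ("*", orig_aa):
                return cand
    raise SchemeConfigError(f"no suitable mutant for codon {codon}")


def _synonymous_mutant(codon: str) -> str:
    for cand in _hamming_neighbors(codon):
        if translate_codon(cand) == translate_codon(codon) != "*":
            return cand
    raise SchemeConfigError(f"no synonymous neighbour for codon {codon}")


@dataclass
class Prototype:
    """A node prototype plus its per-nucleotide reference coordinates."""

    node: str
    seq: NucSequence
    #: for each local 0-based position, the 1-based reference position
    #: (0 for inserted nucleotides)
    ref_positions: list[int]


@dataclass
class Realization:
    """Concrete mutation states realized for one generated panel."""

    ancestor: NucSequence
    outgroup: NucSequence
    prototypes: dict[str, Prototype]
    sites: dict[str, list[DiagnosticSite]]   # node -> realized sites
    masked_ref_nts: set[int]                 # all diagnostic nt positions


def _ancestral_codons(cfg: SchemeConfig, rng: np.random.Generator) -> list[str]:
    n = cfg.n_codons
    codons = [str(rng.choice(_CODING_CODONS)) for _ in range(n)]
    codons[0] = "ATG"
    codons[2] = "TAC"  # codon 3, duplicated in subclade A3
    # codon 4 must not start with T so the duplication's right-normalized
    # placement is pinned immediately after reference position 9
    while codons[3][0] == "T":
        codons[3] = str(rng.choice(_CODING_CODONS))
    codons[n - 1] = "TAA"
    for codon_idx, codon in _ANCESTOR_CODONS.items():
        codons[codon_idx - 1] = codon
    for node in cfg.nodes.values():
        for c in node.syn_codons:
            codons[c - 1] = str(rng.choice(_FOURFOLD))
        for c in node.nonsense_codons:
            codons[c - 1] = str(rng.choice(_PRESTOP))
        if node.forced_aa:
            for c in node.aa_codons:
                codons[c - 1] = str(rng.choice(_PRESER))
    # B1 3-bp deletion at 755 straddles codons 252/253: the fused codon
    # (s754, s758, s759) must not be a stop, and s755 != s758 keeps the
    # deletion's right-normalized placement unique at 755.
    while (
        codons[251][0] + codons[252][1] + codons[252][2] in STOP_CODONS
        or codons[251][1] == codons[252][1]
    ):
        codons[252] = str(rng.choice(_CODING_CODONS))
    # B2 4-bp deletion at 153..156: s153 != s157 pins placement at 153.
    while codons[50][2] == codons[52][0]:
        codons[52] = str(rng.choice(_CODING_CODONS))
    return codons


def _apply_node_mutations(
    cfg: SchemeConfig, node: SchemeNode, codons: list[str]
) -> tuple[list[str], list[DiagnosticSite]]:
    """Apply one node's planted substitutions to a codon list; return the
    mutated codons and the realized substitution sites."""
    codons = list(codons)
    sites: list[DiagnosticSite] = []
    source = node
    if node.inherit_sites:
        inherited = cfg.nodes[node.inherit_sites]
        for s in inherited.explicit_sites:
            codons, site = _apply_explicit(codons, s, node.name)
            sites.append(site)
        for c in inherited.aa_codons:
            codons, site = _apply_aa(codons, c, node.name, inherited.forced_aa)
            sites.append(site)
    for s in source.explicit_sites:
        codons, site = _apply_explicit(codons, s, node.name)
        sites.append(site)
    for c in source.aa_codons:
        codons, site = _apply_aa(codons, c, node.name, source.forced_aa)
        sites.append(site)
    for c in source.syn_codons:
        new = _synonymous_mutant(codons[c - 1])
        diff = next(i for i in range(3) if new[i] != codons[c - 1][i])
        codons[c - 1] = new
        sites.append(
            DiagnosticSite(3 * (c - 1) + diff + 1, "nt", new[diff], node.name)
        )
    for c in source.nonsense_codons:
        new = _mutate_codon(codons[c - 1], stop=True)
        codons[c - 1] = new
        sites.append(DiagnosticSite(3 * c - 2, "aa", "*", node.name))
    return codons, sites


def _apply_explicit(codons: list[str], s: dict, owner: str):
    pos, nt, aa = s["pos"], s["nt"], s["aa"]
    codon_idx = math.ceil(pos / 3)
    offset = (pos - 1) % 3
    codon = codons[codon_idx - 1]
    new = codon[:offset] + nt + codon[offset + 1 :]
    if translate_codon(new) != aa:
        raise SchemeConfigError(
            f"printed site {pos}{nt}: codon {codon}->{new} translates to "
            f"{translate_codon(new)}, expected {aa}"
        )
    codons[codon_idx - 1] = new
    return codons, DiagnosticSite(pos, "aa", aa, owner)


def _apply_aa(codons: list[str], codon_idx: int, owner: str, want: str | None):
    new = _mutate_codon(codons[codon_idx - 1], want=want)
    codons[codon_idx - 1] = new
    return codons, DiagnosticSite(
        3 * codon_idx - 2, "aa", translate_codon(new), owner
    )


def _apply_indels(node: SchemeNode, seq: str, ref_positions: list[int]):
    """Apply a node's configured indels, maintaining reference coordinates."""
    sites: list[DiagnosticSite] = []
    for ind in node.indels:
        pos, length = ind["pos"], ind["length"]
        if ind.get("motif") == "dup_codon3":
            # duplication of codon 3: insert a copy of ref nts 7..9 after 9
            idx = ref_positions.index(pos) + 1
            insert = seq[idx - 3 : idx]
            seq = seq[:idx] + insert + seq[idx:]
            ref_positions = ref_positions[:idx] + [0] * 3 + ref_positions[idx:]
            sites.append(
                DiagnosticSite(pos, "nt", "ins3", node.name, "indel", 3)
            )
        elif length < 0:
            idx = ref_positions.index(pos)
            seq = seq[:idx] + seq[idx - length :]
            ref_positions = ref_positions[:idx] + ref_positions[idx - length :]
            sites.append(
                DiagnosticSite(
                    pos, "nt", f"del{-length}", node.name, "indel", length,
                    tuple(ind.get("alt_lengths", [length])),
                )
            )
        else:
            raise SchemeConfigError(f"unsupported indel spec {ind!r}")
    return seq, ref_positions, sites


def make_prototypes(cfg: SchemeConfig, seed: int) -> Realization:
    """Generate the ancestral ORF and all node prototypes.

    The ancestor is a random 1638-nt ORF (ATG start, single terminal stop)
    constrained at printed diagnostic positions so the printed substitutions
    are realizable as single-nucleotide changes.  Each node's prototype is
    the ancestor with the cumulative mutations of its lineage applied in
    branching order; the outgroup is the ancestor at ~10% amino-acid
    divergence outside all diagnostic codons.
    """
    rng = np.random.default_rng([seed, 0])
    codons = _ancestral_codons(cfg, rng)
    ancestor_seq = "".join(codons)
    ancestor = NucSequence("ancestor", ancestor_seq)

    node_codons: dict[str, list[str]] = {"root": codons}
    sites: dict[str, list[DiagnosticSite]] = {}
    prototypes: dict[str, Prototype] = {}

    for name in cfg.order:
        node = cfg.nodes[name]
        parent_codons = node_codons[node.parent]
        mutated, node_sites = _apply_node_mutations(cfg, node, parent_codons)
        node_codons[name] = mutated
        seq = "".join(mutated)
        ref_positions = list(range(1, len(seq) + 1))
        # indels of the whole lineage (an A3 type would inherit the codon dup)
        for lineage_node in cfg.lineage(name):
            seq, ref_positions, indel_sites = _apply_indels(
                lineage_node, seq, ref_positions
            )
            if lineage_node.name == name:
                node_sites.extend(indel_sites)
        sites[name] = node_sites
        prototypes[name] = Prototype(
            name, NucSequence(f"proto_{name}", seq), ref_positions
        )

    diag_codons = cfg.diagnostic_codons()
    masked: set[int] = set()
    for c in diag_codons:
        masked.update(range(3 * c - 2, 3 * c + 1))
    for node in cfg.nodes.values():
        for ind in node.indels:
            lo = ind["pos"] - 6
            hi = ind["pos"] + abs(ind["length"]) + 6
            masked.update(range(max(1, lo), min(cfg.reference_length, hi) + 1))

    # outgroup: ~10% aa divergence outside diagnostic codons
    og_codons = list(codons)
    free = [
        c for c in range(2, cfg.n_codons)
        if c + 1 not in diag_codons and c + 1 not in _INDEL_WINDOW_CODONS
    ]
    n_div = int(round(0.10 * cfg.n_codons))
    for c0 in rng.choice(free, size=n_div, replace=False):
        og_codons[c0] = _mutate_codon(og_codons[c0])
    outgroup = NucSequence("Humulus_group10", "".join(og_codons))

    return Realization(ancestor, outgroup, prototypes, sites, masked)


def apply_background(
    proto: Prototype,
    rate: float,
    rng: np.random.Generator,
    masked_ref_nts: set[int] | None = None,
) -> NucSequence:
    """Uniform single-nucleotide background substitutions at ``rate`` per
    site; positions in ``masked_ref_nts`` (reference coordinates) are left
    untouched when given."""
    if rate <= 0:
        return proto.seq
    chars = list(proto.seq.seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        ref_pos = proto.ref_positions[i]
        if masked_ref_nts and ref_pos in masked_ref_nts:
            continue
        alt = [b for b in _BASES if b != chars[i]]
        chars[i] = str(rng.choice(alt))
    return NucSequence(proto.seq.id, "".join(chars), proto.seq.description)


def default_panel(
    cfg: SchemeConfig, seed: int, rate: float = 0.0, mask_diagnostics: bool = True
):
    """The default labelled panel: one sequence per scheme leaf plus the
    outgroup.  Returns (records, labels, realization) where labels maps
    sequence id -> dict(clade, subclade, group, type)."""
    real = make_prototypes(cfg, seed)
    rng = np.random.default_rng([seed, 1])
    records: list[NucSequence] = []
    labels: dict[str, dict] = {}
    for leaf in cfg.leaves():
        proto = real.prototypes[leaf]
        seq = apply_background(
            proto, rate, rng, real.masked_ref_nts if mask_diagnostics else None
        )
        records.append(seq)
        lineage = {n.kind: n.name for n in cfg.lineage(leaf)}
        labels[seq.id] = {
            "clade": lineage.get("clade"),
            "subclade": lineage.get("subclade", lineage.get("clade")),
            "group": lineage.get("group"),
            "type": lineage.get("type"),
        }
    records.append(real.outgroup)
    labels[real.outgroup.id] = {
        "clade": "outgroup", "subclade": "outgroup", "group": None, "type": None,
    }
    return records, labels, real


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    seed: int
    profile: str
    rate: float = 0.0
    mask_diagnostics: bool = True
    spacer_range: tuple[int, int] = (2000, 10000)

    def __post_init__(self) -> None:
        if not 0 <= self.rate <= 0.05:
            raise ValueError("background rate must be in [0, 0.05]")


@dataclass
class SimulatedGenome:
    genome_id: str
    contigs: list[AnnotatedContig]
    sequences: dict[str, str]
    loci: list[NucSequence]        # oxidocyclase loci, coding orientation
    truth: "object"                # pandas DataFrame

    def fasta_records(self) -> list[NucSequence]:
        return [NucSequence(cid, seq) for cid, seq in self.sequences.items()]


_BLOCK1_FLANK_3P = ["BBE_5.2", "RLP", "Patellin", "TWINKLE", "ClpP"]
_BLOCK2_FLANK_5P = ["ZnF", "RLK"]
_BLOCK2_FLANK_3P = ["Ankyrin", "NPF"]


def _random_gene_seq(rng: np.random.Generator) -> str:
    n = int(rng.integers(600, 1500))
    return "".join(str(b) for b in rng.choice(list(_BASES), size=n))


def _spacer(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi))
    return "".join(str(b) for b in rng.choice(list(_BASES), size=n))


def _pseudogenize(
    proto: Prototype, kind: str, rng: np.random.Generator,
    masked_ref_nts: set[int],
) -> Prototype:
    """Plant one pseudogenizing lesion (nonsense or 1-2 nt frameshift
    deletion) at a random position clear of all diagnostic sites."""
    seq = proto.seq.seq
    refs = list(proto.ref_positions)
    n_codons = len(seq) // 3
    while True:
        c0 = int(rng.integers(20, n_codons - 20))  # 0-based codon index
        if any(refs[min(i, len(refs) - 1)] in masked_ref_nts
               for i in range(3 * c0, 3 * c0 + 3)):
            continue
        if kind == "nonsense":
            codon = seq[3 * c0 : 3 * c0 + 3]
            if codon in STOP_CODONS:
                continue
            new = _mutate_codon(codon, stop=True)
            seq = seq[: 3 * c0] + new + seq[3 * c0 + 3 :]
        else:
            ndel = int(rng.integers(1, 3))
            i = 3 * c0
            seq = seq[:i] + seq[i + ndel :]
            refs = refs[:i] + refs[i + ndel :]
        return Prototype(proto.node, NucSequence(proto.seq.id, seq), refs)


def simulate_genome(cfg: SchemeConfig, sim: SimConfig) -> SimulatedGenome:
    """Simulate one cultivar genome: annotated contigs realizing the two
    syntenic blocks, with oxidocyclase copy numbers drawn exactly from the
    cultivar's profile."""
    if sim.profile not in cfg.profiles:
        raise KeyError(
            f"unknown profile {sim.profile!r}; available: "
            f"{sorted(cfg.profiles)}"
        )
    profile = cfg.profiles[sim.profile]
    counts = {k: tuple(v) for k, v in profile["counts"].items()}
    real = make_prototypes(cfg, sim.seed)
    gid = sim.profile.replace(" ", "_").replace("(", "").replace(")", "")

    import pandas as pd

    # --- decide locus list per subclade -----------------------------------
    c_types = [n.name for n in cfg.children_of("C")]
    b2_types = [n.name for n in cfg.children_of("B2")]

    def build_loci(subclade: str, cd: int, nf: int, rng) -> list[dict]:
        out = []
        if subclade == "A1_THCAS":
            tname = str(profile.get("a1_type", "1/1"))
            for _ in range(cd):
                out.append({"type": tname, "status": "cd"})
        elif subclade == "B1_CBDAS":
            tname = str(profile.get("b1_type", "B1-1"))
            for _ in range(cd):
                out.append({"type": tname, "status": "cd"})
        elif subclade == "A2_CBCAS":
            out += [{"type": "A2_CBCAS", "status": "cd"}] * cd
            out += [{"type": "A2_CBCAS", "status": "nf"}] * nf
        elif subclade == "A3":
            out += [{"type": "A3", "status": "cd"}] * cd
            out += [{"type": "A3", "status": "nf"}] * nf
        elif subclade == "A4":
            # type 1 travels with CBDAS haplotypes, type 2 with THCAS ones
            if nf == 1:
                has_cbdas = counts.get("B1_CBDAS", (0, 0))[0] > 0
                out.append({"type": "A4-1" if has_cbdas else "A4-2",
                            "status": "nf"})
            else:
                for i in range(nf):
                    out.append({"type": ["A4-1", "A4-2"][i % 2], "status": "nf"})
        elif subclade == "B2":
            for i in range(nf):
                out.append({"type": b2_types[i % len(b2_types)], "status": "nf"})
        elif subclade == "C":
            for i in range(cd):
                out.append({"type": c_types[i % len(c_types)], "status": "cd"})
            for i in range(nf):
                out.append({"type": c_types[(cd + i) % len(c_types)],
                            "status": "nf"})
        return out

    rng_master = np.random.default_rng([sim.seed, 100])
    loci_by_subclade = {
        sc: build_loci(sc, *counts.get(sc, (0, 0)), rng_master)
        for sc in counts
    }

    # inherently nonfunctional subclades need no extra lesion
    inherently_nf = {"A4", "B2"}

    def materialize(subclade: str, locus: dict, rng, idx: int) -> NucSequence:
        proto = real.prototypes[locus["type"]]
        if locus["status"] == "nf" and subclade not in inherently_nf:
            kind = "nonsense" if idx % 2 == 0 else "frameshift"
            proto = _pseudogenize(proto, kind, rng, real.masked_ref_nts)
        seq = apply_background(
            proto, sim.rate, rng,
            real.masked_ref_nts if sim.mask_diagnostics else None,
        )
        return seq

    # --- haplotype layout --------------------------------------------------
    thca_hap = (
        counts.get("A1_THCAS", (0, 0))[0] + sum(counts.get("B2", (0, 0))) > 0
    )
    cbda_hap = sum(counts.get("B1_CBDAS", (0, 0))) > 0

    a3_in_block2 = bool(profile.get("a3_nf_in_block2", False))

    hap_genes: dict[str, list[tuple[str, dict]]] = {}
    if thca_hap:
        genes = [("A1_THCAS", l) for l in loci_by_subclade.get("A1_THCAS", [])]
        genes += [("B2", l) for l in loci_by_subclade.get("B2", [])]
        if not a3_in_block2:
            genes += [
                ("A3", l) for l in loci_by_subclade.get("A3", [])
                if l["status"] == "nf"
            ]
        hap_genes["thca"] = genes
    if cbda_hap:
        genes = [("B1_CBDAS", l) for l in loci_by_subclade.get("B1_CBDAS", [])]
        genes += [
            ("A3", l) for l in loci_by_subclade.get("A3", [])
            if l["status"] == "cd"
        ]
        hap_genes["cbda"] = genes
        if not thca_hap:
            genes += [
                ("A3", l) for l in loci_by_subclade.get("A3", [])
                if l["status"] == "nf" and not a3_in_block2
            ]

    # A4 copies: type 1 travels with the CBDAS haplotype, type 2 with THCAS
    a4 = loci_by_subclade.get("A4", [])
    for i, locus in enumerate(a4):
        if "cbda" in hap_genes and (locus["type"] == "A4-1" or
                                    "thca" not in hap_genes):
            hap_genes["cbda"].append(("A4", locus))
        elif "thca" in hap_genes:
            hap_genes["thca"].append(("A4", locus))
        elif "cbda" in hap_genes:
            hap_genes["cbda"].append(("A4", locus))

    # clade C array split across haplotypes
    c_loci = loci_by_subclade.get("C", [])
    hap_names = [h for h in ("thca", "cbda") if h in hap_genes] or ["thca"]
    if "thca" not in hap_genes and "cbda" not in hap_genes and c_loci:
        hap_genes["thca"] = []
    c_assign: dict[str, list] = {h: [] for h in hap_names}
    if "c_split" in profile and len(hap_names) == 2:
        split = profile["c_split"]
        cd_pool = [l for l in c_loci if l["status"] == "cd"]
        nf_pool = [l for l in c_loci if l["status"] == "nf"]
        for h, (ncd, nnf) in zip(hap_names, split):
            c_assign[h] = [cd_pool.pop() for _ in range(ncd)] + [
                nf_pool.pop() for _ in range(nnf)
            ]
    else:
        c_assign[hap_names[0]] = list(c_loci)

    contigs: list[AnnotatedContig] = []
    sequences: dict[str, str] = {}
    all_loci: list[NucSequence] = []
    truth_rows: list[dict] = []
    locus_counter = itertools.count(1)

    def add_contig(contig_id: str, parts: list[tuple[str, dict | None]],
                   stream: int) -> None:
        """parts: ordered (family, locus-dict-or-None-for-flanker) items."""
        rng = np.random.default_rng([sim.seed, stream])
        lo, hi = sim.spacer_range
        seq_parts: list[str] = []
        genes: list[Gene] = []
        pos = 0
        for family, locus in parts:
            spacer = _spacer(rng, lo, hi)
            seq_parts.append(spacer)
            pos += len(spacer)
            if locus is None:
                gseq = _random_gene_seq(rng)
                strand = "+" if rng.random() < 0.7 else "-"
                gene_id = f"{gid}_{family}_{pos}"
                status = "cd"
            else:
                subclade = locus["subclade"]
                k = next(locus_counter)
                gene_id = f"{gid}_locus{k:02d}_{subclade}"
                nseq = materialize(subclade, locus, rng, k)
                oriented = NucSequence(gene_id, nseq.seq)
                strand = "+" if rng.random() < 0.8 else "-"
                gseq = (
                    oriented.seq if strand == "+"
                    else oriented.reverse_complement().seq
                )
                status = locus["status"]
                all_loci.append(oriented)
                lineage = {n.kind: n.name for n in cfg.lineage(locus["type"])}
                truth_rows.append({
                    "seq_id": gene_id,
                    "contig": contig_id,
                    "start": pos + 1,
                    "end": pos + len(gseq),
                    "strand": strand,
                    "clade": lineage.get("clade"),
                    "subclade": lineage.get("subclade", lineage.get("clade")),
                    "group": lineage.get("group") or "",
                    "type": lineage.get("type") or lineage.get("subclade"),
                    "status": status,
                })
            genes.append(Gene(
                gene_id=gene_id,
                family=family,
                strand=strand,
                start=pos + 1,
                end=pos + len(gseq),
                status=status,
            ))
            seq_parts.append(gseq)
            pos += len(gseq)
        seq_parts.append(_spacer(rng, lo, hi))
        sequences[contig_id] = "".join(seq_parts)
        contigs.append(AnnotatedContig(contig_id, gid, genes))

    # block 1: divergent 5' region + group 5.2 BBE + clade C array + 3' flank
    for i, hap in enumerate(hap_names):
        if hap not in hap_genes and not c_assign.get(hap):
            continue
        parts: list[tuple[str, dict | None]] = []
        for subclade, locus in hap_genes.get(hap, []):
            parts.append((subclade, {**locus, "subclade": subclade}))
        parts.append(("BBE_5.2", None))
        for locus in c_assign.get(hap, []):
            parts.append(("C", {**locus, "subclade": "C"}))
        for fam in _BLOCK1_FLANK_3P:
            parts.append((fam, None))
        add_contig(f"{gid}_block1_hap{i + 1}", parts, stream=200 + i)

    # block 2: CBCAS tandem array, absent when the profile has no A2 copies
    a2 = loci_by_subclade.get("A2_CBCAS", [])
    if a2:
        parts = [(fam, None) for fam in _BLOCK2_FLANK_5P]
        a2_parts = [("A2_CBCAS", {**l, "subclade": "A2_CBCAS"}) for l in a2]
        if a3_in_block2:
            a3_nf = [l for l in loci_by_subclade.get("A3", [])
                     if l["status"] == "nf"]
            insert_at = max(1, len(a2_parts) // 2)
            for l in a3_nf:
                a2_parts.insert(insert_at, ("A3", {**l, "subclade": "A3"}))
        parts += a2_parts
        parts += [(fam, None) for fam in _BLOCK2_FLANK_3P]
        add_contig(f"{gid}_block2_hap1", parts, stream=300)

    truth = pd.DataFrame(
        truth_rows,
        columns=["seq_id", "contig", "start", "end", "strand", "clade",
                 "subclade", "group", "type", "status"],
    )
    return SimulatedGenome(gid, contigs, sequences, all_loci, truth)
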