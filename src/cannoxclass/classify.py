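"""Diagnostic-character discovery and hierarchical clade/type assignment.

The classification follows the clade-diagnostic-substitution logic used to
delimit cannabinoid oxidocyclase clades: a character state (amino acid,
nucleotide, or shared indel) at a reference-projected position is diagnostic
for a clade when it is constant within the clade and absent outside it,
given current sampling.  Sequences are then assigned top-down — clade (A, B,
C), subclade, group, type — by the fraction of a node's diagnostic states
they match; a level is only assigned when the best child clears a threshold
and strictly beats the runner-up, otherwise the sequence is called "novel"
at that level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import pandas as pd

from .annotate import FragmentError, LesionReport, call_lesions, copy_status_counts
from .refcoord import (
    DELETED,
    NucSequence,
    ReferenceFrame,
    align_global,
    build_frame,
    orient_query,
    state_at,
)
from .synthetic_data import DiagnosticSite, SchemeConfig

_AA_AMBIG = {"X"}
_NT_UNAMBIG = set("ACGT")

DEFAULT_THRESHOLD = 0.8


def _informative(state: str, level: str) -> bool:
    if state == DELETED:
        return False
    if level == "aa":
        return state not in _AA_AMBIG
    return state in _NT_UNAMBIG


# ---------------------------------------------------------------------------
# Diagnostic discovery
# ---------------------------------------------------------------------------

def discover_diagnostics(
    panel: dict[str, tuple[NucSequence, ReferenceFrame]],
    partition: dict[str, str | None],
    level: str = "aa",
) -> dict[str, list[DiagnosticSite]]:
    """Find, per label, the positions where all members share a state that no
    non-member carries.

    ``partition`` maps sequence id -> label; ids mapped to ``None`` count as
    background only (they can veto a state's uniqueness but define no label).
    Substitution states that are deleted or ambiguous are never diagnostic;
    indels shared by a whole label and absent outside are reported as
    indel-type sites.  Sites are ordered by reference position.
    """
    labels = sorted({l for l in partition.values() if l is not None})
    if len(labels) < 2:
        raise ValueError("need at least two labels to contrast")
    members: dict[str, list[str]] = {l: [] for l in labels}
    for sid, label in partition.items():
        if label is not None:
            members[label].append(sid)
    for label, ids in members.items():
        if not ids:
            raise ValueError(f"label {label!r} has no members")

    ref_length = next(iter(panel.values()))[1].ref_length
    if level == "aa":
        positions = [3 * c - 2 for c in range(1, ref_length // 3 + 1)]
    else:
        positions = list(range(1, ref_length + 1))

    states: dict[str, list[str]] = {
        sid: [state_at(frame, seq, pos, level) for pos in positions]
        for sid, (seq, frame) in panel.items()
    }

    out: dict[str, list[DiagnosticSite]] = {l: [] for l in labels}
    all_ids = list(panel)
    for k, pos in enumerate(positions):
        for label in labels:
            ids = members[label]
            first = states[ids[0]][k]
            if not _informative(first, level):
                continue
            if any(states[sid][k] != first for sid in ids[1:]):
                continue
            if any(
                states[sid][k] == first
                for sid in all_ids
                if partition.get(sid) != label
            ):
                continue
            out[label].append(DiagnosticSite(pos, level, first, label))

    # shared indels
    indels: dict[str, set[tuple[int, int]]] = {
        sid: set(frame.indel_runs()) for sid, (_s, frame) in panel.items()
    }
    for label in labels:
        ids = members[label]
        shared = set.intersection(*(indels[sid] for sid in ids))
        for pos, length in sorted(shared):
            if any(
                (pos, length) in indels[sid]
                for sid in all_ids
                if partition.get(sid) != label
            ):
                continue
            tag = f"{'ins' if length > 0 else 'del'}{abs(length)}"
            out[label].append(
                DiagnosticSite(pos, "nt", tag, label, "indel", length, (length,))
            )
        out[label].sort(key=lambda s: (s.ref_pos, s.kind))
    return out


# ---------------------------------------------------------------------------
# Scheme with realized states
# ---------------------------------------------------------------------------

@dataclass
class SchemeNodeRealized:
    name: str
    kind: str
    parent: str
    children: list[str] = field(default_factory=list)
    sites: list[DiagnosticSite] = field(default_factory=list)
    alias: str | None = None
    defective: bool = False
    secondary: bool = False
    orf_length: int | None = None


@dataclass
class ClassificationScheme:
    """The hierarchy clade -> subclade -> group -> type with realized
    diagnostic states, plus per-subclade type profiles for nearest-type
    assignment."""

    reference: NucSequence
    nodes: dict[str, SchemeNodeRealized]
    # subclade -> {type -> [(pos, level, expected_state)]}
    type_profiles: dict[str, dict[str, list[tuple[int, str, str]]]]
    threshold: float = DEFAULT_THRESHOLD

    def children_of(self, name: str) -> list[SchemeNodeRealized]:
        return [self.nodes[c] for c in self.nodes[name].children]

    @property
    def clades(self) -> list[SchemeNodeRealized]:
        return [n for n in self.nodes.values() if n.kind == "clade"]

    def types_under(self, subclade: str) -> list[str]:
        out = []
        stack = list(self.nodes[subclade].children)
        while stack:
            child = self.nodes[stack.pop(0)]
            if child.kind == "type":
                out.append(child.name)
            else:
                stack.extend(child.children)
        return out

    def validate(self) -> None:
        """Sibling nodes may not claim the same (pos, level, state)."""
        conflicts = []
        for node in self.nodes.values():
            claims: dict[tuple, str] = {}
            for child in self.children_of(node.name):
                for s in child.sites:
                    if s.inherited:
                        continue
                    key = (s.ref_pos, s.level, s.state)
                    if key in claims and claims[key] != child.name:
                        conflicts.append((claims[key], child.name, key))
                    claims[key] = child.name
        if conflicts:
            raise ValueError(f"contradictory sibling diagnostics: {conflicts}")


def _majority(states: list[str], level: str) -> str | None:
    usable = [s for s in states if _informative(s, level)]
    if not usable:
        return None
    return Counter(usable).most_common(1)[0][0]


def build_scheme(
    panel: list[NucSequence],
    labels: dict[str, dict],
    cfg: SchemeConfig,
    reference: NucSequence | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> ClassificationScheme:
    """Build a realized scheme from a labelled, reference-projected panel.

    Clade- and subclade-level diagnostic sets are *discovered* from the panel
    (constant-within / unique-outside); type- and group-level sites are the
    configured positions with their states read off the owning panel members.
    """
    if reference is None:
        ref_ids = [
            sid for sid, lab in labels.items()
            if lab.get("type") == "1/1" and lab.get("subclade") == "A1_THCAS"
        ]
        if not ref_ids:
            raise ValueError("no reference (A1 type 1/1) sequence in panel")
        reference = next(s for s in panel if s.id == ref_ids[0])

    frames = {
        seq.id: (seq, build_frame(align_global(reference, seq)))
        for seq in panel
    }

    clade_part = {sid: lab.get("clade") for sid, lab in labels.items()}
    for sid, lab in labels.items():
        if lab.get("clade") == "outgroup":
            clade_part[sid] = "outgroup"
    sub_part = {
        sid: (lab.get("subclade") if lab.get("clade") not in (None, "outgroup")
              else lab.get("clade"))
        for sid, lab in labels.items()
    }
    disc_clade = discover_diagnostics(frames, clade_part, "aa")
    disc_sub = discover_diagnostics(frames, sub_part, "aa")

    cfg_indels = {
        n.name: n.indels for n in cfg.nodes.values() if n.indels
    }

    def _attach_alt_lengths(name: str, sites: list[DiagnosticSite]):
        for s in sites:
            if s.kind == "indel":
                for ind in cfg_indels.get(name, []):
                    if ind["pos"] == s.ref_pos and "alt_lengths" in ind:
                        s.alt_lengths = tuple(ind["alt_lengths"])
        return sites

    nodes: dict[str, SchemeNodeRealized] = {
        "root": SchemeNodeRealized("root", "root", "")
    }
    for name in cfg.order:
        cn = cfg.nodes[name]
        nodes[name] = SchemeNodeRealized(
            name, cn.kind, cn.parent, alias=cn.alias, defective=cn.defective,
            secondary=cn.secondary, orf_length=cn.orf_length,
        )
        nodes[cn.parent if cn.parent != "root" else "root"].children.append(name)

    members_of_type: dict[str, list[str]] = {}
    for sid, lab in labels.items():
        t = lab.get("type")
        if t:
            members_of_type.setdefault(t, []).append(sid)

    def probe(type_name: str, pos: int, level: str) -> str | None:
        ids = members_of_type.get(type_name, [])
        sts = [state_at(frames[i][1], frames[i][0], pos, level) for i in ids]
        return _majority(sts, level)

    # realized type/group sites from configured positions
    def realized_sites(name: str) -> list[DiagnosticSite]:
        cn = cfg.nodes[name]
        sites: list[DiagnosticSite] = []
        source_names = [name] + ([cn.inherit_sites] if cn.inherit_sites else [])
        for src_name in source_names:
            src = cfg.nodes[src_name]
            inherited = src_name != name
            owner_for_probe = name if cn.kind == "type" else None
            for s in src.explicit_sites:
                sites.append(DiagnosticSite(s["pos"], "aa", s["aa"], name,
                                            inherited=inherited))
            for c in src.aa_codons:
                pos = 3 * c - 2
                st = (probe(owner_for_probe, pos, "aa")
                      if owner_for_probe else None)
                if st is None and cn.kind == "group":
                    # group site: probe any member of a child type
                    for t in cfg.nodes[name].children:
                        st = probe(t, pos, "aa")
                        if st is not None:
                            break
                if st is not None:
                    sites.append(DiagnosticSite(pos, "aa", st, name,
                                                inherited=inherited))
            for c in src.syn_codons:
                base = 3 * c - 2
                # locate the realized synonymous change within the codon
                ref_codon = reference.seq[base - 1 : base + 2]
                st = None
                for off in range(3):
                    got = (probe(owner_for_probe, base + off, "nt")
                           if owner_for_probe else None)
                    if got is not None and got != ref_codon[off]:
                        st = (base + off, got)
                        break
                if st:
                    sites.append(DiagnosticSite(st[0], "nt", st[1], name))
            for c in src.nonsense_codons:
                sites.append(DiagnosticSite(3 * c - 2, "aa", "*", name))
        return sites

    for name in cfg.order:
        cn = cfg.nodes[name]
        if cn.kind == "clade":
            nodes[name].sites = disc_clade.get(name, [])
        elif cn.kind == "subclade":
            nodes[name].sites = _attach_alt_lengths(
                name, disc_sub.get(name, [])
            )
        else:
            nodes[name].sites = realized_sites(name)

    # per-subclade nearest-type profiles over the union of type/group sites
    # (a clade owning types directly, like clade C, acts as its own subclade)
    type_profiles: dict[str, dict[str, list[tuple[int, str, str]]]] = {}
    all_types = [t for t in cfg.order if cfg.nodes[t].kind == "type"]
    type_parents = sorted(
        {cfg.subclade_of(t) for t in all_types}, key=cfg.order.index
    )
    for sub in type_parents:
        scheme_types = [t for t in all_types if cfg.subclade_of(t) == sub]
        if not scheme_types:
            continue
        own_sites: dict[str, dict[tuple[int, str], str]] = {}
        for t in scheme_types:
            sites = list(nodes[t].sites)
            parent = cfg.nodes[t].parent
            if cfg.nodes[parent].kind == "group":
                sites += nodes[parent].sites
            own_sites[t] = {(s.ref_pos, s.level): s.state for s in sites
                            if s.kind == "sub"}
        union = sorted({k for d in own_sites.values() for k in d})
        sub_ids = [
            sid for sid, lab in labels.items() if lab.get("subclade") == sub
        ]
        profiles: dict[str, list[tuple[int, str, str]]] = {}
        consensus: dict[tuple[int, str], str | None] = {}
        for pos, level in union:
            owners = {t for t, d in own_sites.items() if (pos, level) in d}
            non_owner_ids = [
                sid for sid in sub_ids
                if labels[sid].get("type") not in owners
            ]
            sts = [
                state_at(frames[i][1], frames[i][0], pos, level)
                for i in non_owner_ids
            ]
            consensus[(pos, level)] = _majority(sts, level)
        for t in scheme_types:
            prof = []
            for pos, level in union:
                exp = own_sites[t].get((pos, level), consensus[(pos, level)])
                if exp is not None:
                    prof.append((pos, level, exp))
            profiles[t] = prof
        type_profiles[sub] = profiles

    scheme = ClassificationScheme(reference, nodes, type_profiles, threshold)
    scheme.validate()
    return scheme


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    seq_id: str
    clade: str = "novel"
    subclade: str = "novel"
    group: str | None = None
    type: str = "novel"
    fractions: dict[str, float] = field(default_factory=dict)
    status: str | None = None
    notes: list[str] = field(default_factory=list)
    partial: bool = False

    @property
    def alias(self) -> str | None:
        return None


def _site_fraction(
    query: NucSequence,
    frame: ReferenceFrame,
    sites: list[DiagnosticSite],
    query_indels: set[tuple[int, int]],
) -> float:
    matched = informative = 0
    for s in sites:
        if s.kind == "indel":
            informative += 1
            allowed = set(s.alt_lengths) | {s.indel_length}
            if any(
                pos == s.ref_pos and length in allowed
                for pos, length in query_indels
            ):
                matched += 1
        else:
            st = state_at(frame, query, s.ref_pos, s.level)
            if not _informative(st, s.level):
                continue
            informative += 1
            if st == s.state:
                matched += 1
    return matched / informative if informative else 0.0


def _profile_fraction(
    query: NucSequence,
    frame: ReferenceFrame,
    profile: list[tuple[int, str, str]],
) -> float:
    matched = informative = 0
    for pos, level, exp in profile:
        st = state_at(frame, query, pos, level)
        if not _informative(st, level):
            continue
        informative += 1
        if st == exp:
            matched += 1
    return matched / informative if informative else 0.0


def _pick(
    scored: list[tuple[str, float]], threshold: float
) -> tuple[str | None, bool]:
    """Best child if above threshold and strictly ahead; mixed flag when
    more than one child clears the threshold."""
    scored = sorted(scored, key=lambda t: (-t[1], t[0]))
    above = [s for s in scored if s[1] >= threshold]
    mixed = len(above) >= 2
    if not above:
        return None, False
    if len(scored) > 1 and scored[0][1] == scored[1][1]:
        return None, mixed
    return scored[0][0], mixed


def classify_sequence(
    query: NucSequence,
    scheme: ClassificationScheme,
    frame: ReferenceFrame | None = None,
) -> ClassificationResult:
    """Top-down assignment of one reference-projected sequence."""
    if frame is None:
        oriented, _ = orient_query(scheme.reference, query)
        query = oriented
        frame = build_frame(align_global(scheme.reference, query))
    res = ClassificationResult(query.id)
    q_indels = set(frame.indel_runs())

    covered = len(frame.ref_to_query)
    if covered < 0.9 * frame.ref_length:
        res.partial = True
        res.notes.append("partial reference coverage")

    # clade level
    scored = []
    for clade in scheme.clades:
        f = _site_fraction(query, frame, clade.sites, q_indels)
        res.fractions[clade.name] = f
        scored.append((clade.name, f))
    pick, mixed = _pick(scored, scheme.threshold)
    if mixed:
        res.notes.append("mixed profile (clade level)")
    if pick is None:
        return res
    res.clade = pick

    # subclade level (a clade with no subclade children, like clade C,
    # is its own subclade)
    subclades = [n for n in scheme.children_of(pick) if n.kind == "subclade"]
    if subclades:
        scored = []
        for sub in subclades:
            f = _site_fraction(query, frame, sub.sites, q_indels)
            res.fractions[sub.name] = f
            scored.append((sub.name, f))
        pick, mixed = _pick(scored, scheme.threshold)
        if mixed:
            res.notes.append("mixed profile (subclade level)")
        if pick is None:
            return res
    res.subclade = pick

    # type level: nearest type over the union profile
    profiles = scheme.type_profiles.get(pick)
    if not profiles:
        res.type = "n/a"
        return res
    scored = []
    for tname, prof in profiles.items():
        f = _profile_fraction(query, frame, prof)
        res.fractions[f"type:{tname}"] = f
        scored.append((tname, f))
    tpick, _ = _pick(scored, scheme.threshold)
    if tpick is None:
        return res
    res.type = tpick
    if res.fractions[f"type:{tpick}"] < 1.0:
        res.notes.append("nearest type (imperfect profile match)")
    parent = scheme.nodes[tpick].parent
    if scheme.nodes[parent].kind == "group":
        res.group = parent
    if scheme.nodes[tpick].defective:
        res.notes.append("known-defective allele")
    if scheme.nodes[tpick].alias:
        res.notes.append(f"alias {scheme.nodes[tpick].alias}")
    return res


def classify_batch(
    records: list[NucSequence],
    scheme: ClassificationScheme,
) -> tuple[list[ClassificationResult], pd.DataFrame]:
    """Classify every record, call lesions against the scheme reference, and
    aggregate a copy-number (cd/nf) matrix by subclade."""
    results: list[ClassificationResult] = []
    reports: list[LesionReport] = []
    clade_labels: dict[str, str] = {}
    for rec in records:
        oriented, _ = orient_query(scheme.reference, rec)
        frame = build_frame(align_global(scheme.reference, oriented))
        res = classify_sequence(oriented, scheme, frame)
        try:
            report = call_lesions(oriented, scheme.reference, frame)
            res.status = report.status
            reports.append(report)
            clade_labels[rec.id] = res.subclade
        except FragmentError:
            res.status = "fragment"
            res.partial = True
            res.notes.append("fragment: too short for status call")
        results.append(res)
    matrix = copy_status_counts(reports, clade_labels)
    return results, matrix


def results_to_tsv(results: list[ClassificationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tclade\tsubclade\tgroup\ttype\tstatus\tnotes\n")
        for r in results:
            fh.write(
                f"{r.seq_id}\t{r.clade}\t{r.subclade}\t{r.group or ''}\t"
                f"{r.type}\t{r.status or ''}\t{';'.join(r.notes)}\n"
            )
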