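"""Gene-order microsynteny: tandem arrays and collinear blocks.

The two syntenic blocks that carry all cannabinoid oxidocyclase genes are
compared at the gene-family level: every gene on an annotated contig carries
a family label from a controlled vocabulary (oxidocyclase subclades plus the
conserved flanking markers), tandem arrays are maximal same-family runs with
a bounded number of intervening genes, and collinear blocks are maximal
chains of family-matched gene pairs that are monotone on both contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

FAMILY_VOCAB = {
    "BBE_5.2", "BBE_10",
    "A1_THCAS", "A2_CBCAS", "A3", "A4", "B1_CBDAS", "B2", "C",
    "RLP", "Patellin", "TWINKLE", "ClpP",
    "ZnF", "RLK", "Ankyrin", "NPF",
    "other",
}

#: Defaults: arrays tolerate the occasional inserted gene (e.g. the A3
#: pseudogene inside a CBCAS array); blocks need three anchors.
DEFAULT_MIN_ANCHORS = 3
DEFAULT_MAX_GAP = 2
DEFAULT_MAX_INTERVENERS = 2


@dataclass(frozen=True)
class Gene:
    gene_id: str
    family: str
    strand: str
    start: int
    end: int
    status: str = "cd"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class AnnotatedContig:
    contig_id: str
    genome_id: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: g.start)
        for a, b in zip(self.genes, self.genes[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.contig_id}: overlapping genes {a.gene_id}/{b.gene_id}"
                )
        unknown = {g.family for g in self.genes} - FAMILY_VOCAB
        if unknown:
            raise ValueError(
                f"{self.contig_id}: families outside vocabulary: {sorted(unknown)}"
            )


@dataclass
class TandemArray:
    contig_id: str
    family: str
    members: list[str]
    intervening: int

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SyntenyBlock:
    contig_a: str
    contig_b: str
    anchors: list[tuple[str, str]]
    orientation: str  # "same" | "inverted"

    def __len__(self) -> int:
        return len(self.anchors)


def find_tandem_arrays(
    contig: AnnotatedContig,
    family: str,
    max_interveners: int = DEFAULT_MAX_INTERVENERS,
) -> list[TandemArray]:
    """Maximal runs of >=2 same-family genes with at most ``max_interveners``
    non-family genes between consecutive members, reported left to right."""
    if family not in FAMILY_VOCAB:
        raise ValueError(f"unknown family {family!r}")
    idx = [i for i, g in enumerate(contig.genes) if g.family == family]
    arrays: list[TandemArray] = []
    run: list[int] = []
    for i in idx:
        if run and i - run[-1] - 1 > max_interveners:
            if len(run) >= 2:
                arrays.append(_make_array(contig, family, run))
            run = []
        run.append(i)
    if len(run) >= 2:
        arrays.append(_make_array(contig, family, run))
    return arrays


def _make_array(contig: AnnotatedContig, family: str, run: list[int]) -> TandemArray:
    members = [contig.genes[i].gene_id for i in run]
    intervening = (run[-1] - run[0] + 1) - len(run)
    return TandemArray(contig.contig_id, family, members, intervening)


def collinear_blocks(
    a: AnnotatedContig,
    b: AnnotatedContig,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[SyntenyBlock]:
    """Maximal chains of family-matched gene pairs, monotone on both contigs
    (increasing for same orientation, decreasing on ``b`` for inverted),
    allowing up to ``max_gap`` unmatched genes between consecutive anchors on
    either contig.  Both orientations are searched."""
    blocks: list[SyntenyBlock] = []
    for orientation in ("same", "inverted"):
        pairs = [
            (i, j)
            for i, ga in enumerate(a.genes)
            for j, gb in enumerate(b.genes)
            if ga.family == gb.family
        ]
        if orientation == "inverted":
            pairs = [(i, len(b.genes) - 1 - j) for i, j in pairs]
        pairs.sort()
        # longest-chain DP over anchor pairs with bounded gaps
        n = len(pairs)
        best_len = [1] * n
        prev = [-1] * n
        for k in range(n):
            ik, jk = pairs[k]
            for m in range(k):
                im, jm = pairs[m]
                if (
                    im < ik
                    and jm < jk
                    and ik - im - 1 <= max_gap
                    and jk - jm - 1 <= max_gap
                    and best_len[m] + 1 > best_len[k]
                ):
                    best_len[k] = best_len[m] + 1
                    prev[k] = m
        used = [False] * n
        for k in sorted(range(n), key=lambda x: -best_len[x]):
            if used[k] or best_len[k] < min_anchors:
                continue
            chain = []
            m = k
            while m != -1:
                if used[m]:
                    break
                chain.append(m)
                used[m] = True
                m = prev[m]
            chain.reverse()
            if len(chain) < min_anchors:
                continue
            anchors = []
            for m in chain:
                i, j = pairs[m]
                jj = j if orientation == "same" else len(b.genes) - 1 - j
                anchors.append((a.genes[i].gene_id, b.genes[jj].gene_id))
            blocks.append(SyntenyBlock(a.contig_id, b.contig_id, anchors,
                                       orientation))
    # prefer the orientation explaining more anchors; drop blocks whose
    # anchors are a subset of a larger one in the other orientation
    blocks.sort(key=len, reverse=True)
    kept: list[SyntenyBlock] = []
    seen_pairs: set[tuple[str, str]] = set()
    for blk in blocks:
        fresh = [p for p in blk.anchors if p not in seen_pairs]
        if len(fresh) >= min_anchors:
            kept.append(blk)
            seen_pairs.update(blk.anchors)
    return kept


@dataclass
class FlankingReport:
    upstream: list[str]    # 5' neighbour families, nearest first
    downstream: list[str]  # 3' neighbour families, nearest first
    truncated_5p: bool
    truncated_3p: bool


def flanking_report(
    array: TandemArray, contig: AnnotatedContig, k: int = 4
) -> FlankingReport:
    """Families of up to ``k`` neighbours on each side of a tandem array."""
    ids = {g.gene_id: i for i, g in enumerate(contig.genes)}
    try:
        first = min(ids[m] for m in array.members)
        last = max(ids[m] for m in array.members)
    except KeyError as e:
        raise ValueError(f"array member {e} not on contig {contig.contig_id}")
    up = [g.family for g in contig.genes[max(0, first - k) : first]][::-1]
    down = [g.family for g in contig.genes[last + 1 : last + 1 + k]]
    return FlankingReport(
        upstream=up,
        downstream=down,
        truncated_5p=len(up) < k,
        truncated_3p=len(down) < k,
    )


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def write_gff3(contigs: list[AnnotatedContig], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in contigs:
            for g in contig.genes:
                attrs = (
                    f"ID={g.gene_id};family={g.family};status={g.status}"
                )
                fh.write(
                    f"{contig.contig_id}\tcannoxclass\tgene\t{g.start}\t"
                    f"{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_gff3(path: str | Path, genome_id: str = "") -> list[AnnotatedContig]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    by_contig: dict[str, list[Gene]] = {}
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        fam = feat.attributes.get("family", ["other"])[0]
        status = feat.attributes.get("status", ["cd"])[0]
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        by_contig.setdefault(feat.seqid, []).append(
            Gene(gene_id, fam, feat.strand, feat.start, feat.end, status)
        )
    return [
        AnnotatedContig(cid, genome_id, genes)
        for cid, genes in sorted(by_contig.items())
    ]


def arrays_to_tsv(arrays: list[TandemArray], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tfamily\tn_members\tintervening\tmembers\n")
        for a in arrays:
            fh.write(
                f"{a.contig_id}\t{a.family}\t{len(a)}\t{a.intervening}\t"
                + ",".join(a.members) + "\n"
            )


def blocks_to_tsv(blocks: list[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_a\tcontig_b\torientation\tn_anchors\tanchors\n")
        for b in blocks:
            fh.write(
                f"{b.contig_a}\t{b.contig_b}\t{b.orientation}\t{len(b)}\t"
                + ",".join(f"{x}|{y}" for x, y in b.anchors) + "\n"
            )
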