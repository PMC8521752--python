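"""Reference-coordinate projection for cannabinoid oxidocyclase sequences.

All site numbers used in the classification scheme (e.g. "706 C", the 3-bp
deletion at position 755) are 1-based nucleotide positions on the ungapped
THCAS open reading frame (1638 nt).  This module provides the plumbing to get
there: FASTA I/O, affine-gap global pairwise alignment of a query against the
reference ORF, and a :class:`ReferenceFrame` that maps query positions onto
reference numbering so that any downstream operation (diagnostic-site lookup,
lesion calling, distance computation) can speak in reference coordinates.

Amino-acid positions are derived as ``ceil(nt/3)`` so that, e.g., nucleotide
706 lies in codon 236.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

IUPAC_NT = set("ACGTURYSWKMBDHVN")
#: Sentinel returned by :func:`state_at` for reference positions absent from
#: the query.
DELETED = "deleted"

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: Default scoring: strongly favours one contiguous gap so that the named
#: indels of the classification scheme align as single events.
DEFAULT_ALIGN_PARAMS = {
    "match": 2.0,
    "mismatch": -3.0,
    "gap_open": -8.0,
    "gap_extend": -1.0,
}


class FastaParseError(ValueError):
    """Malformed FASTA input (empty record, duplicate ids, ...)."""


class SequenceError(ValueError):
    """Sequence violates the IUPAC nucleotide alphabet."""


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence, stored uppercase, IUPAC-restricted."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper().replace("U", "T"))
        if not self.seq:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - IUPAC_NT
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(
            self.id, str(Seq(self.seq).reverse_complement()), self.description
        )


def translate_codon(codon: str) -> str:
    """Translate one codon; any ambiguity yields 'X', stops yield '*'."""
    return _CODON_TABLE.get(codon, "X")


def translate(seq: str) -> str:
    return "".join(
        translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3)
    )


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a (multi-)FASTA file into a list of :class:`NucSequence`.

    Record order is preserved; sequences are uppercased.  Raises
    :class:`FastaParseError` on records with empty sequences or duplicated ids.
    """
    records: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaParseError(f"record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FastaParseError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(NucSequence(rec.id, str(rec.seq), desc))
    return records


def write_fasta(records: Iterable[NucSequence], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Pairwise global alignment
# ---------------------------------------------------------------------------

@dataclass
class PairwiseAlignment:
    """A global alignment of a query against the reference.

    ``aligned_ref`` and ``aligned_query`` are equal-length gapped strings;
    removing gaps recovers the inputs exactly and no column is gap/gap.
    """

    ref_id: str
    query_id: str
    aligned_ref: str
    aligned_query: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValueError("aligned rows differ in length")

    @property
    def ops(self) -> list[tuple[str, int]]:
        """Run-length ops over columns: M (both), D (gap in query), I (gap in ref)."""
        out: list[tuple[str, int]] = []
        for r, q in zip(self.aligned_ref, self.aligned_query):
            op = "M" if (r != "-" and q != "-") else ("D" if q == "-" else "I")
            if out and out[-1][0] == op:
                out[-1] = (op, out[-1][1] + 1)
            else:
                out.append((op, 1))
        return out


def _make_aligner(params: dict) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params["match"]
    aligner.mismatch_score = params["mismatch"]
    # biopython charges open_gap_score for the first gap position; our
    # convention is cost(L) = open + L*extend.
    aligner.open_gap_score = params["gap_open"] + params["gap_extend"]
    aligner.extend_gap_score = params["gap_extend"]
    return aligner


def _right_normalize(ref: str, query: str, aligned_ref: str, aligned_query: str):
    """Shift every gap run as far 3' as score-equivalence allows.

    A deletion of ref[p:p+L] may slide right while ref[p] == ref[p+L] (and
    symmetrically for insertions).  This implements the deterministic
    "gaps later" tie-break and anchors tandem-duplication insertions at the
    3' copy (e.g. the codon-3 TAC duplication lands after reference 9).
    """
    ops: list[list] = []  # [op, length]
    for r, q in zip(aligned_ref, aligned_query):
        op = "M" if (r != "-" and q != "-") else ("D" if q == "-" else "I")
        if ops and ops[-1][0] == op:
            ops[-1][1] += 1
        else:
            ops.append([op, 1])

    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(ops) - 1:
            op, length = ops[i]
            nxt_op, nxt_len = ops[i + 1]
            if op in "DI" and nxt_op == "M":
                # ungapped start offsets of this run
                rpos = sum(l for o, l in ops[:i] if o in "MD")
                qpos = sum(l for o, l in ops[:i] if o in "MI")
                shift = 0
                if op == "D":
                    while (
                        shift < nxt_len
                        and rpos + length + shift < len(ref)
                        and ref[rpos + shift] == ref[rpos + length + shift]
                    ):
                        shift += 1
                else:
                    while (
                        shift < nxt_len
                        and qpos + length + shift < len(query)
                        and query[qpos + shift] == query[qpos + length + shift]
                    ):
                        shift += 1
                if shift:
                    changed = True
                    pre = [["M", shift]] if shift else []
                    rest = [[nxt_op, nxt_len - shift]] if nxt_len - shift else []
                    ops[i : i + 2] = pre + [[op, length]] + rest
                    # merge adjacent same-op runs
                    j = 1
                    while j < len(ops):
                        if ops[j][0] == ops[j - 1][0]:
                            ops[j - 1][1] += ops[j][1]
                            del ops[j]
                        else:
                            j += 1
            i += 1

    a_ref, a_query = [], []
    rp = qp = 0
    for op, length in ops:
        if op == "M":
            a_ref.append(ref[rp : rp + length])
            a_query.append(query[qp : qp + length])
            rp += length
            qp += length
        elif op == "D":
            a_ref.append(ref[rp : rp + length])
            a_query.append("-" * length)
            rp += length
        else:
            a_ref.append("-" * length)
            a_query.append(query[qp : qp + length])
            qp += length
    return "".join(a_ref), "".join(a_query)


def align_global(
    ref: NucSequence,
    query: NucSequence,
    params: dict | None = None,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of ``query`` against ``ref``.

    Ties between co-optimal alignments are broken deterministically by
    preferring gaps later in the query, then in the reference (gap runs are
    right-normalized after alignment).
    """
    p = dict(DEFAULT_ALIGN_PARAMS)
    if params:
        p.update(params)
    aligner = _make_aligner(p)
    aln = aligner.align(ref.seq, query.seq)[0]
    a_ref, a_query = str(aln[0]), str(aln[1])
    a_ref, a_query = _right_normalize(ref.seq, query.seq, a_ref, a_query)
    return PairwiseAlignment(ref.id, query.id, a_ref, a_query, float(aln.score))


def orient_query(
    ref: NucSequence, query: NucSequence, params: dict | None = None
) -> tuple[NucSequence, bool]:
    """Reverse-complement pre-pass: return the orientation of ``query`` that
    aligns best to ``ref`` (reverse strand chosen only when it scores >=20%
    higher), plus a flag indicating whether it was flipped."""
    p = dict(DEFAULT_ALIGN_PARAMS)
    if params:
        p.update(params)
    aligner = _make_aligner(p)
    fwd = float(aligner.score(ref.seq, query.seq))
    rc = query.reverse_complement()
    rev = float(aligner.score(ref.seq, rc.seq))
    if rev >= fwd + 0.2 * abs(fwd):
        return rc, True
    return query, False


# ---------------------------------------------------------------------------
# Reference frame
# ---------------------------------------------------------------------------

@dataclass
class ReferenceFrame:
    """Projection of one query onto reference (THCAS-frame) numbering.

    ``ref_to_query`` maps matched reference positions to query positions
    (both 1-based).  ``deleted`` holds reference positions absent from the
    query.  ``insertions`` holds query positions present between reference
    positions, as ``(ref_anchor, offset, query_pos)`` with offset >= 1; an
    anchor of 0 means the insertion precedes reference position 1.
    """

    ref_id: str
    query_id: str
    ref_length: int
    ref_to_query: dict[int, int]
    deleted: frozenset[int]
    insertions: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def query_to_ref(self) -> dict[int, int]:
        return {q: r for r, q in self.ref_to_query.items()}

    def indel_runs(self) -> list[tuple[int, int]]:
        """Signed indel runs as (ref_pos, signed_length).

        Deletions: (first deleted reference position, -run_length).
        Insertions: (reference anchor, +run_length).
        """
        runs: list[tuple[int, int]] = []
        dels = sorted(self.deleted)
        i = 0
        while i < len(dels):
            j = i
            while j + 1 < len(dels) and dels[j + 1] == dels[j] + 1:
                j += 1
            runs.append((dels[i], -(j - i + 1)))
            i = j + 1
        i = 0
        ins = self.insertions
        while i < len(ins):
            anchor = ins[i][0]
            j = i
            while j + 1 < len(ins) and ins[j + 1][0] == anchor:
                j += 1
            runs.append((anchor, j - i + 1))
            i = j + 1
        return sorted(runs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("query_id\tquery_pos\tref_pos\top\n")
            rows = [(q, r, "M") for r, q in self.ref_to_query.items()]
            rows += [(q, a, "I") for a, _off, q in self.insertions]
            rows += [(None, r, "D") for r in sorted(self.deleted)]
            rows.sort(key=lambda t: (t[1], t[2]))
            for q, r, op in rows:
                fh.write(f"{self.query_id}\t{'' if q is None else q}\t{r}\t{op}\n")


def build_frame(aln: PairwiseAlignment) -> ReferenceFrame:
    """Build the reference coordinate map from a global alignment."""
    ref_to_query: dict[int, int] = {}
    deleted: set[int] = set()
    insertions: list[tuple[int, int, int]] = []
    rpos = qpos = 0
    ins_offset = 0
    last_anchor = 0
    for r, q in zip(aln.aligned_ref, aln.aligned_query):
        if r != "-" and q != "-":
            rpos += 1
            qpos += 1
            ref_to_query[rpos] = qpos
            ins_offset = 0
            last_anchor = rpos
        elif q == "-":
            rpos += 1
            deleted.add(rpos)
            ins_offset = 0
            last_anchor = rpos
        else:
            qpos += 1
            ins_offset += 1
            insertions.append((last_anchor, ins_offset, qpos))
    return ReferenceFrame(
        ref_id=aln.ref_id,
        query_id=aln.query_id,
        ref_length=rpos,
        ref_to_query=ref_to_query,
        deleted=frozenset(deleted),
        insertions=insertions,
    )


def project(
    ref: NucSequence, query: NucSequence, params: dict | None = None
) -> tuple[ReferenceFrame, NucSequence]:
    """Orient, align and project ``query`` onto ``ref`` coordinates."""
    oriented, _flipped = orient_query(ref, query, params)
    frame = build_frame(align_global(ref, oriented, params))
    return frame, oriented


def state_at(
    frame: ReferenceFrame,
    query: NucSequence,
    ref_pos: int,
    level: Literal["nt", "aa"] = "nt",
) -> str:
    """The query's state at a reference position.

    At ``nt`` level: the query nucleotide aligned to ``ref_pos`` (IUPAC
    ambiguity codes verbatim), or :data:`DELETED`.  At ``aa`` level the codon
    ``ceil(ref_pos/3)`` (reference nts 3c-2..3c) is translated from the query
    nucleotides aligned to it; any deleted position makes the whole codon
    :data:`DELETED`, any ambiguity yields 'X'.
    """
    if not 1 <= ref_pos <= frame.ref_length:
        raise ValueError(
            f"ref_pos {ref_pos} outside reference 1..{frame.ref_length}"
        )
    if level == "nt":
        q = frame.ref_to_query.get(ref_pos)
        if q is None:
            return DELETED
        return query.seq[q - 1]
    codon_idx = math.ceil(ref_pos / 3)
    nts = []
    for pos in range(3 * codon_idx - 2, 3 * codon_idx + 1):
        if pos > frame.ref_length:
            return DELETED
        q = frame.ref_to_query.get(pos)
        if q is None:
            return DELETED
        nts.append(query.seq[q - 1])
    return translate_codon("".join(nts))
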