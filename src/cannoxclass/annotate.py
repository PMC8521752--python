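"""ORF annotation and pseudogene lesion calling.

Cannabinoid oxidocyclase genes are intronless, so gene models reduce to a
single ORF (1638 nt for THCAS-like, 1635 nt for CBDAS-like sequences).
Pseudogene annotation follows the homologous-codon convention: a query is
aligned to a functional reference CDS, the coding frame is kept homologous to
the reference, and every frameshift indel, premature stop (nonsense) and
amino-acid replacement (missense) is reported in reference coordinates.
Lesions downstream of the first frameshift are flagged ``secondary`` —
they are carried along in the annotation but arose after the frame was
already broken.

A sequence is *nonfunctional* iff it carries at least one frameshift or one
nonsense lesion.  Missense-only defective alleles (B_T0, B_D01, B_D02, B_DW)
remain *coding*: copy-number bookkeeping counts them as full-length coding,
and their defectiveness is a type-level annotation of the classification
scheme, not a lesion status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd

from .refcoord import (
    DELETED,
    NucSequence,
    ReferenceFrame,
    STOP_CODONS,
    state_at,
    translate_codon,
)

#: Row layout mirrors the copy-number table of the classification scheme.
SUBCLADE_ORDER = ["A1_THCAS", "A2_CBCAS", "A3", "A4", "B1_CBDAS", "B2", "C"]

LesionKind = Literal["frameshift", "nonsense", "missense", "inframe_indel"]


class FragmentError(ValueError):
    """Query too short relative to the reference to be classifiable."""


@dataclass(frozen=True)
class OrfAnnotation:
    seq_id: str
    start: int
    end: int
    length: int
    has_start_codon: bool
    has_stop_codon: bool


@dataclass(frozen=True)
class Lesion:
    kind: LesionKind
    ref_pos: int
    detail: str
    secondary: bool = False


@dataclass
class LesionReport:
    seq_id: str
    lesions: list[Lesion] = field(default_factory=list)

    @property
    def status(self) -> str:
        bad = any(l.kind in ("frameshift", "nonsense") for l in self.lesions)
        return "nonfunctional" if bad else "coding"

    def of_kind(self, kind: LesionKind) -> list[Lesion]:
        return [l for l in self.lesions if l.kind == kind]


def find_orf(seq: NucSequence) -> OrfAnnotation:
    """Longest ATG-initiated, stop-terminated ORF on the forward strand.

    If no stop-terminated ORF exists, returns the longest stop-free
    ATG-initiated stretch with ``has_stop_codon=False``; with no ATG at all,
    an empty annotation is returned.
    """
    s = seq.seq
    best: tuple[int, int, bool] | None = None  # (start0, end0, stopped)
    for frame in range(3):
        i = frame
        open_start: int | None = None
        while i + 3 <= len(s):
            codon = s[i : i + 3]
            if open_start is None and codon == "ATG":
                open_start = i
            if open_start is not None and codon in STOP_CODONS:
                cand = (open_start, i + 3, True)
                if best is None or _orf_key(cand) > _orf_key(best):
                    best = cand
                open_start = None
            i += 3
        if open_start is not None:
            end = len(s) - (len(s) - open_start) % 3
            cand = (open_start, end, False)
            if best is None or _orf_key(cand) > _orf_key(best):
                best = cand
    if best is None:
        return OrfAnnotation(seq.id, 0, 0, 0, False, False)
    start0, end0, stopped = best
    return OrfAnnotation(seq.id, start0 + 1, end0, end0 - start0, True, stopped)


def _orf_key(cand: tuple[int, int, bool]) -> tuple[int, int, int]:
    start0, end0, stopped = cand
    # prefer stop-terminated, then longest, then leftmost
    return (int(stopped), end0 - start0, -start0)


def call_lesions(
    query: NucSequence,
    ref_cds: NucSequence,
    frame: ReferenceFrame,
    min_fraction: float = 0.10,
) -> LesionReport:
    """Annotate all lesions of ``query`` relative to a functional reference CDS.

    ``frame`` must come from a global alignment of ``ref_cds`` (reference)
    against ``query``.  Indels are reported at their reference position with
    signed length; an indel whose length is not a multiple of 3 is a
    frameshift.  Translation is performed per homologous reference codon:
    a stop in any codon strictly before the reference stop codon is nonsense,
    any other amino-acid replacement is missense.  Lesions downstream of the
    first frameshift are flagged secondary.
    """
    covered = len(frame.ref_to_query)
    if covered < min_fraction * frame.ref_length:
        raise FragmentError(
            f"{query.id}: only {covered}/{frame.ref_length} reference positions "
            "covered; fragment not classifiable"
        )

    lesions: list[Lesion] = []
    first_frameshift_pos: int | None = None
    offset = 0
    for ref_pos, length in frame.indel_runs():
        if length % 3 != 0:
            kind: LesionKind = "frameshift"
            if first_frameshift_pos is None or ref_pos < first_frameshift_pos:
                first_frameshift_pos = ref_pos
        else:
            kind = "inframe_indel"
        direction = "ins" if length > 0 else "del"
        secondary = (
            first_frameshift_pos is not None
            and ref_pos > first_frameshift_pos
        )
        lesions.append(
            Lesion(kind, ref_pos, f"{direction}{abs(length)}", secondary)
        )
        offset += length

    n_codons = frame.ref_length // 3
    # last reference codon is the reference stop; lesions are called strictly
    # before it
    for codon_idx in range(1, n_codons):
        ref_codon = ref_cds.seq[3 * codon_idx - 3 : 3 * codon_idx]
        ref_aa = translate_codon(ref_codon)
        q_aa = state_at(frame, query, 3 * codon_idx, level="aa")
        if q_aa == DELETED or q_aa == "X" or q_aa == ref_aa:
            continue
        pos = 3 * codon_idx - 2
        secondary = (
            first_frameshift_pos is not None and pos > first_frameshift_pos
        )
        if q_aa == "*":
            lesions.append(Lesion("nonsense", pos, f"{ref_aa}->*", secondary))
        else:
            lesions.append(Lesion("missense", pos, f"{ref_aa}->{q_aa}", secondary))

    lesions.sort(key=lambda l: (l.ref_pos, l.kind))
    return LesionReport(query.id, lesions)


def copy_status_counts(
    reports: Iterable[LesionReport],
    clade_labels: dict[str, str],
) -> pd.DataFrame:
    """Copy-number matrix: (sub)clade rows x {cd, nf} columns with sums.

    ``clade_labels`` maps seq_id -> subclade label; ids missing from the map
    (or labelled "novel") are counted under "unclassified".  The row layout
    mirrors the published copy-number table (A1_THCAS .. C).
    """
    rows = {k: {"cd": 0, "nf": 0} for k in SUBCLADE_ORDER}
    rows["unclassified"] = {"cd": 0, "nf": 0}
    for rep in reports:
        label = clade_labels.get(rep.seq_id, "unclassified")
        if label not in rows:
            label = "unclassified"
        col = "cd" if rep.status == "coding" else "nf"
        rows[label][col] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")[["cd", "nf"]]
    if df.loc["unclassified"].sum() == 0:
        df = df.drop(index="unclassified")
    df.loc["Sums"] = df.sum()
    df["total"] = df.sum(axis=1)
    return df


def report_to_tsv(reports: Iterable[LesionReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tkind\tref_pos\tdetail\tsecondary\tstatus\n")
        for rep in reports:
            if not rep.lesions:
                fh.write(f"{rep.seq_id}\t.\t.\t.\t.\t{rep.status}\n")
            for l in rep.lesions:
                fh.write(
                    f"{rep.seq_id}\t{l.kind}\t{l.ref_pos}\t{l.detail}\t"
                    f"{str(l.secondary).lower()}\t{rep.status}\n"
                )
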