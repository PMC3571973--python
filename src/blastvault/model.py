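"""Hierarchical, lossless in-memory model of a BLAST plain-text result set.

The object tree mirrors the structure of the report itself::

    GeneralInfo                      report header (program, database)
    QueryResult                      one per ``Query=`` block
      └── Iteration                  one per PSI-BLAST round (classic
          └── SubjectAlignment        programs get a single round 0)
              └── Hsp                one per ``Score =`` anchor

Raw text sections that carry no further structure (report header, the
one-line-summary block, the Karlin–Altschul footer, each HSP's grades
block) are retained verbatim so nothing printed by BLAST is lost.

Percentages in legacy BLAST output are *truncated*, not rounded: the
printed ``(35%)`` next to ``Identities = 168/468`` is ``floor(100*168/468)``.
Both the raw counts and the printed integer percent are stored; the floor
relation is an invariant of a well-formed model, not a substitute for
parsing what the report actually printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

from .errors import CorruptModelError

GAP = "-"

#: Programs whose reports the package understands.
KNOWN_PROGRAMS = ("BLASTP", "BLASTN", "BLASTX", "PSIBLAST")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneralInfo:
    """Report-level metadata parsed from the header block."""

    program_name: str = ""
    program_version: str = ""
    database_name: str = ""
    database_posted_date: str = ""
    database_num_sequences: Optional[int] = None
    database_num_letters: Optional[int] = None
    raw_header: str = ""


@dataclass
class HspStats:
    """The statistics printed on an HSP's Score/Identities lines.

    ``evalue_token`` keeps the e-value exactly as printed (``3e-39``,
    ``0.0``, ``e-104``) so formatting round-trips bit-exactly;
    ``evalue`` is its numeric value.  ``num_positives`` is ``None`` for
    nucleotide output, which prints no Positives clause.  ``gaps_printed``
    records whether a Gaps clause was present (reports omit it for
    gap-free HSPs); when absent ``num_gaps`` and ``gap_pct`` default to 0.
    """

    bit_score: float
    raw_score: int
    evalue: float
    evalue_token: str
    num_identities: int
    alignment_length: int
    num_positives: Optional[int] = None
    num_gaps: int = 0
    identity_pct: int = 0
    positive_pct: Optional[int] = None
    gap_pct: int = 0
    gaps_printed: bool = True


@dataclass
class Hsp:
    """One high-scoring segment pair, alignment strings included.

    Coordinates are stored exactly as printed: 1-based, inclusive, and
    possibly descending (minus-strand blastn subjects, negative blastx
    frames).  Strand/frame is explicit; coordinates are never swapped.
    """

    stats: HspStats
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    aligned_query: str
    midline: str
    aligned_subject: str
    query_frame: Optional[int] = None
    query_strand: Optional[str] = None
    subject_strand: Optional[str] = None
    raw_stats_text: str = ""


@dataclass
class SubjectAlignment:
    """All HSPs between the query and one database subject."""

    subject_id: str
    subject_description: str
    subject_length: int
    hsps: List[Hsp] = field(default_factory=list)


@dataclass
class Iteration:
    """One PSI-BLAST round; classic programs have exactly one, index 0."""

    round_index: int = 0
    converged: bool = False
    alignments: List[SubjectAlignment] = field(default_factory=list)


@dataclass
class FooterStats:
    """The Karlin–Altschul parameter block closing a query's report."""

    lambda_ungapped: Optional[float] = None
    k_ungapped: Optional[float] = None
    h_ungapped: Optional[float] = None
    lambda_gapped: Optional[float] = None
    k_gapped: Optional[float] = None
    h_gapped: Optional[float] = None
    matrix_name: Optional[str] = None
    gap_open: Optional[int] = None
    gap_extend: Optional[int] = None
    raw_footer: str = ""


@dataclass
class QueryResult:
    """Everything the report says about one queried sequence."""

    query_id: str
    query_title: str
    query_length: int
    iterations: List[Iteration] = field(default_factory=list)
    summary_text: str = ""
    footer: Optional[FooterStats] = None


@dataclass
class ResultRow:
    """One flat row of a manager table; unused columns stay ``None``."""

    query_id: str
    round_index: int
    subject_id: str
    evalue: float
    evalue_token: str
    query_length: Optional[int] = None
    align_length: Optional[int] = None
    identity_pct: Optional[float] = None
    positive_pct: Optional[float] = None
    num_gaps: Optional[int] = None


#: Table schemas and their exact header strings.
TABLE_HEADERS = {
    "EVALUE": "##query | iter | subject | e-value",
    "IDENTITY": "##query | iter | subject | Ident.%",
    "BY_QUERY": "##queryid len descr round subjectid eval align ident. Pos. gaps",
    "BY_SUBJECT": "##queryid round subjectid eval align ident. Pos. gaps",
}


@dataclass
class ResultTable:
    schema: str
    rows: List[ResultRow] = field(default_factory=list)
    header_line: Optional[str] = None
    retrieved_count: int = 0
    elapsed_seconds: float = 0.0


# ---------------------------------------------------------------------------
# derived-value operations
# ---------------------------------------------------------------------------

def compute_truncated_pct(count: int, total: int) -> int:
    """Integer percentage as legacy BLAST prints it: ``floor(100*count/total)``.

    BLAST truncates rather than rounds (69/468 prints 14%, not 15%).

    Raises
    ------
    ValueError
        If ``total`` is zero (invalid denominator) or the pair is out of
        range.
    """
    if total <= 0:
        raise ValueError("invalid denominator: total must be >= 1")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    return (100 * count) // total


def format_hsp_stats(stats: HspStats) -> Tuple[str, str]:
    """Render the two-line grades block exactly as BLAST prints it.

    Returns the ``Score = ...`` line and the ``Identities = ...`` line.
    When ``stats`` was produced by the parser, the output reproduces the
    input block byte-for-byte (the e-value token is kept verbatim).
    """
    line1 = (
        f"Score = {stats.bit_score:g} bits ({stats.raw_score}), "
        f"Expect = {stats.evalue_token}"
    )
    L = stats.alignment_length
    parts = [f"Identities = {stats.num_identities}/{L} ({stats.identity_pct}%)"]
    if stats.num_positives is not None:
        parts.append(f"Positives = {stats.num_positives}/{L} ({stats.positive_pct}%)")
    if stats.gaps_printed:
        parts.append(f"Gaps = {stats.num_gaps}/{L} ({stats.gap_pct}%)")
    return line1, ", ".join(parts)


def best_hsp(alignment: SubjectAlignment) -> Hsp:
    """The alignment's most significant HSP.

    Minimal e-value; ties broken by maximal bit score, then by printed
    order.  This is the HSP manager tables summarise a subject by.
    """
    if not alignment.hsps:
        raise CorruptModelError(
            f"alignment {alignment.subject_id!r} has no HSPs"
        )
    best = alignment.hsps[0]
    for hsp in alignment.hsps[1:]:
        if hsp.stats.evalue < best.stats.evalue or (
            hsp.stats.evalue == best.stats.evalue
            and hsp.stats.bit_score > best.stats.bit_score
        ):
            best = hsp
    return best


# ---------------------------------------------------------------------------
# invariant checking
# ---------------------------------------------------------------------------

def validate_hsp(hsp: Hsp) -> None:
    """Check one HSP's structural invariants; raise CorruptModelError if broken."""
    s = hsp.stats
    L = s.alignment_length
    if not (len(hsp.aligned_query) == len(hsp.midline) == len(hsp.aligned_subject) == L):
        raise CorruptModelError(
            f"aligned string lengths {len(hsp.aligned_query)}/{len(hsp.midline)}"
            f"/{len(hsp.aligned_subject)} != alignment_length {L}"
        )
    if s.evalue < 0 or s.bit_score < 0:
        raise CorruptModelError("negative e-value or bit score")
    if not 0 <= s.num_gaps <= L:
        raise CorruptModelError("gap count out of range")
    if s.num_positives is not None and not (
        0 <= s.num_identities <= s.num_positives <= L
    ):
        raise CorruptModelError("identities/positives counts out of order")
    if s.identity_pct != compute_truncated_pct(s.num_identities, L):
        raise CorruptModelError("identity percentage is not the truncated value")
    if s.num_positives is not None and s.positive_pct != compute_truncated_pct(
        s.num_positives, L
    ):
        raise CorruptModelError("positive percentage is not the truncated value")
    if s.gaps_printed and s.gap_pct != compute_truncated_pct(s.num_gaps, L):
        raise CorruptModelError("gap percentage is not the truncated value")
    for a, b in zip(hsp.aligned_query, hsp.aligned_subject):
        if a == GAP and b == GAP:
            raise CorruptModelError("gap in both sequences at the same column")
    # query-side span check: 1 residue per column for protein queries,
    # 3 nucleotides per aligned residue when a blastx frame was parsed
    non_gap_q = sum(1 for c in hsp.aligned_query if c != GAP)
    if non_gap_q:
        span = abs(hsp.query_end - hsp.query_start) + 1
        step = 3 if hsp.query_frame is not None else 1
        if span != step * non_gap_q:
            raise CorruptModelError(
                f"query span {span} inconsistent with {non_gap_q} residues (step {step})"
            )


def validate_result(result: QueryResult) -> None:
    """Check a QueryResult subtree; raise CorruptModelError on any violation."""
    if not result.iterations:
        raise CorruptModelError("result has no iterations")
    if result.query_length < 1:
        raise CorruptModelError("query_length < 1")
    for i, itr in enumerate(result.iterations):
        if itr.round_index != i:
            raise CorruptModelError("round indices not consecutive from 0")
        for aln in itr.alignments:
            if not aln.hsps:
                raise CorruptModelError(f"subject {aln.subject_id!r} has no HSPs")
            if aln.subject_length < 1:
                raise CorruptModelError("subject_length < 1")
            for hsp in aln.hsps:
                validate_hsp(hsp)


def validate_models(results: Iterable[QueryResult]) -> None:
    for result in results:
        validate_result(result)
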