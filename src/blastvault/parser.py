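"""Streaming parser for legacy NCBI BLAST plain-text ("pairwise") reports.

The report is consumed push-style: :func:`scan_query_blocks` walks the
stream line by line and yields one text block per ``Query=`` anchor, so
peak memory is bounded by the largest single query block, never by the
file.  Each block is then cut into sections with a handful of regular
expression anchors:

=============  ====================================================
section        anchor
=============  ====================================================
report header  program-name line (``BLASTP 2.2.26 ...``)
query          line-initial ``Query=``
round          ``Results from round N`` (PSI-BLAST)
summary        ``Sequences producing significant alignments:``
subject        line-initial ``>``
HSP            ``Score =`` line
footer         the ``Lambda   K   H`` block
=============  ====================================================

Both legacy ``(468 letters)`` and newer ``Length=468`` length
declarations are accepted; the dialect is detected once per report.

Malformed blocks raise :class:`~blastvault.errors.CorruptBlockError`.
At the report level the default policy is skip-and-diagnose — the bad
block becomes a :class:`ParseDiagnostics` warning and parsing continues —
so a truncated multi-gigabyte run still yields every intact result.
``strict=True`` aborts on the first bad block instead.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterator, List, Optional, Tuple, Union

from .errors import CorruptBlockError, NotABlastReportError
from .model import (
    GAP,
    FooterStats,
    GeneralInfo,
    Hsp,
    HspStats,
    Iteration,
    KNOWN_PROGRAMS,
    QueryResult,
    SubjectAlignment,
    compute_truncated_pct,
)

# --- section anchors -------------------------------------------------------

QUERY_RE = re.compile(r"^Query=\s*(.*)$")
ROUND_RE = re.compile(r"^Results from round\s+(\d+)\s*$")
SUBJECT_RE = re.compile(r"^>\s*(\S+)\s*(.*)$")
SCORE_RE = re.compile(
    r"^\s*Score\s*=\s*(\d+(?:\.\d+)?(?:e[+-]?\d+)?)\s+bits\s+\((\d+)\)"
    r",\s*Expect(?:\(\d+\))?\s*=\s*([^,\s]+)"
)
IDENT_RE = re.compile(r"Identities\s*=\s*(\d+)/(\d+)\s*\((\d+)%\)")
POSIT_RE = re.compile(r"Positives\s*=\s*(\d+)/(\d+)\s*\((\d+)%\)")
GAPS_RE = re.compile(r"Gaps\s*=\s*(\d+)/(\d+)\s*\((\d+)%\)")
FRAME_RE = re.compile(r"Frame\s*=\s*([+-]\d)")
STRAND_RE = re.compile(r"Strand\s*=\s*(Plus|Minus)\s*/\s*(Plus|Minus)")
LETTERS_LEN_RE = re.compile(r"^\s*\(\s*([\d,]+)\s+letters\s*\)\s*$")
KEYWORD_LEN_RE = re.compile(r"^\s*Length\s*=\s*([\d,]+)\s*$")
ALIGN_ROW_RE = re.compile(r"^(Query|Sbjct):?\s+(\d+)(\s+)([A-Za-z\-*]+)\s+(\d+)\s*$")
FOOTER_RE = re.compile(r"^Lambda\s+K\s+H\s*$")
SUMMARY_RE = re.compile(r"^Sequences producing significant alignments:")
NO_HITS_RE = re.compile(r"No hits found")
PROGRAM_RE = re.compile(
    r"^(" + "|".join(KNOWN_PROGRAMS) + r")\s+(\S+)", re.IGNORECASE
)
DB_RE = re.compile(r"^\s*Database:\s*(.+?)\s*$")
POSTED_RE = re.compile(r"Posted date:\s*(.+?)\s*$")
DB_STATS_RE = re.compile(r"([\d,]+)\s+sequences;\s*([\d,]+)\s+total letters")
FLOAT3_RE = re.compile(
    r"^\s*([\d.eE+-]+)\s+([\d.eE+-]+)\s+([\d.eE+-]+)\s*$"
)
MATRIX_RE = re.compile(r"^\s*Matrix:\s*(.+?)\s*$")
GAP_PEN_RE = re.compile(
    r"Gap Penalties:\s*Existence:\s*(\d+),\s*Extension:\s*(\d+)"
)


@dataclass
class ReportDialect:
    """Format variant detected once per report from its first query block."""

    program_family: str = "blastp"
    length_line_style: str = "letters"  # "letters" | "length_eq"


@dataclass
class ParseDiagnostics:
    """Warnings accumulated while parsing; ``truncated`` marks a cut tail."""

    warnings: List[Tuple[int, str]] = field(default_factory=list)
    truncated: bool = False

    def warn(self, line_number: int, message: str) -> None:
        self.warnings.append((line_number, message))


def _to_int(token: str) -> int:
    return int(token.replace(",", ""))


def parse_evalue_token(token: str) -> float:
    """Numeric value of an Expect token as BLAST prints it.

    Bare exponents (``e-104``) carry an implicit mantissa of 1.
    """
    tok = token.strip().rstrip(",")
    if not tok:
        raise CorruptBlockError("empty e-value token")
    if tok[0] in "eE":
        tok = "1" + tok
    try:
        value = float(tok)
    except ValueError as exc:
        raise CorruptBlockError(f"unparseable e-value token {token!r}") from exc
    if value < 0:
        raise CorruptBlockError(f"negative e-value {token!r}")
    return value


# ---------------------------------------------------------------------------
# block scanning (the push phase)
# ---------------------------------------------------------------------------

def scan_query_blocks(
    report: Union[str, IO[str]]
) -> Iterator[Tuple[str, int]]:
    """Yield ``(block_text, starting_line_number)`` per ``Query=`` anchor.

    Header text before the first anchor is attached to the first block,
    and trailing text after the last query stays with the last block, so
    the concatenation of all yielded blocks reproduces the input exactly.
    Memory is bounded by the largest single block.

    Raises NotABlastReportError if no ``Query=`` anchor exists at all.
    """
    stream = io.StringIO(report) if isinstance(report, str) else report
    buffer: List[str] = []
    block_start = 1
    seen_anchor = False
    line_no = 0
    for line_no, line in enumerate(stream, start=1):
        if QUERY_RE.match(line) and seen_anchor:
            yield "".join(buffer), block_start
            buffer = []
            block_start = line_no
        elif QUERY_RE.match(line):
            seen_anchor = True
        buffer.append(line)
    if not seen_anchor:
        raise NotABlastReportError("no 'Query=' anchor found in input")
    if buffer:
        yield "".join(buffer), block_start


# ---------------------------------------------------------------------------
# section parsers (the pull phase, per block)
# ---------------------------------------------------------------------------

def parse_stats_block(text: str) -> Tuple[HspStats, dict]:
    """Parse one grades block (Score line onward) into HspStats.

    Returns the stats plus an annotations dict with any ``frame``,
    ``query_strand`` / ``subject_strand`` parsed from Strand/Frame lines.
    A missing Gaps clause means a gap-free HSP; missing Positives means
    nucleotide output.
    """
    m = SCORE_RE.search(text)
    if not m:
        raise CorruptBlockError(f"malformed Score line in {text[:80]!r}")
    bit_score = float(m.group(1))
    raw_score = int(m.group(2))
    evalue_token = m.group(3).rstrip(",")
    evalue = parse_evalue_token(evalue_token)

    mi = IDENT_RE.search(text)
    if not mi:
        raise CorruptBlockError("missing Identities clause in grades block")
    num_identities, alignment_length = int(mi.group(1)), int(mi.group(2))
    identity_pct = int(mi.group(3))

    mp = POSIT_RE.search(text)
    num_positives = positive_pct = None
    if mp:
        if int(mp.group(2)) != alignment_length:
            raise CorruptBlockError("Positives denominator disagrees with Identities")
        num_positives, positive_pct = int(mp.group(1)), int(mp.group(3))

    mg = GAPS_RE.search(text)
    if mg:
        if int(mg.group(2)) != alignment_length:
            raise CorruptBlockError("Gaps denominator disagrees with Identities")
        num_gaps, gap_pct, gaps_printed = int(mg.group(1)), int(mg.group(3)), True
    else:
        num_gaps, gap_pct, gaps_printed = 0, 0, False

    stats = HspStats(
        bit_score=bit_score,
        raw_score=raw_score,
        evalue=evalue,
        evalue_token=evalue_token,
        num_identities=num_identities,
        alignment_length=alignment_length,
        num_positives=num_positives,
        num_gaps=num_gaps,
        identity_pct=identity_pct,
        positive_pct=positive_pct,
        gap_pct=gap_pct,
        gaps_printed=gaps_printed,
    )

    annotations: dict = {}
    mf = FRAME_RE.search(text)
    if mf:
        annotations["frame"] = int(mf.group(1))
    ms = STRAND_RE.search(text)
    if ms:
        annotations["query_strand"] = ms.group(1).lower()
        annotations["subject_strand"] = ms.group(2).lower()
    return stats, annotations


def _line_step_and_dir(start: int, end: int, non_gaps: int) -> Tuple[int, int]:
    """Residues-per-coordinate step (1 or 3) and direction (+1/-1) of a row."""
    span = abs(end - start) + 1
    if non_gaps == 0:
        return 1, 1
    if span == non_gaps:
        step = 1
    elif span == 3 * non_gaps:
        step = 3
    else:
        raise CorruptBlockError(
            f"coordinate span {span} inconsistent with {non_gaps} residues"
        )
    direction = 1 if end >= start else -1
    return step, direction


def parse_alignment_rows(text: str) -> Tuple[int, int, int, int, str, str, str]:
    """Concatenate a run of Query/midline/Sbjct triplets.

    Returns ``(query_start, query_end, subject_start, subject_end,
    aligned_query, midline, aligned_subject)``.  The midline is sliced by
    the column offset of the sequence field in its flanking Query line,
    preserving leading spaces (mismatch columns).  Segment-length or
    coordinate discontinuities raise CorruptBlockError.
    """
    lines = text.splitlines()
    aq_parts: List[str] = []
    mid_parts: List[str] = []
    as_parts: List[str] = []
    q_start = q_end = s_start = s_end = None
    i = 0
    n = len(lines)
    while i < n:
        m = ALIGN_ROW_RE.match(lines[i])
        if not m or m.group(1) != "Query":
            # only blank separators may appear between triplets; anything
            # else (a stray Sbjct row, a truncated Score line) is damage
            if lines[i].strip():
                raise CorruptBlockError(
                    f"unrecognised line inside alignment block: {lines[i]!r}"
                )
            i += 1
            continue
        seq = m.group(4)
        col = m.start(4)
        if i + 2 >= n:
            raise CorruptBlockError("truncated alignment triplet")
        mid_line = lines[i + 1]
        mid = mid_line[col : col + len(seq)]
        mid = mid.ljust(len(seq))
        ms = ALIGN_ROW_RE.match(lines[i + 2])
        if not ms or ms.group(1) != "Sbjct":
            raise CorruptBlockError("Query row not followed by Sbjct row")
        sseq = ms.group(4)
        if len(sseq) != len(seq):
            raise CorruptBlockError("triplet segment-length mismatch")

        qs, qe = int(m.group(2)), int(m.group(5))
        ss, se = int(ms.group(2)), int(ms.group(5))
        _line_step_and_dir(qs, qe, sum(1 for c in seq if c != GAP))
        _line_step_and_dir(ss, se, sum(1 for c in sseq if c != GAP))
        if q_start is None:
            q_start, s_start = qs, ss
        else:
            for prev_end, new_start, s_seq in ((q_end, qs, seq), (s_end, ss, sseq)):
                non_gaps = sum(1 for c in s_seq if c != GAP)
                if non_gaps == 0:
                    continue
                direction = 1 if new_start >= prev_end else -1
                if new_start != prev_end + direction:
                    raise CorruptBlockError(
                        f"coordinate discontinuity: {prev_end} -> {new_start}"
                    )
        q_end, s_end = qe, se
        aq_parts.append(seq)
        mid_parts.append(mid)
        as_parts.append(sseq)
        i += 3
    if q_start is None:
        raise CorruptBlockError("no alignment rows found for HSP")
    return (
        q_start,
        q_end,
        s_start,
        s_end,
        "".join(aq_parts),
        "".join(mid_parts),
        "".join(as_parts),
    )


def _parse_hsp(text: str) -> Hsp:
    """One HSP: grades block plus its Query/Sbjct triplets."""
    lines = text.splitlines()
    # the grades block runs from the Score line to the first blank line
    stats_end = len(lines)
    for j, line in enumerate(lines):
        if not line.strip():
            stats_end = j
            break
    raw_stats_text = "\n".join(lines[:stats_end])
    stats, annotations = parse_stats_block(raw_stats_text)
    qs, qe, ss, se, aq, mid, asb = parse_alignment_rows(
        "\n".join(lines[stats_end:])
    )
    if len(aq) != stats.alignment_length:
        raise CorruptBlockError(
            f"alignment strings have length {len(aq)}, "
            f"grades declare {stats.alignment_length}"
        )
    return Hsp(
        stats=stats,
        query_start=qs,
        query_end=qe,
        subject_start=ss,
        subject_end=se,
        aligned_query=aq,
        midline=mid,
        aligned_subject=asb,
        query_frame=annotations.get("frame"),
        query_strand=annotations.get("query_strand"),
        subject_strand=annotations.get("subject_strand"),
        raw_stats_text=raw_stats_text,
    )


def parse_subject_block(text: str) -> SubjectAlignment:
    """One ``>`` subject block: id, wrapped description, length, HSPs."""
    lines = text.splitlines()
    m = SUBJECT_RE.match(lines[0])
    if not m:
        raise CorruptBlockError("subject block does not start with '>'")
    subject_id = m.group(1)
    desc_parts = [m.group(2).strip()] if m.group(2).strip() else []
    subject_length = None
    body_start = len(lines)
    for j, line in enumerate(lines[1:], start=1):
        ml = KEYWORD_LEN_RE.match(line)
        if ml:
            subject_length = _to_int(ml.group(1))
            body_start = j + 1
            break
        if line.strip():
            desc_parts.append(line.strip())
    if subject_length is None:
        raise CorruptBlockError(
            f"subject {subject_id!r} has no Length declaration"
        )
    description = " ".join(desc_parts)

    # split the remainder at Score anchors
    body = lines[body_start:]
    anchors = [j for j, line in enumerate(body) if SCORE_RE.match(line)]
    if not anchors:
        raise CorruptBlockError(f"subject {subject_id!r} has no HSP")
    if any(line.strip() for line in body[: anchors[0]]):
        raise CorruptBlockError(
            f"unrecognised text before first HSP of subject {subject_id!r}"
        )
    hsps = []
    for k, a in enumerate(anchors):
        end = anchors[k + 1] if k + 1 < len(anchors) else len(body)
        hsps.append(_parse_hsp("\n".join(body[a:end])))
    return SubjectAlignment(
        subject_id=subject_id,
        subject_description=description,
        subject_length=subject_length,
        hsps=hsps,
    )


def _strip_blank_edges(lines: List[str]) -> List[str]:
    start, end = 0, len(lines)
    while start < end and not lines[start].strip():
        start += 1
    while end > start and not lines[end - 1].strip():
        end -= 1
    return lines[start:end]


def _parse_footer(lines: List[str]) -> FooterStats:
    footer = FooterStats(raw_footer="\n".join(_strip_blank_edges(lines)))
    triples: List[Tuple[float, float, float]] = []
    expect_values = False
    for line in lines:
        if FOOTER_RE.match(line):
            expect_values = True
            continue
        if expect_values:
            mv = FLOAT3_RE.match(line)
            if mv:
                triples.append(tuple(float(g) for g in mv.groups()))
            expect_values = False
        mm = MATRIX_RE.match(line)
        if mm and not mm.group(1).startswith("="):
            footer.matrix_name = mm.group(1)
        mg = GAP_PEN_RE.search(line)
        if mg:
            footer.gap_open, footer.gap_extend = int(mg.group(1)), int(mg.group(2))
    if triples:
        footer.lambda_ungapped, footer.k_ungapped, footer.h_ungapped = triples[0]
    if len(triples) > 1:
        footer.lambda_gapped, footer.k_gapped, footer.h_gapped = triples[1]
    return footer


def _parse_iteration_body(
    body: List[str], round_index: int, result: QueryResult
) -> Iteration:
    """Subjects (and optionally the summary block) of one round."""
    iteration = Iteration(round_index=round_index)
    # one-line summaries: from the summary header to the first blank line
    for j, line in enumerate(body):
        if SUMMARY_RE.match(line):
            k = j
            while k < len(body) and body[k].strip():
                k += 1
            if not result.summary_text:
                result.summary_text = "\n".join(body[j:k])
            break
    if any("CONVERGED!" in line for line in body):
        iteration.converged = True
        body = [line for line in body if "CONVERGED!" not in line]
    anchors = [j for j, line in enumerate(body) if SUBJECT_RE.match(line)]
    for k, a in enumerate(anchors):
        end = anchors[k + 1] if k + 1 < len(anchors) else len(body)
        iteration.alignments.append(
            parse_subject_block("\n".join(body[a:end]))
        )
    return iteration


def parse_query_block(
    block: str, start_line: int = 1, dialect: Optional[ReportDialect] = None
) -> QueryResult:
    """Parse one ``Query=`` block into a QueryResult.

    Raises CorruptBlockError if the block lacks a length declaration or
    contains a malformed subject/HSP section.
    """
    lines = block.splitlines()
    qi = next((j for j, line in enumerate(lines) if QUERY_RE.match(line)), None)
    if qi is None:
        raise CorruptBlockError("block has no Query= anchor", start_line)
    title_parts = [QUERY_RE.match(lines[qi]).group(1).strip()]
    query_length = None
    j = qi + 1
    while j < len(lines):
        line = lines[j]
        ml = LETTERS_LEN_RE.match(line) or KEYWORD_LEN_RE.match(line)
        if ml:
            query_length = _to_int(ml.group(1))
            j += 1
            break
        if SUBJECT_RE.match(line) or ROUND_RE.match(line) or SUMMARY_RE.match(line):
            break
        if line.strip():
            title_parts.append(line.strip())
        j += 1
    if query_length is None:
        raise CorruptBlockError(
            f"query block at line {start_line} has no length declaration",
            start_line,
        )
    query_title = " ".join(p for p in title_parts if p)
    if not query_title:
        raise CorruptBlockError("empty query title", start_line)
    result = QueryResult(
        query_id=query_title.split()[0],
        query_title=query_title,
        query_length=query_length,
    )

    body = lines[j:]
    # cut the Karlin–Altschul footer off the tail first
    fi = next((k for k, line in enumerate(body) if FOOTER_RE.match(line)), None)
    if fi is not None:
        result.footer = _parse_footer(body[fi:])
        body = body[:fi]

    round_marks = [
        (k, int(ROUND_RE.match(line).group(1)))
        for k, line in enumerate(body)
        if ROUND_RE.match(line)
    ]
    if not round_marks:
        result.iterations.append(_parse_iteration_body(body, 0, result))
    else:
        for k, (pos, printed_round) in enumerate(round_marks):
            end = round_marks[k + 1][0] if k + 1 < len(round_marks) else len(body)
            result.iterations.append(
                _parse_iteration_body(body[pos + 1 : end], printed_round - 1, result)
            )
    return result


# ---------------------------------------------------------------------------
# whole-report driver
# ---------------------------------------------------------------------------

def _parse_header(header_text: str) -> Tuple[GeneralInfo, ReportDialect]:
    info = GeneralInfo(raw_header="\n".join(_strip_blank_edges(header_text.splitlines())))
    dialect = ReportDialect()
    for line in header_text.splitlines():
        mp = PROGRAM_RE.match(line)
        if mp and not info.program_name:
            info.program_name = mp.group(1).upper()
            info.program_version = mp.group(2)
            dialect.program_family = info.program_name.lower()
        md = DB_RE.match(line)
        if md and not info.database_name:
            info.database_name = md.group(1)
        mpd = POSTED_RE.search(line)
        if mpd and not info.database_posted_date:
            info.database_posted_date = mpd.group(1)
        mst = DB_STATS_RE.search(line)
        if mst and info.database_num_sequences is None:
            info.database_num_sequences = _to_int(mst.group(1))
            info.database_num_letters = _to_int(mst.group(2))
    return info, dialect


def parse_report(
    report: Union[str, IO[str]], strict: bool = False
) -> Tuple[GeneralInfo, Iterator[QueryResult], ParseDiagnostics]:
    """Parse a whole report into ``(info, results, diagnostics)``.

    ``results`` is lazy: blocks are parsed as the iterator advances, so a
    report larger than memory streams through.  ``diagnostics`` is filled
    in while iterating; a block that fails to parse is recorded there and
    skipped (or re-raised if ``strict``).  A failure in the final block
    also sets ``diagnostics.truncated``.
    """
    blocks = scan_query_blocks(report)
    try:
        first_block, first_line = next(blocks)
    except StopIteration:  # scan raises NotABlastReportError before this
        raise NotABlastReportError("empty input")

    anchor = next(
        j for j, line in enumerate(first_block.splitlines(keepends=True))
        if QUERY_RE.match(line)
    )
    header_lines = first_block.splitlines(keepends=True)[:anchor]
    info, dialect = _parse_header("".join(header_lines))
    first_query_text = "".join(first_block.splitlines(keepends=True)[anchor:])
    if LETTERS_LEN_RE.search(first_query_text):
        dialect.length_line_style = "letters"
    elif re.search(r"^Length=", first_query_text, re.MULTILINE):
        dialect.length_line_style = "length_eq"

    diagnostics = ParseDiagnostics()

    def results() -> Iterator[QueryResult]:
        pending: Optional[Tuple[str, int]] = (first_query_text, first_line + anchor)
        source = blocks
        last_failed = False
        while True:
            if pending is not None:
                block_text, line_no = pending
                pending = None
            else:
                try:
                    block_text, line_no = next(source)
                except StopIteration:
                    break
            try:
                yield parse_query_block(block_text, line_no, dialect)
                last_failed = False
            except CorruptBlockError as exc:
                if strict:
                    raise
                diagnostics.warn(
                    exc.line_number or line_no, f"skipped corrupt block: {exc}"
                )
                last_failed = True
        if last_failed:
            diagnostics.truncated = True

    return info, results(), diagnostics
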