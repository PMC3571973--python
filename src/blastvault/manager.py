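"""SQL-like select/filter/sort layer over a store, with flat-table export.

Five operations mirror what a practitioner asks of a BLAST run: the two
threshold filters (e-value below, identity percent above), a per-query
identity sort, and direct lookups by query id or subject id.  Each yields
a :class:`~blastvault.model.ResultTable` of one row per
(query, iteration, subject), summarising the subject by its best HSP
(minimal e-value, ties to the higher bit score).  Filters use *strict*
inequalities; a subject exactly at the threshold is excluded.

``per_hsp=True`` switches any operation to one row per HSP instead of
one per subject; the default matches the single-row-per-subject display.
"""

from __future__ import annotations

import sys
import time
from typing import IO, Iterator, List, Optional, Tuple, Union

from .errors import InvalidThresholdError
from .model import (
    Hsp,
    QueryResult,
    ResultRow,
    ResultTable,
    SubjectAlignment,
    TABLE_HEADERS,
    best_hsp,
)
from .storage import StorageHandle


def _walk(
    results: Iterator[QueryResult], per_hsp: bool
) -> Iterator[Tuple[QueryResult, int, SubjectAlignment, Hsp]]:
    """Flatten a result stream into (query, round, subject, hsp) rows."""
    for result in results:
        for iteration in result.iterations:
            for alignment in iteration.alignments:
                if per_hsp:
                    for hsp in alignment.hsps:
                        yield result, iteration.round_index, alignment, hsp
                else:
                    yield result, iteration.round_index, alignment, best_hsp(alignment)


def _make_row(
    result: QueryResult, round_index: int, alignment: SubjectAlignment, hsp: Hsp
) -> ResultRow:
    s = hsp.stats
    return ResultRow(
        query_id=result.query_id,
        round_index=round_index,
        subject_id=alignment.subject_id,
        evalue=s.evalue,
        evalue_token=s.evalue_token,
        query_length=result.query_length,
        align_length=s.alignment_length,
        identity_pct=float(s.identity_pct),
        positive_pct=None if s.positive_pct is None else float(s.positive_pct),
        num_gaps=s.num_gaps,
    )


def _finish(
    schema: str, rows: List[ResultRow], with_header: bool, started: float
) -> ResultTable:
    return ResultTable(
        schema=schema,
        rows=rows,
        header_line=TABLE_HEADERS[schema] if with_header else None,
        retrieved_count=len(rows),
        elapsed_seconds=time.perf_counter() - started,
    )


def select_where_evalue_lower_than(
    handle: StorageHandle,
    threshold: float,
    with_header: bool = False,
    per_hsp: bool = False,
) -> ResultTable:
    """Rows whose best-HSP e-value is strictly below ``threshold``."""
    if threshold < 0:
        raise InvalidThresholdError("e-value threshold must be >= 0")
    started = time.perf_counter()
    rows = [
        _make_row(res, rnd, aln, hsp)
        for res, rnd, aln, hsp in _walk(handle.iter_results(), per_hsp)
        if hsp.stats.evalue < threshold
    ]
    return _finish("EVALUE", rows, with_header, started)


def select_where_identity_pct_higher_than(
    handle: StorageHandle,
    threshold: float,
    with_header: bool = False,
    per_hsp: bool = False,
) -> ResultTable:
    """Rows whose best-HSP identity percentage is strictly above ``threshold``."""
    if not 0 <= threshold <= 100:
        raise InvalidThresholdError(
            f"identity threshold {threshold!r} outside [0, 100]"
        )
    started = time.perf_counter()
    rows = [
        _make_row(res, rnd, aln, hsp)
        for res, rnd, aln, hsp in _walk(handle.iter_results(), per_hsp)
        if hsp.stats.identity_pct > threshold
    ]
    return _finish("IDENTITY", rows, with_header, started)


def sort_by_identity_pct(
    handle: StorageHandle, with_header: bool = False, per_hsp: bool = False
) -> ResultTable:
    """All rows; queries stay in stored order, rows within each query are
    sorted by identity percent descending (ties: ascending e-value, then
    original subject order — the sort is stable)."""
    started = time.perf_counter()
    rows: List[ResultRow] = []
    for result in handle.iter_results():
        query_rows = [
            _make_row(res, rnd, aln, hsp)
            for res, rnd, aln, hsp in _walk(iter([result]), per_hsp)
        ]
        query_rows.sort(key=lambda r: (-r.identity_pct, r.evalue))
        rows.extend(query_rows)
    return _finish("IDENTITY", rows, with_header, started)


def select_by_query_id(
    handle: StorageHandle,
    query_id: str,
    with_header: bool = False,
    per_hsp: bool = False,
) -> ResultTable:
    """Every (round, subject) row of one query, by direct keyed access.

    Raises MissingQueryError for an unknown id.
    """
    started = time.perf_counter()
    result = handle.get_result(query_id)
    rows = [
        _make_row(res, rnd, aln, hsp)
        for res, rnd, aln, hsp in _walk(iter([result]), per_hsp)
    ]
    return _finish("BY_QUERY", rows, with_header, started)


def select_by_subject_id(
    handle: StorageHandle,
    subject_id: str,
    with_header: bool = False,
    per_hsp: bool = False,
) -> ResultTable:
    """Rows from every query whose alignments include ``subject_id``.

    An absent subject yields an empty table, not an error.
    """
    started = time.perf_counter()
    rows = [
        _make_row(res, rnd, aln, hsp)
        for res, rnd, aln, hsp in _walk(handle.iter_results(), per_hsp)
        if aln.subject_id == subject_id
    ]
    return _finish("BY_SUBJECT", rows, with_header, started)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _fmt_pct(value: Optional[float]) -> str:
    return "" if value is None else f"{value:.1f}"


def format_row(row: ResultRow, schema: str) -> str:
    """One tab-separated output line in the schema's column order.

    The ``descr`` column of BY_QUERY and an absent Positives percent
    (nucleotide output) print as empty fields.
    """
    if schema == "EVALUE":
        fields = [row.query_id, str(row.round_index), row.subject_id, row.evalue_token]
    elif schema == "IDENTITY":
        fields = [
            row.query_id,
            str(row.round_index),
            row.subject_id,
            _fmt_pct(row.identity_pct),
        ]
    elif schema == "BY_QUERY":
        fields = [
            row.query_id,
            str(row.query_length),
            "",  # descr
            str(row.round_index),
            row.subject_id,
            row.evalue_token,
            str(row.align_length),
            _fmt_pct(row.identity_pct),
            _fmt_pct(row.positive_pct),
            str(row.num_gaps),
        ]
    elif schema == "BY_SUBJECT":
        fields = [
            row.query_id,
            str(row.round_index),
            row.subject_id,
            row.evalue_token,
            str(row.align_length),
            _fmt_pct(row.identity_pct),
            _fmt_pct(row.positive_pct),
            str(row.num_gaps),
        ]
    else:
        raise ValueError(f"unknown table schema {schema!r}")
    return "\t".join(fields)


def render_table(table: ResultTable) -> str:
    """The full export text: optional header, rows, retrieved-count trailer."""
    lines: List[str] = []
    if table.header_line is not None:
        lines.append(table.header_line)
    for row in table.rows:
        lines.append(format_row(row, table.schema))
    lines.append(
        f"retrieved {table.retrieved_count} results; "
        f"query time: {table.elapsed_seconds} seconds"
    )
    return "\n".join(lines) + "\n"


def export_table(
    table: ResultTable, destination: Union[None, str, IO[str]] = None
) -> None:
    """Write a table to standard output (default), a path, or a stream."""
    text = render_table(table)
    if destination is None:
        sys.stdout.write(text)
    elif isinstance(destination, str):
        with open(destination, "w") as fh:
            fh.write(text)
    else:
        destination.write(text)
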