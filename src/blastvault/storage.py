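"""Single-file keyed store for parsed BLAST results.

A store is one SQLite file holding one pickled record per query id plus a
metadata record (format-version tag, :class:`~blastvault.model.GeneralInfo`,
the query order as it appeared in the report, and the parse diagnostics).
Once built, any single result is retrieved by key without scanning the
rest of the file and without ever touching the original report again.

The file layout is private; compatibility across package versions is
promised only through the format-version tag, which is checked on open.
"""

from __future__ import annotations

import os
import pickle
import sqlite3
from typing import Iterator, List, Optional, Tuple, Union

from .errors import (
    ClosedStoreError,
    IncompatibleStoreError,
    MissingQueryError,
    NotABlastReportError,
    StorageIOError,
)
from .model import GeneralInfo, QueryResult
from .parser import ParseDiagnostics, parse_report

FORMAT_TAG = "blastvault-store"
FORMAT_VERSION = 1
_PROTO = pickle.HIGHEST_PROTOCOL

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, payload BLOB NOT NULL);
CREATE TABLE records (
    query_id TEXT PRIMARY KEY,
    ord      INTEGER NOT NULL,
    payload  BLOB NOT NULL
);
"""


class StorageHandle:
    """Handle over one store file.

    ``mode`` is ``building`` while a report is being ingested, ``reading``
    afterwards/on open, and ``closed`` after :meth:`close`.  The handle
    counts payload reads in :attr:`records_read` so access patterns are
    observable (random access must not degenerate into a full scan).
    """

    def __init__(self, db_path: str, conn: sqlite3.Connection, mode: str):
        self.db_path = db_path
        self._conn: Optional[sqlite3.Connection] = conn
        self.mode = mode
        self.query_order: List[str] = []
        self._general_info: Optional[GeneralInfo] = None
        self.records_read = 0

    # -- lifecycle ---------------------------------------------------------

    def _require_open(self) -> sqlite3.Connection:
        if self.mode == "closed" or self._conn is None:
            raise ClosedStoreError(f"store {self.db_path!r} is closed")
        return self._conn

    def close(self) -> None:
        """Flush and close; idempotent."""
        if self._conn is not None:
            self._conn.commit()
            self._conn.close()
            self._conn = None
        self.mode = "closed"

    def __enter__(self) -> "StorageHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- reads -------------------------------------------------------------

    def get_result(self, query_id: str) -> QueryResult:
        conn = self._require_open()
        row = conn.execute(
            "SELECT payload FROM records WHERE query_id = ?", (query_id,)
        ).fetchone()
        if row is None:
            raise MissingQueryError(f"no result stored for query id {query_id!r}")
        self.records_read += 1
        return pickle.loads(row[0])

    def iter_results(self) -> Iterator[QueryResult]:
        self._require_open()
        for query_id in list(self.query_order):
            yield self.get_result(query_id)

    def __iter__(self) -> Iterator[QueryResult]:
        return self.iter_results()

    def general_info(self) -> GeneralInfo:
        self._require_open()
        assert self._general_info is not None
        return self._general_info

    def list_query_ids(self) -> List[str]:
        self._require_open()
        return list(self.query_order)

    def __len__(self) -> int:
        return len(self.query_order)


def _write_meta(conn: sqlite3.Connection, key: str, value) -> None:
    conn.execute(
        "INSERT OR REPLACE INTO meta (key, payload) VALUES (?, ?)",
        (key, pickle.dumps(value, _PROTO)),
    )


def _read_meta(conn: sqlite3.Connection, key: str):
    row = conn.execute("SELECT payload FROM meta WHERE key = ?", (key,)).fetchone()
    return None if row is None else pickle.loads(row[0])


def build_store(
    db_path: Union[str, os.PathLike],
    report: Union[str, os.PathLike],
    strict: bool = False,
) -> Tuple[StorageHandle, ParseDiagnostics]:
    """Parse ``report`` (a path or readable stream) into a new store file.

    Results stream straight from the parser into the database, one record
    per query id; a duplicate id overwrites the earlier record (with a
    diagnostic) while keeping its original position in the query order.
    The returned handle is already readable.
    """
    db_path = os.fspath(db_path)
    if not db_path:
        raise StorageIOError("empty store path")
    if os.path.exists(db_path):
        os.remove(db_path)
    try:
        conn = sqlite3.connect(db_path)
        conn.executescript(_SCHEMA)
    except sqlite3.Error as exc:
        raise StorageIOError(f"cannot create store at {db_path!r}: {exc}") from exc

    close_stream = False
    if isinstance(report, (str, os.PathLike)) and "\n" not in str(report):
        try:
            stream = open(report, "r")
        except OSError as exc:
            conn.close()
            os.remove(db_path)
            raise StorageIOError(f"cannot read report {report!r}: {exc}") from exc
        close_stream = True
    else:
        import io

        stream = io.StringIO(report) if isinstance(report, str) else report

    handle = StorageHandle(db_path, conn, mode="building")
    try:
        info, results, diagnostics = parse_report(stream, strict=strict)
        position: dict = {}
        order: List[str] = []
        for result in results:
            qid = result.query_id
            if qid in position:
                diagnostics.warn(
                    0, f"duplicate query id {qid!r}: later record replaces earlier"
                )
            else:
                position[qid] = len(order)
                order.append(qid)
            conn.execute(
                "INSERT OR REPLACE INTO records (query_id, ord, payload) "
                "VALUES (?, ?, ?)",
                (qid, position[qid], pickle.dumps(result, _PROTO)),
            )
        _write_meta(conn, "format", (FORMAT_TAG, FORMAT_VERSION))
        _write_meta(conn, "general_info", info)
        _write_meta(conn, "query_order", order)
        _write_meta(conn, "diagnostics", diagnostics)
        conn.commit()
    except Exception:
        conn.close()
        if os.path.exists(db_path):
            os.remove(db_path)
        raise
    finally:
        if close_stream:
            stream.close()

    handle.mode = "reading"
    handle.query_order = order
    handle._general_info = info
    return handle, diagnostics


def open_store(db_path: Union[str, os.PathLike]) -> StorageHandle:
    """Open an existing store for reading; the original report is not needed.

    Raises StorageIOError for a missing file and IncompatibleStoreError
    for anything that is not a store with a supported format tag.
    """
    db_path = os.fspath(db_path)
    if not os.path.exists(db_path):
        raise StorageIOError(f"no such store file: {db_path!r}")
    conn = sqlite3.connect(db_path)
    try:
        tag = _read_meta(conn, "format")
    except (sqlite3.Error, pickle.UnpicklingError) as exc:
        conn.close()
        raise IncompatibleStoreError(
            f"{db_path!r} is not a blastvault store: {exc}"
        ) from exc
    if tag is None or tuple(tag) != (FORMAT_TAG, FORMAT_VERSION):
        conn.close()
        raise IncompatibleStoreError(
            f"{db_path!r} has format tag {tag!r}, "
            f"expected {(FORMAT_TAG, FORMAT_VERSION)!r}"
        )
    handle = StorageHandle(db_path, conn, mode="reading")
    handle.query_order = _read_meta(conn, "query_order") or []
    handle._general_info = _read_meta(conn, "general_info")
    return handle


# thin functional aliases matching the handle methods
def get_result(handle: StorageHandle, query_id: str) -> QueryResult:
    return handle.get_result(query_id)


def iter_results(handle: StorageHandle) -> Iterator[QueryResult]:
    return handle.iter_results()


def get_general_info(handle: StorageHandle) -> GeneralInfo:
    return handle.general_info()


def list_query_ids(handle: StorageHandle) -> List[str]:
    return handle.list_query_ids()


def get_diagnostics(handle: StorageHandle) -> Optional[ParseDiagnostics]:
    conn = handle._require_open()
    return _read_meta(conn, "diagnostics")


def close_store(handle: StorageHandle) -> None:
    handle.close()
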