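"""Manager queries against an independent brute-force oracle, strict
inequality boundaries, and bit-stable export."""

import io

import pytest

from blastvault.errors import InvalidThresholdError, MissingQueryError
from blastvault.fixtures import GeneratorSpec, generate_report, render_report
from blastvault.manager import (
    export_table,
    render_table,
    select_by_query_id,
    select_by_subject_id,
    select_where_evalue_lower_than,
    select_where_identity_pct_higher_than,
    sort_by_identity_pct,
)
from blastvault.model import TABLE_HEADERS
from blastvault.storage import build_store


def oracle_rows(results, per_hsp=False):
    """Independent flattening: (query_id, round, subject_id, hsp) tuples,
    choosing the best HSP by explicit pairwise comparison."""
    flat = []
    for result in results:
        for iteration in result.iterations:
            for aln in iteration.alignments:
                if per_hsp:
                    chosen = list(aln.hsps)
                else:
                    best = aln.hsps[0]
                    for hsp in aln.hsps[1:]:
                        if hsp.stats.evalue < best.stats.evalue:
                            best = hsp
                        elif (hsp.stats.evalue == best.stats.evalue
                              and hsp.stats.bit_score > best.stats.bit_score):
                            best = hsp
                    chosen = [best]
                for hsp in chosen:
                    flat.append(
                        (result.query_id, iteration.round_index,
                         aln.subject_id, hsp)
                    )
    return flat


@pytest.fixture(scope="module")
def oracle_store(tmp_path_factory):
    """A psiblast store with multiple rounds and multi-HSP subjects."""
    spec = GeneratorSpec(
        seed=77, num_queries=40, program_family="psiblast",
        rounds_per_query=2, subjects_per_query=(1, 4), hsps_per_subject=(2, 4),
        planted_subject_ids=["PLANTED_SUBJECT_1"],
    )
    _, results, text = generate_report(spec)
    db = tmp_path_factory.mktemp("mgr") / "oracle.db"
    handle, _ = build_store(str(db), text)
    yield handle, results
    handle.close()


class TestFilters:
    def test_evalue_filter_agrees_with_brute_force(self, oracle_store):
        handle, results = oracle_store
        for threshold in (1e-100, 1e-40, 1e-3, 5.0):
            table = select_where_evalue_lower_than(handle, threshold)
            expected = [
                (q, r, s) for q, r, s, h in oracle_rows(results)
                if h.stats.evalue < threshold
            ]
            assert [(r.query_id, r.round_index, r.subject_id)
                    for r in table.rows] == expected
            assert table.retrieved_count == len(table.rows)

    def test_evalue_boundary_is_strict(self, oracle_store):
        handle, results = oracle_store
        evalues = sorted({h.stats.evalue for *_, h in oracle_rows(results)})
        boundary = evalues[len(evalues) // 2]
        table = select_where_evalue_lower_than(handle, boundary)
        assert all(r.evalue < boundary for r in table.rows)
        assert not any(r.evalue == boundary for r in table.rows)

    def test_evalue_zero_threshold_empty(self, oracle_store):
        handle, _ = oracle_store
        assert select_where_evalue_lower_than(handle, 0.0).rows == []

    def test_identity_filter_agrees_with_brute_force(self, oracle_store):
        handle, results = oracle_store
        for threshold in (0, 35, 50, 80):
            table = select_where_identity_pct_higher_than(handle, threshold)
            expected = [
                (q, r, s) for q, r, s, h in oracle_rows(results)
                if h.stats.identity_pct > threshold
            ]
            assert [(r.query_id, r.round_index, r.subject_id)
                    for r in table.rows] == expected

    def test_identity_boundary_strict_and_range_checked(self, oracle_store):
        handle, results = oracle_store
        pcts = sorted({h.stats.identity_pct for *_, h in oracle_rows(results)})
        boundary = pcts[len(pcts) // 2]
        table = select_where_identity_pct_higher_than(handle, boundary)
        assert all(r.identity_pct > boundary for r in table.rows)
        assert select_where_identity_pct_higher_than(handle, 100).rows == []
        with pytest.raises(InvalidThresholdError):
            select_where_identity_pct_higher_than(handle, 101)
        with pytest.raises(InvalidThresholdError):
            select_where_identity_pct_higher_than(handle, -1)

    def test_per_hsp_rows(self, oracle_store):
        handle, results = oracle_store
        table = select_where_evalue_lower_than(handle, 1e9, per_hsp=True)
        assert len(table.rows) == len(oracle_rows(results, per_hsp=True))


class TestSort:
    def test_per_query_descending_runs(self, oracle_store):
        handle, results = oracle_store
        table = sort_by_identity_pct(handle)
        # queries appear contiguously, in stored order
        seen_order = []
        for row in table.rows:
            if not seen_order or seen_order[-1] != row.query_id:
                seen_order.append(row.query_id)
        assert seen_order == [r.query_id for r in results]
        # within each query the percentages never increase
        by_query = {}
        for row in table.rows:
            by_query.setdefault(row.query_id, []).append(row)
        for rows in by_query.values():
            pcts = [r.identity_pct for r in rows]
            assert pcts == sorted(pcts, reverse=True)
            for a, b in zip(rows, rows[1:]):
                if a.identity_pct == b.identity_pct:
                    assert a.evalue <= b.evalue

    def test_all_equal_percentages_keep_subject_order(self, tmp_path):
        spec = GeneratorSpec(seed=12, num_queries=1, subjects_per_query=(4, 4),
                             identity_rate=1.0, gap_rate=0.0,
                             hsps_per_subject=(1, 1))
        _, results, text = generate_report(spec)
        handle, _ = build_store(str(tmp_path / "eq.db"), text)
        table = sort_by_identity_pct(handle)
        assert all(r.identity_pct == 100.0 for r in table.rows)
        in_order = [a.subject_id for a in results[0].iterations[0].alignments]
        by_evalue = sorted(
            range(len(in_order)),
            key=lambda i: results[0].iterations[0].alignments[i].hsps[0].stats.evalue,
        )
        assert [r.subject_id for r in table.rows] == [in_order[i] for i in by_evalue]
        handle.close()


class TestLookups:
    def test_by_query_id_matches_best_hsp_fields(self, oracle_store):
        handle, results = oracle_store
        target = results[5]
        table = select_by_query_id(handle, target.query_id, with_header=True)
        expected = [t for t in oracle_rows([target])]
        assert len(table.rows) == len(expected)
        for row, (q, rnd, sid, hsp) in zip(table.rows, expected):
            assert row.query_id == q and row.subject_id == sid
            assert row.round_index == rnd
            assert row.query_length == target.query_length
            assert row.align_length == hsp.stats.alignment_length
            assert row.identity_pct == float(hsp.stats.identity_pct)
            assert row.positive_pct == float(hsp.stats.positive_pct)
            assert row.num_gaps == hsp.stats.num_gaps
            assert row.evalue_token == hsp.stats.evalue_token

    def test_by_query_unknown_id_raises(self, oracle_store):
        handle, _ = oracle_store
        with pytest.raises(MissingQueryError):
            select_by_query_id(handle, "nope")

    def test_by_subject_planted_and_absent(self, oracle_store):
        handle, results = oracle_store
        table = select_by_subject_id(handle, "PLANTED_SUBJECT_1")
        assert table.retrieved_count == 1
        assert table.rows[0].subject_id == "PLANTED_SUBJECT_1"
        empty = select_by_subject_id(handle, "NEVER_SEEN")
        assert empty.rows == [] and empty.retrieved_count == 0


class TestExport:
    def test_header_strings_are_exact(self, oracle_store):
        handle, _ = oracle_store
        assert (
            select_where_evalue_lower_than(handle, 1, with_header=True).header_line
            == "##query | iter | subject | e-value"
        )
        assert (
            select_where_identity_pct_higher_than(handle, 1, with_header=True).header_line
            == "##query | iter | subject | Ident.%"
        )
        assert (
            select_by_query_id(handle, handle.list_query_ids()[0],
                               with_header=True).header_line
            == "##queryid len descr round subjectid eval align ident. Pos. gaps"
        )
        assert (
            select_by_subject_id(handle, "x", with_header=True).header_line
            == "##queryid round subjectid eval align ident. Pos. gaps"
        )
        assert set(TABLE_HEADERS) == {"EVALUE", "IDENTITY", "BY_QUERY", "BY_SUBJECT"}

    def test_golden_export_bytes(self, tmp_path, tiny_model):
        """Byte-stable output for a hand-checked table, elapsed zeroed."""
        info, results = tiny_model
        text = render_report(info, results)
        handle, _ = build_store(str(tmp_path / "tiny.db"), text)
        table = select_where_evalue_lower_than(handle, 10.0, with_header=True)
        table.elapsed_seconds = 0.0
        assert render_table(table) == (
            "##query | iter | subject | e-value\n"
            "Q0001\t0\tS1\t1e-50\n"
            "Q0001\t0\tS2\t2.1\n"
            "retrieved 2 results; query time: 0.0 seconds\n"
        )
        by_query = select_by_query_id(handle, "Q0001", with_header=True)
        by_query.elapsed_seconds = 0.0
        assert render_table(by_query) == (
            "##queryid len descr round subjectid eval align ident. Pos. gaps\n"
            "Q0001\t20\t\t0\tS1\t1e-50\t10\t100.0\t100.0\t0\n"
            "Q0001\t20\t\t0\tS2\t2.1\t10\t100.0\t100.0\t0\n"
            "retrieved 2 results; query time: 0.0 seconds\n"
        )
        handle.close()

    def test_empty_table_prints_trailer_only(self, oracle_store):
        handle, _ = oracle_store
        table = select_where_evalue_lower_than(handle, 0.0, with_header=True)
        table.elapsed_seconds = 0.0
        assert render_table(table) == (
            "##query | iter | subject | e-value\n"
            "retrieved 0 results; query time: 0.0 seconds\n"
        )

    def test_export_destinations_agree(self, oracle_store, tmp_path):
        handle, _ = oracle_store
        table = select_where_evalue_lower_than(handle, 1e-3, with_header=True)
        buf = io.StringIO()
        export_table(table, buf)
        path = tmp_path / "out.tsv"
        export_table(table, str(path))
        assert buf.getvalue() == path.read_text() == render_table(table)
        reread = path.read_text().strip().split("\n")
        assert len(reread) == table.retrieved_count + 2  # header + trailer
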