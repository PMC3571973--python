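# blastvault

Lossless parsing, single-file storage and SQL-like querying of NCBI BLAST
plain-text results.

## The problem

Large similarity-search studies (transcriptome annotation, all-against-all
ortholog screens) produce multi-query BLAST reports that run to gigabytes.
Most parsers either discard the alignment section, force a full re-parse
for every access, or require a relational database to ask simple questions
like *"which subjects does query X hit below e-value 10⁻³?"*.

`blastvault` targets the legacy plain-text "pairwise" output (the default
`-m 0` format of `blastp`, `blastn`, `blastx` and `psiblast`, versions up
to 2.2.26 and the `Length=` dialect). It:

- parses a report **without losing anything** — every high-scoring segment
  pair (HSP) keeps its bit score *S'*, raw score *S*, e-value *E*,
  identity/positive/gap counts with their printed percentages, 1-based
  coordinates, strand/frame, and the three gapped alignment strings
  (query, midline, subject); the raw header, one-line-summary and
  Karlin–Altschul footer blocks are retained verbatim;
- stores all results in **one** random-access database file keyed by query
  id, so any single result is fetched later without re-parsing the report
  (or reading the other records);
- exposes five SQL-like operations — filter by e-value, filter by identity
  percent, sort by identity percent, select by query id, select by subject
  id — that export flat tables to stdout or files.

The object hierarchy mirrors the report: one `QueryResult` per `Query=`
block, one `Iteration` per PSI-BLAST round (classic programs get a single
round 0), one `SubjectAlignment` per subject, one `Hsp` per `Score =`
anchor. A detail worth knowing: the percentages BLAST prints are
**truncated**, not rounded — `Identities = 168/468 (35%)` is
⌊100·168/468⌋, and `Gaps = 69/468 (14%)` would read 15% under rounding.
`blastvault` stores both the counts and the printed percent and enforces
the floor relation as a model invariant.

A built-in generator (`blastvault.fixtures`) produces synthetic reports
with exact ground-truth models; `parse(render(model)) == model` is the
package's central correctness oracle.

## Worked example

```sh
$ blastvault export-fixture --seed 11 --num-queries 3 --out demo.blast
wrote synthetic blastp report (3 queries) to demo.blast
$ blastvault store demo.db demo.blast
stored 3 results in demo.db
$ blastvault query demo.db --evalue-lt 0.001 --header --no-timing
##query | iter | subject | e-value
synq011_0000	0	SYN011_00001	9e-164
synq011_0000	0	SYN011_00002	6e-5
synq011_0000	0	SYN011_00003	2e-125
synq011_0000	0	SYN011_00004	3e-94
synq011_0001	0	SYN011_00005	2e-49
synq011_0001	0	SYN011_00006	6e-149
synq011_0001	0	SYN011_00007	4e-23
synq011_0002	0	SYN011_00008	5e-178
synq011_0002	0	SYN011_00010	3e-138
retrieved 9 results; query time: 0.0 seconds
```

Each row is one (query, round, subject) whose **best HSP** (minimal
e-value, ties to the higher bit score) passes the strict `< 0.001` filter;
the trailer counts the retrieved rows. Round is 0 throughout because
blastp has a single implicit iteration. Direct access to one query prints
the full per-subject statistics:

```sh
$ blastvault query demo.db --query-id synq011_0000 --header --no-timing
##queryid len descr round subjectid eval align ident. Pos. gaps
synq011_0000	126		0	SYN011_00001	9e-164	109	49.0	75.0	8
synq011_0000	126		0	SYN011_00002	6e-5	97	54.0	78.0	2
synq011_0000	126		0	SYN011_00003	2e-125	71	49.0	73.0	3
synq011_0000	126		0	SYN011_00004	3e-94	97	47.0	81.0	9
retrieved 4 results; query time: 0.0 seconds
```

(`len` is the query length, `align` the HSP alignment length, `ident.` /
`Pos.` the truncated identity/positive percentages, `gaps` the gap count;
`--no-timing` zeroes the elapsed seconds so output is byte-stable.)

The same session in Python:

```python
from blastvault import build_store, open_store, manager

handle, diagnostics = build_store("demo.db", "demo.blast")
handle.close()

handle = open_store("demo.db")            # report file no longer needed
result = handle.get_result("synq011_0000")     # one keyed read
hsp = result.iterations[0].alignments[0].hsps[0]
print(hsp.aligned_query)                  # alignments are retained
table = manager.select_where_identity_pct_higher_than(handle, 50, with_header=True)
manager.export_table(table)
handle.close()
```

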