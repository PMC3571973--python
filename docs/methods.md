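# Methods

## Scope and data model

`blastvault` handles the legacy NCBI BLAST plain-text "pairwise" report
(the default, non-tabular, non-XML output) for blastp, blastn, blastx and
psiblast, including the newer `Length=N` length-declaration dialect
alongside the classic `(N letters)` form. tblastn/tblastx, BLAST XML,
tabular (`-m 8/9`) and archive formats are out of scope, as is any
recomputation of alignment statistics: bit scores, e-values and counts are
parsed, never recalculated.

The in-memory model is a strict hierarchy — `QueryResult` → `Iteration` →
`SubjectAlignment` → `Hsp` — chosen to mirror the report's own structure
so that losslessness is a representation property, not a parsing
afterthought. Sections that carry no further structure (report header,
one-line-summary block, Karlin–Altschul footer, each HSP's grades block)
are kept verbatim; everything else is parsed into typed fields. Classic
programs always get exactly one `Iteration` with `round_index` 0, so
downstream code never branches on program family; PSI-BLAST's printed
"Results from round N" maps to `round_index` N−1 and `CONVERGED!` sets a
flag on the round it closes.

### The truncation rule

Legacy BLAST prints integer percentages by truncation: all printed values
equal `floor(100*count/total)`, and pairs such as 69/468 (printed 14, not
15), 165/474 (34, not 35) and 79/474 (16, not 17) rule out rounding. Both
the raw counts and the printed percent are stored; `validate_hsp` enforces
the floor relation as an invariant rather than trusting either value
alone.

### Coordinates, strands, frames

Coordinates are stored exactly as printed: 1-based, inclusive, descending
for minus-strand blastn subjects and negative blastx frames. Strand and
frame are explicit fields; coordinates are never silently swapped. The
query-span invariant is `|end − start| + 1 = residues` for protein
queries and `3 × residues` when a Frame line was parsed (nucleotide
coordinates over a translated alignment); it is checked only when the
frame is known.

## Parser design

The parser is a push/pull hybrid: `scan_query_blocks` streams the input
line by line and yields one text block per `Query=` anchor, so peak
memory is bounded by the largest single block — a property the tests
verify by counting lines consumed before the first result is yielded.
Each block is then cut with a small set of regular-expression anchors
(program line, `Query=`, `Results from round`, line-initial `>`,
`Score =`, the `Lambda K H` footer).

Numeric parsing choices:

- **E-value tokens** keep their printed form (`3e-39`, `0.0`, `e-104`)
  for bit-exact re-formatting; the numeric value is derived once, with a
  bare exponent given the standard implicit mantissa of 1.
- A missing `Gaps` clause means a gap-free HSP (count 0); a missing
  `Positives` clause marks nucleotide output, where the field is absent
  rather than zero.
- The midline is sliced from its line by the column offset of the
  sequence field in the flanking `Query:` row, preserving leading spaces
  (mismatch columns) and padding trailing ones.
- Per-row coordinate checks infer the residues-per-coordinate step (1 or
  3) and direction from the row itself; discontinuities between
  consecutive rows, segment-length mismatches, and any non-blank line
  inside an alignment region that is not part of a triplet are treated as
  corruption. The last rule is what turns a report truncated mid-HSP into
  a diagnostic instead of a silently shortened alignment.

**Corruption policy.** A malformed block raises `CorruptBlockError`; the
report-level driver converts it into a `(line, message)` diagnostic and
skips to the next `Query=` anchor, so one damaged query never costs the
rest of a large run. A failure in the final block additionally sets
`diagnostics.truncated`. `strict=True` propagates the first error instead
— useful when a pipeline would rather fail fast. The skipped-block
granularity is the whole query: salvaging earlier subjects of a damaged
query was considered and rejected because a partially parsed query is
ambiguous to consumers (is a missing subject absent or lost?).

## Storage

One SQLite file holds one pickled record per query id plus a metadata
record (format-version tag, `GeneralInfo`, input-order id list, parse
diagnostics). SQLite was chosen over a dbm-backed shelf because it
guarantees the single-file contract on every platform, gives keyed
B-tree access without loading other records, and ships in the standard
library. Results stream from the parser straight into the database, so
building a store never materialises the whole report. Iteration follows
input order — the only reproducible choice. Duplicate query ids keep the
first position in the order but the later record wins, with a diagnostic.
The handle counts payload reads (`records_read`) so tests can assert that
fetching one of 1000 records reads one record, not a thousand. Opening
anything without the expected format tag raises `IncompatibleStoreError`
rather than risking a misread.

## Manager semantics

Tables have one row per (query, iteration, subject), summarising the
subject by its **best HSP** — minimal e-value, ties broken by the higher
bit score, then printed order. This matches the one-row-per-subject
display of the by-query table even when a subject carries several HSPs;
`per_hsp=True` is available where per-HSP rows are wanted. Both filters
are strict inequalities (`LowerThan`, `HigherThan`), so a value exactly
at the threshold is excluded — tested at occupied boundary values. The
identity sort keeps queries in stored order and sorts rows within each
query by identity percent descending, ties by ascending e-value, then
stable original order. Percent columns print with one decimal (`95.0`),
e-values print their stored token, fields are tab-separated, and the
trailer line reports the retrieved count and the predicate-evaluation
time (export I/O is not timed; `--no-timing` zeroes the field for
golden-file comparison). The `descr` column and an absent positives
percent (blastn) print as empty fields.

## The synthetic-report generator

`GeneratorSpec` defaults describe a small protein search: 5 queries, 1–4
subjects each, 1–2 HSPs per subject, alignment lengths 30–120, gap rate
0.05, identity rate 0.55, wrap width 60 columns. The generator draws the
*model* first — counts, then percentages by truncation, then coordinates
derived from the gap placements — and renders text from it, so ground
truth is exact by construction. Residues come from a reduced 10-letter
alphabet with a fixed toy similarity rule (each letter has one "similar"
partner) that makes the positives count well-defined without a real
substitution matrix; blastn uses `ACGT`, `|` identity midlines, no
positives, and minus-strand subjects with descending coordinates; blastx
draws frames from ±1..3 with the 3× query span.

Fixture-dialect simplifications, deliberate and documented:

- grades lines are emitted flush-left exactly as `format_hsp_stats`
  prints them (the parser still accepts the report's leading-space form);
- the one-line-summary block puts hit rows directly under its header with
  no internal blank line, and appears once per query (round 1 for
  PSI-BLAST); the parser stores the first summary block it sees;
- scores and e-values are arbitrary self-consistent values, not drawn
  from any alignment statistics.

Consequently, passing round-trip tests demonstrate that the parser
inverts this format family — covering the anchors, dialects, wrapped
descriptions, multi-round and multi-HSP structure, strand/frame
variants and truncated percentages of real legacy reports — but they do
not exercise every cosmetic variation historical BLAST builds ever
printed (e.g. `Method:` continuation lines are tolerated, not
round-tripped). `corrupt_report` damages a rendered report
deterministically in three ways (tail truncation inside the final HSP, a
mangled `Score` line, a dropped length declaration) chosen to hit the
three main parser sections.

## Problem sizes and numerical choices

The test suite and acceptance script use sizes at which every check is
exact and the whole run stays in seconds: 100 seeded round-trip models
across the four program families and both dialects, 50 store/reload
cycles plus a 1000-query store for access instrumentation, a 200-query
two-round PSI-BLAST store with 3–4 HSPs per subject for the
manager-vs-brute-force comparison, and a 10,000-query report for the
scalability smoke run. All equality checks are exact value equality —
parsing and formatting are deterministic, and floats compare equal
because each numeric field is derived from the same printed token on
both sides of a round trip. Derived seeds are kept below 2³¹.

## Known limitations

- Only the legacy pairwise layout (≤ 2.2.26) plus the `Length=` dialect;
  modern BLAST+ reports with other textual deviations surface as
  diagnostics rather than results.
- `Method:` lines are retained inside the HSP's raw grades text but not
  parsed into fields.
- No concurrent writers, no incremental append to an existing store; a
  store is rebuilt from its report.
- The one-line-summary section is retained verbatim but not parsed into
  structured rows (the full alignments carry strictly more information).
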