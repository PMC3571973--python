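"""Synthetic BLAST plain-text reports with exact ground-truth models.

The generator builds a result model first — counts drawn before text, so
every printed percentage, coordinate and alignment string is known — and
then renders it in the legacy pairwise layout the parser understands.
``parse(render(model)) == model`` is the package's central oracle.

The reports are *format* fixtures, not biology: residues come from a
reduced alphabet with a fixed toy similarity rule (letters are "similar"
to one partner letter), so the Positives count is well-defined without a
real substitution matrix.  Scores and e-values are arbitrary
self-consistent values.  Nucleotide (blastn) reports use ``ACGT``, print
no Positives clause and mark identities with ``|`` on the midline, as
legacy blastn does.
"""

from __future__ import annotations

import random
import textwrap
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .errors import InvalidSpecError
from .model import (
    GAP,
    FooterStats,
    GeneralInfo,
    Hsp,
    HspStats,
    Iteration,
    QueryResult,
    SubjectAlignment,
    compute_truncated_pct,
    format_hsp_stats,
    validate_result,
)

# reduced protein alphabet; the "similar" partner of a letter is its
# neighbour in the pair (A~C, D~E, F~G, H~I, K~L)
PROTEIN_ALPHABET = "ACDEFGHIKL"
NUCLEOTIDE_ALPHABET = "ACGT"

_WORDS = (
    "synthetic putative conserved hypothetical domain protein kinase "
    "transporter receptor binding factor subunit family member isoform "
    "chain precursor fragment homolog regulator"
).split()

PROGRAM_FAMILIES = ("blastp", "blastn", "blastx", "psiblast")
LENGTH_STYLES = ("letters", "length_eq")


@dataclass
class GeneratorSpec:
    """Knobs of the synthetic report generator; all ranges are inclusive."""

    seed: int = 0
    num_queries: int = 5
    program_family: str = "blastp"
    rounds_per_query: int = 1
    subjects_per_query: Tuple[int, int] = (1, 4)
    hsps_per_subject: Tuple[int, int] = (1, 2)
    alignment_length: Tuple[int, int] = (30, 120)
    gap_rate: float = 0.05
    identity_rate: float = 0.55
    length_line_style: str = "letters"
    wrap_width: int = 60
    planted_subject_ids: Optional[Sequence[str]] = None

    def validate(self) -> None:
        if self.program_family not in PROGRAM_FAMILIES:
            raise InvalidSpecError(f"unknown program family {self.program_family!r}")
        if self.length_line_style not in LENGTH_STYLES:
            raise InvalidSpecError(f"unknown length style {self.length_line_style!r}")
        if self.num_queries < 1:
            raise InvalidSpecError("num_queries must be >= 1")
        if self.rounds_per_query < 1:
            raise InvalidSpecError("rounds_per_query must be >= 1")
        if self.rounds_per_query > 1 and self.program_family != "psiblast":
            raise InvalidSpecError("only psiblast reports have multiple rounds")
        for name in ("subjects_per_query", "hsps_per_subject", "alignment_length"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise InvalidSpecError(f"empty or negative range for {name}")
        if self.hsps_per_subject[0] < 1:
            raise InvalidSpecError("subjects need at least one HSP")
        if self.alignment_length[0] < 1:
            raise InvalidSpecError("alignments need at least one column")
        for name in ("gap_rate", "identity_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidSpecError(f"{name} outside [0, 1]")
        if self.wrap_width < 10:
            raise InvalidSpecError("wrap_width must be >= 10")


# ---------------------------------------------------------------------------
# model generation
# ---------------------------------------------------------------------------

def _partner(letter: str) -> str:
    i = PROTEIN_ALPHABET.index(letter)
    return PROTEIN_ALPHABET[i ^ 1]


def _make_alignment_columns(
    rng: random.Random, length: int, spec: GeneratorSpec, protein: bool
) -> Tuple[str, str, str, int, Optional[int], int]:
    """Build the three aligned strings column by column.

    Returns (query, midline, subject, identities, positives, gaps);
    positives is None for nucleotide output.
    """
    alphabet = PROTEIN_ALPHABET if protein else NUCLEOTIDE_ALPHABET
    q: List[str] = []
    m: List[str] = []
    s: List[str] = []
    for _ in range(length):
        if rng.random() < spec.gap_rate:
            letter = rng.choice(alphabet)
            if rng.random() < 0.5:
                q.append(GAP), m.append(" "), s.append(letter)
            else:
                q.append(letter), m.append(" "), s.append(GAP)
        elif rng.random() < spec.identity_rate:
            letter = rng.choice(alphabet)
            q.append(letter)
            m.append(letter if protein else "|")
            s.append(letter)
        else:
            letter = rng.choice(alphabet)
            if protein and rng.random() < 0.5:
                q.append(letter), m.append("+"), s.append(_partner(letter))
            else:
                other = rng.choice([c for c in alphabet if c != letter])
                plus = protein and other == _partner(letter)
                q.append(letter), m.append("+" if plus else " "), s.append(other)
    # a side with no residues at all has no printable coordinates;
    # force one identity column so both spans are anchored
    if all(c == GAP for c in q) or all(c == GAP for c in s):
        letter = rng.choice(alphabet)
        q[0], m[0], s[0] = letter, (letter if protein else "|"), letter
    # count from the finished strings so repairs above stay consistent
    identities = sum(1 for a, b in zip(q, s) if a == b and a != GAP)
    gaps = q.count(GAP) + s.count(GAP)
    if protein:
        positives = identities + m.count("+")
        return "".join(q), "".join(m), "".join(s), identities, positives, gaps
    return "".join(q), "".join(m), "".join(s), identities, None, gaps


def _make_evalue_token(rng: random.Random) -> str:
    r = rng.random()
    if r < 0.70:
        return f"{rng.randint(1, 9)}e-{rng.randint(5, 180)}"
    if r < 0.80:
        return "0.0"
    if r < 0.90:
        return f"e-{rng.randint(100, 180)}"
    return rng.choice(["0.001", "0.012", "2.1", "0.15"])


def _evalue_value(token: str) -> float:
    return float("1" + token) if token.startswith("e") else float(token)


def _make_hsp(rng: random.Random, spec: GeneratorSpec) -> Hsp:
    family = spec.program_family
    protein = family != "blastn"
    length = rng.randint(*spec.alignment_length)
    aq, mid, asb, identities, positives, gaps = _make_alignment_columns(
        rng, length, spec, protein
    )
    token = _make_evalue_token(rng)
    bits = float(rng.randint(25, 900))
    stats = HspStats(
        bit_score=bits,
        raw_score=int(bits * 2.2) + rng.randint(0, 5),
        evalue=_evalue_value(token),
        evalue_token=token,
        num_identities=identities,
        alignment_length=length,
        num_positives=positives,
        num_gaps=gaps,
        identity_pct=compute_truncated_pct(identities, length),
        positive_pct=(
            None if positives is None else compute_truncated_pct(positives, length)
        ),
        gap_pct=compute_truncated_pct(gaps, length),
        gaps_printed=True,
    )

    frame = query_strand = subject_strand = None
    q_step, q_dir, s_dir = 1, 1, 1
    if family == "blastx":
        frame = rng.choice([1, 2, 3, -1, -2, -3])
        q_step = 3
        q_dir = 1 if frame > 0 else -1
    elif family == "blastn":
        query_strand = "plus"
        subject_strand = rng.choice(["plus", "minus"])
        s_dir = 1 if subject_strand == "plus" else -1

    nq = sum(1 for c in aq if c != GAP)
    ns = sum(1 for c in asb if c != GAP)
    q_lo = rng.randint(1, 40)
    s_lo = rng.randint(1, 40)
    if q_dir > 0:
        q_start, q_end = q_lo, q_lo + q_step * nq - 1
    else:
        q_start, q_end = q_lo + q_step * nq - 1, q_lo
    if s_dir > 0:
        s_start, s_end = s_lo, s_lo + ns - 1
    else:
        s_start, s_end = s_lo + ns - 1, s_lo

    annotation_lines = []
    if frame is not None:
        annotation_lines.append(f"Frame = {frame:+d}")
    if subject_strand is not None:
        annotation_lines.append(
            f"Strand = {query_strand.capitalize()} / {subject_strand.capitalize()}"
        )
    raw_stats_text = "\n".join(list(format_hsp_stats(stats)) + annotation_lines)

    return Hsp(
        stats=stats,
        query_start=q_start,
        query_end=q_end,
        subject_start=s_start,
        subject_end=s_end,
        aligned_query=aq,
        midline=mid,
        aligned_subject=asb,
        query_frame=frame,
        query_strand=query_strand,
        subject_strand=subject_strand,
        raw_stats_text=raw_stats_text,
    )


def _make_description(rng: random.Random) -> str:
    return " ".join(rng.choice(_WORDS) for _ in range(rng.randint(3, 14)))


def _summary_text(alignments: Sequence[SubjectAlignment]) -> str:
    lines = [
        "Sequences producing significant alignments:                      (bits) Value"
    ]
    for aln in alignments:
        top = aln.hsps[0]
        lines.append(
            f"{aln.subject_id:<42} {int(top.stats.bit_score):>5}   "
            f"{top.stats.evalue_token}"
        )
    return "\n".join(lines)


def _footer(rng: random.Random, protein: bool) -> FooterStats:
    lam = float(f"{rng.uniform(0.2, 0.4):.3f}")
    k = float(f"{rng.uniform(0.02, 0.2):.3f}")
    h = float(f"{rng.uniform(0.3, 0.6):.3f}")
    lam_g = float(f"{rng.uniform(0.2, 0.4):.3f}")
    k_g = float(f"{rng.uniform(0.02, 0.2):.3f}")
    h_g = float(f"{rng.uniform(0.3, 0.6):.3f}")
    matrix = "BLOSUM62" if protein else None
    gap_open, gap_extend = (11, 1) if protein else (5, 2)
    lines = [
        "Lambda     K      H",
        f"   {lam:.3f}    {k:.3f}    {h:.3f}",
        "",
        "Gapped",
        "Lambda     K      H",
        f"   {lam_g:.3f}    {k_g:.3f}    {h_g:.3f}",
    ]
    if matrix:
        lines += ["", f"Matrix: {matrix}"]
    lines.append(f"Gap Penalties: Existence: {gap_open}, Extension: {gap_extend}")
    return FooterStats(
        lambda_ungapped=lam,
        k_ungapped=k,
        h_ungapped=h,
        lambda_gapped=lam_g,
        k_gapped=k_g,
        h_gapped=h_g,
        matrix_name=matrix,
        gap_open=gap_open,
        gap_extend=gap_extend,
        raw_footer="\n".join(lines),
    )


def generate_model(spec: GeneratorSpec) -> Tuple[GeneralInfo, List[QueryResult]]:
    """Deterministically build a ground-truth model for ``spec``.

    All model invariants hold by construction; the same spec (same seed)
    always yields an identical model.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    protein = spec.program_family != "blastn"
    program = spec.program_family.upper()

    database = f"synthdb{rng.randint(1, 99)}"
    info = GeneralInfo(
        program_name=program,
        program_version="2.2.26",
        database_name=database,
        database_posted_date=(
            f"{rng.choice(['Jan', 'May', 'Sep'])} {rng.randint(1, 28)}, "
            f"{rng.randint(2005, 2012)}  {rng.randint(1, 12)}:{rng.randint(10, 59)} PM"
        ),
        database_num_sequences=rng.randint(10_000, 9_000_000),
        database_num_letters=rng.randint(1_000_000, 900_000_000),
    )
    info.raw_header = "\n".join(
        [
            f"{program} {info.program_version} [Sep-21-2011]",
            "",
            "Reference: synthetic fixture report (not a real search)",
            "",
            f"Database: {info.database_name}",
            f"           Posted date:  {info.database_posted_date}",
            f"           {info.database_num_sequences:,} sequences; "
            f"{info.database_num_letters:,} total letters",
        ]
    )

    planted = list(spec.planted_subject_ids or [])
    subject_counter = 0
    results: List[QueryResult] = []
    for qi in range(spec.num_queries):
        query_id = f"synq{spec.seed % 997:03d}_{qi:04d}"
        title_extra = rng.choice(["", "", f" {_make_description(rng)}"])
        iterations: List[Iteration] = []
        max_q_coord = 1
        for round_index in range(spec.rounds_per_query):
            alignments: List[SubjectAlignment] = []
            for _ in range(rng.randint(*spec.subjects_per_query)):
                if planted:
                    sid = planted.pop(0)
                else:
                    subject_counter += 1
                    sid = f"SYN{spec.seed % 997:03d}_{subject_counter:05d}"
                hsps = [
                    _make_hsp(rng, spec)
                    for _ in range(rng.randint(*spec.hsps_per_subject))
                ]
                subject_length = max(
                    max(h.subject_start, h.subject_end) for h in hsps
                ) + rng.randint(0, 30)
                alignments.append(
                    SubjectAlignment(
                        subject_id=sid,
                        subject_description=_make_description(rng),
                        subject_length=subject_length,
                        hsps=hsps,
                    )
                )
                for h in hsps:
                    max_q_coord = max(max_q_coord, h.query_start, h.query_end)
            iterations.append(
                Iteration(
                    round_index=round_index,
                    converged=(
                        spec.program_family == "psiblast"
                        and round_index == spec.rounds_per_query - 1
                        and spec.rounds_per_query > 1
                    ),
                    alignments=alignments,
                )
            )
        result = QueryResult(
            query_id=query_id,
            query_title=f"{query_id}{title_extra}",
            query_length=max_q_coord + rng.randint(0, 50),
            iterations=iterations,
            footer=_footer(rng, protein),
        )
        if iterations[0].alignments:
            result.summary_text = _summary_text(iterations[0].alignments)
        results.append(result)
    return info, results


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _chunk_coords(
    start: int, direction: int, step: int, segment: str
) -> Tuple[int, int, int]:
    """Printed (start, end, next_start) for one wrapped row of one side."""
    non_gaps = sum(1 for c in segment if c != GAP)
    if non_gaps == 0:
        prev = start - direction
        return prev, prev, start
    end = start + direction * (step * non_gaps - 1)
    return start, end, end + direction


def _render_hsp_alignment(hsp: Hsp, wrap_width: int) -> List[str]:
    q_dir = 1 if hsp.query_end >= hsp.query_start else -1
    s_dir = 1 if hsp.subject_end >= hsp.subject_start else -1
    q_step = 3 if hsp.query_frame is not None else 1
    coords = (
        hsp.query_start,
        hsp.query_end,
        hsp.subject_start,
        hsp.subject_end,
    )
    width = max(len(str(c)) for c in coords)
    lines: List[str] = []
    q_pos, s_pos = hsp.query_start, hsp.subject_start
    for off in range(0, len(hsp.aligned_query), wrap_width):
        q_seg = hsp.aligned_query[off : off + wrap_width]
        m_seg = hsp.midline[off : off + wrap_width]
        s_seg = hsp.aligned_subject[off : off + wrap_width]
        qs, qe, q_pos = _chunk_coords(q_pos, q_dir, q_step, q_seg)
        ss, se, s_pos = _chunk_coords(s_pos, s_dir, 1, s_seg)
        lines.append(f"Query: {qs:<{width}} {q_seg} {qe}")
        lines.append(" " * (7 + width + 1) + m_seg)
        lines.append(f"Sbjct: {ss:<{width}} {s_seg} {se}")
        lines.append("")
    return lines


def _render_subject(
    aln: SubjectAlignment, style: str, wrap_width: int
) -> List[str]:
    header = f">{aln.subject_id} {aln.subject_description}".rstrip()
    lines = textwrap.wrap(
        header, width=wrap_width + 10, subsequent_indent=" ", break_long_words=False
    ) or [header]
    if style == "length_eq":
        lines.append(f"Length={aln.subject_length}")
    else:
        lines.append(f"          Length = {aln.subject_length}")
    lines.append("")
    for hsp in aln.hsps:
        lines.extend(hsp.raw_stats_text.splitlines())
        lines.append("")
        lines.extend(_render_hsp_alignment(hsp, wrap_width))
    return lines


def render_report(
    info: GeneralInfo,
    results: Sequence[QueryResult],
    length_line_style: str = "letters",
    wrap_width: int = 60,
) -> str:
    """Render a model back into legacy pairwise report text.

    Raises CorruptModelError when the model violates its invariants (the
    output would not parse back to the same model).
    """
    for result in results:
        validate_result(result)
    style = length_line_style
    if style not in LENGTH_STYLES:
        raise InvalidSpecError(f"unknown length style {style!r}")
    psiblast = info.program_name.upper() == "PSIBLAST"
    out: List[str] = [info.raw_header, ""]
    for result in results:
        out.append(f"Query= {result.query_title}")
        if style == "length_eq":
            out.append(f"Length={result.query_length}")
        else:
            out.append(f"         ({result.query_length} letters)")
        out.append("")
        for iteration in result.iterations:
            if psiblast:
                out.append(f"Results from round {iteration.round_index + 1}")
                out.append("")
            if iteration.round_index == 0 and result.summary_text:
                out.append(result.summary_text)
                out.append("")
            if not iteration.alignments:
                out.append(" ***** No hits found ******")
                out.append("")
            for aln in iteration.alignments:
                out.extend(_render_subject(aln, style, wrap_width))
            if iteration.converged:
                out.append("CONVERGED!")
                out.append("")
        if result.footer is not None and result.footer.raw_footer:
            out.append(result.footer.raw_footer)
            out.append("")
        out.append("")
    return "\n".join(out)


def generate_report(spec: GeneratorSpec) -> Tuple[GeneralInfo, List[QueryResult], str]:
    """Convenience: model plus its rendered text in one call."""
    info, results = generate_model(spec)
    text = render_report(
        info, results, length_line_style=spec.length_line_style,
        wrap_width=spec.wrap_width,
    )
    return info, results, text


# ---------------------------------------------------------------------------
# controlled corruption
# ---------------------------------------------------------------------------

CORRUPTION_MODES = ("none", "truncate_tail", "mangle_score_line", "drop_length_line")


def corrupt_report(text: str, seed: int, mode: str) -> str:
    """Deterministically damage a rendered report for robustness tests.

    ``truncate_tail`` cuts mid-HSP inside the final subject block;
    ``mangle_score_line`` garbles one Score line; ``drop_length_line``
    removes one query's length declaration.  ``none`` returns the input.
    """
    if mode not in CORRUPTION_MODES:
        raise InvalidSpecError(f"unknown corruption mode {mode!r}")
    if mode == "none":
        return text
    rng = random.Random(seed)
    if mode == "truncate_tail":
        last_score = text.rfind("\nScore =")
        last_sbjct = text.rfind("\nSbjct:")
        if last_score < 0 or last_sbjct < last_score:
            raise InvalidSpecError("report has no complete HSP to truncate")
        cut = rng.randint(last_score + 10, last_sbjct + 8)
        return text[:cut]
    if mode == "mangle_score_line":
        offsets = []
        pos = text.find("\nScore =")
        while pos >= 0:
            offsets.append(pos + 1)
            pos = text.find("\nScore =", pos + 1)
        if not offsets:
            raise InvalidSpecError("report has no Score line to mangle")
        start = rng.choice(offsets)
        end = text.index("\n", start)
        return text[:start] + "Score = ??? bits" + text[end:]
    # drop_length_line
    lines = text.split("\n")
    query_idx = [i for i, line in enumerate(lines) if line.startswith("Query=")]
    chosen = rng.choice(query_idx)
    for j in range(chosen + 1, len(lines)):
        stripped = lines[j].strip()
        if stripped.startswith("(") and stripped.endswith("letters)"):
            return "\n".join(lines[:j] + lines[j + 1 :])
        if stripped.replace(" ", "").startswith("Length="):
            return "\n".join(lines[:j] + lines[j + 1 :])
    raise InvalidSpecError("no length line found after chosen query")
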