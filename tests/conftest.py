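import pytest
from hypothesis import HealthCheck, settings

from blastvault.fixtures import GeneratorSpec, generate_report
from blastvault.model import (
    GeneralInfo,
    Hsp,
    HspStats,
    Iteration,
    QueryResult,
    SubjectAlignment,
    compute_truncated_pct,
    format_hsp_stats,
)
from blastvault.storage import build_store

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_stats(
    bits: float,
    raw: int,
    token: str,
    identities: int,
    length: int,
    positives=None,
    gaps: int = 0,
) -> HspStats:
    """Self-consistent HspStats with truncated percentages."""
    return HspStats(
        bit_score=bits,
        raw_score=raw,
        evalue=float("1" + token) if token.startswith("e") else float(token),
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
    )


def make_hsp(token: str, bits: float = 100.0, length: int = 10) -> Hsp:
    """A gap-free identical-sequence HSP with the given e-value token."""
    seq = ("ACDEFGHIKL" * ((length + 9) // 10))[:length]
    stats = make_stats(bits, int(bits * 2.2), token, length, length,
                       positives=length, gaps=0)
    hsp = Hsp(
        stats=stats,
        query_start=1,
        query_end=length,
        subject_start=1,
        subject_end=length,
        aligned_query=seq,
        midline=seq,
        aligned_subject=seq,
    )
    hsp.raw_stats_text = "\n".join(format_hsp_stats(stats))
    return hsp


@pytest.fixture
def tiny_model():
    """One query, two single-HSP subjects; small enough to reason by hand."""
    info = GeneralInfo(
        program_name="BLASTP",
        program_version="2.2.26",
        database_name="tinydb",
        raw_header="BLASTP 2.2.26 [Sep-21-2011]\n\nDatabase: tinydb",
    )
    subjects = [
        SubjectAlignment("S1", "first subject", 40, [make_hsp("1e-50")]),
        SubjectAlignment("S2", "second subject", 40, [make_hsp("2.1", bits=30.0)]),
    ]
    result = QueryResult(
        query_id="Q0001",
        query_title="Q0001 tiny fixture query",
        query_length=20,
        iterations=[Iteration(0, False, subjects)],
    )
    return info, [result]


@pytest.fixture
def small_store(tmp_path):
    """A 20-query blastp store built from a generated report."""
    spec = GeneratorSpec(seed=42, num_queries=20, hsps_per_subject=(1, 3))
    info, results, text = generate_report(spec)
    handle, diagnostics = build_store(str(tmp_path / "small.db"), text)
    assert not diagnostics.warnings
    yield handle, info, results
    handle.close()
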