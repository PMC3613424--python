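"""Shared fixtures: the S1 verification scenario and its pipeline runs.

The heavy pipeline runs (SAP and direct at both cutoffs) execute once per
session and are shared by the pipeline and acceptance tests.
"""

import io

import pytest
from hypothesis import HealthCheck, settings

from sapkit.refdb_io import ReferenceRecord
from sapkit.sap_pipeline import attach_direct, run_direct, run_sap
from sapkit.search_backend import ScoringParams
from sapkit.synth_fixtures import ScenarioSpec, generate_trap_case

settings.register_profile(
    "sapkit",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("sapkit")

CUTOFFS = (1e-5, 1e-10)


def make_record(gi: int, sequence: str, acc: str = None, description: str = "test protein"):
    acc = acc or f"NP_{gi:06d}.1"
    header = f"gi|{gi}|ref|{acc}| {description}"
    return ReferenceRecord(
        primary_gi=gi,
        canonical_id=f"gi|{gi}|ref|{acc}",
        all_headers=[header],
        sequence=sequence.upper(),
    )


@pytest.fixture(scope="session")
def s1_scenario():
    """Scenario S1: 3 target families x 5 members, 2 traps, 40 background, 500 reads."""
    return generate_trap_case(ScenarioSpec())


@pytest.fixture(scope="session")
def s1_results(s1_scenario):
    """SAP summaries (direct counts attached) for S1 at cutoffs 1e-5 and 1e-10."""
    sc = s1_scenario
    results = {}
    for cutoff in CUTOFFS:
        scoring = ScoringParams(evalue_cutoff=cutoff)
        sap = run_sap(sc.reads, sc.bundle.records, sc.bundle.fmap, sc.bundle.target, scoring=scoring)
        direct = run_direct(
            sc.reads, sc.bundle.records, sc.bundle.fmap, sc.bundle.target, scoring=scoring
        )
        results[cutoff] = attach_direct(sap, direct)
    return results


@pytest.fixture
def text_stream():
    return io.StringIO
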