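from datetime import datetime, timedelta, timezone

import pandas as pd
import pytest

from fedaccess.broker import Broker
from fedaccess.clock import VirtualClock
from fedaccess.datastore import LocalDatastore
from fedaccess.model import CoverLetter, RequestManifest, Requester
from fedaccess.node import NodeClient

T0 = datetime(2024, 1, 1, 8, 0, 0, tzinfo=timezone.utc)

LETTER = CoverLetter(
    rationale="Test rationale.",
    research_questions_and_outcomes="Test questions.",
    inclusion_criteria_and_variables="All encounters.",
    processors_and_purpose="Test processors.",
    ethics_and_privacy_commitments="Test commitments.",
)


def make_manifest(
    request_id="REQ-001",
    query_type="single",
    targets=("ED-01",),
    syntax="SELECT triage_level, COUNT(*) FROM encounters GROUP BY triage_level",
    execution_date=T0,
    series_interval=None,
    series_count=None,
    language="sql",
    retroactive=False,
):
    return RequestManifest(
        request_id=request_id,
        query_type=query_type,
        syntax_language=language,
        syntax_body=syntax,
        requester=Requester("A. Tester", "Test Lab", "tester@example.org"),
        reference_date=T0,
        execution_date=execution_date,
        cover_letter=LETTER,
        target_nodes=frozenset(targets),
        series_interval=series_interval,
        series_count=series_count,
        retroactive=retroactive,
    )


@pytest.fixture
def clock():
    return VirtualClock(T0)


@pytest.fixture
def broker(clock):
    return Broker(clock=clock)


# Hand-auditable 10-row encounter table: 6 adults; triage levels 1..5
# present with counts 2,2,3,1,2.
TEN_ROWS = pd.DataFrame(
    {
        "encounter_id": [f"E{i}" for i in range(1, 11)],
        "age_group": ["adult"] * 6 + ["child", "child", "elderly", "elderly"],
        "triage_level": [1, 2, 3, 4, 5, 3, 2, 3, 1, 5],
        "diagnosis_code": ["J06", "I21", "S93", "R10", "J44", "J06",
                           "T78", "J06", "I21", "R10"],
        "disposition": ["discharged", "admitted", "discharged", "discharged",
                        "admitted", "discharged", "discharged", "admitted",
                        "admitted", "transferred"],
    }
)


@pytest.fixture
def ten_row_store():
    return LocalDatastore({"encounters": TEN_ROWS.copy()})


@pytest.fixture
def node(broker, clock, ten_row_store):
    reg = broker.register_node("ED-01")
    return NodeClient("ED-01", reg.api_key, broker, datastore=ten_row_store,
                      clock=clock)


def make_node(broker, clock, node_id, datastore=None, review_default=False):
    reg = broker.register_node(node_id)
    return NodeClient(node_id, reg.api_key, broker, datastore=datastore,
                      clock=clock, review_default=review_default)
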