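"""Shared fixtures: small simulated genomes and libraries, generated
programmatically so the suite carries no data files."""

from __future__ import annotations

import pytest

from attrace.pipeline import run_trace_records
from attrace.simulate import SimParams, simulate_prophage_genome, simulate_read_mixture


@pytest.fixture(scope="session")
def toy_params() -> SimParams:
    # excision-rich mixture: evidence for both junction types is
    # essentially certain at this coverage
    return SimParams(
        genome_len=100_000,
        att_len=30,
        att_mismatches=0,  # identical att copies: endpoint recovery is exact
        prophage_size=20_000,
        ratios=(2, 1, 1),
        depth=60,
        error_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def toy_truth(toy_params):
    return simulate_prophage_genome(toy_params)


@pytest.fixture(scope="session")
def toy_library(toy_truth):
    return simulate_read_mixture(toy_truth)


@pytest.fixture(scope="session")
def toy_result(toy_truth, toy_library):
    _, records = toy_library
    return run_trace_records(iter(records), {"chr": toy_truth.wt_seq}, mode="chromosome")
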