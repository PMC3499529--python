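"""Shared fixtures: a small synthetic scenario exercised by several suites."""

from __future__ import annotations

import pytest

from mirseed import MatureReference, preprocess, synthetic


@pytest.fixture(scope="session")
def small_scenario():
    """Six planted precursors (3 conserved, 3 novel), 10 decoys, background."""
    truth = synthetic.make_scenario(seed=3, n_conserved=3, n_novel=3,
                                    n_decoys=10)
    records, ledger = synthetic.simulate_library(
        truth, background_reads=100, rng_seed=4, low_quality_fraction=0.1)
    return truth, records, ledger


@pytest.fixture(scope="session")
def small_fastq(small_scenario, tmp_path_factory):
    _, records, _ = small_scenario
    path = tmp_path_factory.mktemp("sim") / "reads.fastq"
    synthetic.write_fastq(records, path)
    return path


@pytest.fixture(scope="session")
def small_library(small_fastq):
    return preprocess.preprocess_fastq(
        small_fastq, adapter3p=synthetic.DEFAULT_ADAPTER_3P)


@pytest.fixture(scope="session")
def small_mature_ref(small_scenario):
    truth, _, _ = small_scenario
    return MatureReference.from_entries(truth.mature_reference)
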