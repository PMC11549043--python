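"""Shared fixtures: simulated libraries generated once per session."""
from __future__ import annotations

import numpy as np
import pytest

from perseq.consensus import ConsensusConfig, call_all_molecules
from perseq.readprep import process_paired_fastq
from perseq.simulate import ErrorModel, LibrarySimConfig, simulate_library


@pytest.fixture(scope="session")
def tiny_clean_library(tmp_path_factory):
    """A small error-free library (all rates zero): ground truth is the
    reference everywhere."""
    cfg = LibrarySimConfig(
        n_molecules=60,
        seed=11,
        roi_length=240,
        error_model=ErrorModel.uniform(0.0),
        artifact_rate=0.0,
        seq_error_rate=0.0,
    )
    lib = simulate_library(cfg, tmp_path_factory.mktemp("tiny_clean"))
    return lib


@pytest.fixture(scope="session")
def small_noisy_library(tmp_path_factory):
    """A 3000-molecule library with realistic artifact/sequencing noise
    and an elevated true error rate, for truth-join tests."""
    cfg = LibrarySimConfig(
        n_molecules=3000,
        seed=12,
        roi_length=250,
        error_model=ErrorModel.uniform(1e-3),
        artifact_rate=1e-3,
        seq_error_rate=1e-3,
    )
    lib = simulate_library(cfg, tmp_path_factory.mktemp("small_noisy"))
    return lib


@pytest.fixture(scope="session")
def small_noisy_calls(small_noisy_library):
    lib = small_noisy_library
    batches, report = process_paired_fastq(
        lib.fastq1, lib.fastq2, lib.config.layout, lib.sample_sheet,
        lib.annotation,
    )
    mcs = call_all_molecules(batches[lib.sample_id], lib.annotation,
                             ConsensusConfig())
    return lib, batches[lib.sample_id], mcs, report
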