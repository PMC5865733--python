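"""Shared fixtures: a small simulated dataset for unit tests and a
full-default-scale analysis reused by the recovery and calibration checks."""
from __future__ import annotations

import pytest

from ribote.align import align_reads, build_index, count_hits, exclude_rdna
from ribote.pipeline import trim_adapter
from ribote.quantify import average_replicates, rpkm
from ribote.simulate import (SimulationConfig, build_transcriptome,
                             simulate_all_libraries)
from ribote.te import te_table


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=30, reads_per_library=8000, seed=11)


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    return build_transcriptome(small_config)


@pytest.fixture(scope="session")
def small_libraries(small_transcriptome):
    return simulate_all_libraries(small_transcriptome)


def run_analysis(transcriptome, libraries):
    """Trim, align, exclude rDNA, count, normalize and test: the in-memory
    core of the pipeline, shared by recovery tests."""
    index = build_index(transcriptome.sequences, k=20)
    hits_by_lib = {}
    for key, reads in libraries.items():
        trimmed, _ = trim_adapter(reads, transcriptome.config.adapter)
        hits, _ = align_reads(trimmed, index)
        _, hits, _ = exclude_rdna(transcriptome.models, hits)
        hits_by_lib[key] = hits
    retained = [m for m in transcriptome.models if not m.is_rdna]
    counts = count_hits(hits_by_lib, retained)
    lengths = {m.transcript_id: m.length for m in retained}
    expression = average_replicates(rpkm(counts, lengths))
    results = te_table(expression, counts)
    return counts, expression, results


@pytest.fixture(scope="session")
def small_analysis(small_transcriptome, small_libraries):
    return run_analysis(small_transcriptome, small_libraries)


@pytest.fixture(scope="session")
def default_transcriptome():
    """Default study-condition fixture (120 genes, 100k reads/library)."""
    return build_transcriptome(SimulationConfig(seed=2024))


@pytest.fixture(scope="session")
def default_analysis(default_transcriptome):
    libraries = simulate_all_libraries(default_transcriptome)
    return run_analysis(default_transcriptome, libraries)
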