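"""Aligner contracts: brute-force oracle equivalence, the multi-mapping
suppression rule, rDNA exclusion and hit counting."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribote.align import (align_reads, build_index, count_hits, exclude_rdna,
                          SubstringIndex)
from ribote.models import LibraryKey, ReadHit, TranscriptModel


def brute_force_occurrences(sequences: dict[str, str], read: str):
    """Independent oracle: scan every transcript for every exact occurrence."""
    out = []
    for tid, seq in sequences.items():
        start = seq.find(read)
        while start != -1:
            out.append((tid, start))
            start = seq.find(read, start + 1)
    return out


def _random_sequences(rng, n, lo=50, hi=300):
    return {f"T{i:03d}.1": "".join(rng.choice(list("ACGT"), rng.integers(lo, hi)))
            for i in range(n)}


def test_empty_index_yields_no_hits():
    index = SubstringIndex({}, k=4)
    assert index.locate("ACGTACGT") == []


def test_locate_simple_occurrence():
    index = SubstringIndex({"t": "ACGTACGT"}, k=4)
    assert index.locate("GTAC") == [("t", 2)]


def test_duplicate_ids_rejected():
    models = [TranscriptModel("a.1", 40, 0, 40), TranscriptModel("a.1", 40, 0, 40)]
    with pytest.raises(ValueError):
        build_index(models, k=4, seq_lookup={"a.1": "ACGT" * 10})


def test_oracle_equivalence_random_instances():
    """On random instances the aligner's hit set equals brute-force substring
    search under the same suppression cap."""
    rng = np.random.default_rng(5)
    sequences = _random_sequences(rng, 100)
    index = build_index(sequences, k=8)
    reads = []
    ids = list(sequences)
    for i in range(400):
        tid = ids[rng.integers(len(ids))]
        seq = sequences[tid]
        ln = int(rng.integers(8, 31))
        start = int(rng.integers(0, len(seq) - ln + 1))
        reads.append((f"r{i}", seq[start:start + ln]))
    for i in range(100):  # random reads, mostly unalignable
        reads.append((f"q{i}", "".join(rng.choice(list("ACGT"), 12))))
    for cap in (1, 3, 25):
        hits, _ = align_reads(reads, index, max_multimap=cap)
        got = {(h.read_id, h.transcript_id, h.start) for h in hits}
        expected = set()
        for rid, seq in reads:
            occ = brute_force_occurrences(sequences, seq)
            if 1 <= len(occ) <= cap:
                expected |= {(rid, tid, s) for tid, s in occ}
        assert got == expected


def test_suppression_over_cap():
    sequences = {f"c{i}.1": "A" * 30 + "ACGTACGTACGTACGTACGTACGT" + "G" * 30
                 for i in range(26)}
    index = build_index(sequences, k=8)
    hits, summary = align_reads([("r", "ACGTACGTACGTACGTACGTACGT")], index,
                                max_multimap=25)
    assert hits == []
    assert summary.n_suppressed == 1
    hits26, _ = align_reads([("r", "ACGTACGTACGTACGTACGTACGT")], index,
                            max_multimap=26)
    assert len(hits26) == 26


def test_suppression_monotonicity():
    rng = np.random.default_rng(9)
    sequences = _random_sequences(rng, 40, lo=40, hi=120)
    # force shared subsequences
    shared = "".join(rng.choice(list("ACGT"), 25))
    for tid in list(sequences)[:10]:
        sequences[tid] += shared
    index = build_index(sequences, k=8)
    reads = [("s", shared)] + [
        (f"r{i}", sequences[tid][:20])
        for i, tid in enumerate(list(sequences)[:15])]
    n_hits = []
    for cap in (1, 2, 5, 10, 25):
        hits, _ = align_reads(reads, index, max_multimap=cap)
        n_hits.append(len(hits))
    assert n_hits == sorted(n_hits)


def test_mismatched_read_unaligned(small_transcriptome):
    tr = small_transcriptome
    tid, seq = next(iter(tr.sequences.items()))
    read = seq[10:40]
    bad = ("T" if read[15] != "T" else "A")
    mutated = read[:15] + bad + read[16:]
    index = build_index(tr.sequences, k=20)
    assert brute_force_occurrences(tr.sequences, mutated) == []
    hits, summary = align_reads([("m", mutated)], index)
    assert hits == [] and summary.n_unaligned == 1
    hits, _ = align_reads([("ok", read)], index)
    assert any(h.transcript_id == tid and h.start == 10 for h in hits)


def test_short_reads_skipped_with_count():
    index = build_index({"t.1": "ACGT" * 20}, k=20)
    hits, summary = align_reads([("short", "ACGTACGT")], index)
    assert hits == [] and summary.n_too_short == 1


def test_exclude_rdna_accounting():
    """Model accounting mirrors the reference-set reduction: flagged models
    are removed and the retained count is input minus removed."""
    models = ([TranscriptModel(f"g{i}.1", 100, 10, 90) for i in range(500)]
              + [TranscriptModel(f"r{i}.1", 100, 10, 90, is_rdna=True)
                 for i in range(132)])
    hits = [ReadHit("a", "g0.1", 0, 30), ReadHit("b", "r5.1", 0, 30)]
    retained, kept_hits, removed = exclude_rdna(models, hits)
    assert removed == 132
    assert len(retained) == len(models) - removed
    assert kept_hits == [hits[0]]
    # no flags: identity
    retained2, kept2, removed2 = exclude_rdna(models[:500], hits[:1])
    assert removed2 == 0 and kept2 == hits[:1]


def test_exclude_rdna_share_tracks_contamination(small_config,
                                                 small_transcriptome,
                                                 small_libraries):
    from ribote.pipeline import trim_adapter
    key = sorted(small_libraries)[0]
    reads, _ = trim_adapter(small_libraries[key], small_config.adapter)
    index = build_index(small_transcriptome.sequences, k=20)
    hits, _ = align_reads(reads, index)
    _, kept, _ = exclude_rdna(small_transcriptome.models, hits)
    # oracle: source tags embedded in read ids
    n_rdna_reads = sum(1 for rid, _ in reads if "rDNA" in rid.split(":")[-1])
    removed_frac = 1 - len(kept) / len(hits)
    source_frac = n_rdna_reads / len(reads)
    assert removed_frac == pytest.approx(source_frac, abs=0.05)


def test_count_hits_multimap_and_totals():
    models = [TranscriptModel("A.1", 100, 0, 100),
              TranscriptModel("B.1", 100, 0, 100)]
    key = LibraryKey("C25", "CT", 1)
    hits = [ReadHit("r1", "A.1", 0, 30), ReadHit("r1", "B.1", 5, 30),
            ReadHit("r2", "A.1", 10, 28)]
    cm = count_hits({key: hits}, models)
    assert cm.counts.loc["A.1", key.label] == 2
    assert cm.counts.loc["B.1", key.label] == 1
    assert cm.total_mapped[key.label] == 3
    empty = count_hits({key: []}, models)
    assert (empty.counts == 0).all().all() and empty.total_mapped[key.label] == 0
    with pytest.raises(ValueError, match="unknown transcript"):
        count_hits({key: [ReadHit("r", "Z.1", 0, 30)]}, models)


def test_column_sums_equal_hit_tally(small_analysis):
    counts, _, _ = small_analysis
    assert (counts.total_mapped == counts.counts.sum(axis=0)).all()
    assert not any("rDNA" in t for t in counts.counts.index)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=30))
def test_error_free_reads_align_to_source(seed_offset):
    """Every emitted read (no errors, >= k long) aligns at least to the
    transcript it was sampled from."""
    rng = np.random.default_rng(1000 + seed_offset)
    sequences = _random_sequences(rng, 10, lo=60, hi=200)
    index = build_index(sequences, k=20)
    tid = list(sequences)[int(rng.integers(10))]
    seq = sequences[tid]
    ln = int(rng.integers(20, 35))
    start = int(rng.integers(0, len(seq) - ln + 1))
    hits, _ = align_reads([("r", seq[start:start + ln])], index)
    assert any(h.transcript_id == tid for h in hits)


def test_coverage_bedgraph_depth(tmp_path):
    """Interval depths in the exported track equal a direct per-base pileup."""
    hits = [ReadHit("a", "t.1", 0, 10), ReadHit("b", "t.1", 5, 10),
            ReadHit("c", "t.1", 30, 5)]
    from ribote.align import coverage_bedgraph
    path = tmp_path / "cov.bedgraph"
    coverage_bedgraph(hits, {"t.1": 50}, path)
    depth = [0] * 50
    for h in hits:
        for i in range(h.start, h.start + h.length):
            depth[i] += 1
    rebuilt = [0] * 50
    for line in path.read_text().splitlines():
        tid, a, b, d = line.split("\t")
        for i in range(int(a), int(b)):
            rebuilt[i] = int(d)
    assert rebuilt == depth
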