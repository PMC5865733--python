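"""Exact-match short-read alignment against the transcript set.

The contract mirrors a zero-mismatch Bowtie-style run with a multi-mapping
cap: a read with 1..max_multimap exact full-length occurrences yields one hit
per occurrence, a read occurring more often is suppressed entirely, and a
read with no occurrence is unaligned.  Counting then credits every retained
occurrence of a multi-mapped read (deterministic, unlike report-one-random).
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .models import TranscriptModel, ReadHit, CountMatrix, LibraryKey
from .utils import reverse_complement

DEFAULT_SEED_LENGTH = 20
DEFAULT_MAX_MULTIMAP = 25


class SubstringIndex:
    """k-mer anchored exact substring index over a transcript set.

    Every read of length >= k is located by looking up its first k-mer and
    verifying the full-length extension; this finds all exact occurrences.
    """

    def __init__(self, sequences: Mapping[str, str], k: int = DEFAULT_SEED_LENGTH):
        if k <= 0:
            raise ValueError("seed length k must be positive")
        ids = list(sequences)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript ids in index input")
        self.k = k
        self.sequences = dict(sequences)
        self._kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for tid, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                self._kmers[seq[i:i + k]].append((tid, i))

    def locate(self, read: str) -> list[tuple[str, int]]:
        """All exact full-length occurrences of ``read``; requires len >= k."""
        if len(read) < self.k:
            raise ValueError(f"read shorter than seed length {self.k}")
        out = []
        for tid, i in self._kmers.get(read[:self.k], ()):
            if self.sequences[tid][i:i + len(read)] == read:
                out.append((tid, i))
        return out


def build_index(sequences: Mapping[str, str] | Sequence[TranscriptModel],
                k: int = DEFAULT_SEED_LENGTH,
                *, seq_lookup: Mapping[str, str] | None = None) -> SubstringIndex:
    if not isinstance(sequences, Mapping):
        if seq_lookup is None:
            raise ValueError("need sequences for transcript models")
        models = list(sequences)
        if len({m.transcript_id for m in models}) != len(models):
            raise ValueError("duplicate transcript ids in index input")
        sequences = {m.transcript_id: seq_lookup[m.transcript_id] for m in models}
    return SubstringIndex(sequences, k=k)


@dataclass
class AlignmentSummary:
    n_reads: int = 0
    n_aligned: int = 0
    n_unaligned: int = 0
    n_suppressed: int = 0
    n_too_short: int = 0
    n_hits: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def align_reads(reads: Iterable[tuple[str, str]], index: SubstringIndex,
                max_multimap: int = DEFAULT_MAX_MULTIMAP,
                mismatches_allowed: int = 0,
                both_strands: bool = False,
                first_match_only: bool = False,
                ) -> tuple[list[ReadHit], AlignmentSummary]:
    """Align reads; returns retained hits plus per-read accounting.

    ``mismatches_allowed`` must be 0 (reserved).  With ``first_match_only``
    a multi-mapped read under the cap is credited to its lexicographically
    first (transcript, position) occurrence only.
    """
    if mismatches_allowed != 0:
        raise NotImplementedError("only zero-mismatch alignment is implemented")
    hits: list[ReadHit] = []
    summary = AlignmentSummary()
    for rid, seq in reads:
        summary.n_reads += 1
        if len(seq) < index.k:
            summary.n_too_short += 1
            continue
        occ = index.locate(seq)
        if both_strands:
            occ = occ + index.locate(reverse_complement(seq))
        if not occ:
            summary.n_unaligned += 1
        elif len(occ) > max_multimap:
            summary.n_suppressed += 1
        else:
            summary.n_aligned += 1
            if first_match_only:
                occ = [min(occ)]
            for tid, start in occ:
                hits.append(ReadHit(rid, tid, start, len(seq)))
                summary.n_hits += 1
    return hits, summary


def coverage_bedgraph(hits: Iterable[ReadHit], lengths: Mapping[str, int],
                      path) -> None:
    """Per-base coverage as bedGraph (0-based half-open intervals per
    transcript), the flat-file stand-in for a browser coverage track."""
    import numpy as np

    depth: dict[str, "np.ndarray"] = {}
    for h in hits:
        arr = depth.setdefault(h.transcript_id,
                               np.zeros(lengths[h.transcript_id], dtype=int))
        arr[h.start:h.start + h.length] += 1
    with open(path, "w") as fh:
        for tid in sorted(depth):
            arr = depth[tid]
            boundaries = [0] + (np.flatnonzero(np.diff(arr)) + 1).tolist() \
                + [len(arr)]
            for a, b in zip(boundaries, boundaries[1:]):
                if arr[a]:
                    fh.write(f"{tid}\t{a}\t{b}\t{arr[a]}\n")


def exclude_rdna(models: Sequence[TranscriptModel], hits: Iterable[ReadHit],
                 ) -> tuple[list[TranscriptModel], list[ReadHit], int]:
    """Drop rDNA-flagged models and every hit to them; report removed count."""
    rdna = {m.transcript_id for m in models if m.is_rdna}
    retained_models = [m for m in models if not m.is_rdna]
    retained_hits = [h for h in hits if h.transcript_id not in rdna]
    return retained_models, retained_hits, len(rdna)


def count_hits(hits_by_library: Mapping[LibraryKey, Iterable[ReadHit]],
               models: Sequence[TranscriptModel]) -> CountMatrix:
    """Tally retained hits per transcript per library (multi-map: one count
    per transcript hit)."""
    ids = [m.transcript_id for m in models]
    known = set(ids)
    keys = sorted(hits_by_library)
    columns = {}
    for key in keys:
        tally: dict[str, int] = defaultdict(int)
        for h in hits_by_library[key]:
            if h.transcript_id not in known:
                raise ValueError(f"hit to unknown transcript {h.transcript_id}")
            tally[h.transcript_id] += 1
        columns[key.label] = tally
    counts = pd.DataFrame(columns, index=ids).fillna(0).astype(int)
    return CountMatrix(counts, libraries=keys)
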