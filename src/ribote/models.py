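"""Core records shared across the pipeline.

A *transcript model* is a cDNA with a three-way partition into 5'UTR, CDS and
3'UTR given in transcript coordinates (0-based, half-open internally; the
GFF3 boundary converts to 1-based inclusive).  Transcript identifiers carry a
terminal splice-variant index (``Gene.1``, ``Gene.2``); stripping it yields
the gene identifier used for unique-gene collapsing.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

_VARIANT_SUFFIX = re.compile(r"\.\d+$")


def gene_id_of(transcript_id: str) -> str:
    """Strip the terminal ``.N`` splice-variant index, if present."""
    return _VARIANT_SUFFIX.sub("", transcript_id)


@dataclass(frozen=True)
class TranscriptModel:
    """A gene model: the unit of alignment and quantification."""

    transcript_id: str
    length: int
    cds_start: int  # 0-based inclusive
    cds_end: int    # exclusive
    is_rdna: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start <= self.cds_end <= self.length):
            raise ValueError(
                f"{self.transcript_id}: invalid CDS interval "
                f"[{self.cds_start}, {self.cds_end}) on length {self.length}"
            )

    @property
    def gene_id(self) -> str:
        return gene_id_of(self.transcript_id)

    @property
    def utr5(self) -> tuple[int, int]:
        return (0, self.cds_start)

    @property
    def cds(self) -> tuple[int, int]:
        return (self.cds_start, self.cds_end)

    @property
    def utr3(self) -> tuple[int, int]:
        return (self.cds_end, self.length)


@dataclass(frozen=True, order=True)
class LibraryKey:
    """Identifies one sequencing library: stage x type x replicate."""

    stage: str
    lib_type: str  # "CT" (fragmented total RNA control) or "FP" (footprints)
    replicate: int

    def __post_init__(self) -> None:
        if self.lib_type not in ("CT", "FP"):
            raise ValueError(f"library type must be CT or FP, got {self.lib_type!r}")

    @property
    def label(self) -> str:
        return f"{self.stage}{self.lib_type}_{self.replicate}"

    @classmethod
    def from_label(cls, label: str) -> "LibraryKey":
        m = re.fullmatch(r"(.+?)(CT|FP)_(\d+)", label)
        if m is None:
            raise ValueError(f"cannot parse library label {label!r}")
        return cls(m.group(1), m.group(2), int(m.group(3)))


@dataclass(frozen=True)
class ReadHit:
    """One exact full-length occurrence of a read on a transcript."""

    read_id: str
    transcript_id: str
    start: int
    length: int


@dataclass
class CountMatrix:
    """Raw hit counts per transcript per library, rDNA rows excluded.

    ``total_mapped`` per library is the column sum over retained transcripts
    (a multi-mapped read contributes once per transcript it hit).
    """

    counts: pd.DataFrame  # index: transcript_id, columns: library labels
    libraries: list[LibraryKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.libraries:
            self.libraries = [LibraryKey.from_label(c) for c in self.counts.columns]

    @property
    def total_mapped(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def column(self, key: LibraryKey) -> pd.Series:
        return self.counts[key.label]


def models_by_id(models: Iterable[TranscriptModel]) -> Mapping[str, TranscriptModel]:
    out: dict[str, TranscriptModel] = {}
    for m in models:
        if m.transcript_id in out:
            raise ValueError(f"duplicate transcript id {m.transcript_id}")
        out[m.transcript_id] = m
    return out
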