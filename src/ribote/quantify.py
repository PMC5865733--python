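"""RPKM normalization, replicate averaging and region-level coverage.

RPKM = count x 10^9 / (transcript length in nt x total mapped reads in the
library); replicate averaging is of RPKMs, then an optional floor (default
0.1) is applied so that the FP/CT ratio is defined for every transcript and
the degenerate both-at-floor case yields TE exactly 1.00.

Region coverage assigns each hit to 5'UTR/CDS/3'UTR by base majority
(5'-most region wins exact ties; alternatively by 5'-end position) and
normalizes footprint-to-control region ratios so the CDS reads 1.00.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .models import TranscriptModel, ReadHit, CountMatrix, LibraryKey
from .utils import round_half_away

REGIONS = ("utr5", "cds", "utr3")
DEFAULT_RPKM_FLOOR = 0.1


@dataclass
class ExpressionTable:
    """Per-library RPKM plus replicate-averaged values per (stage, type)."""

    rpkm: pd.DataFrame                # index transcript, columns library labels
    rep_avg: pd.DataFrame | None = None  # columns (stage, type) MultiIndex
    floor_value: float = DEFAULT_RPKM_FLOOR
    floor_applied: bool = False


def rpkm(counts: CountMatrix, lengths: Mapping[str, int]) -> ExpressionTable:
    total = counts.total_mapped
    zero = total[total <= 0]
    if len(zero):
        raise ValueError(f"zero mapped reads in library {zero.index[0]}")
    L = pd.Series({t: lengths[t] for t in counts.counts.index}, dtype=float)
    if (L <= 0).any():
        raise ValueError("non-positive transcript length")
    values = counts.counts.astype(float).mul(1e9).div(L, axis=0).div(total, axis=1)
    return ExpressionTable(values)


def average_replicates(table: ExpressionTable,
                       floor_value: float = DEFAULT_RPKM_FLOOR,
                       apply_floor: bool = True) -> ExpressionTable:
    """Mean RPKM over replicates per (stage, type); optional floor after."""
    cols = [LibraryKey.from_label(c) for c in table.rpkm.columns]
    groups: dict[tuple[str, str], list[str]] = {}
    for key in cols:
        groups.setdefault((key.stage, key.lib_type), []).append(key.label)
    avg = pd.DataFrame(
        {grp: table.rpkm[labels].mean(axis=1) for grp, labels in groups.items()})
    avg.columns = pd.MultiIndex.from_tuples(avg.columns, names=["stage", "type"])
    if apply_floor:
        avg = avg.clip(lower=floor_value)
    return ExpressionTable(table.rpkm, avg, floor_value, apply_floor)


def assign_region(hit: ReadHit, model: TranscriptModel,
                  by_five_prime_end: bool = False) -> str:
    """Region holding the majority of the read's bases (tie: 5'-most)."""
    if hit.length <= 0:
        raise ValueError("zero-length read")
    if hit.start < 0 or hit.start + hit.length > model.length:
        raise ValueError(f"hit [{hit.start}, {hit.start + hit.length}) off transcript "
                         f"{model.transcript_id} of length {model.length}")
    if by_five_prime_end:
        pos = hit.start
        for name, (a, b) in zip(REGIONS, (model.utr5, model.cds, model.utr3)):
            if a <= pos < b:
                return name
        raise AssertionError("unreachable")
    s, e = hit.start, hit.start + hit.length
    overlaps = [max(0, min(e, b) - max(s, a))
                for (a, b) in (model.utr5, model.cds, model.utr3)]
    return REGIONS[int(np.argmax(overlaps))]  # argmax takes first maximum: 5'-most


def region_counts(hits: Iterable[ReadHit], models: Mapping[str, TranscriptModel],
                  by_five_prime_end: bool = False) -> pd.DataFrame:
    """Per-transcript counts of hits per region (columns utr5/cds/utr3)."""
    tally: dict[str, np.ndarray] = {}
    for h in hits:
        row = tally.setdefault(h.transcript_id, np.zeros(3, dtype=int))
        region = assign_region(h, models[h.transcript_id], by_five_prime_end)
        row[REGIONS.index(region)] += 1
    df = pd.DataFrame.from_dict(tally, orient="index", columns=list(REGIONS))
    return df.astype(int)


@dataclass
class RegionRatioRow:
    """CDS-normalized FP/CT ratios for one transcript (CDS fixed at 1.00)."""

    transcript_id: str
    ct: tuple[int, int, int]
    fp: tuple[int, int, int]
    utr5_ratio: float | None
    cds_ratio: float | None
    utr3_ratio: float | None
    computable: bool
    undefined_regions: tuple[str, ...] = ()


def region_ratio_row(transcript_id: str,
                     ct_counts: tuple[int, int, int],
                     fp_counts: tuple[int, int, int]) -> RegionRatioRow:
    """(FP_region/CT_region) / (FP_cds/CT_cds), 2 decimals.

    FP_region = 0 gives 0.00 outright; CT_region = 0 with FP_region > 0 is
    flagged undefined; a zero CDS count in either library makes the whole
    row non-computable.
    """
    ct_u5, ct_cds, ct_u3 = ct_counts
    fp_u5, fp_cds, fp_u3 = fp_counts
    if ct_cds <= 0 or fp_cds <= 0:
        return RegionRatioRow(transcript_id, ct_counts, fp_counts,
                              None, None, None, computable=False)
    cds_scale = fp_cds / ct_cds
    ratios: dict[str, float | None] = {}
    undefined: list[str] = []
    for name, fp_n, ct_n in (("utr5", fp_u5, ct_u5), ("utr3", fp_u3, ct_u3)):
        if fp_n == 0:
            ratios[name] = 0.00
        elif ct_n == 0:
            ratios[name] = None
            undefined.append(name)
        else:
            ratios[name] = round_half_away((fp_n / ct_n) / cds_scale, 2)
    return RegionRatioRow(transcript_id, ct_counts, fp_counts,
                          ratios["utr5"], 1.00, ratios["utr3"],
                          computable=True, undefined_regions=tuple(undefined))


def region_ratio_table(ct_region_counts: pd.DataFrame,
                       fp_region_counts: pd.DataFrame) -> pd.DataFrame:
    """Table of CDS-normalized region ratios over the shared transcript set."""
    rows = []
    for tid in ct_region_counts.index.intersection(fp_region_counts.index):
        ct = tuple(int(x) for x in ct_region_counts.loc[tid, list(REGIONS)])
        fp = tuple(int(x) for x in fp_region_counts.loc[tid, list(REGIONS)])
        r = region_ratio_row(tid, ct, fp)
        rows.append({
            "transcript_id": tid,
            "ct_utr5": ct[0], "ct_cds": ct[1], "ct_utr3": ct[2],
            "fp_utr5": fp[0], "fp_cds": fp[1], "fp_utr3": fp[2],
            "utr5_ratio": r.utr5_ratio, "cds_ratio": r.cds_ratio,
            "utr3_ratio": r.utr3_ratio, "computable": r.computable,
        })
    return pd.DataFrame(rows).set_index("transcript_id") if rows else pd.DataFrame()
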