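"""Organelle-homology flagging and chloroplast CDS translational profiling.

A nuclear gene model is flagged against an organelle genome when its best
local alignment (either strand) reaches >= 90% identity over >= 75% of its
CDS length (both thresholds inclusive).  Identity counts matching columns
over all alignment columns including gaps; coverage is aligned CDS bases
over CDS length.

Chloroplast profiling aligns reads to the extracted chloroplast CDS
sequences with the same exact-match engine as the nuclear stage and
normalizes RPKM by the *nuclear* mapped totals, so organelle expression is
expressed on the same per-library scale as the gene models.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from skbio import DNA
from skbio.alignment import pair_align

from .align import build_index, align_reads, count_hits
from .models import LibraryKey, ReadHit
from .quantify import average_replicates, DEFAULT_RPKM_FLOOR
from .utils import reverse_complement, round_half_away

MIN_IDENTITY = 0.90
MIN_COVERAGE = 0.75
# local alignment scoring: match +1, mismatch -2, gap -2.5
SUB_SCORE = (1.0, -2.0)
GAP_COST = 2.5


@dataclass
class OrganelleFlag:
    gene_id: str
    identities: dict[str, float]   # organelle -> best identity fraction
    coverages: dict[str, float]    # organelle -> CDS coverage fraction
    verdict: str                   # chloroplast / mitochondria / both / neither


def _best_local(cds: str, genome: str) -> tuple[float, float]:
    """(identity, CDS coverage) of the best-scoring local alignment over
    both strands of the genome."""
    best = (0.0, 0.0, float("-inf"))
    for target in (genome, reverse_complement(genome)):
        res = pair_align(DNA(cds), DNA(target), mode="local",
                         sub_score=SUB_SCORE, gap_cost=GAP_COST)
        if not res.paths or res.score <= best[2]:
            continue
        path = res.paths[0]
        aligned = path.to_aligned((DNA(cds), DNA(target)))
        a, b = str(aligned[0]), str(aligned[1])
        cols = len(a)
        if cols == 0:
            continue
        matches = sum(x == y and x != "-" for x, y in zip(a, b))
        (q0, q1), _ = path.ranges
        best = (matches / cols, (q1 - q0) / len(cds), float(res.score))
    return best[0], best[1]


def flag_organelle_homology(gene_id: str, cds_seq: str,
                            organelle_genomes: Mapping[str, str],
                            min_identity: float = MIN_IDENTITY,
                            min_coverage: float = MIN_COVERAGE) -> OrganelleFlag:
    """Apply the identity/coverage threshold rule against each organelle."""
    if not cds_seq:
        raise ValueError("empty CDS sequence")
    identities: dict[str, float] = {}
    coverages: dict[str, float] = {}
    passing: list[str] = []
    for org, genome in organelle_genomes.items():
        ident, cov = _best_local(cds_seq, genome)
        identities[org] = ident
        coverages[org] = cov
        if ident >= min_identity and cov >= min_coverage:
            passing.append(org)
    if len(passing) >= 2:
        verdict = "both"
    elif passing:
        verdict = {"chloroplast": "chloroplast",
                   "mitochondrion": "mitochondria"}.get(passing[0], passing[0])
    else:
        verdict = "neither"
    return OrganelleFlag(gene_id, identities, coverages, verdict)


def flag_table(flags: Iterable[OrganelleFlag]) -> pd.DataFrame:
    rows = []
    for f in flags:
        rows.append({
            "gene_id": f.gene_id,
            "cp_identity": f.identities.get("chloroplast", 0.0),
            "cp_coverage": f.coverages.get("chloroplast", 0.0),
            "mt_identity": f.identities.get("mitochondrion", 0.0),
            "mt_coverage": f.coverages.get("mitochondrion", 0.0),
            "verdict": f.verdict,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def chloroplast_profile(reads_by_library: Mapping[LibraryKey, Iterable[tuple[str, str]]],
                        cds_sequences: Mapping[str, str],
                        nuclear_total_mapped: Mapping[str, int],
                        floor_value: float = DEFAULT_RPKM_FLOOR,
                        seed_length: int = 20) -> pd.DataFrame:
    """Per chloroplast CDS per stage: ct_rpkm, fp_rpkm, te.

    RPKM denominators are the nuclear mapped totals per library, never the
    chloroplast-mapped totals.
    """
    index = build_index(cds_sequences, k=seed_length)
    hits: dict[LibraryKey, list[ReadHit]] = {}
    for key, reads in reads_by_library.items():
        if key.label not in nuclear_total_mapped:
            raise ValueError(f"missing nuclear mapped total for {key.label}")
        hits[key], _ = align_reads(reads, index)

    from .models import TranscriptModel
    models = [TranscriptModel(cid, len(s), 0, len(s))
              for cid, s in cds_sequences.items()]
    counts = count_hits(hits, models)
    keys = sorted(hits)
    lengths = pd.Series({cid: float(len(s)) for cid, s in cds_sequences.items()})
    rpkm_df = counts.counts.astype(float).mul(1e9).div(lengths, axis=0)
    for key in keys:
        total = nuclear_total_mapped[key.label]
        if total <= 0:
            raise ValueError(f"non-positive nuclear total for {key.label}")
        rpkm_df[key.label] /= total

    from .quantify import ExpressionTable
    avg = average_replicates(ExpressionTable(rpkm_df), floor_value=floor_value,
                             apply_floor=True).rep_avg
    stages = list(dict.fromkeys(k.stage for k in keys))
    rows = []
    for cid in rpkm_df.index:
        for stage in stages:
            ct = float(avg.loc[cid, (stage, "CT")])
            fp = float(avg.loc[cid, (stage, "FP")])
            rows.append({"cds_id": cid, "stage": stage,
                         "ct_rpkm": ct, "fp_rpkm": fp,
                         "te": fp / ct,
                         "te_rounded": round_half_away(fp / ct, 2)})
    return pd.DataFrame(rows)
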