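"""Seeded synthetic transcriptomes and CT/FP read libraries with ground truth.

The generator emulates the statistical structure of cotyledon ribosome
profiling data: control (CT) libraries are fragmented total RNA with read
lengths fairly uniform over 26-28 nt, footprint (FP) libraries peak at
31-33 nt within the 26-34 nt size selection, footprint reads concentrate in
the CDS with only a small leakage fraction starting in the UTRs, a large
configurable share of reads derives from rDNA-annotated models, and a few
nuclear models are near-identity copies of organelle genes.

Every library draw is deterministic given ``(seed, stage, type, replicate)``.
Truth abundances are expressed directly as expected control RPKM, and
``te_true`` is the exact estimand of the downstream FP/CT RPKM ratio (see
docs/methods.md for the per-stage rescaling that makes this hold).
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import TranscriptModel, LibraryKey

BASES = np.array(list("ACGT"))

#: classes of simulated genes; "organelle" marks organelle-genome CDS read
#: sources (ids prefixed with the organelle name), which never appear in the
#: nuclear transcript set.
GENE_CLASSES = (
    "ordinary", "high_te_early", "low_te", "storage_like",
    "rdna", "organelle_homolog", "organelle",
)

DEFAULT_ADAPTER = "CTGTAGGCACCATCAAT"

# control fragments: fairly uniform 26-28 nt mode; footprints: 31-33 nt peak
DEFAULT_CT_LENGTH_DIST = {
    26: 0.17, 27: 0.17, 28: 0.17, 29: 0.11, 30: 0.09,
    31: 0.08, 32: 0.08, 33: 0.07, 34: 0.06,
}
DEFAULT_FP_LENGTH_DIST = {
    26: 0.02, 27: 0.03, 28: 0.05, 29: 0.07, 30: 0.10,
    31: 0.22, 32: 0.25, 33: 0.18, 34: 0.08,
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_genes: int = 120
    utr5_len_range: tuple[int, int] = (60, 200)
    cds_len_range: tuple[int, int] = (300, 1500)
    utr3_len_range: tuple[int, int] = (60, 250)
    n_rdna_models: int = 4
    n_organelle_genes: Mapping[str, int] = field(
        default_factory=lambda: {"chloroplast": 6, "mitochondrion": 3})
    organelle_genome_length: Mapping[str, int] = field(
        default_factory=lambda: {"chloroplast": 12000, "mitochondrion": 18000})
    organelle_copy_identities: Sequence[float] = (1.0, 0.85)
    n_paralog_pairs: int = 1
    stages: Sequence[str] = ("C25", "C100", "C300")
    replicates: int = 2
    reads_per_library: int = 100_000
    ct_length_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CT_LENGTH_DIST))
    fp_length_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FP_LENGTH_DIST))
    utr_leakage: float = 0.05
    rrna_fraction: float = 0.3
    error_rate: float = 0.0
    adapter: str = DEFAULT_ADAPTER
    append_adapter: bool = True
    # log10-normal control abundance (expected control RPKM)
    abundance_log10_mean: float = 0.9
    abundance_log10_sd: float = 0.7
    # class composition of nuclear genes (remainder is ordinary)
    frac_high_te_early: float = 0.10
    frac_low_te: float = 0.10
    frac_storage_like: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        for name in ("utr5_len_range", "cds_len_range", "utr3_len_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} is degenerate: ({lo}, {hi})")
        if self.cds_len_range[0] < 36:
            raise ConfigurationError("cds_len_range must allow a full footprint (>= 36 nt)")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.reads_per_library <= 0:
            raise ConfigurationError("reads_per_library must be positive")
        if not 0.0 <= self.rrna_fraction <= 1.0:
            raise ConfigurationError("rrna_fraction must lie in [0, 1]")
        if not 0.0 <= self.utr_leakage <= 1.0:
            raise ConfigurationError("utr_leakage must lie in [0, 1]")
        for name in ("ct_length_dist", "fp_length_dist"):
            dist = getattr(self, name)
            if any(not 26 <= l <= 34 for l in dist):
                raise ConfigurationError(f"{name} has lengths outside 26-34 nt")
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ConfigurationError(f"{name} does not sum to 1")
        for f in self.organelle_copy_identities:
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("copy identities must lie in [0, 1]")


@dataclass
class Transcriptome:
    """Sequences, models, organelle genomes and truth for one simulation."""

    sequences: dict[str, str]                 # nuclear transcript id -> cDNA
    models: list[TranscriptModel]
    organelle_genomes: dict[str, str]         # organelle name -> genome
    organelle_cds: dict[str, tuple[int, int]] # cds id -> (start, end) on genome
    truth: pd.DataFrame                       # SimulationTruth table
    config: SimulationConfig

    def model_map(self) -> dict[str, TranscriptModel]:
        return {m.transcript_id: m for m in self.models}


def _rng_for(seed: int, *tokens) -> np.random.Generator:
    """Independent stream keyed by arbitrary tokens, stable across runs."""
    digest = hashlib.sha256(("|".join(map(str, tokens))).encode()).digest()
    child = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng([seed, child])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _mutate_to_identity(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute a (1-identity) fraction of positions, no indels."""
    n = len(seq)
    n_mut = int(round(n * (1.0 - identity)))
    out = list(seq)
    for i in rng.choice(n, size=n_mut, replace=False):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def build_transcriptome(config: SimulationConfig) -> Transcriptome:
    """Generate nuclear transcripts, organelle genomes and ground truth.

    Nuclear gene classes follow configured fractions; one nuclear near-copy
    of an organelle CDS is added per entry in ``organelle_copy_identities``
    (class ``organelle_homolog``); ``n_paralog_pairs`` duplicate full
    transcripts under new gene ids to exercise multi-mapping.
    """
    config.validate()
    rng = _rng_for(config.seed, "transcriptome")

    sequences: dict[str, str] = {}
    models: list[TranscriptModel] = []
    rows: list[dict] = []

    # --- organelle genomes first (nuclear near-copies depend on them)
    organelle_genomes: dict[str, str] = {}
    organelle_cds: dict[str, tuple[int, int]] = {}
    for org, n_cds in config.n_organelle_genes.items():
        glen = config.organelle_genome_length[org]
        genome = _random_seq(rng, glen)
        organelle_genomes[org] = genome
        if n_cds == 0:
            continue
        slot = glen // n_cds
        for j in range(n_cds):
            clen = int(rng.integers(config.cds_len_range[0],
                                    min(config.cds_len_range[1], slot - 10) + 1))
            start = j * slot + int(rng.integers(0, max(1, slot - clen)))
            organelle_cds[f"{org}:cds{j + 1}"] = (start, start + clen)

    # --- nuclear gene class assignment
    n = config.n_genes
    n_high = int(round(n * config.frac_high_te_early))
    n_low = int(round(n * config.frac_low_te))
    n_stor = int(round(n * config.frac_storage_like))
    classes = (["high_te_early"] * n_high + ["low_te"] * n_low
               + ["storage_like"] * n_stor)
    classes += ["ordinary"] * (n - len(classes))
    rng.shuffle(classes)

    def make_structure(cds_seq: str | None = None):
        u5 = int(rng.integers(*config.utr5_len_range, endpoint=True))
        u3 = int(rng.integers(*config.utr3_len_range, endpoint=True))
        if cds_seq is None:
            clen = int(rng.integers(*config.cds_len_range, endpoint=True))
            cds_seq = _random_seq(rng, clen)
        seq = _random_seq(rng, u5) + cds_seq + _random_seq(rng, u3)
        return seq, u5, u5 + len(cds_seq)

    for i, cls in enumerate(classes):
        tid = f"Syn.{i + 1:04d}G.1"
        seq, a, b = make_structure()
        sequences[tid] = seq
        models.append(TranscriptModel(tid, len(seq), a, b))
        rows.append({"transcript_id": tid, "class": cls, "paralog": False})

    # --- nuclear near-copies of organelle genes
    cds_ids = sorted(organelle_cds)
    for j, ident in enumerate(config.organelle_copy_identities):
        if not cds_ids:
            break
        src = cds_ids[j % len(cds_ids)]
        org = src.split(":")[0]
        s, e = organelle_cds[src]
        cds_seq = _mutate_to_identity(rng, organelle_genomes[org][s:e], ident)
        tid = f"Syn.OH{j + 1:02d}G.1"
        seq, a, b = make_structure(cds_seq)
        sequences[tid] = seq
        models.append(TranscriptModel(tid, len(seq), a, b))
        rows.append({"transcript_id": tid, "class": "organelle_homolog",
                     "paralog": False, "copy_identity": ident, "copy_source": src})

    # --- paralog duplications (identical sequence, new gene id)
    ordinary = [r["transcript_id"] for r in rows if r["class"] == "ordinary"]
    for j in range(min(config.n_paralog_pairs, len(ordinary))):
        src = ordinary[j]
        tid = f"Syn.P{j + 1:03d}G.1"
        m = next(m for m in models if m.transcript_id == src)
        sequences[tid] = sequences[src]
        models.append(TranscriptModel(tid, m.length, m.cds_start, m.cds_end))
        rows.append({"transcript_id": tid, "class": "ordinary", "paralog": True})
        for r in rows:
            if r["transcript_id"] == src:
                r["paralog"] = True

    # --- rDNA-tagged models (ordinary sequences; contamination is modelled
    #     at read sampling, not by sequence similarity)
    for j in range(config.n_rdna_models):
        tid = f"Syn.rDNA{j + 1:02d}G.1"
        seq, a, b = make_structure()
        sequences[tid] = seq
        models.append(TranscriptModel(tid, len(seq), a, b, is_rdna=True))
        rows.append({"transcript_id": tid, "class": "rdna", "paralog": False})

    base = pd.DataFrame(rows)
    truth = _assign_truth(base, sequences, organelle_cds, config, rng)
    return Transcriptome(sequences, models, organelle_genomes, organelle_cds,
                         truth, config)


def _assign_truth(base: pd.DataFrame, sequences: Mapping[str, str],
                  organelle_cds: Mapping[str, tuple[int, int]],
                  config: SimulationConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Per-(transcript, stage) latent abundances and TE trajectories.

    ``ct_abundance`` is expected control RPKM.  After drawing, abundances and
    TEs are rescaled per stage so that (i) the expected control RPKM of a
    transcript equals its stored ct_abundance exactly and (ii) footprint and
    control library weights match, making te_true the exact estimand of the
    FP/CT RPKM ratio.  rDNA rows carry no TE (excluded downstream).
    """
    stages = list(config.stages)
    extra_cols = [c for c in ("copy_identity", "copy_source") if c in base]
    records: list[dict] = []
    for _, row in base.iterrows():
        tid, cls = row["transcript_id"], row["class"]
        extras = {c: row[c] for c in extra_cols}
        if cls == "rdna":
            for s in stages:
                records.append({"transcript_id": tid, "stage": s, "class": cls,
                                "paralog": row["paralog"],
                                "ct_abundance": np.nan, "te_true": np.nan,
                                **extras})
            continue
        base_ab = 10.0 ** rng.normal(config.abundance_log10_mean,
                                     config.abundance_log10_sd)
        if cls in ("low_te", "organelle_homolog"):
            base_ab = max(base_ab, 10.0 ** rng.uniform(1.3, 2.3))  # CT >= 10 RPKM side
        elif cls == "high_te_early":
            base_ab = max(base_ab, 10.0 ** rng.uniform(0.7, 1.7))
        elif cls == "storage_like":
            base_ab = max(base_ab, 10.0 ** rng.uniform(1.5, 2.8))
        for k, s in enumerate(stages):
            ab = base_ab * 10.0 ** rng.normal(0.0, 0.1)
            if cls == "storage_like":
                # mRNA peaks mid-stage, as for major seed storage proteins
                ab *= (0.3, 1.0, 0.8)[min(k, 2)]
                te = (0.4, 0.7, 1.3)[min(k, 2)] * 10.0 ** rng.normal(0.0, 0.05)
            elif cls == "high_te_early":
                te = (rng.uniform(6.0, 25.0) if k == 0
                      else 10.0 ** rng.normal(0.0, 0.1))
            elif cls in ("low_te", "organelle_homolog"):
                te = rng.uniform(0.02, 0.08)
            else:
                te = 10.0 ** rng.normal(0.0, 0.15)
            records.append({"transcript_id": tid, "stage": s, "class": cls,
                            "paralog": row["paralog"], "ct_abundance": ab,
                            "te_true": te, **extras})

    # organelle-genome CDS read sources: modest abundance, very low TE
    for cid, (s0, e0) in sorted(organelle_cds.items()):
        base_ab = 10.0 ** rng.uniform(1.0, 2.0)
        for s in stages:
            records.append({"transcript_id": cid, "stage": s, "class": "organelle",
                            "paralog": False,
                            "ct_abundance": base_ab * 10.0 ** rng.normal(0.0, 0.1),
                            "te_true": rng.uniform(0.03, 0.08)})

    truth = pd.DataFrame.from_records(records)
    lengths = {tid: len(seq) for tid, seq in sequences.items()}
    for cid, (s0, e0) in organelle_cds.items():
        lengths[cid] = e0 - s0
    nuclear = truth["class"].isin(("ordinary", "high_te_early", "low_te",
                                   "storage_like", "organelle_homolog"))
    for s in stages:
        st = truth["stage"] == s
        L = truth.loc[st, "transcript_id"].map(lengths).to_numpy(float)
        a = truth.loc[st, "ct_abundance"].to_numpy(float)
        te = truth.loc[st, "te_true"].to_numpy(float)
        nuc = nuclear[st].to_numpy()
        w_nuc = np.nansum(a[nuc] * L[nuc])
        # expected control RPKM equals ct_abundance: scale so sum(a*L)=1e9
        truth.loc[st, "ct_abundance"] = a * (1e9 / w_nuc)
        # footprint library weight matches control weight: te estimand exact
        w_all_ct = np.nansum(a * L)
        w_all_fp = np.nansum(te * a * L)
        truth.loc[st, "te_true"] = te * (w_all_ct / w_all_fp)
    return truth


# ---------------------------------------------------------------------------
# read simulation


def _draw_lengths(rng, dist: Mapping[int, float], n: int) -> np.ndarray:
    lengths = np.array(sorted(dist))
    probs = np.array([dist[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(lengths, size=n, p=probs)


def simulate_library(truth: pd.DataFrame, transcriptome: Transcriptome,
                     library_type: str, stage: str, replicate: int,
                     config: SimulationConfig | None = None,
                     ) -> list[tuple[str, str]]:
    """Draw one library of exact-substring reads; returns (read_id, seq) pairs.

    Read ids embed the source transcript (``stage TYPE rep:i:source``) so
    downstream truth-based accounting never needs a separate lookup.  Reads
    are exact substrings unless ``error_rate > 0``, matching the
    zero-mismatch alignment policy downstream.
    """
    config = config or transcriptome.config
    if library_type not in ("CT", "FP"):
        raise ValueError(f"library_type must be CT or FP, got {library_type!r}")
    if stage not in config.stages:
        raise ValueError(f"unknown stage {stage!r}; configured: {list(config.stages)}")
    rng = _rng_for(config.seed, "library", stage, library_type, replicate)

    st = truth[truth["stage"] == stage].set_index("transcript_id")
    model_map = transcriptome.model_map()
    lengths: dict[str, int] = {tid: len(s) for tid, s in transcriptome.sequences.items()}
    seqs: dict[str, str] = dict(transcriptome.sequences)
    # organelle CDS sources
    for cid, (s0, e0) in transcriptome.organelle_cds.items():
        org = cid.split(":")[0]
        seqs[cid] = transcriptome.organelle_genomes[org][s0:e0]
        lengths[cid] = e0 - s0

    rdna_ids = [m.transcript_id for m in transcriptome.models if m.is_rdna]
    source_ids = [t for t in st.index if st.loc[t, "class"] not in ("rdna",)]
    missing = [t for t in source_ids if t not in seqs]
    if missing:
        raise ValueError(f"truth covers unknown transcripts: {missing[:3]}")

    n_total = config.reads_per_library
    n_rdna = rng.binomial(n_total, config.rrna_fraction) if rdna_ids else 0
    n_usable = n_total - n_rdna

    ab = st.loc[source_ids, "ct_abundance"].to_numpy(float)
    te = st.loc[source_ids, "te_true"].to_numpy(float)
    L = np.array([lengths[t] for t in source_ids], dtype=float)
    w = ab * L if library_type == "CT" else te * ab * L
    if not np.all(np.isfinite(w)) or w.sum() <= 0:
        raise ValueError("degenerate abundance weights for this library")
    counts = rng.multinomial(n_usable, w / w.sum())

    max_len = max(max(config.ct_length_dist), max(config.fp_length_dist))
    if np.any(L[counts > 0] < max_len):
        raise ValueError("requested reads exceed representable depth on short transcripts")

    dist = config.ct_length_dist if library_type == "CT" else config.fp_length_dist
    reads: list[tuple[str, str]] = []
    serial = 0

    def emit(tid: str, start: int, rlen: int) -> None:
        nonlocal serial
        seq = seqs[tid][start:start + rlen]
        if config.error_rate > 0:
            arr = list(seq)
            for i in range(len(arr)):
                if rng.random() < config.error_rate:
                    arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
            seq = "".join(arr)
        if config.append_adapter and config.adapter:
            seq = seq + config.adapter
        serial += 1
        reads.append((f"{stage}{library_type}{replicate}:{serial:07d}:{tid}", seq))

    for tid, n_reads in zip(source_ids, counts):
        if n_reads == 0:
            continue
        rlens = _draw_lengths(rng, dist, n_reads)
        m = model_map.get(tid)
        tlen = lengths[tid]
        for rlen in rlens:
            rlen = int(rlen)
            if (library_type == "FP" and m is not None
                    and rng.random() >= config.utr_leakage
                    and m.cds_end - m.cds_start >= rlen):
                start = int(rng.integers(m.cds_start, m.cds_end - rlen + 1))
            else:
                start = int(rng.integers(0, tlen - rlen + 1))
            emit(tid, start, rlen)

    if n_rdna:
        rw = np.array([lengths[t] for t in rdna_ids], dtype=float)
        rcounts = rng.multinomial(n_rdna, rw / rw.sum())
        for tid, n_reads in zip(rdna_ids, rcounts):
            rlens = _draw_lengths(rng, dist, n_reads)
            for rlen in rlens:
                rlen = int(rlen)
                start = int(rng.integers(0, lengths[tid] - rlen + 1))
                emit(tid, start, rlen)

    return reads


def all_library_keys(config: SimulationConfig) -> list[LibraryKey]:
    return [LibraryKey(s, t, r)
            for s in config.stages
            for t in ("CT", "FP")
            for r in range(1, config.replicates + 1)]


def simulate_all_libraries(transcriptome: Transcriptome,
                           ) -> dict[LibraryKey, list[tuple[str, str]]]:
    cfg = transcriptome.config
    return {key: simulate_library(transcriptome.truth, transcriptome,
                                  key.lib_type, key.stage, key.replicate, cfg)
            for key in all_library_keys(cfg)}
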