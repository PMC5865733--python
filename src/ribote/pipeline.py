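"""End-to-end orchestration: simulate -> trim -> align -> quantify -> test ->
filter -> cluster -> organelle -> report.

Every stage is a function over a run directory with flat TSV contracts, so
stages can be re-run individually (the CLI maps onto them 1:1) and a full
run is reproducible from its manifest.  Read accounting (total, trimmed,
rDNA-removed, mapped) is logged at every stage.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import io as rio
from .align import align_reads, build_index, count_hits, exclude_rdna
from .models import CountMatrix, LibraryKey, gene_id_of, models_by_id
from .quantify import (ExpressionTable, average_replicates, region_counts,
                       region_ratio_table, rpkm)
from .simulate import (SimulationConfig, Transcriptome, build_transcriptome,
                       simulate_all_libraries, DEFAULT_ADAPTER)
from .te import (FilterCriteria, collapse_unique_genes, expressed_counts,
                 filter_transcripts, percentage, te_table)
from .cluster import (drop_zero_variance, kmeans_cluster, replicate_correlations,
                      summarize_clusters)
from .organelle import chloroplast_profile, flag_organelle_homology, flag_table

log = logging.getLogger("ribote")

DEFAULT_TRIM_MIN_LEN = 20
ADAPTER_MIN_SUFFIX = 6


@dataclass
class PipelineConfig:
    """All analysis parameters, each defaulting to the study's value."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    max_multimap: int = 25
    mismatches: int = 0
    seed_length: int = 20
    rpkm_floor: float = 0.1
    apply_floor: bool = True
    expressed_threshold: float = 1.0
    high_te: FilterCriteria = field(default_factory=FilterCriteria.high_te)
    low_te: FilterCriteria = field(default_factory=FilterCriteria.low_te)
    k_clusters: int = 3
    cluster_seed: int = 0
    cluster_max_iter: int = 5_000_000
    adapter: str = DEFAULT_ADAPTER
    trim_min_len: int = DEFAULT_TRIM_MIN_LEN
    region_table_top_n: int = 10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        if isinstance(sim, Mapping):
            sim = dict(sim)
            for key in ("utr5_len_range", "cds_len_range", "utr3_len_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            for key in ("ct_length_dist", "fp_length_dist"):
                if key in sim:
                    sim[key] = {int(k): float(v) for k, v in sim[key].items()}
            for key in ("stages", "organelle_copy_identities"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        for name in ("high_te", "low_te"):
            if isinstance(data.get(name), Mapping):
                data[name] = FilterCriteria(**data[name])
        return cls(simulation=sim, **data)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=False)


# ---------------------------------------------------------------------------
# adapter trimming


def trim_adapter(reads: Iterable[tuple[str, str]],
                 adapter: str = DEFAULT_ADAPTER,
                 min_len: int = DEFAULT_TRIM_MIN_LEN,
                 ) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Exact-match adapter trimming.

    Truncate at the first full internal occurrence of the adapter, else at a
    terminal prefix of the adapter (>= 6 nt) at the read's 3' end.  Reads
    shorter than ``min_len`` after trimming are dropped and counted.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    out: list[tuple[str, str]] = []
    stats = {"input": 0, "trimmed": 0, "untrimmed": 0, "dropped_short": 0}
    for rid, seq in reads:
        stats["input"] += 1
        pos = seq.find(adapter)
        if pos < 0:
            for n in range(min(len(adapter) - 1, len(seq)), ADAPTER_MIN_SUFFIX - 1, -1):
                if seq.endswith(adapter[:n]):
                    pos = len(seq) - n
                    break
        if pos >= 0:
            stats["trimmed"] += 1
            seq = seq[:pos]
        else:
            stats["untrimmed"] += 1
        if len(seq) < min_len:
            stats["dropped_short"] += 1
        else:
            out.append((rid, seq))
    return out, stats


# ---------------------------------------------------------------------------
# stages (file contracts against a run directory)


def _fixture_dir(run_dir: Path) -> Path:
    return Path(run_dir) / "fixture"


def stage_simulate(config: PipelineConfig, run_dir: Path) -> Transcriptome:
    tr = build_transcriptome(config.simulation)
    libraries = simulate_all_libraries(tr)
    rio.write_fixture(tr, libraries, _fixture_dir(run_dir))
    log.info("simulate: %d transcripts, %d libraries x %d reads",
             len(tr.models), len(libraries), config.simulation.reads_per_library)
    return tr


def _library_keys(run_dir: Path) -> list[LibraryKey]:
    reads_dir = _fixture_dir(run_dir) / "reads"
    return sorted(LibraryKey.from_label(p.stem) for p in reads_dir.glob("*.fastq"))


def stage_trim(config: PipelineConfig, run_dir: Path) -> None:
    run_dir = Path(run_dir)
    trimmed_dir = run_dir / "trimmed"
    trimmed_dir.mkdir(parents=True, exist_ok=True)
    all_stats = []
    for key in _library_keys(run_dir):
        reads = rio.read_fastq(_fixture_dir(run_dir) / "reads" / f"{key.label}.fastq")
        trimmed, stats = trim_adapter(reads, config.adapter, config.trim_min_len)
        rio.write_fastq(trimmed_dir / f"{key.label}.fastq", trimmed)
        assert stats["input"] == len(trimmed) + stats["dropped_short"]
        all_stats.append({"library": key.label, **stats})
        log.info("trim %s: %d in, %d trimmed, %d dropped short",
                 key.label, stats["input"], stats["trimmed"], stats["dropped_short"])
    pd.DataFrame(all_stats).to_csv(run_dir / "trim_stats.tsv", sep="\t", index=False)


def stage_align(config: PipelineConfig, run_dir: Path) -> CountMatrix:
    """Align trimmed reads, drop rDNA models/hits, count, write region counts."""
    run_dir = Path(run_dir)
    fixture = _fixture_dir(run_dir)
    sequences = rio.read_fasta(fixture / "transcripts.fasta")
    models = rio.read_gff3(fixture / "annotation.gff3")
    index = build_index(sequences, k=config.seed_length)
    model_map = models_by_id(models)

    hits_by_lib = {}
    align_stats = []
    region_frames = {}
    for key in _library_keys(run_dir):
        path = run_dir / "trimmed" / f"{key.label}.fastq"
        if not path.exists():  # untrimmed fallback
            path = fixture / "reads" / f"{key.label}.fastq"
        reads = rio.read_fastq(path)
        hits, summary = align_reads(reads, index,
                                    max_multimap=config.max_multimap,
                                    mismatches_allowed=config.mismatches)
        retained_models, retained_hits, n_rdna_models = exclude_rdna(models, hits)
        n_rdna_hits = summary.n_hits - len(retained_hits)
        hits_by_lib[key] = retained_hits
        align_stats.append({
            "library": key.label, **summary.as_dict(),
            "rdna_models_removed": n_rdna_models,
            "rdna_hits_removed": n_rdna_hits,
            "retained_hits": len(retained_hits),
        })
        log.info("align %s: %d reads, %d aligned, %d suppressed, "
                 "%d rDNA hits removed, %d retained",
                 key.label, summary.n_reads, summary.n_aligned,
                 summary.n_suppressed, n_rdna_hits, len(retained_hits))
        region_frames[key.label] = region_counts(retained_hits, model_map)

    retained_models = [m for m in models if not m.is_rdna]
    counts = count_hits(hits_by_lib, retained_models)
    counts.counts.to_csv(run_dir / "counts.tsv", sep="\t",
                         index_label="transcript_id")
    pd.DataFrame(align_stats).to_csv(run_dir / "align_stats.tsv", sep="\t",
                                     index=False)
    regions_dir = run_dir / "region_counts"
    regions_dir.mkdir(exist_ok=True)
    for label, frame in region_frames.items():
        frame.to_csv(regions_dir / f"{label}.tsv", sep="\t",
                     index_label="transcript_id")
    return counts


def _load_counts(run_dir: Path) -> CountMatrix:
    df = pd.read_csv(Path(run_dir) / "counts.tsv", sep="\t",
                     index_col="transcript_id")
    return CountMatrix(df)


def stage_quantify(config: PipelineConfig, run_dir: Path) -> ExpressionTable:
    """RPKM, replicate averages (post-floor), replicate QC, Table-1-style
    region ratio table for the most expressed transcripts."""
    run_dir = Path(run_dir)
    counts = _load_counts(run_dir)
    models = rio.read_gff3(_fixture_dir(run_dir) / "annotation.gff3")
    lengths = {m.transcript_id: m.length for m in models}
    table = rpkm(counts, lengths)
    table = average_replicates(table, floor_value=config.rpkm_floor,
                               apply_floor=config.apply_floor)
    table.rpkm.to_csv(run_dir / "rpkm.tsv", sep="\t", index_label="transcript_id")
    flat = table.rep_avg.copy()
    flat.columns = [f"{s}_{t}" for s, t in flat.columns]
    flat.to_csv(run_dir / "rpkm_rep_avg.tsv", sep="\t", index_label="transcript_id")
    replicate_correlations(table.rpkm).to_csv(run_dir / "replicate_qc.tsv",
                                              sep="\t", index=False)

    # region ratio table at the last stage, replicates summed, top transcripts
    stages = list(config.simulation.stages)
    last = stages[-1]
    regions_dir = run_dir / "region_counts"
    ct_frames, fp_frames = [], []
    for key in counts.libraries:
        if key.stage != last:
            continue
        frame = pd.read_csv(regions_dir / f"{key.label}.tsv", sep="\t",
                            index_col="transcript_id")
        (ct_frames if key.lib_type == "CT" else fp_frames).append(frame)
    if ct_frames and fp_frames:
        ct_sum = sum(f.reindex(counts.counts.index, fill_value=0) for f in ct_frames)
        fp_sum = sum(f.reindex(counts.counts.index, fill_value=0) for f in fp_frames)
        top = (ct_sum.sum(axis=1)
               .sort_values(ascending=False)
               .head(config.region_table_top_n).index)
        ratios = region_ratio_table(ct_sum.loc[top], fp_sum.loc[top])
        ratios.to_csv(run_dir / "region_ratios.tsv", sep="\t")
    log.info("quantify: floor %.2f applied=%s", config.rpkm_floor,
             config.apply_floor)
    return table


def stage_te(config: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    run_dir = Path(run_dir)
    counts = _load_counts(run_dir)
    models = rio.read_gff3(_fixture_dir(run_dir) / "annotation.gff3")
    lengths = {m.transcript_id: m.length for m in models}
    expression = average_replicates(rpkm(counts, lengths),
                                    floor_value=config.rpkm_floor,
                                    apply_floor=config.apply_floor)
    results = te_table(expression, counts, stages=config.simulation.stages)
    results.to_csv(run_dir / "te_table.tsv", sep="\t", index=False)
    log.info("te: %d transcript x stage rows", len(results))
    return results


def _load_te_table(run_dir: Path) -> pd.DataFrame:
    return pd.read_csv(Path(run_dir) / "te_table.tsv", sep="\t")


def stage_filter(config: PipelineConfig, run_dir: Path) -> dict:
    run_dir = Path(run_dir)
    results = _load_te_table(run_dir)
    stages = list(config.simulation.stages)
    sets = {}
    for name, crit in (("high", config.high_te), ("low", config.low_te)):
        per_stage = {s: sorted(filter_transcripts(results, crit, s))
                     for s in stages}
        gs = collapse_unique_genes(per_stage)
        sets[name] = {
            "per_stage": per_stage,
            "per_stage_genes": {s: sorted(g) for s, g in gs.per_stage_genes.items()},
            "union_genes": sorted(gs.union_genes),
        }
        for s in stages:
            sub = results[(results["stage"] == s)
                          & results["transcript_id"].isin(per_stage[s])]
            sub.to_csv(run_dir / f"filter_{name}_{s}.tsv", sep="\t", index=False)
        log.info("filter %s: %s transcripts/stage, %d unique genes", name,
                 {s: len(v) for s, v in per_stage.items()},
                 len(sets[name]["union_genes"]))
    with open(run_dir / "filter_sets.json", "w") as fh:
        json.dump(sets, fh, indent=1)
    return sets


def _load_filter_sets(run_dir: Path) -> dict:
    with open(Path(run_dir) / "filter_sets.json") as fh:
        return json.load(fh)


def stage_cluster(config: PipelineConfig, run_dir: Path) -> None:
    """Cluster TE trajectories of the filtered (high + low) transcripts."""
    run_dir = Path(run_dir)
    results = _load_te_table(run_dir)
    sets = _load_filter_sets(run_dir)
    selected = sorted({t for name in ("high", "low")
                       for s in sets[name]["per_stage"].values() for t in s})
    stages = list(config.simulation.stages)
    profile = (results[results["transcript_id"].isin(selected)]
               .pivot(index="transcript_id", columns="stage", values="te")
               [stages])
    profile, flagged = drop_zero_variance(profile)
    if len(profile) < max(config.k_clusters, 2):
        log.info("cluster: only %d usable profiles, skipping", len(profile))
        return
    assignment = kmeans_cluster(profile, config.k_clusters,
                                seed=config.cluster_seed,
                                max_iter=config.cluster_max_iter)
    out = profile.copy()
    out["cluster"] = assignment.labels
    out.to_csv(run_dir / "clusters.tsv", sep="\t")
    pd.DataFrame(assignment.centroids,
                 columns=stages).to_csv(run_dir / "cluster_centroids.tsv",
                                        sep="\t", index_label="cluster")
    truth_path = _fixture_dir(run_dir) / "truth.tsv"
    annotations = {}
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        annotations = dict(truth.drop_duplicates("transcript_id")
                           [["transcript_id", "class"]].itertuples(index=False))
    summary = summarize_clusters(assignment, annotations)
    summary.to_csv(run_dir / "cluster_summary.tsv", sep="\t")
    log.info("cluster: k=%d, %d profiles, %d zero-variance dropped, "
             "%d iterations", config.k_clusters, len(profile), len(flagged),
             assignment.iterations_run)


def stage_organelle(config: PipelineConfig, run_dir: Path) -> None:
    """Flag low-TE gene models against the organelle genomes; profile TE over
    the chloroplast CDS set with nuclear normalization factors."""
    run_dir = Path(run_dir)
    fixture = _fixture_dir(run_dir)
    genomes = rio.read_fasta(fixture / "organelles.fasta")
    sequences = rio.read_fasta(fixture / "transcripts.fasta")
    models = {m.transcript_id: m for m in rio.read_gff3(fixture / "annotation.gff3")}
    sets = _load_filter_sets(run_dir)

    low_tids = sorted({t for s in sets["low"]["per_stage"].values() for t in s})
    flags = []
    for tid in low_tids:
        m = models[tid]
        cds_seq = sequences[tid][m.cds_start:m.cds_end]
        flags.append(flag_organelle_homology(gene_id_of(tid), cds_seq, genomes))
    if flags:
        flag_table(flags).to_csv(run_dir / "organelle_flags.tsv", sep="\t")
        n_flagged = sum(f.verdict != "neither" for f in flags)
        log.info("organelle: %d/%d low-TE models flagged", n_flagged, len(flags))

    cds_coords = rio.read_organelle_cds_gff3(fixture / "organelle_cds.gff3")
    cp_cds = {cid: genomes[cid.split(":")[0]][s:e]
              for cid, (s, e) in cds_coords.items()
              if cid.startswith("chloroplast")}
    if not cp_cds:
        return
    counts = _load_counts(run_dir)
    totals = counts.total_mapped.to_dict()
    reads_by_lib = {}
    for key in counts.libraries:
        path = run_dir / "trimmed" / f"{key.label}.fastq"
        if not path.exists():
            path = fixture / "reads" / f"{key.label}.fastq"
        reads_by_lib[key] = rio.read_fastq(path)
    profile = chloroplast_profile(reads_by_lib, cp_cds, totals,
                                  floor_value=config.rpkm_floor,
                                  seed_length=config.seed_length)
    profile.to_csv(run_dir / "chloroplast_profile.tsv", sep="\t", index=False)
    log.info("organelle: chloroplast profile over %d CDS", len(cp_cds))


def report_summary(config: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    """Filter-count summary per stage: total transcripts, primary transcripts
    (unique genes per stage), cross-stage unique genes, expressed
    denominators and high-TE percentages."""
    run_dir = Path(run_dir)
    results = _load_te_table(run_dir)
    sets = _load_filter_sets(run_dir)
    stages = list(config.simulation.stages)
    expressed = expressed_counts(results, config.expressed_threshold)
    rows = []
    for name in ("high", "low"):
        row = {"category": f"{name}_te"}
        for s in stages:
            row[f"{s}_transcripts"] = len(sets[name]["per_stage"][s])
            row[f"{s}_primary"] = len(sets[name]["per_stage_genes"][s])
        row["unique_genes"] = len(sets[name]["union_genes"])
        rows.append(row)
    row = {"category": f"ct_ge_{config.expressed_threshold:g}_rpkm"}
    for s in stages:
        row[f"{s}_transcripts"] = int(expressed.loc[s, "transcripts"])
        row[f"{s}_primary"] = int(expressed.loc[s, "unique_genes"])
    row["unique_genes"] = None
    rows.append(row)
    row = {"category": "high_te_pct_of_expressed"}
    for s in stages:
        row[f"{s}_primary"] = percentage(
            len(sets["high"]["per_stage_genes"][s]),
            int(expressed.loc[s, "unique_genes"]))
    rows.append(row)
    summary = pd.DataFrame(rows)
    summary.to_csv(run_dir / "summary.tsv", sep="\t", index=False)
    return summary


STAGES = ("simulate", "trim", "align", "quantify", "te", "filter",
          "cluster", "organelle", "report")


def run_pipeline(config: PipelineConfig, run_dir: Path) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for name in STAGES:
        try:
            if name == "simulate":
                stage_simulate(config, run_dir)
            elif name == "trim":
                stage_trim(config, run_dir)
            elif name == "align":
                stage_align(config, run_dir)
            elif name == "quantify":
                stage_quantify(config, run_dir)
            elif name == "te":
                stage_te(config, run_dir)
            elif name == "filter":
                stage_filter(config, run_dir)
            elif name == "cluster":
                stage_cluster(config, run_dir)
            elif name == "organelle":
                stage_organelle(config, run_dir)
            elif name == "report":
                report_summary(config, run_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    config.to_yaml(run_dir / "config.yaml")
    with open(_fixture_dir(run_dir) / "manifest.json") as fh:
        fixture_manifest = json.load(fh)
    manifest = {
        "config": json.loads(json.dumps(config.to_dict())),
        "stages": list(STAGES),
        "fixture_checksums": fixture_manifest["checksums"],
    }
    with open(run_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
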