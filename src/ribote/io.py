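"""Fixture serialization: FASTA, GFF3, FASTQ, truth TSV and a checksum manifest.

GFF3 uses 1-based inclusive coordinates with features
gene/mRNA/five_prime_UTR/CDS/three_prime_UTR in transcript coordinates (the
seqid of each feature is the transcript itself, since quantification is
against cDNA models, not the genome).  FASTQ carries constant placeholder
qualities (Sanger offset 33).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import TranscriptModel, LibraryKey
from .simulate import Transcriptome

PLACEHOLDER_QUALITY = 40  # 'I'


def write_fasta(path: Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=tid, description="") for tid, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: Path, reads: Iterable[tuple[str, str]]) -> int:
    n = 0
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def read_fastq(path: Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_gff3(path: Path, models: Iterable[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            tid, L = m.transcript_id, m.length
            attrs_gene = f"ID=gene:{tid}"
            if m.is_rdna:
                attrs_gene += ";rdna=true"
            fh.write(f"{tid}\tribote\tgene\t1\t{L}\t.\t+\t.\t{attrs_gene}\n")
            fh.write(f"{tid}\tribote\tmRNA\t1\t{L}\t.\t+\t.\tID={tid};Parent=gene:{tid}\n")
            if m.cds_start > 0:
                fh.write(f"{tid}\tribote\tfive_prime_UTR\t1\t{m.cds_start}\t.\t+\t.\tParent={tid}\n")
            fh.write(f"{tid}\tribote\tCDS\t{m.cds_start + 1}\t{m.cds_end}\t.\t+\t0\tParent={tid}\n")
            if m.cds_end < L:
                fh.write(f"{tid}\tribote\tthree_prime_UTR\t{m.cds_end + 1}\t{L}\t.\t+\t.\tParent={tid}\n")


def read_gff3(path: Path) -> list[TranscriptModel]:
    """Re-parse transcript models (inverse of :func:`write_gff3`)."""
    spans: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, _src, ftype, start, end, _score, _strand, _phase, attrs = \
                line.rstrip("\n").split("\t")
            rec = spans.setdefault(seqid, {"is_rdna": False})
            if ftype == "gene":
                rec["length"] = int(end)
                rec["is_rdna"] = "rdna=true" in attrs
            elif ftype == "CDS":
                rec["cds"] = (int(start) - 1, int(end))
    return [TranscriptModel(tid, rec["length"], rec["cds"][0], rec["cds"][1],
                            is_rdna=rec["is_rdna"])
            for tid, rec in spans.items()]


def write_organelle_cds_gff3(path: Path, organelle_cds: Mapping[str, tuple[int, int]]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, (s, e) in sorted(organelle_cds.items()):
            org = cid.split(":")[0]
            fh.write(f"{org}\tribote\tCDS\t{s + 1}\t{e}\t.\t+\t0\tID={cid}\n")


def read_organelle_cds_gff3(path: Path) -> dict[str, tuple[int, int]]:
    out: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            _seqid, _src, ftype, start, end, _sc, _st, _ph, attrs = \
                line.rstrip("\n").split("\t")
            if ftype != "CDS":
                continue
            cid = dict(kv.split("=", 1) for kv in attrs.split(";"))["ID"]
            out[cid] = (int(start) - 1, int(end))
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(transcriptome: Transcriptome,
                  libraries: Mapping[LibraryKey, list[tuple[str, str]]],
                  directory: Path) -> dict:
    """Write the complete fixture and return its manifest (also saved as JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "reads").mkdir(exist_ok=True)

    write_fasta(directory / "transcripts.fasta", transcriptome.sequences)
    write_gff3(directory / "annotation.gff3", transcriptome.models)
    write_fasta(directory / "organelles.fasta", transcriptome.organelle_genomes)
    write_organelle_cds_gff3(directory / "organelle_cds.gff3",
                             transcriptome.organelle_cds)
    truth = transcriptome.truth
    truth.to_csv(directory / "truth.tsv", sep="\t", index=False,
                 float_format="%.6g")
    for key, reads in libraries.items():
        write_fastq(directory / "reads" / f"{key.label}.fastq", reads)

    files = sorted(p for p in directory.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": transcriptome.config.seed,
        "n_genes": transcriptome.config.n_genes,
        "libraries": sorted(k.label for k in libraries),
        "checksums": {str(p.relative_to(directory)): _sha256(p) for p in files},
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
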