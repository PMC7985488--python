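"""Readers and writers for the package's interchange formats.

Gene models travel as GTF (exon features, transcript coordinates on a
per-gene "chromosome") plus a FASTA of pre-mRNA sequences; junction probes
as FASTA with structured headers plus a TSV of discriminating offsets;
reads as plain FASTQ (Biopython).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gene_models import GeneModel, IsoformModel, JunctionProbe

__all__ = [
    "write_gene_models",
    "read_gene_models",
    "write_probes",
    "read_probes",
    "read_fastq_sequences",
]


def write_gene_models(
    genes: dict[str, GeneModel],
    isoforms: dict[str, IsoformModel],
    gtf_path,
    fasta_path,
) -> None:
    """GTF exon features (1-based inclusive, per GTF convention) + FASTA."""
    records = [
        SeqRecord(Seq(g.transcript_sequence), id=gid,
                  description=f"pre-mRNA cds_start={g.cds_start}")
        for gid, g in sorted(genes.items())
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gtf_path, "w") as fh:
        for gid, gene in sorted(genes.items()):
            for k, (s, e) in enumerate(gene.exons, start=1):
                attrs = (f'gene_id "{gid}"; transcript_id "{gid}.pre"; '
                         f'exon_number "{k}";')
                fh.write(f"{gid}\ta3splice\texon\t{s + 1}\t{e}\t.\t+\t.\t{attrs}\n")
        for iso_id, iso in sorted(isoforms.items()):
            for k, (s, e) in enumerate(iso.segments, start=1):
                attrs = (f'gene_id "{iso.parent_gene}"; transcript_id "{iso_id}"; '
                         f'exon_number "{k}";')
                fh.write(
                    f"{iso.parent_gene}\ta3splice\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"{attrs}\n"
                )


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if part:
            key, _, val = part.partition(" ")
            out[key] = val.strip().strip('"')
    return out


def read_gene_models(gtf_path, fasta_path) -> tuple[dict, dict]:
    """Inverse of :func:`write_gene_models`."""
    seqs = {}
    cds = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq)
        for token in rec.description.split():
            if token.startswith("cds_start="):
                cds[rec.id] = int(token.split("=", 1)[1])
    exons: dict[str, list] = {}
    segments: dict[str, tuple[str, list]] = {}
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _, feature, start, end, *_rest, attrs = line.rstrip("\n").split("\t")
            if feature != "exon":
                continue
            a = _parse_attrs(attrs)
            iv = (int(start) - 1, int(end))
            if a["transcript_id"].endswith(".pre"):
                exons.setdefault(chrom, []).append(iv)
            else:
                segments.setdefault(a["transcript_id"], (a["gene_id"], []))[1].append(iv)
    genes = {
        gid: GeneModel(gid, seqs[gid], tuple(sorted(ivs)), cds[gid])
        for gid, ivs in exons.items()
    }
    isoforms = {}
    for iso_id, (gid, ivs) in segments.items():
        iso = IsoformModel(iso_id, gid, tuple(sorted(ivs)),
                           canonical=tuple(sorted(ivs)) == genes[gid].exons)
        iso.validate_against(genes[gid])
        isoforms[iso_id] = iso
    return genes, isoforms


def write_probes(probes: list[JunctionProbe], fasta_path, tsv_path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.junction_id,
                  description=f"isoform={p.isoform_id} flank_len={p.flank_len}")
        for p in probes
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {"junction_id": p.junction_id, "isoform_id": p.isoform_id,
         "flank_len": p.flank_len,
         "discriminating_offsets": ",".join(
             map(str, sorted(p.discriminating_offsets))) or "."}
        for p in probes
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_probes(fasta_path, tsv_path) -> list[JunctionProbe]:
    meta = pd.read_csv(tsv_path, sep="\t").set_index("junction_id")
    probes = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = meta.loc[rec.id]
        f = int(row["flank_len"])
        raw = row["discriminating_offsets"]
        offs = frozenset() if raw == "." else frozenset(
            int(x) for x in str(raw).split(","))
        seq = str(rec.seq)
        probes.append(
            JunctionProbe(rec.id, row["isoform_id"], seq[:f], seq[f:], f, offs)
        )
    return probes


def read_fastq_sequences(path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(Path(path)), "fastq")]
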