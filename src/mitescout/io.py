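"""Readers and writers for the on-disk formats the pipeline touches.

FASTA/FASTQ via Biopython, GFF3 gene models via gffutils, plus simple writers
for MITE annotations (GFF3), intervals (BED), report tables (TSV) and aligned
FASTA. Internal coordinates are 0-based half-open; GFF3 output is converted
back to 1-based inclusive and BED stays 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import MultipleAlignment
from .models import GeneModel, GenomeSequence, GenomicInterval

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_reads",
    "write_fastq",
    "read_gff3",
    "write_genes_gff",
    "write_candidates_gff",
    "read_candidates_gff",
    "write_bed",
    "write_tsv",
    "read_alignment_fasta",
    "write_alignment_fasta",
]

log = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read FASTA records in file order; an empty file yields an empty list."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        out.append(GenomeSequence(id=rec.id, residues=seq))
    return out


def write_fasta(records: list[GenomeSequence] | list[tuple[str, str]], path: str | Path) -> None:
    recs = []
    for r in records:
        if isinstance(r, GenomeSequence):
            recs.append(SeqRecord(Seq(r.residues), id=r.id, description=""))
        else:
            rid, seq = r
            recs.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read sequencing reads from FASTQ, or plain FASTA as a fallback."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.read(1)
    if not first:
        return []
    fmt = "fastq" if first == "@" else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene/exon features into GeneModel objects.

    Exons may point at a gene directly or through an mRNA; a gene without exon
    children becomes a single exon spanning the gene. 1-based inclusive GFF
    coordinates are converted to 0-based half-open.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    gene_ids = {g.id for g in db.features_of_type("gene")}
    # orphan-exon check
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents:
            raise ValueError(f"exon at {exon.seqid}:{exon.start} has no Parent")
        for p in parents:
            if p in gene_ids:
                continue
            try:
                feat = db[p]
            except gffutils.exceptions.FeatureNotFoundError:
                raise ValueError(f"exon Parent {p!r} is not a known feature")
            anc = feat.attributes.get("Parent", [])
            if not any(a in gene_ids for a in anc):
                raise ValueError(f"exon Parent {p!r} does not resolve to a gene")

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        span = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand or ".")
        exons = []
        for e in db.children(g, featuretype="exon", order_by="start"):
            if e.start - 1 < span.start or e.end > span.end:
                raise ValueError(f"gene {g.id}: exon outside gene span")
            exons.append(GenomicInterval(e.seqid, e.start - 1, e.end, g.strand or "."))
        genes.append(GeneModel(gene_id=g.id, span=span, exons=exons))
    return genes


def write_genes_gff(genes: list[GeneModel], path: str | Path, source: str = "mitescout") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s = g.span
            fh.write(
                f"{s.seqid}\t{source}\tgene\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\tID={g.gene_id}\n"
            )
            for i, e in enumerate(g.exons, 1):
                fh.write(
                    f"{e.seqid}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# MITE annotations
# ---------------------------------------------------------------------------


def write_candidates_gff(candidates, path: str | Path, source: str = "mitescout") -> None:
    """Write MITE candidates as GFF3 'MITE' features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(candidates):
            iv = c.element
            attrs = [f"ID=mite{i + 1}"]
            if c.family_id:
                attrs.append(f"family={c.family_id}")
            attrs.append(f"tir_len={c.tir_len}")
            attrs.append(f"tir_identity={c.tir_identity:.4f}")
            attrs.append(f"tsd={c.tsd if c.tsd else 'NA'}")
            attrs.append(f"at_fraction={c.at_fraction:.4f}")
            fh.write(
                f"{iv.seqid}\t{source}\tMITE\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                + ";".join(attrs)
                + "\n"
            )


def read_candidates_gff(path: str | Path):
    """Round-trip reader for write_candidates_gff output."""
    from .discovery import MITECandidate  # local import to avoid a cycle

    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2] != "MITE":
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            iv = GenomicInterval(cols[0], int(cols[3]) - 1, int(cols[4]), cols[6])
            out.append(
                MITECandidate(
                    element=iv,
                    sequence="",
                    tir_len=int(attrs.get("tir_len", 0)),
                    tir_identity=float(attrs.get("tir_identity", 0.0)),
                    tsd=None if attrs.get("tsd") in (None, "NA") else attrs["tsd"],
                    at_fraction=float(attrs.get("at_fraction", 0.0)),
                    family_id=attrs.get("family"),
                )
            )
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path, names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"feature{i + 1}"
            fh.write(f"{iv.seqid}\t{iv.start}\t{iv.end}\t{name}\t.\t{iv.strand}\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# aligned FASTA
# ---------------------------------------------------------------------------


def read_alignment_fasta(path: str | Path) -> MultipleAlignment:
    recs = read_fasta(path)
    return MultipleAlignment(taxa=[r.id for r in recs], rows=[r.residues for r in recs])


def write_alignment_fasta(msa: MultipleAlignment, path: str | Path) -> None:
    write_fasta(list(zip(msa.taxa, msa.rows)), path)
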