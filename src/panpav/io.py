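"""Readers and writers for the pipeline's file formats.

FASTA goes through Biopython; everything tabular is plain TSV via pandas.
Alignment tables use 0-based half-open contig coordinates; GFF3 output
converts to its 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .contigclass import AlignmentRecord

__all__ = [
    "read_fasta", "write_fasta", "write_gff3", "read_gff3_genes",
    "read_alignments", "write_alignments", "read_paf",
    "read_pav_matrix", "write_pav_matrix", "read_groups", "read_coverage",
    "read_traits", "read_fai",
]

ALIGNMENT_COLUMNS = [
    "contig_id", "contig_start", "contig_end",
    "ref_chrom", "ref_start", "ref_end", "identity",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = (SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items())
    SeqIO.write(records, str(path), "fasta")


def write_gff3(gene_models: pd.DataFrame, path) -> None:
    """Write gene models (0-based half-open ``start``/``end``) as GFF3 genes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in gene_models.iterrows():
            fh.write(
                f"{row['chrom']}\tpanpav\tgene\t{int(row['start']) + 1}\t{int(row['end'])}\t.\t"
                f"{row.get('strand', '+')}\t.\tID={row['gene_id']}\n"
            )


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features of a GFF3 file, converted to 0-based half-open coordinates."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "gene_id": attrs.get("ID", ""),
                    "chrom": fields[0],
                    "start": int(fields[3]) - 1,
                    "end": int(fields[4]),
                    "strand": fields[6],
                }
            )
    return pd.DataFrame(rows)


def read_alignments(path) -> list[AlignmentRecord]:
    """Read the coords-style alignment TSV (contig coordinates ascending)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table lacks columns: {sorted(missing)}")
    return [
        AlignmentRecord(
            str(r.contig_id), int(r.contig_start), int(r.contig_end),
            str(r.ref_chrom), int(r.ref_start), int(r.ref_end), float(r.identity),
        )
        for r in df.itertuples()
    ]


def write_alignments(records: Iterable[AlignmentRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "contig_id": r.contig_id, "contig_start": r.contig_start,
                "contig_end": r.contig_end, "ref_chrom": r.ref_chrom,
                "ref_start": r.ref_start, "ref_end": r.ref_end, "identity": r.identity,
            }
            for r in records
        ],
        columns=ALIGNMENT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_paf(path) -> list[AlignmentRecord]:
    """Read minimap2-style PAF into alignment records.

    Uses query name/start/end, target name/start/end, and derives percent
    identity as matches / alignment block length. PAF query coordinates
    always ascend regardless of strand, so no normalization is needed.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 11:
                continue
            matches, block = int(f[9]), int(f[10])
            identity = 100.0 * matches / block if block else 0.0
            out.append(
                AlignmentRecord(f[0], int(f[2]), int(f[3]), f[5], int(f[7]), int(f[8]), identity)
            )
    return out


def read_pav_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    df.columns.name = "accession_id"
    return df.astype("int8")


def write_pav_matrix(pav: pd.DataFrame, path) -> None:
    pav.to_csv(path, sep="\t")


def read_groups(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("accession_id")["group"]


def read_coverage(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("accession_id")


def read_fai(path) -> pd.Series:
    """Chromosome lengths from a samtools .fai-style index (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "length"])
    return df.set_index("chrom")["length"]
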