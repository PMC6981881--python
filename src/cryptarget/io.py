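"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython, GFF3 through gffutils, BED through pandas.
BED intervals (0-based half-open) are converted to the internal GFF3
convention (1-based closed) on read and back on write.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .duplex import TargetSite, normalize_rna
from .expression import CtTable, validate_expression
from .lncrna import TranscriptModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_target_table",
    "write_target_gff3",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_ct_tsv",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, RNA-normalized sequence) pairs; DNA T is converted to U."""
    return [(rec.id, normalize_rna(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """FASTQ reads as (id, RNA sequence); qualities are parsed and discarded."""
    return [(rec.id, normalize_rna(str(rec.seq))) for rec in SeqIO.parse(str(path), "fastq")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


_TARGET_COLUMNS = [
    "transcript_id",
    "start",
    "end",
    "site_5to3",
    "pairing",
    "total_mismatch",
    "five_prime_mismatch",
    "energy_ratio",
    "total_ok",
    "forbidden_ok",
    "five_prime_ok",
    "energy_ok",
    "passes",
]


def write_target_table(sites: Iterable[TargetSite], path: str | Path) -> pd.DataFrame:
    """Tab-separated site table (0-based half-open transcript coordinates)."""
    rows = []
    for s in sites:
        rows.append(
            {
                "transcript_id": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "site_5to3": s.duplex.site_5to3,
                "pairing": s.duplex.pairing,
                "total_mismatch": s.total_mismatch,
                "five_prime_mismatch": s.five_prime_mismatch,
                "energy_ratio": "" if s.energy_ratio is None else round(s.energy_ratio, 4),
                "total_ok": s.verdict.total_ok,
                "forbidden_ok": s.verdict.forbidden_ok,
                "five_prime_ok": s.verdict.five_prime_ok,
                "energy_ok": s.verdict.energy_ok,
                "passes": s.verdict.passes,
            }
        )
    df = pd.DataFrame(rows, columns=_TARGET_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_target_gff3(sites: Iterable[TargetSite], path: str | Path, mirna_id: str) -> None:
    """GFF3-style dump of sites (converted to 1-based closed coordinates)."""
    lines = ["##gff-version 3"]
    for i, s in enumerate(sites):
        attrs = (
            f"ID=site{i};miRNA={mirna_id};total_mismatch={s.total_mismatch};"
            f"passes={str(s.verdict.passes).lower()}"
        )
        lines.append(
            "\t".join(
                [
                    s.transcript_id,
                    "cryptarget",
                    "miRNA_target_site",
                    str(s.start + 1),
                    str(s.end),
                    ".",
                    "+",
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Features x conditions TSV with a header row and feature ids in column 1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_expression(df)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t")


def read_ct_tsv(path: str | Path, reference_gene: str, calibrator_sample: str) -> CtTable:
    """Long-format Ct table (columns sample, gene, ct[, replicate])."""
    return CtTable(
        data=pd.read_csv(path, sep="\t"),
        reference_gene=reference_gene,
        calibrator_sample=calibrator_sample,
    )


_LNC_TYPES = {"lnc_RNA", "lncRNA", "lincRNA"}
_CODING_TYPES = {"gene", "mRNA", "protein_coding_gene"}


def read_gff3(path: str | Path, featuretypes: set[str] | None = None) -> list[TranscriptModel]:
    """Load gene/lncRNA features from GFF3 into TranscriptModel records."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    wanted = featuretypes or (_LNC_TYPES | _CODING_TYPES)
    out = []
    for feat in db.all_features():
        if feat.featuretype not in wanted:
            continue
        biotype = "lncRNA" if feat.featuretype in _LNC_TYPES else "coding"
        out.append(
            TranscriptModel(
                id=feat.id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                biotype=biotype,
            )
        )
    return out


def read_bed(path: str | Path, biotype: str = "coding") -> list[TranscriptModel]:
    """BED6 (0-based half-open) to TranscriptModel (1-based closed)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return [
        TranscriptModel(
            id=str(name),
            chrom=str(chrom),
            start=int(start) + 1,
            end=int(end),
            strand=str(strand),
            biotype=biotype,
        )
        for chrom, start, end, name, _score, strand in df.itertuples(index=False, name=None)
    ]


def write_gff3(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """TranscriptModel records to a minimal GFF3 (gene / lnc_RNA features)."""
    lines = ["##gff-version 3"]
    for m in models:
        ftype = "lnc_RNA" if m.biotype == "lncRNA" else "gene"
        lines.append(
            f"{m.chrom}\tcryptarget\t{ftype}\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={m.id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """TranscriptModel (1-based closed) to BED6 (0-based half-open)."""
    lines = [
        f"{m.chrom}\t{m.start - 1}\t{m.end}\t{m.id}\t0\t{m.strand}" for m in models
    ]
    Path(path).write_text("\n".join(lines) + "\n")
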