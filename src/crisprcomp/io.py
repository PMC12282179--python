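"""File-format boundaries: FASTA, FASTQ, GFF3, BED and the TSV tables.

Coordinate conventions
----------------------
Internally everything is 0-based half-open.  GFF3 is written and read as
1-based inclusive (converted at this boundary); BED is 0-based half-open
and passes through unchanged.  Prophage BED rows carry the region id in
column 4 and the completeness label (``intact`` / ``questionable`` /
``incomplete``) in column 7.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclasses.dataclass
class GffFeature:
    """One GFF3 feature row, converted to 0-based half-open coordinates."""

    contig_id: str
    source: str
    ftype: str
    start: int  # 0-based inclusive
    end: int  # half-open
    strand: str
    attributes: dict[str, str]

    @property
    def name(self) -> str:
        return self.attributes.get("Name", self.attributes.get("ID", ""))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{contig_id: sequence}`` mapping.

    Duplicate contig ids are rejected: downstream interval bookkeeping
    keys on the id.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(records)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` pairs; qualities are not used."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: int = 40) -> None:
    """Write reads with a constant phred+33 quality."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")


def read_gff(path: str | Path, ftype: str | None = None) -> list[GffFeature]:
    """Read GFF3 features (via gffutils), converting to 0-based half-open."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    feats = []
    it = db.features_of_type(ftype) if ftype is not None else db.all_features()
    for f in it:
        feats.append(
            GffFeature(
                contig_id=f.seqid,
                source=f.source,
                ftype=f.featuretype,
                start=f.start - 1,
                end=f.end,
                strand=f.strand,
                attributes={k: v[0] for k, v in f.attributes.items()},
            )
        )
    return feats


def write_gff(features: Iterable[GffFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        f.source,
                        f.ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


_BED_COLUMNS = ["contig_id", "start", "end", "region_id", "score", "strand", "completeness"]


def read_prophage_bed(path: str | Path) -> pd.DataFrame:
    """Read prophage regions from 7-column BED (completeness in column 7)."""
    df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLUMNS, comment="#")
    bad = set(df["completeness"]) - {"intact", "questionable", "incomplete"}
    if bad:
        raise ValueError(f"unknown completeness labels in {path}: {sorted(bad)}")
    return df


def write_prophage_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[_BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_repeat_catalog_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a repeat catalog TSV with columns repeat, type, subtype."""
    df = pd.read_csv(path, sep="\t")
    required = {"repeat", "type", "subtype"}
    if not required <= set(df.columns):
        raise ValueError(f"repeat catalog {path} must have columns {sorted(required)}")
    return list(df[["repeat", "type", "subtype"]].itertuples(index=False, name=None))


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
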