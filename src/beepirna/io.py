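"""Reading and writing of the flat-file formats the pipeline exchanges.

Sequence files go through Biopython; feature tables (GFF3/BED) are plain
tab-separated tables handled with pandas. All genomic intervals are 0-based
half-open in memory; GFF3 is converted to/from its 1-based closed convention
at the file boundary.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")

FEATURE_COLUMNS = ["feature_id", "type", "chrom", "start", "end", "strand"]


class FastqParseError(ValueError):
    """Raised when a FASTQ file cannot be parsed as 4-line records."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returned in DNA letters)."""
    return seq.translate(_COMPLEMENT)[::-1]


def as_dna(seq: str) -> str:
    """Canonical internal alphabet: uppercase DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def as_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered {name: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path: str | Path) -> Iterable[tuple[str, str]]:
    """Yield (title, sequence) from a FASTQ file.

    Raises FastqParseError (with the approximate line number) on malformed
    records.
    """
    n = 0
    try:
        with open(path) as fh:
            for title, seq, _qual in FastqGeneralIterator(fh):
                n += 1
                yield title, seq
    except ValueError as exc:
        raise FastqParseError(
            f"{path}: malformed FASTQ near line {4 * n + 1}: {exc}"
        ) from exc


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    """Write (name, sequence) pairs as FASTQ with a constant quality string."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_gff3(path: str | Path, features: pd.DataFrame, source: str = "beepirna") -> None:
    """Write a feature table (FEATURE_COLUMNS) as GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\t{row.type}\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.feature_id}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file into the internal feature table (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "frame", "attributes"],
        dtype={"chrom": str},
    )
    ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    out = pd.DataFrame(
        {
            "feature_id": ids.fillna(df.index.to_series().map(lambda i: f"feature{i}")),
            "type": df["type"],
            "chrom": df["chrom"],
            "start": df["start"].astype(int) - 1,
            "end": df["end"].astype(int),
            "strand": df["strand"].where(df["strand"].isin(["+", "-"]), "+"),
        }
    )
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (>=4 columns; optional column 7 carries the class)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame(
        {
            "feature_id": df[3] if df.shape[1] > 3 else [f"feature{i}" for i in range(len(df))],
            "type": df[6] if df.shape[1] > 6 else "region",
            "chrom": df[0].astype(str),
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "strand": df[5] if df.shape[1] > 5 else "+",
        }
    )
    return out


def read_features(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return read_bed(path)
    return read_gff3(path)


def read_term_map(paths, default_namespace: str = "pathway"):
    """Load gene->term TSVs (gene, term[, label[, namespace]]) into a TermMap.

    Imported lazily by netenrich to avoid a circular import; kept here because
    it is pure file plumbing.
    """
    from .netenrich import TermMap

    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    gene2terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    for p in paths:
        df = pd.read_csv(p, sep="\t", header=None, comment="#", dtype=str)
        for row in df.itertuples(index=False):
            gene, term = row[0], row[1]
            gene2terms.setdefault(gene, set()).add(term)
            labels[term] = row[2] if len(row) > 2 and pd.notna(row[2]) else term
            namespaces[term] = (
                row[3] if len(row) > 3 and pd.notna(row[3]) else default_namespace
            )
    return TermMap(gene2terms=gene2terms, labels=labels, namespaces=namespaces)
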