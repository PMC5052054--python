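"""Readers and writers for the plain-text formats the pipeline uses.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based,
inclusive) is converted at this boundary.  bedGraph is 0-based half-open
as per the format.  Expression matrices are TSVs with a ``gene_id``
column followed by one column per sample.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_gff3",
    "write_gff3",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_fasta",
    "write_fasta",
    "coverage_arrays",
]

_GFF_COLS = ["seqid", "source", "featuretype", "start", "end", "score", "strand", "frame"]


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph -> DataFrame with chrom, start, end (0-based half-open), value."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#"
    )
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def coverage_arrays(bedgraph: pd.DataFrame, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand interval-form bedGraph into dense per-base arrays (one per chromosome)."""
    out = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    for chrom, sub in bedgraph.groupby("chrom"):
        arr = out.get(chrom)
        if arr is None:
            raise KeyError(f"bedGraph chromosome {chrom!r} absent from chrom_sizes")
        for start, end, value in sub[["start", "end", "value"]].itertuples(index=False):
            if end > arr.size or start < 0:
                raise ValueError(f"interval {chrom}:{start}-{end} off chromosome")
            arr[start:end] += value
    return out


def read_gff3(path) -> pd.DataFrame:
    """Parse GFF3 into a DataFrame (0-based half-open start/end, attributes dict).

    Uses gffutils' feature parser line-by-line; attribute values are
    single strings (first value kept).
    """
    rows = []
    for feat in gffutils.iterators.DataIterator(str(path)):
        attrs = {k: v[0] if v else "" for k, v in feat.attributes.items()}
        rows.append(
            {
                "seqid": feat.seqid,
                "source": feat.source,
                "featuretype": feat.featuretype,
                "start": feat.start - 1,
                "end": feat.end,
                "score": feat.score,
                "strand": feat.strand,
                "frame": feat.frame,
                "attributes": attrs,
            }
        )
    return pd.DataFrame(rows)


def write_gff3(df: pd.DataFrame, path) -> None:
    """Write features (0-based half-open internally) as GFF3 (1-based inclusive)."""
    buf = _io.StringIO()
    buf.write("##gff-version 3\n")
    for row in df.itertuples(index=False):
        attrs = ";".join(f"{k}={v}" for k, v in row.attributes.items())
        fields = [
            row.seqid,
            row.source,
            row.featuretype,
            str(int(row.start) + 1),
            str(int(row.end)),
            str(row.score),
            row.strand,
            str(row.frame),
            attrs,
        ]
        buf.write("\t".join(fields) + "\n")
    Path(path).write_text(buf.getvalue())


def read_expression_tsv(path) -> pd.DataFrame:
    """Expression matrix TSV -> DataFrame indexed by gene_id, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValueError("expression TSV must start with a 'gene_id' column")
    return df.set_index("gene_id")


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("gene_id").reset_index().to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
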