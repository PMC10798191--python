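"""Readers and writers for the genomic file formats the pipeline exchanges.

All intervals are 0-based half-open, matching BED on disk.  Interval sets
travel as pandas DataFrames with at least ``chrom``, ``start``, ``end``
columns; alignments travel as :class:`AlignmentBlock` lists anchored to
reference-genome coordinates (MAF on disk, read and written through
Bio.AlignIO).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class AlignmentBlock:
    """One gap-free alignment block anchored to reference coordinates.

    ``sequences`` maps species name to an aligned string of length
    ``end - start``; species missing from the mapping are absent from the
    block.  The reference species carries the coordinates.
    """

    chrom: str
    start: int
    end: int
    sequences: dict = field(default_factory=dict)
    ref: str = "ref"

    @property
    def width(self) -> int:
        return self.end - self.start

    def present_species(self):
        """Species with at least one non-missing base in the block."""
        return [
            sp
            for sp, seq in self.sequences.items()
            if any(c not in "-Nn?" for c in seq)
        ]


def write_maf(blocks, path, chrom_sizes=None):
    """Write alignment blocks as MAF; the reference row goes first."""
    alignments = []
    for b in blocks:
        recs = []
        order = [b.ref] + sorted(sp for sp in b.sequences if sp != b.ref)
        for sp in order:
            if sp not in b.sequences:
                continue
            src_size = (chrom_sizes or {}).get(b.chrom, b.end)
            rec = SeqRecord(Seq(b.sequences[sp]), id=f"{sp}.{b.chrom}")
            rec.annotations.update(
                start=b.start, size=b.width, strand=1, srcSize=src_size
            )
            recs.append(rec)
        alignments.append(MultipleSeqAlignment(recs))
    with open(path, "w") as fh:
        AlignIO.write(alignments, fh, "maf")


def read_maf(path, ref="ref"):
    """Read MAF blocks back into :class:`AlignmentBlock` objects."""
    blocks = []
    for msa in AlignIO.parse(str(path), "maf"):
        seqs, chrom, start, width = {}, None, None, None
        for rec in msa:
            sp, _, chrom_part = rec.id.partition(".")
            seqs[sp] = str(rec.seq).upper()
            if sp == ref:
                chrom = chrom_part
                start = int(rec.annotations["start"])
                width = int(rec.annotations["size"])
        if chrom is None:
            raise ValueError(f"MAF block without reference species {ref!r}")
        blocks.append(AlignmentBlock(chrom, start, start + width, seqs, ref))
    return blocks


# ---------------------------------------------------------------------------
# interval tables


def read_bed(path) -> pd.DataFrame:
    """Read a 3-6 column BED file into a DataFrame (missing columns filled)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=BED_COLUMNS,
        usecols=range(6),
        engine="python",
    )
    if df.empty:
        return pd.DataFrame(columns=BED_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["name"] = df["name"].fillna(".")
    df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(0.0)
    df["strand"] = df["strand"].fillna(".")
    return df


def write_bed(df: pd.DataFrame, path, columns=None):
    cols = columns or [c for c in BED_COLUMNS if c in df.columns]
    out = df.copy()
    for c in cols:
        if c not in out.columns:
            out[c] = "." if c in ("name", "strand") else 0
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path) -> pd.DataFrame:
    names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=names,
                     usecols=range(8), engine="python")
    if df.empty:
        return pd.DataFrame(columns=names)
    for c in ("start1", "end1", "start2", "end2"):
        df[c] = df[c].astype(int)
    return df


def write_bedpe(df: pd.DataFrame, path):
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    extra = [c for c in ("name", "score") if c in df.columns]
    df[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_tss_table(path) -> pd.DataFrame:
    """Gene model table: gene_id, chrom, strand, tss, tes [, exons, cds]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "tss", "tes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def read_chrom_sizes(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: dict, path):
    pd.DataFrame(sorted(sizes.items())).to_csv(path, sep="\t", header=False, index=False)


def read_expression(matrix_path, meta_path):
    """Expression TSV (genes x samples) plus per-sample age/region metadata."""
    expr = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if "age" not in meta.columns:
        raise ValueError("sample metadata needs an 'age' column")
    missing = set(expr.columns) - set(meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    if (expr.values < 0).any():
        raise ValueError("expression values must be nonnegative")
    return expr, meta.loc[expr.columns]


def parse_exon_field(text) -> list:
    """Parse 'start-end,start-end' exon strings from the gene table."""
    if not isinstance(text, str) or not text.strip():
        return []
    out = []
    for part in text.split(","):
        a, b = part.split("-")
        out.append((int(a), int(b)))
    return out


def elements_from_bed(df: pd.DataFrame):
    """Iterate (chrom, start, end) tuples from a BED DataFrame."""
    return list(zip(df["chrom"], df["start"].astype(int), df["end"].astype(int)))


def sort_bed(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def gc_content(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def overlap_any(starts, ends, qstart, qend):
    """Vectorized: which [start,end) intervals overlap [qstart,qend)."""
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    return (starts < qend) & (ends > qstart)
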