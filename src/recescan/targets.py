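"""Linking elements to genes via promoters and chromatin loops.

A gene promoter is the 2 kb upstream + 1 kb downstream window around the
TSS (strand-aware, truncated at chromosome edges).  Promoters overlapping
an H3K4me3 peak are "active".  Elements overlapping active promoters give
the proximal gene set; elements falling in the distal partner of a loop
anchor that overlaps a gene promoter (a promoter-interacting region) give
the loop gene set.  The two sets are reported separately.
"""

from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree

PROMOTER_UP = 2000
PROMOTER_DOWN = 1000


def promoter_window(tss: int, strand: str, chrom_size: int | None = None,
                    up: int = PROMOTER_UP, down: int = PROMOTER_DOWN):
    """Half-open promoter interval around a TSS, truncated to the chromosome."""
    if strand == "+":
        lo, hi = tss - up, tss + down
    elif strand == "-":
        lo, hi = tss - down, tss + up
    else:
        raise ValueError(f"gene strand must be '+' or '-', got {strand!r}")
    lo = max(0, lo)
    if chrom_size is not None:
        hi = min(hi, chrom_size)
    return lo, hi


def promoter_windows(genes: pd.DataFrame, chrom_sizes: dict | None = None) -> pd.DataFrame:
    """Promoter windows for a gene table (gene_id, chrom, strand, tss)."""
    rows = []
    for g in genes.itertuples(index=False):
        size = (chrom_sizes or {}).get(g.chrom)
        lo, hi = promoter_window(int(g.tss), g.strand, size)
        rows.append(dict(gene_id=g.gene_id, chrom=g.chrom, start=lo, end=hi,
                         strand=g.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _trees(df: pd.DataFrame, payload=None) -> dict:
    trees = {}
    for i, r in enumerate(df.itertuples(index=False)):
        if int(r.end) > int(r.start):
            data = payload(r) if payload else i
            trees.setdefault(r.chrom, IntervalTree()).addi(int(r.start), int(r.end), data)
    return trees


def active_promoters(promoters: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Promoters with >= 1 bp overlap with any H3K4me3 peak."""
    peak_trees = _trees(peaks)
    keep = []
    for i, p in enumerate(promoters.itertuples(index=False)):
        tree = peak_trees.get(p.chrom)
        if tree is not None and tree.overlap(int(p.start), int(p.end)):
            keep.append(i)
    return promoters.iloc[keep].reset_index(drop=True)


def proximal_genes(elements: pd.DataFrame, promoters: pd.DataFrame):
    """Genes whose (active) promoter overlaps an element.

    Returns (sorted gene list, deduplicated (element, gene) pair table).
    """
    prom_trees = _trees(promoters, payload=lambda r: r.gene_id)
    pairs = set()
    for e in elements.itertuples(index=False):
        tree = prom_trees.get(e.chrom)
        if tree is None:
            continue
        ename = getattr(e, "name", f"{e.chrom}:{e.start}-{e.end}")
        for hit in tree.overlap(int(e.start), int(e.end)):
            pairs.add((ename, e.chrom, int(e.start), int(e.end), hit.data))
    table = pd.DataFrame(sorted(pairs),
                         columns=["element", "chrom", "start", "end", "gene_id"])
    return sorted(table["gene_id"].unique()), table


def loop_genes(elements: pd.DataFrame, loops: pd.DataFrame,
               promoters: pd.DataFrame, same_chrom_only: bool = True):
    """Genes reached by elements through promoter-anchored loops.

    Both anchor orientations are evaluated: if one anchor overlaps gene g's
    promoter, the partner anchor is a promoter-interacting region for g and
    any element overlapping it yields (element, loop, g).  Anchors that
    both overlap the promoter and contain the element contribute only
    through their partner (the distal side carries the regulatory call).
    Returns (sorted gene list, deduplicated (element, loop, gene) triples).
    """
    prom_trees = _trees(promoters, payload=lambda r: r.gene_id)
    elem_trees = _trees(
        elements,
        payload=lambda r: (getattr(r, "name", None) or f"{r.chrom}:{r.start}-{r.end}",
                           int(r.start), int(r.end)),
    )
    triples = set()
    for lp in loops.itertuples(index=False):
        if same_chrom_only and lp.chrom1 != lp.chrom2:
            continue
        a = (lp.chrom1, int(lp.start1), int(lp.end1))
        b = (lp.chrom2, int(lp.start2), int(lp.end2))
        lname = getattr(lp, "name", None) or f"{a[0]}:{a[1]}-{b[2]}"
        for prom_anchor, distal_anchor in ((a, b), (b, a)):
            ptree = prom_trees.get(prom_anchor[0])
            if ptree is None:
                continue
            genes_hit = {h.data for h in ptree.overlap(prom_anchor[1], prom_anchor[2])}
            if not genes_hit:
                continue
            etree = elem_trees.get(distal_anchor[0])
            if etree is None:
                continue
            for eh in etree.overlap(distal_anchor[1], distal_anchor[2]):
                ename = eh.data[0]
                for g in genes_hit:
                    triples.add((ename, distal_anchor[0], eh.data[1], eh.data[2],
                                 lname, g))
    table = pd.DataFrame(
        sorted(triples),
        columns=["element", "chrom", "start", "end", "loop", "gene_id"])
    return sorted(table["gene_id"].unique()), table
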