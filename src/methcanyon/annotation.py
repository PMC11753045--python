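"""Genomic-context classification: CpG-island features, gene location,
promoter windows, and the CIMP marker panel.

Island context uses the universal shore/shelf convention: positions inside
an island are ``island``; within 2 kb of the nearest island base, ``shore``;
within 2--4 kb, ``shelf``; everything else is ``open_sea``.  Distance is
measured in bases from the nearest base belonging to an island (the first
base outside has distance 1) and the bands are shore = [1, 2000),
shelf = [2000, 4000), so a position exactly 2,000 bp outside an edge is a
shelf.  The nearest island governs when several are in range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ISLAND_CLASSES = ["island", "shore", "shelf", "open_sea"]
GENE_CLASSES = ["promoter", "5utr", "exon", "3utr", "intron", "intergenic"]

SHORE_BP = 2000
SHELF_BP = 4000

#: promoter window extent relative to the TSS, in transcription orientation
PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 500


def promoter_windows(genes: pd.DataFrame) -> pd.DataFrame:
    """Build 1.5-kb promoter windows: 1 kb upstream to 500 bp downstream of
    each TSS, in transcription orientation.

    ``genes`` needs columns ``gene, chrom, tss, strand``.  For a + strand
    gene the window is ``[tss-1000, tss+500)``; for a − strand gene,
    ``[tss-500, tss+1000)``.  Windows are clipped at position 0.
    """
    for col in ("gene", "chrom", "tss", "strand"):
        if col not in genes.columns:
            raise ValueError(f"gene table missing column '{col}'")
    strand = genes["strand"].to_numpy()
    if not np.isin(strand, ["+", "-"]).all():
        bad = genes.loc[~np.isin(strand, ["+", "-"]), "gene"].iloc[0]
        raise ValueError(f"gene {bad!r} has missing or invalid strand")
    tss = genes["tss"].to_numpy(dtype=np.int64)
    start = np.where(strand == "+", tss - PROMOTER_UPSTREAM, tss - PROMOTER_DOWNSTREAM)
    end = np.where(strand == "+", tss + PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM)
    start = np.maximum(start, 0)
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "name": genes["gene"].to_numpy(),
            "strand": strand,
            "tss": tss,
        }
    )
    out.index = pd.Index(genes["gene"], name="gene")
    return out


def classify_island_context(positions, islands: pd.DataFrame, chrom: str | None = None):
    """Classify positions by distance to the nearest CpG island.

    ``positions`` is an int array on one chromosome; ``islands`` an interval
    frame (filtered to ``chrom`` if given).  Returns an object array of
    ``island | shore | shelf | open_sea``; the nearest island governs.
    """
    pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
    if chrom is not None and "chrom" in islands.columns:
        islands = islands[islands["chrom"] == chrom]
    out = np.full(pos.shape, "open_sea", dtype=object)
    if len(islands) == 0:
        return out
    starts = np.sort(islands["start"].to_numpy(dtype=np.int64))
    ends = np.sort(islands["end"].to_numpy(dtype=np.int64))
    # distance to nearest island: 0 if inside (#starts passed > #ends passed)
    n_started = np.searchsorted(starts, pos, side="right")
    n_ended = np.searchsorted(ends, pos, side="right")
    inside = n_started > n_ended
    # gap to previous island end (position >= end: distance pos - end + 1 for
    # the first base after the island => use pos - (end - 1))
    prev_end = np.where(n_ended > 0, ends[np.minimum(n_ended, len(ends)) - 1], -np.inf)
    dist_left = pos - (prev_end - 1)
    next_start = np.where(n_started < len(starts), starts[np.minimum(n_started, len(starts) - 1)], np.inf)
    dist_right = next_start - pos
    dist = np.minimum(dist_left, dist_right)
    out[(~inside) & (dist < SHORE_BP)] = "shore"
    out[(~inside) & (dist >= SHORE_BP) & (dist < SHELF_BP)] = "shelf"
    out[inside] = "island"
    return out


@dataclass
class GeneModel:
    """Minimal exon-aware gene model for region classification.

    ``exons`` are genomic intervals; ``utr5``/``utr3`` are optional genomic
    intervals for the untranslated ends.  The promoter window is derived
    from ``tss``/``strand`` with :func:`promoter_windows` arithmetic.
    """

    gene: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int
    exons: list = field(default_factory=list)
    utr5: tuple | None = None
    utr3: tuple | None = None

    @property
    def promoter(self) -> tuple:
        if self.strand == "+":
            return (max(self.tss - PROMOTER_UPSTREAM, 0), self.tss + PROMOTER_DOWNSTREAM)
        return (max(self.tss - PROMOTER_DOWNSTREAM, 0), self.tss + PROMOTER_UPSTREAM)


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def classify_gene_context(interval, gene_models) -> str:
    """Label a region by the highest-precedence gene feature it overlaps.

    Precedence: promoter > 5'UTR > exon > 3'UTR > intron > intergenic.
    ``interval`` is ``(chrom, start, end)``; ``gene_models`` an iterable of
    :class:`GeneModel`.  Every region gets exactly one label.
    """
    chrom, start, end = interval
    hit = {c: False for c in GENE_CLASSES}
    for gm in gene_models:
        if gm.chrom != chrom:
            continue
        p0, p1 = gm.promoter
        if _overlaps(start, end, p0, p1):
            hit["promoter"] = True
        if gm.utr5 is not None and _overlaps(start, end, *gm.utr5):
            hit["5utr"] = True
        for e0, e1 in gm.exons:
            if _overlaps(start, end, e0, e1):
                hit["exon"] = True
                break
        if gm.utr3 is not None and _overlaps(start, end, *gm.utr3):
            hit["3utr"] = True
        if _overlaps(start, end, gm.start, gm.end):
            hit["intron"] = True  # inside gene body; refined by precedence
    for cls in GENE_CLASSES[:-1]:
        if hit[cls]:
            return cls
    return "intergenic"


def cimp_panel() -> list[str]:
    """The six traditional CpG-island methylator phenotype marker genes, in
    fixed order."""
    return ["RUNX3", "IGF2", "SOCS1", "CACNA1G", "MLH1", "NEUROG1"]
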