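"""Position of elements relative to gene models.

Each element receives exactly one category with precedence
exon > intron > upstream/downstream (within the genic window) > intergenic.
Upstream means 5' of the transcription start site on the gene's strand;
downstream means 3' of the termination site. Overlap is judged on the full
element interval; distance-profile binning uses the element midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .models import GeneModel, GenomicInterval

__all__ = [
    "PositionCall",
    "nearest_gene",
    "classify_position",
    "proximal_fraction",
    "tss_tts_profile",
]

PROXIMAL_CATEGORIES = frozenset({"exon", "intron", "upstream", "downstream"})


@dataclass
class PositionCall:
    element_id: str
    category: str  # exon | intron | upstream | downstream | intergenic
    nearest_gene_id: str | None
    distance: int | None  # bp; 0 when overlapping; None when no gene on seqid


def _signed_distance(element: GenomicInterval, gene: GeneModel) -> int:
    """Gap length to the gene span; negative when the element is 5' of the TSS."""
    if element.overlaps(gene.span):
        return 0
    if element.end <= gene.span.start:
        gap = gene.span.start - element.end
        five_prime = gene.strand != "-"
    else:
        gap = element.start - gene.span.end
        five_prime = gene.strand == "-"
    return -gap if five_prime else gap


def nearest_gene(
    element: GenomicInterval, genes: list[GeneModel]
) -> tuple[str | None, int | None]:
    """Closest gene on the element's seqid and the signed gap distance.

    Ties on distance are broken by the lexicographically smaller gene_id.
    Returns (None, None) when the seqid carries no gene.
    """
    same = [g for g in genes if g.span.seqid == element.seqid]
    if not same:
        return None, None
    best = min(
        same, key=lambda g: (abs(_signed_distance(element, g)), g.gene_id)
    )
    return best.gene_id, _signed_distance(element, best)


def classify_position(
    element: GenomicInterval,
    genes: list[GeneModel],
    config: PipelineConfig,
    element_id: str = "element",
) -> PositionCall:
    same = [g for g in genes if g.span.seqid == element.seqid]
    if not same:
        return PositionCall(element_id, "intergenic", None, None)

    overlapping = [g for g in same if element.overlaps(g.span)]
    if overlapping:
        # larger overlap wins; ties prefer the gene yielding an exon call
        def rank(g: GeneModel):
            is_exon = any(element.overlaps(e) for e in g.exons)
            return (-element.overlap_length(g.span), 0 if is_exon else 1, g.gene_id)

        g = min(overlapping, key=rank)
        category = "exon" if any(element.overlaps(e) for e in g.exons) else "intron"
        return PositionCall(element_id, category, g.gene_id, 0)

    gene_id, signed = nearest_gene(element, same)
    assert gene_id is not None and signed is not None
    dist = abs(signed)
    if dist <= config.genic_window:
        category = "upstream" if signed < 0 else "downstream"
        return PositionCall(element_id, category, gene_id, dist)
    return PositionCall(element_id, "intergenic", gene_id, dist)


def proximal_fraction(calls: list[PositionCall] | int, total: int) -> tuple[int, int]:
    """Count and rounded percentage of gene-proximal elements.

    Accepts either a list of PositionCalls or a precomputed proximal count.
    Percent is rounded half away from zero to the nearest integer, matching
    how contingency percentages are conventionally printed.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if isinstance(calls, int):
        count = calls
    else:
        count = sum(1 for c in calls if c.category in PROXIMAL_CATEGORIES)
    if count > total:
        raise ValueError("proximal count exceeds total")
    percent = int(np.floor(100.0 * count / total + 0.5))
    return count, percent


def tss_tts_profile(
    elements: list[GenomicInterval],
    genes: list[GeneModel],
    window: int = 5000,
    bin: int = 500,
) -> dict:
    """Histogram of element midpoints around transcription start/stop sites.

    Distances are strand-normalized (negative = upstream of the TSS, or
    inside-gene side of the TTS); each element contributes at most once per
    anchor, at its nearest TSS and nearest TTS. Elements beyond the window are
    excluded.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    if window % bin != 0:
        raise ValueError("bin must divide window")
    nbins = 2 * window // bin
    edges = np.arange(-window, window + bin, bin)
    counts = {"tss": np.zeros(nbins, dtype=int), "tts": np.zeros(nbins, dtype=int)}
    for element in elements:
        m = element.midpoint
        for anchor in ("tss", "tts"):
            best = None
            for g in genes:
                if g.span.seqid != element.seqid:
                    continue
                pos = g.tss if anchor == "tss" else g.tts
                d = m - pos if g.strand != "-" else pos - m
                if best is None or abs(d) < abs(best):
                    best = d
            if best is None or not (-window <= best < window):
                continue
            counts[anchor][(best + window) // bin] += 1
    return {"edges": edges, "tss": counts["tss"], "tts": counts["tts"]}
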