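"""Centromere prediction for RIP-shaped fungal chromosomes.

In *Trichoderma* and *Neurospora*-like genomes the centromere of each
chromosome coincides with (i) its longest AT-rich block and (ii) its longest
region devoid of annotated genes.  A call is *concordant* when the two
criteria point at overlapping loci (>= 1 bp of overlap); discordance is
surfaced as a data-quality signal rather than silently resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .atrich import AtRichBlock
from .genome_io import Chromosome, GeneModel, Genome, Interval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrfFreeRegion:
    interval: Interval
    tied: bool = False  # another gap of identical length exists (leftmost kept)
    no_genes: bool = False  # chromosome had no annotated genes at all


@dataclass(frozen=True)
class CentromereCall:
    chromosome: str
    block: AtRichBlock
    orf_free: OrfFreeRegion
    concordant: bool
    #: overlap of block and gap, when concordant
    intersection: Interval | None

    @property
    def confidence(self) -> str:
        return "concordant" if self.concordant else "discordant"


def longest_orf_free_region(
    chromosome: Chromosome, genes: Sequence[GeneModel]
) -> OrfFreeRegion:
    """Longest interval containing no annotated gene span.

    Chromosome ends count as gap boundaries.  Ties break to the leftmost gap
    and are reported.  With no genes at all the whole chromosome is returned
    flagged ``no_genes``.
    """
    length = chromosome.length
    spans = sorted(
        (g.start, g.end) for g in genes if g.chromosome == chromosome.name
    )
    if not spans:
        logger.warning(
            "chromosome %s has no annotated genes; whole chromosome returned",
            chromosome.name,
        )
        return OrfFreeRegion(Interval(chromosome.name, 0, length), no_genes=True)
    # merge gene spans, then walk the complement
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps: list[tuple[int, int]] = []
    cursor = 0
    for s, e in merged:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        gaps.append((cursor, length))
    if not gaps:
        raise ValueError(
            f"chromosome {chromosome.name} is fully covered by gene spans; "
            "no ORF-free region exists"
        )
    best = max(gaps, key=lambda g: g[1] - g[0])
    best_len = best[1] - best[0]
    leftmost = next(g for g in gaps if g[1] - g[0] == best_len)
    tied = sum(1 for g in gaps if g[1] - g[0] == best_len) > 1
    return OrfFreeRegion(Interval(chromosome.name, *leftmost), tied=tied)


def predict_centromeres(
    genome: Genome,
    genes: Sequence[GeneModel],
    blocks: Sequence[AtRichBlock],
) -> list[CentromereCall]:
    """One centromere call per chromosome with at least one AT-rich block.

    The longest block (ties to the leftmost) is paired with the longest
    ORF-free region; chromosomes without blocks are omitted with a warning.
    """
    by_chrom: dict[str, list[AtRichBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chromosome, []).append(b)
    calls: list[CentromereCall] = []
    for chrom in genome:
        chrom_blocks = by_chrom.get(chrom.name, [])
        if not chrom_blocks:
            logger.warning(
                "chromosome %s has no AT-rich blocks; centromere call omitted",
                chrom.name,
            )
            continue
        best = max(chrom_blocks, key=lambda b: (b.length, -b.start))
        gap = longest_orf_free_region(chrom, genes)
        concordant = best.interval.overlaps(gap.interval)
        intersection = None
        if concordant:
            intersection = Interval(
                chrom.name,
                max(best.start, gap.interval.start),
                min(best.end, gap.interval.end),
            )
        calls.append(
            CentromereCall(
                chromosome=chrom.name,
                block=best,
                orf_free=gap,
                concordant=concordant,
                intersection=intersection,
            )
        )
    return calls
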