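"""AT-rich block segmentation under dual GC-deficit thresholds.

An AT-rich block is an interval of at least ``min_block_len`` bases (500 by
default) whose GC content is both ``delta_gene`` points (12) below the mean
GC of annotated genes and ``delta_genome`` points (6) below the genome-wide
GC.  Both conditions must hold, so the effective ceiling is

    ceiling = min(gene_gc - delta_gene, genome_gc - delta_genome).

In RIP-active fungi such blocks are relics of transposon copies degenerated
by repeat-induced point mutation, and they dominate centromeres and
rearrangement-prone regions.

Segmentation procedure (base resolution):

1. every base is classified AT-rich iff the GC of the ``window``-wide window
   centred on it (clipped into chromosome bounds) is <= ceiling;
2. maximal runs of AT-rich bases become candidates; candidates separated by
   fewer than ``merge_gap`` non-flagged bases are merged, so single high-GC
   islands do not fragment one relic;
3. each end is refined inward while the terminal ``edge_window`` bases still
   have GC above the ceiling, which removes the overhang the centred window
   produces around a sharp GC step;
4. ends are trimmed to A/T bases and the whole block is shrunk from the left
   until its own GC is <= ceiling;
5. blocks shorter than ``min_block_len`` are discarded.

Every emitted block therefore satisfies length >= min_block_len and
GC <= ceiling, and blocks are disjoint and sorted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import Chromosome, GeneModel, Genome, Interval

_A, _C, _G, _T = (ord(b) for b in "ACGT")


@dataclass
class GcContext:
    """GC statistics and thresholds governing segmentation.

    ``gene_gc`` is the mean GC over the union of annotated gene spans
    (introns included); ``genome_gc`` is the whole-genome GC, N excluded.
    """

    genome_gc: float
    gene_gc: float
    delta_gene: float = 12.0
    delta_genome: float = 6.0
    min_block_len: int = 500
    window: int = 500
    step: int = 100
    merge_gap: int = 100
    edge_window: int = 100

    def __post_init__(self) -> None:
        for gc in (self.genome_gc, self.gene_gc):
            if not (0.0 <= gc <= 100.0):
                raise ValueError(f"GC percent out of range: {gc}")
        if self.delta_gene <= 0 or self.delta_genome <= 0:
            raise ValueError("GC-deficit deltas must be positive")
        if self.min_block_len < 1:
            raise ValueError("min_block_len must be >= 1")


@dataclass(frozen=True)
class AtRichBlock:
    interval: Interval
    gc: float

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def chromosome(self) -> str:
        return self.interval.chromosome

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def gc_ceiling(context: GcContext) -> float:
    """Effective GC ceiling: both deficit conditions enforced jointly."""
    ceiling = min(
        context.gene_gc - context.delta_gene,
        context.genome_gc - context.delta_genome,
    )
    if ceiling <= 0:
        raise ValueError(
            f"degenerate thresholds: effective GC ceiling {ceiling:.2f} <= 0"
        )
    return ceiling


def _encode(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)


def _prefix_counts(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative GC and non-N counts, each of length len(arr) + 1."""
    is_gc = (arr == _G) | (arr == _C)
    is_acgt = is_gc | (arr == _A) | (arr == _T)
    cg = np.concatenate(([0], np.cumsum(is_gc, dtype=np.int64)))
    cn = np.concatenate(([0], np.cumsum(is_acgt, dtype=np.int64)))
    return cg, cn


def gc_percent(sequence: str) -> float:
    """GC percent of a sequence, N excluded; 0.0 for an all-N sequence."""
    arr = _encode(sequence)
    gc = int(((arr == _G) | (arr == _C)).sum())
    non_n = int((arr != ord("N")).sum())
    return 100.0 * gc / non_n if non_n else 0.0


def genome_gc_percent(genome: Genome) -> float:
    gc = 0
    non_n = 0
    for chrom in genome:
        arr = _encode(chrom.sequence)
        gc += int(((arr == _G) | (arr == _C)).sum())
        non_n += int((arr != ord("N")).sum())
    return 100.0 * gc / non_n if non_n else 0.0


def gene_gc_percent(genome: Genome, genes: Sequence[GeneModel]) -> float:
    """Mean GC over the union of gene spans (introns included)."""
    if not genes:
        raise ValueError("no genes supplied; pass gene_gc explicitly instead")
    gc = 0
    non_n = 0
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for name, chrom_genes in by_chrom.items():
        chrom = genome[name]
        mask = np.zeros(chrom.length, dtype=bool)
        for g in chrom_genes:
            mask[g.start : g.end] = True
        arr = _encode(chrom.sequence)[mask]
        gc += int(((arr == _G) | (arr == _C)).sum())
        non_n += int((arr != ord("N")).sum())
    return 100.0 * gc / non_n if non_n else 0.0


def compute_gc_context(
    genome: Genome,
    genes: Sequence[GeneModel] | None = None,
    gene_gc: float | None = None,
    **kwargs,
) -> GcContext:
    """Build a :class:`GcContext` from a genome and its annotation.

    ``gene_gc`` may be supplied directly when no annotation is available.
    """
    if gene_gc is None:
        if not genes:
            raise ValueError("either genes or an explicit gene_gc is required")
        gene_gc = gene_gc_percent(genome, genes)
    return GcContext(genome_gc=genome_gc_percent(genome), gene_gc=gene_gc, **kwargs)


def gc_profile(
    chromosome: Chromosome, window: int, step: int
) -> list[tuple[Interval, float]]:
    """Tiled GC profile: windows every ``step`` bases, ``window`` wide.

    A final partial window is kept when it spans at least ``step`` bases.
    A window wider than the chromosome degrades to a single whole-chromosome
    window.  Windows of only N bases report 0.0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not (1 <= step <= window):
        raise ValueError("step must satisfy 1 <= step <= window")
    length = chromosome.length
    if window >= length:
        return [(Interval(chromosome.name, 0, length), gc_percent(chromosome.sequence))]
    cg, cn = _prefix_counts(_encode(chromosome.sequence))
    out = []
    for start in range(0, length, step):
        end = min(start + window, length)
        if end - start < step and start > 0:
            break
        non_n = cn[end] - cn[start]
        gc = 100.0 * (cg[end] - cg[start]) / non_n if non_n else 0.0
        out.append((Interval(chromosome.name, start, end), gc))
    return out


def _flag_bases(arr: np.ndarray, window: int, ceiling: float) -> np.ndarray:
    """Per-base AT-rich flags from the centred-window rule."""
    length = arr.shape[0]
    w = min(window, length)
    cg, cn = _prefix_counts(arr)
    lo = np.clip(np.arange(length) - w // 2, 0, length - w)
    hi = lo + w
    gc = cg[hi] - cg[lo]
    non_n = cn[hi] - cn[lo]
    flags = np.zeros(length, dtype=bool)
    ok = non_n > 0
    flags[ok] = (100.0 * gc[ok] / non_n[ok]) <= ceiling
    return flags


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def _merge_runs(runs: list[tuple[int, int]], merge_gap: int) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _refine_block(
    arr: np.ndarray,
    cg: np.ndarray,
    cn: np.ndarray,
    start: int,
    end: int,
    ceiling: float,
    edge_window: int,
) -> tuple[int, int]:
    """Steps 3-4 of the segmentation procedure (see module docstring)."""

    def seg_gc_ok(a: int, b: int) -> bool:
        non_n = cn[b] - cn[a]
        if non_n == 0:
            return False
        return 100.0 * (cg[b] - cg[a]) / non_n <= ceiling

    # edge refinement: walk each end inward while the terminal edge_window
    # bases are still above the ceiling
    while end > start and not seg_gc_ok(start, min(start + edge_window, end)):
        start += 1
    while end > start and not seg_gc_ok(max(end - edge_window, start), end):
        end -= 1
    # terminal bases must be A or T, and the whole block must obey the ceiling
    while end > start:
        if arr[start] != _A and arr[start] != _T:
            start += 1
            continue
        if arr[end - 1] != _A and arr[end - 1] != _T:
            end -= 1
            continue
        if seg_gc_ok(start, end):
            break
        start += 1
    return start, end


def segment_chromosome(
    chromosome: Chromosome, context: GcContext
) -> list[AtRichBlock]:
    """Segment one chromosome into AT-rich blocks (sorted, disjoint)."""
    ceiling = gc_ceiling(context)
    arr = _encode(chromosome.sequence)
    flags = _flag_bases(arr, context.window, ceiling)
    cg, cn = _prefix_counts(arr)
    blocks: list[AtRichBlock] = []
    for s, e in _merge_runs(_runs(flags), context.merge_gap):
        s, e = _refine_block(arr, cg, cn, s, e, ceiling, context.edge_window)
        if e - s >= context.min_block_len:
            non_n = cn[e] - cn[s]
            gc = 100.0 * (cg[e] - cg[s]) / non_n if non_n else 0.0
            blocks.append(AtRichBlock(Interval(chromosome.name, s, e), gc))
    return blocks


def segment_at_rich_blocks(
    genome: Genome,
    genes: Sequence[GeneModel] | None = None,
    context: GcContext | None = None,
    **kwargs,
) -> list[AtRichBlock]:
    """Segment every chromosome of a genome into AT-rich blocks.

    When no ``context`` is given it is computed from the genome and its
    annotation; extra keyword arguments are forwarded to :class:`GcContext`.
    """
    if context is None:
        context = compute_gc_context(genome, genes=genes, **kwargs)
    blocks: list[AtRichBlock] = []
    for chrom in genome:
        blocks.extend(segment_chromosome(chrom, context))
    return blocks


def atrich_summary(
    blocks: Sequence[AtRichBlock | Interval],
    genome: Genome | int,
) -> tuple[int, int, float]:
    """(count, total bp, percent of genome) for a set of blocks.

    ``genome`` may be a :class:`Genome` or a plain genome length in bases;
    the percent is reported to two decimals, matching published tables.
    """
    genome_length = genome.total_length if isinstance(genome, Genome) else int(genome)
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    total = sum(b.length for b in blocks)
    percent = round(100.0 * total / genome_length, 2)
    return len(blocks), total, percent


def block_length_spectrum(
    blocks: Sequence[AtRichBlock | Interval],
    bin_edges: Sequence[int],
) -> np.ndarray:
    """Histogram of block lengths over right-closed bins (lo, hi].

    A length equal to a bin edge belongs to the bin it closes on the right.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing, length >= 2")
    lengths = np.array([b.length for b in blocks], dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for ln in lengths:
        # right-closed: (edges[i], edges[i+1]]
        idx = int(np.searchsorted(edges, ln, side="left")) - 1
        if 0 <= idx < len(counts):
            counts[idx] += 1
        elif ln == edges[0]:
            counts[0] += 1
    return counts
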