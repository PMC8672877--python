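"""Synteny blocks, breakpoints, and AT-block association testing.

Synteny is computed at whole-gene resolution: each genome's genes are ranked
along their chromosomes, and ortholog pairs are chained into blocks whose
ranks are strictly monotone in both genomes (increasing, or decreasing for
inverted blocks) with at most ``max_gene_gap`` ranks skipped between
consecutive pairs.  Blocks are extracted longest-first (ties broken toward
the leftmost chain), so a long collinear backbone is never fragmented by a
short interleaved chain; chains below ``min_block_genes`` are discarded.

A breakpoint is the interval between the flanking genes of two adjacent
blocks on a chromosome.  Whether breakpoints co-locate with AT-rich blocks
is assessed by a permutation test that redraws equally many intervals of the
same lengths uniformly per chromosome and reports the empirical p-value
``(1 + #{null >= observed}) / (1 + n_perm)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atrich import AtRichBlock
from .genome_io import GeneModel, Genome, Interval


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    score: float | None = None


@dataclass(frozen=True)
class SyntenyBlock:
    chromosome_a: str
    chromosome_b: str
    pairs: tuple[OrthologPair, ...]
    orientation: str  # "same" | "inverted"
    span_a: Interval
    span_b: Interval

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class Breakpoint:
    """Gap between adjacent synteny blocks in one genome.

    ``start == end`` marks a degenerate (zero-length) breakpoint where the
    flanking blocks abut with no intervening sequence between their genes.
    """

    genome: str  # "A" | "B"
    chromosome: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AssociationResult:
    observed_fraction: float
    null_mean: float
    empirical_p: float
    n_breakpoints: int
    n_perm: int

    def __iter__(self):
        # allows tuple-unpacking: observed, null_mean, p = result
        return iter((self.observed_fraction, self.null_mean, self.empirical_p))


def _rank_map(genes: Sequence[GeneModel]) -> dict[str, tuple[str, int, int, int]]:
    """gene_id -> (chromosome, rank, start, end), ranks per chromosome."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out: dict[str, tuple[str, int, int, int]] = {}
    for chrom, group in by_chrom.items():
        group.sort(key=lambda g: (g.start, g.end))
        for rank, g in enumerate(group):
            out[g.gene_id] = (chrom, rank, g.start, g.end)
    return out


def _compatible(
    pa: tuple[int, int], pb: tuple[int, int], sign: int, max_gap: int
) -> bool:
    """Can pair pb follow pair pa in a chain of orientation ``sign``?"""
    da = pb[0] - pa[0]
    db = sign * (pb[1] - pa[1])
    return 0 < da <= max_gap and 0 < db <= max_gap


def _longest_chain(ranks: list[tuple[int, int]], max_gap: int) -> list[int]:
    """Longest rank-monotone chain; ties resolve to the lexicographically
    smallest index tuple.  ``ranks`` must be sorted by rank_a."""
    n = len(ranks)
    best_len = {}
    for sign in (1, -1):
        f = [1] * n
        for i in range(n - 1, -1, -1):
            for j in range(i + 1, n):
                if ranks[j][0] - ranks[i][0] > max_gap:
                    break
                if _compatible(ranks[i], ranks[j], sign, max_gap) and f[j] + 1 > f[i]:
                    f[i] = f[j] + 1
        best_len[sign] = f
    total = max(max(best_len[1]), max(best_len[-1]))
    start = min(
        i for i in range(n) if max(best_len[1][i], best_len[-1][i]) == total
    )
    chain = [start]
    if total == 1:
        return chain
    # first step: pick the smallest successor over both admissible signs
    sign = 0
    cur, remaining = start, total - 1
    while remaining:
        candidates = []
        for s in ((1, -1) if sign == 0 else (sign,)):
            if best_len[s][cur] < remaining + 1:
                continue
            for j in range(cur + 1, len(ranks)):
                if ranks[j][0] - ranks[cur][0] > max_gap:
                    break
                if (
                    _compatible(ranks[cur], ranks[j], s, max_gap)
                    and best_len[s][j] == remaining
                ):
                    candidates.append((j, s))
                    break  # smallest j for this sign
        j, s = min(candidates)
        chain.append(j)
        sign, cur, remaining = s, j, remaining - 1
    return chain


def build_synteny_blocks(
    pairs: Sequence[OrthologPair | tuple[str, str]],
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    min_block_genes: int = 3,
    max_gene_gap: int = 5,
) -> list[SyntenyBlock]:
    """Decompose ortholog pairs into synteny blocks, longest chain first.

    Pairs must be one-to-one (reciprocal-best filtering is upstream); a gene
    occurring in more than one pair is an error.
    """
    norm = [
        p if isinstance(p, OrthologPair) else OrthologPair(p[0], p[1])
        for p in pairs
    ]
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    for p in norm:
        if p.gene_a in seen_a or p.gene_b in seen_b:
            raise ValueError(f"duplicated gene in ortholog pairs: {p}")
        seen_a.add(p.gene_a)
        seen_b.add(p.gene_b)

    map_a = _rank_map(genes_a)
    map_b = _rank_map(genes_b)
    for p in norm:
        if p.gene_a not in map_a:
            raise ValueError(f"unresolvable gene in genome A: {p.gene_a}")
        if p.gene_b not in map_b:
            raise ValueError(f"unresolvable gene in genome B: {p.gene_b}")

    groups: dict[tuple[str, str], list[OrthologPair]] = {}
    for p in norm:
        key = (map_a[p.gene_a][0], map_b[p.gene_b][0])
        groups.setdefault(key, []).append(p)

    blocks: list[SyntenyBlock] = []
    for (chrom_a, chrom_b), group in sorted(groups.items()):
        group.sort(key=lambda p: map_a[p.gene_a][1])
        remaining = group
        while remaining:
            ranks = [
                (map_a[p.gene_a][1], map_b[p.gene_b][1]) for p in remaining
            ]
            idx = _longest_chain(ranks, max_gene_gap)
            if len(idx) < min_block_genes:
                break
            chain = [remaining[i] for i in idx]
            rb = [map_b[p.gene_b][1] for p in chain]
            orientation = "inverted" if len(rb) > 1 and rb[1] < rb[0] else "same"
            a_coords = [(map_a[p.gene_a][2], map_a[p.gene_a][3]) for p in chain]
            b_coords = [(map_b[p.gene_b][2], map_b[p.gene_b][3]) for p in chain]
            blocks.append(
                SyntenyBlock(
                    chromosome_a=chrom_a,
                    chromosome_b=chrom_b,
                    pairs=tuple(chain),
                    orientation=orientation,
                    span_a=Interval(
                        chrom_a,
                        min(s for s, _ in a_coords),
                        max(e for _, e in a_coords),
                    ),
                    span_b=Interval(
                        chrom_b,
                        min(s for s, _ in b_coords),
                        max(e for _, e in b_coords),
                    ),
                )
            )
            used = set(idx)
            remaining = [p for i, p in enumerate(remaining) if i not in used]
    blocks.sort(key=lambda b: (b.chromosome_a, b.span_a.start))
    return blocks


def find_breakpoints(
    blocks: Sequence[SyntenyBlock],
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    include_ends: bool = False,
) -> list[Breakpoint]:
    """Breakpoints between adjacent blocks, one list entry per genome side.

    The interval spans from the end of the last gene of one block to the
    start of the first gene of the next; abutting or overlapping blocks give
    a zero-length breakpoint at the boundary coordinate.  Chromosome-end
    boundaries are excluded unless ``include_ends``.
    """
    maps = {"A": _rank_map(genes_a), "B": _rank_map(genes_b)}
    out: list[Breakpoint] = []
    for side in ("A", "B"):
        gmap = maps[side]
        by_chrom: dict[str, list[tuple[int, int, SyntenyBlock]]] = {}
        for blk in blocks:
            gene_ids = [
                p.gene_a if side == "A" else p.gene_b for p in blk.pairs
            ]
            starts = [gmap[g][2] for g in gene_ids]
            ends = [gmap[g][3] for g in gene_ids]
            chrom = blk.chromosome_a if side == "A" else blk.chromosome_b
            by_chrom.setdefault(chrom, []).append((min(starts), max(ends), blk))
        for chrom, entries in by_chrom.items():
            entries.sort(key=lambda t: t[0])
            for (s1, e1, _), (s2, e2, _) in zip(entries, entries[1:]):
                if s2 > e1:
                    out.append(Breakpoint(side, chrom, e1, s2))
                else:  # degenerate: blocks abut or interleave
                    out.append(Breakpoint(side, chrom, s2, s2))
        if include_ends:
            raise NotImplementedError(
                "chromosome-end boundaries are excluded by design"
            )
    return out


def _overlap_hits(
    starts: np.ndarray,
    lengths: np.ndarray,
    block_starts: np.ndarray,
    block_ends: np.ndarray,
) -> np.ndarray:
    """Boolean hits of half-open intervals against sorted disjoint blocks.

    Zero-length intervals hit only when strictly inside a block.
    """
    if block_starts.size == 0:
        return np.zeros(starts.shape, dtype=bool)
    ends = starts + lengths
    idx = np.searchsorted(block_ends, starts, side="right")
    idx_c = np.minimum(idx, block_starts.size - 1)
    hits = (idx < block_starts.size) & (block_starts[idx_c] < ends)
    zero = lengths == 0
    if np.any(zero):
        # a point x is inside a block iff b_start < x < b_end
        inside = (
            (idx < block_starts.size)
            & (block_starts[idx_c] < starts)
            & (starts < block_ends[idx_c])
        )
        hits = np.where(zero, inside, hits)
    return hits


def breakpoint_atblock_association(
    breakpoints: Sequence[Breakpoint],
    atblocks: Sequence[AtRichBlock | Interval],
    genome: Genome,
    n_perm: int = 1000,
    seed: int = 0,
    widen_zero_length: int = 1000,
) -> AssociationResult:
    """Permutation test of breakpoint/AT-block co-location.

    ``observed_fraction`` is the share of breakpoints overlapping any AT-rich
    block (>= 1 bp; zero-length breakpoints are widened by
    ``widen_zero_length`` on each side, since breakpoints mark neighbourhoods
    rather than single bases).  The null redraws, per chromosome, the same
    number of intervals with the same (post-widening) lengths uniformly at
    random; ``empirical_p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if not breakpoints:
        raise ValueError("no breakpoints to test")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)

    block_arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom_blocks: dict[str, list[tuple[int, int]]] = {}
    for b in atblocks:
        iv = b.interval if isinstance(b, AtRichBlock) else b
        by_chrom_blocks.setdefault(iv.chromosome, []).append((iv.start, iv.end))
    for chrom, ivs in by_chrom_blocks.items():
        ivs.sort()
        block_arrays[chrom] = (
            np.array([s for s, _ in ivs], dtype=np.int64),
            np.array([e for _, e in ivs], dtype=np.int64),
        )
    empty = (np.array([], dtype=np.int64), np.array([], dtype=np.int64))

    # effective (possibly widened) intervals, grouped per chromosome;
    # sorting makes the result invariant to breakpoint input order
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for bp in sorted(breakpoints, key=lambda b: (b.chromosome, b.start, b.end)):
        chrom_len = genome[bp.chromosome].length
        s, e = bp.start, bp.end
        if e - s == 0:
            s, e = max(0, s - widen_zero_length), min(chrom_len, e + widen_zero_length)
        per_chrom.setdefault(bp.chromosome, []).append((s, e - s))

    n_bp = sum(len(v) for v in per_chrom.values())
    observed_hits = 0
    null_hits = np.zeros(n_perm, dtype=np.int64)
    for chrom, items in sorted(per_chrom.items()):
        bs, be = block_arrays.get(chrom, empty)
        starts = np.array([s for s, _ in items], dtype=np.int64)
        lens = np.array([ln for _, ln in items], dtype=np.int64)
        observed_hits += int(_overlap_hits(starts, lens, bs, be).sum())
        chrom_len = genome[chrom].length
        lens_c = np.minimum(lens, chrom_len)
        high = chrom_len - lens_c + 1
        rand_starts = rng.integers(0, high, size=(n_perm, len(items)))
        hits = _overlap_hits(
            rand_starts.ravel(),
            np.tile(lens_c, n_perm),
            bs,
            be,
        ).reshape(n_perm, len(items))
        null_hits += hits.sum(axis=1)

    observed_fraction = observed_hits / n_bp
    null_fracs = null_hits / n_bp
    exceed = int(np.sum(null_fracs >= observed_fraction - 1e-12))
    empirical_p = (1 + exceed) / (1 + n_perm)
    return AssociationResult(
        observed_fraction=observed_fraction,
        null_mean=float(null_fracs.mean()),
        empirical_p=empirical_p,
        n_breakpoints=n_bp,
        n_perm=n_perm,
    )


def ortholog_conservation_summary(
    query_gene_ids: Sequence[str],
    presence_by_genome: pd.DataFrame | Mapping[str, Sequence[bool]],
) -> tuple[int, int]:
    """(n_conserved, percent) of query genes present in *all* genomes.

    ``presence_by_genome`` is indexed by gene_id with one boolean column per
    comparison genome.  Percent is rounded to the nearest integer, matching
    published summaries such as "190 (52%)".
    """
    if len(query_gene_ids) == 0:
        raise ValueError("empty query gene list")
    df = (
        presence_by_genome
        if isinstance(presence_by_genome, pd.DataFrame)
        else pd.DataFrame(presence_by_genome)
    )
    if "gene_id" in df.columns:
        df = df.set_index("gene_id")
    missing = [g for g in query_gene_ids if g not in df.index]
    if missing:
        raise KeyError(f"query genes absent from presence table: {missing[:5]}")
    conserved = df.loc[list(query_gene_ids)].astype(bool).all(axis=1)
    n_conserved = int(conserved.sum())
    percent = int(round(100.0 * n_conserved / len(query_gene_ids)))
    return n_conserved, percent


def read_ortholog_pairs(path) -> list[OrthologPair]:
    """Read an ortholog-pair TSV with columns gene_a, gene_b [, score]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError("ortholog table needs gene_a and gene_b columns")
    scores = (
        df["score"].astype(float).tolist()
        if "score" in df.columns
        else [None] * len(df)
    )
    return [
        OrthologPair(a, b, s)
        for a, b, s in zip(df["gene_a"], df["gene_b"], scores)
    ]
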