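"""Independent brute-force oracles used by the test suite.

Each oracle re-implements the documented behaviour of one operation with the
simplest possible code (plain Python loops, exhaustive enumeration), sharing
nothing with the library's implementation paths.
"""

from __future__ import annotations


# ---------------------------------------------------------------------------
# AT-rich segmentation: per-base sliding-window classification
# ---------------------------------------------------------------------------

def _gc_counts(seq: str) -> tuple[int, int]:
    gc = sum(1 for b in seq if b in "GC")
    non_n = sum(1 for b in seq if b != "N")
    return gc, non_n


def _gc_le(seq: str, ceiling: float) -> bool:
    gc, non_n = _gc_counts(seq)
    return non_n > 0 and 100.0 * gc / non_n <= ceiling


def oracle_at_blocks(
    seq: str,
    ceiling: float,
    window: int = 500,
    min_len: int = 500,
    merge_gap: int = 100,
    edge: int = 100,
) -> list[tuple[int, int]]:
    """Brute-force per-base classification followed by run merging/refining."""
    length = len(seq)
    w = min(window, length)
    # GC percent of every window offset, by incremental sliding
    gc = sum(1 for b in seq[:w] if b in "GC")
    non_n = sum(1 for b in seq[:w] if b != "N")
    win_ok = []
    for lo in range(length - w + 1):
        if lo > 0:
            out_b, in_b = seq[lo - 1], seq[lo + w - 1]
            gc += (in_b in "GC") - (out_b in "GC")
            non_n += (in_b != "N") - (out_b != "N")
        win_ok.append(non_n > 0 and 100.0 * gc / non_n <= ceiling)
    # per-base flag: the window centred on the base, clipped into bounds
    flags = []
    for i in range(length):
        lo = min(max(i - w // 2, 0), length - w)
        flags.append(win_ok[lo])
    # maximal runs of flagged bases
    runs = []
    i = 0
    while i < length:
        if flags[i]:
            j = i
            while j < length and flags[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    # merge runs separated by < merge_gap
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # refine and trim each block
    blocks = []
    for s, e in merged:
        while e > s and not _gc_le(seq[s : min(s + edge, e)], ceiling):
            s += 1
        while e > s and not _gc_le(seq[max(e - edge, s) : e], ceiling):
            e -= 1
        while e > s:
            if seq[s] not in "AT":
                s += 1
                continue
            if seq[e - 1] not in "AT":
                e -= 1
                continue
            if _gc_le(seq[s:e], ceiling):
                break
            s += 1
        if e - s >= min_len:
            blocks.append((s, e))
    return blocks


# ---------------------------------------------------------------------------
# Cluster calling: exhaustive contiguous-window enumeration
# ---------------------------------------------------------------------------

def oracle_clusters(
    roles: list[str | None],
    max_gap: int = 2,
    min_caz: int = 3,
    min_caz_sig: int = 2,
    min_sig: int = 1,
) -> list[tuple[int, ...]]:
    """All maximal qualifying windows over a per-gene role list.

    ``roles[i]`` is 'caz', 'sig' or None.  Returns sorted tuples of member
    gene indices.
    """
    n = len(roles)
    valid = []
    for i in range(n):
        if roles[i] is None:
            continue
        for j in range(i, n):
            if roles[j] is None:
                continue
            marks = [(k, roles[k]) for k in range(i, j + 1) if roles[k]]
            if any(b[0] - a[0] - 1 > max_gap for a, b in zip(marks, marks[1:])):
                continue
            caz = [k for k, r in marks if r == "caz"]
            if not caz:
                continue
            first_c, last_c = caz[0], caz[-1]
            terminal_sig_ok = all(
                (first_c - k - 1 <= max_gap if k < first_c else k - last_c - 1 <= max_gap)
                for k, r in marks
                if r == "sig" and not (first_c <= k <= last_c)
            )
            if not terminal_sig_ok:
                continue
            n_caz, n_sig = len(caz), len(marks) - len(caz)
            if n_caz >= min_caz or (n_caz >= min_caz_sig and n_sig >= min_sig):
                valid.append((i, j, tuple(k for k, _ in marks)))
    maximal = [
        v
        for v in valid
        if not any(w is not v and w[0] <= v[0] and v[1] <= w[1] for w in valid)
    ]
    return sorted({m[2] for m in maximal})


# ---------------------------------------------------------------------------
# Synteny: exhaustive longest-chain decomposition
# ---------------------------------------------------------------------------

def _chain_ok(pa, pb, sign, max_gap):
    da = pb[0] - pa[0]
    db = sign * (pb[1] - pa[1])
    return 0 < da <= max_gap and 0 < db <= max_gap


def oracle_decompose(
    ranks: list[tuple[int, int]], max_gap: int, min_block: int
) -> list[tuple[tuple[int, int], ...]]:
    """Iterated extraction of the longest chain (lexicographic tie-break)
    from a rank list sorted by rank_a; chains < min_block discarded."""
    remaining = sorted(ranks)
    blocks = []
    while remaining:
        best: tuple[int, tuple[int, ...]] | None = None

        def dfs(chain: list[int], sign: int | None) -> None:
            nonlocal best
            key = (-len(chain), tuple(chain))
            if best is None or key < best:
                best = key
            last = chain[-1]
            for j in range(last + 1, len(remaining)):
                for s in ((1, -1) if sign is None else (sign,)):
                    if _chain_ok(remaining[last], remaining[j], s, max_gap):
                        dfs(chain + [j], s)

        for i in range(len(remaining)):
            dfs([i], None)
        assert best is not None
        idx = best[1]
        if len(idx) < min_block:
            break
        blocks.append(tuple(remaining[i] for i in idx))
        used = set(idx)
        remaining = [p for i, p in enumerate(remaining) if i not in used]
    return blocks


# ---------------------------------------------------------------------------
# NUMTs: naive substring scan
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def oracle_numt_regions(
    nuclear: str, mito: str, min_len: int, circular: bool = True
) -> list[tuple[int, int]]:
    """Maximal nuclear regions whose every min_len-window occurs in the
    mitogenome (either strand; doubled when circular)."""
    fwd = mito + mito if circular else mito
    rev = mito.translate(_RC)[::-1]
    rev = rev + rev if circular else rev
    n = len(nuclear)
    flagged = []
    for i in range(n - min_len + 1):
        w = nuclear[i : i + min_len]
        flagged.append(w in fwd or w in rev)
    regions = []
    i = 0
    while i < len(flagged):
        if flagged[i]:
            j = i
            while j < len(flagged) and flagged[j]:
                j += 1
            regions.append((i, j - 1 + min_len))
            i = j
        else:
            i += 1
    return regions
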