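"""Telomeric-repeat detection and NUMT (nuclear mitochondrial DNA) search.

Fungal chromosome assemblies that reach the telomeres carry tandem copies of
the unit TTAGGG at the 3' terminus and its reverse complement CCCTAA at the
5' terminus.  Detection counts perfect tandem copies of the unit inside a
terminal search window.

NUMTs — fragments of the circular mitogenome integrated into nuclear
chromosomes — are found by exact seed-and-extend matching against both
mitogenome strands, with nearby collinear hits merged across small gaps so
that "almost identical" insertions with scattered point mutations are
reported as one hit with a percent identity.  The mitogenome is treated as
circular by doubling its sequence and canonicalizing coordinates modulo its
length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .atrich import AtRichBlock
from .genome_io import Chromosome, Genome, Interval

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TelomereCall:
    chromosome: str
    end: str  # "five_prime" | "three_prime"
    repeat_copies: int
    present: bool


@dataclass(frozen=True)
class NumtHit:
    """A nuclear match to the mitogenome.

    Nuclear coordinates are 0-based half-open.  ``mito_start`` is in
    [0, mito length); ``mito_end = mito_start + matched span`` and may exceed
    the mitogenome length when the hit wraps the circular origin.  ``strand``
    is '+' when the nuclear sequence matches the mitogenome forward strand.
    """

    chromosome: str
    start: int
    end: int
    mito_start: int
    mito_end: int
    strand: str
    identity: float
    matched: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.chromosome, self.start, self.end)

    def report_1based(self) -> tuple[int, int, int]:
        """(start, end, length) in the 1-based inclusive convention of
        printed reports, where length == end - start + 1."""
        return self.start + 1, self.end, self.end - self.start


def _max_tandem(window: str, unit: str) -> int:
    """Maximal tandem run of ``unit`` in ``window`` (no mismatches)."""
    u = len(unit)
    n = len(window)
    if u == 0 or n < u:
        return 0
    runs = [0] * n
    best = 0
    for i in range(n - u, -1, -1):
        if window[i : i + u] == unit:
            runs[i] = 1 + (runs[i + u] if i + u <= n - u else 0)
            if runs[i] > best:
                best = runs[i]
    return best


def detect_telomeres(
    genome: Genome,
    repeat_unit: str = "TTAGGG",
    min_copies: int = 3,
    search_window: int = 500,
) -> list[TelomereCall]:
    """Count tandem telomeric repeats in each chromosome's terminal windows.

    The 3' window is scanned for ``repeat_unit`` and the 5' window for its
    reverse complement; a call is present when at least ``min_copies``
    perfect tandem copies are found.  Chromosomes shorter than the window are
    scanned whole.
    """
    if not repeat_unit:
        raise ValueError("repeat_unit must be non-empty")
    if search_window < min_copies * len(repeat_unit):
        raise ValueError("search_window must cover min_copies repeat units")
    unit = repeat_unit.upper()
    rc_unit = reverse_complement(unit)
    calls: list[TelomereCall] = []
    for chrom in genome:
        w = min(search_window, chrom.length)
        five = _max_tandem(chrom.sequence[:w], rc_unit)
        three = _max_tandem(chrom.sequence[-w:], unit)
        calls.append(
            TelomereCall(chrom.name, "five_prime", five, five >= min_copies)
        )
        calls.append(
            TelomereCall(chrom.name, "three_prime", three, three >= min_copies)
        )
    return calls


def _seed_index(target: str, k: int, n_positions: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(n_positions):
        index.setdefault(target[i : i + k], []).append(i)
    return index


def _exact_matches(
    query: str, target: str, k: int, n_seed_positions: int
) -> list[tuple[int, int, int]]:
    """Maximal exact matches (q_start, t_start, length) of query vs target.

    Seeds of length ``k`` anchored at target positions < n_seed_positions are
    extended maximally in both directions; per diagonal, seeds inside an
    already-extended match are skipped.
    """
    index = _seed_index(target, k, n_seed_positions)
    nq, nt = len(query), len(target)
    covered: dict[int, int] = {}  # diagonal -> query end already matched
    matches: list[tuple[int, int, int]] = []
    for qi in range(nq - k + 1):
        positions = index.get(query[qi : qi + k])
        if not positions:
            continue
        for ti in positions:
            diag = qi - ti
            if covered.get(diag, -1) >= qi + k:
                continue
            qs, ts = qi, ti
            while qs > 0 and ts > 0 and query[qs - 1] == target[ts - 1]:
                qs -= 1
                ts -= 1
            qe, te = qi + k, ti + k
            while qe < nq and te < nt and query[qe] == target[te]:
                qe += 1
                te += 1
            covered[diag] = qe
            matches.append((qs, ts, qe - qs))
    return matches


def _merge_matches(
    matches: list[tuple[int, int, int]], merge_gap: int, k: int
) -> list[tuple[int, int, int, int, int]]:
    """Merge collinear nearby matches.

    Returns (q_start, q_end, t_start, t_end, matched_bases).  Two matches
    merge when their query and target gaps are each <= merge_gap and the
    diagonal drift is <= merge_gap (small substitutions/indels).
    """
    matches = sorted(matches)
    merged: list[list[int]] = []  # [qs, qe, ts, te, matched]
    for qs, ts, ln in matches:
        qe, te = qs + ln, ts + ln
        if merged:
            m = merged[-1]
            qgap = qs - m[1]
            tgap = ts - m[3]
            if (
                -k <= qgap <= merge_gap
                and -k <= tgap <= merge_gap
                and abs(qgap - tgap) <= merge_gap
            ):
                m[1] = max(m[1], qe)
                m[3] = max(m[3], te)
                m[4] = min(m[1] - m[0], m[4] + ln)
                continue
        merged.append([qs, qe, ts, te, ln])
    return [tuple(m) for m in merged]


def find_numts(
    genome: Genome,
    mitogenome: Chromosome | str,
    min_len: int = 100,
    min_identity: float = 90.0,
    seed_len: int = 15,
    merge_gap: int = 50,
    circular: bool = True,
) -> list[NumtHit]:
    """Find nuclear insertions of mitogenome sequence.

    Exact seeds of ``seed_len`` bases are extended maximally against both
    mitogenome strands; collinear hits within ``merge_gap`` are merged, and
    merged hits must reach ``min_len`` bases and ``min_identity`` percent
    (matched bases over nuclear span).  Hits contained in a longer hit on the
    same chromosome are dropped.
    """
    mito = (
        mitogenome.sequence if isinstance(mitogenome, Chromosome) else mitogenome
    ).upper()
    if not mito:
        raise ValueError("mitogenome is empty")
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    if not (1 <= seed_len <= min_len):
        raise ValueError("seed_len must be in [1, min_len]")
    m = len(mito)
    hits: list[NumtHit] = []
    strands = {"+": mito, "-": reverse_complement(mito)}
    for chrom in genome:
        chrom_hits: list[NumtHit] = []
        for strand, frame in strands.items():
            target = frame + frame if circular else frame
            n_seed_positions = (
                m if circular else max(0, len(frame) - seed_len + 1)
            )
            raw = _exact_matches(
                chrom.sequence, target, seed_len, n_seed_positions
            )
            for qs, qe, ts, te, matched in _merge_matches(raw, merge_gap, seed_len):
                span = qe - qs
                identity = 100.0 * min(matched, span) / span
                if span < min_len or identity < min_identity:
                    continue
                # canonicalize mito coordinates to the forward strand
                if strand == "+":
                    ms, me = ts, te
                else:
                    total = len(frame)
                    ms, me = total * (2 if circular else 1) - te, None
                    me = ms + (te - ts)
                ms_canon = ms % m
                chrom_hits.append(
                    NumtHit(
                        chromosome=chrom.name,
                        start=qs,
                        end=qe,
                        mito_start=ms_canon,
                        mito_end=ms_canon + (te - ts),
                        strand=strand,
                        identity=round(identity, 2),
                        matched=min(matched, span),
                    )
                )
        # drop hits nested inside a longer hit (circular doubling artefacts)
        chrom_hits.sort(key=lambda h: (h.start, -(h.end - h.start)))
        kept: list[NumtHit] = []
        for h in chrom_hits:
            if any(
                k.start <= h.start and h.end <= k.end and k.length > h.length
                for k in kept
            ):
                continue
            kept.append(h)
        hits.extend(kept)
    hits.sort(key=lambda h: (h.chromosome, h.start))
    return hits


def numt_atblock_adjacency(
    hits: Sequence[NumtHit],
    atblocks: Sequence[AtRichBlock | Interval],
    flank: int = 500,
) -> list[str]:
    """Classify each hit as 'within', 'adjacent' or 'distant' to AT blocks.

    'within': fully contained in a block; 'adjacent': within ``flank`` bases
    of a block (or partially overlapping); otherwise 'distant'.
    """
    blocks = [
        b.interval if isinstance(b, AtRichBlock) else b for b in atblocks
    ]
    by_chrom: dict[str, list[Interval]] = {}
    for iv in blocks:
        by_chrom.setdefault(iv.chromosome, []).append(iv)
    flags: list[str] = []
    for h in hits:
        flag = "distant"
        for iv in by_chrom.get(h.chromosome, []):
            if iv.start <= h.start and h.end <= iv.end:
                flag = "within"
                break
            if h.start < iv.end + flank and iv.start - flank < h.end:
                flag = "adjacent"
        flags.append(flag)
    return flags
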