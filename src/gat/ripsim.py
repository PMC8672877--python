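"""Synthetic fungal genome simulator with planted ground truth.

The generator emulates the architecture of a chromosome-level, RIP-active
fungal genome: a moderately GC-rich background carrying annotated genes,
transposon copies degenerated into AT-rich relics by repeat-induced point
mutation (RIP), one long relic per chromosome sitting inside the largest
gene desert (the centromere), telomeric repeat tracts capping both termini,
clustered CAZyme/signature genes, a secreted-protein feature table with
effector candidates, and mitogenome fragments (NUMTs) inserted inside AT
relics.  Every planted feature is recorded in a truth ledger sufficient to
score all analysis modules without external data.

RIP is modelled with the canonical fungal dinucleotide preference: each C in
a CpA context mutates to T with probability ``rip_rate``, and symmetrically
each G in a TpG context (a CpA on the complementary strand) mutates to A.
Contexts are evaluated on the input sequence and all mutations applied
simultaneously.  Only duplicated (transposon) copies are RIP-eligible;
background sequence is never mutated.  A ``context_free`` flag lifts the
dinucleotide restriction for sensitivity analyses.

Chromosome construction: each chromosome of exact length ``chromosome_length``
is laid out as  [5' telomere | zone A | centromeric desert | zone B |
3' telomere].  Genes and transposon relics are placed in the two zones with
near-uniform spacers (at most one relic between consecutive genes), which
bounds every ordinary intergenic gap well below the desert length, so the
planted desert is always the longest ORF-free region and the planted long
relic the longest AT-rich block.  All randomness flows from a single
``numpy`` generator seeded once; construction order is fixed (mitogenome,
transposon master, then chromosome by chromosome), so identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import Chromosome, GeneModel, Genome, Interval
from .telonumt import reverse_complement

_A, _C, _G, _T = (ord(b) for b in "ACGT")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ClusterSpec:
    """A planted gene cluster: member composition and intervening-gene gaps.

    ``gaps`` has one entry per consecutive member pair (so length
    ``n_caz + n_sig - 1``), each the number of plain genes between the two
    members; entries must not exceed the caller's intergenic bound if the
    cluster is meant to be recovered.
    """

    n_caz: int
    n_sig: int
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_caz < 1:
            raise ValueError("a cluster needs at least one CAZyme")
        if self.n_caz + self.n_sig > 1 and self.n_caz < 2:
            raise ValueError("multi-member clusters must be CAZyme-anchored at both ends")
        if len(self.gaps) != self.n_caz + self.n_sig - 1:
            raise ValueError("gaps must have n_members - 1 entries")

    @property
    def n_members(self) -> int:
        return self.n_caz + self.n_sig

    @property
    def gene_span(self) -> int:
        return self.n_members + sum(self.gaps)


@dataclass(frozen=True)
class NumtSpec:
    """A planted NUMT: a mitogenome interval copied into a target AT relic
    (identified by chromosome index and relic rank on that chromosome)."""

    mito_start: int
    length: int
    chromosome: int
    relic: int


@dataclass
class SimConfig:
    n_chromosomes: int = 3
    chromosome_length: int = 200_000
    background_gc: float = 55.0
    n_genes_per_chromosome: int = 50
    gene_length_range: tuple[int, int] = (1200, 1800)
    transposon_length: int = 2000
    n_transposon_copies: int = 8  # per chromosome, centromere excluded
    transposon_gc: float = 45.0
    rip_rate: float = 0.8
    #: RIP rounds applied to each relic copy; successive rounds open fresh
    #: dinucleotide contexts, emulating repeated sexual cycles, so relics are
    #: AT-rich end to end rather than only at initially CpA-dense stretches
    n_rip_rounds: int = 3
    rip_context_free: bool = False
    centromere_block_length: int = 6000
    desert_pad: int = 7000  # gene-free background on each side of the centromere
    cluster_specs: tuple[ClusterSpec, ...] = (
        ClusterSpec(3, 0, (1, 1)),
        ClusterSpec(2, 1, (0, 1)),
        ClusterSpec(4, 1, (1, 0, 2, 0)),
    )
    n_background_cazymes: int = 4
    n_background_signatures: int = 4
    numt_specs: tuple[NumtSpec, ...] = (
        NumtSpec(1000, 139, 0, 0),
        NumtSpec(5000, 166, 0, 1),
        NumtSpec(9000, 170, 1, 0),
    )
    mito_length: int = 30_000
    mito_gc: float = 28.0
    telomere_unit: str = "TTAGGG"
    telomere_copies: int = 10
    sp_fraction: float = 0.12
    n_effectors_per_chromosome: int = 3
    min_spacer: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rip_rate <= 1.0):
            raise ValueError("rip_rate must be in [0, 1]")
        for name in (
            "n_chromosomes",
            "chromosome_length",
            "transposon_length",
            "centromere_block_length",
            "mito_length",
            "telomere_copies",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimTruth:
    """Planted-feature ledger; coordinates are 0-based half-open."""

    at_blocks: list[Interval] = field(default_factory=list)
    centromeres: dict[str, dict[str, Interval]] = field(default_factory=dict)
    clusters: list[dict] = field(default_factory=list)
    numts: list[dict] = field(default_factory=list)
    telomeres: dict[str, dict[str, int]] = field(default_factory=dict)
    effectors: list[str] = field(default_factory=list)
    relic_gc: dict[Interval, float] = field(default_factory=dict)


@dataclass
class SimResult:
    genome: Genome
    genes: list[GeneModel]
    features: pd.DataFrame
    mitogenome: Chromosome
    truth: SimTruth
    config: SimConfig


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random nucleotide sequence at the requested GC percent."""
    g = gc / 200.0
    a = (100.0 - gc) / 200.0
    idx = rng.choice(4, size=length, p=[a, g, g, a])
    return _BASES[idx].tobytes().decode("ascii")


def rip_mutate(
    sequence: str,
    rate: float,
    rng: np.random.Generator,
    context_free: bool = False,
) -> str:
    """Apply RIP mutations: C:G pairs become T:A at eligible sites.

    With the default dinucleotide context, eligible sites are Cs in CpA and
    Gs in TpG (the complementary-strand CpA); with ``context_free`` every C
    and G is eligible.  Each eligible site converts independently with
    probability ``rate``; contexts are read from the input, mutations applied
    simultaneously, and length is preserved.  One uniform draw is consumed
    per eligible site regardless of ``rate``, so runs at different rates from
    identically seeded generators are monotonically coupled.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    if context_free:
        c_sites = np.flatnonzero(arr == _C)
        g_sites = np.flatnonzero(arr == _G)
    else:
        c_sites = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _A))
        g_sites = np.flatnonzero((arr[:-1] == _T) & (arr[1:] == _G)) + 1
    sites = np.sort(np.concatenate([c_sites, g_sites]))
    if sites.size:
        hit = rng.random(sites.size) < rate
        hit_sites = sites[hit]
        is_c = arr[hit_sites] == _C
        arr[hit_sites[is_c]] = _T
        arr[hit_sites[~is_c]] = _A
    return arr.tobytes().decode("ascii")


def rip_eligible_sites(sequence: str, context_free: bool = False) -> int:
    """Number of RIP-eligible sites in a sequence (for calibration)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    if context_free:
        return int(((arr == _C) | (arr == _G)).sum())
    cpa = int(((arr[:-1] == _C) & (arr[1:] == _A)).sum())
    tpg = int(((arr[:-1] == _T) & (arr[1:] == _G)).sum())
    return cpa + tpg


def _rip_copy(template: str, config: SimConfig, rng: np.random.Generator) -> str:
    """A relic copy: the template after ``n_rip_rounds`` of RIP mutation."""
    seq = template
    for _ in range(max(1, config.n_rip_rounds)):
        seq = rip_mutate(seq, config.rip_rate, rng, config.rip_context_free)
    return seq


def _spacers(
    rng: np.random.Generator, total: int, n: int, min_spacer: int
) -> list[int]:
    """n spacer lengths summing exactly to ``total``, each >= min_spacer and
    near-uniform (between 0.5x and 1.5x the mean of the free mass)."""
    if total < n * min_spacer:
        raise ValueError("infeasible packing: features exceed chromosome length")
    raw = rng.uniform(0.5, 1.5, size=n)
    free = total - n * min_spacer
    alloc = np.floor(raw / raw.sum() * free).astype(int)
    alloc[-1] += free - int(alloc.sum())
    return (alloc + min_spacer).tolist()


def _layout_zone(
    rng: np.random.Generator,
    zone_start: int,
    zone_end: int,
    gene_lengths: list[int],
    n_relics: int,
    relic_length: int,
    min_spacer: int,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Place genes and relics in a zone; at most one relic per gene gap.

    Returns (gene intervals, relic intervals) in coordinate order.
    """
    n_genes = len(gene_lengths)
    if n_relics > n_genes + 1:
        raise ValueError("infeasible packing: more relics than gene gaps")
    slots = rng.choice(n_genes + 1, size=n_relics, replace=False)
    units: list[tuple[str, int]] = []
    for i in range(n_genes + 1):
        if i in slots:
            units.append(("relic", relic_length))
        if i < n_genes:
            units.append(("gene", gene_lengths[i]))
    total_units = sum(length for _, length in units)
    spacers = _spacers(
        rng, zone_end - zone_start - total_units, len(units) + 1, min_spacer
    )
    genes: list[tuple[int, int]] = []
    relics: list[tuple[int, int]] = []
    pos = zone_start
    for (kind, length), spacer in zip(units, spacers):
        pos += spacer
        target = genes if kind == "gene" else relics
        target.append((pos, pos + length))
        pos += length
    return genes, relics


def _assign_features(
    rng: np.random.Generator,
    config: SimConfig,
    genes: list[GeneModel],
    genes_by_chrom: dict[str, list[GeneModel]],
    truth: SimTruth,
) -> pd.DataFrame:
    """Build the per-gene feature table and plant clusters/effectors.

    Cluster members are assigned so that CAZymes anchor both ends; scattered
    background CAZymes/signature genes are isolated from every other member
    gene by at least four plain genes, so they can never chain under an
    intergenic bound of two.
    """
    chrom_names = list(genes_by_chrom)
    roles: dict[str, str] = {}
    member_index: dict[str, set[int]] = {name: set() for name in chrom_names}

    # planted clusters, round-robin over chromosomes
    cursor = {name: 3 for name in chrom_names}
    for j, spec in enumerate(config.cluster_specs):
        chrom = chrom_names[j % len(chrom_names)]
        ordered = genes_by_chrom[chrom]
        anchor = cursor[chrom]
        if anchor + spec.gene_span > len(ordered) - 3:
            raise ValueError("infeasible packing: cluster does not fit on chromosome")
        member_roles = ["caz"]
        if spec.n_members > 1:
            interior = ["sig"] * spec.n_sig + ["caz"] * (spec.n_caz - 2)
            member_roles += interior + ["caz"]
        idx = anchor
        member_ids = []
        for pos, role in enumerate(member_roles):
            gid = ordered[idx].gene_id
            roles[gid] = role
            member_ids.append(gid)
            member_index[chrom].add(idx)
            if pos < len(spec.gaps):
                idx += spec.gaps[pos] + 1
        cursor[chrom] = idx + 5
        truth.clusters.append(
            {
                "chromosome": chrom,
                "member_ids": tuple(member_ids),
                "n_caz": spec.n_caz,
                "n_sig": spec.n_sig,
            }
        )

    # scattered background members, isolated by >= 4 plain genes
    def scatter(chrom: str, n: int, role: str) -> None:
        ordered = genes_by_chrom[chrom]
        taken = member_index[chrom]
        placed = 0
        i = max(taken) + 5 if taken else 3
        while placed < n and i < len(ordered) - 1:
            if all(abs(i - t) >= 4 for t in taken):
                roles[ordered[i].gene_id] = role
                taken.add(i)
                placed += 1
                i += 5
            else:
                i += 1

    for ci, chrom in enumerate(chrom_names):
        scatter(chrom, config.n_background_cazymes // len(chrom_names) + 1, "caz")
        scatter(chrom, config.n_background_signatures // len(chrom_names) + 1, "sig")

    caz_classes = ["GH", "GT", "CE", "AA", "PL", "CBM"]
    rows = []
    sig_toggle = 0
    for g in genes:
        role = roles.get(g.gene_id)
        caz = ""
        is_tp = is_tf = False
        if role == "caz":
            caz = caz_classes[int(rng.integers(0, len(caz_classes)))]
        elif role == "sig":
            if sig_toggle % 2 == 0:
                is_tp = True
            else:
                is_tf = True
            sig_toggle += 1
        has_sp = bool(rng.random() < config.sp_fraction)
        tm = int(rng.integers(1, 8)) if rng.random() < 0.15 else 0
        gpi = bool(rng.random() < 0.05)
        plen = int(rng.integers(150, 1200))
        rows.append([g.gene_id, caz, is_tp, is_tf, has_sp, tm, gpi, plen])

    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "cazyme_class",
            "is_transporter",
            "is_tf",
            "has_sp",
            "tm_count",
            "has_gpi",
            "protein_length",
        ],
    )
    # plant unambiguous effector candidates per chromosome
    df = df.set_index("gene_id", drop=False)
    for chrom in chrom_names:
        ordered = genes_by_chrom[chrom]
        picks = rng.choice(
            len(ordered), size=config.n_effectors_per_chromosome, replace=False
        )
        for i in picks:
            gid = ordered[i].gene_id
            df.loc[gid, ["has_sp", "tm_count", "has_gpi"]] = [True, 0, False]
            df.loc[gid, "protein_length"] = int(rng.integers(80, 300))
            truth.effectors.append(gid)
    return df.reset_index(drop=True)


def simulate_genome(config: SimConfig = SimConfig()) -> SimResult:
    """Generate a genome, annotation, feature table, mitogenome and truth.

    Deterministic under ``config.seed``: identical configs give
    byte-identical outputs.  Raises on infeasible packing before emitting
    anything.
    """
    rng = np.random.default_rng(config.seed)
    tel3 = config.telomere_unit.upper() * config.telomere_copies
    tel5 = reverse_complement(config.telomere_unit.upper()) * config.telomere_copies
    tel_len = len(tel3)
    L = config.chromosome_length
    desert_len = config.centromere_block_length + 2 * config.desert_pad
    desert_start = L // 2 - desert_len // 2
    if desert_start <= tel_len or desert_start + desert_len >= L - tel_len:
        raise ValueError("infeasible packing: desert does not fit between telomeres")

    mito = Chromosome("mitogenome", random_sequence(rng, config.mito_length, config.mito_gc))
    master = random_sequence(rng, config.transposon_length, config.transposon_gc)
    cen_reps = -(-config.centromere_block_length // config.transposon_length)
    cen_template = (master * cen_reps)[: config.centromere_block_length]

    truth = SimTruth()
    chroms: list[Chromosome] = []
    genes: list[GeneModel] = []
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    relics_by_chrom: dict[str, list[Interval]] = {}

    for ci in range(config.n_chromosomes):
        name = f"chr{ci + 1}"
        arr = np.frombuffer(
            random_sequence(rng, L, config.background_gc).encode("ascii"),
            dtype=np.uint8,
        ).copy()
        arr[:tel_len] = np.frombuffer(tel5.encode("ascii"), dtype=np.uint8)
        arr[L - tel_len :] = np.frombuffer(tel3.encode("ascii"), dtype=np.uint8)

        n_genes = config.n_genes_per_chromosome
        na = n_genes // 2 + n_genes % 2
        nb = n_genes - na
        nr = config.n_transposon_copies
        ra = nr // 2 + nr % 2
        rb = nr - ra
        lengths_a = rng.integers(*config.gene_length_range, size=na).tolist()
        lengths_b = rng.integers(*config.gene_length_range, size=nb).tolist()
        genes_a, relics_a = _layout_zone(
            rng, tel_len, desert_start, lengths_a, ra,
            config.transposon_length, config.min_spacer,
        )
        genes_b, relics_b = _layout_zone(
            rng, desert_start + desert_len, L - tel_len, lengths_b, rb,
            config.transposon_length, config.min_spacer,
        )

        # centromere: one long RIP-degenerated relic array centred in the desert
        cen_start = desert_start + config.desert_pad
        cen_seq = _rip_copy(cen_template, config, rng)
        cen_iv = Interval(name, cen_start, cen_start + len(cen_seq))
        arr[cen_iv.start : cen_iv.end] = np.frombuffer(
            cen_seq.encode("ascii"), dtype=np.uint8
        )
        truth.at_blocks.append(cen_iv)
        truth.relic_gc[cen_iv] = _gc_of(cen_seq)
        truth.centromeres[name] = {
            "block": cen_iv,
            "desert": Interval(name, desert_start, desert_start + desert_len),
        }

        chrom_relics: list[Interval] = []
        for s, e in relics_a + relics_b:
            relic_seq = _rip_copy(master, config, rng)
            arr[s:e] = np.frombuffer(relic_seq.encode("ascii"), dtype=np.uint8)
            iv = Interval(name, s, e)
            chrom_relics.append(iv)
            truth.at_blocks.append(iv)
            truth.relic_gc[iv] = _gc_of(relic_seq)
        chrom_relics.sort(key=lambda iv: iv.start)
        relics_by_chrom[name] = chrom_relics

        chrom_genes: list[GeneModel] = []
        for k, (s, e) in enumerate(sorted(genes_a + genes_b)):
            gid = f"{name}_g{k + 1:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            chrom_genes.append(GeneModel(gid, name, s, e, strand))
        genes_by_chrom[name] = chrom_genes
        genes.extend(chrom_genes)

        chroms.append(Chromosome(name, arr.tobytes().decode("ascii")))
        truth.telomeres[name] = {
            "five_prime": config.telomere_copies,
            "three_prime": config.telomere_copies,
        }

    # NUMTs: copy mitogenome fragments into the middle of target relics
    seq_arrays = {
        c.name: np.frombuffer(c.sequence.encode("ascii"), dtype=np.uint8).copy()
        for c in chroms
    }
    for spec in config.numt_specs:
        chrom_name = f"chr{spec.chromosome + 1}"
        relics = relics_by_chrom[chrom_name]
        if spec.relic >= len(relics):
            raise ValueError("infeasible packing: NUMT target relic does not exist")
        relic = relics[spec.relic]
        if spec.length + 2 > relic.length:
            raise ValueError("infeasible packing: NUMT longer than target relic")
        ms, me = spec.mito_start, spec.mito_start + spec.length
        if me > mito.length:
            raise ValueError("NUMT source interval outside mitogenome")
        ns = relic.start + (relic.length - spec.length) // 2
        arr = seq_arrays[chrom_name]
        frag = np.frombuffer(mito.sequence[ms:me].encode("ascii"), dtype=np.uint8)
        arr[ns : ns + spec.length] = frag
        # make the flanks mismatch the mitogenome so the planted interval is
        # exactly the maximal match
        for gpos, mbase in ((ns - 1, mito.sequence[ms - 1] if ms > 0 else None),
                            (ns + spec.length, mito.sequence[me] if me < mito.length else None)):
            if mbase is not None and chr(arr[gpos]) == mbase:
                arr[gpos] = ord("A") if mbase != "A" else ord("T")
        truth.numts.append(
            {
                "chromosome": chrom_name,
                "nuclear": Interval(chrom_name, ns, ns + spec.length),
                "mito_start": ms,
                "mito_end": me,
                "length": spec.length,
            }
        )
    chroms = [
        Chromosome(c.name, seq_arrays[c.name].tobytes().decode("ascii"))
        for c in chroms
    ]

    genome = Genome(chroms, name=f"sim-seed{config.seed}")
    features = _assign_features(rng, config, genes, genes_by_chrom, truth)
    truth.at_blocks.sort(key=lambda iv: (iv.chromosome, iv.start))
    return SimResult(genome, genes, features, mito, truth, config)


def _gc_of(seq: str) -> float:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return 100.0 * float(((arr == _G) | (arr == _C)).sum()) / len(arr)


# ---------------------------------------------------------------------------
# Rearranged genome pairs
# ---------------------------------------------------------------------------

@dataclass
class SimPair:
    a: SimResult
    genome_b: Genome
    genes_b: list[GeneModel]
    ortholog_pairs: list[tuple[str, str]]
    breakpoints: list[dict]  # {"genome": "A"|"B", "chromosome", "position"}
    script: list[tuple]


def relic_cut_script(
    result: SimResult, chromosomes: Sequence[str] | None = None
) -> list[tuple]:
    """One inversion per chromosome with both cuts at planted relic midpoints.

    The non-centromere relics nearest the chromosome quarter points are used,
    so the inverted segment spans many genes and several genes remain outside
    both cuts — every breakpoint is then flanked by detectable synteny blocks.
    """
    script: list[tuple] = []
    cen = {name: info["block"] for name, info in result.truth.centromeres.items()}
    by_chrom: dict[str, list[Interval]] = {}
    for iv in result.truth.at_blocks:
        if iv != cen.get(iv.chromosome):
            by_chrom.setdefault(iv.chromosome, []).append(iv)
    for name in chromosomes or result.genome.names:
        relics = sorted(by_chrom.get(name, []), key=lambda iv: iv.start)
        if len(relics) < 2:
            continue
        length = result.genome[name].length
        first = min(relics, key=lambda iv: abs((iv.start + iv.end) // 2 - length // 4))
        last = min(relics, key=lambda iv: abs((iv.start + iv.end) // 2 - 3 * length // 4))
        if first is last:
            first, last = relics[0], relics[-1]
        script.append(
            ("inversion", name, (first.start + first.end) // 2, (last.start + last.end) // 2)
        )
    return script


def simulate_rearranged_pair(
    config: SimConfig = SimConfig(),
    script: list[tuple] | None = None,
) -> SimPair:
    """Simulate genome A, derive genome B by a rearrangement script.

    Script operations, applied in order to the evolving genome B:

    - ``("inversion", chrom, start, end)`` — reverse-complement the segment;
    - ``("translocation", chrom1, pos1, chrom2, pos2)`` — reciprocal exchange
      of the two chromosome tails.

    Cut positions must not fall inside genes, and operations may not touch a
    previously rearranged region (overlapping script segments are an error).
    The ortholog map is the identity on gene ids and the truth breakpoints
    are the cut positions.
    """
    result = simulate_genome(config)
    if script is None:
        script = relic_cut_script(result)

    seqs = {c.name: c.sequence for c in result.genome}
    genes_b = {g.gene_id: g for g in result.genes}
    touched: dict[str, list[tuple[int, int]]] = {}
    breakpoints: list[dict] = []

    def check_cut(chrom: str, pos: int) -> None:
        for g in genes_b.values():
            if g.chromosome == chrom and g.start < pos < g.end:
                raise ValueError(f"cut {chrom}:{pos} falls inside gene {g.gene_id}")

    def mark(chrom: str, start: int, end: int) -> None:
        for s, e in touched.get(chrom, []):
            if start < e and s < end:
                raise ValueError("overlapping script segments")
        touched.setdefault(chrom, []).append((start, end))

    for op in script:
        if op[0] == "inversion":
            _, chrom, start, end = op
            if not (0 <= start < end <= len(seqs[chrom])):
                raise ValueError(f"invalid inversion bounds on {chrom}")
            check_cut(chrom, start)
            check_cut(chrom, end)
            mark(chrom, start, end)
            seq = seqs[chrom]
            seqs[chrom] = seq[:start] + reverse_complement(seq[start:end]) + seq[end:]
            for gid, g in list(genes_b.items()):
                if g.chromosome == chrom and g.start >= start and g.end <= end:
                    genes_b[gid] = GeneModel(
                        gid,
                        chrom,
                        start + (end - g.end),
                        start + (end - g.start),
                        "-" if g.strand == "+" else "+",
                    )
            for pos in (start, end):
                breakpoints.append({"genome": "A", "chromosome": chrom, "position": pos})
                breakpoints.append({"genome": "B", "chromosome": chrom, "position": pos})
        elif op[0] == "translocation":
            _, c1, p1, c2, p2 = op
            if c1 == c2:
                raise ValueError("translocation requires two distinct chromosomes")
            check_cut(c1, p1)
            check_cut(c2, p2)
            mark(c1, p1, len(seqs[c1]))
            mark(c2, p2, len(seqs[c2]))
            tail1, tail2 = seqs[c1][p1:], seqs[c2][p2:]
            seqs[c1] = seqs[c1][:p1] + tail2
            seqs[c2] = seqs[c2][:p2] + tail1
            for gid, g in list(genes_b.items()):
                if g.chromosome == c1 and g.start >= p1:
                    genes_b[gid] = GeneModel(
                        gid, c2, p2 + (g.start - p1), p2 + (g.end - p1), g.strand
                    )
                elif g.chromosome == c2 and g.start >= p2:
                    genes_b[gid] = GeneModel(
                        gid, c1, p1 + (g.start - p2), p1 + (g.end - p2), g.strand
                    )
            for chrom, pos in ((c1, p1), (c2, p2)):
                breakpoints.append({"genome": "A", "chromosome": chrom, "position": pos})
                breakpoints.append({"genome": "B", "chromosome": chrom, "position": pos})
        else:
            raise ValueError(f"unknown script operation: {op[0]!r}")

    genome_b = Genome(
        [Chromosome(name, seqs[name]) for name in result.genome.names],
        name=result.genome.name + "-rearranged",
    )
    order = {n: i for i, n in enumerate(genome_b.names)}
    genes_b_list = sorted(
        genes_b.values(), key=lambda g: (order[g.chromosome], g.start)
    )
    pairs = [(g.gene_id, g.gene_id) for g in result.genes]
    return SimPair(result, genome_b, genes_b_list, pairs, breakpoints, list(script))
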