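"""Shared coordinate-safe data model and file I/O.

All coordinates inside the package are 0-based half-open.  The two places
where 1-based inclusive coordinates appear are the GFF3 boundary (per the
format standard) and human-facing span reports (:func:`span_length`), which
follow the convention used in genome papers, e.g. a fragment printed as
"139 bp (211,858 to 211,996)" means ``211996 - 211858 + 1 = 139``.

N bases are legal in sequences; they count toward length but are excluded
from both numerator and denominator of every GC computation in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

#: columns a per-gene feature table must carry (verdicts of upstream
#: annotation tools such as dbCAN2, SignalP, TMHMM and big-PI)
FEATURE_COLUMNS = (
    "gene_id",
    "cazyme_class",
    "is_transporter",
    "is_tf",
    "has_sp",
    "tm_count",
    "has_gpi",
    "protein_length",
)


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open interval on a named chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chromosome}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Chromosome:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"chromosome {self.name!r} has empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"chromosome {self.name!r} contains invalid characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """An ordered collection of uniquely named chromosomes."""

    chromosomes: list[Chromosome]
    name: str = ""

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome")
        self._by_name = {c.name: c for c in self.chromosomes}

    def __getitem__(self, name: str) -> Chromosome:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


@dataclass(frozen=True)
class GeneModel:
    """A gene span.  Strand is recorded but interval arithmetic is
    strand-agnostic throughout the package."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def interval(self) -> Interval:
        return Interval(self.chromosome, self.start, self.end)


def span_length(start_1based: int, end_1based: int) -> int:
    """Length of a 1-based inclusive span, the convention of printed reports.

    ``span_length(211858, 211996) == 139``.
    """
    if start_1based < 1 or end_1based < 1:
        raise ValueError("1-based coordinates must be >= 1")
    if end_1based < start_1based:
        raise ValueError(f"end {end_1based} < start {start_1based}")
    return end_1based - start_1based + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, name: str = "") -> Genome:
    """Read a (multi-)FASTA into a :class:`Genome`.

    Sequences are uppercased, record order is preserved, duplicate headers
    and empty records are errors.
    """
    chroms: list[Chromosome] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty FASTA record: {rec.id!r}")
        chroms.append(Chromosome(rec.id, seq))
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(chroms, name=name or Path(path).stem)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description="")
        for c in genome.chromosomes
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(
    path: str | Path,
    genome: Genome | None = None,
    feature_type: str = "gene",
) -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    GFF3 is 1-based inclusive; spans are converted to internal 0-based
    half-open coordinates.  Genes are returned sorted by (chromosome, start),
    with chromosome order taken from ``genome`` when given.  A gene extending
    past its chromosome end is an error naming the offending gene_id.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        start0, end0 = feat.start - 1, feat.end  # 1-based inclusive -> half-open
        if genome is not None:
            if feat.seqid not in genome:
                raise ValueError(
                    f"gene {gene_id}: unknown chromosome {feat.seqid!r}"
                )
            if end0 > genome[feat.seqid].length or start0 < 0:
                raise ValueError(
                    f"gene {gene_id}: span ({feat.start}, {feat.end}) outside "
                    f"chromosome {feat.seqid} bounds"
                )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=feat.seqid,
                start=start0,
                end=end0,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
            )
        )
    order = {n: i for i, n in enumerate(genome.names)} if genome else {}
    genes.sort(key=lambda g: (order.get(g.chromosome, 0), g.chromosome, g.start))
    return genes


def write_gff3(
    genes: Sequence[GeneModel],
    path: str | Path,
    genome: Genome | None = None,
    source: str = "gat",
) -> None:
    """Write gene models as a minimal GFF3 (gene features only)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if genome is not None:
            for c in genome.chromosomes:
                fh.write(f"##sequence-region {c.name} 1 {c.length}\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.chromosome,
                        source,
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(
    intervals: Iterable[Interval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    """Write intervals as sorted BED (0-based half-open, tab-separated)."""
    rows = list(intervals)
    if names is not None and len(names) != len(rows):
        raise ValueError("names must match intervals one-to-one")
    order = sorted(range(len(rows)), key=lambda i: (rows[i].chromosome, rows[i].start, rows[i].end))
    with open(path, "w") as fh:
        for i in order:
            iv = rows[i]
            line = f"{iv.chromosome}\t{iv.start}\t{iv.end}"
            if names is not None:
                line += f"\t{names[i]}"
            fh.write(line + "\n")


def read_bed(path: str | Path) -> list[Interval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            intervals.append(Interval(parts[0], int(parts[1]), int(parts[2])))
    return intervals


# ---------------------------------------------------------------------------
# Feature tables (TSV)
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a per-gene feature TSV (CAZyme class, SP/TM/GPI verdicts, ...).

    Boolean columns accept 0/1 or True/False; ``cazyme_class`` is empty or
    one of AA/CBM/CE/GH/GT/PL.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    for col in ("is_transporter", "is_tf", "has_sp", "has_gpi"):
        df[col] = df[col].astype(bool)
    df["tm_count"] = df["tm_count"].astype(int)
    df["protein_length"] = df["protein_length"].astype(int)
    df["cazyme_class"] = df["cazyme_class"].fillna("").astype(str)
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def resolve_features(
    features: pd.DataFrame, genes: Sequence[GeneModel]
) -> tuple[pd.DataFrame, int]:
    """Split a feature table into rows resolvable against the annotation.

    Returns the resolvable subset and the number of orphaned rows; orphans
    trigger a warning rather than an error so partial tables remain usable.
    """
    known = {g.gene_id for g in genes}
    mask = features["gene_id"].isin(known)
    n_orphans = int((~mask).sum())
    if n_orphans:
        warnings.warn(
            f"{n_orphans} feature-table rows do not match any annotated gene",
            stacklevel=2,
        )
    return features[mask].reset_index(drop=True), n_orphans
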