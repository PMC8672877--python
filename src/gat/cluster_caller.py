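"""CAZyme gene-cluster (CAZ-GC) calling.

A cluster is a physically linked run of carbohydrate-active-enzyme genes,
optionally with *signature* genes (transporters or transcription factors).
The qualification rule is deliberately stringent: a cluster must contain at
least ``min_members_alone`` CAZyme genes (3), or at least
``min_members_with_signature`` CAZymes (2) together with at least
``min_signatures`` signature genes (1), all members lying within
``max_intergenic_distance`` intergenic distances of each other.

"Within <= 2 intergenic distances" is interpreted as at most two intervening
genes between consecutive member genes, counting genes on both strands — a
gene-adjacency metric rather than base pairs, which keeps the rule
scale-free across genomes of different gene densities.

Clusters are named positionally, e.g. ``CAZ-GC 3.2`` is the second cluster
from the left arm (lower coordinates) of the third chromosome.  The same
engine can carry a different member ontology (e.g. SM-BGC-style names), but
no secondary-metabolite detection is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import GeneModel, Interval

logger = logging.getLogger(__name__)

CAZYME_CLASSES = frozenset({"AA", "CBM", "CE", "GH", "GT", "PL"})


@dataclass(frozen=True)
class ClusterRules:
    min_members_alone: int = 3
    min_members_with_signature: int = 2
    min_signatures: int = 1
    max_intergenic_distance: int = 2

    def __post_init__(self) -> None:
        if min(
            self.min_members_alone,
            self.min_members_with_signature,
            self.min_signatures,
        ) < 1:
            raise ValueError("cluster rule counts must be >= 1")
        if self.max_intergenic_distance < 0:
            raise ValueError("max_intergenic_distance must be >= 0")


@dataclass(frozen=True)
class GeneCluster:
    chromosome: str
    member_ids: tuple[str, ...]
    n_cazymes: int
    n_signatures: int
    span: Interval
    name: str = ""


def gene_roles(features: pd.DataFrame) -> dict[str, str]:
    """Map gene_id -> role: 'caz' for a CAZyme, 'sig' for transporter/TF.

    A CAZyme annotation wins over signature flags when both are present.
    """
    roles: dict[str, str] = {}
    for row in features.itertuples(index=False):
        caz = str(getattr(row, "cazyme_class", "") or "").strip()
        if caz and caz in CAZYME_CLASSES:
            roles[row.gene_id] = "caz"
        elif bool(getattr(row, "is_transporter", False)) or bool(
            getattr(row, "is_tf", False)
        ):
            roles[row.gene_id] = "sig"
    return roles


def _trim_chain(
    chain: list[tuple[int, str]], max_gap: int
) -> list[tuple[int, str]]:
    """Drop terminal signature genes not adjacent (within the intervening-
    gene bound) to a CAZyme; interior signatures are anchored by CAZymes."""
    caz_positions = [i for i, role in chain if role == "caz"]
    if not caz_positions:
        return []
    first_c, last_c = caz_positions[0], caz_positions[-1]
    kept = [
        (i, role)
        for i, role in chain
        if role == "caz"
        or (first_c <= i <= last_c)  # anchored by CAZymes on both sides
        or (i < first_c and first_c - i - 1 <= max_gap)
        or (i > last_c and i - last_c - 1 <= max_gap)
    ]
    return kept


def call_clusters(
    genes: Sequence[GeneModel],
    features: pd.DataFrame,
    rules: ClusterRules = ClusterRules(),
) -> list[GeneCluster]:
    """Call maximal qualifying gene clusters on every chromosome.

    ``genes`` must cover the full annotation (member *and* non-member genes)
    since the distance metric counts intervening genes.  Feature rows whose
    gene_id is absent from the annotation are skipped with a warning.
    """
    known = {g.gene_id for g in genes}
    orphans = set(features["gene_id"]) - known
    if orphans:
        logger.warning(
            "%d feature rows reference genes absent from the annotation; skipped",
            len(orphans),
        )
    roles = {
        gid: role for gid, role in gene_roles(features).items() if gid in known
    }

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    clusters: list[GeneCluster] = []
    max_gap = rules.max_intergenic_distance
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end))
        marks = [
            (i, roles[g.gene_id])
            for i, g in enumerate(ordered)
            if g.gene_id in roles
        ]
        # split into maximal chains at intervening-gene gaps > max_gap
        chains: list[list[tuple[int, str]]] = []
        for mark in marks:
            if chains and mark[0] - chains[-1][-1][0] - 1 <= max_gap:
                chains[-1].append(mark)
            else:
                chains.append([mark])
        for chain in chains:
            trimmed = _trim_chain(chain, max_gap)
            if not trimmed:
                continue
            n_caz = sum(1 for _, role in trimmed if role == "caz")
            n_sig = sum(1 for _, role in trimmed if role == "sig")
            qualifies = n_caz >= rules.min_members_alone or (
                n_caz >= rules.min_members_with_signature
                and n_sig >= rules.min_signatures
            )
            if not qualifies:
                continue
            members = [ordered[i] for i, _ in trimmed]
            clusters.append(
                GeneCluster(
                    chromosome=chrom,
                    member_ids=tuple(m.gene_id for m in members),
                    n_cazymes=n_caz,
                    n_signatures=n_sig,
                    span=Interval(chrom, members[0].start, members[-1].end),
                )
            )
    return clusters


def name_clusters(
    clusters: Sequence[GeneCluster],
    chromosome_order: Sequence[str],
    prefix: str = "CAZ-GC",
) -> list[GeneCluster]:
    """Assign positional names: ``<prefix> <chrom index>.<rank>``.

    Chromosome indices are 1-based positions in ``chromosome_order``; ranks
    run from the left arm (lowest start coordinate).
    """
    index = {name: i + 1 for i, name in enumerate(chromosome_order)}
    unknown = {c.chromosome for c in clusters} - set(index)
    if unknown:
        raise ValueError(f"clusters on chromosomes not in order list: {sorted(unknown)}")
    named: list[GeneCluster] = []
    by_chrom: dict[str, list[GeneCluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chromosome, []).append(c)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda c: c.span.start)
        for rank, c in enumerate(group, start=1):
            named.append(replace(c, name=f"{prefix} {index[chrom]}.{rank}"))
    named.sort(key=lambda c: (index[c.chromosome], c.span.start))
    return named


def compare_cluster_sets(
    set_a: Sequence[GeneCluster],
    set_b: Sequence[GeneCluster],
    ortholog_pairs: Iterable[tuple[str, str]],
) -> tuple[int, int, int]:
    """(shared, a_specific, b_specific) under the half-overlap rule.

    Two clusters are shared when at least half of the smaller cluster's
    members have orthologs among the other cluster's members.  ``shared``
    counts clusters of set A with at least one partner in set B (for an
    identity ortholog map on identical cluster sets this equals the count in
    either set); the *_specific counts are clusters without any partner.
    """
    a_to_b: dict[str, set[str]] = {}
    b_to_a: dict[str, set[str]] = {}
    for ga, gb in ortholog_pairs:
        a_to_b.setdefault(ga, set()).add(gb)
        b_to_a.setdefault(gb, set()).add(ga)

    def is_shared(ca: GeneCluster, cb: GeneCluster) -> bool:
        members_a, members_b = set(ca.member_ids), set(cb.member_ids)
        if len(members_a) <= len(members_b):
            small, other, fmap = members_a, members_b, a_to_b
        else:
            small, other, fmap = members_b, members_a, b_to_a
        hits = sum(1 for gid in small if fmap.get(gid, set()) & other)
        return 2 * hits >= len(small)

    a_matched = [any(is_shared(ca, cb) for cb in set_b) for ca in set_a]
    b_matched = [any(is_shared(ca, cb) for ca in set_a) for cb in set_b]
    shared = sum(a_matched)
    return shared, len(set_a) - shared, len(set_b) - sum(b_matched)
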