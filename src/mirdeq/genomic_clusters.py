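"""Polycistronic miRNA cluster detection and per-cluster deregulation summary.

Mature loci are grouped per (chromosome, strand) by single-linkage chaining:
arms of one precursor are collapsed into a single interval, intervals are
sorted by start, and a new cluster starts whenever the gap between
consecutive precursor intervals exceeds ``max_gap`` (a gap of exactly
``max_gap`` still chains). Clusters are summarized against per-miRNA DE
records using raw (unadjusted) p-values: a cluster is reported when at least
``min_significant`` mature members are significant and all significant
members share one direction.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

from mirdeq.counts_io import MiRNALocus
from mirdeq.diffexp import DERecord

_ARM_SUFFIX_RE = re.compile(r"-(5p|3p)(\.\d+)?\*?$")
_SPECIES_PREFIX_RE = re.compile(r"^[a-z]{3}-")
_FAMILY_PREFIX_RE = re.compile(r"^(miR-|mir-|let-)", re.IGNORECASE)


def strip_arm(mirna_id: str) -> str:
    """Precursor-level name: drop a trailing -5p/-3p arm suffix."""
    return _ARM_SUFFIX_RE.sub("", mirna_id)


def _core_name(precursor: str) -> str:
    """'hsa-miR-130b' -> 'miR-130b'; used for cluster naming."""
    return _SPECIES_PREFIX_RE.sub("", precursor)


@dataclass
class MiRNACluster:
    """A chain of co-located miRNA loci on one chromosome and strand."""

    cluster_id: str
    members: list[MiRNALocus]
    chrom: str
    strand: str
    span: tuple[int, int]

    @property
    def member_ids(self) -> list[str]:
        return [m.mirna_id for m in self.members]

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class ClusterSummary:
    cluster: MiRNACluster
    member_records: list[DERecord]
    untested_ids: list[str]
    n_significant: int
    consensus_direction: str  # "up" | "down" | "mixed" | "none"
    significant_folds: list[float | None] = field(default_factory=list)


def _cluster_name(precursors: list[str]) -> str:
    first = _core_name(precursors[0])
    if len(precursors) == 1:
        return first
    last = _core_name(precursors[-1])
    # "miR-301b" + "miR-130b" -> "miR-301b-130b"
    last_tail = _FAMILY_PREFIX_RE.sub("", last)
    return f"{first}-{last_tail}"


def group_loci(loci: list[MiRNALocus], max_gap: int = 10_000) -> list[MiRNACluster]:
    """Partition loci into polycistronic clusters by genomic proximity.

    The 5p and 3p arms of one precursor count as one interval for gap
    chaining but remain separate members. Output is deterministic and
    invariant to input order; every locus lands in exactly one cluster
    (singletons become 1-member clusters).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    # collapse arms into precursor-level units
    units: dict[tuple[str, str, str], dict] = {}
    for locus in loci:
        precursor = locus.precursor_id or strip_arm(locus.mirna_id)
        key = (locus.chrom, locus.strand, precursor)
        unit = units.setdefault(
            key, {"precursor": precursor, "start": locus.start, "end": locus.end,
                  "members": []}
        )
        unit["start"] = min(unit["start"], locus.start)
        unit["end"] = max(unit["end"], locus.end)
        unit["members"].append(locus)

    by_strand: dict[tuple[str, str], list[dict]] = defaultdict(list)
    for (chrom, strand, _), unit in units.items():
        by_strand[(chrom, strand)].append(unit)

    clusters: list[MiRNACluster] = []
    for (chrom, strand) in sorted(by_strand):
        chain: list[dict] = []
        chain_end = None
        ordered = sorted(
            by_strand[(chrom, strand)], key=lambda u: (u["start"], u["precursor"])
        )
        for unit in ordered:
            if chain and unit["start"] - chain_end > max_gap:
                clusters.append(_finish(chain, chrom, strand))
                chain = []
            chain.append(unit)
            chain_end = unit["end"] if chain_end is None or len(chain) == 1 else max(
                chain_end, unit["end"]
            )
        if chain:
            clusters.append(_finish(chain, chrom, strand))
    return clusters


def _finish(chain: list[dict], chrom: str, strand: str) -> MiRNACluster:
    members = sorted(
        (m for u in chain for m in u["members"]),
        key=lambda l: (l.start, l.mirna_id),
    )
    name = _cluster_name([u["precursor"] for u in chain])
    span = (min(u["start"] for u in chain), max(u["end"] for u in chain))
    return MiRNACluster(name, members, chrom, strand, span)


def summarize_cluster_deregulation(
    clusters: list[MiRNACluster],
    records: list[DERecord],
    alpha: float = 0.05,
    min_significant: int = 2,
    include_unreported: bool = False,
) -> list[ClusterSummary]:
    """Per-cluster deregulation summaries based on RAW p-values.

    A member is significant when its raw p < ``alpha``. The consensus
    direction is that of the significant members ("mixed" when they
    disagree). By default only reported clusters are returned: those with
    >= ``min_significant`` significant members all sharing one direction.
    Member ids missing from ``records`` are carried as untested, never an
    error.
    """
    by_id = {r.mirna_id: r for r in records}
    summaries: list[ClusterSummary] = []
    for cluster in clusters:
        member_records = [by_id[i] for i in cluster.member_ids if i in by_id]
        untested = [i for i in cluster.member_ids if i not in by_id]
        significant = [r for r in member_records if r.p_raw < alpha]
        directions = {r.direction for r in significant}
        if not significant:
            consensus = "none"
        elif len(directions) == 1:
            consensus = directions.pop()
        else:
            consensus = "mixed"
        summary = ClusterSummary(
            cluster=cluster,
            member_records=member_records,
            untested_ids=untested,
            n_significant=len(significant),
            consensus_direction=consensus,
            significant_folds=[r.fold_change for r in significant],
        )
        reported = (
            len(significant) >= min_significant and consensus in ("up", "down")
        )
        if reported or include_unreported:
            summaries.append(summary)
    return summaries
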