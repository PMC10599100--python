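"""WxL gene-cluster detection.

The survey's cluster definition: a group of adjacent genes — consecutive
relevant genes separated by no more than four annotated genes — that
contains at least one WxLIP and two WxL proteins. Adjacency is applied
transitively (single linkage on gene ordinals), so chains of relevant
genes form one candidate. A qualifying cluster with exactly one WxLIP
and two WxL proteins is the "simple" type, the most common arrangement.
Strand is ignored; replicons are treated as linear (no wrap at the
origin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .architecture import (
    ArchitectureCall,
    RELEVANT_CLASSES,
    WXL_CLASSES,
    WXLIP_FULL,
    proteome_census,
)

DEFAULT_MAX_GAP = 4  # max intervening annotated genes between cluster members


@dataclass(frozen=True)
class GeneClusterCandidate:
    """A maximal single-linkage group of relevant genes on one replicon."""

    replicon_id: str
    members: tuple[tuple[str, int, str], ...]  # (protein_id, ordinal, arch_class)

    @property
    def span_ordinals(self) -> tuple[int, int]:
        ords = [m[1] for m in self.members]
        return (min(ords), max(ords))


@dataclass(frozen=True)
class GeneCluster:
    candidate: GeneClusterCandidate
    n_wxlip: int
    n_wxl: int
    qualifies: bool
    simple: bool


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    census: dict
    n_clusters: int
    n_simple: int
    sparse: bool


def find_candidates(
    calls: Sequence[tuple[ArchitectureCall, int]] | Sequence,
    replicon_id: str,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[GeneClusterCandidate]:
    """Partition a replicon's relevant genes into adjacency candidates.

    ``calls`` is a sequence of ``(ArchitectureCall, ordinal)`` pairs.
    Two relevant genes join the same candidate iff at most ``max_gap``
    annotated genes lie between them, i.e. their ordinals differ by at
    most ``max_gap + 1``; grouping is transitive. Every relevant gene
    lands in exactly one candidate (singletons included).
    """
    relevant = [
        (call, ordinal)
        for call, ordinal in calls
        if call.arch_class in RELEVANT_CLASSES
    ]
    ordinals = [o for _, o in relevant]
    if len(set(ordinals)) != len(ordinals):
        raise ValueError(f"{replicon_id}: duplicate ordinals in input")
    relevant.sort(key=lambda t: t[1])

    candidates: list[GeneClusterCandidate] = []
    group: list[tuple[ArchitectureCall, int]] = []
    for call, ordinal in relevant:
        if group and ordinal - group[-1][1] > max_gap + 1:
            candidates.append(_to_candidate(replicon_id, group))
            group = []
        group.append((call, ordinal))
    if group:
        candidates.append(_to_candidate(replicon_id, group))
    return candidates


def _to_candidate(
    replicon_id: str, group: list[tuple[ArchitectureCall, int]]
) -> GeneClusterCandidate:
    return GeneClusterCandidate(
        replicon_id=replicon_id,
        members=tuple((c.protein_id, o, c.arch_class) for c, o in group),
    )


def evaluate_cluster(candidate: GeneClusterCandidate) -> GeneCluster:
    """Type a candidate: qualifying iff >=1 WxLIP and >=2 WxL members.

    Isolated PGBD or HBD members co-occur in clusters but count toward
    neither tally.
    """
    n_wxlip = sum(1 for _, _, cls in candidate.members if cls == WXLIP_FULL)
    n_wxl = sum(1 for _, _, cls in candidate.members if cls in WXL_CLASSES)
    qualifies = n_wxlip >= 1 and n_wxl >= 2
    simple = qualifies and n_wxlip == 1 and n_wxl == 2
    return GeneCluster(candidate, n_wxlip, n_wxl, qualifies, simple)


def summarize_genome(
    genome_id: str,
    calls: Iterable[ArchitectureCall],
    clusters: Sequence[GeneCluster],
) -> GenomeSummary:
    """Per-genome inventory: class census, cluster counts, sparse flag.

    A genome is "sparse" when it holds only one or two relevant proteins
    in total and no qualifying cluster — the blue-coded genomes of the
    survey's inventory table.
    """
    census = proteome_census(calls)
    n_clusters = sum(1 for c in clusters if c.qualifies)
    n_simple = sum(1 for c in clusters if c.simple)
    sparse = census["total"] in (1, 2) and n_clusters == 0
    return GenomeSummary(genome_id, census, n_clusters, n_simple, sparse)
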