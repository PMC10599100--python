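"""Domain-architecture classification.

Each protein is assigned one of six classes from its merged domain
evidence:

* ``WXLIP_FULL`` — PGBD (DUF916) followed by HBD (DUF3324), the
  two-domain WxL-interacting protein; the domains always occur in this
  order in surveyed genomes, so the reverse order is flagged as a
  violation and classed OTHER.
* ``PGBD_ONLY`` / ``HBD_ONLY`` — an isolated half of the pair.
* ``WXL_SMALL`` — the mature protein is essentially just a WxL domain.
* ``WXL_LARGE`` — a C-terminal WxL domain preceded by other domains.
* ``OTHER`` — everything else, excluded from survey tallies.

The small/large WxL split uses coverage of the mature length (sequence
minus a 25-residue signal peptide): small when the WxL hit covers at
least 60% of it, large when the hit instead ends near the C-terminus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .domain_annotation import DomainHit, SignalCall, TmhSpan, HBD, PGBD, WXL
from .genome_io import ProteinRecord

WXL_SMALL = "WXL_SMALL"
WXL_LARGE = "WXL_LARGE"
WXLIP_FULL = "WXLIP_FULL"
PGBD_ONLY = "PGBD_ONLY"
HBD_ONLY = "HBD_ONLY"
OTHER = "OTHER"

#: Classes that count toward the survey (OTHER is excluded).
RELEVANT_CLASSES = (WXL_SMALL, WXL_LARGE, WXLIP_FULL, PGBD_ONLY, HBD_ONLY)
#: Classes tallied as "WxL proteins" in cluster typing.
WXL_CLASSES = (WXL_SMALL, WXL_LARGE)

SIGNAL_PEPTIDE_LENGTH = 25  # assumed mature-protein offset


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    arch_class: str
    hits: tuple[DomainHit, ...] = ()
    has_tmh: bool = False
    has_insert: bool | None = None
    signal: SignalCall | None = None
    order_violation: bool = False


@dataclass(frozen=True)
class InsertCall:
    """Presence of the ~20-residue buttressing-loop insert in PGBD."""

    protein_id: str
    pgbd_length: int
    insert_present: bool


def classify_architecture(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    tmh: Sequence[TmhSpan] = (),
    signal: SignalCall | None = None,
    *,
    small_coverage: float = 0.60,
    cterm_tolerance: int = 15,
) -> ArchitectureCall:
    """Apply the architecture grammar to one protein's merged evidence.

    Precedence: the PGBD/HBD branch wins over WxL evidence (the survey
    treats WxLIP and WxL as disjoint protein sets). The signal-peptide
    call is recorded but never gates the class.
    """
    for h in hits:
        if h.protein_id != protein.protein_id:
            raise ValueError(
                f"hit for {h.protein_id!r} passed with protein {protein.protein_id!r}"
            )
    pgbd = [h for h in hits if h.domain == PGBD]
    hbd = [h for h in hits if h.domain == HBD]
    wxl = [h for h in hits if h.domain == WXL]
    has_tmh = bool(tmh)
    common = dict(
        protein_id=protein.protein_id,
        hits=tuple(hits),
        has_tmh=has_tmh,
        signal=signal,
    )

    if pgbd and hbd:
        if min(h.env_start for h in pgbd) < min(h.env_start for h in hbd):
            return ArchitectureCall(arch_class=WXLIP_FULL, **common)
        return ArchitectureCall(arch_class=OTHER, order_violation=True, **common)
    if pgbd:
        return ArchitectureCall(arch_class=PGBD_ONLY, **common)
    if hbd:
        return ArchitectureCall(arch_class=HBD_ONLY, **common)
    if wxl:
        mature = max(len(protein.sequence) - SIGNAL_PEPTIDE_LENGTH, 1)
        if any(h.length >= small_coverage * mature for h in wxl):
            return ArchitectureCall(arch_class=WXL_SMALL, **common)
        if any(len(protein.sequence) - h.env_end <= cterm_tolerance for h in wxl):
            return ArchitectureCall(arch_class=WXL_LARGE, **common)
        return ArchitectureCall(arch_class=OTHER, **common)
    return ArchitectureCall(arch_class=OTHER, **common)


def detect_buttressing_insert(
    call: ArchitectureCall, length_threshold: int = 140
) -> InsertCall:
    """Decide whether the PGBD domain carries the buttressing-loop insert.

    In-cluster PGBD runs ~148 residues versus ~125 for Pfam's DUF916
    definition; a hit length at or above the 140-residue midpoint is
    called insert-positive.
    """
    pgbd = [h for h in call.hits if h.domain == PGBD]
    if not pgbd:
        raise ValueError(f"{call.protein_id}: no PGBD hit")
    length = max(h.length for h in pgbd)
    return InsertCall(call.protein_id, length, length >= length_threshold)


def proteome_census(calls: Iterable[ArchitectureCall]) -> dict[str, int]:
    """Tally architecture classes the way the survey reports them.

    WXL_SMALL and WXL_LARGE are also reported under a combined ``WXL``
    key; ``total`` sums the five relevant classes and excludes OTHER.
    """
    calls = list(calls)
    ids = [c.protein_id for c in calls]
    dupes = [pid for pid, n in Counter(ids).items() if n > 1]
    if dupes:
        raise ValueError(f"duplicate protein ids in census: {dupes}")
    counts = Counter(c.arch_class for c in calls)
    census = {cls: counts.get(cls, 0) for cls in RELEVANT_CLASSES}
    census[OTHER] = counts.get(OTHER, 0)
    census["WXL"] = census[WXL_SMALL] + census[WXL_LARGE]
    census["total"] = sum(census[cls] for cls in RELEVANT_CLASSES)
    return census
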