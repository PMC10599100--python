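"""Alignment column conservation.

Implements the invariant-column statistic used to annotate the PGBD and
HBD alignments: a column is conserved when its majority (most frequent
non-gap) residue occurs in at least a fixed number of sequences — 60 of
the 175 survey sequences by default. Conserved columns can be mapped to
ungapped residue positions on a chosen reference row.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO

GAP_CHARS = frozenset("-.")
DEFAULT_THRESHOLD = 60  # invariant in at least this many sequences


class AlignmentFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Alignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class ColumnStat:
    majority_residue: str | None
    majority_count: int
    conserved: bool


@dataclass(frozen=True)
class ConservationProfile:
    columns: tuple[ColumnStat, ...]
    threshold: int

    def conserved_columns(self) -> list[int]:
        return [i for i, c in enumerate(self.columns) if c.conserved]


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA or Clustal file; ragged alignments rejected."""
    path = Path(path)
    text = path.read_text()
    fmt = "clustal" if text.lstrip().upper().startswith("CLUSTAL") else "fasta"
    if fmt == "fasta":
        # parse manually enough to name the offending id on ragged input
        ids, rows, cur = [], [], None
        for line in text.splitlines():
            if line.startswith(">"):
                ids.append(line[1:].split()[0] if line[1:].split() else "")
                rows.append([])
                cur = rows[-1]
            elif line.strip():
                if cur is None:
                    raise AlignmentFormatError(f"{path}: sequence before header")
                cur.append(line.strip())
        seqs = ["".join(r).upper() for r in rows]
    else:
        try:
            aln = AlignIO.read(str(path), "clustal")
        except Exception as exc:
            raise AlignmentFormatError(f"{path}: not parseable as Clustal ({exc})") from exc
        ids = [rec.id for rec in aln]
        seqs = [str(rec.seq).upper() for rec in aln]

    if not seqs:
        raise AlignmentFormatError(f"{path}: empty alignment")
    width = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != width:
            raise AlignmentFormatError(
                f"{path}: row {rid!r} has length {len(s)}, expected {width}"
            )
    return Alignment(ids=tuple(ids), rows=tuple(seqs))


def column_conservation(
    aln: Alignment,
    threshold: int = DEFAULT_THRESHOLD,
    *,
    fraction: float | None = None,
) -> ConservationProfile:
    """Per-column majority residue and the invariant-column call.

    The majority residue is the most frequent non-gap residue (ties
    broken alphabetically); the column is conserved iff its count
    reaches ``threshold``. ``fraction`` switches to a fractional
    threshold (ceil(fraction * n_seqs)) for alignments of other depths.
    """
    if aln.n_seqs < 1:
        raise ValueError("empty alignment")
    if fraction is not None:
        threshold = max(1, math.ceil(fraction * aln.n_seqs))
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    cols = []
    for j in range(aln.n_cols):
        counts = Counter(
            row[j] for row in aln.rows if row[j] not in GAP_CHARS
        )
        if counts:
            # max count, then alphabetical tie-break
            best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            residue, count = best
        else:
            residue, count = None, 0
        cols.append(ColumnStat(residue, count, count >= threshold))
    return ConservationProfile(columns=tuple(cols), threshold=threshold)


def map_to_reference(
    profile: ConservationProfile, aln: Alignment, ref_id: str
) -> tuple[list[int], list[int]]:
    """Map conserved columns to 1-based residue positions on a reference.

    Returns ``(positions, gap_columns)``: the ungapped residue indices of
    conserved columns where the reference is non-gap, and the alignment
    column indices of conserved columns where the reference has a gap.
    """
    if ref_id not in aln.ids:
        raise KeyError(f"reference id {ref_id!r} not in alignment")
    ref = aln.rows[aln.ids.index(ref_id)]
    positions: list[int] = []
    gap_columns: list[int] = []
    residue_index = 0
    conserved = set(profile.conserved_columns())
    for j, aa in enumerate(ref):
        is_gap = aa in GAP_CHARS
        if not is_gap:
            residue_index += 1
        if j in conserved:
            if is_gap:
                gap_columns.append(j)
            else:
                positions.append(residue_index)
    return positions, gap_columns
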