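"""Genome and sequence I/O.

Reads annotated bacterial genomes (GenBank flat files with CDS features)
into an ordered proteome per replicon, and reads/writes protein FASTA.
Internal coordinates are 0-based half-open; the GenBank 1-based inclusive
convention is converted at the parser boundary. Gene order — the basis of
the adjacency rule used downstream — is defined by start coordinate,
irrespective of strand. Only annotated CDS features count toward gene
ordinals; RNA genes and pseudogenes are excluded (``include_pseudo``
restores pseudogene counting for sensitivity analyses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: The 20 standard residues; anything else becomes X at the parser boundary.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class GenomeFormatError(ValueError):
    """Raised when an input genome or sequence file cannot be parsed."""


@dataclass(frozen=True)
class ProteinRecord:
    """One CDS translation with its replicon and gene ordinal.

    ``start``/``end`` are nucleotide coordinates, 0-based half-open.
    ``ordinal`` is the gene's rank in start-coordinate order along its
    replicon, the unit of the cluster adjacency rule.
    """

    protein_id: str
    replicon_id: str
    ordinal: int
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.protein_id}: invalid span {self.start}..{self.end}")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.protein_id}: empty translation")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.protein_id}: strand must be + or -")


@dataclass
class RepliconRecord:
    """An ordered proteome for one replicon (one GenBank LOCUS)."""

    replicon_id: str
    genes: list[ProteinRecord] = field(default_factory=list)


@dataclass
class GenomeRecord:
    """One genome: the unit of the survey. Holds one or more replicons."""

    genome_id: str
    replicons: list[RepliconRecord] = field(default_factory=list)

    def proteins(self) -> Iterable[ProteinRecord]:
        for rep in self.replicons:
            yield from rep.genes


def sanitize_sequence(seq: str, protein_id: str = "?") -> str:
    """Upper-case and map non-standard residues (B, Z, J, U, O, ...) to X."""
    seq = seq.upper().rstrip("*")
    if set(seq) <= STANDARD_RESIDUES:
        return seq
    cleaned = []
    for aa in seq:
        if aa in STANDARD_RESIDUES or aa == "X":
            cleaned.append(aa)
        else:
            logger.warning("%s: ambiguous residue %r mapped to X", protein_id, aa)
            cleaned.append("X")
    return "".join(cleaned)


def _cds_translation(feature, parent_seq, protein_id: str) -> str | None:
    quals = feature.qualifiers
    if "translation" in quals:
        return sanitize_sequence(quals["translation"][0], protein_id)
    try:
        nt = feature.extract(parent_seq)
        aa = str(Seq(nt).translate(table=11, to_stop=True))
    except Exception:
        return None
    if not aa:
        return None
    # drop the GenBank-style leading alternative start normalisation: keep as-is
    return sanitize_sequence(aa, protein_id)


def read_genbank(path: str | Path, *, include_pseudo: bool = False) -> list[GenomeRecord]:
    """Read a GenBank flat file into a list with one :class:`GenomeRecord`.

    One :class:`RepliconRecord` is produced per LOCUS; genes are sorted by
    start coordinate and ordinals assigned after sorting. Translations come
    from the ``/translation`` qualifier when present, otherwise from the
    nucleotide span under translation table 11. A CDS with neither is
    skipped with a logged warning.
    """
    path = Path(path)
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise GenomeFormatError(f"{path}: not parseable as GenBank ({exc})") from exc
    if not seq_records:
        raise GenomeFormatError(f"{path}: no LOCUS records found")

    genome = GenomeRecord(genome_id=path.stem)
    for rec in seq_records:
        replicon = RepliconRecord(replicon_id=rec.id)
        raw: list[tuple[int, int, str, str, str]] = []
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if not include_pseudo and "pseudo" in feat.qualifiers:
                continue
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            pid = (
                feat.qualifiers.get("protein_id")
                or feat.qualifiers.get("locus_tag")
                or [f"{rec.id}_cds{start}"]
            )[0]
            aa = _cds_translation(feat, rec.seq, pid)
            if aa is None:
                logger.warning("%s: CDS %s has no translation; skipped", rec.id, pid)
                continue
            raw.append((start, end, strand, pid, aa))
        raw.sort(key=lambda t: (t[0], t[1]))
        for ordinal, (start, end, strand, pid, aa) in enumerate(raw):
            replicon.genes.append(
                ProteinRecord(
                    protein_id=pid,
                    replicon_id=rec.id,
                    ordinal=ordinal,
                    start=start,
                    end=end,
                    strand=strand,
                    sequence=aa,
                )
            )
        genome.replicons.append(replicon)

    ids = [r.replicon_id for r in genome.replicons]
    if len(set(ids)) != len(ids):
        raise GenomeFormatError(f"{path}: duplicate replicon identifiers {ids}")
    return [genome]


def read_fasta(path: str | Path, *, alignment_mode: bool = False) -> list[tuple[str, str]]:
    """Read FASTA into ``(id, sequence)`` pairs.

    Ids are the first whitespace token of each header. Sequences are
    upper-cased; gap characters are stripped unless ``alignment_mode``.
    Duplicate ids raise an error naming the offending id.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise GenomeFormatError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not alignment_mode:
            seq = seq.replace("-", "").replace(".", "")
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, *, width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA with fixed-width wrapping."""
    with open(path, "w") as fh:
        for rid, seq in records:
            if not rid:
                raise ValueError("empty FASTA id")
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
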