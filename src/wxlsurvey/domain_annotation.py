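"""Domain evidence per protein.

Three evidence channels feed the architecture grammar:

* profile-HMM hits read from HMMER3 ``hmmsearch --domtblout`` output,
  filtered at the survey E-value cutoff (full-sequence E-value < 1e-10);
* sequence motifs — the dual Trp-x-Leu motif of the WxL domain and the
  NQIDKxxxYFDLK anchor near the PGBD N-terminus — for a motif-only mode
  that needs no external tools;
* a Kyte–Doolittle sliding-window detector for the C-terminal
  transmembrane helix, plus an advisory signal-peptide heuristic.

Domain names follow the WxLIP nomenclature: WXL (Pfam PF13731), PGBD
(DUF916, PF06040), HBD (DUF3324, PF11797).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SearchIO

logger = logging.getLogger(__name__)

WXL = "WXL"
PGBD = "PGBD"
HBD = "HBD"
DOMAINS = (WXL, PGBD, HBD)

#: Pfam accession (version stripped) -> internal domain name.
DEFAULT_MODEL_MAP: dict[str, str] = {
    "PF13731": WXL,
    "PF06040": PGBD,
    "PF11797": HBD,
    "WxL": WXL,
    "DUF916": PGBD,
    "DUF3324": HBD,
}

#: Survey inclusion threshold on the full-sequence E-value.
DEFAULT_EVALUE_MAX = 1e-10

#: Pseudo-E-value assigned to motif evidence so it passes the same filter.
MOTIF_PSEUDO_EVALUE = 1e-12

#: Kyte & Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


class DomtbloutParseError(ValueError):
    """Raised for malformed HMMER domtblout input, citing the line number."""


@dataclass(frozen=True)
class DomainHit:
    """A filtered domain-evidence interval on a protein.

    Envelope coordinates are residue positions, 0-based half-open.
    ``source`` records the evidence channel (hmmer | motif | external).
    """

    protein_id: str
    domain: str
    env_start: int
    env_end: int
    evalue: float
    source: str = "hmmer"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if not (0 <= self.env_start < self.env_end):
            raise ValueError(f"bad envelope {self.env_start}..{self.env_end}")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")

    @property
    def length(self) -> int:
        return self.env_end - self.env_start


@dataclass(frozen=True)
class MotifHit:
    """A sequence-motif match (WxL pair or PGBD anchor)."""

    protein_id: str
    motif: str  # WxL_pair | NQIDK_anchor
    positions: tuple[int, ...]
    span: tuple[int, int]


@dataclass(frozen=True)
class TmhSpan:
    """A candidate transmembrane span from the hydropathy scan.

    ``mean_hydropathy`` is the peak window mean inside the span, so it
    always satisfies the detection threshold.
    """

    protein_id: str
    start: int
    end: int
    mean_hydropathy: float


@dataclass(frozen=True)
class SignalCall:
    """Advisory signal-peptide heuristic; never gates classification."""

    protein_id: str
    present: bool
    cleavage_hint: int | None = None


def _find_malformed_line(path: Path) -> int | None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            if len(line.split()) < 22:
                return lineno
    return None


def parse_domtblout(
    path: str | Path,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    model_map: dict[str, str] | None = None,
    *,
    use_domain_evalue: bool = False,
) -> list[DomainHit]:
    """Read hmmsearch per-domain tabular output into filtered DomainHits.

    Only rows whose full-sequence E-value is below ``evalue_max`` are kept
    (``use_domain_evalue`` switches the filter to the per-domain
    independent E-value instead). Envelope coordinates are returned
    0-based half-open. Rows for models absent from ``model_map`` are
    ignored with a warning.
    """
    path = Path(path)
    model_map = DEFAULT_MODEL_MAP if model_map is None else model_map
    hits: list[DomainHit] = []
    try:
        qresults = list(SearchIO.parse(str(path), "hmmsearch3-domtab"))
    except Exception as exc:
        lineno = _find_malformed_line(path)
        where = f" at line {lineno}" if lineno else ""
        raise DomtbloutParseError(f"{path}: malformed domtblout{where} ({exc})") from exc

    for qres in qresults:
        acc = getattr(qres, "accession", "") or ""
        candidates = {qres.id, qres.id.split(".")[0], acc, acc.split(".")[0]}
        domain = next((model_map[c] for c in candidates if c in model_map), None)
        if domain is None:
            logger.warning("%s: unmapped query model %r; rows ignored", path, qres.id)
            continue
        for hit in qres.hits:
            for hsp in hit.hsps:
                evalue = hsp.evalue if use_domain_evalue else hit.evalue
                if evalue >= evalue_max:
                    continue
                hits.append(
                    DomainHit(
                        protein_id=hit.id,
                        domain=domain,
                        env_start=hsp.env_start,
                        env_end=hsp.env_end,
                        evalue=float(evalue),
                        source="hmmer",
                    )
                )
    return hits


def _overlap_frac(a: DomainHit, b: DomainHit) -> float:
    inter = min(a.env_end, b.env_end) - max(a.env_start, b.env_start)
    if inter <= 0:
        return 0.0
    return inter / min(a.length, b.length)


def merge_hits(hits: Sequence[DomainHit], min_overlap: float = 0.5) -> list[DomainHit]:
    """Suppress redundant same-domain hits on one protein.

    Among same-domain hits overlapping by more than ``min_overlap`` of the
    shorter interval, only the lowest-E-value hit survives. Hits of
    different domains are never merged. Output sorted by ``env_start``.
    """
    if len({h.protein_id for h in hits}) > 1:
        raise ValueError("merge_hits expects hits for a single protein")
    ranked = sorted(hits, key=lambda h: (h.evalue, h.env_start, h.env_end))
    kept: list[DomainHit] = []
    for h in ranked:
        if any(
            k.domain == h.domain and _overlap_frac(k, h) > min_overlap for k in kept
        ):
            continue
        kept.append(h)
    return sorted(kept, key=lambda h: (h.env_start, h.env_end))


def scan_wxl_motifs(
    sequence: str,
    protein_id: str = "?",
    *,
    min_separation: int = 40,
    max_span: int = 190,
) -> list[MotifHit]:
    """Find dual Trp-x-Leu motif pairs compatible with one WxL domain.

    The WxL domain is 160–190 residues and carries two Trp-x-Leu motifs,
    so a reported pair (i, j) must fit in a 190-residue window
    (j + 3 − i ≤ ``max_span``) and be non-adjacent (j − i ≥
    ``min_separation``, guarding against spurious neighbouring motifs).
    """
    seq = sequence.upper()
    singles = [
        i for i in range(len(seq) - 2) if seq[i] == "W" and seq[i + 2] == "L"
    ]
    out: list[MotifHit] = []
    for a, i in enumerate(singles):
        for j in singles[a + 1 :]:
            if j + 3 - i > max_span:
                break
            if j - i < min_separation:
                continue
            out.append(
                MotifHit(protein_id, "WxL_pair", positions=(i, j), span=(i, j + 3))
            )
    return out


def scan_pgbd_anchor(sequence: str, protein_id: str = "?") -> list[MotifHit]:
    """Find the conserved PGBD N-terminal anchor NQIDKxxxYFDLK (x = any)."""
    seq = sequence.upper()
    out: list[MotifHit] = []
    for i in range(len(seq) - 12):
        if (
            seq[i : i + 5] == "NQIDK"
            and seq[i + 8 : i + 13] == "YFDLK"
        ):
            out.append(
                MotifHit(
                    protein_id,
                    "NQIDK_anchor",
                    positions=tuple(range(i, i + 13)),
                    span=(i, i + 13),
                )
            )
    return out


def _window_means(seq: str, window: int) -> list[float]:
    vals = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq.upper()]
    if len(vals) < window:
        return []
    means = []
    acc = sum(vals[:window])
    means.append(acc / window)
    for i in range(window, len(vals)):
        acc += vals[i] - vals[i - window]
        means.append(acc / window)
    return means


def detect_tmh(
    sequence: str,
    protein_id: str = "?",
    *,
    window: int = 19,
    threshold: float = 1.6,
    cterm_zone: int = 60,
) -> list[TmhSpan]:
    """Detect C-terminal transmembrane spans by sliding-window hydropathy.

    Window positions with mean Kyte–Doolittle hydropathy >= ``threshold``
    are merged into maximal spans; only spans starting within the final
    ``cterm_zone`` residues are returned, because the WxLIP helix sits at
    the C-terminus.
    """
    means = _window_means(sequence, window)
    if not means:
        return []
    qualifying = [i for i, m in enumerate(means) if m >= threshold]
    spans: list[tuple[int, int, float]] = []
    for i in qualifying:
        lo, hi, peak = i, i + window, means[i]
        if spans and lo <= spans[-1][1]:
            plo, phi, ppeak = spans[-1]
            spans[-1] = (plo, max(phi, hi), max(ppeak, peak))
        else:
            spans.append((lo, hi, peak))
    zone_start = max(0, len(sequence) - cterm_zone)
    return [
        TmhSpan(protein_id, lo, hi, peak)
        for lo, hi, peak in spans
        if lo >= zone_start
    ]


def detect_signal_peptide(sequence: str, protein_id: str = "?") -> SignalCall:
    """Crude Sec-type signal-peptide heuristic (advisory metadata only).

    Requires a basic residue (K/R) in the first 10 positions (n-region)
    and an 8-residue window inside residues 5–30 with mean hydropathy
    >= 1.5 (h-region). The cleavage hint is the h-window end plus five,
    capped at residue 45. Output never depends on residues beyond 45.
    """
    seq = sequence.upper()[:45]
    if len(seq) < 25:
        return SignalCall(protein_id, present=False)
    if not any(aa in "KR" for aa in seq[0:10]):
        return SignalCall(protein_id, present=False)
    for s in range(4, min(22, len(seq) - 8) + 1):
        window = seq[s : s + 8]
        mean = sum(KYTE_DOOLITTLE.get(aa, 0.0) for aa in window) / 8
        if mean >= 1.5:
            hint = min(s + 8 + 5, 45)
            return SignalCall(protein_id, present=True, cleavage_hint=hint)
    return SignalCall(protein_id, present=False)


def motif_evidence(
    protein_id: str,
    sequence: str,
    *,
    pgbd_nominal_length: int = 148,
    pseudo_evalue: float = MOTIF_PSEUDO_EVALUE,
) -> list[DomainHit]:
    """Build DomainHits from sequence motifs alone (motif-only mode).

    WXL evidence comes from the best-spanning Trp-x-Leu pair; PGBD
    evidence from the NQIDK anchor, extended to the nominal in-cluster
    domain length. HBD has no diagnostic motif, so motif-only mode cannot
    produce it — a documented fidelity limit of this mode.
    """
    hits: list[DomainHit] = []
    pairs = scan_wxl_motifs(sequence, protein_id)
    if pairs:
        best = max(pairs, key=lambda m: m.span[1] - m.span[0])
        hits.append(
            DomainHit(protein_id, WXL, best.span[0], best.span[1], pseudo_evalue, "motif")
        )
    anchors = scan_pgbd_anchor(sequence, protein_id)
    if anchors:
        a = anchors[0]
        end = min(a.span[0] + pgbd_nominal_length, len(sequence))
        hits.append(DomainHit(protein_id, PGBD, a.span[0], end, pseudo_evalue, "motif"))
    return hits
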