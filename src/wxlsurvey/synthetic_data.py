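"""Seeded synthetic genomes, domain evidence and alignments.

Everything the survey pipeline consumes can be generated here with known
ground truth: GenBank genomes carrying planted WxL clusters (the default
plant is the canonical 1 WxLIP + 2 WxL arrangement) padded with decoy
genes, hmmsearch domtblout files with true rows (E-values log-uniform in
[1e-50, 1e-11]) plus spurious rows above the survey cutoff, and
alignments with planted invariant columns.

All randomness flows from a single seed. Planted sequences carry the
features the detectors look for: dual Trp-x-Leu motifs inside WxL
domains, the NQIDKxxxYFDLK anchor at the PGBD N-terminus, a 22-residue
hydrophobic C-terminal tract for the transmembrane helix, and a
signal-peptide-like N-terminus. Background residues are drawn uniformly
from the 19 standard residues excluding tryptophan, so no spurious
Trp-x-Leu pairs arise; decoys are likewise motif-scrubbed. No attempt is
made to mimic real codon usage, GC content or phylogenetic correlation.

The truth manifest's qualifying/simple flags are computed by a
brute-force transitive-closure evaluation of the adjacency rule,
independent of the cluster finder's linear sweep, so recovery tests
compare two separate routes.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .architecture import (
    HBD_ONLY,
    PGBD_ONLY,
    RELEVANT_CLASSES,
    WXL_CLASSES,
    WXL_LARGE,
    WXL_SMALL,
    WXLIP_FULL,
)
from .cluster_finder import DEFAULT_MAX_GAP
from .conservation import Alignment
from .domain_annotation import HBD, PGBD, WXL, DomainHit

# background alphabet excludes W so Trp-x-Leu motifs appear only where planted
BACKGROUND_ALPHABET = "ACDEFGHIKLMNPQRSTVY"
HYDROPHOBIC = "LIVF"
FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

PFAM_MODELS = {WXL: ("WxL", "PF13731.8", 170), PGBD: ("DUF916", "PF06040.14", 125),
               HBD: ("DUF3324", "PF11797.10", 112)}


@dataclass(frozen=True)
class ClusterSpec:
    """A planted cluster: member classes in gene order, and the number of
    intervening decoy genes between consecutive members."""

    composition: tuple[str, ...] = (WXLIP_FULL, WXL_SMALL, WXL_LARGE)
    gaps: tuple[int, ...] = (0, 0)

    def __post_init__(self) -> None:
        if len(self.gaps) != len(self.composition) - 1:
            raise ValueError("need |composition| - 1 gaps")
        if any(g < 0 or g > 10 for g in self.gaps):
            raise ValueError("gaps must be in [0, 10]")
        unknown = set(self.composition) - set(RELEVANT_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes {unknown}")


@dataclass
class SyntheticConfig:
    seed: int = 0
    genome_id: str = "SYN"
    n_replicons: int = 1
    genes_per_replicon: int = 40
    planted_clusters: tuple[ClusterSpec, ...] = (ClusterSpec(),)
    n_spurious_hits: int = 5
    max_gap: int = DEFAULT_MAX_GAP


@dataclass(frozen=True)
class TruthProtein:
    protein_id: str
    replicon_id: str
    ordinal: int
    arch_class: str  # one of the five relevant classes, or DECOY
    domains: tuple[tuple[str, int, int], ...]  # (domain, env_start, env_end)


@dataclass(frozen=True)
class TruthCluster:
    replicon_id: str
    ordinals: tuple[int, ...]
    classes: tuple[str, ...]
    qualifies: bool
    simple: bool


@dataclass
class SyntheticTruth:
    """Planted-cluster manifest for recovery testing."""

    genome_id: str
    proteins: list[TruthProtein] = field(default_factory=list)
    clusters: list[TruthCluster] = field(default_factory=list)

    def qualifying(self) -> list[TruthCluster]:
        return [c for c in self.clusters if c.qualifies]

    def to_json(self, path: str | Path) -> None:
        data = {
            "genome_id": self.genome_id,
            "proteins": [vars(p) | {"domains": [list(d) for d in p.domains]}
                         for p in self.proteins],
            "clusters": [vars(c) | {"ordinals": list(c.ordinals),
                                    "classes": list(c.classes)}
                         for c in self.clusters],
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        data = json.loads(Path(path).read_text())
        truth = cls(genome_id=data["genome_id"])
        for p in data["proteins"]:
            truth.proteins.append(
                TruthProtein(p["protein_id"], p["replicon_id"], p["ordinal"],
                             p["arch_class"],
                             tuple((d[0], d[1], d[2]) for d in p["domains"]))
            )
        for c in data["clusters"]:
            truth.clusters.append(
                TruthCluster(c["replicon_id"], tuple(c["ordinals"]),
                             tuple(c["classes"]), c["qualifies"], c["simple"])
            )
        return truth


def _bg(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(BACKGROUND_ALPHABET) for _ in range(n))


def _signal_prefix(rng: random.Random) -> str:
    # n-region with basic residues, then a hydrophobic h-region: trips the
    # signal-peptide heuristic by construction
    return "MKK" + "".join(rng.choice("LIVA") for _ in range(10)) + _bg(rng, 12)


def _anchor(rng: random.Random) -> str:
    return "NQIDK" + _bg(rng, 3) + "YFDLK"


def generate_protein(
    arch_class: str, rng: random.Random, protein_id: str = "?"
) -> tuple[str, list[DomainHit]]:
    """Build one synthetic protein of the given class with true domain spans.

    WxL proteins carry two Trp-x-Leu motifs spaced to fit the 160–190
    residue domain envelope; full WxLIPs are 337–365 residues with a
    ~148-residue PGBD (anchor at its N-terminus), a 112-residue HBD and a
    22-residue hydrophobic C-terminal tract. Isolated PGBD uses the
    Pfam-style ~125-residue domain without the buttressing insert.
    """
    sig = _signal_prefix(rng)  # 25 residues

    def wxl_domain(domlen: int) -> str:
        # motifs at offsets 3 and domlen-13 within the domain
        d = list(_bg(rng, domlen))
        for off in (3, domlen - 13):
            d[off] = "W"
            d[off + 2] = "L"
        return "".join(d)

    if arch_class == WXL_SMALL:
        domlen = rng.randint(160, 190)
        seq = sig + wxl_domain(domlen)
        spans = [(WXL, 25, 25 + domlen)]
    elif arch_class == WXL_LARGE:
        domlen = rng.randint(160, 190)
        extra = rng.randint(150, 300)
        seq = sig + _bg(rng, extra) + wxl_domain(domlen)
        spans = [(WXL, len(seq) - domlen, len(seq))]
    elif arch_class == WXLIP_FULL:
        total = rng.randint(337, 365)
        pad = total - 307  # 25 sig + 148 PGBD + 112 HBD + 22 TMH
        g1 = rng.randint(0, pad)
        g2 = pad - g1
        pgbd = _anchor(rng) + _bg(rng, 135)  # 148 residues
        hbd = _bg(rng, 112)
        tmh = "".join(rng.choice(HYDROPHOBIC) for _ in range(22))
        seq = sig + pgbd + _bg(rng, g1) + hbd + _bg(rng, g2) + tmh
        hbd_start = 25 + 148 + g1
        spans = [(PGBD, 25, 173), (HBD, hbd_start, hbd_start + 112)]
    elif arch_class == PGBD_ONLY:
        pgbd = _anchor(rng) + _bg(rng, 112)  # 125: Pfam-style, no insert
        seq = sig + pgbd + _bg(rng, rng.randint(5, 20))
        spans = [(PGBD, 25, 150)]
    elif arch_class == HBD_ONLY:
        seq = sig + _bg(rng, 112) + _bg(rng, rng.randint(5, 20))
        spans = [(HBD, 25, 137)]
    else:
        raise ValueError(f"unknown class {arch_class!r}")

    hits = [
        DomainHit(protein_id, dom, s, e, 10.0 ** rng.uniform(-50, -11), "hmmer")
        for dom, s, e in spans
    ]
    return seq, hits


def _generate_decoy(rng: random.Random) -> str:
    return "M" + _bg(rng, rng.randint(99, 299))


def _truth_clusters(
    replicon_id: str, planted: list[tuple[int, str]], max_gap: int
) -> list[TruthCluster]:
    """Brute-force transitive closure of the adjacency rule on planted genes."""
    n = len(planted)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(planted[i][0] - planted[j][0]) <= max_gap + 1:
                parent[find(i)] = find(j)
    groups: dict[int, list[tuple[int, str]]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(planted[i])
    out = []
    for members in groups.values():
        members.sort()
        classes = tuple(cls for _, cls in members)
        n_wxlip = sum(1 for c in classes if c == WXLIP_FULL)
        n_wxl = sum(1 for c in classes if c in WXL_CLASSES)
        qualifies = n_wxlip >= 1 and n_wxl >= 2
        out.append(
            TruthCluster(
                replicon_id,
                tuple(o for o, _ in members),
                classes,
                qualifies,
                qualifies and n_wxlip == 1 and n_wxl == 2,
            )
        )
    out.sort(key=lambda c: c.ordinals[0])
    return out


def generate_genome(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Path, Path, SyntheticTruth]:
    """Emit one synthetic genome: GenBank file, domtblout file, truth.

    Planted clusters are distributed round-robin over replicons at random
    loci, their internal gaps filled by decoy genes, with at least
    ``max_gap + 2`` decoys between successive plants so distinct plants
    never merge under the adjacency rule. Spurious domtblout rows carry
    E-values in [1e-9, 1], above the survey cutoff.
    """
    rng = random.Random(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = SyntheticTruth(genome_id=config.genome_id)

    # assign classes to gene slots per replicon
    per_rep: list[list[str]] = [
        ["DECOY"] * config.genes_per_replicon for _ in range(config.n_replicons)
    ]
    planted_per_rep: list[list[tuple[int, str]]] = [[] for _ in range(config.n_replicons)]
    cursors = [rng.randint(0, 2) for _ in range(config.n_replicons)]
    for k, spec in enumerate(config.planted_clusters):
        r = k % config.n_replicons
        pos = cursors[r]
        for m, cls in enumerate(spec.composition):
            if pos >= config.genes_per_replicon:
                raise ValueError("planted clusters exceed replicon capacity")
            per_rep[r][pos] = cls
            planted_per_rep[r].append((pos, cls))
            pos += 1
            if m < len(spec.gaps):
                pos += spec.gaps[m]
        cursors[r] = pos + config.max_gap + 2 + rng.randint(0, 4)

    seq_records: list[SeqRecord] = []
    domtbl_rows: list[str] = []
    all_protein_meta: list[tuple[str, int]] = []  # (protein_id, length)

    for r in range(config.n_replicons):
        replicon_id = f"{config.genome_id}R{r + 1}"
        classes = per_rep[r]
        features = []
        nt_parts: list[str] = []
        nt_pos = 0
        for ordinal, cls in enumerate(classes):
            pid = f"{replicon_id}_P{ordinal:04d}"
            if cls == "DECOY":
                aa = _generate_decoy(rng)
                hits: list[DomainHit] = []
            else:
                aa, hits = generate_protein(cls, rng, pid)
            gap_nt = rng.randint(50, 200)
            start = nt_pos + gap_nt
            end = start + 3 * (len(aa) + 1)
            nt_pos = end
            strand = rng.choice([1, -1])
            features.append(
                SeqFeature(
                    FeatureLocation(start, end, strand=strand),
                    type="CDS",
                    qualifiers={
                        "protein_id": [pid],
                        "locus_tag": [pid],
                        "transl_table": ["11"],
                        "translation": [aa],
                    },
                )
            )
            truth.proteins.append(
                TruthProtein(
                    pid, replicon_id, ordinal,
                    cls,
                    tuple((h.domain, h.env_start, h.env_end) for h in hits),
                )
            )
            all_protein_meta.append((pid, len(aa)))
            for h in hits:
                domtbl_rows.append((h.domain, h.protein_id, _domtbl_row(h, len(aa), 1, 1)))
        genome_len = nt_pos + rng.randint(100, 300)
        dna = "".join(rng.choice("ACGT") for _ in range(genome_len))
        rec = SeqRecord(
            Seq(dna),
            id=replicon_id,
            name=replicon_id,
            description=f"synthetic replicon {r + 1}",
            features=features,
            annotations={"molecule_type": "DNA", "topology": "linear"},
        )
        seq_records.append(rec)
        truth.clusters.extend(
            _truth_clusters(replicon_id, sorted(planted_per_rep[r]), config.max_gap)
        )

    # spurious evidence above the survey cutoff: must never alter any call;
    # never reuse a true (model, protein) pair — hmmsearch reports one
    # full-sequence E-value per pair
    true_pairs = {(d, t) for d, t, _ in domtbl_rows}
    for _ in range(config.n_spurious_hits):
        pid, plen = rng.choice(all_protein_meta)
        dom = rng.choice((WXL, PGBD, HBD))
        if plen < 40 or (dom, pid) in true_pairs:
            continue
        s = rng.randint(0, plen - 30)
        e = min(plen, s + rng.randint(20, 150))
        fake = DomainHit(pid, dom, s, e, 10.0 ** rng.uniform(-9, 0), "hmmer")
        domtbl_rows.append((dom, pid, _domtbl_row(fake, plen, 1, 1)))

    gbk_path = out_dir / f"{config.genome_id}.gbk"
    with open(gbk_path, "w") as fh:
        SeqIO.write(seq_records, fh, "genbank")
    dom_path = out_dir / f"{config.genome_id}.domtblout"
    with open(dom_path, "w") as fh:
        fh.write("#" + " " * 21 + "--- full sequence --- -------------- this domain"
                 " -------------\n")
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  "
                 "acc description of target\n")
        # hmmsearch groups output by query model, then target
        for _, _, row in sorted(domtbl_rows):
            fh.write(row + "\n")
    return gbk_path, dom_path, truth


def _domtbl_row(hit: DomainHit, tlen: int, dom_i: int, dom_n: int) -> str:
    qname, qacc, qlen = PFAM_MODELS[hit.domain]
    ev = hit.evalue
    # 1-based inclusive coordinates in the flat file
    f, t = hit.env_start + 1, hit.env_end
    return (
        f"{hit.protein_id:<20} -  {tlen:5d} {qname:<20} {qacc:<11} {qlen:5d} "
        f"{ev:9.2g} {100.0:6.1f} {0.1:5.1f} {dom_i:3d} {dom_n:3d} {ev:9.2g} "
        f"{ev:9.2g} {90.0:6.1f} {0.1:5.1f} {1:5d} {qlen:5d} {f:5d} {t:5d} "
        f"{f:5d} {t:5d} 0.98 -"
    )


def survey_matrix_configs(seed: int, n_genomes: int = 50) -> list[SyntheticConfig]:
    """The standard recovery-test matrix: one planted cluster per genome,
    cycling composition over {1 WxLIP + 2 WxL, 2 WxLIP + 3 WxL,
    1 WxLIP + 1 WxL (non-qualifying)} and member gaps over 0–6 genes, so
    both merging (gap <= 4) and splitting (gap >= 5) plants are exercised."""
    compositions = (
        (WXLIP_FULL, WXL_SMALL, WXL_LARGE),
        (WXLIP_FULL, WXLIP_FULL, WXL_SMALL, WXL_SMALL, WXL_LARGE),
        (WXLIP_FULL, WXL_SMALL),
    )
    configs = []
    for i in range(n_genomes):
        comp = compositions[i % len(compositions)]
        gaps = tuple((i + k) % 7 for k in range(len(comp) - 1))
        configs.append(
            SyntheticConfig(
                seed=seed + i,
                genome_id=f"ACC{i:03d}",
                genes_per_replicon=50,
                planted_clusters=(ClusterSpec(comp, gaps),),
                n_spurious_hits=5,
            )
        )
    return configs


def generate_msa(
    n_seqs: int,
    n_cols: int,
    conserved_cols: list[int],
    threshold_count: int,
    rng: random.Random,
) -> tuple[Alignment, set[int]]:
    """Alignment with planted invariant columns at an exact majority count.

    At each planted column exactly ``threshold_count`` rows share one
    residue; everywhere else (and among the non-consensus rows of planted
    columns) every residue count stays strictly below ``threshold_count``.
    """
    if any(c < 0 or c >= n_cols for c in conserved_cols):
        raise ValueError("conserved column index out of range")
    others = n_seqs - threshold_count
    if others < 0:
        raise ValueError("threshold_count exceeds n_seqs")
    if others and -(-others // (len(FULL_ALPHABET) - 1)) >= threshold_count:
        raise ValueError("alphabet too small to keep background below threshold")
    if -(-n_seqs // len(FULL_ALPHABET)) >= threshold_count:
        raise ValueError("alphabet too small to keep background below threshold")

    planted = set(conserved_cols)
    cols: list[list[str]] = []
    for j in range(n_cols):
        if j in planted:
            consensus = rng.choice(FULL_ALPHABET)
            rest = [aa for aa in FULL_ALPHABET if aa != consensus]
            col = [consensus] * threshold_count + [
                rest[i % len(rest)] for i in range(others)
            ]
        else:
            col = [FULL_ALPHABET[i % len(FULL_ALPHABET)] for i in range(n_seqs)]
        rng.shuffle(col)
        cols.append(col)
    rows = tuple("".join(cols[j][i] for j in range(n_cols)) for i in range(n_seqs))
    ids = tuple(f"s{i:04d}" for i in range(n_seqs))
    return Alignment(ids=ids, rows=rows), planted
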