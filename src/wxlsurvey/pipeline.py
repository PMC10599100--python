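"""End-to-end survey driver.

Runs genomes → domain evidence → architecture calls → clusters → genome
summaries, plus optional property and conservation tables, writing TSV
outputs. Deterministic given inputs and configuration. In motif-only
mode the sequence scanners stand in for HMM evidence (lower fidelity:
the HBD domain has no diagnostic motif).
"""

from __future__ import annotations

import hashlib
import logging
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import architecture as arch
from . import cluster_finder as cf
from . import conservation as cons
from . import domain_annotation as da
from . import genome_io as gio
from . import physchem as pc

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genomes_dir: str | Path = "."
    domtblout_dir: str | Path | None = None  # None => motif-only mode
    alignments: tuple[str, ...] = ()
    output_dir: str | Path = "survey_out"
    evalue_max: float = da.DEFAULT_EVALUE_MAX
    max_gap: int = cf.DEFAULT_MAX_GAP
    conservation_threshold: int = cons.DEFAULT_THRESHOLD
    tmh_window: int = 19
    tmh_threshold: float = 1.6
    tmh_cterm_zone: int = 60
    insert_threshold: int = 140
    small_coverage: float = 0.60
    cterm_tolerance: int = 15

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat key=value config file (# comments allowed)."""
        kwargs: dict = {}
        casts = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            if key == "alignments":
                kwargs[key] = tuple(v for v in value.split(",") if v)
            elif key in ("evalue_max", "tmh_threshold", "small_coverage"):
                kwargs[key] = float(value)
            elif key in ("max_gap", "conservation_threshold", "tmh_window",
                         "tmh_cterm_zone", "insert_threshold", "cterm_tolerance"):
                kwargs[key] = int(value)
            elif key == "domtblout_dir":
                kwargs[key] = None if value in ("", "motif-only") else value
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class SurveyResult:
    protein_table: pd.DataFrame
    cluster_table: pd.DataFrame
    genome_table: pd.DataFrame
    property_table: pd.DataFrame
    conservation_table: pd.DataFrame
    summaries: list[cf.GenomeSummary] = field(default_factory=list)
    config_hash: str = ""


def _gather_evidence(
    genome: gio.GenomeRecord, config: PipelineConfig, domtbl: Path | None
) -> dict[str, list[da.DomainHit]]:
    by_protein: dict[str, list[da.DomainHit]] = defaultdict(list)
    if domtbl is not None:
        for hit in da.parse_domtblout(domtbl, config.evalue_max):
            by_protein[hit.protein_id].append(hit)
    else:
        for prot in genome.proteins():
            by_protein[prot.protein_id].extend(
                da.motif_evidence(prot.protein_id, prot.sequence)
            )
    return {pid: da.merge_hits(hits) for pid, hits in by_protein.items()}


def survey_genome(
    genome: gio.GenomeRecord, config: PipelineConfig, domtbl: Path | None
) -> tuple[list[arch.ArchitectureCall], dict[str, int], list[cf.GeneCluster],
           cf.GenomeSummary]:
    """Classify one genome's proteins and find its WxL clusters."""
    evidence = _gather_evidence(genome, config, domtbl)
    calls: list[arch.ArchitectureCall] = []
    ordinals: dict[str, int] = {}
    clusters: list[cf.GeneCluster] = []
    for rep in genome.replicons:
        rep_calls: list[tuple[arch.ArchitectureCall, int]] = []
        for prot in rep.genes:
            hits = evidence.get(prot.protein_id, [])
            tmh = da.detect_tmh(
                prot.sequence, prot.protein_id,
                window=config.tmh_window, threshold=config.tmh_threshold,
                cterm_zone=config.tmh_cterm_zone,
            )
            signal = da.detect_signal_peptide(prot.sequence, prot.protein_id)
            call = arch.classify_architecture(
                prot, hits, tmh, signal,
                small_coverage=config.small_coverage,
                cterm_tolerance=config.cterm_tolerance,
            )
            calls.append(call)
            ordinals[prot.protein_id] = prot.ordinal
            rep_calls.append((call, prot.ordinal))
        for cand in cf.find_candidates(rep_calls, rep.replicon_id, config.max_gap):
            clusters.append(cf.evaluate_cluster(cand))
    summary = cf.summarize_genome(genome.genome_id, calls, clusters)
    return calls, ordinals, clusters, summary


def run_survey(config: PipelineConfig) -> SurveyResult:
    """Run the full survey over every GenBank file in ``genomes_dir``.

    Per genome ``G.gbk``, HMM evidence is read from ``<domtblout_dir>/
    G.domtblout`` when present; otherwise (or in motif-only mode) the
    sequence scanners supply evidence. Writes protein, cluster, genome,
    and (when alignments are given) conservation TSVs plus the property
    table into ``output_dir``.
    """
    genomes_dir = Path(config.genomes_dir)
    paths = sorted(genomes_dir.glob("*.gbk")) + sorted(genomes_dir.glob("*.gb"))
    if not paths:
        raise FileNotFoundError(f"no GenBank files (*.gbk, *.gb) in {genomes_dir}")

    protein_rows, cluster_rows, genome_rows, prop_rows = [], [], [], []
    summaries = []
    for path in paths:
        (genome,) = gio.read_genbank(path)
        domtbl = None
        if config.domtblout_dir is not None:
            cand = Path(config.domtblout_dir) / f"{path.stem}.domtblout"
            if cand.exists():
                domtbl = cand
            else:
                logger.warning("%s: no domtblout found; motif-only for this genome",
                               path.stem)
        calls, ordinals, clusters, summary = survey_genome(genome, config, domtbl)
        summaries.append(summary)
        by_id = {p.protein_id: p for p in genome.proteins()}
        for call in calls:
            prot = by_id[call.protein_id]
            insert = None
            if any(h.domain == da.PGBD for h in call.hits):
                insert = arch.detect_buttressing_insert(
                    call, config.insert_threshold
                ).insert_present
            protein_rows.append({
                "genome_id": genome.genome_id,
                "replicon_id": prot.replicon_id,
                "protein_id": call.protein_id,
                "ordinal": prot.ordinal,
                "arch_class": call.arch_class,
                "domains": ";".join(
                    f"{h.domain}:{h.env_start}-{h.env_end}" for h in call.hits),
                "has_tmh": call.has_tmh,
                "has_insert": insert,
                "signal_peptide": call.signal.present if call.signal else False,
            })
            if call.arch_class in arch.RELEVANT_CLASSES:
                prof = pc.physchem_profile(call.protein_id, prot.sequence)
                prop_rows.append({
                    "protein_id": prof.protein_id,
                    "length": prof.length,
                    "mw_da": round(prof.mw, 2),
                    "mw_kda": round(prof.mw / 1000.0, 1),
                    "pi": round(prof.pi, 2),
                    "acidity": prof.acidity,
                })
        for i, cluster in enumerate(clusters):
            cluster_rows.append({
                "genome_id": genome.genome_id,
                "replicon_id": cluster.candidate.replicon_id,
                "cluster_index": i,
                "members": ";".join(m[0] for m in cluster.candidate.members),
                "ordinals": ";".join(str(m[1]) for m in cluster.candidate.members),
                "classes": ";".join(m[2] for m in cluster.candidate.members),
                "n_wxlip": cluster.n_wxlip,
                "n_wxl": cluster.n_wxl,
                "qualifies": cluster.qualifies,
                "simple": cluster.simple,
            })
        genome_rows.append({
            "genome_id": summary.genome_id,
            **{k: summary.census[k] for k in
               (*arch.RELEVANT_CLASSES, "WXL", "total")},
            "n_clusters": summary.n_clusters,
            "n_simple": summary.n_simple,
            "sparse": summary.sparse,
        })

    cons_rows = []
    for aln_path in config.alignments:
        aln = cons.read_alignment(aln_path)
        profile = cons.column_conservation(aln, config.conservation_threshold)
        for j, col in enumerate(profile.columns):
            cons_rows.append({
                "alignment": Path(aln_path).name,
                "column": j,
                "majority_residue": col.majority_residue or "-",
                "majority_count": col.majority_count,
                "conserved": col.conserved,
            })

    cfg_hash = hashlib.sha256(repr(sorted(asdict(config).items())).encode()
                              ).hexdigest()[:12]
    result = SurveyResult(
        protein_table=pd.DataFrame(protein_rows),
        cluster_table=pd.DataFrame(cluster_rows),
        genome_table=pd.DataFrame(genome_rows),
        property_table=pd.DataFrame(prop_rows),
        conservation_table=pd.DataFrame(cons_rows),
        summaries=summaries,
        config_hash=cfg_hash,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.protein_table.to_csv(out / "proteins.tsv", sep="\t", index=False)
    result.cluster_table.to_csv(out / "clusters.tsv", sep="\t", index=False)
    result.genome_table.to_csv(out / "genomes.tsv", sep="\t", index=False)
    result.property_table.to_csv(out / "properties.tsv", sep="\t", index=False)
    result.conservation_table.to_csv(out / "conservation.tsv", sep="\t", index=False)
    return result


def validate_result(result: SurveyResult) -> list[str]:
    """Internal-consistency audit; an empty list means pass.

    Checks census sums (per-class counts add up to the reported total),
    cluster-membership referential integrity, and that every qualifying
    cluster satisfies the >=1 WxLIP / >=2 WxL definition.
    """
    findings: list[str] = []
    pt, gt, ct = result.protein_table, result.genome_table, result.cluster_table
    known = set(pt["protein_id"]) if len(pt) else set()
    for _, row in gt.iterrows():
        class_sum = sum(int(row[c]) for c in arch.RELEVANT_CLASSES)
        if class_sum != int(row["total"]):
            findings.append(
                f"{row['genome_id']}: census classes sum to {class_sum}, "
                f"total says {row['total']}"
            )
    for _, row in ct.iterrows():
        for pid in str(row["members"]).split(";"):
            if pid and pid not in known:
                findings.append(
                    f"cluster in {row['genome_id']} references unknown protein {pid}"
                )
        qualifies = bool(row["qualifies"])
        should = int(row["n_wxlip"]) >= 1 and int(row["n_wxl"]) >= 2
        if qualifies != should:
            findings.append(
                f"cluster in {row['genome_id']} qualifies={qualifies} but "
                f"census says {should}"
            )
    return findings
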