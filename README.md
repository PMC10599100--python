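# wxlsurvey

Survey toolkit for **WxL protein gene clusters** in annotated bacterial
genomes.

WxL proteins are cell-surface proteins of firmicutes (notably
*Enterococcus*, *Listeria* and *Lactiplantibacillus* species) whose
~160–190-residue WxL domain — named for its two conserved Trp-x-Leu
motifs — binds peptidoglycan and is implicated in virulence. WxL genes
occur in characteristic clusters that also encode a **WxLIP**
(WxL-Interacting Protein): a two-domain protein made of a
peptidoglycan-binding domain (PGBD, Pfam DUF916/PF06040), a host-binding
domain (HBD, DUF3324/PF11797) in that fixed order, and a C-terminal
transmembrane helix (TMH). `wxlsurvey` reimplements the genome-survey
side of that analysis as a reusable, fully testable pipeline:

* **genome_io** — ordered proteomes from GenBank flat files; FASTA I/O.
* **domain_annotation** — HMMER3 `hmmsearch --domtblout` parsing with
  the survey E-value cutoff (full-sequence E < 1e-10), Trp-x-Leu and
  NQIDKxxxYFDLK motif scanners, a Kyte–Doolittle C-terminal TMH
  detector, and a signal-peptide heuristic.
* **architecture** — a classification grammar over merged domain
  evidence: `WXL_SMALL`, `WXL_LARGE`, `WXLIP_FULL`, `PGBD_ONLY`,
  `HBD_ONLY`, `OTHER`; plus detection of the ~20-residue
  buttressing-loop insert that distinguishes in-cluster PGBD (~148 aa)
  from Pfam's DUF916 (~125 aa).
* **cluster_finder** — single-linkage grouping of relevant genes with at
  most four intervening annotated genes between neighbours; a group
  qualifies as a WxL cluster when it holds ≥1 WxLIP and ≥2 WxL proteins
  ("simple" = exactly 1 + 2).
* **conservation** — the invariant-column statistic (majority residue in
  ≥60 of 175 aligned sequences by default) with mapping of conserved
  columns onto a reference sequence.
* **physchem** — length, average molecular weight, and theoretical pI by
  bisection of the Henderson–Hasselbalch net-charge curve (EMBOSS pKa
  set), with an acidic/neutral/basic call.
* **synthetic_data** — seeded generator of genomes with planted
  clusters, matching domtblout evidence, and alignments with planted
  invariant columns, each with a machine-readable truth manifest.

## Worked example

Generate two seeded synthetic genomes and survey them:

```bash
$ wxlsurvey synth --seed 42 --n-genomes 2 --out fixtures
fixtures/SYN1.gbk  fixtures/SYN1.domtblout  (1 qualifying planted)
fixtures/SYN2.gbk  fixtures/SYN2.domtblout  (1 qualifying planted)

$ wxlsurvey survey --genomes-dir fixtures --domtblout-dir fixtures --out survey_out
genomes: 2  proteins (relevant): 6  qualifying clusters: 2  simple: 2
```

Each genome planted one canonical cluster (1 WxLIP + 2 WxL); the survey
recovered both, typed them "simple", and wrote per-protein, per-cluster
and per-genome TSVs:

```
$ head -4 survey_out/genomes.tsv
genome_id  WXL_SMALL  WXL_LARGE  WXLIP_FULL  PGBD_ONLY  HBD_ONLY  WXL  total  n_clusters  n_simple  sparse
SYN1       1          1          1           0          0         2    3      1           1         False
SYN2       1          1          1           0          0         2    3      1           1         False
```

The `total` column is the per-genome census (sum of the five relevant
classes); `sparse` flags genomes holding only one or two relevant
proteins and no qualifying cluster. Property tables work on any FASTA:

```
$ wxlsurvey props pep.fa
protein_id  length  mw_da    mw_kda  pi    acidity
EfmDemo     26      2811.29  2.8     9.19  basic
```

(a 26-residue peptide of 2811.29 Da whose zero-charge pH, 9.19, falls in
the basic band — the band reported for *L. plantarum* WxLIPs, whereas
*Enterococcus* WxLIPs are acidic.)

`wxlsurvey survey --motif-only` runs without HMMER evidence, using the
Trp-x-Leu and NQIDK anchor scanners instead (lower fidelity: HBD has no
diagnostic motif, so full WxLIPs cannot be called in this mode).

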