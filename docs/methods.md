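# Methods

## The survey model

The pipeline operates on one genome at a time, represented as ordered
proteomes: every annotated CDS of a replicon, sorted by start
coordinate, receives an ordinal 0..n−1. The ordinal — not the nucleotide
coordinate — is the unit of the cluster adjacency rule, because the rule
is phrased in numbers of intervening annotated genes. Strand is ignored
throughout: the cluster definition concerns gene neighbourhood, not
operon structure. Only CDS features count toward ordinals; RNA genes and
pseudogenes are excluded by default (`include_pseudo` restores
pseudogenes), since "annotated genes" in the source definition is
ambiguous and protein-coding context is what matters for the clusters.

### Domain evidence

The primary evidence channel is `hmmsearch --domtblout` output for the
three Pfam families WxL (PF13731), DUF916/PGBD (PF06040) and
DUF3324/HBD (PF11797). A row is accepted when its **full-sequence
E-value** is below 1e-10; the per-domain independent E-value is
available as an alternative filter (`use_domain_evalue`) but full-
sequence is the default because it matches hmmsearch's own ranking.
Envelope coordinates are converted to 0-based half-open at the parser
boundary. Same-domain hits on one protein that overlap by more than 50%
of the shorter interval are reduced to the lowest-E-value hit.

A motif-only channel allows running with no external tools: WxL
evidence from pairs of Trp-x-Leu motifs that fit one 160–190-residue
domain and are at least 40 residues apart (the lower bound suppresses
spurious adjacent-motif pairs; both knobs are configurable), and PGBD
evidence from the NQIDKxxxYFDLK anchor (exactly three arbitrary
residues at the x positions; no gaps) extended to the nominal
148-residue domain length. Motif evidence carries a pseudo-E-value of
1e-12 so it flows through the same filter path. HBD has no diagnostic
sequence motif, so motif-only mode cannot produce full-WxLIP calls;
it is a degraded mode for exploration, not a substitute for HMM
evidence.

The C-terminal transmembrane helix is detected by a sliding
Kyte–Doolittle window (width 19, mean ≥ 1.6, standard single-span
hydropathy practice); qualifying windows are merged into maximal spans
and only spans starting in the final 60 residues are reported, because
the WxLIP helix is C-terminal. A span's reported hydropathy is its peak
window mean, so it always satisfies the threshold on re-scoring. Note
that alanine (1.8) exceeds the 1.6 threshold, so long Ala-rich tracts
score as hydrophobic — inherent to the Kyte–Doolittle scale at this
threshold, and harmless here because the TMH flag is metadata, not a
classification gate. The signal-peptide heuristic (basic residue in the
first 10 positions plus a hydrophobic 8-mer inside residues 5–30) is
likewise advisory only: survey proteins are classified from domain
content alone.

### Architecture grammar

Classification from merged hits, in precedence order: PGBD+HBD in the
canonical order → `WXLIP_FULL`; the reverse order → `OTHER` with an
order-violation flag (the survey found the order invariant, so a
violation is surfaced rather than silently accepted); an isolated half
→ `PGBD_ONLY`/`HBD_ONLY`; otherwise WxL evidence is considered:
`WXL_SMALL` when a WxL hit covers ≥60% of the mature length (sequence
minus an assumed 25-residue signal peptide), `WXL_LARGE` when a hit
ends within 15 residues of the C-terminus, else `OTHER`. The 60%/15
knobs are configurable; they encode the qualitative small/large
dichotomy (small ≈ nothing but the WxL domain; large ≈ C-terminal WxL
preceded by host-binding domains). A protein with both PGBD/HBD and WxL
hits is classed by the PGBD/HBD branch — the surveyed genomes treat the
two protein families as disjoint. One known edge: a natural WxLIP
truncated to its PGBD (as in the anomalously short *E. faecium* locus B
protein) classes as `PGBD_ONLY`; the literal call is recorded rather
than special-cased.

The buttressing-loop insert call uses PGBD hit length alone: in-cluster
PGBD runs ≈148 residues, Pfam's DUF916 ≈125, and the inclusive midpoint
140 discriminates. Alignment against a Pfam reference would be more
precise but needs an external profile; hit length is what the evidence
already carries.

### Clusters

Relevant genes (the five non-OTHER classes) on one replicon are grouped
by single linkage: neighbours join when at most `max_gap` = 4 annotated
genes intervene (ordinal difference ≤ 5), applied transitively. The
transitivity reading is deliberate: observed clusters with up to nine
WxL genes imply chained adjacency. Replicons are linear (no wrap at a
circular origin; configurable off by default because GenBank ordinals
are linear). A group qualifies when it contains ≥1 `WXLIP_FULL` and ≥2
WxL members; `PGBD_ONLY`/`HBD_ONLY` members are listed but count toward
neither tally. A genome is "sparse" when it holds only one or two
relevant proteins and no qualifying cluster.

### Conservation

A column is conserved when its majority non-gap residue occurs in at
least `threshold` = 60 sequences — an absolute count, exactly as the
statistic is defined for the 175-sequence survey alignments; a
fractional variant (default 60/175 ≈ 0.343) is provided for other
depths. Identity is strict (no conservative-substitution classes), ties
break alphabetically for determinism, `.` and `-` are gaps, and gaps
never count toward a majority. Mapping to a reference returns 1-based
ungapped positions; conserved columns where the reference is gapped are
reported separately rather than dropped.

### Physicochemistry

Molecular weight sums average (not monoisotopic) residue masses plus
one water, matching the kDa figures produced by ProtParam-style tools;
`X` contributes the mean residue mass. The theoretical pI bisects the
Henderson–Hasselbalch net charge, which is strictly decreasing in pH,
on (0, 14) to |charge| < 1e-4 or width < 1e-6. The default pKa table is
the EMBOSS set (N-term 8.6, C-term 3.6, D 3.9, E 4.1, C 8.5, Y 10.1,
H 6.5, K 10.8, R 12.5); the table is pluggable because ProtParam's
internal set differs, typically shifting pI by ≲0.5 pH. Two numerical
consequences of this table worth knowing: dipeptides without ionizable
side chains land exactly at the terminal-pKa midpoint (GG → 6.10), and
arginine retains ≈+0.03 charge even at pH 14, so "full deprotonation"
closed forms hold only for arginine-free sequences. Acidity bands:
acidic < 6.5, basic > 7.5, neutral between — chosen so the reported
acidic (5.1–6.8) and basic (8–11) WxLIP groups fall in the intended
bands; both cut points are configurable.

## The synthetic generator

`synthetic_data` emulates the statistical structure the survey rules
respond to, not real genomes. Each genome is a set of linear replicons
whose gene slots are decoys except where a `ClusterSpec` plants members
(class sequence plus intervening-decoy counts, 0–10). Plants are
separated by at least `max_gap + 2` decoys so distinct plants never
merge. Planted proteins carry exactly the features the detectors test
for: motif geometry inside WxL domains, the PGBD anchor, a
22-residue L/I/V/F C-terminal tract (guaranteed to fire the hydropathy
detector at defaults), a signal-like N-terminus, and class-appropriate
domain spans (WxLIP total length 337–365; isolated PGBD at the
insert-free ~125). Background residues are uniform over the 19
standard residues excluding tryptophan, so Trp-x-Leu pairs exist only
where planted; decoys are likewise motif-scrubbed. Emitted files are
standard GenBank and domtblout (rows grouped by query model, one
full-sequence E-value per model–target pair; true rows log-uniform in
[1e-50, 1e-11], spurious rows in [1e-9, 1]). All randomness derives
from the single config seed; identical configs are byte-identical.

The truth manifest's qualifies/simple flags are computed by a
brute-force union-find transitive closure inside the generator —
independent of the cluster finder's linear sweep — so planted-recovery
tests compare two separately implemented routes. What passing recovery
tests show: the deterministic rules are implemented exactly (the rules
admit no sampling error, so precision and recall are required to be
100%). What they do not show: robustness to real-data phenomena the
generator omits — fragmented assemblies, annotation errors, atypical
domain lengths, compositional bias, or genuinely borderline HMM scores.

The MSA generator plants columns where exactly `threshold_count` rows
share a residue while every other residue count (planted and
background columns alike) stays strictly below it, making the
conservation boundary exact by construction; it rejects configurations
where the 20-letter alphabet cannot keep background counts below the
threshold.

## Problem sizes and determinism

The standard recovery matrix is 51 genomes of 50 genes each, cycling
cluster composition over {1 WxLIP + 2 WxL, 2 + 3, 1 + 1 non-qualifying}
and member gaps over 0–6 — enough to exercise every rule branch
(merging, splitting, non-qualifying fragments) many times over while a
full run stays in seconds. Oracle comparisons use 200 random ordinal
sets (clustering), 1000 random strings (motif scanners), and 100 random
sequences (pI against a two-stage 1e-4-resolution grid search; the
two-stage refinement is valid because |net charge| is unimodal in pH).
The pipeline is deterministic given inputs and configuration; reruns
produce identical tables.

## Known limitations

* Architecture calls are only as good as the domain evidence; the
  motif-only mode misses HBD entirely and under-calls WxLIP.
* The signal-peptide and TMH heuristics are crude stand-ins for
  dedicated predictors and are deliberately excluded from
  classification decisions.
* The insert call ignores alignment register; a PGBD hit whose envelope
  is truncated by the HMM (not the protein) can be mis-called.
* Cluster detection assumes complete, correctly ordered annotation;
  a missed CDS changes ordinals and can split a true cluster.
* pI values depend on the pKa table; cross-tool comparisons are
  expected to agree only within a few tenths of a pH unit.
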