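import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from wxlsurvey.domain_annotation import (
    DEFAULT_EVALUE_MAX,
    DomainHit,
    DomtbloutParseError,
    detect_signal_peptide,
    detect_tmh,
    KYTE_DOOLITTLE,
    merge_hits,
    motif_evidence,
    parse_domtblout,
    scan_pgbd_anchor,
    scan_wxl_motifs,
)
from wxlsurvey.synthetic_data import _domtbl_row


def _write_domtbl(tmp_path, hits_with_tlen, name="t.domtblout"):
    p = tmp_path / name
    lines = ["# comment line"]
    for hit, tlen in hits_with_tlen:
        lines.append(_domtbl_row(hit, tlen, 1, 1))
    p.write_text("\n".join(lines) + "\n")
    return p


class TestParseDomtblout:
    def test_comments_only(self, tmp_path):
        p = tmp_path / "empty.domtblout"
        p.write_text("# nothing here\n#\n")
        assert parse_domtblout(p) == []

    def test_evalue_filter_boundary(self, tmp_path):
        """Survey cutoff: E-value strictly below 1e-10 is included.

        Distinct targets, because hmmsearch reports one full-sequence
        E-value per (model, target) pair."""
        keep = DomainHit("prot1", "WXL", 10, 180, 1e-11)
        drop = DomainHit("prot2", "WXL", 10, 180, 1e-9)
        p = _write_domtbl(tmp_path, [(keep, 200), (drop, 200)])
        got = parse_domtblout(p)
        assert [h.evalue for h in got] == [1e-11]

    def test_coordinate_conversion(self, tmp_path):
        """Envelope 11..50 (1-based inclusive) becomes 10..50 half-open."""
        hit = DomainHit("protA", "PGBD", 10, 50, 1e-20)
        p = _write_domtbl(tmp_path, [(hit, 120)])
        (got,) = parse_domtblout(p)
        assert (got.env_start, got.env_end) == (10, 50)
        assert got.domain == "PGBD"
        # the flat file itself holds the 1-based coordinates
        row = [l for l in p.read_text().splitlines() if not l.startswith("#")][0]
        fields = row.split()
        assert (int(fields[19]), int(fields[20])) == (11, 50)

    def test_manual_filter_oracle(self, tmp_path, rng):
        """Random rows vs an independent threshold filter on the raw text."""
        hits = []
        for i in range(10):
            ev = 10.0 ** rng.uniform(-20, -5)
            hits.append((DomainHit(f"p{i}", "HBD", 5, 100, ev), 150))
        p = _write_domtbl(tmp_path, hits)
        got = {h.protein_id for h in parse_domtblout(p)}
        expected = set()
        for line in p.read_text().splitlines():
            if line.startswith("#"):
                continue
            f = line.split()
            if float(f[6]) < DEFAULT_EVALUE_MAX:
                expected.add(f[0])
        assert got == expected

    def test_unmapped_model_ignored(self, tmp_path, caplog):
        p = tmp_path / "u.domtblout"
        row = _domtbl_row(DomainHit("p1", "WXL", 0, 100, 1e-30), 150, 1, 1)
        row = row.replace("WxL", "Zzz").replace("PF13731.8", "PF99999.1")
        p.write_text(row + "\n")
        assert parse_domtblout(p) == []

    def test_malformed_row_cites_line(self, tmp_path):
        p = tmp_path / "bad.domtblout"
        p.write_text("# header\ntoo few fields here\n")
        with pytest.raises(DomtbloutParseError, match="line 2"):
            parse_domtblout(p)

    def test_filter_monotonicity(self, tmp_path, rng):
        hits = [(DomainHit(f"p{i}", "WXL", 0, 170, 10.0 ** rng.uniform(-30, -2)), 200)
                for i in range(20)]
        p = _write_domtbl(tmp_path, hits)
        loose = {(h.protein_id, h.evalue) for h in parse_domtblout(p, 1e-5)}
        tight = {(h.protein_id, h.evalue) for h in parse_domtblout(p, 1e-15)}
        assert tight <= loose


def _brute_merge(hits):
    """Independent suppression oracle: walk hits best-E first; a hit is
    suppressed iff a surviving same-domain hit overlaps >50% of the shorter."""
    def overlap(a, b):
        inter = min(a.env_end, b.env_end) - max(a.env_start, b.env_start)
        return 0.0 if inter <= 0 else inter / min(a.length, b.length)

    survivors = []
    for h in sorted(hits, key=lambda h: (h.evalue, h.env_start, h.env_end)):
        if not any(s.domain == h.domain and overlap(s, h) > 0.5 for s in survivors):
            survivors.append(h)
    return sorted(survivors, key=lambda h: (h.env_start, h.env_end))


class TestMergeHits:
    def test_single_hit_identity(self):
        h = DomainHit("p", "WXL", 0, 170, 1e-20)
        assert merge_hits([h]) == [h]

    def test_overlapping_keeps_best_evalue(self):
        a = DomainHit("p", "PGBD", 10, 150, 1e-20)
        b = DomainHit("p", "PGBD", 20, 160, 1e-12)
        assert merge_hits([a, b]) == [a]

    def test_different_domains_never_merged(self):
        a = DomainHit("p", "PGBD", 10, 150, 1e-20)
        b = DomainHit("p", "HBD", 10, 150, 1e-12)
        assert merge_hits([a, b]) == [a, b]

    def test_mixed_proteins_rejected(self):
        with pytest.raises(ValueError):
            merge_hits([DomainHit("p1", "WXL", 0, 100, 1e-20),
                        DomainHit("p2", "WXL", 0, 100, 1e-20)])

    def test_random_sets_match_suppression_oracle(self, rng):
        for _ in range(200):
            hits = []
            for _ in range(rng.randint(1, 12)):
                s = rng.randint(0, 300)
                e = s + rng.randint(20, 150)
                dom = rng.choice(["WXL", "PGBD", "HBD"])
                hits.append(DomainHit("p", dom, s, e, 10.0 ** rng.uniform(-40, -11)))
            assert merge_hits(hits) == _brute_merge(hits)


def _brute_wxl_pairs(seq, min_sep=40, max_span=190):
    singles = [i for i in range(len(seq) - 2)
               if seq[i] == "W" and seq[i + 2] == "L"]
    return [(i, j) for i, j in itertools.combinations(singles, 2)
            if j + 3 - i <= max_span and j - i >= min_sep]


class TestWxlMotifs:
    def test_no_tryptophan(self):
        assert scan_wxl_motifs("AAAA") == []

    def test_planted_pair(self):
        seq = list("A" * 200)
        for off in (10, 150):
            seq[off], seq[off + 2] = "W", "L"
        (hit,) = scan_wxl_motifs("".join(seq))
        assert hit.positions == (10, 150)
        assert hit.span == (10, 153)

    def test_pair_beyond_domain_envelope_rejected(self):
        """Two motifs 240 residues apart cannot fit one 160-190 aa domain."""
        seq = list("A" * 300)
        for off in (10, 250):
            seq[off], seq[off + 2] = "W", "L"
        assert scan_wxl_motifs("".join(seq)) == []

    def test_short_sequence(self):
        assert scan_wxl_motifs("WA") == []

    def test_random_sequences_match_enumeration_oracle(self, rng):
        for _ in range(1000):
            n = rng.randint(0, 250)
            seq = "".join(rng.choice("AWL") for _ in range(n))
            got = [h.positions for h in scan_wxl_motifs(seq)]
            assert sorted(got) == sorted(_brute_wxl_pairs(seq))


class TestPgbdAnchor:
    def test_exact_anchor(self):
        (hit,) = scan_pgbd_anchor("NQIDKAAAYFDLK")
        assert hit.span == (0, 13)

    def test_last_position_violated(self):
        assert scan_pgbd_anchor("NQIDKAAAYFDLA") == []

    def test_wildcards_free(self):
        assert len(scan_pgbd_anchor("XXNQIDKWPYYFDLKXX")) == 1

    def test_random_sequence_matches_bruteforce(self, rng):
        seq = "".join(rng.choice("NQIDKYFLA") for _ in range(10000))
        brute = [i for i in range(len(seq) - 12)
                 if all(seq[i + k] == c for k, c in enumerate("NQIDK") )
                 and all(seq[i + 8 + k] == c for k, c in enumerate("YFDLK"))]
        assert [h.span[0] for h in scan_pgbd_anchor(seq)] == brute


class TestTmh:
    def test_poly_aspartate_empty(self):
        assert detect_tmh("D" * 100) == []

    def test_cterminal_polyleucine_detected(self):
        # serine background (hydropathy -0.8) so only the tract can fire
        (span,) = detect_tmh("S" * 100 + "L" * 22)
        assert span.start >= 100 - 19  # windows reaching into the tract
        assert span.end == 122
        assert span.mean_hydropathy >= 1.6

    def test_nterminal_span_rejected(self):
        assert detect_tmh("L" * 22 + "S" * 100) == []

    def test_short_sequence_empty(self):
        assert detect_tmh("LLLL") == []

    def test_spans_disjoint_and_above_threshold(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice("LIVADEKR") for _ in range(rng.randint(19, 200)))
            spans = detect_tmh(seq, cterm_zone=10**6)  # zone off: check all spans
            for a, b in zip(spans, spans[1:]):
                assert a.end <= b.start
            for s in spans:
                window_means = [
                    sum(KYTE_DOOLITTLE[aa] for aa in seq[i:i + 19]) / 19
                    for i in range(s.start, s.end - 18)
                ]
                assert max(window_means) >= 1.6
                assert abs(max(window_means) - s.mean_hydropathy) < 1e-9


class TestSignalPeptide:
    def test_classic_signal(self):
        call = detect_signal_peptide("MKKLLLLLLLLAAS" + "A" * 50)
        assert call.present
        assert call.cleavage_hint is not None and call.cleavage_hint <= 45

    def test_poly_glutamate_negative(self):
        assert not detect_signal_peptide("E" * 60).present

    def test_too_short_negative(self):
        assert not detect_signal_peptide("MKKLLLL").present

    def test_invariant_to_tail(self, rng):
        head = "MKK" + "L" * 10 + "A" * 32  # 45 residues
        for _ in range(20):
            tail = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(60))
            assert detect_signal_peptide(head + tail) == detect_signal_peptide(
                head + "A" * 60)


def test_motif_evidence_modes():
    seq = list("A" * 225)
    for off in (30, 170):
        seq[off], seq[off + 2] = "W", "L"
    hits = motif_evidence("p", "".join(seq))
    assert [h.domain for h in hits] == ["WXL"]
    assert all(h.source == "motif" and h.evalue < 1e-10 for h in hits)
    anchored = "M" * 25 + "NQIDKAAAYFDLK" + "A" * 200
    hits = motif_evidence("p", anchored)
    assert [h.domain for h in hits] == ["PGBD"]
    assert hits[0].env_start == 25
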