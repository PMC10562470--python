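"""In-silico PCR: binding-site scan against a naive oracle, amplicon
pairing, strand-mirror invariance, and per-taxon coverage."""

import pytest

from archamp.align import reverse_complement
from archamp.io import IUPAC_SETS, Lineage, SeqRecord
from archamp.pcr import (BindParams, find_binding_sites, panel_coverage,
                         predict_amplicons, amplicon_record)
from archamp.primers import pair_from_cores

from conftest import random_seq


def naive_sites(template: str, core: str, params: BindParams):
    """Position-by-position scan oracle, both strands."""
    def compat(x, y):
        return bool(IUPAC_SETS[x] & IUPAC_SETS[y])

    out = []
    m = len(core)
    for strand, probe, anchor in (
            ("+", core, range(m - params.anchor3_len, m)),
            ("-", reverse_complement(core), range(0, params.anchor3_len))):
        for pos in range(len(template) - m + 1):
            window = template[pos:pos + m]
            mism = [not compat(p, t) for p, t in zip(probe, window)]
            if sum(mism) <= params.max_mismatch and \
                    not any(mism[k] for k in anchor):
                out.append((pos, pos + m, strand, sum(mism)))
    out.sort(key=lambda s: (s[0], s[2]))
    return out


class TestBindingSites:
    def test_exact_core_single_site(self, rng):
        core = "AGCGTAAGCTTCGCAT"
        t = random_seq(rng, 300)
        template = SeqRecord("t", t[:100] + core + t[100:])
        sites = [s for s in find_binding_sites(template, core)
                 if s.strand == "+"]
        assert any(s.start == 100 and s.mismatches == 0 for s in sites)

    def test_degenerate_base_covers_template(self):
        template = SeqRecord("t", "GGGGACTGCTGGGGGG")
        sites = find_binding_sites(template, "ACKGCT",
                                   BindParams(max_mismatch=0))
        assert any(s.start == 4 and s.strand == "+" and s.mismatches == 0
                   for s in sites)

    def test_anchor_mismatch_disqualifies(self):
        template = SeqRecord("t", "GGGGGGACGTACGAAGGGGGG")
        core = "ACGTACGT"  # template has ...ACGTACGA...: 3' anchor broken
        sites = [s for s in find_binding_sites(
            template, core, BindParams(max_mismatch=2, anchor3_len=3))
            if s.strand == "+" and s.start == 6]
        assert sites == []

    def test_matches_naive_scan_oracle(self, rng):
        core_alpha = list("ACGTKMRY")
        for _ in range(100):
            template = SeqRecord("t", random_seq(rng, 120))
            m = int(rng.integers(6, 12))
            core = "".join(rng.choice(core_alpha, m))
            params = BindParams(max_mismatch=int(rng.integers(0, 3)),
                                anchor3_len=int(rng.integers(0, 4)))
            got = [(s.start, s.end, s.strand, s.mismatches)
                   for s in find_binding_sites(template, core, params)]
            assert got == naive_sites(template.sequence, core, params)


def _planted_template(rng, fwd_core, rev_core, amp_len=1440, gid="syn"):
    """Template whose planted sites would amplify exactly ``amp_len``
    bases (forward site start to reverse site end)."""
    left = random_seq(rng, 30)
    spacer = random_seq(rng, amp_len - len(fwd_core) - len(rev_core))
    right = random_seq(rng, 30)
    seq = left + fwd_core + spacer + reverse_complement(rev_core) + right
    return SeqRecord(gid, seq)


class TestPredictAmplicons:
    def test_planted_pair_single_amplicon(self, rng):
        pair = pair_from_cores("AGCGTAAGCTTCGCAT", "ACGGCTCAGTAACACGTG")
        template = _planted_template(rng, pair.forward.core_iupac,
                                     pair.reverse.core_iupac)
        (amp,) = predict_amplicons(template, pair)
        assert amp.length == 1440
        assert amp.f_site.strand == "+" and amp.r_site.strand == "-"

    def test_forward_site_only_no_amplicon(self, rng):
        pair = pair_from_cores("AGCGTAAGCTTCGCAT", "ACGGCTCAGTAACACGTG")
        t = random_seq(rng, 500)
        template = SeqRecord("t", t[:50] + pair.forward.core_iupac + t[50:])
        assert predict_amplicons(template, pair) == []

    def test_two_forward_one_reverse_pairings(self, rng):
        f, r = "AGCGTAAGCTTCGCAT", "ACGGCTCAGTAACACGTG"
        pair = pair_from_cores(f, r)
        seq = (random_seq(rng, 20) + f + random_seq(rng, 100) + f +
               random_seq(rng, 200) + reverse_complement(r) +
               random_seq(rng, 20))
        template = SeqRecord("t", seq)
        amps = predict_amplicons(template, pair,
                                 BindParams(max_amplicon=3000))
        assert len(amps) == 2
        assert amps[0].start == 20
        assert amps[1].start == 20 + len(f) + 100
        assert amps[0].end == amps[1].end

    def test_strand_mirror_invariance(self, rng):
        pair = pair_from_cores("AGCGTAAGCTTCGCAT", "ACGGCTCAGTAACACGTG")
        template = _planted_template(rng, pair.forward.core_iupac,
                                     pair.reverse.core_iupac)
        mirrored = SeqRecord("m", reverse_complement(template.sequence))
        a1 = predict_amplicons(template, pair)
        a2 = predict_amplicons(mirrored, pair)
        L = len(template.sequence)
        assert [(a.length,) for a in a1] == [(a.length,) for a in a2]
        assert [(L - a.end, L - a.start) for a in a1] == \
            [(a.start, a.end) for a in a2]
        assert amplicon_record(template, a1[0]).sequence == \
            amplicon_record(mirrored, a2[0]).sequence

    def test_amplified_sequence_orientation(self, rng):
        pair = pair_from_cores("AGCGTAAGCTTCGCAT", "ACGGCTCAGTAACACGTG")
        template = _planted_template(rng, pair.forward.core_iupac,
                                     pair.reverse.core_iupac)
        (amp,) = predict_amplicons(template, pair)
        rec = amplicon_record(template, amp)
        assert rec.sequence.startswith(pair.forward.core_iupac)
        assert rec.sequence.endswith(
            reverse_complement(pair.reverse.core_iupac))


class TestPanelCoverage:
    def _db(self, rng, pair, n_hit, n_miss, sk):
        recs, tax = [], {}
        for i in range(n_hit):
            recs.append(_planted_template(rng, pair.forward.core_iupac,
                                          pair.reverse.core_iupac,
                                          gid=f"{sk}_hit{i}"))
            tax[f"{sk}_hit{i}"] = Lineage((sk, "P", "C", "O", "F",
                                           f"g{i}", f"s{i}"))
        for i in range(n_miss):
            recs.append(SeqRecord(f"{sk}_miss{i}", random_seq(rng, 1600)))
            tax[f"{sk}_miss{i}"] = Lineage((sk, "P", "C", "O", "F",
                                            f"m{i}", f"ms{i}"))
        return recs, tax

    def test_full_coverage_on_designed_clade(self, rng):
        pair = pair_from_cores("AGCGTAAGCTTCGCAT", "ACGGCTCAGTAACACGTG")
        db, tax = self._db(rng, pair, n_hit=4, n_miss=0, sk="Archaea")
        report = panel_coverage(db, tax, pair, rank="superkingdom")
        row = report.per_superkingdom.iloc[0]
        assert row.taxon == "Archaea" and row.coverage == 1.0

    def test_diverged_sites_zero_coverage(self, rng):
        pair = pair_from_cores("AGCGTAAGCTTCGCAT", "ACGGCTCAGTAACACGTG")
        db, tax = self._db(rng, pair, n_hit=0, n_miss=3, sk="Archaea")
        report = panel_coverage(db, tax, pair, rank="superkingdom")
        assert report.per_superkingdom.iloc[0].coverage == 0.0

    def test_counts_conserved_in_mixed_community(self, rng):
        pair = pair_from_cores("AGCGTAAGCTTCGCAT", "ACGGCTCAGTAACACGTG")
        db_a, tax_a = self._db(rng, pair, 2, 1, "Archaea")
        db_b, tax_b = self._db(rng, pair, 3, 0, "Bacteria")
        report = panel_coverage(db_a + db_b, {**tax_a, **tax_b}, pair,
                                rank="genus")
        assert report.per_taxon.n_sequences.sum() == 6
        assert report.per_superkingdom.n_sequences.sum() == 6
        assert (report.per_taxon.n_amplified <=
                report.per_taxon.n_sequences).all()

    def test_coverage_monotone_in_max_mismatch(self, rng):
        pair = pair_from_cores("AGCGTAAGCTTCGCAT", "ACGGCTCAGTAACACGTG")
        db, tax = [], {}
        for i in range(6):  # plant sites then sprinkle mutations
            t = _planted_template(rng, pair.forward.core_iupac,
                                  pair.reverse.core_iupac, gid=f"g{i}")
            seq = list(t.sequence)
            for k in range(i):
                seq[33 + 2 * k] = "ACGT"[("ACGT".index(seq[33 + 2 * k])
                                          + 1) % 4]
            db.append(SeqRecord(f"g{i}", "".join(seq)))
            tax[f"g{i}"] = Lineage(("Bacteria",))
        prev = -1.0
        for mm in (0, 1, 2, 3):
            rep = panel_coverage(db, tax, pair,
                                 BindParams(max_mismatch=mm),
                                 rank="superkingdom")
            cov = rep.per_superkingdom.iloc[0].coverage
            assert cov >= prev
            prev = cov

    def test_empty_db_rejected(self):
        pair = pair_from_cores("AGCGTAAGCTTCGCAT", "ACGGCTCAGTAACACGTG")
        with pytest.raises(ValueError, match="empty"):
            panel_coverage([], {}, pair)
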