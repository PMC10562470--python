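"""Read classification: length filter semantics, strict threshold gates,
conservation laws, and per-rank classifier agreement."""

import numpy as np
import pytest

from archamp.classify import (ClassifyParams, TaxonAssignment,
                              abundance_table, assign_read,
                              compare_classifiers, krona_abundance,
                              length_filter, read_assignments,
                              write_assignments)
from archamp.io import Lineage, RANKS, SeqRecord

from conftest import random_seq


def _lineage(sk="Bacteria", genus="G1", species="S1"):
    return Lineage((sk, "P", "C", "O", "F", genus, species))


class TestLengthFilter:
    def test_inclusive_boundaries(self, rng):
        reads = [SeqRecord(f"r{n}", random_seq(rng, n))
                 for n in (1249, 1250, 1500, 1750, 1751)]
        kept, removed = length_filter(reads)
        assert [len(r) for r in kept] == [1250, 1500, 1750]
        assert [len(r) for r in removed] == [1249, 1751]

    def test_empty_input(self):
        assert length_filter([]) == ([], [])

    def test_partition_law(self, rng):
        reads = [SeqRecord(f"r{i}", random_seq(
            rng, int(rng.integers(1000, 2000)))) for i in range(40)]
        kept, removed = length_filter(reads)
        assert len(kept) + len(removed) == len(reads)
        assert {r.id for r in kept} | {r.id for r in removed} == \
            {r.id for r in reads}


class TestAssignRead:
    def test_identical_read_fully_classified(self, rng):
        seq = random_seq(rng, 1500)
        refdb = [SeqRecord("refA", seq),
                 SeqRecord("refB", random_seq(rng, 1500))]
        tax = {"refA": _lineage(), "refB": _lineage(genus="G2")}
        read = SeqRecord("q", seq)
        a = assign_read(read, refdb, tax)
        assert a.status == "classified" and a.best_ref == "refA"
        assert a.identity == 1.0 and a.ref_coverage == 1.0
        assert a.lineage == tax["refA"]

    def test_low_coverage_gate(self, rng):
        ref_seq = random_seq(rng, 1500)
        refdb = [SeqRecord("ref", ref_seq)]
        tax = {"ref": _lineage()}
        read = SeqRecord("q", ref_seq[:800])  # covers 53% of the reference
        params = ClassifyParams(len_lo=1, len_hi=10000)
        a = assign_read(read, refdb, tax, params)
        assert a.status == "unclassified"
        assert a.identity > 0.95 and a.ref_coverage < 0.60

    def test_boundary_coverage_exactly_060_unclassified(self, rng):
        # a read that is an exact 60%-slice of the reference: coverage is
        # exactly 0.60, and "more than 60%" is read strictly
        ref_seq = random_seq(rng, 1500)
        refdb = [SeqRecord("ref", ref_seq)]
        read = SeqRecord("q", ref_seq[:900])
        params = ClassifyParams(len_lo=1, len_hi=10000)
        a = assign_read(read, refdb, {"ref": _lineage()}, params)
        assert a.ref_coverage == pytest.approx(0.60)
        assert a.status == "unclassified"

    def test_boundary_identity_exactly_080_unclassified(self):
        # 100-column gapless alignment with exactly 20 evenly spread
        # mismatches: identity exactly 0.80 -> strictly-greater gate fails
        base = ("ACGTA" * 20)
        read_chars = list(base)
        for k in range(2, 100, 5):
            read_chars[k] = {"A": "C", "C": "A", "G": "T",
                             "T": "G"}[read_chars[k]]
        read = SeqRecord("q", "".join(read_chars))
        params = ClassifyParams(len_lo=1, len_hi=10000)
        a = assign_read(read, [SeqRecord("ref", base)],
                        {"ref": _lineage()}, params)
        assert a.identity == pytest.approx(0.80)
        assert a.ref_coverage == 1.0
        assert a.status == "unclassified"

    def test_tie_breaks_to_smallest_reference_id(self, rng):
        seq = random_seq(rng, 1400)
        refdb = [SeqRecord("zeta", seq), SeqRecord("alpha", seq)]
        tax = {"zeta": _lineage(genus="Gz"), "alpha": _lineage(genus="Ga")}
        params = ClassifyParams(len_lo=1, len_hi=10000)
        a = assign_read(SeqRecord("q", seq), refdb, tax, params)
        assert a.best_ref == "alpha"
        # and the result is independent of database order
        b = assign_read(SeqRecord("q", seq), refdb[::-1], tax, params)
        assert b == a

    def test_reverse_strand_reads_classified(self, rng):
        from archamp.align import reverse_complement
        seq = random_seq(rng, 1500)
        a = assign_read(SeqRecord("q", reverse_complement(seq)),
                        [SeqRecord("ref", seq)], {"ref": _lineage()},
                        ClassifyParams(len_lo=1, len_hi=10000))
        assert a.status == "classified" and a.identity == 1.0

    def test_missing_lineage_for_best_ref_is_error(self, rng):
        seq = random_seq(rng, 1400)
        with pytest.raises(ValueError, match="no lineage"):
            assign_read(SeqRecord("q", seq), [SeqRecord("ref", seq)], {},
                        ClassifyParams(len_lo=1, len_hi=10000))


class TestAbundance:
    def _assignments(self):
        lin = _lineage()
        rows = [TaxonAssignment(f"r{i}", "classified", "ref", 0.95, 0.9,
                                lin) for i in range(10)]
        rows.append(TaxonAssignment("u1", "unclassified", "ref", 0.5, 0.5,
                                    Lineage(())))
        rows.append(TaxonAssignment("f1", "length_filtered", None, 0.0,
                                    0.0, Lineage(())))
        return rows

    def test_single_species_at_every_rank(self):
        rows = self._assignments()[:10]
        for rank in RANKS:
            table = abundance_table(rows, rank)
            assert sum(table.counts.values()) == 10
            assert len(table.counts) == 1

    def test_totals_conserved_across_statuses(self):
        rows = self._assignments()
        table = abundance_table(rows, "genus")
        assert table.total_reads == 12
        assert sum(table.counts.values()) + table.n_unclassified + \
            table.n_length_filtered == 12

    def test_krona_round_trip(self, tmp_path):
        from archamp.io import read_krona_tsv, write_krona_tsv
        rows = self._assignments()
        table = krona_abundance(rows)
        assert sum(table.values()) == len(rows)
        p = tmp_path / "k.tsv"
        write_krona_tsv(table, p)
        assert read_krona_tsv(p) == table

    def test_shallow_lineage_counts_as_unranked(self):
        rows = [TaxonAssignment("r", "classified", "ref", 1.0, 1.0,
                                Lineage(("Bacteria",)))]
        assert abundance_table(rows, "genus").counts == {"unranked": 1}


def _random_assignments(rng, read_ids, genus_pool=4):
    """Random classified assignments over one consistent taxonomy: genus
    g determines every coarser rank, species is chosen within genus."""
    out = []
    for rid in read_ids:
        g = int(rng.integers(0, genus_pool))
        s = int(rng.integers(0, 3))
        lin = Lineage((f"SK{g % 2}", f"P{g % 2}", f"C{g % 2}", f"O{g}",
                       f"F{g}", f"G{g}", f"S{g}_{s}"))
        out.append(TaxonAssignment(rid, "classified", f"ref{g}", 0.95,
                                   0.9, lin))
    return out


class TestCompare:
    def test_self_comparison(self, rng):
        rows = _random_assignments(rng, [f"r{i}" for i in range(30)])
        frame = compare_classifiers(rows, rows)
        assert (frame.agreement == 1.0).all()
        assert (frame.l1_distance == 0.0).all()

    def test_genus_agreement_species_disagreement(self):
        a = [TaxonAssignment(f"r{i}", "classified", "x", 0.9, 0.9,
                             _lineage(species="S1")) for i in range(10)]
        b = [TaxonAssignment(f"r{i}", "classified", "y", 0.9, 0.9,
                             _lineage(species="S2")) for i in range(10)]
        frame = compare_classifiers(a, b).set_index("rank")
        assert frame.loc["genus", "agreement"] == 1.0
        assert frame.loc["species", "agreement"] == 0.0

    def test_rank_monotonic_agreement(self, rng):
        # prefix-closed lineages force agreement to fall as ranks sharpen
        ids = [f"r{i}" for i in range(40)]
        for _ in range(50):
            a = _random_assignments(rng, ids)
            b = _random_assignments(rng, ids)
            frame = compare_classifiers(a, b)
            agreement = frame.set_index("rank").agreement
            ordered = [agreement[r] for r in RANKS]
            assert all(x >= y - 1e-12 for x, y in zip(ordered, ordered[1:]))

    def test_disjoint_read_sets_rejected(self, rng):
        a = _random_assignments(rng, ["a1", "a2"])
        b = _random_assignments(rng, ["b1"])
        with pytest.raises(ValueError, match="no common reads"):
            compare_classifiers(a, b)


class TestAssignmentTable:
    def test_round_trip(self, tmp_path, rng):
        rows = _random_assignments(rng, [f"r{i}" for i in range(5)])
        rows.append(TaxonAssignment("u", "unclassified", None, 0.25, 0.125,
                                    Lineage(())))
        p = tmp_path / "a.tsv"
        write_assignments(rows, p)
        back = read_assignments(p)
        assert [(r.read_id, r.status, r.best_ref, r.lineage)
                for r in back] == \
            [(r.read_id, r.status, r.best_ref, r.lineage) for r in rows]
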