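"""Long-read 16S classification and classifier comparison.

Reads are first filtered to the full-length 16S window (1250-1750 bp,
inclusive), then each read is assigned to its best reference by local
alignment score; the assignment counts as classified only when the
alignment covers more than 60% of the reference and exceeds 80% pairwise
similarity (both strict inequalities — boundary reads stay unclassified).
Pairwise similarity is matches / alignment columns, gap columns included.

Two classifiers over the same reads are compared per taxonomic rank: the
fraction of reads classified by both that agree on the taxon name, plus the
L1 distance between the two rank-level relative abundance vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .align import (ScoringScheme, identity_and_coverage, local_align,
                    local_align_score, reverse_complement)
from .io import Lineage, RANKS, SeqRecord


@dataclass(frozen=True)
class ClassifyParams:
    len_lo: int = 1250
    len_hi: int = 1750
    min_ref_cov: float = 0.60
    min_identity: float = 0.80

    def __post_init__(self) -> None:
        if self.len_lo > self.len_hi:
            raise ValueError("len_lo > len_hi")
        for f in (self.min_ref_cov, self.min_identity):
            if not (0.0 < f <= 1.0):
                raise ValueError("thresholds must be in (0, 1]")


@dataclass(frozen=True)
class TaxonAssignment:
    read_id: str
    status: str  # 'classified' | 'unclassified' | 'length_filtered'
    best_ref: str | None
    identity: float
    ref_coverage: float
    lineage: Lineage


def length_filter(reads: Sequence[SeqRecord],
                  params: ClassifyParams | None = None
                  ) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Exact partition into (kept, removed) by inclusive length bounds."""
    params = params or ClassifyParams()
    kept, removed = [], []
    for r in reads:
        (kept if params.len_lo <= len(r) <= params.len_hi
         else removed).append(r)
    return kept, removed


def assign_read(read: SeqRecord, refdb: Sequence[SeqRecord],
                taxonomy: Mapping[str, Lineage],
                params: ClassifyParams | None = None,
                scoring: ScoringScheme | None = None,
                both_strands: bool = True) -> TaxonAssignment:
    """Assign one read to its best reference.

    Best is by local alignment score (over both read strands unless
    ``both_strands`` is false); score ties go to the lexicographically
    smallest reference id. The read is classified iff reference coverage
    > min_ref_cov and identity > min_identity, both strict.
    """
    if not refdb:
        raise ValueError("empty reference database")
    params = params or ClassifyParams()
    scoring = scoring or ScoringScheme()
    queries = [read.sequence]
    if both_strands:
        queries.append(reverse_complement(read.sequence))
    # score-only pass picks the winner (cheap); one full alignment follows
    best: tuple[int, str, int] | None = None
    best_ref: SeqRecord | None = None
    for ref in refdb:
        for qi, q in enumerate(queries):
            score = local_align_score(q, ref.sequence, scoring)
            key = (-score, ref.id, qi)
            if best is None or key < best:
                best = key
                best_ref = ref
    best_aln = local_align(queries[best[2]], best_ref.sequence, scoring)
    identity, coverage = identity_and_coverage(best_aln,
                                               len(best_ref.sequence))
    if coverage > params.min_ref_cov and identity > params.min_identity:
        if best_ref.id not in taxonomy:
            raise ValueError(f"no lineage for reference {best_ref.id!r}")
        return TaxonAssignment(read.id, "classified", best_ref.id,
                               identity, coverage, taxonomy[best_ref.id])
    return TaxonAssignment(read.id, "unclassified", best_ref.id,
                           identity, coverage, Lineage(()))


def classify_reads(reads: Sequence[SeqRecord], refdb: Sequence[SeqRecord],
                   taxonomy: Mapping[str, Lineage],
                   params: ClassifyParams | None = None,
                   scoring: ScoringScheme | None = None
                   ) -> list[TaxonAssignment]:
    """Length-filter then assign every read; filtered reads keep a
    'length_filtered' record so totals are conserved."""
    params = params or ClassifyParams()
    kept, removed = length_filter(reads, params)
    out = [TaxonAssignment(r.id, "length_filtered", None, 0.0, 0.0,
                           Lineage(())) for r in removed]
    out.extend(assign_read(r, refdb, taxonomy, params, scoring)
               for r in kept)
    out.sort(key=lambda a: a.read_id)
    return out


@dataclass(frozen=True)
class AbundanceTable:
    rank: str
    counts: dict[str, int]          # classified reads, per taxon at rank
    total_reads: int                # classified + unclassified + filtered
    n_unclassified: int
    n_length_filtered: int


def abundance_table(assignments: Sequence[TaxonAssignment],
                    rank: str) -> AbundanceTable:
    """Read counts per taxon at ``rank``; classified reads whose lineage
    does not reach the rank are counted as "unranked"."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    counts: dict[str, int] = {}
    n_unc = n_filt = 0
    for a in assignments:
        if a.status == "classified":
            taxon = a.lineage.at_rank(rank) or "unranked"
            counts[taxon] = counts.get(taxon, 0) + 1
        elif a.status == "unclassified":
            n_unc += 1
        else:
            n_filt += 1
    return AbundanceTable(rank=rank, counts=counts,
                          total_reads=len(assignments),
                          n_unclassified=n_unc, n_length_filtered=n_filt)


def krona_abundance(assignments: Sequence[TaxonAssignment]
                    ) -> dict[Lineage, int]:
    """Full-lineage abundance map for Krona text export; unclassified and
    filtered reads appear under their own single-rank labels so the total
    read count is conserved."""
    table: dict[Lineage, int] = {}
    for a in assignments:
        key = a.lineage if a.status == "classified" \
            else Lineage((a.status,))
        table[key] = table.get(key, 0) + 1
    return table


def compare_classifiers(assign_a: Sequence[TaxonAssignment],
                        assign_b: Sequence[TaxonAssignment],
                        ranks: Sequence[str] = RANKS) -> pd.DataFrame:
    """Per-rank agreement between two classifiers over common reads.

    For each rank, over reads classified by BOTH with a name at that rank:
    agreement = fraction assigned the identical taxon name. The L1 distance
    is between the two rank-level relative abundance vectors over the union
    of taxa. Raises ValueError when the read id sets are disjoint.
    """
    a_by_id = {a.read_id: a for a in assign_a}
    b_by_id = {b.read_id: b for b in assign_b}
    common = sorted(set(a_by_id) & set(b_by_id))
    if not common:
        raise ValueError("no common reads between the two assignment sets")
    rows = []
    for rank in ranks:
        n_both = n_agree = 0
        for rid in common:
            a, b = a_by_id[rid], b_by_id[rid]
            if a.status != "classified" or b.status != "classified":
                continue
            ta, tb = a.lineage.at_rank(rank), b.lineage.at_rank(rank)
            if ta is None or tb is None:
                continue
            n_both += 1
            n_agree += int(ta == tb)

        def _rel(assignments: Mapping[str, TaxonAssignment]) -> dict[str, float]:
            counts: dict[str, int] = {}
            for a in assignments.values():
                if a.status == "classified":
                    t = a.lineage.at_rank(rank)
                    if t is not None:
                        counts[t] = counts.get(t, 0) + 1
            total = sum(counts.values())
            return {t: c / total for t, c in counts.items()} if total else {}

        rel_a, rel_b = _rel(a_by_id), _rel(b_by_id)
        taxa = set(rel_a) | set(rel_b)
        l1 = sum(abs(rel_a.get(t, 0.0) - rel_b.get(t, 0.0)) for t in taxa)
        rows.append({"rank": rank, "n_both_classified": n_both,
                     "n_agree": n_agree,
                     "agreement": (n_agree / n_both) if n_both else float("nan"),
                     "l1_distance": l1})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Assignment table round-trip (CLI surface)
# --------------------------------------------------------------------------

ASSIGNMENT_COLUMNS = ["read_id", "status", "best_ref", "identity",
                      "ref_coverage", "lineage"]


def write_assignments(assignments: Sequence[TaxonAssignment],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for a in assignments:
            fh.write("\t".join([
                a.read_id, a.status, a.best_ref or "",
                f"{a.identity:.6f}", f"{a.ref_coverage:.6f}",
                a.lineage.to_string()]) + "\n")


def read_assignments(path: str | Path) -> list[TaxonAssignment]:
    out: list[TaxonAssignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ASSIGNMENT_COLUMNS:
            raise ValueError(f"{path}: unexpected assignment table header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(TaxonAssignment(
                read_id=f[0], status=f[1], best_ref=f[2] or None,
                identity=float(f[3]), ref_coverage=float(f[4]),
                lineage=Lineage.from_string(f[5])))
    return out
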