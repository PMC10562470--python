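"""Locate the 16S locus in each genome, extract and reorient it, and
assemble the panel that downstream primer design aligns.

The 16S gene sits on either strand of a genome; both strands are searched
and every extracted entry is reported in the reference orientation, so the
panel is directly alignable. Coordinates are always reported on the genome
forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import (ScoringScheme, identity_and_coverage, local_align,
                    reverse_complement)
from .io import SeqRecord, TabularHit


@dataclass(frozen=True)
class LocusHit:
    """Best 16S-like locus of one genome; 0-based half-open, forward strand."""

    genome_id: str
    start: int
    end: int
    strand: str
    identity: float
    score: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid locus span")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity out of [0, 1]")


@dataclass(frozen=True)
class PanelEntry:
    """A genome's extracted 16S in reference orientation."""

    genome_id: str
    oriented_seq: str
    source: LocusHit


@dataclass(frozen=True)
class SkippedGenome:
    genome_id: str
    reason: str


def _best_locus(genome: SeqRecord, ref16s: SeqRecord,
                scoring: ScoringScheme
                ) -> tuple[LocusHit, float] | None:
    """Best local hit over both strands, with its reference coverage, or
    None when nothing aligns with positive score."""
    fwd = local_align(genome.sequence, ref16s.sequence, scoring)
    rev = local_align(reverse_complement(genome.sequence), ref16s.sequence,
                      scoring)
    glen = len(genome.sequence)
    if rev.score > fwd.score:
        aln, strand = rev, "-"
        start, end = glen - aln.a_end, glen - aln.a_start
    else:
        aln, strand = fwd, "+"
        start, end = aln.a_start, aln.a_end
    if aln.score <= 0:
        return None
    identity, coverage = identity_and_coverage(aln, len(ref16s.sequence))
    return LocusHit(genome.id, start, end, strand, identity,
                    aln.score), coverage


def find_16s_locus(genome: SeqRecord, ref16s: SeqRecord,
                   scoring: ScoringScheme | None = None,
                   min_identity: float = 0.70,
                   min_cov: float = 0.50) -> LocusHit | None:
    """Best local alignment of the reference 16S over both genome strands.

    Returns None when the best hit falls below ``min_identity`` or covers
    less than ``min_cov`` of the reference. On a tie between strands the
    forward strand wins.
    """
    found = _best_locus(genome, ref16s, scoring or ScoringScheme())
    if found is None:
        return None
    hit, coverage = found
    if hit.identity < min_identity or coverage < min_cov:
        return None
    return hit


def extract_oriented(genome: SeqRecord, hit: LocusHit,
                     flank: int = 0) -> PanelEntry:
    """Slice ``[start - flank, end + flank)`` (clamped to the genome) and
    reverse complement when the hit is on the minus strand, so every panel
    entry shares the reference orientation."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    glen = len(genome.sequence)
    if hit.start >= glen or hit.end > glen:
        raise ValueError(
            f"hit {hit.start}:{hit.end} outside genome {genome.id!r} "
            f"(length {glen})")
    lo = max(0, hit.start - flank)
    hi = min(glen, hit.end + flank)
    seq = genome.sequence[lo:hi]
    if hit.strand == "-":
        seq = reverse_complement(seq)
    return PanelEntry(genome.id, seq, hit)


def loci_from_tabular_hits(hits: Iterable[TabularHit]) -> dict[str, LocusHit]:
    """Convert precomputed tabular hits (reference 16S as query, genomes as
    subjects) into one best locus per genome, by bit score.

    Subject coordinates address the genome, so extraction uses the subject
    span; a minus-strand hit (s_start > s_end) maps to strand '-'.
    """
    best: dict[str, TabularHit] = {}
    for h in hits:
        cur = best.get(h.subject_id)
        if cur is None or h.bitscore > cur.bitscore:
            best[h.subject_id] = h
    loci = {}
    for gid, h in best.items():
        start, end = h.subject_span()
        loci[gid] = LocusHit(gid, start, end, h.strand,
                             h.pct_identity / 100.0, int(round(h.bitscore)))
    return loci


def build_panel(genomes: Sequence[SeqRecord], ref16s: SeqRecord,
                scoring: ScoringScheme | None = None,
                min_identity: float = 0.70, min_cov: float = 0.50,
                flank: int = 0,
                precomputed: dict[str, LocusHit] | None = None
                ) -> tuple[list[PanelEntry], list[SkippedGenome]]:
    """One oriented panel entry per genome with a qualifying 16S hit.

    Genomes without a qualifying hit are listed in the skipped report with
    the failing criterion; output order follows input order. Raises
    ValueError("empty panel") when no genome qualifies.
    """
    if not genomes:
        raise ValueError("no genomes given")
    scoring = scoring or ScoringScheme()
    entries: list[PanelEntry] = []
    skipped: list[SkippedGenome] = []
    for genome in genomes:
        if precomputed is not None:
            hit = precomputed.get(genome.id)
            if hit is None:
                skipped.append(SkippedGenome(genome.id, "no precomputed hit"))
                continue
            if hit.identity < min_identity:
                skipped.append(
                    SkippedGenome(genome.id, "identity below threshold"))
                continue
        else:
            found = _best_locus(genome, ref16s, scoring)
            if found is None:
                skipped.append(SkippedGenome(genome.id, "no alignment"))
                continue
            hit, coverage = found
            if hit.identity < min_identity:
                skipped.append(
                    SkippedGenome(genome.id, "identity below threshold"))
                continue
            if coverage < min_cov:
                skipped.append(SkippedGenome(
                    genome.id, "reference coverage below threshold"))
                continue
        entries.append(extract_oriented(genome, hit, flank))
    if not entries:
        raise ValueError("empty panel")
    return entries, skipped


def panel_records(entries: Iterable[PanelEntry]) -> list[SeqRecord]:
    """Panel entries as sequence records, ready to write as FASTA."""
    return [SeqRecord(id=e.genome_id, sequence=e.oriented_seq,
                      description=f"16S {e.source.start}-{e.source.end}"
                                  f"({e.source.strand})")
            for e in entries]
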