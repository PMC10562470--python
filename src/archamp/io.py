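"""Readers and writers for the external formats the pipeline touches.

Strict dialects, documented here once:

* FASTA — multi-record, ``>`` header lines, sequences uppercased on read and
  wrapped at a fixed width on write; round-trips exactly.
* FASTQ — read-only; quality lines are ignored (downstream filtering is by
  length only).
* Tabular hits — BLAST-style "tabular with comment lines": ``#`` comments,
  12 tab-separated columns (query id, subject id, % identity, alignment
  length, mismatches, gap opens, q.start, q.end, s.start, s.end, e-value,
  bit score). On the subject, ``s_start > s_end`` encodes a minus-strand hit.
* Taxonomy TSV — two columns, sequence id and a semicolon-joined lineage over
  the fixed rank list; lineages must be prefix-closed.
* Krona text import TSV — one line per lineage: count, then rank names
  root-to-leaf, tab-separated.

Internal coordinates everywhere in this package are 0-based half-open; the
tabular dialect converts from 1-based inclusive at this boundary only.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

# --------------------------------------------------------------------------
# IUPAC nucleotide alphabet
# --------------------------------------------------------------------------

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def validate_sequence(seq: str, record_id: str = "<anonymous>") -> None:
    """Raise ValueError naming the record and 0-based offset of the first
    character outside the IUPAC nucleotide alphabet."""
    for off, ch in enumerate(seq):
        if ch not in IUPAC_ALPHABET:
            raise ValueError(
                f"record {record_id!r}: invalid character {ch!r} at offset {off}"
            )


# --------------------------------------------------------------------------
# SeqRecord
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SeqRecord:
    """An identified nucleotide sequence; backbone of all I/O.

    ``id`` is a whitespace-free token, ``sequence`` an uppercase IUPAC
    string. ``description`` is the free text after the id on the header line.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id {self.id!r}")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        validate_sequence(self.sequence, self.id)

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a multi-record FASTA file.

    Sequences are uppercased and whitespace-stripped; record order is
    preserved. Raises ValueError on an empty file ("no records") or on a
    character outside the IUPAC alphabet.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read FASTQ, discarding quality lines (length-only filtering downstream)."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, sequence=str(rec.seq).upper(),
                                 description=desc))
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def read_sequences(path: str | Path) -> list[SeqRecord]:
    """Read FASTA or FASTQ, sniffing the format from the first character."""
    with open(path) as fh:
        first = fh.read(1)
    return read_fastq(path) if first == "@" else read_fasta(path)


def write_fasta(records: Iterable[SeqRecord], path: str | Path,
                width: int = 70) -> None:
    """Write records as wrapped FASTA; inverse of :func:`read_fasta`.

    Raises ValueError listing duplicate ids, if any.
    """
    records = list(records)
    seen: dict[str, int] = {}
    for r in records:
        seen[r.id] = seen.get(r.id, 0) + 1
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"duplicate record ids: {', '.join(dups)}")
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id} {r.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i:i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records as FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.id} {r.description}".rstrip() + "\n")
            fh.write(r.sequence + "\n+\n" + "I" * len(r.sequence) + "\n")


# --------------------------------------------------------------------------
# BLAST-style tabular hits
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TabularHit:
    """One line of 12-column tabular output.

    Raw 1-based inclusive coordinates are kept as parsed; use
    :meth:`subject_span` / :attr:`strand` for normalized 0-based half-open
    forward-strand coordinates.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"hit {self.query_id}/{self.subject_id}: q_start > q_end")
        if self.aln_len < 1:
            raise ValueError("alignment length < 1")

    @property
    def strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    def subject_span(self) -> tuple[int, int]:
        """Normalized (start, end), 0-based half-open on the subject forward
        strand, regardless of hit orientation."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi

    def query_span(self) -> tuple[int, int]:
        return self.q_start - 1, self.q_end


def read_tabular_hits(path: str | Path) -> list[TabularHit]:
    """Parse tabular-with-comment-lines alignment output.

    Lines starting ``#`` are comments; data lines must have exactly 12
    tab-separated fields. Hit order and count are preserved.
    """
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated fields, "
                    f"got {len(fields)}")
            try:
                hits.append(TabularHit(
                    query_id=fields[0], subject_id=fields[1],
                    pct_identity=float(fields[2]), aln_len=int(fields[3]),
                    mismatches=int(fields[4]), gap_opens=int(fields[5]),
                    q_start=int(fields[6]), q_end=int(fields[7]),
                    s_start=int(fields[8]), s_end=int(fields[9]),
                    evalue=float(fields[10]), bitscore=float(fields[11])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


# --------------------------------------------------------------------------
# Lineages and taxonomy tables
# --------------------------------------------------------------------------

RANKS: tuple[str, ...] = (
    "superkingdom", "phylum", "class", "order", "family", "genus", "species",
)


@dataclass(frozen=True)
class Lineage:
    """A rank-ordered lineage over the fixed seven-rank list.

    Names may be absent from any *suffix* of the list (prefix-closed): a
    lineage classified to genus has names for every rank down to genus and
    none below.
    """

    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.names) > len(RANKS):
            raise ValueError(f"lineage deeper than {len(RANKS)} ranks")
        if any(not n for n in self.names):
            raise ValueError(
                "empty rank name inside lineage violates prefix closure")

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        text = text.strip()
        if not text:
            return cls(())
        parts = [p.strip() for p in text.split(";")]
        # trailing empties are a shallow lineage; internal empties are a gap
        while parts and not parts[-1]:
            parts.pop()
        return cls(tuple(parts))

    def to_string(self) -> str:
        return ";".join(self.names)

    @property
    def depth(self) -> int:
        return len(self.names)

    def at_rank(self, rank: str) -> str | None:
        """Name at ``rank``, or None if the lineage does not reach it."""
        i = RANKS.index(rank)
        return self.names[i] if i < len(self.names) else None

    def truncated(self, rank: str) -> "Lineage":
        i = RANKS.index(rank)
        return Lineage(self.names[: i + 1])

    def __bool__(self) -> bool:
        return bool(self.names)


def read_taxonomy_table(path: str | Path) -> dict[str, Lineage]:
    """Read a two-column taxonomy TSV: id, semicolon-joined lineage.

    Prefix closure is enforced; a repeated id with a conflicting lineage is
    an error. An empty lineage field means fully unclassified.
    """
    table: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = parts + [""]
            seq_id, lineage_text = parts[0].strip(), parts[1]
            try:
                lineage = Lineage.from_string(lineage_text)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if seq_id in table and table[seq_id] != lineage:
                raise ValueError(
                    f"{path}:{lineno}: id {seq_id!r} repeated with "
                    f"conflicting lineage")
            table[seq_id] = lineage
    return table


def write_taxonomy_table(table: Mapping[str, Lineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id in table:
            fh.write(f"{seq_id}\t{table[seq_id].to_string()}\n")


# --------------------------------------------------------------------------
# Krona text import
# --------------------------------------------------------------------------

def write_krona_tsv(abundance: Mapping[Lineage, int], path: str | Path) -> None:
    """Write a Krona text-import table: count, then rank names root-to-leaf.

    Total read count is conserved (one line per lineage, counts unmodified).
    Raises ValueError on a negative count.
    """
    buf = _stdio.StringIO()
    for lineage, count in abundance.items():
        if count < 0:
            raise ValueError(
                f"negative count {count} for lineage {lineage.to_string()!r}")
        buf.write("\t".join([str(count), *lineage.names]) + "\n")
    Path(path).write_text(buf.getvalue())


def read_krona_tsv(path: str | Path) -> dict[Lineage, int]:
    """Inverse of :func:`write_krona_tsv`."""
    table: dict[Lineage, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            lineage = Lineage(tuple(parts[1:]))
            table[lineage] = table.get(lineage, 0) + int(parts[0])
    return table
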