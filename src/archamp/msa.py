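"""Desk-scale multiple alignment and per-column conservation profiling.

The aligner is a deterministic center-star: the center is the input sequence
maximizing its summed pairwise global alignment score against all others,
and the remaining sequences are merged against it under "once a gap, always
a gap". At panel scale (tens of sequences x ~1.6 kb) this is fast and, on
the near-identical 16S panels it is meant for, indistinguishable from a
progressive aligner. An aligned-FASTA/Clustal reader is provided so an
externally produced alignment can be substituted.

Conservation of a column is the majority-base fraction among non-gap rows;
gap pressure is controlled separately through a per-column gap-fraction
threshold, because primers must avoid indel-rich columns explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import ScoringScheme, global_align
from .io import SeqRecord

#: Default scoring for panel alignment. Marker-gene panels are indel-sparse
#: (near-equal-length sequences diverging by substitutions), so the gap
#: penalties are much stiffer than read-alignment defaults: this stops the
#: aligner from fabricating shift-by-one gap pairs inside hypervariable
#: blocks, where a cheap double gap can otherwise buy a few chance matches.
MSA_SCORING = ScoringScheme(match=2, mismatch=-3, gap_open=16, gap_extend=6)


@dataclass(frozen=True)
class MSA:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows have unequal lengths")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def slice_columns(self, start: int, end: int) -> "MSA":
        return MSA(self.ids, tuple(r[start:end] for r in self.rows))


@dataclass(frozen=True)
class ColumnProfile:
    col: int
    base_counts: dict[str, int]
    gap_count: int
    conservation: float
    gap_fraction: float


@dataclass(frozen=True)
class ConservedWindow:
    """A 0-based half-open column span suitable for primer placement."""

    start: int
    end: int
    mean_conservation: float
    max_gap_fraction: float


def _merge_into_star(master_center: list[str], rows: list[list[str]],
                     center_gapped: str, other_gapped: str) -> list[str]:
    """Merge one pairwise alignment (center vs new sequence) into the
    running star alignment; existing gap columns are never removed."""
    new_row: list[str] = []
    out_center: list[str] = []
    out_rows: list[list[str]] = [[] for _ in rows]
    p = 0  # over pairwise columns
    q = 0  # over master columns
    np_, nq = len(center_gapped), len(master_center)
    while p < np_ or q < nq:
        pc = center_gapped[p] if p < np_ else None
        qc = master_center[q] if q < nq else None
        if qc == "-":
            # master gap column the pairwise alignment doesn't know of
            out_center.append("-")
            for r, o in zip(rows, out_rows):
                o.append(r[q])
            new_row.append("-")
            q += 1
            continue
        if pc == "-":
            # pairwise inserted a gap into the center: new column everywhere
            out_center.append("-")
            for o in out_rows:
                o.append("-")
            new_row.append(other_gapped[p])
            p += 1
            continue
        # both consume one center residue
        out_center.append(qc)  # == pc
        for r, o in zip(rows, out_rows):
            o.append(r[q])
        new_row.append(other_gapped[p])
        p += 1
        q += 1
    rows[:] = out_rows
    rows.append(new_row)
    return out_center


def center_star_msa(seqs: Sequence[SeqRecord],
                    scoring: ScoringScheme | None = None) -> MSA:
    """Deterministic center-star multiple alignment of >= 2 sequences.

    Ties for the center go to the earliest input sequence; merge order is
    input order. Row order follows input order regardless of which sequence
    is the center.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    scoring = scoring or MSA_SCORING
    n = len(seqs)
    pair_score = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            score, _, _ = global_align(seqs[i].sequence, seqs[j].sequence,
                                       scoring)
            pair_score[i, j] = pair_score[j, i] = score
    center = int(np.argmax(pair_score.sum(axis=1)))
    master_center = list(seqs[center].sequence)
    rows: list[list[str]] = []
    order = [i for i in range(n) if i != center]
    for i in order:
        _, g_center, g_other = global_align(seqs[center].sequence,
                                            seqs[i].sequence, scoring)
        master_center = _merge_into_star(master_center, rows,
                                         g_center, g_other)
    all_rows: list[str] = [""] * n
    all_rows[center] = "".join(master_center)
    for k, i in enumerate(order):
        all_rows[i] = "".join(rows[k])
    return MSA(tuple(s.id for s in seqs), tuple(all_rows))


def column_profiles(msa: MSA) -> list[ColumnProfile]:
    """Per-column base counts, gap counts, conservation and gap fraction.

    Rows must contain only A/C/G/T and '-'; counts sum to the row number in
    every column. Conservation of an all-gap column is defined as 0.
    """
    profiles: list[ColumnProfile] = []
    n_rows = msa.n_rows
    for col in range(msa.n_cols):
        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
        gaps = 0
        for row in msa.rows:
            ch = row[col]
            if ch == "-":
                gaps += 1
            elif ch in counts:
                counts[ch] += 1
            else:
                raise ValueError(
                    f"column {col}: unsupported symbol {ch!r} in profile "
                    f"(only A/C/G/T/- are profiled)")
        non_gap = n_rows - gaps
        conservation = max(counts.values()) / non_gap if non_gap else 0.0
        profiles.append(ColumnProfile(
            col=col, base_counts=counts, gap_count=gaps,
            conservation=conservation, gap_fraction=gaps / n_rows))
    return profiles


def find_conserved_windows(profiles: Sequence[ColumnProfile],
                           win_len: int = 18,
                           min_mean_cons: float = 0.90,
                           max_gap_frac: float = 0.10
                           ) -> list[ConservedWindow]:
    """All maximal conserved windows, merged over overlaps, sorted by start.

    A window [i, j) *qualifies* when j - i >= win_len, every column's gap
    fraction is <= max_gap_frac, and its mean conservation is
    >= min_mean_cons. A qualifying window is *maximal* when no strictly
    larger qualifying window contains it; overlapping maximal windows are
    merged into their union span (whose own mean conservation is reported
    and can, on adversarial profiles, fall below the threshold).
    """
    if win_len < 1:
        raise ValueError("win_len must be >= 1")
    n = len(profiles)
    cons = np.array([p.conservation for p in profiles])
    gapf = np.array([p.gap_fraction for p in profiles])
    allowed = gapf <= max_gap_frac
    ccons = np.concatenate([[0.0], np.cumsum(cons)])
    # g[j] - g[i] >= 0  <=>  mean conservation of [i, j) >= threshold
    g = ccons - min_mean_cons * np.arange(n + 1)

    # best_end[i] = largest j such that [i, j) qualifies, restricted to the
    # contiguous run of allowed columns containing i
    run_end = np.full(n, -1, dtype=int)   # exclusive end of allowed run
    j = 0
    while j < n:
        if allowed[j]:
            k = j
            while k < n and allowed[k]:
                k += 1
            run_end[j:k] = k
            j = k
        else:
            j += 1

    best_end = np.full(n, -1, dtype=int)
    eps = 1e-12
    for i in range(n):
        if not allowed[i]:
            continue
        hi = run_end[i]
        lo = i + win_len
        if lo > hi:
            continue
        js = np.arange(lo, hi + 1)
        ok = g[js] >= g[i] - eps
        if ok.any():
            best_end[i] = int(js[np.nonzero(ok)[0][-1]])

    # maximal windows: (i, best_end[i]) with best_end strictly above the
    # running maximum over smaller i (otherwise an earlier window with an
    # end at least as large contains it)
    maximal: list[tuple[int, int]] = []
    running = -1
    for i in range(n):
        if best_end[i] > running:
            maximal.append((i, best_end[i]))
            running = best_end[i]

    # merge overlapping maximal windows into union spans
    merged: list[list[int]] = []
    for s, e in maximal:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    out = []
    for s, e in merged:
        out.append(ConservedWindow(
            start=s, end=e,
            mean_conservation=float(cons[s:e].mean()),
            max_gap_fraction=float(gapf[s:e].max())))
    return out


# --------------------------------------------------------------------------
# Aligned-format readers/writers (so an external MSA can be substituted)
# --------------------------------------------------------------------------

def write_aligned_fasta(msa: MSA, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


def read_aligned_fasta(path: str | Path) -> MSA:
    ids: list[str] = []
    rows: list[str] = []
    with open(path) as fh:
        cur: list[str] = []
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if ids:
                    rows.append("".join(cur))
                ids.append(line[1:].split()[0])
                cur = []
            elif line:
                cur.append(line.upper())
        if ids:
            rows.append("".join(cur))
    if not ids:
        raise ValueError(f"{path}: no records")
    return MSA(tuple(ids), tuple(rows))


def read_clustal(path: str | Path) -> MSA:
    """Read a Clustal-format alignment (header line, interleaved blocks)."""
    ids: list[str] = []
    chunks: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.upper().startswith("CLUSTAL"):
            raise ValueError(f"{path}: not a Clustal file")
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith((" ", "\t")):
                continue  # blank or conservation line
            parts = line.split()
            if len(parts) < 2:
                continue
            name, seg = parts[0], parts[1]
            if name not in chunks:
                ids.append(name)
                chunks[name] = []
            chunks[name].append(seg.upper())
    if not ids:
        raise ValueError(f"{path}: no records")
    return MSA(tuple(ids), tuple("".join(chunks[i]) for i in ids))
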