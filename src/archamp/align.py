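"""Affine-gap pairwise alignment core.

Smith-Waterman-Gotoh local alignment (and a global variant used by the
multiple aligner), with IUPAC-aware matching: two symbols score as a match
iff their nucleotide sets intersect, which is what degenerate primers need.

A gap of length L costs ``gap_open + gap_extend * L``. The default scoring
(+2 match, -3 mismatch, open 5, extend 2) mirrors common megablast-style
nucleotide defaults.

Determinism: among equal-scoring end cells the one with the smallest end on
sequence ``a``, then on ``b``, is chosen; during traceback diagonal moves are
preferred over vertical (gap in ``b``) over horizontal (gap in ``a``), and a
gap is closed rather than extended on ties.

The dynamic programs are numba-compiled; sequences are encoded as 4-bit base
masks so degenerate symbols cost nothing extra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .io import COMPLEMENT, IUPAC_SETS, validate_sequence

_NEG = np.int32(-(10 ** 8))

# 4-bit masks: A=1, C=2, G=4, T=8; ambiguity codes are unions
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_MASK = {code: sum(_BASE_BIT[b] for b in bases)
              for code, bases in IUPAC_SETS.items()}

_ENCODE_LUT = np.zeros(128, dtype=np.uint8)
for _code, _mask in _CODE_MASK.items():
    _ENCODE_LUT[ord(_code)] = _mask


def encode(seq: str) -> np.ndarray:
    """Encode an IUPAC string as a uint8 array of 4-bit base masks."""
    validate_sequence(seq)
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def compatible(x: str, y: str) -> bool:
    """True iff the IUPAC sets of two symbols intersect."""
    return bool(_CODE_MASK[x] & _CODE_MASK[y])


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (an involution)."""
    try:
        return "".join(COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch penalty must be negative")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass(frozen=True)
class LocalAlignment:
    """A scored local alignment; spans are 0-based half-open."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    score: int
    matches: int
    columns: int
    gapped_a: str
    gapped_b: str

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b) or \
                len(self.gapped_a) != self.columns:
            raise ValueError("gapped strings inconsistent with column count")
        if self.matches > self.columns:
            raise ValueError("matches exceed columns")


@njit(cache=True)
def _gotoh_local_fill(a, b, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)
    F = np.full((n + 1, m + 1), _NEG, np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai & b[j - 1]) != 0 else mismatch
            e = max(E[i, j - 1] - gap_ext, H[i, j - 1] - gap_open - gap_ext)
            f = max(F[i - 1, j] - gap_ext, H[i - 1, j] - gap_open - gap_ext)
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _gotoh_local_score(a, b, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    """Score-only variant with O(m) memory."""
    n, m = a.size, b.size
    Hp = np.zeros(m + 1, np.int32)
    Ep = np.full(m + 1, _NEG, np.int32)
    Fp = np.full(m + 1, _NEG, np.int32)
    best = np.int32(0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        diag = Hp[0]
        Hp[0] = 0
        for j in range(1, m + 1):
            s = match if (ai & b[j - 1]) != 0 else mismatch
            e = max(Ep[j - 1] - gap_ext, Hp[j - 1] - gap_open - gap_ext)
            f = max(Fp[j] - gap_ext, Hp[j] - gap_open - gap_ext)
            h = diag + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = Hp[j]
            Ep[j] = e
            Fp[j] = f
            Hp[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def _gotoh_global_fill(a, b, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    n, m = a.size, b.size
    H = np.full((n + 1, m + 1), _NEG, np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)
    F = np.full((n + 1, m + 1), _NEG, np.int32)
    H[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = -gap_open - gap_ext * j
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = -gap_open - gap_ext * i
        H[i, 0] = F[i, 0]
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai & b[j - 1]) != 0 else mismatch
            e = max(E[i, j - 1] - gap_ext, H[i, j - 1] - gap_open - gap_ext)
            f = max(F[i - 1, j] - gap_ext, H[i - 1, j] - gap_open - gap_ext)
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    return H, E, F


def _traceback(a: str, b: str, am, bm, H, E, F, scheme: ScoringScheme,
               i: int, j: int, local: bool) -> tuple[int, int, str, str, int]:
    """Walk back from (i, j); returns (a_start, b_start, gapped_a, gapped_b,
    matches). Diagonal > vertical > horizontal on ties; close gaps eagerly."""
    go, ge = scheme.gap_open, scheme.gap_extend
    ga: list[str] = []
    gb: list[str] = []
    matches = 0
    state = "H"
    while i > 0 or j > 0:
        if local and state == "H" and H[i, j] == 0:
            break
        if state == "H":
            if not local and i == 0:
                state = "E"
                continue
            if not local and j == 0:
                state = "F"
                continue
            s = scheme.match if (am[i - 1] & bm[j - 1]) else scheme.mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                ga.append(a[i - 1])
                gb.append(b[j - 1])
                if am[i - 1] & bm[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            elif j > 0 and H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - inconsistent matrices
                raise AssertionError("traceback failed")
        elif state == "F":
            ga.append(a[i - 1])
            gb.append("-")
            if F[i, j] == H[i - 1, j] - go - ge:
                state = "H"
            i -= 1
        else:  # E
            ga.append("-")
            gb.append(b[j - 1])
            if E[i, j] == H[i, j - 1] - go - ge:
                state = "H"
            j -= 1
    return i, j, "".join(reversed(ga)), "".join(reversed(gb)), matches


def local_align(a: str, b: str,
                scoring: ScoringScheme | None = None) -> LocalAlignment:
    """Maximum-scoring local alignment of ``a`` against ``b`` under affine
    gaps, with the deterministic tie-breaking documented in the module
    docstring. Score is always >= 0; a zero score yields an empty span."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or ScoringScheme()
    am, bm = encode(a), encode(b)
    H, E, F, best, bi, bj = _gotoh_local_fill(
        am, bm, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend)
    if best <= 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0, "", "")
    a0, b0, ga, gb, matches = _traceback(
        a, b, am, bm, H, E, F, scoring, bi, bj, local=True)
    return LocalAlignment(a0, bi, b0, bj, int(best), matches, len(ga), ga, gb)


def local_align_score(a: str, b: str,
                      scoring: ScoringScheme | None = None) -> int:
    """Score of the best local alignment (low-memory, no traceback)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or ScoringScheme()
    return int(_gotoh_local_score(
        encode(a), encode(b), scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend))


def global_align(a: str, b: str,
                 scoring: ScoringScheme | None = None
                 ) -> tuple[int, str, str]:
    """Global (end-to-end) affine-gap alignment; returns
    (score, gapped_a, gapped_b). Used by the center-star multiple aligner."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or ScoringScheme()
    am, bm = encode(a), encode(b)
    H, E, F = _gotoh_global_fill(
        am, bm, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend)
    _, _, ga, gb, _ = _traceback(
        a, b, am, bm, H, E, F, scoring, len(a), len(b), local=False)
    return int(H[len(a), len(b)]), ga, gb


def identity_and_coverage(aln: LocalAlignment,
                          ref_len: int) -> tuple[float, float]:
    """(identity, reference coverage) of an alignment whose ``b`` side is the
    reference.

    identity = matches / columns (gap columns included in the denominator);
    ref_coverage = aligned reference span / reference length.
    """
    if ref_len <= 0:
        raise ValueError("reference length must be positive")
    if aln.b_end - aln.b_start > ref_len:
        raise ValueError("alignment span exceeds reference length")
    if aln.columns == 0:
        return 0.0, 0.0
    return aln.matches / aln.columns, (aln.b_end - aln.b_start) / ref_len
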