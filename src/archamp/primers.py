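"""Tailed, degenerate, Tm-matched primer pairs from conserved alignment
windows.

Each primer is a gene-specific degenerate core (an IUPAC consensus of a
conserved window) behind a constant 5' tag ("tail") used for downstream
barcoding. Melting temperature is computed on the core only — the tail is
not present in the template during the first cycles — and cores are
Tm-matched to a target (typically the partner primer set's Tm) by shortening
from the 5' end, keeping the 3' anchor on its conserved position.

Tm methods
----------
* ``nearest_neighbor`` (default): unified duplex nearest-neighbor
  parameters, Tm = dH / (dS + R ln(C_T / 4)) - 273.15 + 16.6 log10([Na+]),
  with dH in cal/mol, dS in cal/(mol K), R = 1.987 cal/(mol K), C_T the
  total oligo concentration and the classic Schildkraut-Lifson monovalent
  salt correction. For a degenerate core the statistics (mean/min/max) are
  taken over all expanded non-degenerate variants.
* ``wallace``: the 2(A+T) + 4(G+C) rule, for quick sanity checks on short
  oligos.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

from .align import reverse_complement
from .io import IUPAC_SETS, SET_TO_CODE
from .msa import MSA, ColumnProfile, column_profiles

# --------------------------------------------------------------------------
# Published thermophilic 16S primer set (constant 5' tags + cores)
# --------------------------------------------------------------------------

#: The two constant 5' barcoding tags used by the tailed primers.
TAIL_A = "TTTCTGTTGGTGCTGATATTGC"
TAIL_B = "ACTTGCCTGTCGCTCTATCTTC"

#: Known tailed primers (name -> (tail, core)). The universal bacterial pair
#: carries the canonical 27F/1492R cores; the archaea-targeted set was
#: designed on an archaeal genome panel. Names are opaque labels.
KNOWN_PRIMERS: dict[str, tuple[str, str]] = {
    "Tailed-27For": (TAIL_A, "AGAGTTTGATCMTGGCTCAG"),
    "Tailed-1492Rev": (TAIL_B, "CGGTTACCTTGTTACGACTT"),
    "For27": (TAIL_B, "TACGGCTACCTTGTTACGAC"),
    "Rev621": (TAIL_A, "CTGAAACTTAAAGGAATTGGC"),
    "Rev1413": (TAIL_A, "ACKGCTCAGTAACACGTG"),
}

# --------------------------------------------------------------------------
# Degeneracy
# --------------------------------------------------------------------------


def degeneracy(iupac_seq: str) -> int:
    """Product over positions of the IUPAC symbol set sizes."""
    d = 1
    for ch in iupac_seq:
        try:
            d *= len(IUPAC_SETS[ch])
        except KeyError:
            raise ValueError(f"invalid IUPAC symbol {ch!r}") from None
    return d


def expand(iupac_seq: str, cap: int = 64) -> list[str]:
    """All non-degenerate variants, lexicographically ordered.

    Raises ValueError with the count when degeneracy exceeds ``cap``.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    d = degeneracy(iupac_seq)
    if d > cap:
        raise ValueError(
            f"degeneracy {d} exceeds expansion cap {cap}")
    choices = [sorted(IUPAC_SETS[ch]) for ch in iupac_seq]
    return ["".join(p) for p in itertools.product(*choices)]


# --------------------------------------------------------------------------
# Melting temperature
# --------------------------------------------------------------------------

#: Unified duplex nearest-neighbor parameters: 5'->3' dinucleotide ->
#: (dH kcal/mol, dS cal/(mol K)).
NN_TABLE: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

#: Duplex-initiation terms per terminal base pair.
NN_INIT_GC = (0.1, -2.8)
NN_INIT_AT = (2.3, 4.1)

_R = 1.987  # gas constant, cal/(mol K)


@dataclass(frozen=True)
class TmParams:
    method: str = "nearest_neighbor"
    na_mM: float = 50.0
    primer_uM: float = 0.25

    def __post_init__(self) -> None:
        if self.method not in ("nearest_neighbor", "wallace"):
            raise ValueError(f"unknown Tm method {self.method!r}")
        if self.na_mM <= 0 or self.primer_uM <= 0:
            raise ValueError("salt and oligo concentrations must be positive")


@dataclass(frozen=True)
class TmStats:
    mean_C: float
    min_C: float
    max_C: float
    n_variants: int

    def __post_init__(self) -> None:
        if not (self.min_C <= self.mean_C + 1e-9 and
                self.mean_C <= self.max_C + 1e-9):
            raise ValueError("inconsistent Tm statistics")


def _tm_nn_single(seq: str, params: TmParams) -> float:
    dh = 0.0  # kcal/mol
    ds = 0.0  # cal/(mol K)
    for end in (seq[0], seq[-1]):
        init = NN_INIT_GC if end in "GC" else NN_INIT_AT
        dh += init[0]
        ds += init[1]
    for i in range(len(seq) - 1):
        h, s = NN_TABLE[seq[i:i + 2]]
        dh += h
        ds += s
    c_t = params.primer_uM * 1e-6
    tm_k = (dh * 1000.0) / (ds + _R * math.log(c_t / 4.0))
    return tm_k - 273.15 + 16.6 * math.log10(params.na_mM / 1000.0)


def _tm_wallace(seq: str) -> float:
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


def melt_tm(core: str, params: TmParams | None = None,
            cap: int = 64) -> TmStats:
    """Melting-temperature statistics of a (possibly degenerate) core.

    The core must be at least 6 bases; a degenerate core is expanded (up to
    ``cap`` variants) and mean/min/max are taken over the variants.
    """
    params = params or TmParams()
    if len(core) < 6:
        raise ValueError(f"core {core!r} shorter than 6 bases")
    variants = expand(core, cap)
    if params.method == "wallace":
        tms = [_tm_wallace(v) for v in variants]
    else:
        tms = [_tm_nn_single(v, params) for v in variants]
    return TmStats(mean_C=sum(tms) / len(tms), min_C=min(tms),
                   max_C=max(tms), n_variants=len(variants))


def trim_to_tm(core: str, target_C: float, tol_C: float = 5.0,
               params: TmParams | None = None, min_len: int = 15,
               cap: int = 64) -> str:
    """Shorten a core from its 5' end until its mean Tm best matches
    ``target_C``.

    Only 5' bases are removed — the 3' end stays on its conserved anchor for
    specificity. Among admissible suffixes (length >= ``min_len``) the one
    minimizing |Tm - target| wins; ties go to the longer primer. Raises
    ValueError reporting the best achievable Tm when nothing falls within
    ``tol_C`` of the target.
    """
    params = params or TmParams()
    if len(core) <= 6:
        raise ValueError("core too short to trim")
    min_len = max(min_len, 6)
    best_core = None
    best_diff = math.inf
    for length in range(len(core), min_len - 1, -1):
        suffix = core[len(core) - length:]
        diff = abs(melt_tm(suffix, params, cap).mean_C - target_C)
        if diff < best_diff:  # strict: ties keep the longer primer
            best_diff = diff
            best_core = suffix
    if best_core is None:
        raise ValueError(f"core length {len(core)} below floor {min_len}")
    if best_diff > tol_C:
        best_tm = melt_tm(best_core, params, cap).mean_C
        raise ValueError(
            f"no suffix within {tol_C} degC of target {target_C}; best "
            f"achievable Tm {best_tm:.2f} degC at length {len(best_core)}")
    return best_core


# --------------------------------------------------------------------------
# Consensus and pair assembly
# --------------------------------------------------------------------------


def degenerate_consensus(msa: MSA, window: tuple[int, int],
                         f_min: float = 0.10,
                         max_gap_frac: float = 0.10,
                         profiles: Sequence[ColumnProfile] | None = None
                         ) -> str:
    """IUPAC consensus of an MSA window.

    Per column, the code of the set of bases whose frequency among non-gap
    rows is >= ``f_min`` (minor alleles below the threshold are suppressed;
    if no base reaches it, the majority bases are used). A column whose gap
    fraction exceeds ``max_gap_frac`` is an error naming the column —
    primers must not span indel-rich columns.
    """
    if not (0.0 < f_min <= 0.5):
        raise ValueError("f_min must be in (0, 0.5]")
    start, end = window
    if not (0 <= start < end <= msa.n_cols):
        raise ValueError(f"window {window} outside alignment")
    if profiles is None:
        profiles = column_profiles(msa.slice_columns(start, end))
        offset = start
    else:
        profiles = profiles[start:end]
        offset = 0
    out = []
    for k, p in enumerate(profiles):
        if p.gap_fraction > max_gap_frac:
            raise ValueError(
                f"column {start + k if offset else p.col}: gap fraction "
                f"{p.gap_fraction:.2f} exceeds {max_gap_frac}")
        non_gap = sum(p.base_counts.values())
        if non_gap == 0:
            raise ValueError(f"column {p.col}: all rows are gaps")
        kept = {b for b, c in p.base_counts.items()
                if c > 0 and c / non_gap >= f_min}
        if not kept:
            peak = max(p.base_counts.values())
            kept = {b for b, c in p.base_counts.items() if c == peak}
        out.append(SET_TO_CODE[frozenset(kept)])
    return "".join(out)


@dataclass(frozen=True)
class PrimerCandidate:
    """Degenerate IUPAC core + constant 5' tail + Tm statistics."""

    core_iupac: str
    tail: str
    window: tuple[int, int]
    orientation: str
    tm: TmStats
    degeneracy: int

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        if self.degeneracy != degeneracy(self.core_iupac):
            raise ValueError("degeneracy inconsistent with core")

    @property
    def full_oligo(self) -> str:
        return self.tail + self.core_iupac


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    expected_len_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.forward.window[1] > self.reverse.window[0]:
            raise ValueError("forward window must precede reverse window")


def assemble_pair(msa: MSA, fwd_window: tuple[int, int],
                  rev_window: tuple[int, int],
                  tails: tuple[str, str] = (TAIL_A, TAIL_B),
                  target_tm: float | None = None,
                  tol_C: float = 5.0,
                  params: TmParams | None = None,
                  f_min: float = 0.10, max_gap_frac: float = 0.10,
                  amplicon_range: tuple[int, int] = (1250, 1750),
                  cap: int = 64, min_len: int = 15) -> PrimerPair:
    """Build a tailed, Tm-matched primer pair from two conserved windows.

    The forward core is the window consensus; the reverse core is the
    reverse complement of its window's consensus (so the oligo reads 5'->3'
    on the opposite strand). When ``target_tm`` is given both cores are
    trimmed from their 5' ends toward it. The expected amplicon length range
    (reverse window end to forward window start, per panel row, tails
    excluded) must fall inside ``amplicon_range``.
    """
    if fwd_window[1] >= rev_window[0]:
        raise ValueError("forward window must end before reverse window")
    params = params or TmParams()
    fwd_core = degenerate_consensus(msa, fwd_window, f_min, max_gap_frac)
    rev_core = reverse_complement(
        degenerate_consensus(msa, rev_window, f_min, max_gap_frac))
    f_start, r_end = fwd_window[0], rev_window[1]
    if target_tm is not None:
        trimmed_f = trim_to_tm(fwd_core, target_tm, tol_C, params, min_len,
                               cap)
        # 5' of the forward core sits at the window start
        f_start += len(fwd_core) - len(trimmed_f)
        fwd_core = trimmed_f
        trimmed_r = trim_to_tm(rev_core, target_tm, tol_C, params, min_len,
                               cap)
        # 5' of the reverse core sits at the window end
        r_end -= len(rev_core) - len(trimmed_r)
        rev_core = trimmed_r
    # per-row ungapped span between forward start and reverse end
    lengths = [sum(1 for ch in row[f_start:r_end] if ch != "-")
               for row in msa.rows]
    len_range = (min(lengths), max(lengths))
    if len_range[0] < amplicon_range[0] or len_range[1] > amplicon_range[1]:
        raise ValueError(
            f"expected amplicon length {len_range} outside "
            f"{amplicon_range}")
    fwd = PrimerCandidate(
        core_iupac=fwd_core, tail=tails[0],
        window=(f_start, f_start + len(fwd_core)), orientation="forward",
        tm=melt_tm(fwd_core, params, cap), degeneracy=degeneracy(fwd_core))
    rev = PrimerCandidate(
        core_iupac=rev_core, tail=tails[1],
        window=(r_end - len(rev_core), r_end), orientation="reverse",
        tm=melt_tm(rev_core, params, cap), degeneracy=degeneracy(rev_core))
    return PrimerPair(forward=fwd, reverse=rev, expected_len_range=len_range)


def pair_from_cores(fwd_core: str, rev_core: str,
                    tails: tuple[str, str] = (TAIL_A, TAIL_B),
                    fwd_start: int = 0, rev_end: int = 1500,
                    params: TmParams | None = None,
                    cap: int = 64) -> PrimerPair:
    """Wrap two known cores (e.g. a published primer set) as a PrimerPair
    with nominal reference coordinates, for in-silico PCR evaluation."""
    params = params or TmParams()
    fwd = PrimerCandidate(
        core_iupac=fwd_core, tail=tails[0],
        window=(fwd_start, fwd_start + len(fwd_core)),
        orientation="forward", tm=melt_tm(fwd_core, params, cap),
        degeneracy=degeneracy(fwd_core))
    rev = PrimerCandidate(
        core_iupac=rev_core, tail=tails[1],
        window=(rev_end - len(rev_core), rev_end),
        orientation="reverse", tm=melt_tm(rev_core, params, cap),
        degeneracy=degeneracy(rev_core))
    return PrimerPair(forward=fwd, reverse=rev,
                      expected_len_range=(rev_end - fwd_start,
                                          rev_end - fwd_start))


def design_pairs(msa: MSA, windows, target_tm: float | None = None,
                 tol_C: float = 5.0, params: TmParams | None = None,
                 tails: tuple[str, str] = (TAIL_A, TAIL_B),
                 core_len: int = 22, f_min: float = 0.10,
                 max_gap_frac: float = 0.10,
                 amplicon_range: tuple[int, int] = (1250, 1750),
                 cap: int = 64) -> list[PrimerPair]:
    """Enumerate admissible primer pairs over a list of conserved windows.

    Within each window the ``core_len``-column subspan with the highest
    mean conservation is the primer footprint (maximal windows can overhang
    into variable flanks, so window edges are poor anchors); ties go to the
    leftmost subspan for forward primers and the rightmost for reverse.
    Every (forward, reverse) window combination whose pair assembles within
    the amplicon constraint is returned, earliest forward window first.
    """
    profiles = column_profiles(msa)
    cons = [p.conservation for p in profiles]

    def _best_subspan(w, rightmost: bool) -> tuple[int, int] | None:
        length = min(core_len, w.end - w.start)
        if length < 15:
            return None
        spans = [(s, s + length) for s in range(w.start, w.end - length + 1)]
        if rightmost:
            spans.reverse()
        return max(spans, key=lambda sp: sum(cons[sp[0]:sp[1]]))

    pairs: list[PrimerPair] = []
    for wf in windows:
        f_span = _best_subspan(wf, rightmost=False)
        if f_span is None:
            continue
        for wr in windows:
            r_span = _best_subspan(wr, rightmost=True)
            if r_span is None or f_span[1] >= r_span[0]:
                continue
            try:
                pairs.append(assemble_pair(
                    msa, f_span, r_span, tails, target_tm, tol_C, params,
                    f_min, max_gap_frac, amplicon_range, cap))
            except ValueError:
                continue
    return pairs
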