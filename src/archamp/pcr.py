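"""In-silico PCR: predict primer binding sites and amplicons across a
labeled sequence database, and summarize per-taxon amplification coverage.

Binding is modeled on the degenerate core only (tails are universal tags and
never match the template): a primer base and a template base are compatible
when their IUPAC sets intersect, a site may carry up to ``max_mismatch``
incompatibilities overall but none within the 3'-terminal anchor, whose
extension the polymerase requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import encode, reverse_complement
from .io import Lineage, RANKS, SeqRecord
from .primers import PrimerPair


@dataclass(frozen=True)
class BindParams:
    max_mismatch: int = 2
    anchor3_len: int = 3
    max_amplicon: int = 3000

    def __post_init__(self) -> None:
        if self.max_mismatch < 0 or self.anchor3_len < 0:
            raise ValueError("negative binding parameter")


@dataclass(frozen=True)
class BindingSite:
    """A primer-core placement; 0-based half-open on the template forward
    strand. Strand '+' means the core reads left-to-right on the forward
    strand; '-' means its reverse complement does."""

    template_id: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int
    end: int
    f_site: BindingSite
    r_site: BindingSite

    @property
    def length(self) -> int:
        return self.end - self.start


def _scan(template_mask: np.ndarray, core_mask: np.ndarray,
          anchor_at_start: bool, anchor_len: int,
          max_mismatch: int) -> list[tuple[int, int]]:
    """All (position, mismatches) where the core is compatible with the
    template, with zero mismatches inside the anchor."""
    n, m = template_mask.size, core_mask.size
    if m > n:
        return []
    n_pos = n - m + 1
    mism = np.zeros(n_pos, dtype=np.int32)
    anchor_ok = np.ones(n_pos, dtype=bool)
    if anchor_at_start:
        anchor_idx = range(0, min(anchor_len, m))
    else:
        anchor_idx = range(max(0, m - anchor_len), m)
    anchor_set = set(anchor_idx)
    for k in range(m):
        compat = (template_mask[k:k + n_pos] & core_mask[k]) != 0
        mism += ~compat
        if k in anchor_set:
            anchor_ok &= compat
    hits = np.nonzero((mism <= max_mismatch) & anchor_ok)[0]
    return [(int(p), int(mism[p])) for p in hits]


def find_binding_sites(template: SeqRecord, primer_core: str,
                       params: BindParams | None = None
                       ) -> list[BindingSite]:
    """All binding sites of a degenerate core on both template strands.

    Sites are sorted by start, '+' before '-' at equal start. The 3' anchor
    of the core must match exactly (set-intersection) on either strand; on
    the '-' strand the anchor therefore sits at the *left* edge of the
    template-forward window.
    """
    params = params or BindParams()
    if params.anchor3_len > len(primer_core):
        raise ValueError("anchor longer than primer core")
    tmask = encode(template.sequence)
    m = len(primer_core)
    sites: list[BindingSite] = []
    for pos, mm in _scan(tmask, encode(primer_core), False,
                         params.anchor3_len, params.max_mismatch):
        sites.append(BindingSite(template.id, pos, pos + m, "+", mm))
    rc_core = reverse_complement(primer_core)
    for pos, mm in _scan(tmask, encode(rc_core), True,
                         params.anchor3_len, params.max_mismatch):
        sites.append(BindingSite(template.id, pos, pos + m, "-", mm))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(template: SeqRecord, pair: PrimerPair,
                      params: BindParams | None = None) -> list[Amplicon]:
    """All amplicons a primer pair would produce on one template.

    An amplicon is a (forward '+' site, reverse-primer '-' site) combination
    with 0 < length <= max_amplicon, spanning the forward site start to the
    reverse site end — plus the strand-mirrored arrangement (forward on '-',
    reverse on '+', reverse site upstream). Sorted by start, then end.
    """
    params = params or BindParams()
    f_sites = find_binding_sites(template, pair.forward.core_iupac, params)
    r_sites = find_binding_sites(template, pair.reverse.core_iupac, params)
    out: list[Amplicon] = []
    for f in (s for s in f_sites if s.strand == "+"):
        for r in (s for s in r_sites if s.strand == "-"):
            length = r.end - f.start
            if 0 < length <= params.max_amplicon:
                out.append(Amplicon(template.id, f.start, r.end, f, r))
    for f in (s for s in f_sites if s.strand == "-"):
        for r in (s for s in r_sites if s.strand == "+"):
            length = f.end - r.start
            if 0 < length <= params.max_amplicon:
                out.append(Amplicon(template.id, r.start, f.end, f, r))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def amplicon_record(template: SeqRecord, amp: Amplicon,
                    name: str | None = None) -> SeqRecord:
    """The amplified subsequence, oriented 5'->3' from the forward primer."""
    seq = template.sequence[amp.start:amp.end]
    if amp.f_site.strand == "-":
        seq = reverse_complement(seq)
    return SeqRecord(id=name or f"{template.id}_amp_{amp.start}_{amp.end}",
                     sequence=seq,
                     description=f"source={template.id}")


@dataclass
class CoverageReport:
    """Per-taxon amplification coverage plus superkingdom rollups."""

    rank: str
    per_taxon: pd.DataFrame
    per_superkingdom: pd.DataFrame


def panel_coverage(db: Sequence[SeqRecord],
                   taxonomy: Mapping[str, Lineage],
                   pair: PrimerPair,
                   params: BindParams | None = None,
                   rank: str = "genus") -> CoverageReport:
    """Fraction of database sequences a primer pair amplifies, per taxon at
    ``rank`` (sequences without a name at that rank group as "unassigned"),
    with a superkingdom rollup. "Amplified" means at least one amplicon
    within the length bound."""
    if not db:
        raise ValueError("empty sequence database")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    params = params or BindParams()
    rows: dict[str, list[int]] = {}
    sk_rows: dict[str, list[int]] = {}
    for rec in db:
        lineage = taxonomy.get(rec.id, Lineage(()))
        taxon = lineage.at_rank(rank) or "unassigned"
        sk = lineage.at_rank("superkingdom") or "unassigned"
        amplified = bool(predict_amplicons(rec, pair, params))
        for table, key in ((rows, taxon), (sk_rows, sk)):
            cur = table.setdefault(key, [0, 0])
            cur[0] += 1
            cur[1] += int(amplified)

    def _frame(table: dict[str, list[int]]) -> pd.DataFrame:
        data = [{"taxon": t, "n_sequences": n, "n_amplified": a,
                 "coverage": a / n} for t, (n, a) in sorted(table.items())]
        return pd.DataFrame(data,
                            columns=["taxon", "n_sequences", "n_amplified",
                                     "coverage"])

    return CoverageReport(rank=rank, per_taxon=_frame(rows),
                          per_superkingdom=_frame(sk_rows))
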