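"""Deterministic synthetic communities, genomes and long reads with full
ground truth, so every pipeline stage is testable without downloads.

The generator emulates the structure that makes 16S primer design work: one
ancestral template whose alternating conserved and hypervariable blocks
mutate at very different rates across taxa (the conserved blocks are where
primers live, the variable blocks are what classification keys on), a
superkingdom-level "signature" of shared substitutions so archaea and
bacteria form separable clades, genomes that embed the 16S on either
strand, and noisy full-length reads with independent per-base substitution,
insertion and deletion errors.

Everything is driven by numpy Generator streams derived from explicit
seeds; the same seed always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import reverse_complement
from .classify import ClassifyParams, classify_reads
from .io import Lineage, SeqRecord
from .pcr import BindParams, amplicon_record, predict_amplicons
from .primers import PrimerPair, expand

_BASES = np.array(list("ACGT"))


def default_block_layout(template_len: int,
                         conserved_len: int = 90,
                         variable_len: int = 75
                         ) -> list[tuple[int, int, str]]:
    """Alternating conserved/hypervariable spans tiling [0, template_len),
    beginning and ending with a conserved block (primer-suitable ends)."""
    blocks: list[tuple[int, int, str]] = []
    pos = 0
    kind = "conserved"
    while pos < template_len:
        length = conserved_len if kind == "conserved" else variable_len
        end = min(pos + length, template_len)
        blocks.append((pos, end, kind))
        pos = end
        kind = "variable" if kind == "conserved" else "conserved"
    if blocks[-1][2] == "variable":
        s, e, _ = blocks.pop()
        blocks.append((s, e, "conserved"))
    return blocks


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a two-superkingdom mock community."""

    taxa: tuple[tuple[str, Lineage, float], ...]
    template_len: int = 1500
    block_layout: tuple[tuple[int, int, str], ...] | None = None
    cons_rate: float = 0.01
    var_rate: float = 0.20
    clade_signature: int = 25
    seed: int = 0
    #: taxon id -> taxon id of a congeneric sibling it derives from; the
    #: sibling's 16S is the parent's plus ``sibling_rate`` substitutions,
    #: giving realistic within-genus similarity
    sibling_of: tuple[tuple[str, str], ...] = ()
    sibling_rate: float = 0.02

    def __post_init__(self) -> None:
        total = sum(a for _, _, a in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, not 1")
        ids = [tid for tid, _, _ in self.taxa]
        for child, parent in self.sibling_of:
            if parent not in ids or child not in ids or \
                    ids.index(parent) >= ids.index(child):
                raise ValueError(
                    f"sibling {child!r} must appear after its parent "
                    f"{parent!r} in taxa")
        layout = self.block_layout or tuple(
            default_block_layout(self.template_len))
        object.__setattr__(self, "block_layout", tuple(layout))
        pos = 0
        for s, e, kind in self.block_layout:
            if s != pos or e <= s or kind not in ("conserved", "variable"):
                raise ValueError("block layout must tile the template")
            pos = e
        if pos != self.template_len:
            raise ValueError("block layout must tile the template")

    @property
    def abundances(self) -> np.ndarray:
        return np.array([a for _, _, a in self.taxa])

    def taxonomy(self) -> dict[str, Lineage]:
        return {tid: lin for tid, lin, _ in self.taxa}


@dataclass(frozen=True)
class ReadSimParams:
    sub_rate: float = 0.02
    ins_rate: float = 0.015
    del_rate: float = 0.015
    n_reads: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not (0.0 <= r < 0.2):
                raise ValueError("error rates must be in [0, 0.2)")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic FASTA/FASTQ files."""

    template: str = ""
    taxa_16s: dict[str, str] = field(default_factory=dict)
    loci: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    reads: list[tuple[str, str, int]] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _mutate_positions(seq: np.ndarray, idx: np.ndarray,
                      rng: np.random.Generator) -> None:
    """Substitute each position in ``idx`` with a uniformly chosen
    *different* base."""
    shifts = rng.integers(1, 4, size=idx.size)
    seq[idx] = (seq[idx] + shifts) % 4


def _to_str(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def evolve_community(spec: CommunitySpec
                     ) -> tuple[list[SeqRecord], TruthSet]:
    """Derive each taxon's 16S from one ancestral template.

    Conserved blocks mutate at ``cons_rate``, variable blocks at
    ``var_rate``; on top of that each superkingdom shares
    ``clade_signature`` signature substitutions (same positions, same new
    bases for every member), so the two superkingdoms are separable even in
    conserved regions at low rates.
    """
    rng = np.random.default_rng(spec.seed)
    template = _random_seq(rng, spec.template_len)
    rates = np.empty(spec.template_len)
    for s, e, kind in spec.block_layout:
        rates[s:e] = spec.cons_rate if kind == "conserved" else spec.var_rate

    superkingdoms: list[str] = []
    for _, lin, _ in spec.taxa:
        sk = lin.at_rank("superkingdom") or "unassigned"
        if sk not in superkingdoms:
            superkingdoms.append(sk)
    signatures: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sk in superkingdoms:
        pos = rng.choice(spec.template_len, size=spec.clade_signature,
                         replace=False)
        shifts = rng.integers(1, 4, size=spec.clade_signature)
        signatures[sk] = (pos, shifts)

    sibling_parent = dict(spec.sibling_of)
    truth = TruthSet(template=_to_str(template))
    records: list[SeqRecord] = []
    evolved: dict[str, np.ndarray] = {}
    for tid, lin, _ in spec.taxa:
        if tid in sibling_parent:
            seq = evolved[sibling_parent[tid]].copy()
            hit = rng.random(spec.template_len) < spec.sibling_rate
            _mutate_positions(seq, np.nonzero(hit)[0], rng)
        else:
            seq = template.copy()
            sk = lin.at_rank("superkingdom") or "unassigned"
            pos, shifts = signatures[sk]
            seq[pos] = (seq[pos] + shifts) % 4
            hit = rng.random(spec.template_len) < rates
            _mutate_positions(seq, np.nonzero(hit)[0], rng)
        evolved[tid] = seq
        s = _to_str(seq)
        records.append(SeqRecord(id=tid, sequence=s,
                                 description=lin.to_string()))
        truth.taxa_16s[tid] = s
    return records, truth


def embed_in_genome(seq16s: SeqRecord, genome_len: int,
                    seed: int) -> tuple[SeqRecord, tuple[int, int, str]]:
    """Embed a 16S gene at a seeded position and strand inside a random
    background genome of exactly ``genome_len`` bases."""
    m = len(seq16s.sequence)
    if genome_len <= m + 200:
        raise ValueError(
            f"genome length {genome_len} too short for a {m} bp insert")
    rng = np.random.default_rng(seed)
    background = _random_seq(rng, genome_len - m)
    pos = int(rng.integers(0, genome_len - m + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    insert = seq16s.sequence
    if strand == "-":
        insert = reverse_complement(insert)
    genome = _to_str(background[:pos]) + insert + _to_str(background[pos:])
    rec = SeqRecord(id=f"genome_{seq16s.id}", sequence=genome,
                    description=f"16S at {pos}-{pos + m}({strand})")
    return rec, (pos, pos + m, strand)


def _apply_read_errors(seq: str, params: ReadSimParams,
                       rng: np.random.Generator) -> str:
    arr = np.array([("ACGT").index(c) if c in "ACGT" else 0
                    for c in seq], dtype=np.int64)
    # substitutions first
    hit = rng.random(arr.size) < params.sub_rate
    _mutate_positions(arr, np.nonzero(hit)[0], rng)
    # then indels, left to right: delete the base, or insert after it
    dels = rng.random(arr.size) < params.del_rate
    inss = rng.random(arr.size) < params.ins_rate
    ins_bases = rng.integers(0, 4, size=arr.size)
    out: list[int] = []
    for i in range(arr.size):
        if not dels[i]:
            out.append(arr[i])
        if inss[i]:
            out.append(int(ins_bases[i]))
    return _to_str(np.array(out, dtype=np.int64)) if out else "A"


def simulate_reads(amplicons: Sequence[SeqRecord],
                   abundances: Sequence[float],
                   params: ReadSimParams
                   ) -> tuple[list[SeqRecord], list[tuple[str, str, int]]]:
    """Draw noisy reads from amplicons proportional to abundance.

    Returns (reads, truth) where truth rows are (read_id, source amplicon
    id, emitted read length). Fully deterministic under ``params.seed``.
    """
    if not amplicons:
        raise ValueError("no amplicons to sequence")
    p = np.asarray(abundances, dtype=float)
    if p.size != len(amplicons):
        raise ValueError("abundances do not match amplicons")
    p = p / p.sum()
    rng = np.random.default_rng(params.seed)
    sources = rng.choice(len(amplicons), size=params.n_reads, p=p)
    width = len(str(params.n_reads))
    reads: list[SeqRecord] = []
    truth: list[tuple[str, str, int]] = []
    for k, src in enumerate(sources):
        template = amplicons[src]
        seq = _apply_read_errors(template.sequence, params, rng)
        rid = f"read_{k + 1:0{width}d}"
        reads.append(SeqRecord(id=rid, sequence=seq,
                               description=f"source={template.id}"))
        truth.append((rid, template.id, len(seq)))
    return reads, truth


# --------------------------------------------------------------------------
# Primer-bias scenario
# --------------------------------------------------------------------------

def _plant(seq: str, site: str, at: int) -> str:
    return seq[:at] + site + seq[at + len(site):]


def _diverge(site: str, anchor3: int) -> str:
    """Deterministically mutate a planted site beyond any mismatch
    tolerance: every other position plus the whole 3' anchor."""
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    positions = set(range(0, len(site), 2)) | set(
        range(len(site) - anchor3, len(site)))
    return "".join(swap[c] if i in positions else c
                   for i, c in enumerate(site))


@dataclass(frozen=True)
class PairOutcome:
    n_reads: int
    n_length_filtered: int
    n_unclassified: int
    n_classified: int
    archaeal_read_fraction: float


@dataclass(frozen=True)
class ScenarioReport:
    archaeal_abundance: float
    outcomes: dict[str, PairOutcome]


def scenario_primer_bias(spec: CommunitySpec,
                         universal_pair: PrimerPair,
                         archaeal_pair: PrimerPair,
                         bind_params: BindParams | None = None,
                         read_params: ReadSimParams | None = None,
                         classify_params: ClassifyParams | None = None
                         ) -> ScenarioReport:
    """Reproduce primer-dependent archaeal detection on a mock community.

    Archaea-targeted primer sites are planted (exactly) on *every* taxon —
    they target conserved 16S regions shared across superkingdoms — while
    the universal pair's sites are planted intact on bacteria but diverged
    beyond any mismatch tolerance on archaea. The full workflow (in-silico
    PCR, read simulation proportional to abundance, classification against
    the community 16S references) then runs once per primer pair, and the
    archaeal fraction of classified reads is reported for each.
    """
    bind_params = bind_params or BindParams()
    read_params = read_params or ReadSimParams(n_reads=200)
    classify_params = classify_params or ClassifyParams()

    records, truth = evolve_community(spec)
    taxonomy = spec.taxonomy()
    L = spec.template_len

    uf = expand(universal_pair.forward.core_iupac,
                cap=max(64, universal_pair.forward.degeneracy))[0]
    ur = expand(universal_pair.reverse.core_iupac,
                cap=max(64, universal_pair.reverse.degeneracy))[0]
    af = expand(archaeal_pair.forward.core_iupac,
                cap=max(64, archaeal_pair.forward.degeneracy))[0]
    ar = expand(archaeal_pair.reverse.core_iupac,
                cap=max(64, archaeal_pair.reverse.degeneracy))[0]
    ur_site = reverse_complement(ur)   # reverse primer binds as its rc
    ar_site = reverse_complement(ar)

    anchor = bind_params.anchor3_len
    templates: list[SeqRecord] = []
    for rec in records:
        sk = taxonomy[rec.id].at_rank("superkingdom") or ""
        is_archaeon = sk.lower() == "archaea"
        seq = rec.sequence
        seq = _plant(seq, af, 35)
        seq = _plant(seq, ar_site, L - 35 - len(ar_site))
        u_fwd = _diverge(uf, anchor) if is_archaeon else uf
        # the reverse-site 3' anchor sits at the LEFT edge of the planted rc
        u_rev = reverse_complement(
            _diverge(ur, anchor)) if is_archaeon else ur_site
        seq = _plant(seq, u_fwd, 10)
        seq = _plant(seq, u_rev, L - 10 - len(u_rev))
        templates.append(SeqRecord(id=rec.id, sequence=seq,
                                   description=rec.description))

    refdb = templates
    abundance_by_id = {tid: a for tid, _, a in spec.taxa}
    archaeal_abundance = sum(
        a for tid, lin, a in spec.taxa
        if (lin.at_rank("superkingdom") or "").lower() == "archaea")

    outcomes: dict[str, PairOutcome] = {}
    for name, pair in (("universal", universal_pair),
                       ("archaeal", archaeal_pair)):
        amp_records: list[SeqRecord] = []
        amp_weights: list[float] = []
        for rec in templates:
            amps = predict_amplicons(rec, pair, bind_params)
            if amps:
                amp_records.append(
                    amplicon_record(rec, amps[0], name=rec.id))
                amp_weights.append(abundance_by_id[rec.id])
        if not amp_records:
            outcomes[name] = PairOutcome(0, 0, 0, 0, 0.0)
            continue
        reads, _ = simulate_reads(amp_records, amp_weights, read_params)
        assignments = classify_reads(reads, refdb, taxonomy,
                                     classify_params)
        n_cls = sum(a.status == "classified" for a in assignments)
        n_unc = sum(a.status == "unclassified" for a in assignments)
        n_filt = sum(a.status == "length_filtered" for a in assignments)
        n_arch = sum(
            a.status == "classified" and
            (a.lineage.at_rank("superkingdom") or "").lower() == "archaea"
            for a in assignments)
        outcomes[name] = PairOutcome(
            n_reads=len(reads), n_length_filtered=n_filt,
            n_unclassified=n_unc, n_classified=n_cls,
            archaeal_read_fraction=(n_arch / n_cls) if n_cls else 0.0)
    return ScenarioReport(archaeal_abundance=archaeal_abundance,
                          outcomes=outcomes)


def example_community(n_bacteria: int = 7, n_archaea: int = 3,
                      archaeal_abundance: float = 0.3,
                      congeneric_pairs: int = 0,
                      seed: int = 0, **kwargs) -> CommunitySpec:
    """A ready-made two-superkingdom community with distinct genera, evenly
    splitting each superkingdom's abundance among its taxa.

    ``congeneric_pairs`` gives the first so-many bacterial genera a second,
    closely related species (same lineage through genus, the parent's
    abundance split in half), which is what makes classifier comparisons at
    species rank interesting.
    """
    bac_share = (1.0 - archaeal_abundance) / n_bacteria
    taxa: list[tuple[str, Lineage, float]] = []
    siblings: list[tuple[str, str]] = []
    for i in range(n_bacteria):
        lin = Lineage(("Bacteria", f"B_phylum_{i % 3}", f"B_class_{i % 3}",
                       f"B_order_{i}", f"B_family_{i}", f"B_genus_{i}",
                       f"B_species_{i}"))
        paired = i < congeneric_pairs
        taxa.append((f"bac_{i}", lin,
                     bac_share / 2 if paired else bac_share))
    for i in range(n_archaea):
        lin = Lineage(("Archaea", f"A_phylum_{i % 2}", f"A_class_{i % 2}",
                       f"A_order_{i}", f"A_family_{i}", f"A_genus_{i}",
                       f"A_species_{i}"))
        taxa.append((f"arc_{i}", lin, archaeal_abundance / n_archaea))
    for i in range(congeneric_pairs):
        lin = Lineage(("Bacteria", f"B_phylum_{i % 3}", f"B_class_{i % 3}",
                       f"B_order_{i}", f"B_family_{i}", f"B_genus_{i}",
                       f"B_species_{i}b"))
        taxa.append((f"bac_{i}b", lin, bac_share / 2))
        siblings.append((f"bac_{i}b", f"bac_{i}"))
    return CommunitySpec(taxa=tuple(taxa), seed=seed,
                         sibling_of=tuple(siblings), **kwargs)
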