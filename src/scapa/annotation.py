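"""Poly(A)-site (PAS) and 3'-UTR annotation integration.

Builds the merged PAS set from several annotation databases (within-database
collapse followed by a sequential cross-database union), selects one
representative 3'-UTR model per gene, and links PASs to genes in spliced
(intron-subtracted) UTR coordinates.

Coordinate conventions
----------------------
All intervals are BED-style 0-based half-open.  A PAS is stored as the
0-based genomic coordinate of the last transcribed base (the cleavage
position).  ``utr_length`` of a genomic position is its 0-based spliced
distance from the stop-codon coordinate along the exon blocks of the UTR,
so a PAS one intron-free kilobase downstream of the stop codon has
utr_length 1000 regardless of any intervening intron removed by splicing.
"Downstream" is always the 3' direction of the annotated strand.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

__all__ = [
    "PasRecord",
    "PasSet",
    "UtrResourceEntry",
    "UtrModel",
    "IntegrationConfig",
    "OverlapCounts",
    "LinkResult",
    "NucleotideProfile",
    "collapse_within_database",
    "sequential_union",
    "pairwise_overlap",
    "integrate_utrs",
    "select_representative_transcript",
    "link_pas_to_gene",
    "nucleotide_profile",
    "fetch_sequence",
    "revcomp",
]


def _check_strand(strand: str) -> None:
    if strand not in STRANDS:
        raise ValueError(f"invalid strand {strand!r}: must be '+' or '-'")


@dataclass(frozen=True)
class PasRecord:
    """One cleavage/polyadenylation site.

    ``pos`` is the 0-based genomic coordinate of the last transcribed
    nucleotide; ``source`` records the database the site came from.
    """

    chrom: str
    strand: str
    pos: int
    source: str
    id: str

    def __post_init__(self) -> None:
        _check_strand(self.strand)
        if self.pos < 0:
            raise ValueError(f"PAS position must be >= 0, got {self.pos}")


@dataclass
class PasSet:
    """A collection of PAS records with ordered source provenance."""

    records: list[PasRecord]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("PAS ids must be unique within a PasSet")
        if not self.provenance:
            self.provenance = sorted({r.source for r in self.records})

    def __len__(self) -> int:
        return len(self.records)

    def by_chrom_strand(self) -> dict[tuple[str, str], list[PasRecord]]:
        """Records grouped by (chrom, strand), sorted by genomic position."""
        groups: dict[tuple[str, str], list[PasRecord]] = defaultdict(list)
        for rec in self.records:
            groups[(rec.chrom, rec.strand)].append(rec)
        for key in groups:
            groups[key].sort(key=lambda r: (r.pos, r.id))
        return dict(groups)

    def positions(self) -> dict[tuple[str, str], np.ndarray]:
        return {
            key: np.array([r.pos for r in recs], dtype=np.int64)
            for key, recs in self.by_chrom_strand().items()
        }


@dataclass
class UtrResourceEntry:
    """A candidate 3'-UTR annotation from one resource.

    ``exon_blocks`` are 0-based half-open genomic intervals sorted by
    genomic coordinate; transcript (5'->3') order is ascending for '+'
    and descending for '-'.  ``stop_codon`` is the genomic coordinate of
    the first UTR base (block edge adjacent to the stop codon).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    stop_codon: int
    exon_blocks: list[tuple[int, int]]
    source: str = ""

    def __post_init__(self) -> None:
        _check_strand(self.strand)
        blocks = sorted((int(s), int(e)) for s, e in self.exon_blocks)
        for (s, e) in blocks:
            if e <= s:
                raise ValueError(f"empty/inverted block ({s},{e}) in {self.transcript_id}")
        for (_, e1), (s2, _) in zip(blocks, blocks[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping UTR blocks in {self.transcript_id}")
        self.exon_blocks = blocks

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exon_blocks)

    @property
    def terminus(self) -> int:
        """Genomic coordinate of the 3'-most UTR base."""
        if self.strand == "+":
            return self.exon_blocks[-1][1] - 1
        return self.exon_blocks[0][0]

    def spliced_position(self, pos: int) -> int | None:
        """0-based spliced distance of genomic ``pos`` from the stop codon.

        Returns None when ``pos`` is not inside any exon block.
        """
        offset = 0
        if self.strand == "+":
            for s, e in self.exon_blocks:
                if pos < s:
                    return None
                if pos < e:
                    return offset + (pos - s)
                offset += e - s
            return None
        for s, e in reversed(self.exon_blocks):
            if pos >= e:
                return None
            if pos >= s:
                return offset + (e - 1 - pos)
            offset += e - s
        return None

    def genomic_position(self, spliced: int) -> int:
        """Inverse of :meth:`spliced_position` (spliced is 0-based)."""
        if not 0 <= spliced < self.spliced_length:
            raise ValueError(f"spliced position {spliced} outside [0,{self.spliced_length})")
        offset = spliced
        if self.strand == "+":
            for s, e in self.exon_blocks:
                if offset < e - s:
                    return s + offset
                offset -= e - s
        else:
            for s, e in reversed(self.exon_blocks):
                if offset < e - s:
                    return e - 1 - offset
                offset -= e - s
        raise AssertionError("unreachable")


@dataclass
class UtrModel(UtrResourceEntry):
    """Representative 3'-UTR of one gene with its linked PASs.

    ``linked_pas`` holds (pas_id, utr_length) pairs sorted by ascending
    utr_length; utr_length is the spliced distance from the stop codon.
    """

    linked_pas: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class IntegrationConfig:
    """Parameters of the annotation-integration stage."""

    collapse_radius: int = 10
    venn_radius: int = 20
    max_3pseq_extension: int = 5400
    union_order: tuple[str, ...] = ("PolyASite", "PolyA_DB", "Gencode")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.collapse_radius < 0 or self.venn_radius < 0:
            raise ValueError("radii must be >= 0")
        if self.max_3pseq_extension < 0:
            raise ValueError("max_3pseq_extension must be >= 0")


# ---------------------------------------------------------------------------
# PAS set construction
# ---------------------------------------------------------------------------


def collapse_within_database(records: Sequence[PasRecord], radius: int) -> list[PasRecord]:
    """Collapse nearby PASs of one database onto the most downstream site.

    Sites on the same (chrom, strand) are chained 5'->3': a site joins the
    open cluster iff it lies within ``radius`` nt of the cluster's current
    most-downstream member, and each cluster is replaced by its most
    downstream member.  The result is independent of input order.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if not records:
        return []
    sources = {r.source for r in records}
    if len(sources) > 1:
        raise ValueError(f"collapse_within_database requires one source, got {sorted(sources)}")

    out: list[PasRecord] = []
    groups: dict[tuple[str, str], list[PasRecord]] = defaultdict(list)
    for rec in records:
        groups[(rec.chrom, rec.strand)].append(rec)
    for (chrom, strand), recs in sorted(groups.items()):
        # 5'->3' order: ascending positions on '+', descending on '-'
        recs.sort(key=lambda r: (r.pos, r.id), reverse=(strand == "-"))
        rep = recs[0]
        for rec in recs[1:]:
            if abs(rec.pos - rep.pos) <= radius:
                rep = rec  # chain: rec is more downstream than rep
            else:
                out.append(rep)
                rep = rec
        out.append(rep)
    out.sort(key=lambda r: (r.chrom, r.strand, r.pos, r.id))
    return out


def _has_neighbor(sorted_pos: Sequence[int], pos: int, radius: int) -> bool:
    i = bisect_left(sorted_pos, pos - radius)
    return i < len(sorted_pos) and sorted_pos[i] <= pos + radius


def sequential_union(databases: Sequence[PasSet], radius: int) -> PasSet:
    """Union several already-collapsed PAS databases in order.

    Starting from the first set, a record of each later set is added only
    when no record already in the running set lies within ``radius`` nt on
    the same (chrom, strand).  Provenance of every kept record is preserved.
    """
    if not databases:
        raise ValueError("sequential_union requires at least one database")
    kept: list[PasRecord] = list(databases[0].records)
    current: dict[tuple[str, str], list[int]] = defaultdict(list)
    for rec in kept:
        current[(rec.chrom, rec.strand)].append(rec.pos)
    for key in current:
        current[key].sort()
    provenance: list[str] = list(databases[0].provenance)
    for db in databases[1:]:
        provenance.extend(s for s in db.provenance if s not in provenance)
        added: list[PasRecord] = []
        for rec in sorted(db.records, key=lambda r: (r.chrom, r.strand, r.pos, r.id)):
            if not _has_neighbor(current[(rec.chrom, rec.strand)], rec.pos, radius):
                added.append(rec)
        for rec in added:  # new sites of one database do not block each other
            positions = current[(rec.chrom, rec.strand)]
            positions.insert(bisect_right(positions, rec.pos), rec.pos)
            kept.append(rec)
    kept.sort(key=lambda r: (r.chrom, r.strand, r.pos, r.id))
    seen: set[str] = set()
    unique: list[PasRecord] = []
    for rec in kept:
        rid = rec.id
        while rid in seen:
            rid = f"{rec.source}:{rid}"
        seen.add(rid)
        unique.append(rec if rid == rec.id else replace(rec, id=rid))
    return PasSet(records=unique, provenance=provenance)


@dataclass(frozen=True)
class OverlapCounts:
    """Pairwise intersection summary of two PAS sets."""

    a_only: int
    b_only: int
    shared_a: int
    shared_b: int

    @property
    def shared(self) -> int:
        """Shared hits counted from set A's perspective."""
        return self.shared_a


def pairwise_overlap(set_a: PasSet, set_b: PasSet, radius: int) -> OverlapCounts:
    """Count sites unique to, and shared between, two PAS sets.

    A record is shared iff some record of the other set on the same
    (chrom, strand) lies within ``radius`` nt (inclusive).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")

    def split(first: PasSet, second: PasSet) -> tuple[int, int]:
        other = {key: sorted(p.tolist()) for key, p in second.positions().items()}
        shared = sum(
            1
            for rec in first.records
            if _has_neighbor(other.get((rec.chrom, rec.strand), []), rec.pos, radius)
        )
        return len(first.records) - shared, shared

    a_only, shared_a = split(set_a, set_b)
    b_only, shared_b = split(set_b, set_a)
    return OverlapCounts(a_only=a_only, b_only=b_only, shared_a=shared_a, shared_b=shared_b)


# ---------------------------------------------------------------------------
# 3'-UTR integration
# ---------------------------------------------------------------------------


def integrate_utrs(
    resources: Sequence[UtrResourceEntry],
    three_pseq_ends: Sequence[tuple[str, str, int]] = (),
    config: IntegrationConfig | None = None,
) -> list[UtrResourceEntry]:
    """Keep the longest 3'-UTR per stop codon, extended by bulk 3'-end evidence.

    For each unique stop codon the entry with maximal spliced length wins.
    A bulk 3'-end-sequencing cleavage position downstream of the kept
    terminus extends the terminal block out to that position, provided its
    spliced distance from the stop codon stays within
    ``config.max_3pseq_extension`` (default 5400 nt); the farthest
    admissible end is used.
    """
    config = config or IntegrationConfig()
    by_stop: dict[tuple[str, str, int], UtrResourceEntry] = {}
    for entry in resources:
        key = (entry.chrom, entry.strand, entry.stop_codon)
        best = by_stop.get(key)
        if (
            best is None
            or entry.spliced_length > best.spliced_length
            or (entry.spliced_length == best.spliced_length and entry.transcript_id < best.transcript_id)
        ):
            by_stop[key] = entry

    ends_by_cs: dict[tuple[str, str], list[int]] = defaultdict(list)
    for chrom, strand, pos in three_pseq_ends:
        _check_strand(strand)
        ends_by_cs[(chrom, strand)].append(int(pos))
    for key in ends_by_cs:
        ends_by_cs[key].sort()

    out: list[UtrResourceEntry] = []
    for key in sorted(by_stop):
        entry = by_stop[key]
        ends = ends_by_cs.get((entry.chrom, entry.strand), [])
        if ends:
            entry = _extend_by_3pseq(entry, ends, config.max_3pseq_extension)
        out.append(entry)
    return out


def _extend_by_3pseq(
    entry: UtrResourceEntry, sorted_ends: list[int], cap: int
) -> UtrResourceEntry:
    term = entry.terminus
    length = entry.spliced_length
    budget = cap - length  # genomic nt of intron-free extension allowed
    if budget <= 0:
        return entry
    best_ext = 0
    if entry.strand == "+":
        lo = bisect_right(sorted_ends, term)
        hi = bisect_right(sorted_ends, term + budget)
        if hi > lo:
            best_ext = sorted_ends[hi - 1] - term
    else:
        lo = bisect_left(sorted_ends, term - budget)
        hi = bisect_left(sorted_ends, term)
        if hi > lo:
            best_ext = term - sorted_ends[lo]
    if best_ext <= 0:
        return entry
    blocks = list(entry.exon_blocks)
    if entry.strand == "+":
        s, e = blocks[-1]
        blocks[-1] = (s, e + best_ext)
    else:
        s, e = blocks[0]
        blocks[0] = (s - best_ext, e)
    return replace(entry, exon_blocks=blocks)


def select_representative_transcript(
    gene_id: str,
    candidates: Sequence[UtrResourceEntry],
    utr_read_counts: Mapping[str, int] | None = None,
    rng_seed: int = 0,
) -> UtrModel:
    """Choose the single transcript isoform that represents a gene's 3'-UTR.

    The transcript whose 3'-UTR carries the most mapped reads wins; ties
    are broken by a seeded uniform draw among the top-ranked.  Genes with
    no UTR-mapping reads fall back to the longest 3'-UTR.
    """
    if not candidates:
        raise ValueError(f"no candidate transcripts for gene {gene_id}")
    bad = [c.transcript_id for c in candidates if c.gene_id != gene_id]
    if bad:
        raise ValueError(f"candidates {bad} do not belong to gene {gene_id}")
    counts = dict(utr_read_counts or {})
    ranked = sorted(candidates, key=lambda c: c.transcript_id)
    best_count = max((counts.get(c.transcript_id, 0) for c in ranked), default=0)
    if best_count > 0:
        top = [c for c in ranked if counts.get(c.transcript_id, 0) == best_count]
        if len(top) == 1:
            chosen = top[0]
        else:
            rng = np.random.default_rng(rng_seed)
            chosen = top[int(rng.integers(len(top)))]
    else:
        chosen = max(ranked, key=lambda c: (c.spliced_length, c.transcript_id))
    return UtrModel(
        gene_id=gene_id,
        transcript_id=chosen.transcript_id,
        chrom=chosen.chrom,
        strand=chosen.strand,
        stop_codon=chosen.stop_codon,
        exon_blocks=list(chosen.exon_blocks),
        source=chosen.source,
    )


@dataclass
class LinkResult:
    """Outcome of PAS-to-gene linkage."""

    models: list[UtrModel]
    unlinked: list[str]
    ambiguous: list[str]


def link_pas_to_gene(pas: PasSet, utrs: Sequence[UtrModel]) -> LinkResult:
    """Attach each PAS to the gene whose representative 3'-UTR contains it.

    A PAS links to a gene iff it falls inside an exon block of that gene's
    UTR model on the same strand and its spliced distance from the stop
    codon is positive.  Sites inside the UTRs of several distinct genes are
    dropped as gene-ambiguous; sites in no UTR are reported unlinked.
    """
    from .genomics import BlockIndex  # local import to avoid a cycle

    index = BlockIndex.from_models(utrs)
    models = [
        UtrModel(
            gene_id=m.gene_id,
            transcript_id=m.transcript_id,
            chrom=m.chrom,
            strand=m.strand,
            stop_codon=m.stop_codon,
            exon_blocks=list(m.exon_blocks),
            source=m.source,
        )
        for m in utrs
    ]
    by_gene = {m.gene_id: m for m in models}
    unlinked: list[str] = []
    ambiguous: list[str] = []
    for rec in pas.records:
        genes = index.genes_at(rec.chrom, rec.strand, rec.pos)
        if not genes:
            unlinked.append(rec.id)
            continue
        if len(genes) > 1:
            ambiguous.append(rec.id)
            continue
        model = by_gene[genes[0]]
        spliced = model.spliced_position(rec.pos)
        assert spliced is not None
        if spliced <= 0:  # PAS at the stop codon itself carries no UTR
            unlinked.append(rec.id)
            continue
        model.linked_pas.append((rec.id, spliced))
    for model in models:
        model.linked_pas.sort(key=lambda t: t[1])
    return LinkResult(models=models, unlinked=unlinked, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# Sequence QC
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[start:end) as an uppercase string.

    ``genome`` may be a plain mapping chrom -> sequence string or a
    pyfaidx.Fasta-like object supporting slicing.
    """
    seq = genome[chrom][start:end]
    return str(seq).upper()


@dataclass
class NucleotideProfile:
    """Per-position nucleotide frequencies around cleavage sites."""

    matrix: np.ndarray  # 4 x (2*flank+1), rows A,C,G,T
    flank: int
    n_used: int
    n_skipped: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)


def nucleotide_profile(pas: PasSet, genome, flank: int = 50) -> NucleotideProfile:
    """Sense-strand nucleotide frequencies in the +/- flank nt around PASs.

    Minus-strand contexts are reverse-complemented so that column
    ``flank + k`` always reports the base k nt downstream (3') of the
    cleavage site.  Sites too close to a contig edge are skipped.
    """
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=np.int64)
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    used = skipped = 0
    for rec in pas.records:
        start = rec.pos - flank
        end = rec.pos + flank + 1
        if start < 0:
            skipped += 1
            continue
        try:
            seq = fetch_sequence(genome, rec.chrom, start, end)
        except KeyError:
            skipped += 1
            continue
        if len(seq) != width:
            skipped += 1
            continue
        if rec.strand == "-":
            seq = revcomp(seq)
        for j, base in enumerate(seq):
            idx = base_index.get(base)
            if idx is not None:
                counts[idx, j] += 1
        used += 1
    if skipped:
        logger.info("nucleotide_profile: skipped %d PASs near contig edges", skipped)
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / np.where(totals == 0, 1, totals)
    return NucleotideProfile(matrix=freqs, flank=flank, n_used=used, n_skipped=skipped)
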