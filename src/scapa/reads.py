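"""Filtering and PAS assignment of read 3'-ends.

Poly(A)-primed single-cell protocols capture both authentic mRNA 3'-termini
and internal-priming artifacts nucleated at A-rich tracts.  This module
keeps only read ends that fall inside exactly one gene's 3'-UTR and within
the acceptance window around an annotated PAS (-300 to +20 nt in spliced
UTR coordinates by default), then assigns windowed reads to sites with a
two-pass greedy rule: unique reads first, then ambiguous reads to the
candidate with the most uniquely assigned reads.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import PasSet, UtrModel, fetch_sequence, revcomp
from .genomics import BlockIndex

logger = logging.getLogger(__name__)

__all__ = [
    "ReadEnd",
    "AssignmentWindow",
    "AssignmentResult",
    "filter_reads_to_utrs",
    "window_candidates",
    "greedy_assign",
    "assign_reads",
    "offset_histogram",
    "downstream_A_fraction",
    "count_reads_gene_body",
]

DISCARD_NO_UTR = "no_utr"
DISCARD_MULTI_GENE = "multi_gene"
DISCARD_NO_WINDOW = "no_pas_window"


@dataclass(frozen=True)
class ReadEnd:
    """The 3'-most aligned genomic base of one read, with its cell barcode."""

    chrom: str
    strand: str
    end3: int
    barcode: str
    umi: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end3 < 0:
            raise ValueError("end3 must be >= 0")
        if not self.barcode:
            raise ValueError("barcode must be non-empty")


@dataclass(frozen=True)
class AssignmentWindow:
    """Acceptance window around a PAS, in spliced UTR nt (both bounds inclusive)."""

    upstream: int = 300
    downstream: int = 20

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window bounds must be >= 0")

    def contains(self, offset: int) -> bool:
        """True iff offset = utr_length(read) - utr_length(PAS) is acceptable."""
        return -self.upstream <= offset <= self.downstream


@dataclass
class AssignmentResult:
    """Outcome of read filtering and greedy read-to-PAS assignment."""

    assigned: list[tuple[ReadEnd, str, str]]  # (read, gene_id, pas_id)
    discarded: list[tuple[ReadEnd, str]]  # (read, reason)
    counts: dict[tuple[str, str], int] = field(default_factory=dict)  # (gene, pas) -> n
    funnel: dict[str, int] = field(default_factory=dict)

    @property
    def n_assigned(self) -> int:
        return len(self.assigned)

    @property
    def n_discarded(self) -> int:
        return len(self.discarded)


def filter_reads_to_utrs(
    reads: Sequence[ReadEnd], utrs: Sequence[UtrModel]
) -> tuple[list[tuple[ReadEnd, str]], list[tuple[ReadEnd, str]]]:
    """Keep reads whose 3'-end lies in exactly one gene's 3'-UTR.

    Returns (kept, discarded): kept pairs each read with its gene id;
    discarded pairs each read with a reason (``no_utr`` or ``multi_gene``).
    """
    index = BlockIndex.from_models(utrs)
    kept: list[tuple[ReadEnd, str]] = []
    discarded: list[tuple[ReadEnd, str]] = []
    for read in reads:
        genes = index.genes_at(read.chrom, read.strand, read.end3)
        if not genes:
            discarded.append((read, DISCARD_NO_UTR))
        elif len(genes) > 1:
            discarded.append((read, DISCARD_MULTI_GENE))
        else:
            kept.append((read, genes[0]))
    return kept, discarded


def window_candidates(
    read: ReadEnd, gene: UtrModel, window: AssignmentWindow
) -> list[str]:
    """PAS ids of ``gene`` whose acceptance window contains the read end.

    Offsets are computed in spliced UTR coordinates so an upstream window
    never silently spans an intron.
    """
    spliced = gene.spliced_position(read.end3)
    if spliced is None:
        return []
    return [
        pas_id
        for pas_id, utr_len in gene.linked_pas
        if window.contains(spliced - utr_len)
    ]


def greedy_assign(
    reads_with_gene: Sequence[tuple[ReadEnd, str]],
    utrs: Mapping[str, UtrModel] | Sequence[UtrModel],
    window: AssignmentWindow = AssignmentWindow(),
) -> AssignmentResult:
    """Two-pass greedy assignment of UTR-filtered reads to PASs.

    Pass 1 assigns reads with exactly one candidate PAS and tallies unique
    counts; pass 2 sends each multi-candidate read to the candidate with
    the largest unique count, ties broken by the most downstream (longest
    utr_length) candidate.  Reads with no candidate are discarded as
    likely internal-priming artifacts.  The result does not depend on the
    input read order.
    """
    models = (
        {m.gene_id: m for m in utrs} if not isinstance(utrs, Mapping) else dict(utrs)
    )
    assigned: list[tuple[ReadEnd, str, str]] = []
    discarded: list[tuple[ReadEnd, str]] = []
    counts: Counter[tuple[str, str]] = Counter()

    per_gene: dict[str, list[ReadEnd]] = defaultdict(list)
    for read, gene_id in reads_with_gene:
        per_gene[gene_id].append(read)

    for gene_id in sorted(per_gene):
        gene = models[gene_id]
        utr_len_of = dict(gene.linked_pas)
        unique: Counter[str] = Counter()
        ambiguous: list[tuple[ReadEnd, list[str]]] = []
        for read in per_gene[gene_id]:
            cands = window_candidates(read, gene, window)
            if not cands:
                discarded.append((read, DISCARD_NO_WINDOW))
            elif len(cands) == 1:
                unique[cands[0]] += 1
                assigned.append((read, gene_id, cands[0]))
            else:
                ambiguous.append((read, cands))
        for read, cands in ambiguous:
            # max unique count, then most downstream (largest utr_length)
            winner = max(cands, key=lambda p: (unique[p], utr_len_of[p]))
            assigned.append((read, gene_id, winner))
    for read, gene_id, pas_id in assigned:
        counts[(gene_id, pas_id)] += 1
    return AssignmentResult(
        assigned=assigned,
        discarded=discarded,
        counts=dict(counts),
        funnel={},
    )


def assign_reads(
    reads: Sequence[ReadEnd],
    utrs: Sequence[UtrModel],
    window: AssignmentWindow = AssignmentWindow(),
) -> AssignmentResult:
    """Full filter + assignment pipeline with the read-count funnel."""
    kept, discarded_utr = filter_reads_to_utrs(reads, utrs)
    result = greedy_assign(kept, {m.gene_id: m for m in utrs}, window)
    result.discarded = discarded_utr + result.discarded
    result.funnel = {
        "input": len(reads),
        "utr_mapped": len(kept),
        "pas_assigned": len(result.assigned),
    }
    assert result.n_assigned + result.n_discarded == len(reads)
    return result


def offset_histogram(
    reads: Sequence[ReadEnd],
    pas: PasSet,
    max_offset: int = 400,
    bin_size: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of read-end offsets around isolated PASs.

    Only PASs with no same-strand neighbour within +/- ``max_offset`` nt
    contribute, so every read in range has an unambiguous reference site.
    Offsets are strand-aware genomic distances (positive = downstream of
    the PAS); bins are half-open [k*bin_size, (k+1)*bin_size).  Returns
    (bin_left_edges, counts).
    """
    positions = pas.positions()
    isolated: dict[tuple[str, str], np.ndarray] = {}
    for key, pos in positions.items():
        if len(pos) == 1:
            isolated[key] = pos
            continue
        gaps_prev = np.diff(pos, prepend=pos[0] - 2 * max_offset - 1)
        gaps_next = np.diff(pos, append=pos[-1] + 2 * max_offset + 1)
        mask = (gaps_prev > max_offset) & (gaps_next > max_offset)
        isolated[key] = pos[mask]

    edges = np.arange(-max_offset, max_offset + bin_size, bin_size)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for read in reads:
        pos = isolated.get((read.chrom, read.strand))
        if pos is None or len(pos) == 0:
            continue
        i = np.searchsorted(pos, read.end3)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(pos):
                d = abs(read.end3 - pos[j])
                if best is None or d < best[0]:
                    best = (d, pos[j])
        if best is None or best[0] > max_offset:
            continue
        offset = read.end3 - best[1] if read.strand == "+" else best[1] - read.end3
        k = int(math.floor(offset / bin_size)) + max_offset // bin_size
        if 0 <= k < len(counts):
            counts[k] += 1
    return edges[:-1], counts


def downstream_A_fraction(
    reads: Sequence[ReadEnd], genome, window: int = 20
) -> tuple[np.ndarray, float]:
    """Fraction of adenosines immediately 3' of each read end (sense strand).

    Internal-priming artifacts show elevated downstream A-richness because
    oligo(dT) anneals to genomically encoded A-tracts.  Returns the
    per-read fractions (NaN where the window runs off the contig) and
    their mean over valid reads.
    """
    fracs = np.full(len(reads), np.nan)
    skipped = 0
    for i, read in enumerate(reads):
        if read.strand == "+":
            start, end = read.end3 + 1, read.end3 + 1 + window
        else:
            start, end = read.end3 - window, read.end3
        if start < 0:
            skipped += 1
            continue
        try:
            seq = fetch_sequence(genome, read.chrom, start, end)
        except (KeyError, IndexError):
            skipped += 1
            continue
        if len(seq) != window:
            skipped += 1
            continue
        if read.strand == "-":
            seq = revcomp(seq)
        fracs[i] = seq.count("A") / window
    if skipped:
        logger.info("downstream_A_fraction: skipped %d reads at contig edges", skipped)
    valid = fracs[~np.isnan(fracs)]
    mean = float(valid.mean()) if len(valid) else float("nan")
    return fracs, mean


def count_reads_gene_body(
    reads: Sequence[ReadEnd],
    gene_spans: Mapping[str, tuple[str, int, int, str]],
) -> dict[str, int]:
    """Count read ends within each gene's full transcription span.

    ``gene_spans`` maps gene_id -> (chrom, start, end, strand), half-open.
    Intronic reads are counted here but are absent from PAS counts, which
    is exactly the contrast this diagnostic exists to expose.
    """
    counts = {gene_id: 0 for gene_id in gene_spans}
    spans_by_cs: dict[tuple[str, str], list[tuple[int, int, str]]] = defaultdict(list)
    for gene_id, (chrom, start, end, strand) in gene_spans.items():
        spans_by_cs[(chrom, strand)].append((start, end, gene_id))
    for read in reads:
        for start, end, gene_id in spans_by_cs.get((read.chrom, read.strand), []):
            if start <= read.end3 < end:
                counts[gene_id] += 1
    return counts
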