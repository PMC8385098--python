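"""Readers and writers for the pipeline's on-disk formats.

BED intervals are 0-based half-open.  PAS sets travel as BED6 (one file
per source database, name = site id, thickness of score ignored); UTR
models as BED12 with exon blocks; read 3'-ends either as a coordinate
TSV dialect (``readend.tsv``: chrom, end3, strand, barcode, umi) or as a
coordinate-sorted BAM with a cell-barcode tag; matrices as MatrixMarket
with row/column label sidecars, where absence of an entry means missing
rather than zero.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import PasRecord, PasSet, UtrModel, UtrResourceEntry
from .reads import ReadEnd

logger = logging.getLogger(__name__)

__all__ = [
    "read_bed6",
    "write_bed6",
    "read_bed12",
    "write_bed12",
    "read_gtf",
    "read_readends_tsv",
    "write_readends_tsv",
    "read_readends_bam",
    "read_readends",
    "read_cell_labels",
    "write_fasta",
    "write_matrix_mtx",
    "read_matrix_mtx",
    "write_linked_pas_tsv",
    "read_linked_pas_tsv",
]


class FormatError(ValueError):
    """Malformed input file."""


def _parse_int(value: str, path: str, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: bad {what} {value!r}") from None


def _check_coords(start: int, end: int, strand: str, path: str, lineno: int) -> None:
    if start < 0:
        raise FormatError(f"{path}:{lineno}: negative coordinate {start}")
    if end <= start:
        raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
    if strand not in ("+", "-"):
        raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")


def read_bed6(path: str | Path, source: str | None = None) -> PasSet:
    """Read one PAS database from BED6 (pos = last base of the interval's
    transcribed strand; single-base intervals expected, wider ones use the
    strand-aware 3' end)."""
    path = Path(path)
    source = source or path.stem
    records: list[PasRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}")
        chrom, start_s, end_s, name, _score, strand = fields[:6]
        start = _parse_int(start_s, str(path), lineno, "start")
        end = _parse_int(end_s, str(path), lineno, "end")
        _check_coords(start, end, strand, str(path), lineno)
        pos = end - 1 if strand == "+" else start
        rid = name if name and name != "." else f"{source}:{lineno}"
        if rid in seen:
            rid = f"{rid}:{lineno}"
        seen.add(rid)
        records.append(PasRecord(chrom=chrom, strand=strand, pos=pos, source=source, id=rid))
    return PasSet(records=records, provenance=[source])


def write_bed6(pas: PasSet, path: str | Path) -> None:
    """Write a PAS set as single-base BED6 with the source in the name field."""
    lines = []
    for rec in sorted(pas.records, key=lambda r: (r.chrom, r.pos, r.strand, r.id)):
        start = rec.pos if rec.strand == "+" else rec.pos
        lines.append(
            f"{rec.chrom}\t{start}\t{start + 1}\t{rec.source}:{rec.id}\t0\t{rec.strand}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed12(path: str | Path, source: str | None = None) -> list[UtrResourceEntry]:
    """Read UTR models from BED12; blocks are the UTR exons, name is
    ``gene_id|transcript_id`` (or just a shared id)."""
    path = Path(path)
    source = source or path.stem
    entries: list[UtrResourceEntry] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise FormatError(f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}")
        chrom, start_s, end_s, name, _score, strand = fields[:6]
        start = _parse_int(start_s, str(path), lineno, "start")
        end = _parse_int(end_s, str(path), lineno, "end")
        _check_coords(start, end, strand, str(path), lineno)
        n_blocks = _parse_int(fields[9], str(path), lineno, "blockCount")
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise FormatError(f"{path}:{lineno}: blockCount inconsistent with block lists")
        blocks = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
        if blocks[-1][1] != end:
            raise FormatError(
                f"{path}:{lineno}: blocks end at {blocks[-1][1]} but chromEnd is {end}"
            )
        gene_id, _, transcript_id = name.partition("|")
        transcript_id = transcript_id or name
        stop_codon = blocks[0][0] if strand == "+" else blocks[-1][1] - 1
        entries.append(
            UtrResourceEntry(
                gene_id=gene_id,
                transcript_id=transcript_id,
                chrom=chrom,
                strand=strand,
                stop_codon=stop_codon,
                exon_blocks=blocks,
                source=source,
            )
        )
    return entries


def write_bed12(entries: Sequence[UtrResourceEntry], path: str | Path) -> None:
    lines = []
    for e in entries:
        start = e.exon_blocks[0][0]
        end = e.exon_blocks[-1][1]
        sizes = ",".join(str(b - a) for a, b in e.exon_blocks)
        starts = ",".join(str(a - start) for a, _ in e.exon_blocks)
        name = f"{e.gene_id}|{e.transcript_id}"
        lines.append(
            "\t".join(
                [
                    e.chrom,
                    str(start),
                    str(end),
                    name,
                    "0",
                    e.strand,
                    str(start),
                    str(end),
                    "0",
                    str(len(e.exon_blocks)),
                    sizes,
                    starts,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gtf(path: str | Path, source: str | None = None) -> list[UtrResourceEntry]:
    """Build UTR entries from GTF stop_codon + exon features.

    The 3'-UTR of a transcript is taken as the exonic sequence strictly 3'
    of its stop_codon feature.  Transcripts without a stop codon or
    without exonic sequence past it are skipped.
    """
    path = Path(path)
    source = source or path.stem
    exons: dict[str, list[tuple[str, str, int, int, str]]] = {}
    stops: dict[str, tuple[int, int]] = {}
    genes: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise FormatError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
        chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
        if feature not in ("exon", "stop_codon"):
            continue
        start = _parse_int(start_s, str(path), lineno, "start") - 1  # GTF is 1-based
        end = _parse_int(end_s, str(path), lineno, "end")
        _check_coords(start, end, strand, str(path), lineno)
        attr = _parse_gtf_attrs(attrs)
        tid = attr.get("transcript_id")
        gid = attr.get("gene_id", tid)
        if tid is None:
            raise FormatError(f"{path}:{lineno}: missing transcript_id attribute")
        genes[tid] = gid
        if feature == "exon":
            exons.setdefault(tid, []).append((chrom, strand, start, end, gid))
        else:
            cur = stops.get(tid)
            stops[tid] = (
                (min(cur[0], start), max(cur[1], end)) if cur else (start, end)
            )
    entries: list[UtrResourceEntry] = []
    for tid, ex in sorted(exons.items()):
        if tid not in stops:
            continue
        stop_start, stop_end = stops[tid]
        chrom, strand = ex[0][0], ex[0][1]
        blocks = []
        for _, _, s, e, _ in sorted(ex, key=lambda t: t[2]):
            if strand == "+":
                s2 = max(s, stop_end)
                if s2 < e:
                    blocks.append((s2, e))
            else:
                e2 = min(e, stop_start)
                if s < e2:
                    blocks.append((s, e2))
        if not blocks:
            continue
        stop_codon = blocks[0][0] if strand == "+" else blocks[-1][1] - 1
        entries.append(
            UtrResourceEntry(
                gene_id=genes[tid],
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                stop_codon=stop_codon,
                exon_blocks=sorted(blocks),
                source=source,
            )
        )
    return entries


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


# ---------------------------------------------------------------------------
# Read ends
# ---------------------------------------------------------------------------

READEND_COLUMNS = ("chrom", "end3", "strand", "barcode", "umi")


def read_readends_tsv(path: str | Path) -> list[ReadEnd]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "barcode": str, "umi": str})
    missing = set(READEND_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "umi" not in df.columns:
        df["umi"] = None
    return [
        ReadEnd(
            chrom=row.chrom,
            strand=row.strand,
            end3=int(row.end3),
            barcode=row.barcode,
            umi=None if pd.isna(row.umi) else str(row.umi),
        )
        for row in df.itertuples()
    ]


def write_readends_tsv(reads: Sequence[ReadEnd], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.chrom, r.end3, r.strand, r.barcode, r.umi or "") for r in reads],
        columns=list(READEND_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_readends_bam(path: str | Path, barcode_tag: str = "CB") -> list[ReadEnd]:
    """Extract read 3'-ends from a coordinate-sorted BAM.

    Secondary, supplementary, and unmapped alignments are excluded; the
    3'-end is the 3'-most aligned reference base (soft clips ignored).
    Reads missing the barcode tag are skipped with a logged count.
    """
    import pysam

    reads: list[ReadEnd] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            try:
                barcode = aln.get_tag(barcode_tag)
            except KeyError:
                skipped += 1
                continue
            strand = "-" if aln.is_reverse else "+"
            end3 = aln.reference_end - 1 if strand == "+" else aln.reference_start
            umi = None
            if aln.has_tag("UB"):
                umi = aln.get_tag("UB")
            reads.append(
                ReadEnd(
                    chrom=aln.reference_name,
                    strand=strand,
                    end3=end3,
                    barcode=str(barcode),
                    umi=umi,
                )
            )
    if skipped:
        logger.info("read_readends_bam: skipped %d reads without %s tag", skipped, barcode_tag)
    return reads


def read_readends(path: str | Path, barcode_tag: str = "CB") -> list[ReadEnd]:
    """Dispatch on extension: .bam -> BAM reader, otherwise readend TSV."""
    path = Path(path)
    if path.suffix == ".bam":
        return read_readends_bam(path, barcode_tag=barcode_tag)
    return read_readends_tsv(path)


def read_cell_labels(path: str | Path, label: str = "stage") -> dict[str, str]:
    """Read barcode -> label from a cell metadata TSV (column ``label``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "barcode" not in df.columns or label not in df.columns:
        raise FormatError(f"{path}: needs 'barcode' and {label!r} columns")
    return dict(zip(df["barcode"], df[label]))


# ---------------------------------------------------------------------------
# FASTA / matrices / linkage tables
# ---------------------------------------------------------------------------


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_matrix_mtx(matrix: pd.DataFrame, prefix: str | Path) -> None:
    """Write a genes x cells matrix as MTX + row/column label sidecars.

    NaN entries are omitted (missing != 0); explicit zeros are kept.
    """
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    prefix = Path(prefix)
    values = matrix.to_numpy(dtype=float)
    rows, cols = np.nonzero(~np.isnan(values))
    data = values[rows, cols]
    # shift so explicit zeros survive the sparse round-trip
    coo = coo_matrix((data, (rows, cols)), shape=values.shape)
    mmwrite(str(prefix) + ".mtx", coo)
    Path(str(prefix) + ".rows.tsv").write_text("\n".join(map(str, matrix.index)) + "\n")
    Path(str(prefix) + ".cols.tsv").write_text("\n".join(map(str, matrix.columns)) + "\n")
    # mask records which entries are present, so zero values stay distinguishable
    mask = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=values.shape)
    mmwrite(str(prefix) + ".mask.mtx", mask)


def read_matrix_mtx(prefix: str | Path) -> pd.DataFrame:
    from scipy.io import mmread

    prefix = Path(prefix)
    values = mmread(str(prefix) + ".mtx").toarray()
    mask = mmread(str(prefix) + ".mask.mtx").toarray() > 0
    rows = Path(str(prefix) + ".rows.tsv").read_text().splitlines()
    cols = Path(str(prefix) + ".cols.tsv").read_text().splitlines()
    out = np.where(mask, values, np.nan)
    return pd.DataFrame(out, index=rows, columns=cols)


def write_linked_pas_tsv(models: Sequence[UtrModel], path: str | Path) -> None:
    rows = [
        (m.gene_id, m.transcript_id, pas_id, utr_len)
        for m in models
        for pas_id, utr_len in m.linked_pas
    ]
    pd.DataFrame(rows, columns=["gene_id", "transcript_id", "pas_id", "utr_length"]).to_csv(
        path, sep="\t", index=False
    )


def read_linked_pas_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
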