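"""Self-contained synthetic fixtures with exposed ground truth.

Generates a toy genome, multi-exon 3'-UTR gene models, several jittered
PAS annotation databases, labeled cells, and barcoded read 3'-ends whose
structure mirrors the data the pipeline is built for: true reads fall in
a stated offset distribution upstream of a planted PAS, internal-priming
artifact reads terminate immediately upstream of planted A-rich tracts
that lie outside every PAS acceptance window, and per-gene PAS usage
carries a planted stage-wise 3'-UTR lengthening trend plus a subset of
strongly differential genes.  Every simulated read records its origin so
downstream tests can score recovery exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    PasRecord,
    PasSet,
    UtrModel,
    UtrResourceEntry,
)
from .reads import ReadEnd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimAnnotation",
    "SimReads",
    "simulate_annotation",
    "simulate_databases",
    "simulate_reads",
    "simulate_dataset",
    "simulate_null_tables",
    "simulate_shifted_tables",
]

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Knobs of the synthetic generator.

    Defaults describe the study conditions the generator emulates: five
    developmental stages, a handful of cell-type clusters, 2-4 PASs per
    gene spaced so acceptance windows are disjoint, true read 3'-ends
    concentrated in the -300..+20 window with a mode near -10, and half
    of all reads arising from internal priming at planted A-tracts.
    """

    n_genes: int = 30
    pas_per_gene: tuple[int, int] = (2, 4)
    utr_length_range: tuple[int, int] = (1500, 2600)
    intron_count_range: tuple[int, int] = (1, 2)
    intron_length_range: tuple[int, int] = (100, 400)
    n_databases: int = 3
    db_jitter: int = 3
    db_dropout: float = 0.1
    stages: tuple[str, ...] = ("E9.5", "E10.5", "E11.5", "E12.5", "E13.5")
    clusters: tuple[str, ...] = ("neuron", "blood", "mesenchyme", "epithelium")
    n_cells_per_stage: int = 50
    read_depth: int = 20
    artifact_rate: float = 0.5
    lengthening_nt: float = 75.0
    differential_fraction: float = 0.1
    differential_shift: float = 0.3
    induced_fraction: float = 0.2
    stage_induction: float = 2.0
    neuron_induction: float = 4.0
    a_tract_min_len: int = 6
    a_tract_len: int = 15
    min_pas_gap: int = 350
    min_pas_utr_length: int = 400
    offset_model: str = "geometric"  # or "uniform"
    offset_geom_p: float = 0.05
    window_up: int = 300
    window_down: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.db_dropout, self.artifact_rate, self.differential_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.a_tract_len < self.a_tract_min_len:
            raise ValueError("a_tract_len must be >= a_tract_min_len")
        for lo, hi in (
            self.pas_per_gene,
            self.utr_length_range,
            self.intron_length_range,
        ):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive and ordered")
        if self.offset_model not in ("geometric", "uniform"):
            raise ValueError(f"unknown offset_model {self.offset_model!r}")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed for downstream scoring."""

    pas: dict[str, list[tuple[str, int, str, int, str]]]  # gene -> (id, utr_len, chrom, pos, strand)
    usage: dict[str, dict[str, np.ndarray]]  # gene -> stage -> proportions
    differential: dict[str, bool]
    induced: dict[str, bool]
    expected_mean_length: dict[str, dict[str, float]]
    artifact_loci: dict[str, list[tuple[str, str, int]]]  # gene -> (chrom, strand, end3)
    cells: pd.DataFrame | None = None  # barcode, stage, cluster
    read_origins: list[str] = field(default_factory=list)  # "pas:<gene>:<pas_id>" | "artifact:<gene>:<i>"


@dataclass
class SimAnnotation:
    genome: dict[str, str]
    entries: list[UtrResourceEntry]  # resource entries incl. decoy transcripts
    models: list[UtrModel]  # true representative models with linked PASs
    true_pas: PasSet
    gene_spans: dict[str, tuple[str, int, int, str]]
    truth: GroundTruth
    config: SimConfig


@dataclass
class SimReads:
    reads: list[ReadEnd]
    cells: pd.DataFrame  # barcode, stage, cluster
    origins: list[str]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _place_introns(
    rng: np.random.Generator, spliced_len: int, config: SimConfig
) -> list[tuple[int, int]]:
    """Intron insertion points as (spliced_position, intron_length)."""
    n = int(rng.integers(config.intron_count_range[0], config.intron_count_range[1] + 1))
    if n == 0:
        return []
    # insertion points well inside the UTR, pairwise >= 50 nt apart
    for _ in range(100):
        points = np.sort(rng.integers(60, spliced_len - 60, size=n))
        if n == 1 or np.all(np.diff(points) >= 50):
            break
    lengths = rng.integers(
        config.intron_length_range[0], config.intron_length_range[1] + 1, size=n
    )
    return [(int(p), int(l)) for p, l in zip(points, lengths)]


def _local_blocks(spliced_len: int, introns: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Exon blocks in UTR-local coordinates (0 at the stop codon)."""
    blocks = []
    cursor_local = 0
    prev_spliced = 0
    for point, ilen in introns:
        blocks.append((cursor_local, cursor_local + (point - prev_spliced)))
        cursor_local += (point - prev_spliced) + ilen
        prev_spliced = point
    blocks.append((cursor_local, cursor_local + (spliced_len - prev_spliced)))
    return blocks


def _sample_pas_positions(
    rng: np.random.Generator, spliced_len: int, n_pas: int, config: SimConfig
) -> list[int]:
    lo = config.min_pas_utr_length
    hi = spliced_len - config.window_down - 10
    need = lo + (n_pas - 1) * config.min_pas_gap
    if need > hi:
        raise ValueError(
            f"infeasible geometry: {n_pas} PASs need {need} nt but UTR offers {hi}"
        )
    for _ in range(200):
        pos = np.sort(rng.integers(lo, hi + 1, size=n_pas))
        if n_pas == 1 or np.all(np.diff(pos) >= config.min_pas_gap):
            return [int(p) for p in pos]
    # deterministic fallback: evenly spaced
    return [int(lo + i * config.min_pas_gap) for i in range(n_pas)]


def simulate_annotation(config: SimConfig) -> SimAnnotation:
    """Build the toy genome, gene models, true PAS set, and ground truth.

    Genes alternate strands along a single contig, each with 1-2 introns
    inside the 3'-UTR.  A-tracts are written into every intron (and never
    inside any PAS acceptance window, measured in spliced coordinates),
    providing internal-priming loci.  The same seed reproduces the output
    byte for byte.
    """
    rng = _rng(config, 1)
    chrom = "chrSim"
    pad = 300
    cursor = pad
    entries: list[UtrResourceEntry] = []
    models: list[UtrModel] = []
    pas_records: list[PasRecord] = []
    gene_spans: dict[str, tuple[str, int, int, str]] = {}
    truth_pas: dict[str, list[tuple[str, int, str, int, str]]] = {}
    artifact_loci: dict[str, list[tuple[str, str, int]]] = {}
    usage: dict[str, dict[str, np.ndarray]] = {}
    differential: dict[str, bool] = {}
    induced: dict[str, bool] = {}
    expected_ml: dict[str, dict[str, float]] = {}
    tract_writes: list[tuple[int, int]] = []  # genomic (start, end) to fill with A/T

    n_diff = int(round(config.differential_fraction * config.n_genes))
    n_induced = int(round(config.induced_fraction * config.n_genes))
    diff_genes = set(rng.choice(config.n_genes, size=n_diff, replace=False).tolist())
    induced_genes = set(rng.choice(config.n_genes, size=n_induced, replace=False).tolist())

    for gi in range(config.n_genes):
        gene_id = f"g{gi:03d}"
        strand = "+" if gi % 2 == 0 else "-"
        n_pas = int(rng.integers(config.pas_per_gene[0], config.pas_per_gene[1] + 1))
        need = config.min_pas_utr_length + (n_pas - 1) * config.min_pas_gap + config.window_down + 10
        lo = max(config.utr_length_range[0], need)
        if lo > config.utr_length_range[1]:
            raise ValueError(
                f"infeasible geometry for {gene_id}: need UTR >= {lo} nt, "
                f"max allowed {config.utr_length_range[1]}"
            )
        spliced_len = int(rng.integers(lo, config.utr_length_range[1] + 1))
        introns = _place_introns(rng, spliced_len, config)
        local_blocks = _local_blocks(spliced_len, introns)
        glen = local_blocks[-1][1]
        body_pad = 200  # fake CDS/gene-body padding upstream of the UTR

        if strand == "+":
            utr_start = cursor + body_pad
            blocks = [(utr_start + s, utr_start + e) for s, e in local_blocks]
            stop_codon = blocks[0][0]
            span = (cursor, utr_start + glen)
        else:
            utr_start = cursor
            region_end = utr_start + glen
            blocks = sorted((region_end - e, region_end - s) for s, e in local_blocks)
            stop_codon = region_end - 1
            span = (cursor, region_end + body_pad)
        gene_spans[gene_id] = (chrom, span[0], span[1], strand)
        cursor = span[1] + pad

        entry = UtrResourceEntry(
            gene_id=gene_id,
            transcript_id=f"{gene_id}.t1",
            chrom=chrom,
            strand=strand,
            stop_codon=stop_codon,
            exon_blocks=blocks,
            source="sim_truth",
        )
        entries.append(entry)
        # decoy isoform truncated at half length exercises longest-UTR selection
        half = max(100, spliced_len // 2)
        decoy_blocks = _truncate_blocks(entry, half)
        entries.append(
            replace(
                entry,
                transcript_id=f"{gene_id}.t2",
                exon_blocks=decoy_blocks,
                source="sim_decoy",
            )
        )

        model = UtrModel(
            gene_id=gene_id,
            transcript_id=entry.transcript_id,
            chrom=chrom,
            strand=strand,
            stop_codon=stop_codon,
            exon_blocks=list(blocks),
            source="sim_truth",
        )
        # PASs strictly inside exon blocks, clear of block edges so database
        # jitter cannot push a site into an intron
        pas_spliced = _sample_pas_positions(rng, spliced_len, n_pas, config)
        pas_spliced = _nudge_from_edges(model, pas_spliced, config.db_jitter + 2)
        gene_truth = []
        for pi, sp in enumerate(pas_spliced):
            gpos = model.genomic_position(sp)
            pas_id = f"{gene_id}.p{pi}"
            pas_records.append(
                PasRecord(chrom=chrom, strand=strand, pos=gpos, source="truth", id=pas_id)
            )
            model.linked_pas.append((pas_id, sp))
            gene_truth.append((pas_id, sp, chrom, gpos, strand))
        model.linked_pas.sort(key=lambda t: t[1])
        models.append(model)
        truth_pas[gene_id] = gene_truth

        # internal-priming loci: one A-tract per intron, written on the
        # sense strand just downstream (3') of the artifact read end
        loci: list[tuple[str, str, int]] = []
        for ii, (point, ilen) in enumerate(introns):
            off = min(30, max(1, ilen - config.a_tract_len - 2))
            local_start = local_blocks[ii][1]  # intron ii begins where block ii ends
            if strand == "+":
                t0 = utr_start + local_start + off
                tract_writes.append((t0, t0 + config.a_tract_len))
                loci.append((chrom, strand, t0 - 1))
            else:
                region_end = utr_start + glen
                # local t maps to genomic region_end-1-t; the tract runs
                # 3' of the read end, i.e. to lower genomic coordinates
                g_hi = region_end - 1 - (local_start + off)
                tract_writes.append((g_hi - config.a_tract_len + 1, g_hi + 1))
                loci.append((chrom, strand, g_hi + 1))
        artifact_loci[gene_id] = loci

        # per-stage PAS usage with planted lengthening and differential shift
        lengths = np.array([sp for _, sp in model.linked_pas], dtype=float)
        usage[gene_id], expected_ml[gene_id] = _usage_for_gene(
            rng, lengths, config, strong=gi in diff_genes
        )
        differential[gene_id] = gi in diff_genes
        induced[gene_id] = gi in induced_genes

    genome_len = cursor + pad
    seq = rng.choice(BASES, size=genome_len)
    for start, end in tract_writes:
        seq[start:end] = "A"  # sense-strand A for '+' loci
    genome = {"chrSim": "".join(seq)}
    # minus-strand tracts must read as A on the sense strand = T on reference
    seq_list = list(genome["chrSim"])
    for gene_id, loci in artifact_loci.items():
        for chrom_, strand, end3 in loci:
            if strand == "-":
                lo = end3 - config.a_tract_len
                for i in range(max(lo, 0), end3):
                    seq_list[i] = "T"
    genome = {"chrSim": "".join(seq_list)}

    truth = GroundTruth(
        pas=truth_pas,
        usage=usage,
        differential=differential,
        induced=induced,
        expected_mean_length=expected_ml,
        artifact_loci=artifact_loci,
    )
    return SimAnnotation(
        genome=genome,
        entries=entries,
        models=models,
        true_pas=PasSet(records=pas_records, provenance=["truth"]),
        gene_spans=gene_spans,
        truth=truth,
        config=config,
    )


def _truncate_blocks(entry: UtrResourceEntry, spliced_len: int) -> list[tuple[int, int]]:
    """First ``spliced_len`` spliced nt of an entry's blocks (transcript order)."""
    out: list[tuple[int, int]] = []
    remaining = spliced_len
    blocks = entry.exon_blocks if entry.strand == "+" else list(reversed(entry.exon_blocks))
    for s, e in blocks:
        size = e - s
        take = min(size, remaining)
        if entry.strand == "+":
            out.append((s, s + take))
        else:
            out.append((e - take, e))
        remaining -= take
        if remaining <= 0:
            break
    return sorted(out)


def _nudge_from_edges(model: UtrModel, pas_spliced: list[int], margin: int) -> list[int]:
    """Shift spliced PAS positions so each sits >= margin nt from block edges."""
    out = []
    for sp in pas_spliced:
        adj = sp
        for _ in range(margin * 2 + 2):
            gpos = model.genomic_position(adj)
            inside = any(
                s + margin <= gpos < e - margin for s, e in model.exon_blocks
            )
            if inside:
                break
            adj += 1
        out.append(adj)
    return out


def _usage_for_gene(
    rng: np.random.Generator,
    lengths: np.ndarray,
    config: SimConfig,
    strong: bool,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Per-stage PAS proportions implementing the planted lengthening."""
    k = len(lengths)
    base = rng.dirichlet(np.full(k, 2.0))
    # proximal-leaning and distal-leaning mixtures sharing the same support
    order = np.argsort(lengths)
    proximal = np.sort(base)[::-1][np.argsort(order)]  # big mass on short PASs
    distal = proximal[::-1].copy() if k > 1 else proximal.copy()
    m0 = float(proximal @ lengths)
    m1 = float(distal @ lengths)
    usage: dict[str, np.ndarray] = {}
    expected: dict[str, float] = {}
    n_stages = len(config.stages)
    for si, stage in enumerate(config.stages):
        if m1 > m0 and config.lengthening_nt > 0:
            w = min(1.0, si * config.lengthening_nt / (m1 - m0))
        else:
            w = 0.0
        p = (1 - w) * proximal + w * distal
        if strong and k > 1:
            # abrupt extra proximal->distal shift ramped across stages
            shift = config.differential_shift * si / max(1, n_stages - 1)
            shift = min(shift, p[0] * 0.95)
            p = p.copy()
            p[0] -= shift
            p[-1] += shift
        p = p / p.sum()
        usage[stage] = p
        expected[stage] = float(p @ lengths)
    return usage, expected


def simulate_databases(
    true_pas: PasSet, config: SimConfig
) -> list[PasSet]:
    """Derive jittered, lossy annotation databases from the true PAS set.

    Each database keeps every true site with probability 1 - db_dropout
    and perturbs its position by a uniform jitter within +/- db_jitter nt.
    """
    rng = _rng(config, 2)
    out: list[PasSet] = []
    for di in range(config.n_databases):
        source = f"db{di + 1}"
        records: list[PasRecord] = []
        for rec in true_pas.records:
            if rng.random() < config.db_dropout:
                continue
            jitter = int(rng.integers(-config.db_jitter, config.db_jitter + 1))
            records.append(
                PasRecord(
                    chrom=rec.chrom,
                    strand=rec.strand,
                    pos=max(0, rec.pos + jitter),
                    source=source,
                    id=f"{source}:{rec.id}",
                )
            )
        out.append(PasSet(records=records, provenance=[source]))
    return out


def _draw_offset(rng: np.random.Generator, config: SimConfig) -> int:
    """True-read 3'-end offset relative to its PAS, in spliced nt.

    Truncated geometric with mode at -10 falling off upstream (most reads
    slightly upstream of the cleavage site), with a small uniform
    component over (-10, +20]; or fully uniform over [-300, +20].
    """
    if config.offset_model == "uniform":
        return int(rng.integers(-config.window_up, config.window_down + 1))
    if rng.random() < 0.1:
        return int(rng.integers(-9, config.window_down + 1))
    g = int(rng.geometric(config.offset_geom_p)) - 1
    return -10 - min(g, config.window_up - 10)


def simulate_reads(annotation: SimAnnotation, config: SimConfig | None = None) -> SimReads:
    """Generate barcoded read 3'-ends plus cell labels and per-read origins.

    Cells are laid out as ``n_cells_per_stage`` per stage with cluster
    labels assigned round-robin.  Each read is an internal-priming
    artifact with probability ``artifact_rate`` (3'-end at a planted
    A-tract locus of the chosen gene) and otherwise a true 3'-end drawn
    from the cell's stage usage vector with a windowed offset.
    """
    config = config or annotation.config
    rng = _rng(config, 3)
    models = {m.gene_id: m for m in annotation.models}
    genes = sorted(models)
    truth = annotation.truth

    # per-(stage, cluster) gene sampling weights with planted induction
    stage_idx = {s: i for i, s in enumerate(config.stages)}
    base_w = rng.lognormal(mean=0.0, sigma=0.4, size=len(genes))

    cells: list[tuple[str, str, str]] = []
    ci = 0
    for stage in config.stages:
        for _ in range(config.n_cells_per_stage):
            cluster = config.clusters[ci % len(config.clusters)]
            cells.append((f"CELL{ci:05d}", stage, cluster))
            ci += 1

    reads: list[ReadEnd] = []
    origins: list[str] = []
    n_stages = len(config.stages)
    weight_cache: dict[tuple[str, str], np.ndarray] = {}
    for barcode, stage, cluster in cells:
        key = (stage, cluster)
        if key not in weight_cache:
            w = base_w.copy()
            for gi, gene in enumerate(genes):
                if truth.induced[gene]:
                    frac = stage_idx[stage] / max(1, n_stages - 1)
                    w[gi] *= config.stage_induction**frac
                    if cluster.startswith("neuron"):
                        w[gi] *= config.neuron_induction
            weight_cache[key] = w / w.sum()
        weights = weight_cache[key]
        gene_draws = rng.choice(len(genes), size=config.read_depth, p=weights)
        for gi in gene_draws:
            gene = genes[gi]
            model = models[gene]
            if rng.random() < config.artifact_rate and truth.artifact_loci[gene]:
                loci = truth.artifact_loci[gene]
                li = int(rng.integers(len(loci)))
                chrom, strand, end3 = loci[li]
                origin = f"artifact:{gene}:{li}"
            else:
                p = truth.usage[gene][stage]
                pi = int(rng.choice(len(p), p=p))
                pas_id, utr_len = model.linked_pas[pi]
                off = _draw_offset(rng, config)
                spliced = utr_len + off
                spliced = int(np.clip(spliced, 0, model.spliced_length - 1))
                chrom, strand = model.chrom, model.strand
                end3 = model.genomic_position(spliced)
                origin = f"pas:{gene}:{pas_id}"
            reads.append(
                ReadEnd(
                    chrom=chrom,
                    strand=strand,
                    end3=end3,
                    barcode=barcode,
                    umi=f"r{len(reads):07d}",
                )
            )
            origins.append(origin)

    cells_df = pd.DataFrame(cells, columns=["barcode", "stage", "cluster"])
    truth.cells = cells_df
    truth.read_origins = origins
    return SimReads(reads=reads, cells=cells_df, origins=origins)


def simulate_null_tables(
    n_genes: int = 5000,
    n_groups: int = 5,
    depth: int = 500,
    n_pas: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Null PAS x group tables: identical multinomial proportions per gene.

    Each gene draws one Dirichlet proportion vector shared by all groups;
    every group then samples a multinomial of size ``depth``.  Used to
    check false-discovery calibration of the chi-square screen.  Returns
    an array of shape (n_genes, n_pas, n_groups).
    """
    rng = np.random.default_rng(seed)
    out = np.empty((n_genes, n_pas, n_groups), dtype=np.int64)
    for gi in range(n_genes):
        p = rng.dirichlet(np.full(n_pas, 2.0))
        out[gi] = rng.multinomial(depth, p, size=n_groups).T
    return out


def simulate_shifted_tables(
    n_genes: int = 5000,
    n_groups: int = 5,
    depth: int = 500,
    n_pas: int = 4,
    shift: float = 0.3,
    differential_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Tables with a proximal->distal usage shift planted in a gene subset.

    Differential genes move ``shift`` of proportion mass from the most
    proximal to the most distal PAS, ramped linearly across groups; the
    rest are null.  Returns (tables, is_differential flags).
    """
    rng = np.random.default_rng(seed)
    tables = np.empty((n_genes, n_pas, n_groups), dtype=np.int64)
    flags = np.zeros(n_genes, dtype=bool)
    n_diff = int(round(differential_fraction * n_genes))
    diff_idx = rng.choice(n_genes, size=n_diff, replace=False)
    flags[diff_idx] = True
    for gi in range(n_genes):
        base = rng.dirichlet(np.full(n_pas, 2.0))
        for grp in range(n_groups):
            p = base.copy()
            if flags[gi]:
                s = shift * grp / max(1, n_groups - 1)
                s = min(s, p[0] * 0.95)
                p[0] -= s
                p[-1] += s
                p = p / p.sum()
            tables[gi, :, grp] = rng.multinomial(depth, p)
    return tables, flags


def simulate_dataset(config: SimConfig) -> tuple[SimAnnotation, list[PasSet], SimReads]:
    """One-call convenience wrapper: annotation + databases + reads."""
    ann = simulate_annotation(config)
    dbs = simulate_databases(ann.true_pas, config)
    reads = simulate_reads(ann, config)
    return ann, dbs, reads
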