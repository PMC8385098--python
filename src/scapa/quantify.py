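"""APA quantification: count tables, inclusion profiles, lengths, entropy.

The central object is the :class:`PasCountTable`, a long-format tally of
reads per (gene, PAS, group) where a group may be a single cell, a
developmental stage, a cluster, or a trajectory bin.  From it derive the
isoform inclusion rate (IIR, a survival-curve-like step function over the
spliced 3'-UTR), count-weighted mean UTR lengths, per-cell deviation
scores, per-gene entropy, and counts-per-million expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import UtrModel
from .reads import ReadEnd

logger = logging.getLogger(__name__)

GROUP_KINDS = ("cell", "stage", "cluster", "trajectory_bin")

__all__ = [
    "PasCountTable",
    "IirProfile",
    "QuantConfig",
    "build_count_table",
    "compute_iir",
    "weighted_mean_length",
    "build_length_matrix",
    "deviation_matrix",
    "cell_score",
    "aggregate_matrix_by_label",
    "aggregate_scores_by_label",
    "pas_entropy",
    "iir_mad",
    "gene_expression_cpm",
]


@dataclass
class QuantConfig:
    """Thresholds and conventions of the quantification stage."""

    min_cells_per_bin: int = 20
    min_reads_stage: int = 100
    min_reads_cluster: int = 20
    entropy_log_base: float = 2.0
    cpm_log_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if min(self.min_cells_per_bin, self.min_reads_stage, self.min_reads_cluster) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class PasCountTable:
    """Long-format read counts per (gene, PAS, group).

    ``data`` columns: gene_id, pas_id, utr_length, group, count.  Within a
    gene, PASs are ordered by ascending utr_length.
    """

    data: pd.DataFrame
    group_kind: str = "cell"

    COLUMNS = ("gene_id", "pas_id", "utr_length", "group", "count")

    def __post_init__(self) -> None:
        if self.group_kind not in GROUP_KINDS:
            raise ValueError(f"unknown group_kind {self.group_kind!r}")
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"count table missing columns {sorted(missing)}")
        if len(self.data) and (self.data["count"] < 0).any():
            raise ValueError("counts must be >= 0")
        self.data = (
            self.data.loc[:, list(self.COLUMNS)]
            .astype({"utr_length": int, "count": int})
            .sort_values(["gene_id", "utr_length", "group"], kind="stable")
            .reset_index(drop=True)
        )

    @property
    def total(self) -> int:
        return int(self.data["count"].sum())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene_id"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    def gene_matrix(self, gene_id: str) -> pd.DataFrame:
        """PAS x group count matrix of one gene (rows ascending utr_length)."""
        sub = self.data[self.data["gene_id"] == gene_id]
        mat = (
            sub.pivot_table(
                index=["utr_length", "pas_id"],
                columns="group",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .sort_index()
        )
        mat.columns.name = None
        return mat

    def gene_counts(self, gene_id: str, group: str | None = None) -> dict[int, int]:
        """utr_length -> count for one gene, optionally restricted to a group."""
        sub = self.data[self.data["gene_id"] == gene_id]
        if group is not None:
            sub = sub[sub["group"] == group]
        return sub.groupby("utr_length")["count"].sum().to_dict()

    def regroup(self, mapping: Mapping[str, str], group_kind: str) -> "PasCountTable":
        """Aggregate groups through ``mapping`` (e.g. cell barcode -> stage)."""
        data = self.data.copy()
        data["group"] = data["group"].map(mapping)
        dropped = int(data["group"].isna().sum())
        if dropped:
            logger.info("regroup: dropped %d rows with unmapped groups", dropped)
            data = data.dropna(subset=["group"])
        data = (
            data.groupby(["gene_id", "pas_id", "utr_length", "group"], as_index=False)[
                "count"
            ].sum()
        )
        return PasCountTable(data=data, group_kind=group_kind)

    def filter_genes_min_reads(self, min_reads: int) -> "PasCountTable":
        """Keep genes with >= min_reads in every group (group set = all groups)."""
        per = self.data.pivot_table(
            index="gene_id", columns="group", values="count", aggfunc="sum", fill_value=0
        )
        keep = per.index[(per >= min_reads).all(axis=1)]
        return PasCountTable(
            data=self.data[self.data["gene_id"].isin(keep)].copy(),
            group_kind=self.group_kind,
        )


def build_count_table(
    assigned: Sequence[tuple[ReadEnd, str, str]],
    utrs: Mapping[str, UtrModel] | Sequence[UtrModel],
    cell_labels: Mapping[str, str] | None = None,
    group_kind: str = "cell",
) -> PasCountTable:
    """Tally assigned reads into a (gene, PAS, group) count table.

    With ``cell_labels`` absent each barcode is its own group; otherwise
    barcodes are mapped through the labels and unlabeled reads are dropped
    (with a logged count).
    """
    if group_kind not in GROUP_KINDS:
        raise ValueError(f"unknown group_kind {group_kind!r}")
    models = (
        {m.gene_id: m for m in utrs} if not isinstance(utrs, Mapping) else dict(utrs)
    )
    lengths = {
        (gene_id, pas_id): utr_len
        for gene_id, model in models.items()
        for pas_id, utr_len in model.linked_pas
    }
    rows: list[tuple[str, str, int, str]] = []
    dropped = 0
    for read, gene_id, pas_id in assigned:
        if cell_labels is None:
            group = read.barcode
        else:
            group = cell_labels.get(read.barcode)
            if group is None:
                dropped += 1
                continue
        rows.append((gene_id, pas_id, lengths[(gene_id, pas_id)], group))
    if dropped:
        logger.info("build_count_table: dropped %d reads with unlabeled barcodes", dropped)
    if not rows:
        data = pd.DataFrame(columns=list(PasCountTable.COLUMNS))
        return PasCountTable(data=data, group_kind=group_kind)
    df = pd.DataFrame(rows, columns=["gene_id", "pas_id", "utr_length", "group"])
    data = df.groupby(["gene_id", "pas_id", "utr_length", "group"], as_index=False).size()
    data = data.rename(columns={"size": "count"})
    return PasCountTable(data=data, group_kind=group_kind)


@dataclass
class IirProfile:
    """Isoform inclusion rate: fraction of 3'-end reads whose isoform
    extends at least to each position of the spliced 3'-UTR.

    ``values[i]`` is the IIR on the open-closed interval
    (breakpoints[i], breakpoints[i+1]] — i.e. just after the i-th PAS; the
    profile is 1 on [1, breakpoints[0]] and 0 beyond the last breakpoint.
    """

    gene_id: str
    breakpoints: np.ndarray  # ascending PAS utr_lengths
    values: np.ndarray  # IIR after each breakpoint; values[-1] == 0
    spliced_length: int | None = None

    def at(self, positions) -> np.ndarray:
        """Evaluate the IIR at integer position(s) along the spliced UTR."""
        pos = np.atleast_1d(np.asarray(positions))
        levels = np.concatenate(([1.0], self.values))
        # p <= bp[0] -> 1; bp[i-1] < p <= bp[i] -> values[i-1]; p > bp[-1] -> 0
        idx = np.searchsorted(self.breakpoints, pos, side="left")
        out = levels[idx]
        return out if np.ndim(positions) else float(out[0])

    @property
    def mean_length(self) -> float:
        """Discrete integral of the IIR over p = 1..max breakpoint."""
        widths = np.diff(np.concatenate(([0], self.breakpoints)))
        levels = np.concatenate(([1.0], self.values[:-1]))
        return float(np.sum(widths * levels))


def compute_iir(gene_counts: Mapping[int, int], gene_id: str = "",
                spliced_length: int | None = None) -> IirProfile | None:
    """Build the IIR step profile from utr_length -> count of one gene.

    Returns None when the gene has no assigned reads (IIR undefined).
    A read at a PAS of length L still includes position L, so the drop
    happens just after each breakpoint.
    """
    items = sorted((int(l), int(c)) for l, c in gene_counts.items())
    total = sum(c for _, c in items)
    if total <= 0:
        return None
    bps = np.array([l for l, _ in items], dtype=np.int64)
    counts = np.array([c for _, c in items], dtype=np.float64)
    suffix = np.concatenate((np.cumsum(counts[::-1])[::-1][1:], [0.0]))
    return IirProfile(
        gene_id=gene_id,
        breakpoints=bps,
        values=suffix / total,
        spliced_length=spliced_length,
    )


def weighted_mean_length(gene_counts: Mapping[int, int]) -> float | None:
    """Count-weighted mean 3'-UTR isoform length; None when no reads."""
    total = sum(gene_counts.values())
    if total <= 0:
        return None
    return sum(l * c for l, c in gene_counts.items()) / total


def build_length_matrix(table: PasCountTable) -> pd.DataFrame:
    """Gene x group matrix of weighted mean lengths (NaN = no reads)."""
    data = table.data
    if not len(data):
        return pd.DataFrame()
    weighted = data.assign(wl=data["utr_length"] * data["count"])
    num = weighted.pivot_table(
        index="gene_id", columns="group", values="wl", aggfunc="sum"
    )
    den = weighted.pivot_table(
        index="gene_id", columns="group", values="count", aggfunc="sum"
    )
    out = num / den
    out.columns.name = None
    return out


def deviation_matrix(lengths: pd.DataFrame) -> pd.DataFrame:
    """Center each gene row on its mean over nonmissing cells."""
    return lengths.sub(lengths.mean(axis=1, skipna=True), axis=0)


def cell_score(deviations: pd.DataFrame) -> pd.Series:
    """Per-cell mean deviation across genes (NaN for all-missing cells)."""
    return deviations.mean(axis=0, skipna=True)


def aggregate_matrix_by_label(
    deviations: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Gene x group mean deviations, masking bins with < min_cells cells.

    A (gene, group) bin contributes only the cells with nonmissing values;
    bins with fewer than ``min_cells`` such cells are reported missing.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    cols = [c for c in deviations.columns if c in labels.index]
    sub = deviations.loc[:, cols]
    groups = labels.loc[cols]
    means = sub.T.groupby(groups).mean().T
    counts = sub.notna().T.groupby(groups).sum().T
    return means.where(counts >= min_cells)


def aggregate_scores_by_label(
    scores: pd.Series,
    labels: Mapping[str, str] | pd.Series,
    min_cells: int = 20,
) -> pd.Series:
    """Group means of per-cell scores, masking groups with < min_cells cells."""
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    idx = [c for c in scores.index if c in labels.index]
    sub = scores.loc[idx]
    groups = labels.loc[idx]
    means = sub.groupby(groups).mean()
    counts = sub.notna().groupby(groups).sum()
    return means.where(counts >= min_cells)


def pas_entropy(gene_counts: Mapping[int, int] | Mapping[str, int],
                base: float = 2.0) -> float | None:
    """Shannon entropy of a gene's PAS usage proportions (bits by default)."""
    counts = np.array([c for c in gene_counts.values() if c > 0], dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        return None
    p = counts / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def iir_mad(a: IirProfile, b: IirProfile) -> float:
    """Mean absolute deviation between two IIR profiles of the same gene.

    Averaged per nucleotide over p = 1..spliced_length of the gene model
    (the shared extent), yielding a value in [0, 1].
    """
    if a.gene_id != b.gene_id:
        raise ValueError(f"profiles compare different genes: {a.gene_id!r} vs {b.gene_id!r}")
    length = a.spliced_length or b.spliced_length
    if length is None:
        length = int(max(a.breakpoints[-1], b.breakpoints[-1]))
    cuts = np.unique(
        np.concatenate(([0], a.breakpoints, b.breakpoints, [length]))
    )
    cuts = cuts[cuts <= length]
    total = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        # IIR constant on (lo, hi]; evaluate at hi
        total += abs(a.at(int(hi)) - b.at(int(hi))) * (hi - lo)
    return total / length


def gene_expression_cpm(
    table: PasCountTable, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene expression from PAS-assigned reads, per group.

    Gene counts sum the reads of all unique PAS coordinates of the gene;
    cpm normalizes each group to one million; log2 is taken on
    (cpm + pseudocount).  Returns (counts, cpm, log2cpm), genes x groups.
    """
    counts = table.data.pivot_table(
        index="gene_id", columns="group", values="count", aggfunc="sum", fill_value=0
    )
    counts.columns.name = None
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"groups with zero total counts: {zero}")
    cpm = counts * 1e6 / totals
    log2cpm = np.log2(cpm + pseudocount)
    return counts, cpm, log2cpm
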