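"""Shared interval lookups over gene models."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .annotation import UtrModel


@dataclass
class BlockIndex:
    """Strand-aware interval index from UTR exon blocks to gene ids."""

    trees: dict[tuple[str, str], IntervalTree]

    @classmethod
    def from_models(cls, models: Sequence[UtrModel]) -> "BlockIndex":
        trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        for model in models:
            tree = trees[(model.chrom, model.strand)]
            for start, end in model.exon_blocks:
                tree.addi(start, end, model.gene_id)
        return cls(trees=dict(trees))

    def genes_at(self, chrom: str, strand: str, pos: int) -> list[str]:
        """Distinct gene ids whose UTR blocks contain ``pos`` (sorted)."""
        tree = self.trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.at(pos)})
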