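"""Differential APA statistics and the RBP expression screen.

Gene-level and per-PAS chi-square tests of homogeneity on (PAS x group)
contingency tables, Benjamini-Hochberg FDR across genes, one-way ANOVA and
Wilcoxon rank-sum helpers with Bonferroni correction, and the screen for
RNA-binding proteins co-induced across developmental time and in neuronal
cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import PasCountTable, gene_expression_cpm

__all__ = [
    "ChiSqResult",
    "PerPasResult",
    "RbpScreenResult",
    "expected_counts",
    "chisq_gene",
    "chisq_per_pas",
    "chisq_table",
    "bh_fdr",
    "anova_bonferroni",
    "wilcoxon_rank_sum",
    "rbp_screen",
]


def expected_counts(observed: np.ndarray) -> np.ndarray:
    """Expected counts under homogeneity: outer product of the marginals.

    E[i, j] = row_i total * col_j total / grand total; preserves both
    marginals exactly.
    """
    obs = np.asarray(observed, dtype=np.float64)
    total = obs.sum()
    if total <= 0:
        raise ValueError("expected_counts requires a table with positive total")
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total


@dataclass
class PerPasResult:
    pas_id: str
    statistic: float
    df: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class ChiSqResult:
    """Chi-square homogeneity test of one gene's PAS x group table."""

    gene_id: str
    statistic: float
    df: int
    p_value: float
    per_pas: list[PerPasResult] = field(default_factory=list)
    q_value: float | None = None
    reason: str | None = None  # set when the table was degenerate

    @property
    def ok(self) -> bool:
        return self.reason is None


def _clean_table(observed: np.ndarray) -> np.ndarray:
    obs = np.asarray(observed, dtype=np.float64)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    return obs


def chisq_table(observed: np.ndarray, flat_df: bool = False) -> tuple[float, int, float]:
    """Chi-square statistic, df and upper-tail p for a cleaned table.

    The statistic is the cellwise sum of (O - E)^2 / E with E from
    :func:`expected_counts`.  df is the classical contingency
    (r-1)(c-1) by default; ``flat_df`` switches to r*c - 1, the df of a
    one-sample test applied to the flattened table with supplied expected
    counts.
    """
    obs = np.asarray(observed, dtype=np.float64)
    exp = expected_counts(obs)
    stat = float(((obs - exp) ** 2 / exp).sum())
    r, c = obs.shape
    df = r * c - 1 if flat_df else (r - 1) * (c - 1)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else float("nan")
    return stat, df, p


def chisq_gene(
    observed: np.ndarray,
    gene_id: str = "",
    flat_df: bool = False,
    per_pas_ids: Sequence[str] | None = None,
) -> ChiSqResult:
    """Gene-level chi-square homogeneity test across groups.

    Zero-total rows and columns are dropped first; a table left with
    fewer than 2 rows or columns is reported degenerate rather than
    tested.  When ``per_pas_ids`` is given the per-PAS decomposition is
    attached (see :func:`chisq_per_pas`).
    """
    obs = _clean_table(observed)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return ChiSqResult(
            gene_id=gene_id,
            statistic=float("nan"),
            df=0,
            p_value=float("nan"),
            reason=f"degenerate table of shape {obs.shape}",
        )
    stat, df, p = chisq_table(obs, flat_df=flat_df)
    result = ChiSqResult(gene_id=gene_id, statistic=stat, df=df, p_value=p)
    if per_pas_ids is not None:
        result.per_pas = chisq_per_pas(observed, per_pas_ids)
    return result


def chisq_per_pas(
    observed: np.ndarray, pas_ids: Sequence[str] | None = None
) -> list[PerPasResult]:
    """Per-PAS (per-row) chi-square against the column-margin expectation.

    Each row's statistic is its share of the gene statistic's cellwise
    sum, tested on c - 1 degrees of freedom; zero-total rows are skipped.
    """
    obs = np.asarray(observed, dtype=np.float64)
    obs = obs[:, obs.sum(axis=0) > 0]
    if pas_ids is None:
        pas_ids = [str(i) for i in range(obs.shape[0])]
    if len(pas_ids) != obs.shape[0]:
        raise ValueError("pas_ids length must match table rows")
    total = obs.sum()
    if total <= 0:
        return []
    exp = expected_counts(obs)
    out: list[PerPasResult] = []
    c = obs.shape[1]
    for i, pas_id in enumerate(pas_ids):
        if obs[i].sum() <= 0:
            continue
        stat = float(((obs[i] - exp[i]) ** 2 / exp[i]).sum())
        df = c - 1
        out.append(
            PerPasResult(
                pas_id=pas_id,
                statistic=stat,
                df=df,
                p_value=float(sps.chi2.sf(stat, df)),
            )
        )
    return out


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def anova_bonferroni(
    groups: Sequence[Sequence[float]], m_tests: int = 1
) -> tuple[float, float, float]:
    """One-way ANOVA F test with Bonferroni-adjusted p (capped at 1).

    Returns (F, p, p_adj); all NaN when any group has < 2 values or there
    are < 2 groups.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        return float("nan"), float("nan"), float("nan")
    f, p = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p), float(min(1.0, p * m_tests))


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], m_tests: int = 1
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p and its Bonferroni adjustment.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's method='auto').
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0, 1.0
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    return p, float(min(1.0, p * m_tests))


@dataclass
class RbpScreenResult:
    """Output of the RBP regulator screen."""

    table: pd.DataFrame
    pearson_r: float
    spearman_rho: float
    n_tested: int


def rbp_screen(
    stage_table: PasCountTable,
    cluster_table: PasCountTable,
    rbp_genes: Sequence[str],
    neuron_clusters: Sequence[str],
    min_cpm: float = 2.0,
    pseudocount: float = 1.0,
    first_stage: str | None = None,
    last_stage: str | None = None,
) -> RbpScreenResult:
    """Screen RNA-binding proteins for coordinated expression changes.

    For each RBP passing the expression filter (>= ``min_cpm`` cpm in at
    least one stage or cluster sample) computes:

    * ``log2fc_stage`` — log2 cpm at the last stage minus the first;
    * ``log2fc_neuron`` — mean log2 cpm over neuronal clusters minus the
      mean over all other clusters;
    * a chi-square homogeneity p on the 2 x n_stages table of this RBP's
      PAS-mapping counts versus all other RBPs' counts (Bonferroni
      adjusted over tested RBPs);
    * a two-sided Wilcoxon rank-sum p comparing neuronal vs other
      cluster log2 cpm (Bonferroni adjusted).

    Also reports the Pearson and Spearman correlation between the two
    fold-change axes over tested RBPs.
    """
    if not rbp_genes:
        raise ValueError("rbp_genes must be nonempty")
    neuron_clusters = list(neuron_clusters)
    if not neuron_clusters:
        raise ValueError("at least one neuronal cluster must be declared")

    stage_counts, stage_cpm, stage_log2 = gene_expression_cpm(stage_table, pseudocount)
    _, cluster_cpm, cluster_log2 = gene_expression_cpm(cluster_table, pseudocount)

    stages = list(stage_counts.columns)
    first_stage = first_stage or stages[0]
    last_stage = last_stage or stages[-1]
    missing = set(neuron_clusters) - set(cluster_cpm.columns)
    if missing:
        raise ValueError(f"neuron clusters absent from cluster table: {sorted(missing)}")
    other_clusters = [c for c in cluster_cpm.columns if c not in neuron_clusters]
    if not other_clusters:
        raise ValueError("no non-neuronal clusters to compare against")

    rbps = [g for g in rbp_genes if g in stage_cpm.index or g in cluster_cpm.index]
    passing = []
    for gene in rbps:
        vals = []
        if gene in stage_cpm.index:
            vals.append(stage_cpm.loc[gene].max())
        if gene in cluster_cpm.index:
            vals.append(cluster_cpm.loc[gene].max())
        if vals and max(vals) >= min_cpm:
            passing.append(gene)

    rbp_stage_counts = stage_counts.reindex(passing, fill_value=0)
    all_rbp_totals = rbp_stage_counts.sum(axis=0)
    m = len(passing)
    rows = []
    for gene in passing:
        s_cpm = stage_cpm.loc[gene] if gene in stage_cpm.index else pd.Series(0.0, index=stages)
        fc_stage = float(
            np.log2(s_cpm[last_stage] + pseudocount) - np.log2(s_cpm[first_stage] + pseudocount)
        )
        if gene in cluster_log2.index:
            neuron_vals = cluster_log2.loc[gene, neuron_clusters].to_numpy(dtype=float)
            other_vals = cluster_log2.loc[gene, other_clusters].to_numpy(dtype=float)
        else:
            neuron_vals = np.full(len(neuron_clusters), np.log2(pseudocount))
            other_vals = np.full(len(other_clusters), np.log2(pseudocount))
        fc_neuron = float(neuron_vals.mean() - other_vals.mean())

        own = rbp_stage_counts.loc[gene].to_numpy(dtype=float)
        others = (all_rbp_totals - rbp_stage_counts.loc[gene]).to_numpy(dtype=float)
        chi = chisq_gene(np.vstack([own, others]), gene_id=gene)
        chisq_p = chi.p_value if chi.ok else float("nan")
        chisq_p_adj = min(1.0, chisq_p * m) if chi.ok else float("nan")
        wil_p, wil_p_adj = wilcoxon_rank_sum(neuron_vals, other_vals, m_tests=m)
        rows.append(
            {
                "gene_id": gene,
                "is_rbp": True,
                "passes_expression": True,
                "log2fc_stage": fc_stage,
                "log2fc_neuron": fc_neuron,
                "chisq_p": chisq_p,
                "chisq_p_adj": chisq_p_adj,
                "wilcoxon_p": wil_p,
                "wilcoxon_p_adj": wil_p_adj,
            }
        )
    table = pd.DataFrame(rows)
    if (
        len(table) >= 2
        and table["log2fc_stage"].std() > 0
        and table["log2fc_neuron"].std() > 0
    ):
        pear = float(sps.pearsonr(table["log2fc_stage"], table["log2fc_neuron"])[0])
        spear = float(sps.spearmanr(table["log2fc_stage"], table["log2fc_neuron"])[0])
    else:
        pear = spear = float("nan")
    return RbpScreenResult(table=table, pearson_r=pear, spearman_rho=spear, n_tested=m)
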