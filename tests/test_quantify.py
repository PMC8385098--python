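"""Count tables, IIR profiles, length/deviation matrices, entropy, cpm."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scapa.quantify import (
    PasCountTable,
    aggregate_matrix_by_label,
    aggregate_scores_by_label,
    build_count_table,
    build_length_matrix,
    cell_score,
    compute_iir,
    deviation_matrix,
    gene_expression_cpm,
    iir_mad,
    pas_entropy,
    weighted_mean_length,
)
from scapa.reads import ReadEnd
from conftest import make_model


def table_from_rows(rows, group_kind="stage"):
    df = pd.DataFrame(rows, columns=["gene_id", "pas_id", "utr_length", "group", "count"])
    return PasCountTable(df, group_kind=group_kind)


class TestBuildCountTable:
    def _assigned(self):
        model = make_model(blocks=((0, 3000),), linked=[("p0", 400), ("p1", 900)])
        reads = [
            (ReadEnd("chr1", "+", 390, "c1"), "gA", "p0"),
            (ReadEnd("chr1", "+", 395, "c1"), "gA", "p0"),
            (ReadEnd("chr1", "+", 890, "c2"), "gA", "p1"),
            (ReadEnd("chr1", "+", 880, "c3"), "gA", "p1"),
        ]
        return model, reads

    def test_manual_tally_by_stage(self):
        model, reads = self._assigned()
        labels = {"c1": "E9.5", "c2": "E13.5", "c3": "E13.5"}
        table = build_count_table(reads, [model], labels, group_kind="stage")
        mat = table.gene_matrix("gA")
        assert mat.loc[(400, "p0"), "E9.5"] == 2
        assert mat.loc[(900, "p1"), "E13.5"] == 2
        assert table.total == 4

    def test_unlabeled_barcodes_dropped(self):
        model, reads = self._assigned()
        table = build_count_table(reads, [model], {"c1": "E9.5"}, group_kind="stage")
        assert table.total == 2

    def test_empty_assignments(self):
        model, _ = self._assigned()
        table = build_count_table([], [model], {}, group_kind="stage")
        assert table.total == 0 and len(table.data) == 0

    def test_cell_table_regroups_to_stage_table(self):
        model, reads = self._assigned()
        labels = {"c1": "E9.5", "c2": "E13.5", "c3": "E13.5"}
        by_cell = build_count_table(reads, [model], None, group_kind="cell")
        by_stage = build_count_table(reads, [model], labels, group_kind="stage")
        regrouped = by_cell.regroup(labels, "stage")
        pd.testing.assert_frame_equal(regrouped.data, by_stage.data)

    def test_unknown_group_kind(self):
        with pytest.raises(ValueError):
            build_count_table([], [], {}, group_kind="banana")


class TestIir:
    def test_two_pas_profile(self):
        prof = compute_iir({100: 3, 400: 1})
        assert prof.at(1) == 1.0
        assert prof.at(100) == 1.0
        assert prof.at(101) == 0.25
        assert prof.at(400) == 0.25
        assert prof.at(401) == 0.0

    def test_single_pas_step(self):
        prof = compute_iir({250: 10})
        assert prof.at(250) == 1.0 and prof.at(251) == 0.0

    def test_equal_counts_uniform_steps(self):
        prof = compute_iir({100: 5, 200: 5, 300: 5, 400: 5})
        assert np.allclose(prof.values, [0.75, 0.5, 0.25, 0.0])

    def test_zero_total_is_missing(self):
        assert compute_iir({100: 0}) is None

    @given(
        counts=st.dictionaries(
            st.integers(1, 500), st.integers(0, 50), min_size=1, max_size=8
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_bounded_and_integral_identity(self, counts):
        if sum(counts.values()) == 0:
            return
        prof = compute_iir(counts)
        grid = prof.at(np.arange(1, max(counts) + 2))
        assert np.all(np.diff(grid) <= 1e-12)
        assert grid.min() >= 0.0 and grid.max() <= 1.0
        # weighted mean length equals the discrete integral of the IIR
        wml = weighted_mean_length(counts)
        assert prof.mean_length == pytest.approx(wml, abs=1e-9)
        assert float(grid.sum()) == pytest.approx(wml, abs=1e-9)

    def test_weighted_mean_examples(self):
        assert weighted_mean_length({100: 3, 400: 1}) == 175
        assert weighted_mean_length({777: 5}) == 777
        assert weighted_mean_length({100: 0}) is None


class TestIirMad:
    def _prof(self, counts, length=200):
        return compute_iir(counts, gene_id="gA", spliced_length=length)

    def test_identical_profiles(self):
        a = self._prof({100: 3, 150: 1})
        assert iir_mad(a, a) == 0.0

    def test_half_disagreement(self):
        a = self._prof({100: 1})
        b = self._prof({200: 1})
        assert iir_mad(a, b) == pytest.approx(0.5)

    def test_symmetry(self):
        a = self._prof({100: 3, 180: 2})
        b = self._prof({50: 1, 200: 4})
        assert iir_mad(a, b) == pytest.approx(iir_mad(b, a))

    def test_mismatched_genes_rejected(self):
        a = compute_iir({10: 1}, gene_id="gA", spliced_length=100)
        b = compute_iir({10: 1}, gene_id="gB", spliced_length=100)
        with pytest.raises(ValueError):
            iir_mad(a, b)

    def test_matches_per_nucleotide_bruteforce(self, rng):
        for _ in range(10):
            length = 300
            ca = {int(rng.integers(1, length)): int(rng.integers(1, 9)) for _ in range(3)}
            cb = {int(rng.integers(1, length)): int(rng.integers(1, 9)) for _ in range(3)}
            a, b = self._prof(ca, length), self._prof(cb, length)
            grid = np.arange(1, length + 1)
            brute = float(np.mean(np.abs(a.at(grid) - b.at(grid))))
            assert iir_mad(a, b) == pytest.approx(brute, abs=1e-12)


class TestDeviationAndAggregation:
    def test_row_centering(self):
        m = pd.DataFrame({"c1": [100.0], "c2": [200.0], "c3": [300.0]}, index=["g"])
        dev = deviation_matrix(m)
        assert dev.loc["g"].tolist() == [-100.0, 0.0, 100.0]

    def test_missing_preserved(self):
        m = pd.DataFrame({"c1": [100.0], "c2": [np.nan], "c3": [300.0]}, index=["g"])
        dev = deviation_matrix(m)
        assert dev.loc["g", "c1"] == -100.0 and np.isnan(dev.loc["g", "c2"])

    def test_rows_have_zero_mean(self, rng):
        m = pd.DataFrame(rng.uniform(50, 2000, size=(20, 30)))
        m[m < 200] = np.nan
        dev = deviation_matrix(m)
        means = dev.mean(axis=1, skipna=True).to_numpy()
        assert np.nanmax(np.abs(means)) < 1e-9

    def test_cell_score(self):
        dev = pd.DataFrame({"c1": [10.0, -10.0], "c2": [np.nan, np.nan]})
        scores = cell_score(dev)
        assert scores["c1"] == 0.0 and np.isnan(scores["c2"])

    def test_min_cells_masking(self):
        cells = [f"c{i}" for i in range(39)]
        labels = {c: ("A" if i < 19 else "B") for i, c in enumerate(cells)}
        dev = pd.DataFrame([np.full(39, 7.0)], index=["g"], columns=cells)
        agg = aggregate_matrix_by_label(dev, labels, min_cells=20)
        assert np.isnan(agg.loc["g", "A"])  # only 19 cells
        assert agg.loc["g", "B"] == 7.0  # exactly 20 cells

    def test_group_means_by_hand(self):
        dev = pd.DataFrame(
            {"c1": [1.0, 3.0], "c2": [3.0, 5.0], "c3": [10.0, 20.0]}, index=["g1", "g2"]
        )
        labels = {"c1": "A", "c2": "A", "c3": "B"}
        agg = aggregate_matrix_by_label(dev, labels, min_cells=1)
        assert agg.loc["g1", "A"] == 2.0 and agg.loc["g2", "B"] == 20.0
        scores = aggregate_scores_by_label(cell_score(dev), labels, min_cells=1)
        assert scores["A"] == pytest.approx(3.0) and scores["B"] == 15.0


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({1: 5, 2: 5, 3: 5, 4: 5}, 2.0),
            ({1: 9}, 0.0),
            ({1: 2, 2: 1, 3: 1}, 1.5),
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert pas_entropy(counts) == pytest.approx(expected)

    def test_zero_total_missing(self):
        assert pas_entropy({1: 0}) is None

    @given(
        counts=st.lists(st.integers(0, 100), min_size=1, max_size=10)
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds(self, counts):
        d = {i: c for i, c in enumerate(counts)}
        h = pas_entropy(d)
        if h is None:
            return
        k = sum(1 for c in counts if c > 0)
        assert -1e-12 <= h <= np.log2(max(k, 1)) + 1e-12
        if k == 1:
            assert h == 0.0


class TestLengthMatrixAndCpm:
    def test_length_matrix_values_in_range(self, sim_small):
        _, ann, _, sr = sim_small
        from scapa.reads import assign_reads

        result = assign_reads(sr.reads, ann.models)
        table = build_count_table(result.assigned, ann.models, None, "cell")
        lm = build_length_matrix(table)
        lengths = {m.gene_id: m.spliced_length for m in ann.models}
        for gene in lm.index:
            vals = lm.loc[gene].dropna()
            assert ((vals > 0) & (vals <= lengths[gene])).all()

    def test_cpm_hand_example_and_normalization(self):
        rows = [
            ("g1", "p0", 100, "A", 5),
            ("g2", "p1", 300, "A", 5),
            ("g1", "p0", 100, "B", 30),
            ("g2", "p1", 300, "B", 10),
        ]
        table = table_from_rows(rows)
        counts, cpm, log2cpm = gene_expression_cpm(table)
        assert cpm.loc["g1", "A"] == 5e5 and cpm.loc["g2", "A"] == 5e5
        assert cpm.loc["g1", "B"] == 7.5e5
        assert np.allclose(cpm.sum(axis=0), 1e6)
        assert log2cpm.loc["g1", "A"] == pytest.approx(np.log2(5e5 + 1))

    def test_zero_total_group_rejected(self):
        table = table_from_rows([("g1", "p0", 100, "A", 0)])
        with pytest.raises(ValueError):
            gene_expression_cpm(table)


class TestPlantedLengthening:
    def test_stage_means_strictly_increase(self):
        """Planted stage-wise lengthening must surface as strictly
        increasing aggregated stage means of per-cell scores."""
        from scapa.reads import assign_reads
        from scapa.simulate import SimConfig, simulate_annotation, simulate_reads

        cfg = SimConfig(
            n_genes=25, n_cells_per_stage=200, read_depth=12,
            artifact_rate=0.2, lengthening_nt=60.0, seed=5,
        )
        ann = simulate_annotation(cfg)
        sr = simulate_reads(ann, cfg)
        result = assign_reads(sr.reads, ann.models)
        table = build_count_table(result.assigned, ann.models, None, "cell")
        dev = deviation_matrix(build_length_matrix(table))
        scores = cell_score(dev)
        labels = dict(zip(sr.cells.barcode, sr.cells.stage))
        agg = aggregate_scores_by_label(scores, labels, min_cells=20)
        ordered = agg.reindex(list(cfg.stages)).to_numpy()
        assert np.all(np.isfinite(ordered))
        assert np.all(np.diff(ordered) > 0)
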