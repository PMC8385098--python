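"""Annotation integration: collapse, union, overlap, UTR selection, linkage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scapa.annotation import (
    IntegrationConfig,
    PasSet,
    UtrResourceEntry,
    collapse_within_database,
    integrate_utrs,
    link_pas_to_gene,
    nucleotide_profile,
    pairwise_overlap,
    select_representative_transcript,
    sequential_union,
)
from conftest import make_model, make_pas, make_pas_set


def brute_force_collapse(positions, strand, radius):
    """Independent oracle: chain clusters in 5'->3' order, keep the most
    downstream member of each cluster."""
    if not positions:
        return []
    pts = sorted(positions, reverse=(strand == "-"))
    clusters = [[pts[0]]]
    for p in pts[1:]:
        if abs(p - clusters[-1][-1]) <= radius:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    keep = []
    for cl in clusters:
        keep.append(max(cl) if strand == "+" else min(cl))
    return sorted(keep)


class TestCollapse:
    @pytest.mark.parametrize(
        "positions,radius,expected",
        [
            ([100, 105, 130], 10, [105, 130]),
            ([0, 8, 16], 10, [16]),  # chains through the middle site
            ([42], 10, [42]),
            ([100, 111], 10, [100, 111]),  # 11 nt apart: not collapsed
            ([100, 110], 10, [110]),  # exactly radius: collapsed
        ],
    )
    def test_plus_strand_examples(self, positions, radius, expected):
        out = collapse_within_database(make_pas(positions), radius)
        assert sorted(r.pos for r in out) == expected

    def test_minus_strand_keeps_most_downstream(self):
        # on '-' downstream means lower coordinate
        out = collapse_within_database(make_pas([100, 105, 130], strand="-"), 10)
        assert sorted(r.pos for r in out) == [100, 130]

    def test_mixed_sources_rejected(self):
        recs = make_pas([10], source="a") + make_pas([50], source="b", prefix="q")
        with pytest.raises(ValueError, match="one source"):
            collapse_within_database(recs, 10)

    @given(
        positions=st.lists(st.integers(0, 300), min_size=1, max_size=25),
        radius=st.integers(0, 30),
        strand=st.sampled_from(["+", "-"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_oracle(self, positions, radius, strand):
        positions = sorted(set(positions))
        out = collapse_within_database(make_pas(positions, strand=strand), radius)
        assert sorted(r.pos for r in out) == brute_force_collapse(positions, strand, radius)

    @given(
        positions=st.lists(st.integers(0, 500), min_size=2, max_size=20, unique=True),
        radius=st.integers(0, 25),
    )
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance_and_spacing(self, positions, radius):
        rng = np.random.default_rng(0)
        ref = collapse_within_database(make_pas(positions), radius)
        shuffled = list(positions)
        rng.shuffle(shuffled)
        out = collapse_within_database(make_pas(shuffled), radius)
        assert [r.pos for r in out] == [r.pos for r in ref]
        kept = sorted(r.pos for r in out)
        assert all(b - a > radius for a, b in zip(kept, kept[1:]))


class TestSequentialUnion:
    def test_nearby_site_skipped(self):
        a = make_pas_set([105, 130], source="A", prefix="a")
        b = make_pas_set([112, 300], source="B", prefix="b")
        out = sequential_union([a, b], 10)
        assert sorted(r.pos for r in out.records) == [105, 130, 300]

    def test_empty_first_set(self):
        empty = PasSet(records=[], provenance=["A"])
        b = make_pas_set([10, 200], source="B")
        out = sequential_union([empty, b], 10)
        assert sorted(r.pos for r in out.records) == [10, 200]

    def test_idempotent_with_itself(self):
        a = make_pas_set([10, 200, 500], source="A")
        out = sequential_union([a, a], 10)
        assert sorted(r.pos for r in out.records) == [10, 200, 500]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sequential_union([], 10)

    def test_provenance_preserved(self):
        a = make_pas_set([100], source="A", prefix="a")
        b = make_pas_set([500], source="B", prefix="b")
        out = sequential_union([a, b], 10)
        assert {r.source for r in out.records} == {"A", "B"}
        assert out.provenance == ["A", "B"]

    @given(
        sets=st.lists(
            st.lists(st.integers(0, 400), min_size=0, max_size=12, unique=True),
            min_size=1,
            max_size=4,
        ),
        radius=st.integers(0, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_union_respects_pairwise_distance(self, sets, radius):
        """Final union never contains same-strand sites within the radius,
        and matches a brute-force membership check."""
        collapsed = [
            PasSet(
                collapse_within_database(make_pas(p, source=f"s{i}", prefix=f"s{i}_"), radius),
                [f"s{i}"],
            )
            for i, p in enumerate(sets)
        ]
        out = sequential_union(collapsed, radius)
        kept = sorted(r.pos for r in out.records)
        assert all(b - a > radius for a, b in zip(kept, kept[1:]))
        # brute-force sequential membership
        expected: list[int] = []
        for cs in collapsed:
            for rec in sorted(cs.records, key=lambda r: r.pos):
                if all(abs(rec.pos - q) > radius for q in expected):
                    expected.append(rec.pos)
        assert kept == sorted(expected)


class TestPairwiseOverlap:
    def test_identical_sets(self):
        a = make_pas_set([10, 200], source="A", prefix="a")
        b = make_pas_set([10, 200], source="B", prefix="b")
        out = pairwise_overlap(a, b, 20)
        assert (out.a_only, out.b_only) == (0, 0)
        assert out.shared_a == out.shared_b == 2

    @pytest.mark.parametrize("offset,shared", [(20, 1), (21, 0)])
    def test_inclusive_boundary(self, offset, shared):
        a = make_pas_set([1000], source="A", prefix="a")
        b = make_pas_set([1000 + offset], source="B", prefix="b")
        out = pairwise_overlap(a, b, 20)
        assert out.shared_a == shared
        assert out.a_only == 1 - shared

    @given(
        a=st.lists(st.integers(0, 300), min_size=0, max_size=15, unique=True),
        b=st.lists(st.integers(0, 300), min_size=0, max_size=15, unique=True),
        radius=st.integers(0, 30),
    )
    @settings(max_examples=100, deadline=None)
    def test_counts_partition_each_set(self, a, b, radius):
        sa = make_pas_set(a, source="A", prefix="a")
        sb = make_pas_set(b, source="B", prefix="b")
        out = pairwise_overlap(sa, sb, radius)
        assert out.a_only + out.shared_a == len(a)
        assert out.b_only + out.shared_b == len(b)


def _entry(tid, blocks, strand="+", gene="gA", chrom="chr1", source="res"):
    stop = blocks[0][0] if strand == "+" else blocks[-1][1] - 1
    return UtrResourceEntry(
        gene_id=gene, transcript_id=tid, chrom=chrom, strand=strand,
        stop_codon=stop, exon_blocks=list(blocks), source=source,
    )


class TestIntegrateUtrs:
    def test_longest_per_stop_codon_kept(self):
        short = _entry("t1", [(1000, 1500)])
        long_ = _entry("t2", [(1000, 1800)])
        out = integrate_utrs([short, long_])
        assert len(out) == 1 and out[0].transcript_id == "t2"

    def test_3pseq_extension_within_cap(self):
        base = _entry("t1", [(1000, 1800)])  # spliced length 800
        # cleavage evidence 4200 nt past the terminus: spliced distance 5000
        out = integrate_utrs([base], [("chr1", "+", 1799 + 4200)])
        assert out[0].spliced_length == 5000

    def test_3pseq_beyond_cap_ignored(self):
        base = _entry("t1", [(1000, 1800)])
        out = integrate_utrs([base], [("chr1", "+", 1799 + 5200)])  # would be 6000
        assert out[0].spliced_length == 800

    def test_minus_strand_extension(self):
        base = _entry("t1", [(5000, 5800)], strand="-")
        out = integrate_utrs([base], [("chr1", "-", 5000 - 4200)])
        assert out[0].spliced_length == 5000
        assert out[0].exon_blocks[0][0] == 5000 - 4200

    def test_output_length_is_max_over_resources(self, rng):
        """Exhaustive comparison against a per-stop maximum on random input."""
        entries = []
        for stop in (1000, 4000, 9000):
            for t in range(3):
                length = int(rng.integers(100, 2000))
                entries.append(
                    _entry(f"s{stop}.t{t}", [(stop, stop + length)], gene=f"g{stop}")
                )
        out = {e.stop_codon: e.spliced_length for e in integrate_utrs(entries)}
        for stop in (1000, 4000, 9000):
            expect = max(e.spliced_length for e in entries if e.stop_codon == stop)
            assert out[stop] == expect


class TestRepresentativeTranscript:
    def test_argmax_read_count(self):
        cands = [_entry("T1", [(0, 500)]), _entry("T2", [(0, 800)])]
        model = select_representative_transcript("gA", cands, {"T1": 50, "T2": 30})
        assert model.transcript_id == "T1"

    def test_tie_break_is_seeded_and_stable(self):
        cands = [_entry("T1", [(0, 500)]), _entry("T2", [(0, 800)])]
        picks = {
            select_representative_transcript("gA", cands, {"T1": 10, "T2": 10}, rng_seed=7).transcript_id
            for _ in range(5)
        }
        assert len(picks) == 1

    def test_zero_reads_falls_back_to_longest(self):
        cands = [_entry("T1", [(0, 800)]), _entry("T2", [(0, 500)])]
        model = select_representative_transcript("gA", cands, {"T1": 0, "T2": 0})
        assert model.transcript_id == "T1"

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            select_representative_transcript("gA", [])


class TestLinkPasToGene:
    def test_spliced_length_subtracts_intron(self):
        # stop codon 1000(+), intron [1200,1500), PAS at 2000 -> 700
        model = make_model(blocks=((1000, 1200), (1500, 2500)))
        pas = make_pas_set([2000])
        out = link_pas_to_gene(pas, [model])
        assert out.models[0].linked_pas == [("p0", 700)]

    def test_upstream_and_intronic_pas_unlinked(self):
        model = make_model(blocks=((1000, 1200), (1500, 2500)))
        pas = make_pas_set([999, 1350])  # upstream of stop; intronic gap
        out = link_pas_to_gene(pas, [model])
        assert out.models[0].linked_pas == []
        assert sorted(out.unlinked) == ["p0", "p1"]

    def test_multi_gene_pas_dropped_as_ambiguous(self):
        m1 = make_model("gA", blocks=((1000, 2000),))
        m2 = make_model("gB", blocks=((1500, 2500),))
        out = link_pas_to_gene(make_pas_set([1700]), [m1, m2])
        assert out.ambiguous == ["p0"]
        assert all(not m.linked_pas for m in out.models)

    def test_bruteforce_walk_agreement(self, rng):
        """utr_length equals a base-by-base walk over the exon blocks."""
        for strand in "+-":
            blocks = ((1000, 1400), (1700, 2200), (2500, 3100))
            model = make_model(strand=strand, blocks=blocks)
            walk = []  # genomic positions in transcript order
            ordered = blocks if strand == "+" else tuple(reversed(blocks))
            for s, e in ordered:
                span = range(s, e) if strand == "+" else range(e - 1, s - 1, -1)
                walk.extend(span)
            picks = rng.choice(len(walk), size=15, replace=False)
            pas = make_pas_set([walk[i] for i in picks], strand=strand)
            out = link_pas_to_gene(pas, [model])
            got = dict(
                (pid, l) for pid, l in out.models[0].linked_pas
            )
            for j, i in enumerate(picks):
                expected = int(i)  # 0-based spliced index == walk position
                if expected == 0:
                    assert f"p{j}" in out.unlinked
                else:
                    assert got[f"p{j}"] == expected


class TestNucleotideProfile:
    def test_all_A_genome(self):
        genome = {"chr1": "A" * 300}
        prof = nucleotide_profile(make_pas_set([150]), genome, flank=50)
        assert np.allclose(prof.matrix[0], 1.0)
        assert np.allclose(prof.matrix.sum(axis=0), 1.0)

    def test_columns_sum_to_one_and_tally(self):
        rng = np.random.default_rng(5)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=400))}
        pas = make_pas_set([120, 240])
        prof = nucleotide_profile(pas, genome, flank=10)
        assert np.allclose(prof.matrix.sum(axis=0), 1.0)
        # hand tally the center column (the cleavage base itself)
        bases = [genome["chr1"][120], genome["chr1"][240]]
        for bi, base in enumerate("ACGT"):
            assert prof.matrix[bi, 10] == pytest.approx(bases.count(base) / 2)

    def test_minus_strand_is_reverse_complemented(self):
        genome = {"chr1": "G" * 101}
        prof = nucleotide_profile(make_pas_set([50], strand="-"), genome, flank=20)
        assert np.allclose(prof.matrix[1], 1.0)  # complement of G is C

    def test_edge_sites_skipped(self):
        genome = {"chr1": "A" * 100}
        prof = nucleotide_profile(make_pas_set([5, 50]), genome, flank=30)
        assert prof.n_used == 1 and prof.n_skipped == 1
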