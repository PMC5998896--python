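"""Pair-list parsing, tuple censuses and the multiplication signature."""

import pytest

from wgmfrac import (
    PairRecord,
    Region,
    assign_genes_to_regions,
    high_similarity_tuples,
    percent_share,
    read_pairs,
    read_regions,
    share_high_similarity,
    signature_summary,
)


def _write(tmp_path, text, name="pairs.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


def _triangle(sim=0.9):
    return [
        PairRecord("A", "B", sim),
        PairRecord("B", "C", sim),
        PairRecord("A", "C", sim),
    ]


class TestReadPairs:
    def test_three_line_toy_file(self, tmp_path):
        path = _write(tmp_path, "A\tB\t0.9\nB\tC\t0.85\nA\tC\t0.95\n")
        recs = read_pairs(path)
        assert len(recs) == 3

    def test_percent_autoscale(self, tmp_path):
        path = _write(tmp_path, "A\tB\t90\n")
        assert read_pairs(path)[0].similarity == pytest.approx(0.90)

    def test_duplicates_keep_maximum(self, tmp_path):
        path = _write(tmp_path, "A\tB\t0.9\nB\tA\t0.8\n")
        recs = read_pairs(path)
        assert len(recs) == 1
        assert recs[0].similarity == 0.9

    def test_unparseable_line_reports_line_number(self, tmp_path):
        path = _write(tmp_path, "A\tB\t0.9\nA\tC\tnot_a_number\n")
        with pytest.raises(ValueError, match="line 2"):
            read_pairs(path)

    def test_empty_file_gives_empty_sequence(self, tmp_path):
        assert read_pairs(_write(tmp_path, "")) == []

    def test_canonical_ordering(self):
        rec = PairRecord("Z", "A", 0.5, region_a="rz", region_b="ra")
        assert (rec.gene_a, rec.gene_b) == ("A", "Z")
        assert (rec.region_a, rec.region_b) == ("ra", "rz")

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            PairRecord("A", "A", 0.5)


class TestHighSimilarityTuples:
    def test_triangle_is_one_clique_triple(self):
        report = high_similarity_tuples(_triangle(), threshold=0.81)
        assert report.triples == 1
        assert report.clique_triples == 1
        assert report.four_tuples_and_higher == 0

    def test_chain_of_four_is_not_a_triple(self):
        chain = [PairRecord(a, b, 0.9) for a, b in [("A", "B"), ("B", "C"), ("C", "D")]]
        report = high_similarity_tuples(chain, threshold=0.81)
        assert report.triples == 0
        assert report.components_by_size == {4: 1}

    def test_open_triple_counts_but_not_as_clique(self):
        open_triple = [PairRecord("A", "B", 0.9), PairRecord("B", "C", 0.9)]
        report = high_similarity_tuples(open_triple)
        assert report.triples == 1
        assert report.clique_triples == 0

    def test_below_threshold_triangle_vanishes(self):
        report = high_similarity_tuples(_triangle(0.7), threshold=0.81)
        assert report.n_pairs_high == 0
        assert report.components_by_size == {}

    def test_raising_threshold_never_increases_counts(self, rng):
        pairs = [
            PairRecord(f"g{a}", f"g{b}", float(s))
            for (a, b), s in zip(
                {(int(x), int(y)) for x, y in rng.integers(0, 40, size=(300, 2)) if x != y},
                rng.uniform(0.5, 1.0, size=300),
            )
        ]
        prev = None
        for thr in (0.6, 0.7, 0.8, 0.9):
            rep = high_similarity_tuples(pairs, threshold=thr)
            sizes = {
                k: sum(c for kk, c in rep.components_by_size.items() if kk >= k)
                for k in (2, 3, 4)
            }
            if prev is not None:
                assert rep.n_pairs_high <= prev
            prev = rep.n_pairs_high

    def test_order_invariance(self):
        pairs = _triangle() + [PairRecord("D", "E", 0.95)]
        a = high_similarity_tuples(pairs)
        b = high_similarity_tuples(list(reversed(pairs)))
        assert a.components_by_size == b.components_by_size

    def test_unpaired_against_roster(self):
        report = high_similarity_tuples(_triangle(), threshold=0.81, total_genes=10)
        assert report.unpaired == 7


class TestSignature:
    def test_cross_region_pairs_satisfy_signature(self):
        regions = {"A": ("R1", "T1"), "B": ("R2", "T1"), "C": ("R3", "T1")}
        sig = signature_summary(_triangle(), regions)
        assert (sig.among_tuple, sig.within_region, sig.cross_tuple) == (3, 0, 0)
        assert sig.satisfied

    def test_within_region_pairs_violate_signature(self):
        regions = {g: ("R1", "T1") for g in "ABC"}
        sig = signature_summary(_triangle(), regions)
        assert sig.within_region == 3
        assert not sig.satisfied

    def test_unlabeled_genes_counted_not_dropped(self):
        sig = signature_summary(_triangle(), {"A": ("R1", "T1")})
        assert sig.unassigned == 3

    def test_simulated_recent_triplication_satisfies_signature(self, dup_then_trip_dataset):
        sig = signature_summary(
            dup_then_trip_dataset.pair_records(), dup_then_trip_dataset.region_map()
        )
        assert sig.satisfied


class TestShares:
    def test_printed_share_convention(self):
        assert percent_share(13716, 22406) == 61

    def test_all_and_none(self):
        pairs = _triangle()
        assert share_high_similarity(pairs, threshold=0.5) == 100
        assert share_high_similarity(pairs, threshold=0.99) == 0

    def test_region_condition_excludes_within_region_pairs(self):
        pairs = [
            PairRecord("A", "B", 0.9, region_a="R1", region_b="R1"),
            PairRecord("C", "D", 0.9, region_a="R1", region_b="R2"),
        ]
        assert share_high_similarity(pairs) == 50

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            share_high_similarity([])


class TestRegions:
    def test_read_and_assign(self, tmp_path):
        path = tmp_path / "regions.tsv"
        path.write_text("chr1\t0\t100\tR1\tT1\nchr1\t100\t200\tR2\tT1\n")
        regions = read_regions(path)
        assert regions[0] == Region("R1", "T1", "chr1", 0, 100)
        mapping = assign_genes_to_regions(
            regions, {"gA": ("chr1", 50), "gB": ("chr1", 150), "gC": ("chr2", 10)}
        )
        assert mapping == {"gA": ("R1", "T1"), "gB": ("R2", "T1")}
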