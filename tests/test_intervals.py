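"""Interval algebra: merge, containment, promoters, feature partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from temotif.intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    contained_hits,
    feature_partition,
    merge_intervals,
    promoter_window,
    promoters,
    promoter_windows,
)
from temotif.motifs import MotifHit

from conftest import bitmap_total, cover_bitmap, random_gene, random_intervals


def _hit(chrom, start, end, motif="m", strand="+"):
    return MotifHit(motif, motif, GenomicInterval(chrom, start, end, strand), 0.0, 1e-5)


class TestMerge:
    def test_empty(self):
        assert len(merge_intervals(IntervalSet())) == 0

    def test_book_ended_union(self):
        s = IntervalSet([GenomicInterval("chrI", 0, 10), GenomicInterval("chrI", 10, 20)])
        merged = s.merge()
        assert [(iv.start, iv.end) for iv in merged] == [(0, 20)]

    def test_malformed_interval_named(self):
        with pytest.raises(ValueError, match=r"chrI:\[9,9\)"):
            GenomicInterval("chrI", 9, 9)

    def test_random_vs_bitmap_oracle(self):
        rng = np.random.default_rng(42)
        sizes = {"chrI": 10_000}
        for _ in range(25):
            ivs = random_intervals(rng, sizes, 200, max_len=400)
            merged = IntervalSet(ivs).merge()
            oracle = cover_bitmap(ivs, sizes)
            assert merged.total_bp == bitmap_total(oracle)
            remap = cover_bitmap(list(merged), sizes)
            assert (remap["chrI"] == oracle["chrI"]).all()
            # no two members overlap or abut
            prev = None
            for iv in merged:
                if prev is not None:
                    assert iv.start > prev.end
                prev = iv

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 80)), max_size=40))
    def test_idempotent_and_order_independent(self, spec):
        ivs = [GenomicInterval("c", s, s + l) for s, l in spec]
        m1 = IntervalSet(ivs).merge()
        m2 = m1.merge()
        assert [(i.start, i.end) for i in m1] == [(i.start, i.end) for i in m2]
        m3 = IntervalSet(list(reversed(ivs))).merge()
        assert [(i.start, i.end) for i in m1] == [(i.start, i.end) for i in m3]


class TestSubtractIntersect:
    def test_against_bitmaps(self):
        rng = np.random.default_rng(7)
        sizes = {"chrI": 20_000, "chrII": 8_000}
        for _ in range(20):
            a = IntervalSet(random_intervals(rng, sizes, 60, 800))
            b = IntervalSet(random_intervals(rng, sizes, 60, 800))
            am, bm = cover_bitmap(list(a), sizes), cover_bitmap(list(b), sizes)
            inter = a.intersect(b)
            sub = a.subtract(b)
            for c in sizes:
                got_i = cover_bitmap(list(inter), sizes)[c]
                got_s = cover_bitmap(list(sub), sizes)[c]
                assert (got_i == (am[c] & bm[c])).all()
                assert (got_s == (am[c] & ~bm[c])).all()


class TestContainment:
    TES = pd.DataFrame(
        [
            ("chrI", 0, 50, "CELE1", "Tc1/mariner", "DNA"),
            ("chrI", 100, 400, "Helitron2_CE", "Helitron", "RC"),
            ("chrI", 100, 200, "CELE1", "Tc1/mariner", "DNA"),
        ],
        columns=["chrom", "start", "end", "te_type", "te_family", "repeat_class"],
    )

    def test_strict_subset_retained(self):
        kept = contained_hits([_hit("chrI", 5, 12)], self.TES)
        assert len(kept) == 1 and kept[0].te_type == "CELE1"

    def test_boundary_overlap_excluded(self):
        assert contained_hits([_hit("chrI", 45, 55)], self.TES) == []

    def test_tie_break_longest_then_name(self):
        # hit inside both the 300 bp Helitron and the 100 bp CELE1 record
        kept = contained_hits([_hit("chrI", 120, 130)], self.TES)
        assert kept[0].te_type == "Helitron2_CE"
        assert kept[0].ambiguous_te

    def test_planted_recovery(self):
        rng = np.random.default_rng(3)
        sizes = {"chrI": 50_000}
        tes = pd.DataFrame(
            [("chrI", int(s), int(s) + 300, f"T{i%4}", "fam", "DNA")
             for i, s in enumerate(range(1000, 41_000, 800))],
            columns=["chrom", "start", "end", "te_type", "te_family", "repeat_class"],
        )
        hits, inside = [], []
        for j in range(500):
            if j % 2 == 0:
                row = tes.iloc[int(rng.integers(0, len(tes)))]
                s = int(rng.integers(row.start, row.end - 8))
                hits.append(_hit("chrI", s, s + 8, motif=f"h{j}"))
                inside.append(f"h{j}")
            else:  # place in a gap between TE blocks
                block = int(rng.integers(0, 49))
                s = 1000 + block * 800 + 300 + int(rng.integers(0, 490))
                hits.append(_hit("chrI", s, s + 8, motif=f"h{j}"))
        kept = contained_hits(hits, tes)
        assert sorted(h.motif_id for h in kept) == sorted(inside)


class TestPromoters:
    def test_plus_strand_clipped(self):
        win = promoter_window(GenomicInterval("chrI", 1000, 2000, "+"), 2500, 100_000)
        assert (win.start, win.end) == (0, 1000)

    def test_minus_strand_reflected(self):
        win = promoter_window(GenomicInterval("chrI", 1000, 2000, "-"), 2500, 100_000)
        assert (win.start, win.end) == (2000, 4500)

    def test_unstranded_rejected(self):
        with pytest.raises(ValueError, match="unstranded"):
            promoter_window(GenomicInterval("chrI", 10, 20, "."), 2500, 1000)

    def test_window_never_exceeds_upstream_bp(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            size = int(rng.integers(3000, 50_000))
            start = int(rng.integers(0, size - 100))
            strand = "+" if rng.random() < 0.5 else "-"
            span = GenomicInterval("c", start, min(size, start + 100), strand)
            win = promoter_window(span, 2500, size)
            if win is not None:
                assert win.length <= 2500
                assert 0 <= win.start < win.end <= size

    def test_exclusive_subtracts_features(self):
        rng = np.random.default_rng(5)
        sizes = {"chrI": 30_000}
        genes = [random_gene(rng, "chrI", 30_000, f"g{i}") for i in range(8)]
        prom = promoters(genes, None, 2500, exclusive=True, chrom_sizes=sizes)
        raw = promoters(genes, None, 2500, exclusive=False, chrom_sizes=sizes)
        feats = []
        for g in genes:
            feats += list(g.coding_exons) + list(g.utr5) + list(g.utr3) + list(g.introns)
        raw_map = cover_bitmap(list(raw), sizes)["chrI"]
        feat_map = cover_bitmap(feats, sizes)["chrI"]
        got = cover_bitmap(list(prom), sizes)["chrI"]
        assert (got == (raw_map & ~feat_map)).all()

    def test_operon_collapse(self):
        g1 = random_gene(np.random.default_rng(1), "chrI", 50_000, "g1")
        g1.operon_id = "op1"
        operons = {"op1": g1.span}
        wins = promoter_windows([g1], operons, 2500, {"chrI": 50_000}, collapse_operons=True)
        assert set(wins) == {"op1"}
        wins2 = promoter_windows([g1], operons, 2500, {"chrI": 50_000}, collapse_operons=False)
        assert set(wins2) == {"g1"}


class TestFeaturePartition:
    def _setup(self, seed=9, n_genes=10, size=60_000):
        rng = np.random.default_rng(seed)
        sizes = {"chrI": size}
        genes = [random_gene(rng, "chrI", size, f"g{i}") for i in range(n_genes)]
        tes = IntervalSet(random_intervals(rng, sizes, 25, 600))
        return sizes, genes, tes

    def test_disjoint_te_exon(self):
        sizes = {"chrI": 10_000}
        g = random_gene(np.random.default_rng(2), "chrI", 5000, "g0")
        tes = IntervalSet([GenomicInterval("chrI", 8000, 9000)])
        part = feature_partition(sizes, [g], None, tes)
        row = part[part.feature_class == "coding_exons"].iloc[0]
        assert row.te_bp == 0

    def test_te_inside_intron(self):
        sizes = {"chrI": 20_000}
        g = GeneModel(
            "g0",
            GenomicInterval("chrI", 1000, 10_000, "+"),
            coding_exons=IntervalSet(
                [GenomicInterval("chrI", 1000, 2000, "+"), GenomicInterval("chrI", 9000, 10_000, "+")]
            ),
        )
        tes = IntervalSet([GenomicInterval("chrI", 4000, 5000)])
        part = feature_partition(sizes, [g], None, tes).set_index("feature_class")
        assert part.loc["introns", "te_bp"] == 1000
        assert part.loc["distal_intergenic", "te_bp"] == 0

    def test_missing_chrom_length_rejected(self):
        g = random_gene(np.random.default_rng(2), "chrII", 5000, "g0")
        with pytest.raises(ValueError, match="chrII"):
            feature_partition({"chrI": 10_000}, [g], None, IntervalSet())

    def test_against_bitmap_oracle(self):
        sizes, genes, tes = self._setup()
        part = feature_partition(sizes, genes, None, tes).set_index("feature_class")
        te_map = cover_bitmap(list(tes), sizes)["chrI"]
        feats = {
            "coding_exons": [iv for g in genes for iv in g.coding_exons],
            "utr5": [iv for g in genes for iv in g.utr5],
            "utr3": [iv for g in genes for iv in g.utr3],
            "introns": [iv for g in genes for iv in g.introns],
        }
        class_maps = {}
        for name, ivs in feats.items():
            m = cover_bitmap(ivs, sizes)["chrI"]
            class_maps[name] = m
            assert part.loc[name, "class_bp"] == int(m.sum())
            assert part.loc[name, "te_bp"] == int((m & te_map).sum())
        # TE bp + non-TE bp = class bp for every row
        for name in part.index:
            assert 0 <= part.loc[name, "te_bp"] <= part.loc[name, "class_bp"]
        # distal intergenic excludes everything else
        wins = promoter_windows(genes, None, 2500, sizes, collapse_operons=True)
        feat_all = np.zeros(sizes["chrI"], dtype=bool)
        for m in class_maps.values():
            feat_all |= m
        prom_map = cover_bitmap(list(wins.values()), sizes)["chrI"] & ~feat_all
        other = feat_all | prom_map
        assert part.loc["distal_intergenic", "class_bp"] == int((~other).sum())
        assert part.loc["distal_intergenic", "te_bp"] == int((~other & te_map).sum())
        assert part.loc["whole_genome", "class_bp"] == sizes["chrI"]
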