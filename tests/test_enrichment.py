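"""Coverage percentages, fold enrichment, the filter cascade, gene counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from temotif.enrichment import (
    CoverageRow,
    coverage_frame,
    coverage_table,
    filter_enriched,
    genes_with_te_motifs,
    motif_census,
    motif_percent_in_te,
    motif_te_enrichment,
    percent,
    te_type_bp,
)
from temotif.intervals import GenomicInterval
from temotif.motifs import MotifHit
from temotif.stats import binomial_tail


def _part(rows):
    return pd.DataFrame(rows, columns=["feature_class", "class_bp", "te_bp"])


def _hit(chrom, start, end, motif="m", te_type=None):
    h = MotifHit(motif, motif, GenomicInterval(chrom, start, end, "+"), 1.0, 1e-5)
    h.te_type = te_type
    return h


MB = 1_000_000


class TestCoverage:
    def test_genome_percentage_one_decimal(self):
        part = _part([("whole_genome", int(100.29 * MB), int(9.18 * MB))])
        rows = coverage_table(part)
        assert round(rows[0].percent_te, 1) == 9.2

    def test_fold_from_shares(self):
        # 53.1% of TE bases vs 33.3% of non-TE bases -> 1.6-fold enrichment
        from temotif.enrichment import _fold_fields

        fold, direction, disp = _fold_fields(53.1, 33.3)
        assert direction == "enriched"
        assert round(disp, 1) == 1.6

    def test_depletion_reciprocal(self):
        from temotif.enrichment import _fold_fields

        fold, direction, disp = _fold_fields(1.0, 27.8)
        assert direction == "depleted"
        assert round(disp, 1) == 27.8

    def test_zero_te_class_flagged(self):
        part = _part(
            [("whole_genome", 1000, 100), ("introns", 200, 0)]
        )
        rows = {r.feature_class: r for r in coverage_table(part)}
        assert rows["introns"].percent_te == 0.0
        assert rows["introns"].direction == "depleted"
        assert rows["introns"].fold_display == float("inf")

    def test_zero_length_class_no_division(self):
        part = _part([("whole_genome", 1000, 100), ("utr5", 0, 0)])
        rows = {r.feature_class: r for r in coverage_table(part)}
        assert rows["utr5"].direction == "undefined"

    def test_frame_rounding(self):
        part = _part([("whole_genome", int(100.29 * MB), int(9.18 * MB)),
                      ("introns", int(35.17 * MB), int(4.87 * MB))])
        df = coverage_frame(coverage_table(part)).set_index("feature_class")
        assert df.loc["introns", "percent_te"] == 13.8
        assert df.loc["introns", "fold"] == 1.6


class TestMotifTeEnrichment:
    TES = pd.DataFrame(
        [("chrI", 0, 10_000, "T1", "famA", "DNA"),
         ("chrI", 50_000, 60_000, "T2", "famB", "DNA")],
        columns=["chrom", "start", "end", "te_type", "te_family", "repeat_class"],
    )

    def test_fold_definition_arithmetic(self):
        # 20% of instances in a type covering 1% of the genome -> fold 20
        genome_bp = 1_000_000
        tes = pd.DataFrame(
            [("chrI", 0, 10_000, "T1", "famA", "DNA")],
            columns=self.TES.columns,
        )
        hits = [_hit("chrI", 100 + 20 * i, 110 + 20 * i, "m") for i in range(20)]
        hits += [_hit("chrI", 500_000 + 20 * i, 500_010 + 20 * i, "m") for i in range(80)]
        recs = motif_te_enrichment(hits, tes, genome_bp)
        assert len(recs) == 1
        assert recs[0].n_in == 20 and recs[0].n_total == 100
        assert recs[0].fold == pytest.approx(20.0)

    def test_zero_inside_full_tail(self):
        hits = [_hit("chrI", 200_000, 200_010, "m")]
        recs = motif_te_enrichment(hits, self.TES, 1_000_000)
        assert all(r.pvalue == 1.0 for r in recs if r.n_in == 0)

    def test_binomial_example(self):
        assert binomial_tail(5, 10, 0.1) == pytest.approx(1.63e-3, rel=2e-2)

    def test_overlapping_te_fragments_counted_once(self):
        tes = pd.DataFrame(
            [("chrI", 0, 1000, "T1", "f", "DNA"), ("chrI", 500, 1500, "T1", "f", "DNA")],
            columns=self.TES.columns,
        )
        assert te_type_bp(tes)["T1"] == 1500

    def test_fold_invariant_under_uniform_scaling(self):
        hits = [_hit("chrI", 100, 110, "m"), _hit("chrI", 200_000, 200_010, "m")]
        r1 = motif_te_enrichment(hits, self.TES, 1_000_000)
        hits2 = [_hit("chrI", 2 * h.interval.start, 2 * h.interval.start + 10, "m") for h in hits]
        tes2 = self.TES.copy()
        tes2["start"] *= 2
        tes2["end"] *= 2
        r2 = motif_te_enrichment(hits2, tes2, 2_000_000)
        f1 = {x.te_type: x.fold for x in r1}
        f2 = {x.te_type: x.fold for x in r2}
        assert f1 == pytest.approx(f2)


class TestFilterCascade:
    def _rec(self, fold, p, te_bp):
        from temotif.enrichment import EnrichmentRecord

        return EnrichmentRecord("m", "tf", "T", "f", 100, 10, te_bp, 10**6, fold, p)

    def test_all_gates_pass(self):
        assert filter_enriched([self._rec(25, 1e-15, 30_000)]) != []

    def test_te_bp_gate_strict(self):
        assert filter_enriched([self._rec(25, 1e-15, 19_000)]) == []
        assert filter_enriched([self._rec(25, 1e-15, 20_000)]) == []

    def test_fold_gate_strict(self):
        assert filter_enriched([self._rec(20.0, 1e-15, 30_000)]) == []

    def test_p_gate_strict(self):
        assert filter_enriched([self._rec(25, 1e-12, 30_000)]) == []


class TestPercentInTe:
    def _records(self, counts, n_total):
        from temotif.enrichment import EnrichmentRecord

        return [
            EnrichmentRecord("m", "tf", t, "f", n_total, n, 1000, 10**6, 1.0, 0.5)
            for t, n in counts.items()
        ]

    def test_all_inside(self):
        recs = self._records({"A": 60, "B": 40}, 100)
        assert motif_percent_in_te(recs, {"A", "B"}) == 100.0

    def test_empty_selection(self):
        recs = self._records({"A": 60}, 100)
        assert motif_percent_in_te(recs, set()) == 0.0

    def test_census_arithmetic(self):
        assert percent(223, 229) == pytest.approx(97.4, abs=0.05)

    def test_census_counts_motifs_with_any_te_instance(self):
        from temotif.enrichment import EnrichmentRecord

        recs = [
            EnrichmentRecord("m1", "t", "A", "f", 10, 3, 100, 1000, 1.0, 0.5),
            EnrichmentRecord("m1", "t", "B", "f", 10, 0, 100, 1000, 0.0, 1.0),
            EnrichmentRecord("m2", "t", "A", "f", 10, 0, 100, 1000, 0.0, 1.0),
        ]
        with_te, total, pct = motif_census(recs)
        assert (with_te, total) == (1, 2)
        assert pct == 50.0


class TestGenesWithTeMotifs:
    WINS = {
        "g1": GenomicInterval("chrI", 0, 2500, "+"),
        "g2": GenomicInterval("chrI", 2000, 4500, "+"),
        "g3": GenomicInterval("chrII", 0, 2500, "+"),
    }

    def test_single_hit_single_gene(self):
        sets, union = genes_with_te_motifs(self.WINS, [_hit("chrI", 100, 110, "m", "T")])
        assert sets["m"] == {"g1"} and union == {"g1"}

    def test_hit_in_overlapping_windows_counts_both_genes(self):
        sets, union = genes_with_te_motifs(self.WINS, [_hit("chrI", 2100, 2110, "m", "T")])
        assert sets["m"] == {"g1", "g2"}

    def test_union_versus_per_motif_counts(self):
        hits = [
            _hit("chrI", 100, 110, "m1", "T"),
            _hit("chrI", 120, 130, "m2", "T"),
            _hit("chrII", 50, 60, "m2", "T"),
        ]
        sets, union = genes_with_te_motifs(self.WINS, hits)
        assert len(union) <= sum(len(s) for s in sets.values())
        assert union == {"g1", "g3"}

    def test_oracle_assignment(self):
        rng = np.random.default_rng(4)
        wins = {
            f"g{i}": GenomicInterval("chrI", s, s + 2500, "+")
            for i, s in enumerate(range(0, 60_000, 3000))
        }
        hits = []
        expected = {}
        for j in range(150):
            s = int(rng.integers(0, 70_000))
            h = _hit("chrI", s, s + 9, f"m{j % 3}", "T")
            hits.append(h)
            for gid, w in wins.items():
                if w.start <= s and s + 9 <= w.end:
                    expected.setdefault(h.motif_id, set()).add(gid)
        sets, _ = genes_with_te_motifs(wins, hits)
        assert sets == expected


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    n_total=st.integers(1, 300),
    n_in=st.integers(0, 300),
    te_bp=st.integers(1, 50_000),
)
def test_record_invariants(n_total, n_in, te_bp):
    """fold and p stay consistent with their defining arithmetic."""
    n_in = min(n_in, n_total)
    genome_bp = 1_000_000
    p0 = te_bp / genome_bp
    fold = (n_in / n_total) / p0
    p = binomial_tail(n_in, n_total, p0)
    assert 0 <= p <= 1  # p may underflow to 0.0 for extreme enrichments
    if n_in == 0:
        assert p == 1.0
    if n_in > 0:
        assert fold > 0
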