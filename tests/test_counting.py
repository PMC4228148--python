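"""Read assignment, uniqueness filtering, QC statistics, bedGraph export."""

import math

import numpy as np
import pandas as pd
import pytest

from tgmseq import annotate, counting, simulate
from tgmseq.counting import (
    AlignmentRecord,
    antisense_fraction,
    count_reads,
    filter_unique,
    read_alignments,
    replicate_correlation,
    write_bedgraph,
)

from _oracles import pearson_oracle

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chrT\tLN:2300\n"


def rec(start, end, strand="+", chrom="chrT", n_hits=1, mapq=255):
    return AlignmentRecord(chrom, start, end, strand, n_hits=n_hits, mapq=mapq)


class TestReadAlignments:
    def test_bed_row_forward_dialect(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrI\t100\t200\tr1\t255\t+\n")
        (r,) = list(read_alignments(p, "forward"))
        assert (r.chrom, r.start, r.end, r.strand) == ("chrI", 100, 200, "+")

    def test_reverse_dialect_flips_fragment_strand(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrI\t100\t200\tr1\t255\t+\nchrI\t300\t400\tr2\t255\t-\n")
        strands = [r.strand for r in read_alignments(p, "reverse")]
        assert strands == ["-", "+"]

    def test_unknown_dialect_is_config_error(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrI\t100\t200\tr1\t255\t+\n")
        with pytest.raises(ValueError, match="dialect"):
            list(read_alignments(p, "sideways"))

    def test_sam_drops_secondary_and_unmapped(self, tmp_path):
        sam = SAM_HEADER + (
            "r1\t0\tchrT\t101\t42\t50M\t*\t0\t0\t*\t*\tNH:i:1\n"     # kept, plus
            "r2\t16\tchrT\t201\t42\t50M\t*\t0\t0\t*\t*\tNH:i:1\n"    # kept, minus
            "r3\t256\tchrT\t301\t42\t50M\t*\t0\t0\t*\t*\tNH:i:2\n"   # secondary
            "r4\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"                     # unmapped
        )
        p = tmp_path / "a.sam"
        p.write_text(sam)
        recs = list(read_alignments(p, "forward"))
        assert len(recs) == 2
        assert recs[0].start == 100 and recs[0].strand == "+"
        assert recs[1].strand == "-"

    def test_sam_pair_collapsed_to_fragment_span(self, tmp_path):
        # proper pair: r1 at 101 (tlen 200), mate at 251; one fragment [100, 300)
        sam = SAM_HEADER + (
            "p1\t99\tchrT\t101\t42\t50M\t=\t251\t200\t*\t*\tNH:i:1\n"
            "p1\t147\tchrT\t251\t42\t50M\t=\t101\t-200\t*\t*\tNH:i:1\n"
        )
        p = tmp_path / "a.sam"
        p.write_text(sam)
        recs = list(read_alignments(p, "forward"))
        assert len(recs) == 1
        assert (recs[0].start, recs[0].end) == (100, 300)


class TestFilterUnique:
    def test_multi_hit_dropped_and_logged(self):
        records = [rec(0, 50, n_hits=3), rec(0, 50, n_hits=1)]
        kept, drops = filter_unique(records, "hit-count")
        assert len(kept) == 1 and drops["multi_hit"] == 1

    def test_enumeration_of_drop_counts(self):
        records = [rec(i * 10, i * 10 + 50, n_hits=(3 if i < 4 else 1)) for i in range(10)]
        kept, drops = filter_unique(records, "hit-count")
        assert len(kept) == 6 and drops["multi_hit"] == 4

    def test_mapq_policy(self):
        records = [rec(0, 50, mapq=3), rec(0, 50, mapq=30)]
        kept, _ = filter_unique(records, "mapq", mapq_threshold=10)
        assert len(kept) == 1 and kept[0].mapq == 30

    def test_auto_uses_hit_count_when_present(self):
        records = [rec(0, 50, n_hits=2, mapq=60), rec(0, 50, n_hits=-1, mapq=60)]
        kept, _ = filter_unique(records, "auto")
        assert len(kept) == 1


class TestCountReads:
    def test_read_inside_window(self, two_gene_catalog):
        counts = count_reads([rec(120, 220, "+")], two_gene_catalog)
        assert counts.sum() == 1
        hit = counts[counts > 0].index[0]
        df = two_gene_catalog.to_frame()
        assert df.at[hit, "start"] == 0 and df.at[hit, "strand"] == "+"

    def test_boundary_read_assigned_by_five_prime_base(self, two_gene_catalog):
        # plus-strand read spanning window/window boundary: 5' base at 480
        counts = count_reads([rec(480, 580, "+")], two_gene_catalog)
        df = two_gene_catalog.to_frame()
        hit = counts[counts > 0].index[0]
        assert df.at[hit, "start"] == 0 and df.at[hit, "end"] == 500

    def test_minus_read_uses_rightmost_base(self, two_gene_catalog):
        # minus-strand fragment [450, 550): 5' base is 549 -> window [500,1000)
        counts = count_reads([rec(450, 550, "-")], two_gene_catalog)
        df = two_gene_catalog.to_frame()
        hit = counts[counts > 0].index[0]
        assert df.at[hit, "start"] == 500 and df.at[hit, "strand"] == "-"

    def test_zero_reads_zero_column(self, two_gene_catalog):
        assert count_reads([], two_gene_catalog).sum() == 0

    def test_conservation_every_record_counted_once(self, two_gene_catalog, rng):
        records = [
            rec(int(s), int(s) + 100, "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(0, 2200, 500)
        ]
        counts = count_reads(records, two_gene_catalog)
        assert counts.sum() == len(records)

    def test_strand_separation(self, two_gene_catalog, rng):
        records = [rec(int(s), int(s) + 80, "+") for s in rng.integers(0, 2200, 200)]
        counts = count_reads(records, two_gene_catalog)
        df = two_gene_catalog.to_frame()
        assert counts[df["strand"] == "-"].sum() == 0


class TestAntisenseFraction:
    def test_all_sense_is_zero(self, two_gene_catalog):
        records = [rec(1100, 1200, "+")]  # geneA is plus-strand
        assert antisense_fraction(records, two_gene_catalog) == 0.0

    def test_enumerated_fraction(self, two_gene_catalog):
        anti = [rec(1100, 1200, "-"), rec(1300, 1400, "-")]
        sense = [rec(100, 200, "+") for _ in range(8)]
        assert antisense_fraction(anti + sense, two_gene_catalog) == pytest.approx(0.2)

    def test_noncoding_gene_not_in_numerator(self):
        genes = [
            annotate.Region(
                "t1", annotate.GenomicInterval("c", 400, 480, "+"), annotate.ROLE_NONCODING
            )
        ]
        cat = annotate.partition_genome(genes, {"c": 1000})
        assert antisense_fraction([rec(420, 470, "-", chrom="c")], cat) == 0.0

    def test_zero_records_flagged_nan(self, two_gene_catalog):
        assert math.isnan(antisense_fraction([], two_gene_catalog))


class TestReplicateCorrelation:
    def test_identical_replicates_r_one(self, sheet_2v2, rng):
        col = rng.poisson(20, 300)
        mat = pd.DataFrame(
            {"wt_r1": col, "wt_r2": col, "mut_r1": col, "mut_r2": col + 1}
        )
        r = replicate_correlation(mat, sheet_2v2)
        assert r["wt"] == pytest.approx(1.0)

    def test_constant_column_flagged(self, sheet_2v2):
        mat = pd.DataFrame(
            {
                "wt_r1": np.zeros(50),
                "wt_r2": np.arange(50),
                "mut_r1": np.arange(50),
                "mut_r2": np.arange(50),
            }
        )
        assert math.isnan(replicate_correlation(mat, sheet_2v2)["wt"])

    def test_matches_textbook_pearson(self, sheet_2v2, rng):
        mat = pd.DataFrame(
            {s: rng.poisson(50, 10_000) for s in ["wt_r1", "wt_r2", "mut_r1", "mut_r2"]}
        )
        r = replicate_correlation(mat, sheet_2v2)
        for cond, cols in [("wt", ["wt_r1", "wt_r2"]), ("mut", ["mut_r1", "mut_r2"])]:
            expect = pearson_oracle(
                np.log2(mat[cols[0]] + 1), np.log2(mat[cols[1]] + 1)
            )
            assert r[cond] == pytest.approx(expect, abs=1e-12)


class TestBedgraph:
    def read_back(self, path):
        rows = []
        for line in path.read_text().splitlines():
            if line.startswith("track"):
                continue
            c, s, e, v = line.split("\t")
            rows.append((c, int(s), int(e), int(v)))
        return rows

    def test_single_read_single_line(self, tmp_path):
        out = tmp_path / "a.bedgraph"
        write_bedgraph([rec(100, 200, "+")], "+", out)
        assert self.read_back(out) == [("chrT", 100, 200, 1)]

    def test_overlapping_reads_three_runs(self, tmp_path):
        out = tmp_path / "a.bedgraph"
        write_bedgraph([rec(100, 200, "+"), rec(150, 250, "+")], "+", out)
        assert self.read_back(out) == [
            ("chrT", 100, 150, 1),
            ("chrT", 150, 200, 2),
            ("chrT", 200, 250, 1),
        ]

    def test_no_reads_empty_data(self, tmp_path):
        out = tmp_path / "a.bedgraph"
        write_bedgraph([], "+", out)
        assert self.read_back(out) == []

    def test_mass_equals_total_read_length(self, tmp_path, rng):
        records = [
            rec(int(s), int(s) + int(l), "+")
            for s, l in zip(rng.integers(0, 5000, 300), rng.integers(30, 150, 300))
        ]
        out = tmp_path / "a.bedgraph"
        write_bedgraph(records, "+", out)
        mass = sum(v * (e - s) for _, s, e, v in self.read_back(out))
        assert mass == sum(r.end - r.start for r in records)

    def test_other_strand_excluded(self, tmp_path):
        out = tmp_path / "a.bedgraph"
        write_bedgraph([rec(0, 50, "+"), rec(0, 50, "-")], "-", out)
        assert self.read_back(out) == [("chrT", 0, 50, 1)]


class TestEndToEndCounting:
    def test_simulated_reads_reproduce_count_matrix(self, standard_scenario):
        """Round trip: emit reads from counts, re-count, get the same matrix."""
        cfg = standard_scenario["config"]
        catalog = standard_scenario["catalog"]
        counts = standard_scenario["counts"]
        reads = simulate.simulate_reads(counts[["wildtype_rep1"]], catalog, cfg)
        recounted = count_reads(reads["wildtype_rep1"], catalog)
        assert recounted.equals(counts["wildtype_rep1"].rename("count"))
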