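"""Region catalog construction: partitioning, GFF/BED loading, site proximity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgmseq import annotate
from tgmseq.annotate import (
    GenomicInterval,
    PartitionConfig,
    PolIIISite,
    Region,
    load_annotation,
    nearest_polIII_site,
    partition_genome,
)

GFF_SMALL = """##gff-version 3
chrT\tsrc\tgene\t101\t700\t.\t+\t.\tID=YAA001;Name=YAA001
chrT\tsrc\ttRNA_gene\t901\t975\t.\t-\t.\tID=tT1;Name=tW(CAA)T
"""


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadAnnotation:
    def test_gene_and_trna_features(self, tmp_path):
        gff = write(tmp_path, "a.gff3", GFF_SMALL)
        sizes = write(tmp_path, "c.sizes", "chrT\t2000\n")
        genes, sites, chrom_sizes = load_annotation(gff, None, sizes)
        assert len(genes) == 2
        roles = {g.id: g.role for g in genes}
        assert roles["YAA001"] == annotate.ROLE_CODING
        assert roles["tT1"] == annotate.ROLE_NONCODING
        # 1-based inclusive GFF -> 0-based half-open
        assert (genes[0].interval.start, genes[0].interval.end) == (100, 700)
        assert len(sites) == 1 and sites[0].site_class == annotate.SITE_TDNA
        assert sites[0].name == "tW(CAA)T"
        assert chrom_sizes == {"chrT": 2000}

    def test_etc_bed_classified_from_label(self, tmp_path):
        gff = write(tmp_path, "a.gff3", GFF_SMALL)
        sizes = write(tmp_path, "c.sizes", "chrT\t2000\nchrVII\t20000\n")
        bed = write(tmp_path, "etc.bed", "chrVII\t10000\t10120\tETC9\n")
        _, sites, _ = load_annotation(gff, bed, sizes)
        etc = [s for s in sites if s.site_class == annotate.SITE_ETC]
        assert len(etc) == 1
        assert etc[0].name == "ETC9"
        assert (etc[0].interval.start, etc[0].interval.end) == (10000, 10120)

    def test_empty_bed_gives_no_sites_no_error(self, tmp_path):
        gff = write(tmp_path, "a.gff3", GFF_SMALL)
        sizes = write(tmp_path, "c.sizes", "chrT\t2000\n")
        bed = write(tmp_path, "empty.bed", "")
        _, sites, _ = load_annotation(gff, bed, sizes)
        assert [s for s in sites if s.site_class == annotate.SITE_ETC] == []

    def test_unknown_chromosome_is_hard_error(self, tmp_path):
        gff = write(tmp_path, "a.gff3", GFF_SMALL)
        sizes = write(tmp_path, "c.sizes", "chrOther\t2000\n")
        with pytest.raises(ValueError, match="chrT"):
            load_annotation(gff, None, sizes)


class TestPartition:
    def test_empty_chromosome_splits_into_even_windows(self):
        cat = partition_genome([], {"chrT": 1000})
        for strand in "+-":
            wins = [
                (r.interval.start, r.interval.end)
                for r in cat.windows()
                if r.interval.strand == strand
            ]
            assert wins == [(0, 500), (500, 1000)]

    def test_gene_blocks_and_remainder_rule(self, two_gene_catalog):
        plus = [
            (r.interval.start, r.interval.end)
            for r in two_gene_catalog.windows()
            if r.interval.strand == "+"
        ]
        # blocks [0,1000) and [1600,2300); 700-b block -> 500 + 200 remainder window
        assert plus == [(0, 500), (500, 1000), (1600, 2100), (2100, 2300)]

    def test_block_of_exactly_window_size_stays_whole(self):
        genes = [
            Region("g1", GenomicInterval("c", 0, 100, "+"), annotate.ROLE_CODING),
            Region("g2", GenomicInterval("c", 600, 700, "+"), annotate.ROLE_CODING),
        ]
        cat = partition_genome(genes, {"c": 700})
        plus = [
            (r.interval.start, r.interval.end)
            for r in cat.windows()
            if r.interval.strand == "+"
        ]
        assert plus == [(100, 600)]

    def test_short_remainder_merges_into_last_window(self):
        # block of 550: remainder 50 < min_window 100 -> single last window of 550
        cat = partition_genome([], {"c": 1050}, PartitionConfig())
        plus = [
            (r.interval.start, r.interval.end)
            for r in cat.windows()
            if r.interval.strand == "+"
        ]
        assert plus == [(0, 500), (500, 1050)]

    def test_flank_genes_recorded(self, two_gene_catalog):
        df = two_gene_catalog.to_frame()
        right_block = df[(df["strand"] == "+") & (df["start"] == 1600)]
        assert (right_block["flank_left_gene"] == "geneA").all()
        left_block = df[(df["strand"] == "+") & (df["start"] == 0)]
        assert (left_block["flank_right_gene"] == "geneA").all()

    def test_overlapping_genes_merged_into_one_footprint(self):
        genes = [
            Region("g1", GenomicInterval("c", 100, 400, "+"), annotate.ROLE_CODING),
            Region("g2", GenomicInterval("c", 300, 600, "+"), annotate.ROLE_CODING),
        ]
        cat = partition_genome(genes, {"c": 1000})
        plus = [
            (r.interval.start, r.interval.end)
            for r in cat.windows()
            if r.interval.strand == "+"
        ]
        assert plus == [(0, 100), (600, 1000)]

    def test_noncoding_excluded_when_configured(self):
        genes = [Region("t1", GenomicInterval("c", 400, 480, "+"), annotate.ROLE_NONCODING)]
        cfg = PartitionConfig(include_noncoding_in_genespace=False)
        cat = partition_genome(genes, {"c": 1000}, cfg)
        plus = [
            (r.interval.start, r.interval.end)
            for r in cat.windows()
            if r.interval.strand == "+"
        ]
        assert plus == [(0, 500), (500, 1000)]  # tDNA footprint not subtracted

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 4800), st.integers(50, 900), st.sampled_from("+-")
            ),
            min_size=0,
            max_size=12,
        ),
        st.integers(1000, 5000),
    )
    def test_partition_complete_and_disjoint(self, gene_specs, length):
        """Per strand, gene footprints + windows tile [0, length) exactly."""
        genes = [
            Region(
                f"g{i}",
                GenomicInterval("c", s, min(s + l, length), strand),
                annotate.ROLE_CODING,
            )
            for i, (s, l, strand) in enumerate(gene_specs)
            if s < length
        ]
        cat = partition_genome(genes, {"c": length})
        df = cat.to_frame()
        for strand in "+-":
            sub = df[df["strand"] == strand].sort_values("start")
            # merge gene footprints for the coverage check (overlaps allowed in input)
            covered = np.zeros(length, dtype=int)
            for row in sub.itertuples():
                covered[row.start : row.end] += 1
            window_rows = sub[sub["role"] == annotate.ROLE_WINDOW]
            win_cov = np.zeros(length, dtype=int)
            for row in window_rows.itertuples():
                win_cov[row.start : row.end] += 1
            assert (win_cov <= 1).all(), "windows overlap"
            assert (covered >= 1).all(), "partition gap"
            # windows never overlap any same-strand gene
            gene_cov = np.zeros(length, dtype=bool)
            for row in sub[sub["role"] != annotate.ROLE_WINDOW].itertuples():
                gene_cov[row.start : row.end] = True
            assert not (gene_cov & (win_cov > 0)).any()

    def test_partition_idempotent(self, two_gene_catalog):
        """Re-partitioning with the catalog's own gene set reproduces the windows."""
        cat2 = partition_genome(
            two_gene_catalog.genes(),
            two_gene_catalog.chrom_sizes,
            two_gene_catalog.partition_config,
        )
        a = two_gene_catalog.to_frame()[["chrom", "start", "end", "strand", "role"]]
        b = cat2.to_frame()[["chrom", "start", "end", "strand", "role"]]
        assert a.equals(b)

    def test_window_lengths_bounded(self, standard_scenario):
        cfg = standard_scenario["catalog"].partition_config
        for w in standard_scenario["catalog"].windows():
            n = len(w.interval)
            block_windows = [
                x for x in standard_scenario["catalog"].windows() if x.block_id == w.block_id
            ]
            if len(block_windows) == 1:
                assert n < cfg.window_size + cfg.min_window
            else:
                assert cfg.min_window <= n < cfg.window_size + cfg.min_window


class TestNearestSite:
    def site(self, start, end, chrom="c", cls=annotate.SITE_TDNA):
        return PolIIISite(f"s{start}", GenomicInterval(chrom, start, end), cls)

    def test_abutting_interval_distance_zero(self):
        region = GenomicInterval("c", 1000, 1500)
        _, d = nearest_polIII_site(region, [self.site(1500, 1580)])
        assert d == 0

    def test_gap_distance(self):
        region = GenomicInterval("c", 1000, 1500)
        _, d = nearest_polIII_site(region, [self.site(1700, 1780)])
        assert d == 200

    def test_overlap_distance_zero(self):
        region = GenomicInterval("c", 1000, 1500)
        _, d = nearest_polIII_site(region, [self.site(1400, 1475)])
        assert d == 0

    def test_empty_registry_sentinel(self):
        site, d = nearest_polIII_site(GenomicInterval("c", 0, 10), [])
        assert site is annotate.NO_SITE and math.isinf(d)

    def test_tie_broken_by_smaller_start(self):
        region = GenomicInterval("c", 1000, 1500)
        site, d = nearest_polIII_site(
            region, [self.site(1600, 1650), self.site(850, 900)]
        )
        assert d == 100 and site.interval.start == 850

    def test_agrees_with_brute_force(self, rng):
        sites = [
            self.site(int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 99000, 80), rng.integers(60, 150, 80))
        ]
        for _ in range(1000):
            s = int(rng.integers(0, 99000))
            region = GenomicInterval("c", s, s + int(rng.integers(50, 600)))
            best, d = nearest_polIII_site(region, sites)
            brute = min(region.gap_to(x.interval) for x in sites)
            assert d == brute
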