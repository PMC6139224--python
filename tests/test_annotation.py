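"""Genomic annotation: nearest-TSS mapping, region and CpG-context rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medeg import (
    annotate_probes,
    classify_cpg_context,
    classify_region,
    map_probe_to_gene,
    percent,
    summarize_genomic_distribution,
)
from medeg.annotation import REGIONS
from medeg.exceptions import ValidationError


def make_gene(gene_id="g1", chrom="chr1", strand="+", tx_start=10_000,
              tx_end=20_000, cds_start=None, cds_end=None, first_exon_end=None):
    cds_start = cds_start if cds_start is not None else tx_start + 400
    cds_end = cds_end if cds_end is not None else tx_end - 400
    tss = tx_start if strand == "+" else tx_end - 1
    if first_exon_end is None:
        first_exon_end = tx_start + 600 if strand == "+" else tx_end - 600
    return pd.Series(
        {
            "chrom": chrom, "strand": strand, "tss": tss,
            "tx_start": tx_start, "tx_end": tx_end,
            "cds_start": cds_start, "cds_end": cds_end,
            "first_exon_end": first_exon_end,
        },
        name=gene_id,
    )


def gene_frame(genes):
    return pd.DataFrame(genes).rename_axis("gene_id")


class TestNearestTss:
    def test_probe_at_tss(self):
        genes = gene_frame([make_gene("g1")])
        assert map_probe_to_gene(10_000, "chr1", genes) == "g1"

    def test_strict_ten_kb_boundary(self):
        genes = gene_frame([make_gene("g1")])
        assert map_probe_to_gene(0, "chr1", genes) is None          # exactly 10 kb
        assert map_probe_to_gene(1, "chr1", genes) == "g1"          # 9,999 bp

    def test_nearest_of_two(self):
        genes = gene_frame(
            [make_gene("ga", tx_start=10_300, tx_end=20_000),
             make_gene("gb", tx_start=10_500, tx_end=21_000)]
        )
        assert map_probe_to_gene(10_000, "chr1", genes) == "ga"

    def test_tie_lexicographic(self):
        genes = gene_frame(
            [make_gene("gz", tx_start=9_900, tx_end=19_000),
             make_gene("ga", tx_start=10_100, tx_end=20_000)]
        )
        assert map_probe_to_gene(10_000, "chr1", genes) == "ga"

    def test_wrong_chromosome_unmapped(self):
        genes = gene_frame([make_gene("g1")])
        assert map_probe_to_gene(10_000, "chr2", genes) is None

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_all_pairs_scan(self, data):
        n = data.draw(st.integers(1, 50))
        tss = data.draw(
            st.lists(st.integers(0, 500_000), min_size=n, max_size=n)
        )
        genes = gene_frame(
            [make_gene(f"g{i:03d}", tx_start=t, tx_end=t + 10_000)
             for i, t in enumerate(tss)]
        )
        pos = data.draw(st.integers(0, 500_000))
        got = map_probe_to_gene(pos, "chr1", genes)
        # oracle: exhaustive scan with explicit tie rule
        best = None
        for gid, row in genes.iterrows():
            d = abs(int(row["tss"]) - pos)
            if d < 10_000 and (best is None or (d, gid) < best):
                best = (d, gid)
        assert got == (best[1] if best else None)


class TestRegionClassification:
    @pytest.mark.parametrize(
        "pos, expected",
        [
            (9_900, "TSS200"),     # 100 bp upstream
            (9_000, "TSS1500"),    # 1,000 bp upstream
            (10_200, "5'UTR"),
            (10_500, "1stExon"),
            (15_000, "Body"),
            (19_800, "3'UTR"),
            (8_000, "IGR"),        # 2 kb upstream, outside all bands
            (21_000, "IGR"),
        ],
    )
    def test_plus_strand(self, pos, expected):
        assert classify_region(pos, make_gene()) == expected

    @pytest.mark.parametrize(
        "pos, expected",
        [
            (20_050, "TSS200"),
            (20_900, "TSS1500"),
            (19_800, "5'UTR"),
            (19_450, "1stExon"),
            (15_000, "Body"),
            (10_200, "3'UTR"),
            (22_000, "IGR"),
        ],
    )
    def test_minus_strand(self, pos, expected):
        assert classify_region(pos, make_gene(strand="-")) == expected

    def test_malformed_gene_rejected(self):
        bad = make_gene(cds_start=9_000)  # CDS starts before the transcript
        with pytest.raises(ValidationError):
            classify_region(15_000, bad)

    def test_categories_partition(self):
        gene = make_gene()
        for pos in range(8_000, 22_000, 37):
            region = classify_region(pos, gene)
            assert region in REGIONS


class TestCpgContext:
    islands = pd.DataFrame(
        {"chrom": ["chr1"], "start": [10_000], "end": [11_000]}
    )

    @pytest.mark.parametrize(
        "pos, expected",
        [
            (10_500, "island"),
            (12_499, "shore"),     # 1,500 bp past the edge
            (13_999, "shelf"),     # 3,000 bp
            (15_999, "open_sea"),  # 5,000 bp
            (8_500, "shore"),      # upstream side
        ],
    )
    def test_distance_bands(self, pos, expected):
        assert classify_cpg_context(pos, "chr1", self.islands) == expected

    def test_no_islands_open_sea(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        assert classify_cpg_context(500, "chr1", empty) == "open_sea"


class TestAnnotateProbes:
    def test_matches_scalar_operations(self):
        rng = np.random.default_rng(8)
        genes = gene_frame(
            [make_gene(f"g{i:03d}", tx_start=int(t), tx_end=int(t) + 10_000,
                       strand=rng.choice(["+", "-"]))
             for i, t in enumerate(np.sort(rng.integers(0, 400_000, 25)))]
        )
        islands = pd.DataFrame(
            {"chrom": "chr1", "start": [50_000, 150_000], "end": [51_000, 151_500]}
        )
        probes = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.integers(0, 450_000, 300)},
            index=pd.Index([f"cg{i:04d}" for i in range(300)], name="probe_id"),
        )
        ctx = annotate_probes(probes, genes, islands)
        for probe_id, row in probes.iterrows():
            pos = int(row["pos"])
            gid = map_probe_to_gene(pos, "chr1", genes)
            assert ctx.loc[probe_id, "gene_id"] == gid
            expected_region = (
                classify_region(pos, genes.loc[gid]) if gid else "IGR"
            )
            assert ctx.loc[probe_id, "region"] == expected_region
            assert ctx.loc[probe_id, "cpg_context"] == classify_cpg_context(
                pos, "chr1", islands
            )

    def test_every_mapped_probe_has_one_region(self, small_cohort):
        ctx = annotate_probes(
            small_cohort.meth_annotation,
            small_cohort.gene_models,
            small_cohort.cpg_islands,
        )
        assert ctx["region"].isin(REGIONS).all()
        unmapped = ctx["gene_id"].isna()
        assert (ctx.loc[unmapped, "region"] == "IGR").all()


class TestDistributionSummary:
    def test_even_split(self):
        ctx = pd.DataFrame(
            {
                "cpg_context": ["island", "island", "open_sea", "open_sea"],
                "region": ["Body"] * 4,
                "gene_id": None,
                "tss_distance": np.nan,
            },
            index=["a", "b", "c", "d"],
        )
        out = summarize_genomic_distribution(ctx, {"a", "b", "c", "d"})
        cc = out[out["kind"] == "cpg_context"].set_index("category")
        assert cc.loc["island", "percent"] == 50
        assert cc.loc["open_sea", "percent"] == 50

    def test_island_minority_percentage(self):
        # 45 island probes of 925 round to the reported 5%
        assert percent(45, 925) == 5
        assert percent(782, 925) == 85

    def test_empty_dmp_set(self):
        ctx = pd.DataFrame(
            columns=["gene_id", "tss_distance", "region", "cpg_context"]
        )
        out = summarize_genomic_distribution(ctx, set())
        assert out.empty

    def test_percentages_sum_to_about_100(self, small_cohort):
        ctx = annotate_probes(
            small_cohort.meth_annotation,
            small_cohort.gene_models,
            small_cohort.cpg_islands,
        )
        dmps = set(ctx.index[:250])
        out = summarize_genomic_distribution(ctx, dmps)
        for kind in ("cpg_context", "region"):
            sub = out[out["kind"] == kind]
            assert sub["count"].sum() == 250
            assert abs(sub["percent"].sum() - 100) <= len(sub) // 2 + 1
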