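"""CNV surrogate caller: binning, ratios, segmentation, significance,
recurrent regions, summaries, gene overlap."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hapdrive.cnv import (
    bin_coverage,
    call_cnvs,
    gene_overlap,
    ratio_profile,
    recurrent_regions,
    score_segments,
    segment_profile,
    summarize_cnv,
)


def grid_df(n_bins, count, chrom="chr1", bin_size=50_000):
    starts = np.arange(n_bins) * bin_size
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + bin_size,
            "count": np.asarray(count, dtype=int),
        }
    )


def meta_table(clones_by_drug):
    rows = []
    for drug, clones in clones_by_drug.items():
        for c in clones:
            rows.append([c, drug, f"{drug}-WT", c, "WGS"])
    return pd.DataFrame(
        rows, columns=["clone_id", "drug", "parent_id", "lineage_id", "assay"]
    )


def seg(clone, start, end, status="loss", chrom="chr1"):
    return {
        "chrom": chrom, "start": start, "end": end, "n_bins": (end - start) // 50_000,
        "mean_ratio": 0.0 if status == "loss" else 3.0,
        "copy_number": 0 if status == "loss" else 3,
        "status": status, "clone_id": clone,
    }


class TestBinCoverage:
    def test_one_mb_in_50kb_bins_gives_20_bins(self):
        bins = bin_coverage({"chr1": [0, 1]}, {"chr1": 1_000_000})
        assert len(bins) == 20
        assert bins["end"].iloc[-1] == 1_000_000

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 1_000_000, size=5000)
        bins = bin_coverage({"chr1": pos}, {"chr1": 1_000_000})
        assert bins["count"].sum() == 5000

    def test_matches_naive_per_position_tally(self):
        rng = np.random.default_rng(1)
        length, bin_size = 730_001, 50_000  # short terminal bin
        pos = rng.integers(0, length, size=3000)
        bins = bin_coverage({"chr1": pos}, {"chr1": length}, bin_size)
        naive = {}
        for p in pos:
            naive[p // bin_size] = naive.get(p // bin_size, 0) + 1
        for i, row in bins.iterrows():
            assert row["count"] == naive.get(row["start"] // bin_size, 0)


class TestRatioProfile:
    def test_identical_clone_and_parent_gives_unit_ratio(self):
        bins = grid_df(40, np.full(40, 1000))
        profile = ratio_profile(bins, bins)
        assert np.allclose(profile["ratio"], 1.0)

    def test_planted_triplication_has_ratio_near_3(self):
        rng = np.random.default_rng(2)
        parent = grid_df(200, rng.poisson(2000, 200))
        clone_counts = rng.poisson(2000, 200)
        clone_counts[50:110] = rng.poisson(6000, 60)
        clone = grid_df(200, clone_counts)
        profile = ratio_profile(clone, parent)
        inside = profile["ratio"].iloc[50:110].mean()
        assert 2.7 < inside < 3.3

    def test_masked_bins_never_reach_segments(self):
        parent_counts = np.full(40, 1000)
        parent_counts[10:14] = 0  # coverage gap in the control
        clone_counts = np.full(40, 1000)
        clone_counts[10:14] = 4000
        profile = ratio_profile(grid_df(40, clone_counts), grid_df(40, parent_counts))
        assert profile["masked"].iloc[10:14].all()
        segs = segment_profile(profile)
        assert len(segs) == 0

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="grids"):
            ratio_profile(grid_df(10, np.ones(10)), grid_df(11, np.ones(11)))


class TestSegmentation:
    def test_flat_profile_yields_no_segments(self):
        profile = ratio_profile(grid_df(60, np.full(60, 900)), grid_df(60, np.full(60, 900)))
        assert len(segment_profile(profile)) == 0

    def test_planted_homozygous_deletion_recovered_exactly(self):
        rng = np.random.default_rng(3)
        parent = grid_df(100, rng.poisson(3000, 100))
        counts = rng.poisson(3000, 100)
        counts[20:24] = 0  # copy-0 deletion over 4 bins
        profile = ratio_profile(grid_df(100, counts), parent)
        segs = segment_profile(profile)
        assert len(segs) == 1
        s = segs.iloc[0]
        assert s["status"] == "loss" and s["copy_number"] == 0
        assert abs(s["start"] - 20 * 50_000) <= 50_000
        assert abs(s["end"] - 24 * 50_000) <= 50_000

    def test_run_interrupted_by_single_masked_bin_is_merged(self):
        parent_counts = np.full(60, 1000)
        parent_counts[30] = 0
        clone_counts = np.full(60, 1000)
        clone_counts[25:36] = 3000
        profile = ratio_profile(grid_df(60, clone_counts), grid_df(60, parent_counts))
        segs = segment_profile(profile)
        assert len(segs) == 1
        assert segs.iloc[0]["n_bins"] == 10  # 11 bins minus the masked one

    def test_gain_copy_number_rounds_from_mean_ratio(self):
        parent = grid_df(50, np.full(50, 2000))
        counts = np.full(50, 2000)
        counts[10:20] = 6000
        segs = segment_profile(ratio_profile(grid_df(50, counts), parent))
        assert segs.iloc[0]["copy_number"] == 3
        assert segs.iloc[0]["status"] == "gain"


class TestScoring:
    def test_background_identical_segment_dropped(self):
        profile = ratio_profile(grid_df(80, np.full(80, 1000)), grid_df(80, np.full(80, 1000)))
        fake = pd.DataFrame([seg("c1", 0, 150_000)])
        scored = score_segments(fake, profile)
        assert len(scored) == 0  # all-tied input: p = 1, dropped

    def test_strong_planted_gain_retained(self):
        rng = np.random.default_rng(4)
        parent = grid_df(300, rng.poisson(3000, 300))
        counts = rng.poisson(3000, 300)
        counts[100:160] = rng.poisson(9000, 60)
        profile = ratio_profile(grid_df(300, counts), parent)
        segs = segment_profile(profile, clone_id="c1")
        scored = score_segments(segs, profile)
        assert len(scored) == 1
        assert scored.iloc[0]["q_value"] < 0.05

    def test_bh_matches_direct_formula(self):
        """Our q-values equal the step-up formula computed from scratch."""
        from scipy.stats import false_discovery_control

        rng = np.random.default_rng(5)
        pvals = rng.uniform(0, 1, size=17)

        def bh_oracle(p):
            p = np.asarray(p, dtype=float)
            n = len(p)
            order = np.argsort(p)
            q = np.empty(n)
            running = 1.0
            for rank_from_end, idx in enumerate(order[::-1]):
                rank = n - rank_from_end
                running = min(running, p[idx] * n / rank)
                q[idx] = running
            return q

        assert np.allclose(false_discovery_control(pvals, method="bh"), bh_oracle(pvals))


class TestRecurrentRegions:
    def test_shared_deletion_recurrent_single_and_universal_excluded(self):
        meta = meta_table({"TPT": [f"TPT-R{i}" for i in range(1, 7)]})
        segments = pd.DataFrame(
            [
                # shared by R1, R2, R3 out of six: recurrent
                seg("TPT-R1", 1_000_000, 2_000_000),
                seg("TPT-R2", 1_200_000, 2_200_000),
                seg("TPT-R3", 1_100_000, 1_900_000),
                # single clone elsewhere: not recurrent
                seg("TPT-R4", 5_000_000, 5_400_000),
            ]
        )
        regions = recurrent_regions(segments, meta)
        assert len(regions) > 0
        assert (regions["n_clones"] >= 2).all()
        covered = regions[(regions["start"] <= 1_500_000) & (regions["end"] >= 1_400_000)]
        assert len(covered) == 1 and covered.iloc[0]["n_clones"] == 3
        assert not ((regions["start"] >= 5_000_000) & (regions["end"] <= 5_400_000)).any()

    def test_region_in_all_clones_of_drug_excluded(self):
        meta = meta_table({"GEM": ["GEM-R1", "GEM-R2", "GEM-R3"]})
        segments = pd.DataFrame(
            [seg(c, 1_000_000, 2_000_000) for c in ["GEM-R1", "GEM-R2", "GEM-R3"]]
        )
        assert len(recurrent_regions(segments, meta)) == 0

    def test_matches_hand_enumeration_with_partial_overlaps(self):
        meta = meta_table({"DOX": ["DOX-R1", "DOX-R2", "DOX-R3"]})
        segments = pd.DataFrame(
            [
                seg("DOX-R1", 0, 300_000),
                seg("DOX-R2", 100_000, 400_000),
                seg("DOX-R3", 200_000, 250_000),
            ]
        )
        regions = recurrent_regions(segments, meta)
        got = [
            (r["start"], r["end"], r["n_clones"]) for _, r in regions.iterrows()
        ]
        # hand enumeration: [100k,200k) R1+R2; [200k,250k) all three (excluded);
        # [250k,300k) R1+R2
        assert got == [(100_000, 200_000, 2), (250_000, 300_000, 2)]

    def test_supporters_strictly_between_one_and_all(self, small_experiment):
        exp = small_experiment
        meta = exp.metadata
        parent_of = meta.set_index("clone_id")["parent_id"]
        segs = []
        for c in meta["clone_id"]:
            segs.append(
                call_cnvs(
                    exp.clone_bins[c], exp.parent_bins[parent_of[c]], c,
                    diploid_regions=exp.genome.diploid_regions,
                )
            )
        segments = pd.concat(segs, ignore_index=True)
        regions = recurrent_regions(segments, meta)
        n_by_drug = meta.groupby("drug")["clone_id"].nunique()
        for _, r in regions.iterrows():
            assert 2 <= r["n_clones"] < n_by_drug[r["drug"]]


class TestSummary:
    def test_empty_input_gives_zeros(self):
        out = summarize_cnv(pd.DataFrame(columns=["chrom", "start", "end", "status"]),
                            {"chr1": 10})
        assert out["n_gain"] == 0 and out["genome_fraction"] == 0.0

    def test_two_segment_arithmetic(self):
        segments = pd.DataFrame(
            [seg("c", 0, 1_000_000, "gain"), seg("c", 0, 3_000_000, "loss", "chr2")]
        )
        out = summarize_cnv(segments, {"chr1": 10_000_000, "chr2": 10_000_000})
        assert out["n_gain"] == 1 and out["n_loss"] == 1
        assert out["mean_size"] == 2_000_000
        assert out["min_size"] == 1_000_000 and out["max_size"] == 3_000_000
        assert out["genome_fraction"] == pytest.approx(0.2)
        assert out["per_chromosome_density"]["chr2"] == pytest.approx(1e-7)

    def test_summary_matches_planted_truth(self, small_experiment):
        truth = pd.DataFrame(small_experiment.truth.cnvs)
        segments = truth.rename(columns={"copy_number": "copy"}).assign(
            status=lambda d: np.where(d["copy"] >= 2, "gain", "loss")
        )
        chrom_lengths = dict(small_experiment.genome.chromosomes)
        out = summarize_cnv(segments, chrom_lengths)
        sizes = truth["end"] - truth["start"]
        assert out["mean_size"] == pytest.approx(sizes.mean())
        assert out["n_gain"] + out["n_loss"] == len(truth)


class TestGeneOverlap:
    def test_region_with_one_gene_returns_it(self, small_genome):
        g = small_genome.genes.genes[0]
        regions = pd.DataFrame(
            [{"chrom": g.chrom, "start": g.start - 1, "end": g.end}]
        )
        out = gene_overlap(regions, small_genome.genes)
        assert out[(g.chrom, g.start - 1, g.end)] == [g.gene_name]

    def test_matches_brute_force_intersection(self, small_genome):
        rng = np.random.default_rng(6)
        genes = list(small_genome.genes)
        for _ in range(25):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            start = int(rng.integers(0, 1_900_000))
            end = start + int(rng.integers(1, 150_000))
            regions = pd.DataFrame([{"chrom": chrom, "start": start, "end": end}])
            got = gene_overlap(regions, small_genome.genes)[(chrom, start, end)]
            expect = [
                g.gene_name for g in genes
                if g.chrom == chrom and g.end >= start + 1 and g.start <= end
            ]
            assert got == expect
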