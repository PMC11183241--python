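"""Candidate-selection cascade, recurrence rescue, blocklist, reports."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pandas as pd
import pytest

import hapdrive as hd
from hapdrive.prioritize import (
    CASCADE_STAGES,
    PrioritizationConfig,
    af_threshold_from_quantile,
    attach_metadata,
    blocklist_filter,
    build_candidate_table,
    build_secondary_report,
    drug_specific_filter,
    filter_cascade,
    post_impact_variants,
    prioritize,
    recurrence_rescue,
)


def meta_table(rows):
    return pd.DataFrame(
        rows, columns=["clone_id", "drug", "parent_id", "lineage_id", "assay"]
    )


def variant_row(clone, gene, af, impact="MODERATE", so="missense_variant",
                pos=100, chrom="chr1", ref="A", alt="T", dp=40, change="Ala1Val",
                cls="Missense"):
    return {
        "clone_id": clone, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "kind": "SNV", "filter_status": "PASS", "gene_id": gene,
        "gene_name": gene, "transcript_id": f"{gene}.t1", "so_term": so,
        "impact": impact, "consolidated_class": cls, "protein_change": change,
        "protein_pos": 1, "af": af, "dp": dp,
    }


@pytest.fixture
def ptx_meta():
    return meta_table(
        [
            ["PTX-R1", "PTX", "WT", "PTX-R1", "WGS"],
            ["PTX-R2a", "PTX", "WT", "PTX-R2", "WGS"],
            ["PTX-R2b", "PTX", "WT", "PTX-R2", "WGS"],
            ["PTX-R6", "PTX", "WT", "PTX-R6", "WGS"],
            ["GEM-R1", "GEM", "WT", "GEM-R1", "WGS"],
            ["GEM-R2", "GEM", "WT", "GEM-R2", "WGS"],
        ]
    )


class TestQuantileThreshold:
    def test_constant_values_return_that_value(self):
        assert af_threshold_from_quantile([0.3] * 10, 0.975) == 0.3

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.beta(0.8, 3.0, size=10_000)

        def oracle(v, q):
            s = np.sort(np.asarray(v, dtype=float))
            h = (len(s) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(s) - 1)
            return s[lo] + (h - lo) * (s[hi] - s[lo])

        for q in (0.5, 0.9, 0.975, 0.999):
            assert af_threshold_from_quantile(values, q) == pytest.approx(
                oracle(values, q), abs=1e-12
            )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            af_threshold_from_quantile([], 0.975)


class TestDrugSpecificFilter:
    def test_single_drug_variant_kept_shared_variant_removed(self, ptx_meta):
        df = pd.DataFrame(
            [
                variant_row("GEM-R1", "DCK", 0.9, pos=10),
                variant_row("GEM-R1", "X1", 0.9, pos=20),
                variant_row("PTX-R1", "X1", 0.9, pos=20),
            ]
        )
        out = drug_specific_filter(attach_metadata(df, ptx_meta), ptx_meta)
        assert set(out["gene_name"]) == {"DCK"}  # removed from both drugs

    def test_matches_brute_force_cross_drug_oracle(self, ptx_meta):
        rng = random.Random(3)
        clones = list(ptx_meta["clone_id"])
        drug_of = dict(zip(ptx_meta["clone_id"], ptx_meta["drug"]))
        for _ in range(20):
            rows = [
                variant_row(rng.choice(clones), "G", 0.5, pos=rng.randrange(1, 15))
                for _ in range(40)
            ]
            df = attach_metadata(pd.DataFrame(rows), ptx_meta)
            out = drug_specific_filter(df, ptx_meta)
            # oracle: key -> set of drugs
            drugs_by_key = {}
            for r in rows:
                key = (r["chrom"], r["pos"], r["ref"], r["alt"])
                drugs_by_key.setdefault(key, set()).add(drug_of[r["clone_id"]])
            expect = [
                r for r in rows
                if len(drugs_by_key[(r["chrom"], r["pos"], r["ref"], r["alt"])]) == 1
            ]
            assert len(out) == len(expect)


class TestCascade:
    def test_stage_examples(self, ptx_meta):
        df = pd.DataFrame(
            [
                # survives everything: high-AF coding missense
                variant_row("PTX-R1", "TOP2A", 0.89, pos=1),
                # fails the AF stage only (rescued downstream)
                variant_row("GEM-R1", "DCK", 0.78, pos=2, change="Ser129Tyr"),
                # removed at the coding stage despite AF 1.0
                variant_row("PTX-R1", "NONE", 1.0, pos=3, impact="MODIFIER",
                            so="intergenic_variant", cls="Intergenic"),
                # LOW impact removed at the impact stage
                variant_row("PTX-R1", "SYN", 0.95, pos=4, impact="LOW",
                            so="synonymous_variant", cls="Synonymous"),
                # high AF but below callable depth
                variant_row("PTX-R6", "LOWDP", 0.99, pos=5, dp=6),
            ]
        )
        survivors, funnel = filter_cascade(df, PrioritizationConfig(), ptx_meta)
        assert list(survivors["gene_name"]) == ["TOP2A"]
        totals = funnel.totals
        assert list(totals[list(CASCADE_STAGES)]) == [5, 5, 4, 3, 1]

    def test_funnel_counts_non_increasing(self, small_genome):
        config = hd.SimExperimentConfig(
            drugs=("DOX", "TPT"), selections_per_drug=2,
            passenger_model=hd.PassengerModel(rate=150), cnv_specs={}, seed=3,
        )
        exp = hd.simulate_experiment(small_genome, config)
        calls = [c for cs in exp.clone_calls.values() for c in cs]
        ann = attach_metadata(
            hd.annotate_table(calls, small_genome.genes, small_genome.sequences),
            exp.metadata,
        )
        _, funnel = filter_cascade(ann, PrioritizationConfig(), exp.metadata)
        counts = funnel.per_clone[list(CASCADE_STAGES)].to_numpy()
        assert (np.diff(counts, axis=1) <= 0).all()


class TestRecurrenceRescue:
    def test_two_independent_lineages_rescued(self, ptx_meta):
        df = attach_metadata(
            pd.DataFrame(
                [
                    variant_row("PTX-R2b", "SLCO3A1", 0.55, pos=1, change="Ile587Asn"),
                    variant_row("PTX-R6", "SLCO3A1", 0.47, pos=2, change="Ala263Thr"),
                ]
            ),
            ptx_meta,
        )
        rescued = recurrence_rescue(df, ptx_meta, PrioritizationConfig())
        assert list(rescued["gene"]) == ["SLCO3A1"]
        assert rescued["rescue_reason"].iloc[0] == "recurrence"
        assert rescued["n_independent_lineages"].iloc[0] == 2

    def test_same_amino_acid_change_in_two_lineages_counts(self, ptx_meta):
        df = attach_metadata(
            pd.DataFrame(
                [
                    variant_row("GEM-R1", "DCK", 0.78, pos=9, change="Ser129Tyr"),
                    variant_row("GEM-R2", "DCK", 0.70, pos=9, change="Ser129Tyr"),
                ]
            ),
            ptx_meta,
        )
        rescued = recurrence_rescue(df, ptx_meta, PrioritizationConfig())
        assert list(rescued["gene"]) == ["DCK"]

    def test_dependent_clones_collapse_to_one_lineage(self, ptx_meta):
        df = attach_metadata(
            pd.DataFrame(
                [
                    variant_row("PTX-R2a", "USP47", 0.6, pos=1),
                    variant_row("PTX-R2b", "USP47", 0.6, pos=2),
                ]
            ),
            ptx_meta,
        )
        assert len(recurrence_rescue(df, ptx_meta, PrioritizationConfig())) == 0

    def test_below_rescue_floor_not_rescued(self, ptx_meta):
        df = attach_metadata(
            pd.DataFrame(
                [
                    variant_row("PTX-R1", "X", 0.2, pos=1),
                    variant_row("PTX-R6", "X", 0.9, pos=2),
                ]
            ),
            ptx_meta,
        )
        assert len(recurrence_rescue(df, ptx_meta, PrioritizationConfig())) == 0

    def test_matches_brute_force_oracle_on_random_tables(self, ptx_meta):
        """Randomized variant tables against an independent set computation."""
        rng = random.Random(11)
        clones = list(ptx_meta["clone_id"])
        lineage_of = dict(zip(ptx_meta["clone_id"], ptx_meta["lineage_id"]))
        drug_of = dict(zip(ptx_meta["clone_id"], ptx_meta["drug"]))
        config = PrioritizationConfig()
        for trial in range(30):
            rows = [
                variant_row(
                    rng.choice(clones), f"G{rng.randrange(6)}",
                    round(rng.uniform(0.05, 1.0), 2), pos=rng.randrange(1, 30),
                )
                for _ in range(25)
            ]
            df = attach_metadata(pd.DataFrame(rows), ptx_meta)
            got = set(
                zip(
                    recurrence_rescue(df, ptx_meta, config)["drug"],
                    recurrence_rescue(df, ptx_meta, config)["gene"],
                )
            )
            expect = set()
            for (drug, gene) in {
                (drug_of[r["clone_id"]], r["gene_name"]) for r in rows
            }:
                lineages = {
                    lineage_of[r["clone_id"]]
                    for r in rows
                    if drug_of[r["clone_id"]] == drug
                    and r["gene_name"] == gene
                    and r["af"] >= config.rescue_min_af
                    and r["dp"] >= config.min_depth
                }
                if len(lineages) >= config.rescue_min_lineages:
                    expect.add((drug, gene))
            assert got == expect, f"trial {trial}"


class TestBlocklist:
    def test_odorant_receptor_removed_by_default(self):
        table = pd.DataFrame(
            [
                {"drug": "PTX", "gene": "OR5A1", "rescue_reason": "high_af"},
                {"drug": "PTX", "gene": "SLCO3A1", "rescue_reason": "high_af"},
            ]
        )
        out = blocklist_filter(table)
        assert list(out["gene"]) == ["SLCO3A1"]

    def test_empty_blocklist_is_identity(self):
        table = pd.DataFrame([{"drug": "X", "gene": "OR5A1"}])
        assert blocklist_filter(table, ()).equals(table)

    def test_matches_brute_force_pattern_oracle(self):
        import re as _re

        rng = random.Random(2)
        genes = ["OR5A1", "MUC16", "HLA-A", "DCK", "TOP1", "ORAI1", "SMUC1"]
        patterns = (r"^OR\d", r"^MUC\d", r"^HLA-")
        for _ in range(20):
            chosen = [rng.choice(genes) for _ in range(10)]
            table = pd.DataFrame({"drug": "X", "gene": chosen})
            out = blocklist_filter(table, patterns)
            expect = [
                g for g in chosen
                if not any(_re.search(p, g) for p in patterns)
            ]
            assert list(out["gene"]) == expect


class TestCandidateTable:
    def test_empty_input_gives_empty_table_with_header(self):
        table = build_candidate_table(
            pd.DataFrame(columns=["drug", "gene_name", "clone_id", "lineage_id",
                                  "protein_change", "so_term", "af", "pos"]),
            pd.DataFrame(),
        )
        assert len(table) == 0
        assert "rescue_reason" in table.columns

    def test_high_af_and_rescue_are_disjoint(self, small_genome):
        config = hd.SimExperimentConfig(
            passenger_model=hd.PassengerModel(rate=250), cnv_specs={}, seed=17,
        )
        exp = hd.simulate_experiment(small_genome, config)
        calls = [c for cs in exp.clone_calls.values() for c in cs]
        ann = attach_metadata(
            hd.annotate_table(calls, small_genome.genes, small_genome.sequences),
            exp.metadata,
        )
        table, _, _ = prioritize(ann, exp.metadata)
        assert not table.duplicated(subset=["drug", "gene"]).any()

    def test_planted_drivers_fill_the_table(self, small_genome):
        config = hd.SimExperimentConfig(
            drugs=("DOX", "GEM", "TPT"), selections_per_drug=3,
            passenger_model=hd.PassengerModel(rate=0.0), cnv_specs={}, seed=23,
        )
        exp = hd.simulate_experiment(small_genome, config)
        calls = [c for cs in exp.clone_calls.values() for c in cs]
        ann = attach_metadata(
            hd.annotate_table(calls, small_genome.genes, small_genome.sequences),
            exp.metadata,
        )
        table, _, _ = prioritize(ann, exp.metadata)
        truth = exp.truth.driver_genes()
        assert {(r["drug"], r["gene"]) for _, r in table.iterrows()} == {
            (drug, gene) for drug, genes in truth.items() for gene in genes
        }

    def test_dependent_lineage_listed_in_one_row(self, ptx_meta):
        high = attach_metadata(
            pd.DataFrame(
                [
                    variant_row("PTX-R2a", "TOP1", 1.0, pos=7, change="His81fs",
                                so="frameshift_variant", impact="HIGH"),
                    variant_row("PTX-R2b", "TOP1", 1.0, pos=7, change="His81fs",
                                so="frameshift_variant", impact="HIGH"),
                ]
            ),
            ptx_meta,
        )
        table = build_candidate_table(high, pd.DataFrame())
        assert len(table) == 1
        assert table["samples"].iloc[0] == "PTX-R2a, PTX-R2b"
        assert table["n_independent_lineages"].iloc[0] == 1
        assert table["types"].iloc[0] == "FS, FS"


class TestSecondaryReport:
    def test_rule_instantiations(self, ptx_meta):
        config = PrioritizationConfig()
        post = attach_metadata(
            pd.DataFrame(
                [
                    # (b) single HIGH frameshift at AF 0.4
                    variant_row("PTX-R1", "FSGENE", 0.4, pos=1,
                                so="frameshift_variant", impact="HIGH"),
                    # (a) recurrent across lineages below the rescue floor
                    variant_row("GEM-R1", "LOWREC", 0.12, pos=2),
                    variant_row("GEM-R2", "LOWREC", 0.15, pos=3),
                    # high AF variant: not part of the secondary report
                    variant_row("PTX-R1", "HIGHAF", 0.95, pos=4),
                ]
            ),
            ptx_meta,
        )
        report = build_secondary_report(post, config)
        reasons = dict(zip(report["gene"], report["reasons"]))
        assert "disruptive_allele" in reasons["FSGENE"]
        assert "recurrent_low_af" in reasons["LOWREC"]
        assert "HIGHAF" not in reasons

    def test_gene_inside_recurrent_deletion_listed(self, ptx_meta, small_genome):
        config = PrioritizationConfig()
        gene = small_genome.genes.genes[0]
        post = attach_metadata(
            pd.DataFrame(
                [variant_row("PTX-R1", gene.gene_name, 0.4, pos=gene.start,
                             chrom=gene.chrom)]
            ),
            ptx_meta,
        )
        regions = pd.DataFrame(
            [
                {
                    "chrom": gene.chrom, "start": gene.start - 100,
                    "end": gene.end + 100, "drug": "PTX", "status": "loss",
                    "n_clones": 2, "clone_ids": "PTX-R1,PTX-R6",
                }
            ]
        )
        report = build_secondary_report(
            post, config, recurrent_regions=regions, gene_models=small_genome.genes
        )
        assert "recurrent_cnv" in report["reasons"].iloc[0]

    def test_no_qualifying_genes_gives_empty_report(self, ptx_meta):
        post = attach_metadata(
            pd.DataFrame([variant_row("PTX-R1", "G", 0.4, pos=1)]), ptx_meta
        )
        report = build_secondary_report(post, PrioritizationConfig())
        assert len(report) == 0
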