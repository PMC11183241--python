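"""Driver-candidate selection: the filtering cascade and recurrence rescue.

The cascade reduces annotated somatic variants to a compact candidate
table, per clone and per drug:

1. drug-specificity — drop any variant also seen in a clone selected with a
   different drug,
2. coding — drop noncoding-region consequences (intergenic, intron,
   intragenic),
3. functional impact — keep HIGH or MODERATE impact,
4. allele fraction — keep AF > 0.85 (strict) with depth >= 10.

Genes failing the AF stage are rescued when protein-altering variants arose
in at least two independent selection lineages under the same drug
(dependent clones collapse to one lineage).  A secondary report collects
lower-confidence genes: recurrent below the rescue floor, disruptive
(HIGH-impact) alleles, or genes inside recurrent copy-number regions.

All operations take and return pandas DataFrames in the annotated-variant
layout produced by :func:`hapdrive.annotate.annotate_table`, merged with
clone metadata (drug, lineage_id).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# gene families with high background mutability, excluded from candidates
DEFAULT_BLOCKLIST = (r"^OR\d+[A-Z]", r"^HLA-", r"^MUC\d")

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

CASCADE_STAGES = ("input", "drug_specific", "coding", "impact", "allele_fraction")

_NONCODING_TERMS = {"intergenic_variant", "intron_variant", "intragenic_variant"}


@dataclass
class PrioritizationConfig:
    af_threshold: float = 0.85
    af_quantile: float = 0.975
    use_quantile: bool = False
    min_depth: int = 10
    rescue_min_af: float = 0.30
    rescue_min_lineages: int = 2
    blocklist: tuple[str, ...] = DEFAULT_BLOCKLIST
    drug_specific: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.af_threshold <= 1:
            raise ValueError("af_threshold must be in (0, 1]")
        if self.rescue_min_lineages < 2:
            raise ValueError("rescue_min_lineages must be >= 2")


@dataclass
class FunnelReport:
    """Per-stage input/output counts (overall, per clone, per drug)."""

    stages: list[str]
    per_clone: pd.DataFrame  # index clone_id, columns stages
    per_drug: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        return self.per_clone.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = self.per_clone.copy()
        df.index.name = "clone_id"
        return df.reset_index()


def af_threshold_from_quantile(af_values: Sequence[float], q: float) -> float:
    """Empirical q-quantile of allele fractions (linear interpolation)."""
    values = np.asarray(list(af_values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a quantile of an empty AF list")
    if not 0 < q < 1:
        raise ValueError("quantile must be in (0, 1)")
    return float(np.quantile(values, q, method="linear"))


def attach_metadata(variants: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join drug/lineage/assay columns onto the annotated-variant table."""
    unknown = set(variants["clone_id"]) - set(metadata["clone_id"])
    if unknown:
        raise ValueError(f"clones missing from metadata: {sorted(unknown)}")
    meta = metadata.set_index("clone_id")[["drug", "lineage_id", "assay"]]
    out = variants.merge(meta, left_on="clone_id", right_index=True, how="left")
    return out


def drug_specific_filter(variants: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Remove variants whose (chrom, pos, ref, alt) occurs under >1 drug.

    Removal is symmetric: a shared variant is dropped from every clone.
    """
    df = variants if "drug" in variants.columns else attach_metadata(variants, metadata)
    n_drugs = df.groupby(VARIANT_KEY)["drug"].transform("nunique")
    return df[n_drugs == 1].copy()


def filter_cascade(
    variants: pd.DataFrame,
    config: PrioritizationConfig,
    metadata: pd.DataFrame,
) -> tuple[pd.DataFrame, FunnelReport]:
    """Apply the cascade stages in order, recording the funnel.

    Returns the high-AF survivors and a FunnelReport whose per-clone counts
    are non-increasing along the stages.
    """
    df = variants if "drug" in variants.columns else attach_metadata(variants, metadata)
    clones = list(metadata["clone_id"])
    counts: dict[str, pd.Series] = {}

    def record(stage: str, frame: pd.DataFrame) -> None:
        c = frame.groupby("clone_id").size()
        counts[stage] = c.reindex(clones, fill_value=0)

    record("input", df)
    if config.drug_specific:
        df = drug_specific_filter(df, metadata)
    record("drug_specific", df)
    df = df[~df["so_term"].isin(_NONCODING_TERMS)]
    record("coding", df)
    df = df[df["impact"].isin(["HIGH", "MODERATE"])]
    record("impact", df)
    threshold = config.af_threshold
    if config.use_quantile and len(variants):
        threshold = max(
            threshold,
            af_threshold_from_quantile(
                variants["af"].dropna().to_numpy(), config.af_quantile
            ),
        )
    df = df[(df["af"] > threshold) & (df["dp"] >= config.min_depth)]
    record("allele_fraction", df)

    per_clone = pd.DataFrame(counts)[list(CASCADE_STAGES)]
    drug_of = metadata.set_index("clone_id")["drug"]
    per_drug = per_clone.groupby(per_clone.index.map(drug_of)).sum()
    for stage in CASCADE_STAGES:
        log.info("cascade stage %-16s: %d variants", stage, int(per_clone[stage].sum()))
    report = FunnelReport(list(CASCADE_STAGES), per_clone, per_drug)
    return df.copy(), report


def post_impact_variants(
    variants: pd.DataFrame,
    config: PrioritizationConfig,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Variants surviving the cascade up to (and including) the impact
    stage, before the allele-fraction cut."""
    df = variants if "drug" in variants.columns else attach_metadata(variants, metadata)
    if config.drug_specific:
        df = drug_specific_filter(df, metadata)
    df = df[~df["so_term"].isin(_NONCODING_TERMS)]
    df = df[df["impact"].isin(["HIGH", "MODERATE"])]
    return df.copy()


def _candidate_rows(group: pd.DataFrame) -> dict:
    g = group.sort_values(["clone_id", "pos"])
    return {
        "samples": ", ".join(g["clone_id"]),
        "protein_changes": ", ".join(
            str(p) if pd.notna(p) else "." for p in g["protein_change"]
        ),
        "types": ", ".join(_type_code(t) for t in g["so_term"]),
        "afs": ", ".join(f"{a:.2f}" for a in g["af"]),
        "n_independent_lineages": int(g["lineage_id"].nunique()),
    }


def _type_code(so_term: str) -> str:
    if so_term.startswith("frameshift"):
        return "FS"
    if so_term == "missense_variant":
        return "MS"
    if so_term == "stop_gained":
        return "Stop"
    return so_term


def recurrence_rescue(
    post_impact: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PrioritizationConfig,
    high_af_pairs: Iterable[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Rescue genes with protein-altering variants in >= rescue_min_lineages
    independent lineages under one drug, each variant at AF >=
    rescue_min_af.  Dependent clones collapse to one lineage; the rescued
    set is disjoint from ``high_af_pairs`` ((drug, gene) tuples)."""
    df = post_impact[
        (post_impact["af"] >= config.rescue_min_af)
        & (post_impact["dp"] >= config.min_depth)
        & post_impact["gene_name"].notna()
    ]
    taken = set(high_af_pairs)
    rows = []
    for (drug, gene), group in df.groupby(["drug", "gene_name"], sort=True):
        if (drug, gene) in taken:
            continue
        if group["lineage_id"].nunique() >= config.rescue_min_lineages:
            row = {"drug": drug, "gene": gene, "rescue_reason": "recurrence"}
            row.update(_candidate_rows(group))
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "drug", "gene", "samples", "protein_changes", "types", "afs",
            "n_independent_lineages", "rescue_reason",
        ],
    )


def blocklist_filter(
    candidates: pd.DataFrame, blocklist: Sequence[str] = DEFAULT_BLOCKLIST
) -> pd.DataFrame:
    """Drop candidates whose gene name matches a blocklist pattern."""
    if not len(candidates) or not blocklist:
        return candidates.copy()
    patterns = [re.compile(p) for p in blocklist]
    hit = candidates["gene"].map(
        lambda g: any(p.search(str(g)) for p in patterns)
    )
    removed = candidates.loc[hit, "gene"].tolist()
    if removed:
        log.info("blocklist removed genes: %s", ", ".join(sorted(set(removed))))
    return candidates[~hit].copy()


CANDIDATE_COLUMNS = [
    "drug", "gene", "samples", "protein_changes", "types", "afs",
    "n_independent_lineages", "rescue_reason",
]


def build_candidate_table(
    high_af: pd.DataFrame,
    rescued: pd.DataFrame,
) -> pd.DataFrame:
    """One row per (drug, gene), high-AF candidates then rescued ones,
    deterministically ordered by (drug, gene)."""
    rows = []
    if len(high_af):
        for (drug, gene), group in high_af.groupby(["drug", "gene_name"], sort=True):
            row = {"drug": drug, "gene": gene, "rescue_reason": "high_af"}
            row.update(_candidate_rows(group))
            rows.append(row)
    table = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    if len(rescued):
        table = pd.concat([table, rescued[CANDIDATE_COLUMNS]], ignore_index=True)
    return table.sort_values(["drug", "gene"], kind="mergesort").reset_index(drop=True)


def prioritize(
    variants: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PrioritizationConfig | None = None,
) -> tuple[pd.DataFrame, FunnelReport, pd.DataFrame]:
    """Full candidate selection: cascade + rescue + blocklist.

    Returns (candidate table, funnel report, post-impact variant table).
    """
    config = config or PrioritizationConfig()
    survivors, funnel = filter_cascade(variants, config, metadata)
    post = post_impact_variants(variants, config, metadata)
    high_pairs = (
        set(zip(survivors["drug"], survivors["gene_name"]))
        if len(survivors)
        else set()
    )
    rescued = recurrence_rescue(post, metadata, config, high_pairs)
    table = build_candidate_table(survivors, rescued)
    table = blocklist_filter(table, config.blocklist)
    return table, funnel, post


def build_secondary_report(
    post_impact: pd.DataFrame,
    config: PrioritizationConfig,
    recurrent_regions: pd.DataFrame | None = None,
    gene_models=None,
    candidate_pairs: Iterable[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Lower-confidence genes that failed the AF stage but are (a) recurrent
    across lineages below the rescue floor, (b) carry HIGH-impact alleles,
    or (c) sit inside a recurrent CNV region of the same drug.

    ``recurrent_regions`` is the cnv module's recurrent-region table
    (chrom, start, end, drug, ...); ``gene_models`` a GeneSet for overlap.
    """
    df = post_impact[post_impact["gene_name"].notna()]
    df = df[df["af"] <= config.af_threshold]
    taken = set(candidate_pairs)
    region_lookup = None
    if recurrent_regions is not None and gene_models is not None and len(recurrent_regions):
        region_lookup = {}
        for _, r in recurrent_regions.iterrows():
            genes = gene_models.genes_overlapping(
                r["chrom"], int(r["start"]) + 1, int(r["end"])
            )
            for g in genes:
                region_lookup.setdefault((r["drug"], g.gene_name), []).append(
                    f"{r['chrom']}:{r['start']}-{r['end']}"
                )
    rows = []
    for (drug, gene), group in df.groupby(["drug", "gene_name"], sort=True):
        if (drug, gene) in taken:
            continue
        reasons = []
        if group["lineage_id"].nunique() >= config.rescue_min_lineages:
            reasons.append("recurrent_low_af")
        if (group["impact"] == "HIGH").any():
            reasons.append("disruptive_allele")
        if region_lookup and (drug, gene) in region_lookup:
            reasons.append("recurrent_cnv")
        if reasons:
            rows.append(
                {
                    "drug": drug,
                    "gene": gene,
                    "reasons": ";".join(reasons),
                    "n_lineages": int(group["lineage_id"].nunique()),
                    "max_af": float(group["af"].max()),
                    "n_variants": len(group),
                }
            )
    return pd.DataFrame(
        rows, columns=["drug", "gene", "reasons", "n_lineages", "max_af", "n_variants"]
    )
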