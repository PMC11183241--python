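"""End-to-end pipeline: simulate/load -> annotate -> prioritize -> CNV ->
stats -> report bundle.

One configured, logged run producing the candidate table, secondary
report, funnel report, CNV segments with recurrent regions and summary,
the class-count matrix, and a run manifest.  Re-running with the same
config and seed reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import GeneSet, annotate_table, load_fasta
from .cnv import (
    call_cnvs,
    recurrent_regions,
    summarize_cnv,
    write_recurrent_bed,
    write_segments,
)
from .prioritize import (
    PrioritizationConfig,
    attach_metadata,
    build_secondary_report,
    prioritize,
)
from .simulate import (
    SimExperimentConfig,
    generate_genome,
    read_bins,
    simulate_experiment,
)
from .stats import class_count_table, depth_af_r2
from .variants import (
    apply_call_filters,
    read_clone_metadata,
    read_vcf,
    somatic_contrast,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds in one place.

    ``mode`` is "simulate" (generate the experiment from ``genome_params``
    and ``sim_params``) or "files" (read VCFs/GFF3/FASTA/metadata/bins
    from ``paths``).  Threshold defaults are the study constants: AF
    threshold 0.85, minimum callable depth 10, 50-kb coverage bins,
    corrected-p cutoff 0.05.
    """

    mode: str = "simulate"
    seed: int = 0
    out_dir: str = "hapdrive_out"
    genome_params: dict = field(default_factory=dict)
    sim_params: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    af_threshold: float = 0.85
    af_quantile: float = 0.975
    use_quantile: bool = False
    min_depth: int = 10
    require_pass: bool = True
    rescue_min_af: float = 0.30
    rescue_min_lineages: int = 2
    blocklist: tuple = ()
    use_default_blocklist: bool = True
    bin_size: int = 50_000
    gain_threshold: float = 1.5
    loss_threshold: float = 0.5
    min_bins: int = 3
    q_cutoff: float = 0.05
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"mode must be simulate or files, got {self.mode!r}")
        if self.mode == "files":
            for key in ("vcf_dir", "gff3", "fasta", "metadata"):
                if key not in self.paths:
                    raise ValueError(f"files mode requires paths.{key}")
                if not Path(self.paths[key]).exists():
                    raise FileNotFoundError(self.paths[key])

    def prioritization(self) -> PrioritizationConfig:
        from .prioritize import DEFAULT_BLOCKLIST

        block = tuple(self.blocklist)
        if self.use_default_blocklist:
            block = DEFAULT_BLOCKLIST + block
        return PrioritizationConfig(
            af_threshold=self.af_threshold,
            af_quantile=self.af_quantile,
            use_quantile=self.use_quantile,
            min_depth=self.min_depth,
            rescue_min_af=self.rescue_min_af,
            rescue_min_lineages=self.rescue_min_lineages,
            blocklist=block,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["blocklist"] = list(d["blocklist"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "blocklist" in d:
            d["blocklist"] = tuple(d["blocklist"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    candidates: pd.DataFrame
    funnel: pd.DataFrame
    secondary: pd.DataFrame
    annotated: pd.DataFrame
    segments: pd.DataFrame
    recurrent: pd.DataFrame
    cnv_summary: dict
    class_counts: pd.DataFrame
    depth_af_r2: float | None
    manifest: dict
    truth: object = None


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage {name!r} failed: {err}") from err

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig):
    """Execute the full analysis; returns a PipelineResult."""
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    truth = None
    if config.mode == "simulate":
        gp = dict(config.genome_params)
        genome = generate_genome(seed=config.seed, **gp)
        sp = dict(config.sim_params)
        sp.setdefault("seed", config.seed)
        sim_config = SimExperimentConfig(**sp)
        exp = simulate_experiment(genome, sim_config)
        metadata = exp.metadata
        genes = genome.genes
        reference = genome.sequences
        diploid = genome.diploid_regions
        chrom_lengths = dict(genome.chromosomes)
        truth = exp.truth
        clone_calls = exp.clone_calls
        parent_calls = exp.parent_calls
        clone_bins = exp.clone_bins
        parent_bins = exp.parent_bins
        if sim_config.raw_parent_variants > 0:
            parent_of = metadata.set_index("clone_id")["parent_id"]
            clone_calls = {
                clone: somatic_contrast(
                    parent_calls.get(parent_of[clone], []), calls, reference
                )
                for clone, calls in clone_calls.items()
            }
    else:
        metadata = read_clone_metadata(config.paths["metadata"])
        genes = GeneSet.from_gff3(config.paths["gff3"])
        reference = load_fasta(config.paths["fasta"])
        diploid = []
        chrom_lengths = {name: len(seq) for name, seq in reference.items()}
        vcf_dir = Path(config.paths["vcf_dir"])
        clone_calls = {}
        parent_calls = {}
        for clone in metadata["clone_id"]:
            clone_calls[clone] = read_vcf(vcf_dir / f"{clone}.vcf")
        for pid in metadata["parent_id"].unique():
            p = vcf_dir / f"{pid}.vcf"
            parent_calls[pid] = read_vcf(p) if p.exists() else []
        parent_of = metadata.set_index("clone_id")["parent_id"]
        clone_calls = {
            clone: somatic_contrast(
                parent_calls.get(parent_of[clone], []), calls, reference
            )
            for clone, calls in clone_calls.items()
        }
        clone_bins, parent_bins = {}, {}
        bins_dir = config.paths.get("bins_dir")
        if bins_dir:
            bins_dir = Path(bins_dir)
            for clone in metadata["clone_id"]:
                p = bins_dir / f"{clone}.tsv"
                if p.exists():
                    clone_bins[clone] = read_bins(p)
            for pid in metadata["parent_id"].unique():
                p = bins_dir / f"{pid}.tsv"
                if p.exists():
                    parent_bins[pid] = read_bins(p)

    # call-level filters + annotation
    @_stage("annotate")
    def annotate_all():
        all_calls = []
        for clone in metadata["clone_id"]:
            calls = apply_call_filters(
                clone_calls.get(clone, []),
                min_depth=config.min_depth,
                require_pass=config.require_pass,
            )
            all_calls.extend(calls)
        return annotate_table(all_calls, genes, reference)

    annotated = annotate_all()
    if len(annotated):
        annotated = attach_metadata(annotated, metadata)
    else:
        annotated = annotated.assign(drug=None, lineage_id=None, assay=None)

    @_stage("prioritize")
    def run_prioritize():
        return prioritize(annotated, metadata, config.prioritization())

    candidates, funnel, post = run_prioritize()

    @_stage("cnv")
    def run_cnv():
        parent_of = metadata.set_index("clone_id")["parent_id"]
        segs = []
        for clone in metadata["clone_id"]:
            if clone not in clone_bins:
                continue
            pid = parent_of[clone]
            if pid not in parent_bins:
                continue
            segs.append(
                call_cnvs(
                    clone_bins[clone],
                    parent_bins[pid],
                    clone,
                    gain_threshold=config.gain_threshold,
                    loss_threshold=config.loss_threshold,
                    min_bins=config.min_bins,
                    q_cutoff=config.q_cutoff,
                    diploid_regions=diploid,
                )
            )
        from .cnv import SEGMENT_COLUMNS

        if segs:
            segments = pd.concat(segs, ignore_index=True)
        else:
            segments = pd.DataFrame(
                columns=SEGMENT_COLUMNS + ["p_value", "q_value"]
            )
        recurrent = recurrent_regions(segments, metadata)
        summary = summarize_cnv(segments, chrom_lengths)
        return segments, recurrent, summary

    segments, recurrent, cnv_summary = run_cnv()

    @_stage("stats")
    def run_stats():
        counts = (
            class_count_table(annotated, metadata)
            if len(annotated)
            else pd.DataFrame()
        )
        r2 = None
        ok = annotated.dropna(subset=["af", "dp"]) if len(annotated) else annotated
        if len(ok) >= 3:
            r2 = depth_af_r2(ok)
        return counts, r2

    class_counts, r2 = run_stats()

    @_stage("secondary")
    def run_secondary():
        pairs = set(zip(candidates["drug"], candidates["gene"])) if len(candidates) else set()
        return build_secondary_report(
            post,
            config.prioritization(),
            recurrent_regions=recurrent,
            gene_models=genes,
            candidate_pairs=pairs,
        )

    secondary = run_secondary()

    manifest = {
        "package": "hapdrive",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_clones": int(len(metadata)),
        "n_variants_annotated": int(len(annotated)),
        "n_candidates": int(len(candidates)),
        "n_cnv_segments": int(len(segments)),
    }
    return PipelineResult(
        candidates=candidates,
        funnel=funnel.to_frame(),
        secondary=secondary,
        annotated=annotated,
        segments=segments,
        recurrent=recurrent,
        cnv_summary=cnv_summary,
        class_counts=class_counts,
        depth_af_r2=r2,
        manifest=manifest,
        truth=truth,
    )


def write_report(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write the report bundle; returns the files written.

    All tables use fixed float formatting and deterministic ordering, so a
    re-run with the same config and seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def tsv(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)

    tsv(result.candidates, "candidates.tsv")
    tsv(result.funnel, "funnel.tsv")
    tsv(result.secondary, "secondary_report.tsv")
    write_segments(result.segments, out / "cnv_segments.tsv")
    written.append(out / "cnv_segments.tsv")
    write_recurrent_bed(result.recurrent, out / "cnv_recurrent.bed")
    written.append(out / "cnv_recurrent.bed")

    summary_rows = [
        {"metric": k, "value": v}
        for k, v in result.cnv_summary.items()
        if k != "per_chromosome_density"
    ]
    for chrom, d in sorted(result.cnv_summary["per_chromosome_density"].items()):
        summary_rows.append({"metric": f"density_{chrom}", "value": f"{d:.3e}"})
    tsv(pd.DataFrame(summary_rows), "cnv_summary.tsv")

    cc = result.class_counts.copy()
    if len(cc):
        cc.columns = ["|".join(map(str, c)) for c in cc.columns]
        cc = cc.reset_index()
    tsv(cc, "class_counts.tsv")

    r2 = result.depth_af_r2
    tsv(
        pd.DataFrame(
            [{"statistic": "depth_af_r2", "value": "NA" if r2 is None else f"{r2:.4f}"}]
        ),
        "stats.tsv",
    )

    p = out / "manifest.json"
    p.write_text(json.dumps(result.manifest, indent=1, sort_keys=True))
    written.append(p)

    lines = ["Drug-resistance candidate genes", "=" * 34, ""]
    if len(result.candidates):
        for drug, group in result.candidates.groupby("drug", sort=True):
            lines.append(f"{drug}:")
            for _, row in group.iterrows():
                lines.append(
                    f"  {row['gene']:<12} {row['types']:<12} "
                    f"AF {row['afs']}  [{row['rescue_reason']}] "
                    f"({row['samples']})"
                )
            lines.append("")
    else:
        lines.append("(no candidates)")
    p = out / "summary.txt"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written
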