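"""Synthetic in-vitro-evolution experiments with ground truth.

Generates complete desk-scale experiments — a reference genome with gene
models, resistant clones carrying planted driver mutations that swept to
high allele fraction, a passenger mutation load, copy-number events, and
binned coverage — with the statistical structure a haploid selection
experiment produces:

* five drugs with at least three independent selections each,
* drivers sweeping to AF ~ 1 in haploid clones,
* a passenger AF spectrum almost entirely below 0.85
  (Beta(0.8, 3) truncated to (0, 0.999]),
* dependent-clone lineages sharing one driver,
* a residual diploid region where passengers sit at AF ~ 0.5,
* WES target masks versus WGS,
* CNV gains/losses detectable from 50-kb bin ratios.

The generator is fully seeded: identical seeds give byte-identical output
files.  Read-level simulation (FASTQ/BAM) is out of scope; the generator
emits the variant-caller and coverage-binning output formats directly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import (
    Gene,
    GeneSet,
    TranscriptModel,
    revcomp,
    translate_codon,
    CODON_TO_AA,
)
from .coords import IntervalSet, merge_intervals
from .variants import METADATA_COLUMNS, VariantCall, write_vcf

STOP_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa == "*")
SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
# byte -> base lookup (256 divisible by 4: uniform composition)
_BYTE_TO_BASE = bytes(b"ACGT"[i % 4] for i in range(256))


class SizingError(ValueError):
    """Requested gene content cannot fit into the chromosomes."""


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# genome


@dataclass
class SimGenome:
    """Reference genome plus gene models and haploidy structure.

    ``diploid_regions`` model the residual diploid fragment of an otherwise
    haploid line (the chromosome-15 analog); ``exome_mask`` holds the WES
    target intervals.  Both are 0-based half-open.
    """

    chromosomes: list[tuple[str, int]]
    sequences: dict[str, str]
    genes: GeneSet
    diploid_regions: list[tuple[str, int, int]] = field(default_factory=list)
    exome_mask: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if len(self.sequences.get(name, "")) != length:
                raise ValueError(f"sequence length mismatch for {name}")
        for chrom, s, e in list(self.diploid_regions) + list(self.exome_mask):
            if not (0 <= s < e <= lengths[chrom]):
                raise ValueError(f"interval {chrom}:{s}-{e} outside chromosome")
        self._diploid = IntervalSet(self.diploid_regions)
        self._mask = IntervalSet(self.exome_mask)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def in_diploid(self, chrom: str, pos1: int) -> bool:
        return self._diploid.contains(chrom, pos1 - 1)

    def in_exome(self, chrom: str, pos1: int, flank: int = 0) -> bool:
        return self._mask.near(chrom, pos1 - 1, flank) if flank else self._mask.contains(chrom, pos1 - 1)

    @property
    def mask(self) -> IntervalSet:
        return self._mask


DEFAULT_GENE_LENGTH_PARAMS: dict = {
    "cds_codons_min": 100,     # translated codons (stop appended on top)
    "cds_codons_max": 500,
    "max_exons": 3,
    "intron_min": 200,
    "intron_max": 2000,
    "intragenic_pad": 1000,    # gene-span flank outside the transcript
    "min_gap": 2000,           # minimum intergenic gap between gene spans
    "cds_lengths": None,       # explicit per-gene CDS bp (multiples of 3)
}


def _gene_structures(n_genes: int, params: dict, rng: np.random.Generator):
    """Draw (cds_codons, exon_chunks, intron_lengths, strand) per gene."""
    out = []
    explicit = params["cds_lengths"]
    for i in range(n_genes):
        if explicit is not None:
            cds_bp = explicit[i % len(explicit)]
            if cds_bp % 3:
                raise ConfigError(f"cds length {cds_bp} not divisible by 3")
            n_codons = cds_bp // 3
        else:
            n_codons = int(
                rng.integers(params["cds_codons_min"], params["cds_codons_max"] + 1)
            )
        total = 3 * n_codons + 3  # stop codon appended
        max_exons = min(params["max_exons"], max(1, total // 30))
        n_exons = int(rng.integers(1, max_exons + 1))
        if n_exons == 1:
            chunks = [total]
        else:
            while True:
                cuts = np.sort(rng.choice(np.arange(1, total), n_exons - 1, replace=False))
                chunks = np.diff(np.concatenate([[0], cuts, [total]])).tolist()
                if min(chunks) >= 9:
                    break
        introns = [
            int(rng.integers(params["intron_min"], params["intron_max"] + 1))
            for _ in range(n_exons - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        out.append((n_codons, chunks, introns, strand))
    return out


def _coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    body = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    codons = ["ATG"] + [SENSE_CODONS[i] for i in body]
    codons.append(STOP_CODONS[int(rng.integers(0, len(STOP_CODONS)))])
    return "".join(codons)


def generate_genome(
    n_chromosomes: int = 4,
    n_genes: int = 1000,
    gene_length_params: dict | None = None,
    seed: int = 0,
    chrom_length: int = 12_500_000,
    diploid_fraction: float = 0.04,
) -> SimGenome:
    """Generate a random genome with non-overlapping protein-coding genes.

    Deterministic for a fixed seed.  Every gene has one transcript whose
    spliced CDS length is divisible by 3 (ATG start, single terminal stop,
    no internal stops, GT..AG introns).  The exome mask is the merged exon
    set; one diploid region is placed on the last chromosome.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    params = dict(DEFAULT_GENE_LENGTH_PARAMS)
    if gene_length_params:
        params.update(gene_length_params)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 71]))
    chrom_names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    chromosomes = [(name, int(chrom_length)) for name in chrom_names]

    structures = _gene_structures(n_genes, params, rng)
    per_chrom: dict[str, list[int]] = {c: [] for c in chrom_names}
    for gi in range(n_genes):
        per_chrom[chrom_names[gi % n_chromosomes]].append(gi)

    sequences: dict[str, str] = {}
    genes: list[Gene] = []
    mask_intervals: list[tuple[str, int, int]] = []
    pad = params["intragenic_pad"]
    min_gap = params["min_gap"]

    for chrom in chrom_names:
        seq = bytearray(rng.bytes(chrom_length).translate(_BYTE_TO_BASE))
        idxs = per_chrom[chrom]
        spans = []
        for gi in idxs:
            n_codons, chunks, introns, _ = structures[gi]
            span = sum(chunks) + sum(introns) + 2 * pad
            spans.append(span)
        need = sum(spans) + (len(idxs) + 1) * min_gap
        if need > chrom_length:
            raise SizingError(
                f"{chrom}: genes need {need} bp (spans + minimum gaps) "
                f"but chromosome is {chrom_length} bp"
            )
        slack = chrom_length - need
        extra = rng.multinomial(slack, np.full(len(idxs) + 1, 1 / (len(idxs) + 1)))
        cursor = 0
        for k, gi in enumerate(idxs):
            cursor += min_gap + int(extra[k])
            gene_start1 = cursor + 1
            n_codons, chunks, introns, strand = structures[gi]
            coding = _coding_sequence(n_codons, rng)
            genomic_coding = coding if strand == "+" else revcomp(coding)
            # lay exons left to right; genomic order chunks
            g_chunks = chunks if strand == "+" else chunks[::-1]
            g_introns = introns if strand == "+" else introns[::-1]
            exons = []
            p = cursor + pad  # 0-based start of first exon
            consumed = 0
            for j, chunk in enumerate(g_chunks):
                exons.append((p + 1, p + chunk))  # 1-based inclusive
                seq[p : p + chunk] = genomic_coding[consumed : consumed + chunk].encode()
                consumed += chunk
                if j < len(g_introns):
                    ilen = g_introns[j]
                    left = b"GT" if strand == "+" else b"CT"
                    right = b"AG" if strand == "+" else b"AC"
                    seq[p + chunk : p + chunk + 2] = left
                    seq[p + chunk + ilen - 2 : p + chunk + ilen] = right
                    p += chunk + ilen
                else:
                    p += chunk
            gene_end1 = p + pad
            gene_id = f"G{gi + 1:04d}"
            tx = TranscriptModel(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                gene_name=gene_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                cds_start=exons[0][0],
                cds_end=exons[-1][1],
                canonical=True,
            )
            genes.append(
                Gene(
                    gene_id=gene_id,
                    gene_name=gene_id,
                    chrom=chrom,
                    start=gene_start1,
                    end=gene_end1,
                    transcripts=[tx],
                )
            )
            for s1, e1 in exons:
                mask_intervals.append((chrom, s1 - 1, e1))
            cursor = gene_end1
        sequences[chrom] = seq.decode("ascii")

    mask: list[tuple[str, int, int]] = []
    for chrom in chrom_names:
        merged = merge_intervals(
            [(s, e) for c, s, e in mask_intervals if c == chrom]
        )
        mask.extend((chrom, s, e) for s, e in merged)
    diploid = []
    if diploid_fraction > 0:
        last = chrom_names[-1]
        diploid = [(last, 0, int(diploid_fraction * chrom_length))]
    return SimGenome(
        chromosomes=chromosomes,
        sequences=sequences,
        genes=GeneSet(genes),
        diploid_regions=diploid,
        exome_mask=mask,
    )


def write_fasta(genome: SimGenome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, _ in genome.chromosomes:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: GeneSet, genome: SimGenome, path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive; CDS includes the stop)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in genome.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for gene in genes:
            fh.write(
                f"{gene.chrom}\thapdrive\tgene\t{gene.start}\t{gene.end}\t.\t"
                f"{gene.transcripts[0].strand}\t.\tID={gene.gene_id};Name={gene.gene_name}\n"
            )
            for tx in gene.transcripts:
                canon = "1" if tx.canonical else "0"
                fh.write(
                    f"{gene.chrom}\thapdrive\tmRNA\t{tx.start}\t{tx.end}\t.\t"
                    f"{tx.strand}\t.\tID={tx.transcript_id};Parent={gene.gene_id};"
                    f"canonical={canon}\n"
                )
                phase = 0
                segs = tx.cds_segments
                ordered = segs if tx.strand == "+" else segs[::-1]
                phases = []
                consumed = 0
                for s, e in ordered:
                    phases.append((3 - consumed % 3) % 3)
                    consumed += e - s + 1
                phase_by_seg = dict(zip(ordered, phases))
                for i, (s, e) in enumerate(tx.exons):
                    fh.write(
                        f"{gene.chrom}\thapdrive\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t"
                        f"ID={tx.transcript_id}.exon{i + 1};Parent={tx.transcript_id}\n"
                    )
                for i, (s, e) in enumerate(segs):
                    fh.write(
                        f"{gene.chrom}\thapdrive\tCDS\t{s}\t{e}\t.\t{tx.strand}\t"
                        f"{phase_by_seg[(s, e)]}\t"
                        f"ID={tx.transcript_id}.cds{i + 1};Parent={tx.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# experiment configuration


@dataclass(frozen=True)
class DriverSpec:
    """One planted driver: gene (None = auto-assigned), variant kind, target AF."""

    gene: str | None
    kind: str  # missense | frameshift | stop_gained
    af: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("missense", "frameshift", "stop_gained"):
            raise ConfigError(f"unknown driver kind {self.kind!r}")
        if not 0 < self.af <= 1:
            raise ConfigError(f"driver AF must be in (0, 1], got {self.af}")


@dataclass(frozen=True)
class CnvSpec:
    chrom: str
    start: int  # 0-based half-open
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 0 or self.copy_number == 1:
            raise ConfigError(
                "copy_number must be a non-negative integer != 1 "
                f"(1 is the haploid baseline), got {self.copy_number}"
            )
        if self.end <= self.start:
            raise ConfigError("empty CNV interval")


@dataclass(frozen=True)
class PassengerModel:
    """Neutral mutation load accumulated during long-term culture."""

    rate: float = 1500.0          # expected passengers per clone (lambda)
    beta_a: float = 0.8           # AF ~ Beta(a, b) truncated to (0, af_max]
    beta_b: float = 3.0
    af_max: float = 0.999
    indel_fraction: float = 0.05  # indels are a small minority of somatic calls
    non_pass_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigError("passenger rate (lambda) must be >= 0")


@dataclass(frozen=True)
class CoverageModel:
    """Depth model: negative-binomial site depth and bin counts."""

    mean_depth: float = 60.0
    dispersion: float = 50.0      # NB size parameter r (CV ~ sqrt(1/r + 1/mean))
    bin_size: int = 50_000
    read_length: int = 150
    bin_dispersion: float = 100.0
    wes_off_target: float = 0.005  # off-target coverage fraction for WES bins


DEFAULT_DRUGS = ("DOX", "GEM", "ETP", "PTX", "TPT")
DEFAULT_DRIVER_KINDS = {
    "DOX": "missense",
    "GEM": "missense",
    "ETP": "missense",
    "PTX": "missense",
    "TPT": "frameshift",
}


@dataclass
class SimExperimentConfig:
    """Study design: drugs, selections, drivers, passengers, CNVs, assays.

    ``dependent_groups`` maps a lineage id to the clone ids derived from
    that single selection (e.g. ``{"TPT-R4": ["TPT-R4a", "TPT-R4b",
    "TPT-R4c"]}``); those clones share their driver.  ``cnv_specs`` may be
    None (auto-plant one gain and one loss per clone), an empty dict (no
    CNVs), or an explicit per-clone map.
    """

    drugs: tuple[str, ...] = DEFAULT_DRUGS
    selections_per_drug: int = 3
    dependent_groups: dict[str, list[str]] = field(default_factory=dict)
    generations: tuple[int, int] = (49, 210)
    driver_specs: dict[str, list[DriverSpec]] | None = None
    passenger_model: PassengerModel = field(default_factory=PassengerModel)
    cnv_specs: dict[str, list[CnvSpec]] | None = None
    coverage_model: CoverageModel = field(default_factory=CoverageModel)
    assays: dict[str, str] = field(default_factory=dict)  # clone_id -> WGS/WES
    wes_flank: int = 100
    raw_parent_variants: int = 0  # >0: "raw" mode exercising somatic contrast
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selections_per_drug < 1:
            raise ConfigError("selections_per_drug must be >= 1")
        if self.driver_specs is None:
            self.driver_specs = {
                drug: [DriverSpec(None, DEFAULT_DRIVER_KINDS.get(drug, "missense"))]
                for drug in self.drugs
            }
        for clone, assay in self.assays.items():
            if assay not in ("WGS", "WES"):
                raise ConfigError(f"assay for {clone} must be WGS or WES")

    def lineages(self) -> list[tuple[str, str, list[str]]]:
        """(drug, lineage_id, clone_ids) in deterministic order."""
        out = []
        for drug in self.drugs:
            for i in range(self.selections_per_drug):
                lineage = f"{drug}-R{i + 1}"
                clones = self.dependent_groups.get(lineage, [lineage])
                out.append((drug, lineage, list(clones)))
        return out

    def clone_ids(self) -> list[str]:
        return [c for _, _, clones in self.lineages() for c in clones]

    @classmethod
    def paper_like(cls, **kwargs) -> "SimExperimentConfig":
        """Study layout with dependent lineages and mixed WGS/WES assays."""
        dependent = {
            "DOX-R4": ["DOX-R4a", "DOX-R4b"],
            "PTX-R2": ["PTX-R2a", "PTX-R2b"],
            "TPT-R4": ["TPT-R4a", "TPT-R4b", "TPT-R4c"],
        }
        assays: dict[str, str] = {}
        for clone in ("DOX-R4a", "DOX-R4b", "DOX-R5", "ETP-R1", "ETP-R2",
                      "ETP-R3", "GEM-R3", "PTX-R3"):
            assays[clone] = "WES"
        kwargs.setdefault("selections_per_drug", 5)
        kwargs.setdefault("dependent_groups", dependent)
        kwargs.setdefault("assays", assays)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# truth


@dataclass
class SimTruth:
    """Ground truth for a simulated experiment.

    ``drivers``/``cnvs`` are lists of dicts; ``passengers`` a DataFrame with
    one row per emitted passenger; ``lineages`` maps clone_id -> lineage_id.
    """

    drivers: list[dict]
    passengers: pd.DataFrame
    cnvs: list[dict]
    lineages: dict[str, str]

    def driver_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for d in self.drivers:
            out.setdefault(d["drug"], set()).add(d["gene"])
        return out


# ---------------------------------------------------------------------------
# driver construction


def _cds_genomic_positions(tx: TranscriptModel) -> list[int]:
    """Genomic coordinate of each spliced-CDS index, transcript order."""
    segs = tx.cds_segments
    if tx.strand == "+":
        return [p for s, e in segs for p in range(s, e + 1)]
    return [p for s, e in reversed(segs) for p in range(e, s - 1, -1)]


def _make_driver_variant(
    genome: SimGenome, gene: Gene, kind: str, rng: np.random.Generator
) -> tuple[int, str, str, int]:
    """Plant a variant of the requested kind in the gene's canonical CDS.

    Returns (pos, ref, alt, protein_pos) in VCF convention.
    """
    tx = gene.canonical_transcript
    cds = tx.spliced_cds(genome.sequences)
    positions = _cds_genomic_positions(tx)
    seq = genome.sequences[tx.chrom]
    n_codons = len(cds) // 3  # includes stop
    order = rng.permutation(np.arange(1, n_codons - 1))
    if kind == "missense":
        for c in order:
            codon = cds[3 * c : 3 * c + 3]
            aa_ref = translate_codon(codon)
            offs = rng.permutation(3)
            for off in offs:
                for b in "ACGT":
                    if b == codon[off]:
                        continue
                    alt_codon = codon[:off] + b + codon[off + 1 :]
                    aa_alt = translate_codon(alt_codon)
                    if aa_alt != aa_ref and aa_alt != "*":
                        gpos = positions[3 * c + off]
                        ref_base = seq[gpos - 1]
                        alt_base = b if tx.strand == "+" else revcomp(b)
                        if alt_base == ref_base:
                            continue
                        return int(gpos), ref_base, alt_base, int(c) + 1
        raise ConfigError(f"no missense site found in {gene.gene_name}")
    if kind == "stop_gained":
        for c in order:
            codon = cds[3 * c : 3 * c + 3]
            if translate_codon(codon) == "*":
                continue
            for off in range(3):
                for b in "ACGT":
                    if b == codon[off]:
                        continue
                    alt_codon = codon[:off] + b + codon[off + 1 :]
                    if translate_codon(alt_codon) == "*":
                        gpos = positions[3 * c + off]
                        ref_base = seq[gpos - 1]
                        alt_base = b if tx.strand == "+" else revcomp(b)
                        if alt_base == ref_base:
                            continue
                        return int(gpos), ref_base, alt_base, int(c) + 1
        raise ConfigError(f"no stop-gain site found in {gene.gene_name}")
    # frameshift: delete the 2nd and 3rd base of a codon that sits in one exon
    for c in order:
        g1 = positions[3 * c + 1]
        g2 = positions[3 * c + 2]
        lo, hi = min(g1, g2), max(g1, g2)
        if hi - lo != 1:
            continue  # codon split across an intron
        anchor = lo - 1
        if anchor < 1:
            continue
        ref = seq[anchor - 1 : hi]
        alt = seq[anchor - 1]
        return int(anchor), ref, alt, int(c) + 1
    raise ConfigError(f"no frameshift site found in {gene.gene_name}")


# ---------------------------------------------------------------------------
# experiment simulation


@dataclass
class SimulatedExperiment:
    genome: SimGenome
    config: SimExperimentConfig
    metadata: pd.DataFrame
    clone_calls: dict[str, list[VariantCall]]
    parent_calls: dict[str, list[VariantCall]]
    clone_bins: dict[str, pd.DataFrame]
    parent_bins: dict[str, pd.DataFrame]
    truth: SimTruth


def _nb(rng: np.random.Generator, mean, r: float, size=None):
    mean = np.asarray(mean, dtype=float)
    p = r / (r + np.maximum(mean, 1e-12))
    draws = rng.negative_binomial(r, p, size=size if size is not None else mean.shape)
    return np.where(mean <= 0, 0, draws)


def _truncated_beta(
    rng: np.random.Generator, a: float, b: float, af_max: float, n: int
) -> np.ndarray:
    out = rng.beta(a, b, size=n)
    bad = (out > af_max) | (out <= 0)
    while bad.any():
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out > af_max) | (out <= 0)
    return out


def _chrom_choice(rng, chromosomes, n):
    lengths = np.array([l for _, l in chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    return rng.choice(len(chromosomes), size=n, p=probs)


def _passenger_calls(
    genome: SimGenome,
    model: PassengerModel,
    coverage: CoverageModel,
    clone_id: str,
    assay: str,
    wes_flank: int,
    rng: np.random.Generator,
) -> tuple[list[VariantCall], list[float]]:
    n = int(rng.poisson(model.rate))
    if n == 0:
        return [], []
    chrom_idx = _chrom_choice(rng, genome.chromosomes, n)
    afs = _truncated_beta(rng, model.beta_a, model.beta_b, model.af_max, n)
    dps = np.maximum(_nb(rng, np.full(n, coverage.mean_depth), coverage.dispersion), 1)
    kinds = rng.random(n)
    ins_or_del = rng.random(n) < 0.5
    indel_len = rng.integers(1, 4, size=n)
    non_pass = rng.random(n) < model.non_pass_fraction
    calls: list[VariantCall] = []
    targets: list[float] = []
    for i in range(n):
        name, length = genome.chromosomes[int(chrom_idx[i])]
        pos = int(rng.integers(1, length - 5))
        seq = genome.sequences[name]
        ref_base = seq[pos - 1]
        af = float(afs[i])
        genotype = "1"
        if genome.in_diploid(name, pos):
            af = 0.5
            genotype = "0/1"
        if assay == "WES" and not genome.in_exome(name, pos, flank=wes_flank):
            continue
        if kinds[i] < model.indel_fraction:
            L = int(indel_len[i])
            if ins_or_del[i]:
                ins = "".join(
                    "ACGT"[j] for j in rng.integers(0, 4, size=L)
                )
                ref, alt = ref_base, ref_base + ins
                if ref == alt:  # impossible; insertion always differs
                    continue
            else:
                ref = seq[pos - 1 : pos + L]
                alt = ref_base
                if len(ref) < L + 1:
                    continue
        else:
            others = [b for b in "ACGT" if b != ref_base]
            alt = others[int(rng.integers(0, 3))]
            ref = ref_base
        dp = int(dps[i])
        ad = int(rng.binomial(dp, af))
        ad = max(ad, 1)
        calls.append(
            VariantCall(
                chrom=name,
                pos=pos,
                ref=ref,
                alt=alt,
                alt_depth=ad,
                total_depth=dp,
                filter_status="germline_risk" if non_pass[i] else "PASS",
                qual=60.0,
                clone_id=clone_id,
                genotype=genotype,
            )
        )
        targets.append(af)
    return calls, targets


def _auto_cnvs(
    genome: SimGenome, clone_id: str, bin_size: int, rng: np.random.Generator
) -> list[CnvSpec]:
    """One gain (copy 3, 60 bins) and one loss (copy 0, 5 bins) per clone."""
    specs = []
    for copy, n_bins in ((3, 60), (0, 5)):
        for _ in range(50):
            ci = int(rng.integers(0, len(genome.chromosomes)))
            name, length = genome.chromosomes[ci]
            span = n_bins * bin_size
            if span >= length:
                continue
            start = int(rng.integers(0, (length - span) // bin_size)) * bin_size
            cand = CnvSpec(name, start, start + span, copy)
            if any(
                c.chrom == name and c.start < cand.end and cand.start < c.end
                for c in specs
            ):
                continue
            if any(
                r[0] == name and r[1] < cand.end and cand.start < r[2]
                for r in genome.diploid_regions
            ):
                continue
            specs.append(cand)
            break
    return specs


def _bin_grid(genome: SimGenome, bin_size: int) -> pd.DataFrame:
    rows = []
    for name, length in genome.chromosomes:
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _coverage_counts(
    genome: SimGenome,
    grid: pd.DataFrame,
    coverage: CoverageModel,
    cnvs: Sequence[CnvSpec],
    assay: str,
    rng: np.random.Generator,
) -> np.ndarray:
    base_reads = coverage.mean_depth * coverage.bin_size / coverage.read_length
    copy = np.ones(len(grid), dtype=float)
    for chrom, s, e in genome.diploid_regions:
        sel = (grid["chrom"] == chrom) & (grid["start"] < e) & (grid["end"] > s)
        copy[sel.to_numpy()] = 2.0
    for spec in cnvs:
        sel = (
            (grid["chrom"] == spec.chrom)
            & (grid["start"] >= spec.start)
            & (grid["end"] <= spec.end)
        )
        copy[sel.to_numpy()] = float(spec.copy_number)
    frac = np.ones(len(grid), dtype=float)
    if assay == "WES":
        mask = genome.mask
        fracs = []
        for chrom, s, e in zip(grid["chrom"], grid["start"], grid["end"]):
            ov = 0
            for mc, ms, me in mask.intervals():
                if mc != chrom:
                    continue
                ov += max(0, min(me, e) - max(ms, s))
            fracs.append(ov / (e - s))
        frac = np.maximum(np.array(fracs), coverage.wes_off_target)
    scale = (grid["end"] - grid["start"]).to_numpy() / coverage.bin_size
    mean = base_reads * copy * frac * scale
    return _nb(rng, mean, coverage.bin_dispersion)


def simulate_experiment(
    genome: SimGenome, config: SimExperimentConfig
) -> SimulatedExperiment:
    """Simulate one full experiment; see the module docstring for the model.

    Deterministic for a fixed config seed.  Driver genes named in
    ``driver_specs`` must exist in the genome (ConfigError otherwise).
    """
    root = np.random.SeedSequence([int(config.seed), 1])
    rng_assign, rng_parent, rng_clones = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    genes = genome.genes
    cov = config.coverage_model

    # assign driver genes (auto-assignment avoids reuse across drugs)
    assigned: dict[tuple[str, int], Gene] = {}
    used: set[str] = set()
    plus_genes = [
        g for g in genes if g.canonical_transcript.strand in "+-"
    ]
    order = rng_assign.permutation(len(plus_genes))
    cursor = 0
    for drug in config.drugs:
        for si, spec in enumerate(config.driver_specs[drug]):
            if spec.gene is not None:
                try:
                    gene = genes.by_name(spec.gene)
                except KeyError:
                    raise ConfigError(
                        f"driver gene {spec.gene!r} absent from genome"
                    ) from None
            else:
                while True:
                    gene = plus_genes[int(order[cursor])]
                    cursor += 1
                    if gene.gene_name not in used:
                        break
            used.add(gene.gene_name)
            assigned[(drug, si)] = gene

    # per-lineage driver variant instances (distinct sites per lineage)
    lineage_drivers: dict[str, list[tuple[Gene, DriverSpec, tuple]]] = {}
    for drug, lineage, _clones in config.lineages():
        items = []
        for si, spec in enumerate(config.driver_specs[drug]):
            gene = assigned[(drug, si)]
            var = _make_driver_variant(genome, gene, spec.kind, rng_assign)
            items.append((gene, spec, var))
        lineage_drivers[lineage] = items

    grid = _bin_grid(genome, cov.bin_size)

    # parents: one per (drug, assay) present among that drug's clones
    meta_rows = []
    for drug, lineage, clones in config.lineages():
        for clone in clones:
            assay = config.assays.get(clone, "WGS")
            parent_id = f"{drug}-WT-{assay}"
            meta_rows.append(
                {
                    "clone_id": clone,
                    "drug": drug,
                    "parent_id": parent_id,
                    "lineage_id": lineage,
                    "assay": assay,
                }
            )
    metadata = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)

    parent_ids = sorted(metadata["parent_id"].unique())
    parent_calls: dict[str, list[VariantCall]] = {}
    parent_bins: dict[str, pd.DataFrame] = {}
    for pid in parent_ids:
        sub = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), 2, zlib.crc32(pid.encode())])
        )
        assay = pid.rsplit("-", 1)[-1]
        counts = _coverage_counts(genome, grid, cov, [], assay, sub)
        parent_bins[pid] = grid.assign(count=counts)
        pcalls: list[VariantCall] = []
        if config.raw_parent_variants > 0:
            model = replace(
                config.passenger_model,
                rate=float(config.raw_parent_variants),
                non_pass_fraction=0.0,
            )
            pcalls, _ = _passenger_calls(
                genome, model, cov, pid, assay, config.wes_flank, sub
            )
        parent_calls[pid] = pcalls

    clone_calls: dict[str, list[VariantCall]] = {}
    clone_bins: dict[str, pd.DataFrame] = {}
    truth_drivers: list[dict] = []
    truth_pass_rows: list[pd.DataFrame] = []
    truth_cnvs: list[dict] = []
    lineage_map: dict[str, str] = {}

    for drug, lineage, clones in config.lineages():
        for clone in clones:
            lineage_map[clone] = lineage
            assay = config.assays.get(clone, "WGS")
            parent_id = f"{drug}-WT-{assay}"
            sub = np.random.default_rng(
                np.random.SeedSequence(
                    [int(config.seed), 3, zlib.crc32(clone.encode())]
                )
            )
            calls: list[VariantCall] = []
            # planted drivers (shared site across dependent clones)
            for gene, spec, (pos, ref, alt, ppos) in lineage_drivers[lineage]:
                dp = int(max(_nb(sub, np.array([cov.mean_depth]), cov.dispersion)[0], 10))
                if spec.af >= 1.0:
                    ad = dp
                else:
                    ad = int(max(sub.binomial(dp, spec.af), 1))
                calls.append(
                    VariantCall(
                        chrom=gene.chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        alt_depth=ad,
                        total_depth=dp,
                        filter_status="PASS",
                        qual=60.0,
                        clone_id=clone,
                        genotype="1",
                    )
                )
                truth_drivers.append(
                    {
                        "clone_id": clone,
                        "drug": drug,
                        "lineage_id": lineage,
                        "gene": gene.gene_name,
                        "chrom": gene.chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "kind": spec.kind,
                        "af": spec.af,
                        "protein_pos": ppos,
                    }
                )
            passengers, targets = _passenger_calls(
                genome, config.passenger_model, cov, clone, assay,
                config.wes_flank, sub,
            )
            calls.extend(passengers)
            if passengers:
                truth_pass_rows.append(
                    pd.DataFrame(
                        {
                            "clone_id": clone,
                            "chrom": [c.chrom for c in passengers],
                            "pos": [c.pos for c in passengers],
                            "ref": [c.ref for c in passengers],
                            "alt": [c.alt for c in passengers],
                            "af_target": targets,
                        }
                    )
                )
            # parent variants appear in the clone too (raw mode)
            calls.extend(
                replace(c, clone_id=clone) for c in parent_calls[parent_id]
            )
            if config.cnv_specs is None:
                cnvs = _auto_cnvs(genome, clone, cov.bin_size, sub)
            else:
                cnvs = config.cnv_specs.get(clone, [])
            for spec in cnvs:
                truth_cnvs.append(
                    {
                        "clone_id": clone,
                        "chrom": spec.chrom,
                        "start": spec.start,
                        "end": spec.end,
                        "copy_number": spec.copy_number,
                    }
                )
            counts = _coverage_counts(genome, grid, cov, cnvs, assay, sub)
            order_key = {name: i for i, (name, _) in enumerate(genome.chromosomes)}
            calls.sort(key=lambda c: (order_key[c.chrom], c.pos, c.ref, c.alt))
            clone_calls[clone] = calls
            clone_bins[clone] = grid.assign(count=counts)

    passengers_df = (
        pd.concat(truth_pass_rows, ignore_index=True)
        if truth_pass_rows
        else pd.DataFrame(
            columns=["clone_id", "chrom", "pos", "ref", "alt", "af_target"]
        )
    )
    truth = SimTruth(
        drivers=truth_drivers,
        passengers=passengers_df,
        cnvs=truth_cnvs,
        lineages=lineage_map,
    )
    return SimulatedExperiment(
        genome=genome,
        config=config,
        metadata=metadata,
        clone_calls=clone_calls,
        parent_calls=parent_calls,
        clone_bins=clone_bins,
        parent_bins=parent_bins,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# analytic expectations (test support, not used by the pipeline)


def genome_composition(genome: SimGenome) -> dict:
    """Base counts per annotation region, plus SNV consequence fractions
    inside the CDS computed by exhaustive codon scan."""
    L = genome.total_length
    cds = intron = splice_site = splice_region = intragenic = 0
    snv_counts = {
        "Missense": 0, "Synonymous": 0, "Stop gained": 0, "Stop lost": 0,
        "Start lost": 0, "Others": 0,
    }
    for gene in genome.genes:
        tx = gene.canonical_transcript
        span_tx = tx.end - tx.start + 1
        span_gene = gene.end - gene.start + 1
        intragenic += span_gene - span_tx
        cds_seq = tx.spliced_cds(genome.sequences)
        cds += len(cds_seq)
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            ilen = s2 - e1 - 1
            ss = min(4, ilen)
            sr = min(max(ilen - 4, 0), 12)
            splice_site += ss
            splice_region += sr
            intron += max(ilen - ss - sr, 0)
        n_codons = len(cds_seq) // 3
        for c in range(n_codons):
            codon = cds_seq[3 * c : 3 * c + 3]
            aa_ref = translate_codon(codon)
            for off in range(3):
                for b in "ACGT":
                    if b == codon[off]:
                        continue
                    aa_alt = translate_codon(codon[:off] + b + codon[off + 1 :])
                    if c == 0:
                        snv_counts["Start lost"] += 1
                    elif aa_ref == "*":
                        if aa_alt == "*":
                            snv_counts["Others"] += 1
                        else:
                            snv_counts["Stop lost"] += 1
                    elif aa_alt == "*":
                        snv_counts["Stop gained"] += 1
                    elif aa_alt == aa_ref:
                        snv_counts["Synonymous"] += 1
                    else:
                        snv_counts["Missense"] += 1
    total_muts = 3 * cds
    intergenic = L - intragenic - cds - intron - splice_site - splice_region
    return {
        "genome_length": L,
        "cds": cds,
        "intron": intron,
        "splice_site": splice_site,
        "splice_region": splice_region,
        "intragenic": intragenic,
        "intergenic": intergenic,
        "snv_class_fractions": {
            k: (v / total_muts if total_muts else 0.0)
            for k, v in snv_counts.items()
        },
    }


def expected_mutation_counts(
    config: SimExperimentConfig, genome: SimGenome
) -> dict[tuple[str, str], float]:
    """Analytic per-clone expectations per (kind, consolidated class).

    lambda x region probability x conditional class fraction, from the
    genome composition.  Indel class splits ignore codon-boundary effects
    (frameshift 2/3, inframe 1/3 for the 1-3 bp indel lengths used).
    """
    comp = genome_composition(genome)
    lam = config.passenger_model.rate
    p_indel = config.passenger_model.indel_fraction
    L = comp["genome_length"]
    out: dict[tuple[str, str], float] = {}
    lam_snv = lam * (1 - p_indel)
    lam_ind = lam * p_indel
    p_cds = comp["cds"] / L
    for cls, frac in comp["snv_class_fractions"].items():
        out[("SNV", cls)] = out.get(("SNV", cls), 0.0) + lam_snv * p_cds * frac
    out[("SNV", "Intron")] = lam_snv * comp["intron"] / L
    out[("SNV", "Splice region plus intron")] = lam_snv * comp["splice_region"] / L
    out[("SNV", "Others")] = out.get(("SNV", "Others"), 0.0) + lam_snv * comp["splice_site"] / L
    out[("SNV", "Intragenic")] = lam_snv * comp["intragenic"] / L
    out[("SNV", "Intergenic")] = lam_snv * comp["intergenic"] / L
    out[("indel", "Frameshift")] = lam_ind * p_cds * (2 / 3)
    out[("indel", "Inframe insertion")] = lam_ind * p_cds * (1 / 3) * 0.5
    out[("indel", "Inframe deletion")] = lam_ind * p_cds * (1 / 3) * 0.5
    out[("indel", "Intron")] = lam_ind * comp["intron"] / L
    out[("indel", "Splice region plus intron")] = lam_ind * comp["splice_region"] / L
    out[("indel", "Intragenic")] = lam_ind * comp["intragenic"] / L
    out[("indel", "Intergenic")] = lam_ind * comp["intergenic"] / L
    return out


# ---------------------------------------------------------------------------
# file emission


def write_truth(truth: SimTruth, outdir: str | Path) -> None:
    """truth.json (drivers, cnvs, lineages) + truth_passengers.tsv."""
    outdir = Path(outdir)
    payload = {
        "drivers": truth.drivers,
        "cnvs": truth.cnvs,
        "lineages": truth.lineages,
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    truth.passengers.to_csv(outdir / "truth_passengers.tsv", sep="\t", index=False)


def write_bins(bins: pd.DataFrame, path: str | Path) -> None:
    bins[["chrom", "start", "end", "count"]].to_csv(path, sep="\t", index=False)


def read_bins(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "count"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: bin table must have columns {sorted(need)}")
    return df


def write_experiment(exp: SimulatedExperiment, outdir: str | Path) -> None:
    """Emit the full experiment bundle as plain-text files.

    Layout: genome.fasta, genes.gff3, metadata.tsv, truth.json,
    truth_passengers.tsv, vcf/<clone>.vcf, bins/<clone>.tsv (clones and
    parents).
    """
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    (outdir / "bins").mkdir(parents=True, exist_ok=True)
    write_fasta(exp.genome, outdir / "genome.fasta")
    write_gff3(exp.genome.genes, exp.genome, outdir / "genes.gff3")
    exp.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    write_truth(exp.truth, outdir)
    contigs = dict(exp.genome.chromosomes)
    for clone, calls in sorted(exp.clone_calls.items()):
        write_vcf(calls, outdir / "vcf" / f"{clone}.vcf", contigs, clone_id=clone)
    for pid, calls in sorted(exp.parent_calls.items()):
        write_vcf(calls, outdir / "vcf" / f"{pid}.vcf", contigs, clone_id=pid)
    for clone, bins in sorted(exp.clone_bins.items()):
        write_bins(bins, outdir / "bins" / f"{clone}.tsv")
    for pid, bins in sorted(exp.parent_bins.items()):
        write_bins(bins, outdir / "bins" / f"{pid}.tsv")
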