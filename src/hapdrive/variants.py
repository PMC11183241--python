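"""Somatic variant-call I/O and call-level filtering.

Reads and writes the paired tumor/normal VCF dialect used throughout the
package (FORMAT GT:AD:DP, FILTER PASS or a named reason), pairs resistant
clones with their sensitive parents, computes allele fractions, and applies
the depth / PASS-status call filters.  Allele fraction is the fraction of
reads supporting the variant allele relative to total read depth at the
variant position (AD_alt / DP); in a clonal haploid sweep a driver
approaches AF = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

log = logging.getLogger(__name__)

_BASES = set("ACGT")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be parsed."""


class UndefinedAlleleFraction(ValueError):
    """Raised when AF is requested for a call with zero / absent depth."""


@dataclass(frozen=True)
class VariantCall:
    """One somatic call with read support for one clone.

    ``alt_depth``/``total_depth`` may be None when the source record lacked
    AD/DP; such calls are flagged, not dropped, and excluded later by
    :func:`apply_call_filters`.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_depth: int | None = None
    total_depth: int | None = None
    filter_status: str = "PASS"
    qual: float | None = None
    clone_id: str | None = None
    genotype: str = "1"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if set(self.ref) - _BASES or set(self.alt) - _BASES:
            raise ValueError(f"alleles must be over ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if self.alt_depth is not None and self.total_depth is not None:
            if not 0 <= self.alt_depth <= self.total_depth:
                raise ValueError(
                    f"require 0 <= AD ({self.alt_depth}) <= DP ({self.total_depth})"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def kind(self) -> str:
        return "SNV" if self.is_snv else "indel"


@dataclass(frozen=True)
class CloneMeta:
    """Experimental identity of a sequenced clone.

    ``lineage_id`` names the independent selection the clone derives from;
    dependent clones (e.g. TPT-R4a/b/c) share a lineage and are collapsed
    to one lineage for recurrence counting.
    """

    clone_id: str
    drug: str
    parent_id: str
    lineage_id: str
    assay: str  # WGS or WES

    def __post_init__(self) -> None:
        if self.assay not in ("WGS", "WES"):
            raise ValueError(f"assay must be WGS or WES, got {self.assay!r}")


def compute_af(call: VariantCall) -> float:
    """Allele fraction AD_alt / DP, exact rational division."""
    if not call.total_depth:
        raise UndefinedAlleleFraction(
            f"AF undefined at {call.chrom}:{call.pos} (DP={call.total_depth})"
        )
    if call.alt_depth is None:
        raise UndefinedAlleleFraction(
            f"AF undefined at {call.chrom}:{call.pos} (AD absent)"
        )
    return float(Fraction(call.alt_depth, call.total_depth))


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read one-sample VCF into VariantCalls, splitting multi-allelic records.

    Each record-allele becomes one call keeping its own AD; order is
    preserved.  Missing AD/DP leaves depths as None (flagged, not dropped).
    """
    path = Path(path)
    calls: list[VariantCall] = []
    last = "header"
    try:
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            clone_id = samples[0] if samples else None
            for rec in vf:
                last = f"{rec.chrom}:{rec.pos}"
                filters = list(rec.filter.keys())
                status = filters[0] if filters else "PASS"
                sample = rec.samples[clone_id] if clone_id else None
                ad = sample.get("AD") if sample else None
                dp = sample.get("DP") if sample else None
                gt = "1"
                if sample is not None and sample.get("GT") is not None:
                    gt = "/".join(
                        "." if a is None else str(a) for a in sample["GT"]
                    )
                for i, alt in enumerate(rec.alts or ()):
                    alt_depth = None
                    if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                        alt_depth = int(ad[i + 1])
                    calls.append(
                        VariantCall(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            alt_depth=alt_depth,
                            total_depth=None if dp is None else int(dp),
                            filter_status=status,
                            qual=rec.qual,
                            clone_id=clone_id,
                            genotype=gt,
                        )
                    )
    except (ValueError, OSError) as err:
        raise VcfParseError(
            f"{path}: failed to parse (after record {last}): {err}"
        ) from err
    return calls


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    contigs: Mapping[str, int],
    clone_id: str | None = None,
) -> None:
    """Write calls as a one-sample VCF 4.2 with FORMAT GT:AD:DP.

    Calls are written sorted by (contig order, position, ref, alt) so the
    output is deterministic for a given call set.
    """
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for status in sorted({c.filter_status for c in calls} - {"PASS"}):
        header.filters.add(status, None, None, "call-level filter")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth at position")
    sample = clone_id or next(
        (c.clone_id for c in calls if c.clone_id), "SAMPLE"
    )
    header.add_sample(sample)
    order = {name: i for i, name in enumerate(contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (order[c.chrom], c.pos, c.ref, c.alt)):
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos - 1 + len(call.ref),
                alleles=(call.ref, call.alt),
                qual=call.qual,
                filter=call.filter_status,
            )
            gt = call.genotype
            if "/" in gt or "|" in gt:
                alleles = gt.replace("|", "/").split("/")
                rec.samples[sample]["GT"] = tuple(
                    None if a == "." else int(a) for a in alleles
                )
            else:
                rec.samples[sample]["GT"] = (int(gt),)
            if call.total_depth is not None and call.alt_depth is not None:
                rec.samples[sample]["AD"] = (
                    call.total_depth - call.alt_depth,
                    call.alt_depth,
                )
                rec.samples[sample]["DP"] = call.total_depth
            out.write(rec)


def left_align(call: VariantCall, reference: Mapping[str, str]) -> VariantCall:
    """Left-align and trim an indel against the reference (VCF anchor style).

    SNVs are returned unchanged.  Set subtraction requires normalized keys,
    so both parent and clone calls go through this before comparison.
    """
    if call.is_snv:
        return call
    seq = reference[call.chrom]
    pos, ref, alt = call.pos, call.ref, call.alt
    # trim identical trailing bases
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # shift left while the last bases of ref/alt match the preceding base
    while (
        len(ref) != len(alt)
        and ref[-1] == alt[-1]
        and pos > 1
        and seq[pos - 2].upper() == ref[0].upper()
    ):
        prev = seq[pos - 2].upper()
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    if (pos, ref, alt) == (call.pos, call.ref, call.alt):
        return call
    return replace(call, pos=pos, ref=ref, alt=alt)


def somatic_contrast(
    parent_calls: Iterable[VariantCall],
    clone_calls: Iterable[VariantCall],
    reference: Mapping[str, str] | None = None,
) -> list[VariantCall]:
    """De-novo calls: clone calls whose (chrom, pos, ref, alt) key is absent
    from the parent set.  When a reference is supplied, indels on both sides
    are left-aligned first so equivalent representations compare equal."""
    if reference is not None:
        parent_keys = {left_align(c, reference).key for c in parent_calls}
        return [
            c for c in clone_calls if left_align(c, reference).key not in parent_keys
        ]
    parent_keys = {c.key for c in parent_calls}
    return [c for c in clone_calls if c.key not in parent_keys]


def apply_call_filters(
    calls: Iterable[VariantCall],
    min_depth: int = 10,
    require_pass: bool = True,
) -> list[VariantCall]:
    """Retain PASS calls (if required) with DP >= min_depth.

    Calls lacking DP fail any positive depth requirement.  Counts removed
    per reason are logged at INFO.
    """
    kept: list[VariantCall] = []
    removed = {"non_pass": 0, "low_depth": 0}
    for call in calls:
        if require_pass and call.filter_status != "PASS":
            removed["non_pass"] += 1
            continue
        if min_depth > 0 and (
            call.total_depth is None or call.total_depth < min_depth
        ):
            removed["low_depth"] += 1
            continue
        kept.append(call)
    if any(removed.values()):
        log.info(
            "call filters removed %d non-PASS, %d below depth %d",
            removed["non_pass"], removed["low_depth"], min_depth,
        )
    return kept


METADATA_COLUMNS = ["clone_id", "drug", "parent_id", "lineage_id", "assay"]


def read_clone_metadata(path: str | Path) -> pd.DataFrame:
    """Read the clone metadata TSV (clone_id, drug, parent_id, lineage_id, assay)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    if df["clone_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate clone_id entries")
    bad = ~df["assay"].isin(["WGS", "WES"])
    if bad.any():
        raise ValueError(f"{path}: assay must be WGS or WES")
    # one drug per lineage
    per_lineage = df.groupby("lineage_id")["drug"].nunique()
    if (per_lineage > 1).any():
        raise ValueError(f"{path}: a lineage maps to more than one drug")
    return df[METADATA_COLUMNS]


def write_clone_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)
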