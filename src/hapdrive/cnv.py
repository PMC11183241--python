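"""Copy-number analysis from paired clone/parent binned coverage.

A deliberately simple ratio caller for haploid-baseline genomes: per-bin
clone/parent ratios after median normalization, threshold segmentation into
gain/loss runs, rank-sum significance against the clone's own background
with Benjamini-Hochberg correction, recurrent-region detection across
clones of a drug, and summary statistics.  The haploid baseline copy number
is 1 (a residual diploid region may be given baseline 2); gains are copy
>= 2, losses copy 0.

Recurrent regions follow the rule: altered in more than one clone of a
drug, but not in all of them (events in every clone more likely reflect
artifacts shared with the parent).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coords import IntervalSet


@dataclass(frozen=True)
class CoverageBin:
    chrom: str
    start: int  # 0-based half-open
    end: int
    count: int
    gc: float | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("bin count must be >= 0")
        if self.end <= self.start:
            raise ValueError("empty bin")


RATIO_COLUMNS = ["chrom", "start", "end", "count_clone", "count_parent", "ratio", "masked"]
SEGMENT_COLUMNS = [
    "chrom", "start", "end", "n_bins", "mean_ratio", "copy_number", "status",
    "clone_id",
]


def bin_coverage(
    positions: Mapping[str, Sequence[int]] | Sequence[tuple[str, int]],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 50_000,
) -> pd.DataFrame:
    """Tile each chromosome into fixed bins and tally read positions.

    ``positions``: mapping chrom -> 0-based read positions, or an iterable
    of (chrom, pos0) pairs.  The terminal bin may be short; total counts
    are conserved.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if not isinstance(positions, Mapping):
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in positions:
            by_chrom.setdefault(chrom, []).append(pos)
        positions = by_chrom
    frames = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        pos = np.asarray(positions.get(chrom, []), dtype=int)
        if pos.size and (pos.min() < 0 or pos.max() >= length):
            raise ValueError(f"read position outside {chrom}")
        counts = np.bincount(pos // bin_size, minlength=len(starts))
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "count": counts}
            )
        )
    return pd.concat(frames, ignore_index=True)


def ratio_profile(
    clone_bins: pd.DataFrame,
    parent_bins: pd.DataFrame,
    min_parent_count: int = 1,
) -> pd.DataFrame:
    """Per-bin normalized coverage ratio, paired-control design.

    ratio_i = (clone_i / median(clone)) / (parent_i / median(parent));
    bins with parent count below ``min_parent_count`` are masked (ratio
    NaN) and never propagate into segments.
    """
    a = clone_bins.reset_index(drop=True)
    b = parent_bins.reset_index(drop=True)
    if len(a) != len(b) or not (
        (a["chrom"].values == b["chrom"].values).all()
        and (a["start"].values == b["start"].values).all()
        and (a["end"].values == b["end"].values).all()
    ):
        raise ValueError("clone and parent bin grids differ")
    clone = a["count"].to_numpy(dtype=float)
    parent = b["count"].to_numpy(dtype=float)
    med_c = np.median(clone)
    med_p = np.median(parent)
    if med_c <= 0 or med_p <= 0:
        raise ValueError("median bin count is zero; cannot normalize")
    masked = parent < min_parent_count
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (clone / med_c) / (parent / med_p)
    ratio[masked] = np.nan
    return pd.DataFrame(
        {
            "chrom": a["chrom"],
            "start": a["start"],
            "end": a["end"],
            "count_clone": a["count"],
            "count_parent": b["count"],
            "ratio": ratio,
            "masked": masked,
        }
    )


def segment_profile(
    profile: pd.DataFrame,
    gain_threshold: float = 1.5,
    loss_threshold: float = 0.5,
    min_bins: int = 3,
    clone_id: str | None = None,
    diploid_regions: Sequence[tuple[str, int, int]] = (),
) -> pd.DataFrame:
    """Maximal runs of >= min_bins consecutive out-of-band bins.

    Thresholds are midpoints between integer copy states on the haploid
    baseline (1<->2 at 1.5, 1<->0 at 0.5).  Runs interrupted by a single
    masked bin are merged.  copy_number = round(mean_ratio * baseline),
    clipped to >= 2 for gains and 0 for losses; baseline is 2 inside
    ``diploid_regions``, 1 elsewhere.
    """
    diploid = IntervalSet(diploid_regions) if diploid_regions else None
    segments = []
    for chrom, chunk in profile.groupby("chrom", sort=False):
        ratio = chunk["ratio"].to_numpy()
        starts = chunk["start"].to_numpy()
        ends = chunk["end"].to_numpy()
        masked = chunk["masked"].to_numpy()
        n = len(chunk)
        state = np.zeros(n, dtype=int)  # +1 gain, -1 loss, 0 neutral
        state[(~masked) & (ratio > gain_threshold)] = 1
        state[(~masked) & (ratio < loss_threshold)] = -1
        i = 0
        while i < n:
            if state[i] == 0:
                i += 1
                continue
            s = state[i]
            j = i
            last_informative = i
            gap = 0
            while j + 1 < n:
                nxt = j + 1
                if masked[nxt] and gap < 1:
                    gap += 1
                    j = nxt
                    continue
                if state[nxt] == s:
                    gap = 0
                    j = nxt
                    last_informative = nxt
                    continue
                break
            j = last_informative
            idx = np.arange(i, j + 1)
            informative = idx[~masked[idx]]
            if len(informative) >= min_bins:
                mean_ratio = float(np.mean(ratio[informative]))
                baseline = 1
                if diploid is not None and diploid.overlaps(
                    chrom, int(starts[i]), int(ends[j])
                ):
                    baseline = 2
                copy = int(round(mean_ratio * baseline))
                copy = max(copy, 2) if s > 0 else max(min(copy, baseline - 1), 0)
                segments.append(
                    {
                        "chrom": chrom,
                        "start": int(starts[i]),
                        "end": int(ends[j]),
                        "n_bins": int(len(informative)),
                        "mean_ratio": mean_ratio,
                        "copy_number": copy,
                        "status": "gain" if s > 0 else "loss",
                        "clone_id": clone_id,
                    }
                )
            i = j + 1
    return pd.DataFrame(segments, columns=SEGMENT_COLUMNS)


def score_segments(
    segments: pd.DataFrame,
    profile: pd.DataFrame,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Two-sided rank-sum test of each segment's bins against the clone's
    non-segment background, BH-corrected across the clone's segments;
    segments with q >= q_cutoff are dropped.  All-tied input gives p = 1."""
    if not len(segments):
        out = segments.copy()
        out["p_value"] = pd.Series(dtype=float)
        out["q_value"] = pd.Series(dtype=float)
        return out
    in_any = np.zeros(len(profile), dtype=bool)
    for _, seg in segments.iterrows():
        sel = (
            (profile["chrom"] == seg["chrom"])
            & (profile["start"] >= seg["start"])
            & (profile["end"] <= seg["end"])
        )
        in_any |= sel.to_numpy()
    background = profile.loc[~in_any & ~profile["masked"], "ratio"].to_numpy()
    pvals = []
    for _, seg in segments.iterrows():
        sel = (
            (profile["chrom"] == seg["chrom"])
            & (profile["start"] >= seg["start"])
            & (profile["end"] <= seg["end"])
            & (~profile["masked"])
        )
        vals = profile.loc[sel, "ratio"].to_numpy()
        if len(vals) == 0 or len(background) == 0 or (
            np.unique(np.concatenate([vals, background])).size == 1
        ):
            pvals.append(1.0)
            continue
        try:
            _, p = sps.mannwhitneyu(vals, background, alternative="two-sided")
        except ValueError:
            p = 1.0
        pvals.append(float(p))
    out = segments.copy()
    out["p_value"] = pvals
    out["q_value"] = sps.false_discovery_control(pvals, method="bh")
    return out[out["q_value"] < q_cutoff].reset_index(drop=True)


def call_cnvs(
    clone_bins: pd.DataFrame,
    parent_bins: pd.DataFrame,
    clone_id: str,
    gain_threshold: float = 1.5,
    loss_threshold: float = 0.5,
    min_bins: int = 3,
    q_cutoff: float = 0.05,
    min_parent_count: int = 1,
    diploid_regions: Sequence[tuple[str, int, int]] = (),
) -> pd.DataFrame:
    """Convenience wrapper: ratio -> segmentation -> significance."""
    profile = ratio_profile(clone_bins, parent_bins, min_parent_count)
    segs = segment_profile(
        profile, gain_threshold, loss_threshold, min_bins, clone_id,
        diploid_regions,
    )
    return score_segments(segs, profile, q_cutoff)


RECURRENT_COLUMNS = ["chrom", "start", "end", "drug", "status", "n_clones", "clone_ids"]


def recurrent_regions(
    segments: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Regions altered in >1 but not all clones of a drug.

    Breakpoint sweep per (drug, status, chrom): elementary intervals
    covered by k clones with 2 <= k < n_clones(drug) are kept; adjacent
    intervals with identical supporting clone sets are merged.
    """
    drug_of = metadata.set_index("clone_id")["drug"]
    n_clones = metadata.groupby("drug")["clone_id"].nunique()
    if len(segments):
        segments = segments.assign(drug=segments["clone_id"].map(drug_of))
        if segments["drug"].isna().any():
            missing = segments.loc[segments["drug"].isna(), "clone_id"].unique()
            raise ValueError(f"clones missing from metadata: {sorted(missing)}")
    rows = []
    if len(segments):
        for (drug, status, chrom), group in segments.groupby(
            ["drug", "status", "chrom"], sort=True
        ):
            total = int(n_clones[drug])
            # per clone, union its intervals first
            events: list[tuple[int, int, str]] = []
            for clone, cgroup in group.groupby("clone_id"):
                ivals = sorted(zip(cgroup["start"], cgroup["end"]))
                merged: list[list[int]] = []
                for s, e in ivals:
                    if merged and s <= merged[-1][1]:
                        merged[-1][1] = max(merged[-1][1], e)
                    else:
                        merged.append([s, e])
                events.extend((s, e, clone) for s, e in merged)
            points = sorted({p for s, e, _ in events for p in (s, e)})
            prev_support: frozenset | None = None
            for a, b in zip(points, points[1:]):
                support = frozenset(
                    clone for s, e, clone in events if s <= a and b <= e
                )
                if 2 <= len(support) < total:
                    if (
                        rows
                        and prev_support == support
                        and rows[-1]["end"] == a
                        and rows[-1]["chrom"] == chrom
                        and rows[-1]["drug"] == drug
                        and rows[-1]["status"] == status
                    ):
                        rows[-1]["end"] = b
                    else:
                        rows.append(
                            {
                                "chrom": chrom,
                                "start": a,
                                "end": b,
                                "drug": drug,
                                "status": status,
                                "n_clones": len(support),
                                "clone_ids": ",".join(sorted(support)),
                            }
                        )
                    prev_support = support
                else:
                    prev_support = None
    return pd.DataFrame(rows, columns=RECURRENT_COLUMNS)


def summarize_cnv(
    segments: pd.DataFrame, chrom_lengths: Mapping[str, int]
) -> dict:
    """Event counts, size statistics, genome fraction, per-chromosome
    event density (events per bp)."""
    genome = sum(chrom_lengths.values())
    if not len(segments):
        return {
            "n_gain": 0, "n_loss": 0, "mean_size": 0.0, "stdev_size": 0.0,
            "min_size": 0, "max_size": 0, "genome_fraction": 0.0,
            "per_chromosome_density": {c: 0.0 for c in chrom_lengths},
        }
    sizes = (segments["end"] - segments["start"]).to_numpy(dtype=float)
    density = {}
    counts = segments.groupby("chrom").size()
    for chrom, length in chrom_lengths.items():
        density[chrom] = float(counts.get(chrom, 0)) / length
    return {
        "n_gain": int((segments["status"] == "gain").sum()),
        "n_loss": int((segments["status"] == "loss").sum()),
        "mean_size": float(sizes.mean()),
        "stdev_size": float(sizes.std(ddof=1)) if len(sizes) > 1 else 0.0,
        "min_size": int(sizes.min()),
        "max_size": int(sizes.max()),
        "genome_fraction": float(sizes.sum()) / genome,
        "per_chromosome_density": density,
    }


def gene_overlap(regions: pd.DataFrame, gene_models) -> dict[tuple, list[str]]:
    """Genes whose span intersects each region (half-open region coords).

    Returns {(chrom, start, end): [gene names, position-ordered]}.
    """
    out: dict[tuple, list[str]] = {}
    for _, r in regions.iterrows():
        genes = gene_models.genes_overlapping(
            r["chrom"], int(r["start"]) + 1, int(r["end"])
        )
        out[(r["chrom"], int(r["start"]), int(r["end"]))] = [
            g.gene_name for g in genes
        ]
    return out


def write_segments(segments: pd.DataFrame, path: str | Path) -> None:
    segments.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_recurrent_bed(regions: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            name = f"{r['drug']}:{r['status']}:{r['clone_ids']}"
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{name}\n")
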