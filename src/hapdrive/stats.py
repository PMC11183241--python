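"""Supporting statistics: mutation-clustering window probability,
depth-AF correlation, and the per-drug class-count matrix.

The window statistic asks how surprising it is that ``k`` of ``n``
truncating mutations in a protein of ``L`` residues fall inside one window
of ``w`` residues (the hotspot question).  Under the fixed-window null,
positions are placed independently and uniformly, so the count in a given
window is Binomial(n, w/L) and the answer is its upper tail.  The scan
null — the probability that *any* length-w window collects >= k of the n
positions — has no simple closed form and is estimated by seeded Monte
Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ClusterTestSpec:
    """n mutations over L residues; k observed in a window of w residues."""

    n: int
    L: int
    w: int
    k: int
    mode: str = "fixed_window"

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("require 0 <= k <= n")
        if not 1 <= self.w <= self.L:
            raise ValueError("require 1 <= w <= L")
        if self.mode not in ("fixed_window", "scan"):
            raise ValueError(f"unknown mode {self.mode!r}")


def window_cluster_pvalue(
    spec: ClusterTestSpec,
    n_draws: int = 100_000,
    seed: int = 20_240_618,
) -> float:
    """P(window count >= k) under uniform placement.

    fixed_window: exact Binomial(n, w/L) upper tail.  scan: Monte-Carlo
    estimate of P(max over all length-w windows >= k); ``n_draws`` and
    ``seed`` only apply to scan mode.
    """
    if spec.k == 0:
        return 1.0
    if spec.mode == "fixed_window":
        return float(sps.binom.sf(spec.k - 1, spec.n, spec.w / spec.L))
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_draws, 10_000_000 // max(spec.n, 1)))
    remaining = n_draws
    while remaining > 0:
        m = min(chunk, remaining)
        pos = np.sort(rng.integers(1, spec.L + 1, size=(m, spec.n)), axis=1)
        # max count in any w-window: for each i, #positions in [p_i, p_i+w-1]
        best = np.zeros(m, dtype=int)
        for i in range(spec.n):
            upper = pos[:, i] + spec.w - 1
            cnt = np.sum(pos <= upper[:, None], axis=1) - i
            best = np.maximum(best, cnt)
        hits += int(np.sum(best >= spec.k))
        remaining -= m
    return hits / n_draws


def window_cluster_enumeration_oracle(spec: ClusterTestSpec) -> float:
    """Exact fixed-window probability by enumerating all L**n placements.

    Small instances only (L**n <= 1e7); the window is residues 1..w.
    Validates :func:`window_cluster_pvalue` independently.
    """
    if spec.L**spec.n > 10_000_000:
        raise ValueError(f"instance too large to enumerate: {spec.L}**{spec.n}")
    hits = 0
    for placement in product(range(1, spec.L + 1), repeat=spec.n):
        if sum(1 for p in placement if p <= spec.w) >= spec.k:
            hits += 1
    return hits / spec.L**spec.n


def depth_af_r2(variants: pd.DataFrame) -> float | None:
    """Squared Pearson correlation between read depth and allele fraction.

    Expects columns ``dp`` and ``af``; returns None when either variable
    has zero variance (undefined statistic, not an exception).
    """
    df = variants.dropna(subset=["af", "dp"])
    if len(df) < 3:
        raise ValueError("need at least 3 variants with defined AF and DP")
    dp = df["dp"].to_numpy(dtype=float)
    af = df["af"].to_numpy(dtype=float)
    if np.ptp(dp) == 0 or np.ptp(af) == 0:
        return None
    r, _ = sps.pearsonr(dp, af)
    return float(r * r)


def class_count_table(
    variants: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Mean per-clone variant counts by consolidated class.

    Rows: (kind, consolidated class); columns: (assay, drug) with the
    count of clones appended to the drug label.  Per-clone totals are
    conserved: each clone's column-group contribution sums to its variant
    count.
    """
    df = variants.copy()
    if "drug" not in df.columns:
        meta = metadata.set_index("clone_id")[["drug", "assay"]]
        df = df.merge(meta, left_on="clone_id", right_index=True, how="left")
    counts = (
        df.groupby(["clone_id", "kind", "consolidated_class"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    meta = metadata.set_index("clone_id")
    counts["drug"] = counts["clone_id"].map(meta["drug"])
    counts["assay"] = counts["clone_id"].map(meta["assay"])
    # mean over *all* clones of the group, including zero-count clones
    group_sizes = metadata.groupby(["assay", "drug"])["clone_id"].nunique()
    sums = counts.pivot_table(
        index=["kind", "consolidated_class"],
        columns=["assay", "drug"],
        values="n",
        aggfunc="sum",
        fill_value=0,
    )
    means = sums.div(group_sizes, axis=1).dropna(axis=1, how="all")
    means = means.sort_index()
    return means
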