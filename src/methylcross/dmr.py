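"""Windowed differentially-methylated-region (DMR) calling.

Procedure: the genome is tiled in adjacent 50-bp windows; within each
window, methylated/unmethylated calls of one context are pooled per
condition over the cytosine positions covered in both conditions and
compared with a two-sided Fisher's exact test on the 2x2 table
(meth, unmeth) x (condition A, condition B).  Windows with fewer than
three context cytosines, an absolute methylation-proportion difference
below 0.25, or a mean per-cytosine read total below 8 are discarded
before Benjamini-Hochberg correction.  Windows with q below the FDR
cutoff become candidate bins; same-direction bins separated by less than
300 bp are merged into DMRs.

The Fisher p-value is computed in-package: tables whose grand total is at
most ``_EXACT_LIMIT`` are enumerated with exact integer arithmetic
(correctly-rounded to double), larger tables use a log-gamma tail sum
with a 1e-7 relative tie tolerance.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .config import DataError, DmrParams

logger = logging.getLogger(__name__)

_EXACT_LIMIT = 500


# ---------------------------------------------------------------------------
# Fisher's exact test

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    The two-sided p-value sums, over the hypergeometric support with the
    table's margins fixed, the probabilities of all tables no more likely
    than the observed one.
    """
    if min(a, b, c, d) < 0:
        raise DataError("negative cell in 2x2 table")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(c1, r1)
    if n <= _EXACT_LIMIT:
        nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
        obs = nums[a - lo]
        p = Fraction(sum(x for x in nums if x <= obs), sum(nums))
        return float(p)
    ks = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - c1 + ks + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    log_obs = logpmf[a - lo]
    p = np.exp(logpmf[logpmf <= log_obs + 1e-7]).sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# Window tiling and per-window statistics

def tile_windows(chrom_lengths: dict[str, int], params: DmrParams) -> pd.DataFrame:
    """Adjacent window tiles covering each chromosome (final partial tile kept)."""
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length <= 0:
            raise DataError(f"chromosome {chrom!r} has non-positive length {length}")
        for start in range(1, length + 1, params.step):
            rows.append(
                {"chrom": chrom, "start": start,
                 "end": min(start + params.window - 1, length)}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_stats(report_a: pd.DataFrame, report_b: pd.DataFrame, context: str,
                 params: DmrParams | None = None) -> pd.DataFrame:
    """Per-window 2x2 statistics for one context.

    Both reports must be position-filtered (>=3 reads/position) and on the
    same reference.  Counts are pooled over cytosine positions covered in
    both conditions.  Windows failing any of the three filters are marked
    ``tested=False`` and excluded from multiple testing; Fisher p-values are
    computed for tested windows only.
    """
    params = (params or DmrParams()).validate()
    if params.window != params.step:
        raise DataError("window_stats supports adjacent tiles only (window == step)")
    a = report_a.loc[report_a["context"] == context,
                     ["chrom", "pos", "count_meth", "count_unmeth"]]
    b = report_b.loc[report_b["context"] == context,
                     ["chrom", "pos", "count_meth", "count_unmeth"]]
    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if merged.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "context", "n_cytosines",
                     "meth_a", "unmeth_a", "meth_b", "unmeth_b",
                     "prop_a", "prop_b", "diff", "avg_reads", "tested", "p"]
        )
    merged["win"] = (merged["pos"] - 1) // params.step
    grouped = merged.groupby(["chrom", "win"], sort=True).agg(
        n_cytosines=("pos", "size"),
        meth_a=("count_meth_a", "sum"),
        unmeth_a=("count_unmeth_a", "sum"),
        meth_b=("count_meth_b", "sum"),
        unmeth_b=("count_unmeth_b", "sum"),
    ).reset_index()
    grouped["start"] = grouped["win"] * params.step + 1
    grouped["end"] = grouped["start"] + params.window - 1
    grouped["context"] = context
    tot_a = grouped["meth_a"] + grouped["unmeth_a"]
    tot_b = grouped["meth_b"] + grouped["unmeth_b"]
    grouped["prop_a"] = grouped["meth_a"] / tot_a
    grouped["prop_b"] = grouped["meth_b"] / tot_b
    grouped["diff"] = grouped["prop_b"] - grouped["prop_a"]
    grouped["avg_reads"] = (tot_a + tot_b) / (2 * grouped["n_cytosines"])
    grouped["tested"] = (
        (grouped["n_cytosines"] >= params.min_cytosines)
        & (grouped["diff"].abs() >= params.min_diff)
        & (grouped["avg_reads"] >= params.min_avg_reads)
    )
    grouped["p"] = np.nan
    tested = grouped.index[grouped["tested"]]
    grouped.loc[tested, "p"] = [
        fisher_exact_two_sided(
            int(grouped.at[i, "meth_a"]), int(grouped.at[i, "unmeth_a"]),
            int(grouped.at[i, "meth_b"]), int(grouped.at[i, "unmeth_b"]),
        )
        for i in tested
    ]
    return grouped[
        ["chrom", "start", "end", "context", "n_cytosines",
         "meth_a", "unmeth_a", "meth_b", "unmeth_b",
         "prop_a", "prop_b", "diff", "avg_reads", "tested", "p"]
    ]


def window_test(report_a: pd.DataFrame, report_b: pd.DataFrame,
                window: tuple[str, int, int], context: str,
                params: DmrParams | None = None) -> pd.Series | None:
    """Statistics for a single (chrom, start, end) window; None if no data."""
    params = (params or DmrParams()).validate()
    chrom, start, end = window
    cols = ["chrom", "pos", "count_meth", "count_unmeth"]
    sel_a = report_a[(report_a["chrom"] == chrom) & report_a["pos"].between(start, end)
                     & (report_a["context"] == context)][cols]
    sel_b = report_b[(report_b["chrom"] == chrom) & report_b["pos"].between(start, end)
                     & (report_b["context"] == context)][cols]
    merged = sel_a.merge(sel_b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if merged.empty:
        return None
    meth_a, unmeth_a = int(merged["count_meth_a"].sum()), int(merged["count_unmeth_a"].sum())
    meth_b, unmeth_b = int(merged["count_meth_b"].sum()), int(merged["count_unmeth_b"].sum())
    n_cyt = len(merged)
    prop_a = meth_a / (meth_a + unmeth_a)
    prop_b = meth_b / (meth_b + unmeth_b)
    avg_reads = (meth_a + unmeth_a + meth_b + unmeth_b) / (2 * n_cyt)
    tested = (
        n_cyt >= params.min_cytosines
        and abs(prop_b - prop_a) >= params.min_diff
        and avg_reads >= params.min_avg_reads
    )
    return pd.Series(
        {
            "chrom": chrom, "start": start, "end": end, "context": context,
            "n_cytosines": n_cyt, "meth_a": meth_a, "unmeth_a": unmeth_a,
            "meth_b": meth_b, "unmeth_b": unmeth_b,
            "prop_a": prop_a, "prop_b": prop_b, "diff": prop_b - prop_a,
            "avg_reads": avg_reads, "tested": tested,
            "p": fisher_exact_two_sided(meth_a, unmeth_a, meth_b, unmeth_b),
        }
    )


# ---------------------------------------------------------------------------
# DMR calling

def call_dmrs(report_a: pd.DataFrame, report_b: pd.DataFrame, context: str,
              params: DmrParams | None = None,
              direction_labels: tuple[str, str] = ("a_up", "b_up"),
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call DMRs between two conditions for one context.

    Returns (dmrs, windows).  BH correction runs across the windows passing
    the three filters; windows with q < fdr become candidate bins whose
    direction is the sign of prop_b - prop_a (labelled with
    ``direction_labels``); same-direction bins with an inter-bin gap smaller
    than ``join_distance`` are merged.
    """
    params = (params or DmrParams()).validate()
    windows = window_stats(report_a, report_b, context, params)
    windows["q"] = np.nan
    tested = windows[windows["tested"]]
    if tested.empty:
        logger.warning("call_dmrs: no windows passed the filters for context %s", context)
        return _empty_dmrs(), windows
    q = multipletests(tested["p"].to_numpy(), method="fdr_bh")[1]
    windows.loc[tested.index, "q"] = q
    cand = windows[(windows["q"] < params.fdr) & (windows["diff"] != 0)].copy()
    cand["direction"] = np.where(cand["diff"] > 0, direction_labels[1], direction_labels[0])
    bins = cand.rename(columns={"q": "min_q", "prop_a": "mean_prop_a",
                                "prop_b": "mean_prop_b"})
    bins["n_windows"] = 1
    dmrs = merge_bins(bins, params.join_distance)
    return dmrs, windows


_DMR_COLUMNS = ["chrom", "start", "end", "context", "direction",
                "n_windows", "mean_prop_a", "mean_prop_b", "min_q"]


def _empty_dmrs() -> pd.DataFrame:
    return pd.DataFrame(columns=_DMR_COLUMNS)


def merge_bins(bins: pd.DataFrame, join_distance: int) -> pd.DataFrame:
    """Merge same-context, same-direction bins with inter-bin gap < join_distance.

    Bins must carry chrom/start/end/context/direction/n_windows/
    mean_prop_a/mean_prop_b/min_q.  Means are weighted by n_windows, so the
    operation is idempotent: merging its own output changes nothing.
    """
    if bins.empty:
        return _empty_dmrs()
    out = []
    for (chrom, ctx, direction), group in bins.groupby(
            ["chrom", "context", "direction"], sort=True):
        group = group.sort_values("start")
        current = None
        for row in group.itertuples(index=False):
            if current is not None and row.start - current["end"] - 1 < join_distance:
                w = current["n_windows"] + row.n_windows
                current["mean_prop_a"] = (
                    current["mean_prop_a"] * current["n_windows"]
                    + row.mean_prop_a * row.n_windows
                ) / w
                current["mean_prop_b"] = (
                    current["mean_prop_b"] * current["n_windows"]
                    + row.mean_prop_b * row.n_windows
                ) / w
                current["n_windows"] = w
                current["end"] = max(current["end"], row.end)
                current["min_q"] = min(current["min_q"], row.min_q)
            else:
                if current is not None:
                    out.append(current)
                current = {
                    "chrom": chrom, "start": int(row.start), "end": int(row.end),
                    "context": ctx, "direction": direction,
                    "n_windows": int(row.n_windows),
                    "mean_prop_a": float(row.mean_prop_a),
                    "mean_prop_b": float(row.mean_prop_b),
                    "min_q": float(row.min_q),
                }
        if current is not None:
            out.append(current)
    dmrs = pd.DataFrame(out, columns=_DMR_COLUMNS)
    return dmrs.sort_values(["chrom", "start"], ignore_index=True)


# ---------------------------------------------------------------------------
# DMR annotation

_REGION_KINDS = ("LTR_retrotransposon", "gene", "upstream")


def annotate_dmrs(dmrs: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Count DMRs per region category (LTR retrotransposons, genes, upstream).

    A DMR is assigned to every category it overlaps by at least 1 bp, so one
    DMR can count in several rows (per-row semantics of the direction/region
    accounting); DMRs overlapping none fall in 'unassigned'.  Returns a long
    table (region, context, direction, n).
    """
    trees = {region: _feature_tree(features, region) for region in _REGION_KINDS}
    rows = []
    for dmr in dmrs.itertuples(index=False):
        hit_any = False
        for region, tree in trees.items():
            t = tree.get(dmr.chrom)
            if t is not None and t.overlap(dmr.start, dmr.end + 1):
                rows.append({"region": region, "context": dmr.context,
                             "direction": dmr.direction})
                hit_any = True
        if not hit_any:
            rows.append({"region": "unassigned", "context": dmr.context,
                         "direction": dmr.direction})
    if not rows:
        return pd.DataFrame(columns=["region", "context", "direction", "n"])
    return (
        pd.DataFrame(rows)
        .groupby(["region", "context", "direction"], sort=True)
        .size()
        .reset_index(name="n")
    )


def _feature_tree(features: pd.DataFrame, region: str) -> dict[str, IntervalTree]:
    if region == "LTR_retrotransposon":
        sel = features[(features["kind"] == "te")
                       & (features["te_class"] == "LTR_retrotransposon")]
    else:
        sel = features[features["kind"] == region]
    trees: dict[str, IntervalTree] = {}
    for row in sel.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end + 1, row.id)
    return trees


def family_dmr_summary(dmrs: pd.DataFrame, te_features: pd.DataFrame,
                       min_dmrs: int = 5) -> pd.DataFrame:
    """Per-family DMR table for TE families with at least ``min_dmrs`` DMRs.

    Each retained row is one (family, DMR) pair with the DMR's mean
    methylation level under both conditions and its direction, the numbers
    behind per-family DMR dot plots.
    """
    te = te_features[(te_features["kind"] == "te") & (te_features["family"] != "")]
    trees: dict[str, IntervalTree] = {}
    for row in te.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end + 1, row.family)
    rows = []
    for dmr in dmrs.itertuples(index=False):
        t = trees.get(dmr.chrom)
        if t is None:
            continue
        families = {iv.data for iv in t.overlap(dmr.start, dmr.end + 1)}
        for fam in sorted(families):
            rows.append(
                {
                    "family": fam, "chrom": dmr.chrom, "start": dmr.start,
                    "end": dmr.end, "context": dmr.context,
                    "direction": dmr.direction,
                    "mean_prop_a": dmr.mean_prop_a, "mean_prop_b": dmr.mean_prop_b,
                }
            )
    cols = ["family", "chrom", "start", "end", "context", "direction",
            "mean_prop_a", "mean_prop_b"]
    if not rows:
        return pd.DataFrame(columns=cols + ["n_dmrs"])
    table = pd.DataFrame(rows, columns=cols)
    counts = table.groupby("family")["start"].transform("size")
    table["n_dmrs"] = counts
    return table[table["n_dmrs"] >= min_dmrs].reset_index(drop=True)
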