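"""Per-feature weighted methylation from cytosine call tables.

Implements the quantification conventions of the comparative analysis:
only cytosine positions sequenced at least three times are used; a
feature's methylation level per context is the coverage-weighted value
sum(methylated calls) / sum(total calls) over its positions (both strands
pooled); a feature enters downstream comparisons only when at least 25 %
of its cytosine positions pass the coverage floor.  The bisulfite
conversion rate is estimated from the unmethylated chloroplast.  Genotype
comparisons per TE class use the two-sided Wilcoxon rank-sum test on
included features' levels, with the mean difference in percentage points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTEXTS, TE_CLASSES, DataError

logger = logging.getLogger(__name__)

_ACGT = np.frombuffer(b"ACGT", dtype="S1")
_PAD = np.bytes_(b"$")
_COMPLEMENT = {b"A": "T", b"C": "G", b"G": "C", b"T": "A", b"$": ""}


# ---------------------------------------------------------------------------
# Context assignment

def assign_contexts(sequences: Mapping[str, str]) -> pd.DataFrame:
    """Label every cytosine (C on +, G on -) as CG, CHG or CHH.

    The context is read from the 3-base window 5'->3' on the cytosine's own
    strand: CG if the next base is G, CHG if the base after next is G, CHH
    otherwise.  Windows truncated by a contig end default to CHH unless the
    CG call is already decided by the next base.  Positions whose window
    contains a non-ACGT character are skipped (a count is logged).

    Returns a DataFrame (chrom, pos 1-based, strand, context, trinucleotide)
    sorted by chrom and position.
    """
    frames = []
    n_skipped = 0
    for chrom in sorted(sequences):
        seq = sequences[chrom].upper()
        b = np.frombuffer(seq.encode(), dtype="S1")
        pad = np.concatenate([np.full(2, _PAD), b, np.full(2, _PAD)])

        def window_context(pos0, n1, n2):
            nonlocal n_skipped
            valid1 = np.isin(n1, _ACGT)
            valid2 = np.isin(n2, _ACGT)
            is_pad1 = n1 == _PAD
            is_pad2 = n2 == _PAD
            cg = valid1 & (n1 == b"G")
            skip = (~valid1 & ~is_pad1) | (~cg & ~is_pad1 & ~valid2 & ~is_pad2)
            chg = ~cg & valid2 & (n2 == b"G") & valid1
            ctx = np.where(cg, "CG", np.where(chg, "CHG", "CHH"))
            n_skipped += int(skip.sum())
            return pos0[~skip], ctx[~skip], n1[~skip], n2[~skip]

        # plus strand: C at i, window seq[i:i+3]
        pos_c = np.flatnonzero(b == b"C")
        p_pos, p_ctx, p_n1, p_n2 = window_context(pos_c, pad[pos_c + 3], pad[pos_c + 4])
        p_tri = np.array(
            ["C" + n1.decode().replace("$", "") + n2.decode().replace("$", "")
             for n1, n2 in zip(p_n1, p_n2)], dtype=object,
        )
        # minus strand: G at i, window is revcomp(seq[i-2:i+1])
        pos_g = np.flatnonzero(b == b"G")
        m_pos, m_ctx, m_n1, m_n2 = window_context(
            pos_g, _complement_bytes(pad[pos_g + 1]), _complement_bytes(pad[pos_g]),
        )
        m_tri = np.array(
            ["C" + _COMPLEMENT.get(bytes(n1c), "") + _COMPLEMENT.get(bytes(n2c), "")
             for n1c, n2c in zip(_uncomplement(m_n1), _uncomplement(m_n2))], dtype=object,
        )
        frame = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.concatenate([p_pos, m_pos]) + 1,
                "strand": np.array(["+"] * len(p_pos) + ["-"] * len(m_pos)),
                "context": np.concatenate([p_ctx, m_ctx]),
                "trinucleotide": np.concatenate([p_tri, m_tri]),
            }
        )
        frames.append(frame.sort_values("pos", kind="stable"))
    if n_skipped:
        logger.info("assign_contexts: skipped %d positions with non-ACGT windows", n_skipped)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "trinucleotide"])
    return pd.concat(frames, ignore_index=True)


def _complement_bytes(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    for a, b in ((b"A", b"T"), (b"T", b"A"), (b"C", b"G"), (b"G", b"C")):
        out[arr == a] = b
    return out


def _uncomplement(arr: np.ndarray) -> np.ndarray:
    return _complement_bytes(arr)


# ---------------------------------------------------------------------------
# Conversion rate and position filtering

@dataclass
class ConversionEstimate:
    rate: float
    n_calls: int


def estimate_conversion_rate(report: pd.DataFrame,
                             contig: str | None = "chloroplast") -> ConversionEstimate:
    """Estimate bisulfite conversion from an unmethylated control contig.

    rate = sum(unmethylated calls) / sum(all calls) over the contig's
    cytosines; every unmethylated C should read as T, so residual C calls
    measure conversion failure.
    """
    sub = report if contig is None else report[report["chrom"] == contig]
    total = int(sub["count_meth"].sum() + sub["count_unmeth"].sum())
    if total == 0:
        raise DataError(
            f"cannot estimate conversion rate: no calls on contig {contig!r}"
        )
    return ConversionEstimate(rate=float(sub["count_unmeth"].sum()) / total, n_calls=total)


def filter_positions(report: pd.DataFrame, min_reads: int = 3) -> pd.DataFrame:
    """Keep positions sequenced at least ``min_reads`` times."""
    depth = report["count_meth"] + report["count_unmeth"]
    return report[depth >= min_reads].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Feature-level weighted methylation

def feature_methylation(report: pd.DataFrame, features: pd.DataFrame,
                        contexts_map: pd.DataFrame, context: str = "all",
                        min_coverage_fraction: float = 0.25) -> pd.DataFrame:
    """Per-feature, per-context weighted methylation with the 25 % rule.

    ``report`` must already be position-filtered (>=3 reads).  For each
    feature, weighted_level = sum(count_meth)/sum(total) over in-feature
    positions of the context on both strands.  coverage_fraction is the
    fraction of the feature's cytosine positions (any context, from
    ``contexts_map``) that are present in the filtered report; ``included``
    is coverage_fraction >= ``min_coverage_fraction``.  Features without
    cytosines get n_positions=0 and included=False.
    """
    if context == "all":
        requested = list(CONTEXTS)
    elif context in CONTEXTS:
        requested = [context]
    else:
        raise DataError(f"unknown context {context!r}")

    rep = report.sort_values(["chrom", "pos"], kind="stable")
    cmap = contexts_map.sort_values(["chrom", "pos"], kind="stable")
    rep_by_chrom = {c: g for c, g in rep.groupby("chrom", sort=False)}
    map_by_chrom = {c: g for c, g in cmap.groupby("chrom", sort=False)}

    rows = []
    for feat in features.itertuples(index=False):
        r = rep_by_chrom.get(feat.chrom)
        m = map_by_chrom.get(feat.chrom)
        if m is None or len(m) == 0:
            total_cyt = 0
            covered = 0
        else:
            mpos = m["pos"].to_numpy()
            lo, hi = np.searchsorted(mpos, [feat.start, feat.end + 1])
            total_cyt = hi - lo
            if r is None or len(r) == 0:
                covered = 0
            else:
                rpos = r["pos"].to_numpy()
                rlo, rhi = np.searchsorted(rpos, [feat.start, feat.end + 1])
                covered = rhi - rlo
        coverage_fraction = covered / total_cyt if total_cyt else 0.0
        included = total_cyt > 0 and coverage_fraction >= min_coverage_fraction
        for ctx in requested:
            if r is None or len(r) == 0:
                n_pos, level = 0, np.nan
            else:
                sub = r.iloc[rlo:rhi] if covered else r.iloc[0:0]
                sub = sub[sub["context"] == ctx]
                n_pos = len(sub)
                denom = int(sub["count_meth"].sum() + sub["count_unmeth"].sum())
                level = float(sub["count_meth"].sum()) / denom if denom else np.nan
            rows.append(
                {
                    "feature_id": feat.id,
                    "context": ctx,
                    "weighted_level": level,
                    "n_positions": n_pos,
                    "coverage_fraction": coverage_fraction,
                    "included": included,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "context", "weighted_level", "n_positions",
                 "coverage_fraction", "included"],
    )


# ---------------------------------------------------------------------------
# Class-level genotype comparisons

def summarize_by_class(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame,
                       features: pd.DataFrame, context: str,
                       te_class: str | None = None,
                       label_a: str = "a", label_b: str = "b") -> dict:
    """Compare two genotypes' weighted levels for one TE class and context.

    Only features included in *both* genotypes enter; the test is the
    unpaired two-sided Wilcoxon rank-sum (Mann-Whitney) test, and
    ``mean_difference`` is mean(b) - mean(a) in percentage points, matching
    the hybrid-minus-parental convention of the distribution summaries.
    """
    te = features[features["kind"] == "te"]
    if te_class is not None:
        te = te[te["te_class"] == te_class]
    ids = set(te["id"])

    def _pick(profiles):
        sel = profiles[
            (profiles["context"] == context)
            & profiles["included"]
            & profiles["feature_id"].isin(ids)
            & profiles["weighted_level"].notna()
        ]
        return sel.set_index("feature_id")["weighted_level"]

    a = _pick(profiles_a)
    b = _pick(profiles_b)
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    n = len(shared)
    summary = {
        "te_class": te_class or "all",
        "context": context,
        "genotype_a": label_a,
        "genotype_b": label_b,
        "n": n,
        "mean_a": float(a.mean() * 100) if n else np.nan,
        "mean_b": float(b.mean() * 100) if n else np.nan,
        "mean_difference": float((b.mean() - a.mean()) * 100) if n else np.nan,
        "wilcoxon_p": np.nan,
    }
    if n < 2:
        logger.warning("summarize_by_class: n=%d for class=%s context=%s; p undefined",
                       n, te_class, context)
        return summary
    pooled = np.concatenate([a.to_numpy(), b.to_numpy()])
    if np.allclose(pooled, pooled[0]):
        summary["wilcoxon_p"] = 1.0
        return summary
    stat = stats.mannwhitneyu(a, b, alternative="two-sided", use_continuity=True)
    summary["wilcoxon_p"] = float(stat.pvalue)
    return summary


def class_summary_table(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame,
                        features: pd.DataFrame, label_a: str, label_b: str
                        ) -> pd.DataFrame:
    """All-classes x all-contexts comparison table (distribution summaries)."""
    rows = []
    for te_class in (None, *TE_CLASSES):
        for ctx in CONTEXTS:
            rows.append(
                summarize_by_class(profiles_a, profiles_b, features, ctx,
                                   te_class=te_class, label_a=label_a, label_b=label_b)
            )
    return pd.DataFrame(rows)
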