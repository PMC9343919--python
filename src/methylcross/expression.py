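"""Three-genotype expression analysis and pattern classification.

Quantifies expression differences of genes and TE-family representatives
across almond (A), peach (P) and their F1 hybrid (H): median-of-ratios
normalization, per-feature negative-binomial Wald tests with
method-of-moments dispersions shrunk toward a mean-dispersion trend,
BH-corrected significance requiring q < fdr AND |log2FC| >= 1, and the
mapping of the three pairwise calls onto the 13 consistent ordering
patterns over {A, H, P} with a coarse class (equal / peach_up / almond_up /
hybrid_up / hybrid_down).  Also: family-representative selection with the
80 % (retrotransposon) / 40 % (DNA transposon) length-coverage cutoffs,
cross-reference ortholog correlation, and qPCR relative quantification by
the 2^-ΔΔCt method against reference genes.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DataError

logger = logging.getLogger(__name__)

CONTRASTS = ("A-vs-P", "A-vs-H", "P-vs-H")


# ---------------------------------------------------------------------------
# Normalization

def normalize_counts(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    The reference is the per-feature geometric mean over features positive
    in all samples; each sample's size factor is the median of its ratios to
    that reference.  If no feature is positive everywhere, falls back to
    total-count scaling (logged).
    """
    if counts.empty:
        raise DataError("empty count matrix")
    positive = (counts > 0).all(axis=1)
    if positive.any():
        logref = np.log(counts.loc[positive]).mean(axis=1)
        ratios = np.log(counts.loc[positive]).sub(logref, axis=0)
        size_factors = np.exp(ratios.median(axis=0))
    else:
        logger.warning("normalize_counts: no feature positive in all samples; "
                       "falling back to total-count scaling")
        totals = counts.sum(axis=0).astype(float)
        size_factors = totals / np.exp(np.log(totals).mean())
    size_factors.name = "size_factor"
    return size_factors, counts.div(size_factors, axis=1)


def log_normalized(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(normalized count + 1), the heatmap-ready expression measure."""
    _, norm = normalize_counts(counts)
    return np.log2(norm + 1.0)


# ---------------------------------------------------------------------------
# Negative-binomial pairwise tests

def nb_pairwise_test(counts: pd.DataFrame, design: pd.DataFrame,
                     genotype_a: str, genotype_b: str,
                     fdr: float = 0.05, lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Per-feature NB Wald test of genotype_b versus genotype_a.

    log2fc is log2 of the (pseudocount-stabilised) ratio of normalized group
    means, b over a.  The Wald standard error uses NB variance mu + alpha*mu^2
    with a per-feature method-of-moments dispersion shrunk toward the fitted
    trend alpha(mu) = a1 + a0/mu.  Features that are all-zero across both
    groups are reported untested.  ``significant`` requires both q < fdr and
    |log2fc| >= lfc_threshold.
    """
    samples_a = design.loc[design["genotype"] == genotype_a, "sample"].tolist()
    samples_b = design.loc[design["genotype"] == genotype_b, "sample"].tolist()
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise DataError(
            f"need >=2 replicates per genotype, got {len(samples_a)} for "
            f"{genotype_a!r} and {len(samples_b)} for {genotype_b!r}"
        )
    _, norm = normalize_counts(counts)
    na, nb = norm[samples_a], norm[samples_b]
    mean_a, mean_b = na.mean(axis=1), nb.mean(axis=1)
    var_a = na.var(axis=1, ddof=1)
    var_b = nb.var(axis=1, ddof=1)
    n_a, n_b = len(samples_a), len(samples_b)

    testable = (counts[samples_a + samples_b].sum(axis=1) > 0)
    grand = (mean_a * n_a + mean_b * n_b) / (n_a + n_b)
    pooled_var = (var_a * (n_a - 1) + var_b * (n_b - 1)) / (n_a + n_b - 2)
    alpha, shrink_w = _shrunk_dispersion(grand[testable], pooled_var[testable])

    mu_a = mean_a[testable] + 0.5
    mu_b = mean_b[testable] + 0.5
    lfc = np.log2(mu_b / mu_a)
    nb_var_a = mu_a + alpha * mu_a**2
    nb_var_b = mu_b + alpha * mu_b**2
    se = np.sqrt(nb_var_a / (n_a * mu_a**2) + nb_var_b / (n_b * mu_b**2)) / np.log(2)
    z = lfc / se
    # moderated-t reference: shrinking the dispersion toward the trend with
    # weight w borrows w extra units of residual df per unit observed
    # (limma-style prior df), keeping the test calibrated at n=3
    df = (n_a + n_b - 2) * (1 + shrink_w)
    p = 2.0 * stats.t.sf(np.abs(z), df=df)
    q = multipletests(p, method="fdr_bh")[1]

    result = pd.DataFrame(index=counts.index)
    result["contrast"] = f"{genotype_a}-vs-{genotype_b}"
    result["tested"] = testable
    result["base_mean"] = grand
    result["log2fc"] = np.nan
    result["p"] = np.nan
    result["q"] = np.nan
    result.loc[testable, "log2fc"] = lfc
    result.loc[testable, "p"] = p
    result.loc[testable, "q"] = q
    result["significant"] = (
        testable & (result["q"] < fdr) & (result["log2fc"].abs() >= lfc_threshold)
    )
    result.index.name = "feature"
    return result


def _shrunk_dispersion(mean: pd.Series, var: pd.Series,
                       shrink_w: float = 1.0) -> tuple[pd.Series, float]:
    """MoM dispersion per feature, geometrically shrunk toward a 1/mu trend.

    The trend alpha(mu) = a1 + a0/mu is fitted to the *unclipped* moment
    estimates (which may be negative) so that flooring cannot bias the
    intercept upward; the per-feature estimate is then averaged with the
    trend in log space with weight ``shrink_w`` on the trend.
    """
    mu = np.maximum(mean.to_numpy(), 1e-8)
    mom_raw = (var.to_numpy() - mu) / mu**2
    mom = np.clip(mom_raw, 1e-8, 10.0)
    usable = mu > 1.0
    if usable.sum() >= 10:
        X = np.column_stack([np.ones(usable.sum()), 1.0 / mu[usable]])
        coef, *_ = np.linalg.lstsq(X, mom_raw[usable], rcond=None)
        a1, a0 = max(coef[0], 1e-8), max(coef[1], 0.0)
    else:
        a1, a0 = max(float(np.median(mom)), 1e-8), 0.0
    trend = np.clip(a1 + a0 / mu, 1e-8, 10.0)
    shrunk = np.exp((np.log(mom) + shrink_w * np.log(trend)) / (1.0 + shrink_w))
    return pd.Series(shrunk, index=mean.index), shrink_w


def all_pairwise_tests(counts: pd.DataFrame, design: pd.DataFrame,
                       fdr: float = 0.05, lfc_threshold: float = 1.0
                       ) -> dict[str, pd.DataFrame]:
    """The three contrasts A-vs-P, A-vs-H, P-vs-H keyed by contrast name."""
    out = {}
    for first, second in (("A", "P"), ("A", "H"), ("P", "H")):
        out[f"{first}-vs-{second}"] = nb_pairwise_test(
            counts, design, first, second, fdr=fdr, lfc_threshold=lfc_threshold
        )
    return out


# ---------------------------------------------------------------------------
# Pattern classification

def _relation(row) -> int:
    """-1: first < second, 0: tie, +1: first > second (log2fc = second/first)."""
    if not bool(row["significant"]) or not np.isfinite(row["log2fc"]):
        return 0
    return -1 if row["log2fc"] > 0 else 1


def _weak_orders() -> dict[tuple[int, int, int], tuple[tuple[str, ...], ...]]:
    """Map each consistent relation triad to its weak order (groups, descending).

    Keys are (rel_AP, rel_AH, rel_PH) with rel_XY = sign(X - Y) in rank terms;
    there are exactly 13 weak orders of three labelled items, hence 13
    consistent triads out of the 27 possible.
    """
    orders = {}
    # all ordered set partitions of {A, H, P} into 1..3 groups
    labels = ("A", "H", "P")
    partitions: list[tuple[tuple[str, ...], ...]] = [(("A", "H", "P"),)]
    for solo in labels:
        rest = tuple(l for l in labels if l != solo)
        partitions.append(((solo,), rest))
        partitions.append((rest, (solo,)))
    for perm in itertools.permutations(labels):
        partitions.append(tuple((l,) for l in perm))
    for groups in partitions:
        rank = {}
        for depth, group in enumerate(groups):
            for label in group:
                rank[label] = depth  # lower depth = higher expression
        key = (
            int(np.sign(rank["P"] - rank["A"])),  # A vs P: +1 if A higher
            int(np.sign(rank["H"] - rank["A"])),
            int(np.sign(rank["H"] - rank["P"])),
        )
        orders[key] = groups
    return orders


_ORDERS = _weak_orders()


def _format_pattern(groups: tuple[tuple[str, ...], ...]) -> str:
    """Canonical pattern string, A's group written first.

    Descending with '>' when A sits in the top group, otherwise ascending
    with '<' from the bottom; ties are parenthesised with members in A,H,P
    order, e.g. "A>H>P", "(A=H)>P", "A<(H=P)", "A=H=P".
    """
    if len(groups) == 1:
        return "A=H=P"

    def fmt(group):
        return f"({'='.join(sorted(group))})" if len(group) > 1 else group[0]

    if "A" in groups[0]:
        return ">".join(fmt(g) for g in groups)
    return "<".join(fmt(g) for g in reversed(groups))


def _coarse_class(groups: tuple[tuple[str, ...], ...]) -> str:
    rank = {label: depth for depth, group in enumerate(groups) for label in group}
    if len(groups) == 1:
        return "equal"
    if rank["H"] < rank["A"] and rank["H"] < rank["P"]:
        return "hybrid_up"
    if rank["H"] > rank["A"] and rank["H"] > rank["P"]:
        return "hybrid_down"
    if rank["P"] < rank["A"]:
        return "peach_up"
    if rank["A"] < rank["P"]:
        return "almond_up"
    return "equal"


def classify_pattern(row_ap: pd.Series, row_ah: pd.Series, row_ph: pd.Series) -> dict:
    """Map three pairwise calls for one feature to a fine pattern and class.

    Consistent triads resolve to one of the 13 weak orders of {A, H, P}.
    Inconsistent triads (possible with thresholded tests, e.g. A>P, A=H,
    H=P) are classed by the parental A-vs-P contrast — the anchor of the
    category scheme — with H placed equal to the parent whose contrast with
    H has the weaker evidence (larger p); ``consistent`` is set False.
    """
    for name, row in (("A-vs-P", row_ap), ("A-vs-H", row_ah), ("P-vs-H", row_ph)):
        if row is None or (hasattr(row, "empty") and getattr(row, "empty", False)):
            raise DataError(f"missing contrast {name}")
    triad = (_relation(row_ap), _relation(row_ah), _relation(row_ph))
    groups = _ORDERS.get(triad)
    if groups is not None:
        return {
            "fine_pattern": _format_pattern(groups),
            "coarse_class": _coarse_class(groups),
            "consistent": True,
        }
    rel_ap = triad[0]
    p_ah = row_ah["p"] if np.isfinite(row_ah["p"]) else 1.0
    p_ph = row_ph["p"] if np.isfinite(row_ph["p"]) else 1.0
    h_with_a = p_ah >= p_ph
    if rel_ap == 0:
        groups = (("A", "H", "P"),)
    elif rel_ap > 0:  # A above P
        groups = (("A", "H"), ("P",)) if h_with_a else (("A",), ("H", "P"))
    else:  # A below P
        groups = (("P",), ("A", "H")) if h_with_a else (("H", "P"), ("A",))
    return {
        "fine_pattern": _format_pattern(groups),
        "coarse_class": _coarse_class(groups),
        "consistent": False,
    }


def classify_patterns(de: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Classify every feature given the three contrast tables."""
    missing = set(CONTRASTS) - set(de)
    if missing:
        raise DataError(f"missing contrasts: {sorted(missing)}")
    ap, ah, ph = de["A-vs-P"], de["A-vs-H"], de["P-vs-H"]
    rows = []
    for feature in ap.index:
        if feature not in ah.index or feature not in ph.index:
            raise DataError(f"feature {feature!r} missing from a contrast")
        call = classify_pattern(ap.loc[feature], ah.loc[feature], ph.loc[feature])
        call["feature"] = feature
        rows.append(call)
    return pd.DataFrame(rows)[["feature", "fine_pattern", "coarse_class", "consistent"]]


def expressed_features(counts: pd.DataFrame, design: pd.DataFrame,
                       floor: float = 5.0) -> pd.Series:
    """Features with mean normalized count >= floor in at least one genotype."""
    _, norm = normalize_counts(counts)
    geno_means = {}
    for genotype, sub in design.groupby("genotype"):
        geno_means[genotype] = norm[sub["sample"].tolist()].mean(axis=1)
    return pd.DataFrame(geno_means).max(axis=1) >= floor


def summarize_patterns(calls) -> pd.DataFrame:
    """Category counts and percentages (1 decimal) over the classified set.

    ``calls`` is either a DataFrame of pattern calls (with ``coarse_class``)
    or a mapping class -> count.
    """
    if isinstance(calls, pd.DataFrame):
        if calls.empty:
            return pd.DataFrame(columns=["coarse_class", "n", "percent"])
        counts = calls["coarse_class"].value_counts().to_dict()
    else:
        counts = dict(calls)
        if not counts:
            return pd.DataFrame(columns=["coarse_class", "n", "percent"])
    total = sum(counts.values())
    order = ["equal", "peach_up", "almond_up", "hybrid_up", "hybrid_down"]
    rows = []
    for cls in order + sorted(set(counts) - set(order)):
        if cls not in counts:
            continue
        rows.append(
            {
                "coarse_class": cls,
                "n": int(counts[cls]),
                "percent": round(100.0 * counts[cls] / total, 1),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Family representatives

def select_family_representative(table: pd.DataFrame, te_kind: str) -> dict | None:
    """Best genomic copy for one family's assembled contig, or None.

    ``table`` has columns family, contig, copy_id, coverage (fraction of the
    contig length covered by the alignment).  The highest-coverage copy wins
    if it passes the kind-specific cutoff: 0.80 for retrotransposons, 0.40
    for DNA transposons.
    """
    cutoffs = {"retrotransposon": 0.80, "DNA transposon": 0.40}
    if te_kind not in cutoffs:
        raise DataError(f"unknown te_kind {te_kind!r}")
    if table.empty:
        logger.warning("select_family_representative: empty alignment table")
        return None
    if ((table["coverage"] < 0) | (table["coverage"] > 1)).any():
        raise DataError("coverage fractions must be in [0, 1]")
    best = table.loc[table["coverage"].idxmax()]
    if best["coverage"] < cutoffs[te_kind]:
        return None
    return {
        "family": best["family"],
        "contig": best["contig"],
        "copy_id": best["copy_id"],
        "alignment_coverage": float(best["coverage"]),
        "te_kind": te_kind,
    }


# ---------------------------------------------------------------------------
# Ortholog correlation

def ortholog_correlation(expr_ref_a: pd.Series, expr_ref_p: pd.Series,
                         pairs: pd.DataFrame) -> float:
    """Pearson r over per-feature mean log2 expression across paired references.

    ``pairs`` has columns id_a, id_p referencing features of the two
    expression Series (mean log2-normalized expression per feature).
    """
    missing_a = set(pairs["id_a"]) - set(expr_ref_a.index)
    missing_p = set(pairs["id_p"]) - set(expr_ref_p.index)
    if missing_a or missing_p:
        raise DataError(
            f"ortholog pairs reference unknown features: "
            f"{sorted(missing_a)[:3]} / {sorted(missing_p)[:3]}"
        )
    if len(pairs) < 3:
        raise DataError("need at least 3 ortholog pairs for a correlation")
    x = expr_ref_a.loc[pairs["id_a"]].to_numpy(dtype=float)
    y = expr_ref_p.loc[pairs["id_p"]].to_numpy(dtype=float)
    return float(stats.pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# qPCR relative quantification

def ddct_quantify(ct: pd.DataFrame,
                  reference_genes: tuple[str, ...] = ("TEF2", "RPII"),
                  calibrator: str = "P") -> pd.DataFrame:
    """Relative expression per target per genotype by the 2^-ΔΔCt method.

    Per sample, ΔCt = Ct_target - mean(Ct of reference genes); per genotype,
    ΔΔCt = mean ΔCt - mean ΔCt of the calibrator genotype; relative level is
    2^-ΔΔCt.  The reported SD propagates the replicate SD of ΔCt onto the
    linear scale.  Invariant to a constant plate offset on all Ct values.
    """
    needed = {"sample", "genotype", "gene", "ct"}
    if not needed <= set(ct.columns):
        raise DataError(f"Ct table lacks columns {sorted(needed - set(ct.columns))}")
    wide = ct.pivot_table(index=["sample", "genotype"], columns="gene", values="ct")
    for ref in reference_genes:
        if ref not in wide.columns or wide[ref].isna().any():
            bad = "all samples" if ref not in wide.columns else ", ".join(
                str(s) for s, _ in wide.index[wide[ref].isna()]
            )
            raise DataError(f"missing reference Ct for {ref!r} in {bad}")
    if calibrator not in set(ct["genotype"]):
        raise DataError(f"calibrator genotype {calibrator!r} absent from Ct table")
    ref_mean = wide[list(reference_genes)].mean(axis=1)
    targets = [g for g in wide.columns if g not in reference_genes]
    rows = []
    for target in targets:
        dct = wide[target] - ref_mean
        if dct.isna().any():
            dct = dct.dropna()
        by_geno = dct.groupby(level="genotype")
        cal_mean = by_geno.mean().get(calibrator)
        if cal_mean is None or not np.isfinite(cal_mean):
            raise DataError(f"no calibrator ΔCt for target {target!r}")
        for genotype, grp in by_geno:
            if len(grp) < 2:
                raise DataError(
                    f"target {target!r}, genotype {genotype!r}: need >=2 replicates"
                )
            ddct = grp.mean() - cal_mean
            rel = 2.0 ** (-ddct)
            sd = rel * np.log(2.0) * grp.std(ddof=1)
            rows.append(
                {
                    "target": target, "genotype": genotype,
                    "ddct": float(ddct), "relative_expression": float(rel),
                    "sd": float(sd), "n_replicates": int(len(grp)),
                }
            )
    return pd.DataFrame(rows)
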