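"""Synthetic hybrid-trio data generator with known ground truth.

Generates the full input set of the comparative analysis — two parental
genomes plus an unmethylated chloroplast contig, TE/gene annotations,
per-cytosine methylation call tables for each genotype on each parental
reference, RNA-seq count matrices, and qPCR Ct tables — from one seeded
configuration, together with the ground truth needed to score recovery
(SNP positions, per-feature methylation, spiked DMR intervals, true
expression patterns, size factors).

Model sketch
------------
Two parental sequences descend from one ancestral sequence by independent
lineage substitutions (no indels, so the parental coordinate systems align
1:1).  Feature-level methylation is Beta-distributed around per-context
means; per-position coverage is Poisson; methylated counts are Binomial
with incomplete bisulfite conversion folded in (an unmethylated C reads as
C with probability 1 - conversion_rate).  The hybrid methylome on each
parental reference is the 50:50 allelic mixture of the two parental states,
optionally shifted by ``spike_delta`` inside spiked DMR intervals.  RNA-seq
counts are negative binomial with genotype-specific means encoding the
assigned expression pattern and lognormal per-sample size factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import CONTEXTS, TE_CLASSES, ConfigError, SimulationConfig
from .io import FEATURE_COLUMNS, derive_upstream
from .methylation import assign_contexts

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# length ranges (bp) per feature kind; only relative scale matters
_TE_LENGTHS = {
    "LTR_retrotransposon": (2000, 5000),
    "LINE": (1000, 3000),
    "MITE": (200, 600),
    "TIR": (500, 1500),
}
_GENE_LENGTHS = (1500, 3000)
_UPSTREAM = 1000

MAIN_CHROM = "chr1"
CHLOROPLAST = "chloroplast"


@dataclass
class GenomePair:
    """Two parental genomes on a shared coordinate system plus annotations."""

    sequences: dict[str, dict[str, str]]  # genotype -> contig -> sequence
    features: pd.DataFrame                # FeatureSet incl. derived upstream rows
    truth: dict = field(default_factory=dict)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences["A"].items()}


@dataclass
class MethylomeSet:
    """Cytosine reports per (genotype, reference) with generator ground truth."""

    reports: dict[tuple[str, str], pd.DataFrame]
    truth: dict = field(default_factory=dict)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


def _mutate(rng: np.random.Generator, ancestral: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a uniform other base."""
    seq = ancestral.copy()
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    seq[hit] = (seq[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return seq


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# Genomes and annotations

def simulate_genome_pair(config: SimulationConfig) -> GenomePair:
    """Simulate two parental genomes diverged from one ancestor, with features.

    The per-lineage substitution probability is ``divergence / 2``; the
    expected pairwise difference per site is then 2q(1-q) + (2/3)q**2, within
    0.15 SNPs/kb of ``divergence`` for the default 0.02.  TE copies of the
    four classes and genes are placed non-overlapping (with a 1-kb clearance
    upstream of each gene so the derived upstream region is clean); family
    labels, shared across parents, follow a truncated-geometric size
    distribution within each class.
    """
    config.validate()
    if config.n_families < len(TE_CLASSES):
        raise ConfigError(
            f"n_families={config.n_families} < {len(TE_CLASSES)} TE classes; "
            "need at least one family per class"
        )
    rng = _rng(config, 0)
    ancestral = _random_sequence(rng, config.genome_length, config.gc_content)
    chloro = _to_str(_random_sequence(rng, config.chloroplast_length, config.gc_content))

    q = config.divergence / 2.0
    parent_a = _mutate(rng, ancestral, q)
    parent_p = _mutate(rng, ancestral, q)
    snp_pos = np.flatnonzero(parent_a != parent_p) + 1  # 1-based

    features = _place_features(rng, config)
    upstream = derive_upstream(features, {MAIN_CHROM: config.genome_length})
    features = pd.concat([features, upstream], ignore_index=True)

    sequences = {
        "A": {MAIN_CHROM: _to_str(parent_a), CHLOROPLAST: chloro},
        "P": {MAIN_CHROM: _to_str(parent_p), CHLOROPLAST: chloro},
    }
    truth = {
        "snp_positions": [(MAIN_CHROM, int(p)) for p in snp_pos],
        "n_snps": int(snp_pos.size),
        "unmethylated_contigs": [CHLOROPLAST],
    }
    return GenomePair(sequences=sequences, features=features, truth=truth)


def _place_features(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    # (kind, te_class, length, strand); genes reserve 1 kb of clearance on
    # their 5' side so the derived upstream region stays feature-free
    requests: list[tuple[str, str, int, str]] = []
    for te_class in TE_CLASSES:
        lo, hi = _TE_LENGTHS[te_class]
        for _ in range(config.n_te_per_class):
            strand = "+" if rng.random() < 0.5 else "-"
            requests.append(("te", te_class, int(rng.integers(lo, hi + 1)), strand))
    for _ in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        requests.append(("gene", "", int(rng.integers(*_GENE_LENGTHS)), strand))

    demand = sum(length + (_UPSTREAM if kind == "gene" else 0)
                 for kind, _, length, _ in requests)
    requests.sort(key=lambda r: -r[2])

    # exact free-gap sampling: uniform over all admissible start positions,
    # so placement succeeds whenever any admissible position exists
    occupied: list[tuple[int, int]] = []  # half-open (lo, hi), sorted, disjoint
    rows = []
    counters: dict[str, int] = {}
    for kind, te_class, length, strand in requests:
        left_clr = _UPSTREAM if (kind == "gene" and strand == "+") else 0
        right_clr = _UPSTREAM if (kind == "gene" and strand == "-") else 0
        span = length + left_clr + right_clr
        gaps = []
        prev_end = 1
        for lo, hi in occupied:
            if lo - prev_end >= span:
                gaps.append((prev_end, lo))
            prev_end = hi
        if config.genome_length + 1 - prev_end >= span:
            gaps.append((prev_end, config.genome_length + 1))
        slack = [hi - lo - span + 1 for lo, hi in gaps]
        total = int(np.sum(slack)) if slack else 0
        if total == 0:
            raise ConfigError(
                f"cannot place a {length}-bp {te_class or kind} feature: requested "
                f"features need ~{demand} bp but genome_length is {config.genome_length}"
            )
        pick = int(rng.integers(total))
        for (lo, hi), s in zip(gaps, slack):
            if pick < s:
                start = lo + left_clr + pick
                break
            pick -= s
        iv = (start - left_clr, start + length + right_clr)
        idx = 0
        while idx < len(occupied) and occupied[idx][0] < iv[0]:
            idx += 1
        occupied.insert(idx, iv)
        label = te_class or "gene"
        counters[label] = counters.get(label, 0) + 1
        rows.append(
            {
                "id": f"{label}_{counters[label]:03d}",
                "chrom": MAIN_CHROM,
                "start": start,
                "end": start + length - 1,
                "strand": strand,
                "kind": kind,
                "te_class": te_class,
                "family": "",
            }
        )
    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    _assign_families(rng, features, config)
    return features.sort_values(["chrom", "start"], ignore_index=True)


def _assign_families(rng: np.random.Generator, features: pd.DataFrame,
                     config: SimulationConfig) -> None:
    """Distribute `n_families` labels over TE copies, >=1 family per class.

    Family sizes within a class follow a truncated geometric distribution
    (weights (1/2)^i), so a few large families dominate each class.
    """
    fams_per_class = {cls: 1 for cls in TE_CLASSES}
    extra = config.n_families - len(TE_CLASSES)
    for i in range(extra):
        fams_per_class[TE_CLASSES[i % len(TE_CLASSES)]] += 1
    short = {"LTR_retrotransposon": "LTR", "LINE": "LINE", "MITE": "MITE", "TIR": "TIR"}
    fam_counter = 0
    for cls in TE_CLASSES:
        idx = features.index[(features["kind"] == "te") & (features["te_class"] == cls)]
        k = fams_per_class[cls]
        names = [f"{short[cls]}_{fam_counter + i + 1}" for i in range(k)]
        fam_counter += k
        weights = 0.5 ** np.arange(k)
        weights /= weights.sum()
        choice = rng.choice(k, size=len(idx), p=weights)
        # guarantee every family has at least one copy when possible
        for i in range(min(k, len(idx))):
            choice[i] = i
        features.loc[idx, "family"] = [names[c] for c in choice]


# ---------------------------------------------------------------------------
# Methylomes

def simulate_methylomes(pair: GenomePair, config: SimulationConfig,
                        spike: bool = True) -> MethylomeSet:
    """Simulate cytosine reports for A, P and H on each parental reference.

    Feature-level true methylation per (feature, context, genotype) is drawn
    from Beta(m*nu, (1-m)*nu) around the context mean m; positions outside
    features sit at the context mean.  The hybrid methylome is the 50:50
    mixture of the parental feature states, with ``n_spiked_dmrs`` disjoint
    spiked intervals shifted by ``spike_delta`` (recorded in the ground
    truth).  Chloroplast cytosines have true methylation zero, providing the
    unmethylated control for conversion-rate estimation.
    """
    config.validate()
    rng = _rng(config, 1)
    features = pair.features.reset_index(drop=True)

    # per-feature true methylation for each parent; hybrid = allelic mixture
    n_feat = len(features)
    fm: dict[str, dict[str, np.ndarray]] = {}
    for genotype in ("A", "P"):
        fm[genotype] = {}
        for ctx in CONTEXTS:
            m = config.context_means[ctx]
            nu = config.context_dispersion[ctx]
            if m <= 0.0 or m >= 1.0:  # degenerate Beta: point mass at 0 or 1
                fm[genotype][ctx] = np.full(n_feat, float(m))
            else:
                fm[genotype][ctx] = rng.beta(m * nu, (1 - m) * nu, size=n_feat)
    fm["H"] = {ctx: 0.5 * (fm["A"][ctx] + fm["P"][ctx]) for ctx in CONTEXTS}

    ctx_maps = {ref: assign_contexts(pair.sequences[ref]) for ref in ("A", "P")}
    spikes = (
        _choose_spikes(rng, features, config,
                       ctx_maps["A"][ctx_maps["A"]["chrom"] == MAIN_CHROM])
        if spike and config.n_spiked_dmrs else []
    )

    reports: dict[tuple[str, str], pd.DataFrame] = {}
    for ref in ("A", "P"):
        ctx_map = ctx_maps[ref]
        main = ctx_map[ctx_map["chrom"] == MAIN_CHROM].reset_index(drop=True)
        chlo = ctx_map[ctx_map["chrom"] == CHLOROPLAST].reset_index(drop=True)
        m_parent = {g: _position_methylation(main, features, fm[g], config)
                    for g in ("A", "P")}
        m_by_genotype = {
            ref: m_parent[ref],
            "H": _apply_spikes(main, 0.5 * (m_parent["A"] + m_parent["P"]),
                               m_parent, spikes),
        }
        for genotype, m_true in m_by_genotype.items():
            main_rep = _observe(rng, main, m_true, config)
            chlo_rep = _observe(rng, chlo, np.zeros(len(chlo)), config)
            reports[(genotype, ref)] = pd.concat([main_rep, chlo_rep], ignore_index=True)

    truth = {
        "feature_methylation": {
            f"{features.at[i, 'id']}|{ctx}|{g}": float(fm[g][ctx][i])
            for g in ("A", "P", "H") for ctx in CONTEXTS for i in range(n_feat)
        },
        "spiked_dmrs": spikes,
    }
    return MethylomeSet(reports=reports, truth=truth)


def _position_methylation(ctx_map: pd.DataFrame, features: pd.DataFrame,
                          fm_ctx: dict[str, np.ndarray],
                          config: SimulationConfig) -> np.ndarray:
    """Per-position true methylation: feature value inside, context mean outside."""
    feats = features[features["chrom"] == MAIN_CHROM]
    starts = feats["start"].to_numpy()
    ends = feats["end"].to_numpy()
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    feat_idx = feats.index.to_numpy()[order]

    pos = ctx_map["pos"].to_numpy()
    slot = np.searchsorted(starts, pos, side="right") - 1
    inside = (slot >= 0) & (pos <= ends[np.clip(slot, 0, None)])
    owner = np.where(inside, feat_idx[np.clip(slot, 0, None)], -1)

    m = np.empty(len(ctx_map))
    ctx_codes = ctx_map["context"].to_numpy()
    for ctx in CONTEXTS:
        sel = ctx_codes == ctx
        m[sel] = config.context_means[ctx]
        hit = sel & (owner >= 0)
        m[hit] = fm_ctx[ctx][owner[hit]]
    return m


def _choose_spikes(rng: np.random.Generator, features: pd.DataFrame,
                   config: SimulationConfig, ctx_map: pd.DataFrame) -> list[dict]:
    """Pick disjoint spike intervals aligned to the 50-bp window grid.

    Locations cycle over LTR copies, genes, upstream regions and intergenic
    background; contexts cycle CG/CHG (a CHH shift of the default size would
    be clipped away); spikes point toward hypomethylation in the hybrid when
    the context mean leaves no headroom for an upward shift.  Candidate
    intervals are accepted only when every 50-bp window they cover carries at
    least three cytosines of the spiked context, the regime in which the
    window test's own cytosine filter can see the signal.
    """
    ctx_pos = {ctx: ctx_map.loc[ctx_map["context"] == ctx, "pos"].to_numpy()
               for ctx in ("CG", "CHG")}

    def dense_enough(start: int, end: int, ctx: str) -> bool:
        pos = ctx_pos[ctx]
        for w in range(start, end, 50):
            lo, hi = np.searchsorted(pos, [w, w + 50])
            if hi - lo < 3:
                return False
        return True
    cats = ["ltr", "gene", "upstream", "background"]
    pools = {
        "ltr": features[(features["kind"] == "te")
                        & (features["te_class"] == "LTR_retrotransposon")],
        "gene": features[features["kind"] == "gene"],
        "upstream": features[features["kind"] == "upstream"],
    }
    used = IntervalTree()
    spikes: list[dict] = []
    length = int(np.ceil(config.spike_length / 50.0) * 50)
    attempts = 0
    i = 0
    while len(spikes) < config.n_spiked_dmrs and attempts < 200 * config.n_spiked_dmrs:
        attempts += 1
        cat = cats[i % len(cats)]
        ctx = ["CG", "CHG"][i % 2]
        if cat == "background":
            start = int(rng.integers(0, config.genome_length - length)) // 50 * 50 + 1
        else:
            pool = pools[cat]
            pool = pool[(pool["end"] - pool["start"] + 1) >= length + 50]
            if pool.empty:
                i += 1
                continue
            f = pool.iloc[int(rng.integers(len(pool)))]
            lo = (int(f["start"]) + 49) // 50 * 50 + 1
            hi = int(f["end"]) - length + 1
            if hi < lo:
                i += 1
                continue
            start = lo + int(rng.integers((hi - lo) // 50 + 1)) * 50
        end = start + length - 1
        if used.overlap(start, end + 1) or not dense_enough(start, end + 1, ctx):
            continue
        used.addi(start, end + 1)
        m = config.context_means[ctx]
        if m + config.spike_delta > 0.95:
            direction = "parent_up"
        else:
            direction = "hybrid_up" if rng.random() < 0.5 else "parent_up"
        spikes.append(
            {
                "chrom": MAIN_CHROM,
                "start": int(start),
                "end": int(end),
                "context": ctx,
                "direction": direction,
                "delta": float(config.spike_delta),
            }
        )
        i += 1
    spikes.sort(key=lambda s: s["start"])
    return spikes


def _apply_spikes(ctx_map: pd.DataFrame, m_hybrid: np.ndarray,
                  m_parent: dict[str, np.ndarray], spikes: list[dict]) -> np.ndarray:
    """Shift the hybrid methylome inside spike intervals.

    The spiked hybrid level is placed ``delta`` beyond the more extreme of
    the two parental levels (clipped to [0.02, 0.98]) so that the realised
    hybrid-versus-parent contrast on either reference is at least ``delta``
    wherever clipping permits.
    """
    m = m_hybrid.copy()
    pos = ctx_map["pos"].to_numpy()
    ctx_codes = ctx_map["context"].to_numpy()
    for s in spikes:
        sel = (pos >= s["start"]) & (pos <= s["end"]) & (ctx_codes == s["context"])
        if s["direction"] == "hybrid_up":
            target = np.maximum(m_parent["A"][sel], m_parent["P"][sel]) + s["delta"]
        else:
            target = np.minimum(m_parent["A"][sel], m_parent["P"][sel]) - s["delta"]
        m[sel] = np.clip(target, 0.02, 0.98)
    return m


def _observe(rng: np.random.Generator, ctx_map: pd.DataFrame, m_true: np.ndarray,
             config: SimulationConfig) -> pd.DataFrame:
    """Draw coverage and methylated counts; fold in conversion failure."""
    cov = rng.poisson(config.mean_coverage, size=len(ctx_map))
    keep = cov > 0
    p_obs = m_true + (1.0 - m_true) * (1.0 - config.conversion_rate)
    meth = np.zeros(len(ctx_map), dtype=np.int64)
    meth[keep] = rng.binomial(cov[keep], p_obs[keep])
    report = ctx_map.loc[keep, ["chrom", "pos", "strand", "context", "trinucleotide"]].copy()
    report["count_meth"] = meth[keep]
    report["count_unmeth"] = cov[keep] - meth[keep]
    return report[["chrom", "pos", "strand", "count_meth", "count_unmeth",
                   "context", "trinucleotide"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# RNA-seq counts

_PATTERN_MULT = {
    # genotype multipliers (A, P, H) as powers of 2 in units of lfc_effect
    "equal": (0.0, 0.0, 0.0),
    "peach_up": (0.0, 1.0, 0.5),
    "almond_up": (1.0, 0.0, 0.5),
    "hybrid_up": (0.0, 0.0, 1.0),
    "hybrid_down": (0.0, 0.0, -1.0),
}


def simulate_counts(features: pd.DataFrame, config: SimulationConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a 9-sample count matrix for genes and TE-family representatives.

    Counts ~ NB(mean = s_j * mu_i * 2**(lfc_effect * pattern multiplier),
    dispersion alpha); a ``unexpressed_fraction`` of features get a near-zero
    baseline to exercise the expression floor.  Returns (counts, design,
    truth) where truth carries each feature's assigned coarse pattern class,
    its expressed flag and the sample size factors.
    """
    config.validate()
    rng = _rng(config, 2)
    gene_ids = features.loc[features["kind"] == "gene", "id"].tolist()
    fam_ids = sorted(
        f"{fam}_rep" for fam in features.loc[features["kind"] == "te", "family"].unique()
        if fam
    )
    ids = gene_ids + fam_ids
    n = len(ids)

    classes = list(config.pattern_mix)
    probs = np.array([config.pattern_mix[c] for c in classes], dtype=float)
    probs /= probs.sum()
    pattern = rng.choice(len(classes), size=n, p=probs)
    patterns = np.array(classes, dtype=object)[pattern]
    if config.lfc_effect == 0:
        # a zero effect size erases every pattern: truth is all-equal
        patterns = np.array(["equal"] * n, dtype=object)
    expressed = rng.random(n) >= config.unexpressed_fraction

    base = rng.lognormal(np.log(config.mean_expression), 1.0, size=n)
    base = np.where(expressed, base, 0.2)

    genotypes = ["A", "P", "H"]
    sample_ids = [f"{g}_{r + 1}" for g in genotypes for r in range(config.replicates)]
    size_factors = rng.lognormal(0.0, 0.15, size=len(sample_ids))

    mult = np.array([_PATTERN_MULT[p] for p in patterns])  # n x 3
    mu_geno = base[:, None] * 2.0 ** (config.lfc_effect * mult)  # n x 3

    counts = np.zeros((n, len(sample_ids)), dtype=np.int64)
    alpha = config.nb_dispersion
    for j, sample in enumerate(sample_ids):
        g = genotypes.index(sample.split("_")[0])
        mu = mu_geno[:, g] * size_factors[j]
        if alpha <= 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / alpha
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="feature"),
                             columns=sample_ids)
    design = pd.DataFrame(
        {
            "sample": sample_ids,
            "genotype": [s.split("_")[0] for s in sample_ids],
            "replicate": [int(s.split("_")[1]) for s in sample_ids],
        }
    )
    truth = {
        "true_patterns": dict(zip(ids, patterns)),
        "expressed": dict(zip(ids, (bool(e) for e in expressed))),
        "size_factors": dict(zip(sample_ids, size_factors.astype(float))),
    }
    return counts_df, design, truth


# ---------------------------------------------------------------------------
# qPCR

def simulate_qpcr(true_expression: pd.DataFrame, config: SimulationConfig,
                  reference_genes: tuple[str, ...] = ("TEF2", "RPII"),
                  noise_sd: float = 0.2, intercept: float = 30.0) -> pd.DataFrame:
    """Simulate a Ct table from linear-scale expression per genotype.

    Ct = intercept - log2(expression) + Gaussian noise.  ``true_expression``
    is a feature x genotype table including the reference genes, whose
    expression must be identical across genotypes (they anchor ΔCt).
    """
    if (true_expression <= 0).any().any():
        raise ConfigError("qPCR simulation requires strictly positive expression")
    for ref in reference_genes:
        if ref not in true_expression.index:
            raise ConfigError(f"reference gene {ref!r} missing from expression table")
        vals = true_expression.loc[ref]
        if not np.allclose(vals, vals.iloc[0]):
            raise ConfigError(f"reference gene {ref!r} not constant across genotypes")
    rng = _rng(config, 3)
    rows = []
    for genotype in true_expression.columns:
        for rep in range(1, config.replicates + 1):
            for gene in true_expression.index:
                expr = float(true_expression.at[gene, genotype])
                ct = intercept - np.log2(expr)
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "sample": f"{genotype}_{rep}",
                        "genotype": genotype,
                        "gene": gene,
                        "ct": float(ct),
                    }
                )
    return pd.DataFrame(rows)
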