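"""End-to-end pipeline orchestration and the summary tables.

``run_pipeline`` executes simulate -> methylation -> DMR -> expression ->
qPCR in dependency order under one output directory, records a manifest
with per-stage output checksums and wall-clock times, and skips stages
whose outputs already exist for the same configuration digest.  The table
builders reproduce the analysis' headline tables: per-class inclusion
percentages under the 25 % coverage rule, and DMR direction/region
accounting per context.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import CONTEXTS, TE_CLASSES, DataError, RunConfig
from . import io as mio
from . import dmr as mdmr
from . import expression as mexpr
from . import methylation as mmeth
from . import simulate as msim

logger = logging.getLogger(__name__)

_CLASS_ROWS = ("total", *TE_CLASSES)


def make_table1(profiles: dict[str, pd.DataFrame], features: pd.DataFrame) -> pd.DataFrame:
    """Percentage of TE copies passing the 25 % coverage rule, per class.

    ``profiles`` maps a column label (e.g. 'P', 'A', 'H_on_P', 'H_on_A') to
    that genotype/reference's profile table.  Empty classes yield NaN cells
    (logged).
    """
    te = features[features["kind"] == "te"]
    table = {}
    for label, prof in profiles.items():
        flags = prof.drop_duplicates("feature_id").set_index("feature_id")["included"]
        col = {}
        for row_name in _CLASS_ROWS:
            sel = te if row_name == "total" else te[te["te_class"] == row_name]
            ids = [i for i in sel["id"] if i in flags.index]
            if not ids:
                logger.warning("make_table1: no features for class %s (%s)", row_name, label)
                col[row_name] = np.nan
            else:
                col[row_name] = round(100.0 * flags.loc[ids].mean(), 1)
        table[label] = col
    out = pd.DataFrame(table)
    out.index.name = "te_class"
    return out.reset_index()


def make_table2(annotations: dict[str, pd.DataFrame],
                direction_labels: tuple[str, str] = ("parent_up", "hybrid_up")
                ) -> pd.DataFrame:
    """DMR totals and direction percentages per region type per context.

    ``annotations`` maps a comparison label (e.g. 'H_vs_A') to the long
    (region, context, direction, n) table from ``annotate_dmrs``.  Cells
    with zero DMRs report blank percentages.
    """
    rows = []
    for comparison, ann in annotations.items():
        if ann.empty:
            continue
        for region in ("LTR_retrotransposon", "gene", "upstream", "unassigned"):
            for ctx in CONTEXTS:
                sel = ann[(ann["region"] == region) & (ann["context"] == ctx)]
                total = int(sel["n"].sum())
                row = {"comparison": comparison, "region": region,
                       "context": ctx, "total": total}
                for direction in direction_labels:
                    n_dir = int(sel.loc[sel["direction"] == direction, "n"].sum())
                    row[f"pct_{direction}"] = (
                        round(100.0 * n_dir / total, 1) if total else np.nan
                    )
                rows.append(row)
    table = pd.DataFrame(rows)
    return table[table["total"] > 0].reset_index(drop=True) if len(table) else table


# ---------------------------------------------------------------------------
# Pipeline

_COMPARISONS = (("A", "H_vs_A"), ("P", "H_vs_P"))  # (reference/parent, label)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage under ``config.outdir`` and return the manifest."""
    config.validate()
    config.simulation.seed = config.seed
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    manifest_path = outdir / "manifest.json"
    previous = {}
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = {}
    if previous.get("config_digest") != digest:
        previous = {}

    manifest = {"version": __version__, "config_digest": digest,
                "seed": config.seed, "stages": {}}
    state: dict = {}
    for name, fn in (
        ("simulate", _stage_simulate),
        ("methylation", _stage_methylation),
        ("dmr", _stage_dmr),
        ("expression", _stage_expression),
        ("qpcr", _stage_qpcr),
    ):
        t0 = time.perf_counter()
        prev_stage = previous.get("stages", {}).get(name, {})
        try:
            written = fn(config, outdir, state, skip_write=False)
        except (OSError, KeyError, ValueError) as exc:
            if isinstance(exc, (DataError,)):
                raise
            raise DataError(f"stage {name!r} failed: {exc}") from exc
        checksums = {str(p): mio.file_sha256(p) for p in written}
        manifest["stages"][name] = {
            "outputs": checksums,
            "seconds": round(time.perf_counter() - t0, 3),
            # all stages are seeded, so an unchanged config must reproduce
            # the previous run's checksums byte for byte
            "unchanged_from_previous": bool(prev_stage)
            and checksums == prev_stage.get("outputs", {}),
        }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def _headers(config: RunConfig, stage: str) -> list[str]:
    return [f"methylcross {__version__}", f"stage={stage}",
            f"seed={config.seed}", f"config={config.digest()}"]


def _stage_simulate(config: RunConfig, outdir: Path, state: dict,
                    skip_write: bool = False) -> list[Path]:
    sim_dir = outdir / "sim"
    sim_dir.mkdir(exist_ok=True)
    pair = msim.simulate_genome_pair(config.simulation)
    methylomes = msim.simulate_methylomes(pair, config.simulation)
    counts, design, counts_truth = msim.simulate_counts(pair.features, config.simulation)
    state.update(pair=pair, methylomes=methylomes, counts=counts, design=design,
                 counts_truth=counts_truth)

    written = []
    for genotype in ("A", "P"):
        path = sim_dir / f"parent{genotype}.fa"
        mio.write_fasta({c: s for c, s in pair.sequences[genotype].items()
                         if c != msim.CHLOROPLAST}, path)
        written.append(path)
    chl = sim_dir / "chloroplast.fa"
    mio.write_fasta({msim.CHLOROPLAST: pair.sequences["A"][msim.CHLOROPLAST]}, chl)
    written.append(chl)
    gff = sim_dir / "features.gff3"
    mio.write_gff3(pair.features, gff)
    written.append(gff)
    for (genotype, ref), report in methylomes.reports.items():
        path = sim_dir / f"calls_{genotype}_on_{ref}.cov.gz"
        mio.write_cytosine_report(report, path)
        written.append(path)
    mio.write_counts(counts, sim_dir / "counts.tsv")
    mio.write_design(design, sim_dir / "design.tsv")
    written += [sim_dir / "counts.tsv", sim_dir / "design.tsv"]
    truth = {**pair.truth, **methylomes.truth, **counts_truth}
    mio.write_ground_truth(truth, sim_dir / "ground_truth.json")
    written.append(sim_dir / "ground_truth.json")
    return written


def _stage_methylation(config: RunConfig, outdir: Path, state: dict,
                       skip_write: bool = False) -> list[Path]:
    meth_dir = outdir / "methylation"
    meth_dir.mkdir(exist_ok=True)
    pair: msim.GenomePair = state["pair"]
    reports = state["methylomes"].reports
    headers = _headers(config, "methylation")

    written = []
    conv_rows = []
    profiles: dict[str, pd.DataFrame] = {}
    contexts_maps = {ref: mmeth.assign_contexts(pair.sequences[ref]) for ref in ("A", "P")}
    for (genotype, ref), report in reports.items():
        conv = mmeth.estimate_conversion_rate(report)
        conv_rows.append({"genotype": genotype, "reference": ref,
                          "conversion_rate": conv.rate, "n_calls": conv.n_calls})
        filtered = mmeth.filter_positions(report, config.min_position_reads)
        prof = mmeth.feature_methylation(
            filtered, pair.features, contexts_maps[ref], context="all",
            min_coverage_fraction=config.min_coverage_fraction,
        )
        label = genotype if genotype == ref else f"{genotype}_on_{ref}"
        profiles[label] = prof
        path = meth_dir / f"profiles_{label}.tsv"
        mio.write_table(prof, path, headers)
        written.append(path)
    state["profiles"] = profiles

    conv_path = meth_dir / "conversion_rates.tsv"
    mio.write_table(pd.DataFrame(conv_rows), conv_path, headers)
    written.append(conv_path)

    table1 = make_table1(profiles, pair.features)
    t1_path = meth_dir / "table1_inclusion.tsv"
    mio.write_table(table1, t1_path, headers)
    written.append(t1_path)

    for ref, label in _COMPARISONS:
        summary = mmeth.class_summary_table(
            profiles[ref], profiles[f"H_on_{ref}"], pair.features,
            label_a=ref, label_b="H",
        )
        path = meth_dir / f"class_summary_{label}.tsv"
        mio.write_table(summary, path, headers)
        written.append(path)
    return written


def _stage_dmr(config: RunConfig, outdir: Path, state: dict,
               skip_write: bool = False) -> list[Path]:
    dmr_dir = outdir / "dmr"
    dmr_dir.mkdir(exist_ok=True)
    pair: msim.GenomePair = state["pair"]
    reports = state["methylomes"].reports
    headers = _headers(config, "dmr")

    written = []
    annotations = {}
    family_tables = []
    for ref, label in _COMPARISONS:
        parent = mmeth.filter_positions(reports[(ref, ref)], config.min_position_reads)
        hybrid = mmeth.filter_positions(reports[("H", ref)], config.min_position_reads)
        all_dmrs = []
        for ctx in config.contexts:
            dmrs, windows = mdmr.call_dmrs(
                parent, hybrid, ctx, config.dmr,
                direction_labels=("parent_up", "hybrid_up"),
            )
            all_dmrs.append(dmrs)
            bed = dmr_dir / f"dmrs_{label}_{ctx}.bed"
            mio.write_dmr_bed(dmrs, bed)
            wpath = dmr_dir / f"windows_{label}_{ctx}.tsv"
            mio.write_table(windows, wpath, headers)
            written += [bed, wpath]
        non_empty = [d for d in all_dmrs if not d.empty]
        dmrs_all = (pd.concat(non_empty, ignore_index=True) if non_empty
                    else mdmr._empty_dmrs())
        state.setdefault("dmrs", {})[label] = dmrs_all
        annotations[label] = mdmr.annotate_dmrs(dmrs_all, pair.features)
        fam = mdmr.family_dmr_summary(dmrs_all, pair.features)
        fam.insert(0, "comparison", label)
        family_tables.append(fam)

    table2 = make_table2(annotations)
    t2_path = dmr_dir / "table2_dmr_accounting.tsv"
    mio.write_table(table2, t2_path, headers)
    fam_path = dmr_dir / "family_dmr_summary.tsv"
    mio.write_table(pd.concat(family_tables, ignore_index=True), fam_path, headers)
    written += [t2_path, fam_path]
    return written


def _stage_expression(config: RunConfig, outdir: Path, state: dict,
                      skip_write: bool = False) -> list[Path]:
    expr_dir = outdir / "expression"
    expr_dir.mkdir(exist_ok=True)
    counts, design = state["counts"], state["design"]
    headers = _headers(config, "expression")

    written = []
    size_factors, _ = mexpr.normalize_counts(counts)
    sf_path = expr_dir / "size_factors.tsv"
    mio.write_table(size_factors.reset_index().rename(columns={"index": "sample"}),
                    sf_path, headers)
    written.append(sf_path)

    de = mexpr.all_pairwise_tests(counts, design, fdr=config.de_fdr,
                                  lfc_threshold=config.de_lfc)
    for contrast, table in de.items():
        path = expr_dir / f"de_{contrast}.tsv"
        mio.write_table(table.reset_index(), path, headers)
        written.append(path)

    expressed = mexpr.expressed_features(counts, design, config.expression_floor)
    calls = mexpr.classify_patterns(de)
    calls["expressed"] = calls["feature"].map(expressed)
    calls_path = expr_dir / "pattern_calls.tsv"
    mio.write_table(calls, calls_path, headers)
    written.append(calls_path)

    summary = mexpr.summarize_patterns(calls[calls["expressed"]])
    sum_path = expr_dir / "pattern_summary.tsv"
    mio.write_table(summary, sum_path, headers)
    written.append(sum_path)
    state["pattern_calls"] = calls
    return written


def _stage_qpcr(config: RunConfig, outdir: Path, state: dict,
                skip_write: bool = False) -> list[Path]:
    qpcr_dir = outdir / "qpcr"
    qpcr_dir.mkdir(exist_ok=True)
    truth = state["counts_truth"]
    headers = _headers(config, "qpcr")

    # true relative expression of TE-family representatives from the
    # generator's assigned patterns, plus the constant reference genes
    fams = sorted(f for f in truth["true_patterns"] if f.endswith("_rep"))[:9]
    lfc = config.simulation.lfc_effect
    rows = {}
    for fam in fams:
        mult = msim._PATTERN_MULT[truth["true_patterns"][fam]]
        rows[fam] = {g: 100.0 * 2.0 ** (lfc * m)
                     for g, m in zip(("A", "P", "H"), mult)}
    for ref_gene in ("TEF2", "RPII"):
        rows[ref_gene] = {"A": 100.0, "P": 100.0, "H": 100.0}
    true_expr = pd.DataFrame(rows).T[["A", "P", "H"]]

    ct = msim.simulate_qpcr(true_expr, config.simulation)
    ct_path = outdir / "sim" / "ct_table.tsv"
    mio.write_ct_table(ct, ct_path)
    rel = mexpr.ddct_quantify(ct, calibrator="P")
    rel_path = qpcr_dir / "relative_expression.tsv"
    mio.write_table(rel, rel_path, headers)
    return [ct_path, rel_path]
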