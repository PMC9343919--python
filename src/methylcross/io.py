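"""Readers and writers for the file formats the pipeline consumes and emits.

On-disk dialects:

* genomes: FASTA (plain), one record per contig;
* features: GFF3; transposable-element copies are ``transposable_element``
  records carrying ``te_class`` and ``family`` attributes, genes are ``gene``
  records whose span runs from the ATG to the stop codon (introns included);
* methylation calls: Bismark-style cytosine report, tab-separated with
  columns chrom, 1-based position, strand, count methylated, count
  unmethylated, context (CG/CHG/CHH), trinucleotide (plain or gzip);
* counts: TSV matrix (features x samples) with a sidecar design TSV mapping
  sample -> genotype/replicate;
* qPCR: long TSV (sample, genotype, gene, ct);
* DMRs: BED6+ (0-based half-open, name=context:direction,
  score=-10*log10(min_q)).

In-memory containers are pandas DataFrames with the column names given by the
``*_COLUMNS`` constants; coordinates are 1-based inclusive everywhere except
BED output.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import DataError

REPORT_COLUMNS = [
    "chrom", "pos", "strand", "count_meth", "count_unmeth", "context", "trinucleotide",
]
FEATURE_COLUMNS = ["id", "chrom", "start", "end", "strand", "kind", "te_class", "family"]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read FASTA {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# GFF3 features

_KIND_TO_GFF = {"te": "transposable_element", "gene": "gene", "upstream": "upstream_region"}
_GFF_TO_KIND = {v: k for k, v in _KIND_TO_GFF.items()}


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write a FeatureSet DataFrame as GFF3 (1-based inclusive, as native)."""
    lines = ["##gff-version 3"]
    for row in features.itertuples(index=False):
        attrs = [f"ID={row.id}"]
        if isinstance(row.te_class, str) and row.te_class:
            attrs.append(f"te_class={row.te_class}")
        if isinstance(row.family, str) and row.family:
            attrs.append(f"family={row.family}")
        lines.append(
            "\t".join(
                [
                    row.chrom,
                    "methylcross",
                    _KIND_TO_GFF.get(row.kind, row.kind),
                    str(int(row.start)),
                    str(int(row.end)),
                    ".",
                    row.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise DataError(f"cannot read GFF3 {path}: {exc}") from exc
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise DataError(f"malformed GFF3 line in {path}: {line!r}")
        chrom, _, gtype, start, end, _, strand, _, attr_str = parts
        attrs = dict(kv.split("=", 1) for kv in attr_str.split(";") if "=" in kv)
        rows.append(
            {
                "id": attrs.get("ID", f"{gtype}:{chrom}:{start}"),
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "kind": _GFF_TO_KIND.get(gtype, gtype),
                "te_class": attrs.get("te_class", ""),
                "family": attrs.get("family", ""),
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def derive_upstream(features: pd.DataFrame, chrom_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Derive 1000-bp upstream regions for gene features.

    The region is the 1000 bp immediately 5' of the ATG on the gene's strand,
    ending at the base before the start codon, truncated at the contig edge.
    """
    rows = []
    for row in features[features["kind"] == "gene"].itertuples(index=False):
        if row.strand == "-":
            start = row.end + 1
            end = min(row.end + 1000, chrom_lengths[row.chrom])
        else:
            start = max(1, row.start - 1000)
            end = row.start - 1
        if end < start:
            continue
        rows.append(
            {
                "id": f"{row.id}_upstream",
                "chrom": row.chrom,
                "start": start,
                "end": end,
                "strand": row.strand,
                "kind": "upstream",
                "te_class": "",
                "family": "",
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


# ---------------------------------------------------------------------------
# Cytosine reports

def write_cytosine_report(report: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".gz":
        # fixed mtime keeps the compressed bytes reproducible run to run
        with open(path, "wb") as raw, gzip.GzipFile(filename="", fileobj=raw,
                                                    mode="wb", mtime=0) as gz:
            gz.write(report.to_csv(sep="\t", header=False, index=False,
                                   columns=REPORT_COLUMNS).encode())
    else:
        report.to_csv(path, sep="\t", header=False, index=False, columns=REPORT_COLUMNS)


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    try:
        report = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=REPORT_COLUMNS,
            dtype={
                "chrom": str,
                "pos": np.int64,
                "strand": str,
                "count_meth": np.int64,
                "count_unmeth": np.int64,
                "context": str,
                "trinucleotide": str,
            },
        )
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read cytosine report {path}: {exc}") from exc
    if (report[["count_meth", "count_unmeth"]] < 0).any().any():
        raise DataError(f"negative counts in cytosine report {path}")
    return report


# ---------------------------------------------------------------------------
# Count matrices, designs, Ct tables, ortholog pairs

def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature")


def read_counts(path: str | Path) -> pd.DataFrame:
    try:
        counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read count matrix {path}: {exc}") from exc
    if counts.lt(0).any().any():
        raise DataError(f"negative counts in {path}")
    return counts


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    try:
        design = pd.read_csv(path, sep="\t", comment="#")
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read design table {path}: {exc}") from exc
    missing = {"sample", "genotype"} - set(design.columns)
    if missing:
        raise DataError(f"design table {path} lacks columns {sorted(missing)}")
    return design


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    try:
        ct = pd.read_csv(path, sep="\t", comment="#")
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read Ct table {path}: {exc}") from exc
    missing = {"sample", "genotype", "gene", "ct"} - set(ct.columns)
    if missing:
        raise DataError(f"Ct table {path} lacks columns {sorted(missing)}")
    return ct


# ---------------------------------------------------------------------------
# DMR BED export

def write_dmr_bed(dmrs: pd.DataFrame, path: str | Path) -> None:
    """BED6: 0-based half-open, name=context:direction, score=-10*log10(min_q)."""
    lines = []
    for row in dmrs.itertuples(index=False):
        q = max(float(row.min_q), 1e-300)
        score = min(1000, int(round(-10.0 * np.log10(q))))
        lines.append(
            "\t".join(
                [
                    row.chrom,
                    str(int(row.start) - 1),
                    str(int(row.end)),
                    f"{row.context}:{row.direction}",
                    str(score),
                    ".",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Ground truth and provenance

def write_ground_truth(truth: Mapping, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(truth, indent=1, default=_default))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_table(df: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = (),
                index: bool = False) -> None:
    """Write a TSV with ``# key=value`` provenance comment lines on top."""
    buf = _io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=index)
    Path(path).write_text(buf.getvalue())


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
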